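"""Analytics for the validation assays: polysome-trace area ratios,
heavy/light polysome qPCR with spike-in normalization, delta-delta-Ct fold
changes, freezing percentages, and the group-comparison tests used in the
corresponding figures.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datamodel import DataError, PolysomeTrace


# ---------------------------------------------------------------------------
# Polysome traces
# ---------------------------------------------------------------------------


def detect_trace_boundaries(
    trace: PolysomeTrace,
    smooth_window: int = 5,
    manual: tuple | None = None,
) -> tuple[float, float, float]:
    """Locate the monosome/polysome boundary markers (a, b, c).

    Peaks are found on a moving-average smoothed copy; assuming the
    canonical 40S < 60S < 80S < polysome peak order, ``a`` is the valley
    between the 60S and 80S peaks, ``b`` the valley between the 80S and the
    first polysome peak, and ``c`` the end of the trace. A ``manual``
    triple overrides detection and is returned verbatim.
    """
    if manual is not None:
        a, b, c = manual
        if not (a < b < c):
            raise DataError("manual boundaries must satisfy a < b < c")
        return float(a), float(b), float(c)
    y = np.convolve(
        trace.absorbance, np.ones(smooth_window) / smooth_window, mode="same"
    )
    prominence = 0.05 * (y.max() - y.min())
    peaks, _ = find_peaks(y, prominence=prominence)
    if len(peaks) < 4:
        raise DataError(
            f"only {len(peaks)} resolvable peaks; supply manual boundaries (a, b, c)"
        )
    p60s, p80s, poly1 = peaks[1], peaks[2], peaks[3]
    a_idx = p60s + int(np.argmin(y[p60s:p80s]))
    b_idx = p80s + int(np.argmin(y[p80s:poly1]))
    return (
        float(trace.positions[a_idx]),
        float(trace.positions[b_idx]),
        float(trace.positions[-1]),
    )


def _integrate(trace: PolysomeTrace, lo: float, hi: float) -> float:
    """Trapezoidal integral of A254 over [lo, hi] with interpolated endpoints."""
    x, y = trace.positions, trace.absorbance
    inner = (x > lo) & (x < hi)
    xs = np.concatenate(([lo], x[inner], [hi]))
    ys = np.concatenate(([np.interp(lo, x, y)], y[inner], [np.interp(hi, x, y)]))
    return float(np.trapezoid(ys, xs))


def polysome_monosome_ratio(
    trace: PolysomeTrace, a: float, b: float, c: float
) -> float:
    """Area under A254 over the polysome region [b, c] divided by the
    monosome (80S) region [a, b], by trapezoidal integration."""
    if not (a < b < c):
        raise DataError("boundaries must satisfy a < b < c")
    if a < trace.positions[0] or c > trace.positions[-1]:
        raise DataError("boundaries outside the trace position range")
    mono = _integrate(trace, a, b)
    if mono <= 0:
        raise DataError("monosome area is not positive")
    return _integrate(trace, b, c) / mono


# ---------------------------------------------------------------------------
# Heavy/light polysome qPCR
# ---------------------------------------------------------------------------


def heavy_light_ratio(measurements: pd.DataFrame) -> pd.DataFrame:
    """Heavy/light polysome mRNA abundance ratio per gene.

    Expects columns: gene, replicate, fraction ("light"/"heavy"), ct_gene,
    ct_spike (firefly-luciferase spike-in), and optionally
    total_rna_factor (per-fraction total-RNA balance scalar, default 1).
    Per fraction, relative abundance = 2^(ct_spike - ct_gene) x balance
    factor; per-replicate heavy/light ratios are averaged with SEM.
    """
    required = {"gene", "replicate", "fraction", "ct_gene", "ct_spike"}
    missing = required - set(measurements.columns)
    if missing:
        if "ct_spike" in missing:
            raise DataError("spike-in Ct missing: normalization impossible")
        raise DataError(f"missing columns: {sorted(missing)}")
    df = measurements.copy()
    if "total_rna_factor" not in df.columns:
        df["total_rna_factor"] = 1.0
    df["abundance"] = 2.0 ** (df["ct_spike"] - df["ct_gene"]) * df["total_rna_factor"]
    wide = df.pivot_table(
        index=["gene", "replicate"], columns="fraction", values="abundance"
    )
    for frac in ("light", "heavy"):
        if frac not in wide.columns:
            raise DataError(f"no {frac}-fraction measurements")
    ratio = (wide["heavy"] / wide["light"]).rename("ratio").reset_index()
    out = ratio.groupby("gene")["ratio"].agg(
        mean_ratio="mean",
        sem_ratio=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
        n="size",
    )
    return out.reset_index()


# ---------------------------------------------------------------------------
# Delta-delta-Ct
# ---------------------------------------------------------------------------


def ddct_fold_change(
    measurements: pd.DataFrame, baseline_condition: str = "homecage"
) -> pd.DataFrame:
    """Relative expression by the standard delta-delta-Ct method.

    Expects columns gene, condition, ct_gene, ct_loading_control.
    ddCt = (Ct_gene,E - Ct_LC,E) - (Ct_gene,B - Ct_LC,B) against the
    baseline condition; fold change = 2^(-ddCt); log2 fold change also
    reported. Assumes PCR efficiency 2.0 per cycle.
    """
    required = {"gene", "condition", "ct_gene", "ct_loading_control"}
    missing = required - set(measurements.columns)
    if missing:
        if "ct_loading_control" in missing:
            raise DataError("loading-control Ct missing")
        raise DataError(f"missing columns: {sorted(missing)}")
    df = measurements.copy()
    df["dct"] = df["ct_gene"] - df["ct_loading_control"]
    base = df[df["condition"] == baseline_condition].groupby("gene")["dct"].mean()
    rows = []
    for (gene, cond), sub in df.groupby(["gene", "condition"], sort=True):
        if gene not in base.index:
            raise DataError(f"{gene}: no baseline ({baseline_condition}) measurement")
        ddct = sub["dct"].mean() - base[gene]
        rows.append(
            {
                "gene": gene,
                "condition": cond,
                "ddct": ddct,
                "fold_change": 2.0 ** (-ddct),
                "log2_fold_change": -ddct,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Freezing behaviour
# ---------------------------------------------------------------------------


def freezing_percent(scores) -> float:
    """100 x frozen intervals / total intervals for one session."""
    arr = np.asarray(scores)
    if arr.size == 0:
        raise DataError("empty behaviour session")
    if not np.isin(arr, (0, 1)).all():
        raise DataError("freeze scores must be binary")
    return float(100.0 * arr.mean())


def freezing_table(sessions: pd.DataFrame) -> pd.DataFrame:
    """Per-mouse freezing percentage from a wide interval-score table
    (columns mouse_id, group, i000..iNNN)."""
    score_cols = [c for c in sessions.columns if c.startswith("i")]
    if not score_cols:
        raise DataError("no interval-score columns (i###) found")
    out = sessions[["mouse_id", "group"]].copy()
    out["freezing_percent"] = [
        freezing_percent(row) for row in sessions[score_cols].to_numpy()
    ]
    return out


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


def group_compare(
    values,
    groups,
    test: str = "anova",
    posthoc: str = "tukey",
    alpha: float = 0.05,
) -> dict:
    """One-way ANOVA (with Tukey or Bonferroni post-hoc) or two-group t-test.

    Returns F/t, degrees of freedom, p, and the post-hoc table for ANOVA.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(np.unique(groups).tolist())
    samples = {g: values[groups == g] for g in labels}
    if test == "ttest":
        if len(labels) != 2:
            raise DataError("t-test requires exactly two groups")
        x, y = samples[labels[0]], samples[labels[1]]
        t, p = stats.ttest_ind(x, y)
        return {
            "test": "ttest",
            "t": float(t),
            "df": len(x) + len(y) - 2,
            "p": float(p),
            "groups": labels,
        }
    if test != "anova":
        raise DataError(f"unknown test {test!r}")
    for g, v in samples.items():
        if len(v) < 2:
            raise DataError(f"group {g!r} has fewer than 2 values")
    f, p = stats.f_oneway(*[samples[g] for g in labels])
    df_between = len(labels) - 1
    df_within = len(values) - len(labels)
    result = {
        "test": "anova",
        "F": float(f),
        "df": (df_between, df_within),
        "p": float(p),
        "groups": labels,
    }
    if posthoc == "tukey":
        tk = pairwise_tukeyhsd(values, groups, alpha=alpha)
        result["posthoc"] = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
    elif posthoc == "bonferroni":
        n_pairs = len(list(combinations(labels, 2)))
        rows = []
        for g1, g2 in combinations(labels, 2):
            t, praw = stats.ttest_ind(samples[g1], samples[g2])
            rows.append(
                {
                    "group1": g1,
                    "group2": g2,
                    "t": float(t),
                    "p_bonferroni": float(min(1.0, praw * n_pairs)),
                }
            )
        result["posthoc"] = pd.DataFrame(rows)
    elif posthoc is not None:
        raise DataError(f"unknown post-hoc {posthoc!r}")
    return result
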