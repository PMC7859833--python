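"""Fold-change differential calling and contrast set algebra.

Genes are called up/down per stimulated group from the ratio of group-mean
expression (RPKM for transcription-level DEGs, TE for translation-level
DTGs) to the homecage baseline, using strict fold-change cutoffs
(default up > 1.5, down < 0.667). "CFC minus immediate shock" and the
other Venn regions are derived from direction-aware call overlap.

When count matrices are supplied, calling additionally requires the
observed log2 ratio to exceed a multiple (default 3) of its count-based
standard error, so that low-coverage genes whose measurement noise alone
can cross a 1.5-fold cutoff are not called. This pairs the fold-change
cutoff with a reliability test, in the spirit of combining a cutoff with a
significance method for translation changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, DataError
from .quant import ExpressionTable

UP_CUTOFF = 1.5
DOWN_CUTOFF = 1 / 1.5  # 0.667 to the printed precision

CALLS = ("up", "down", "unchanged", "undefined")


@dataclass
class ContrastResult:
    """Per-gene ratios vs homecage and the derived calls and gene sets."""

    level: str  # "transcription" | "translation"
    ratios: pd.DataFrame  # genes x stimulated group
    calls: pd.DataFrame  # genes x stimulated group, values in CALLS
    sets: dict = field(default_factory=dict)  # direction -> region -> sorted list
    cutoffs: tuple = (UP_CUTOFF, DOWN_CUTOFF)


def condition_ratio(
    expr: ExpressionTable,
    group: str,
    baseline: str = "homecage",
    level: str = "transcription",
) -> pd.Series:
    """Per-gene ratio of group-mean expression to the baseline group.

    ``transcription`` uses mean RPKM of total-mRNA libraries; ``translation``
    uses group TE. Genes with an undefined or zero baseline (or undefined
    group value) propagate as NaN and are counted by the caller.
    """
    if level == "transcription":
        means = expr.group_mean_rpkm("total_mrna")
    elif level == "translation":
        if expr.group_te is None:
            raise DataError("translation-level ratios require compute_te output")
        means = expr.group_te
    else:
        raise DataError(f"unknown level {level!r}")
    for g in (group, baseline):
        if g not in means.columns:
            raise DataError(f"group {g!r} absent from expression table")
    num, den = means[group], means[baseline]
    ok = num.notna() & den.notna() & (num > 0) & (den > 0)
    ratio = (num / den).where(ok)
    return ratio.rename(f"{level}:{group}/{baseline}")


def call_changes(
    ratios: pd.Series,
    up_cutoff: float = UP_CUTOFF,
    down_cutoff: float = DOWN_CUTOFF,
    se_log2: pd.Series | None = None,
    min_z: float = 3.0,
) -> pd.Series:
    """up iff ratio > up_cutoff, down iff ratio < down_cutoff (strict:
    boundary values are unchanged); NaN ratios become 'undefined'.

    With ``se_log2`` (per-gene standard error of the log2 ratio), a call
    additionally requires |log2 ratio| > min_z * SE.
    """
    if not (down_cutoff < 1 < up_cutoff):
        raise DataError("cutoffs must satisfy down < 1 < up")
    up = ratios > up_cutoff
    down = ratios < down_cutoff
    if se_log2 is not None:
        log2r = np.log2(ratios.where(ratios > 0))
        reliable = log2r.abs() > min_z * se_log2.reindex(ratios.index)
        up &= reliable.fillna(False)
        down &= reliable.fillna(False)
    calls = pd.Series("unchanged", index=ratios.index, dtype=object)
    calls[up] = "up"
    calls[down] = "down"
    calls[ratios.isna()] = "undefined"
    return calls


def estimate_dispersion(counts: "CountMatrix", min_mean: float = 50.0) -> float:
    """Pooled negative-binomial dispersion alpha (var = mu + alpha mu^2)
    from replicate pairs within each (assay, group).

    Uses size-factor-scaled counts and the moment identity
    E[(c1 - c2)^2] = 2 mu + 2 alpha mu^2 for equal-mean replicates,
    pooled as a ratio of sums over genes with mean above ``min_mean``.
    """
    df = counts.to_frame().astype(float)
    sizes = counts.library_sizes.astype(float)
    df = df / (sizes / sizes.mean())
    num = den = 0.0
    keys = sorted({(l.assay, l.group) for l in counts.libraries})
    for assay, group in keys:
        ids = [
            l.library_id
            for l in sorted(counts.libraries)
            if l.assay == assay and l.group == group
        ]
        for a, b in zip(ids, ids[1:]):
            c1, c2 = df[a].to_numpy(), df[b].to_numpy()
            mu = (c1 + c2) / 2
            ok = mu > min_mean
            num += np.sum((c1[ok] - c2[ok]) ** 2 - (c1[ok] + c2[ok]))
            den += np.sum(2 * mu[ok] ** 2)
    if den == 0:
        return 0.0
    return float(max(num / den, 0.0))


def ratio_standard_error(
    fp_counts: "CountMatrix",
    tot_counts: "CountMatrix",
    level: str,
    group: str,
    baseline: str = "homecage",
    alpha: float | None = None,
) -> pd.Series:
    """Delta-method SE of the per-gene log2 ratio vs baseline.

    Each count contributes variance 1/c + alpha on the log scale
    (negative binomial); a group value averages R replicates
    (variance / R^2 summed over replicates) and the ratio sums the two
    group variances. Translation-level values involve the footprint and
    total count of each replicate pair; transcription-level only the total.
    """
    if alpha is None:
        combined = CountMatrix(
            genes=list(fp_counts.genes),
            libraries=fp_counts.libraries + tot_counts.libraries,
            counts=np.hstack([fp_counts.counts, tot_counts.counts]),
        )
        alpha = estimate_dispersion(combined)
    fdf = fp_counts.to_frame().clip(lower=1).astype(float)
    tdf = tot_counts.to_frame().clip(lower=1).astype(float)
    tot_by_key = {(l.group, l.replicate): l.library_id for l in tot_counts.libraries}

    def group_var(g: str) -> pd.Series:
        v = 0.0
        reps = [l for l in fp_counts.libraries if l.group == g]
        for l in reps:
            ct = tdf[tot_by_key[(g, l.replicate)]]
            if level == "translation":
                v = v + 1 / fdf[l.library_id] + 1 / ct + 2 * alpha
            else:
                v = v + 1 / ct + alpha
        return v / len(reps) ** 2

    var_log = group_var(group) + group_var(baseline)
    return np.sqrt(var_log) / np.log(2)


def compute_contrasts(
    expr: ExpressionTable,
    level: str,
    stim_groups: tuple = ("immediate_shock", "cfc"),
    baseline: str = "homecage",
    up_cutoff: float = UP_CUTOFF,
    down_cutoff: float = DOWN_CUTOFF,
    fp_counts: CountMatrix | None = None,
    tot_counts: CountMatrix | None = None,
    min_z: float = 3.0,
) -> ContrastResult:
    """Ratios, calls and Venn sets for both stimulated groups vs baseline.

    With count matrices supplied, calls carry the min_z x SE reliability
    guard on top of the fold-change cutoff.
    """
    ratios = pd.DataFrame(
        {g: condition_ratio(expr, g, baseline, level) for g in stim_groups}
    )
    alpha = None
    ses: dict[str, pd.Series | None] = {g: None for g in stim_groups}
    if fp_counts is not None and tot_counts is not None:
        combined = CountMatrix(
            genes=list(fp_counts.genes),
            libraries=fp_counts.libraries + tot_counts.libraries,
            counts=np.hstack([fp_counts.counts, tot_counts.counts]),
        )
        alpha = estimate_dispersion(combined)
        ses = {
            g: ratio_standard_error(fp_counts, tot_counts, level, g, baseline, alpha)
            for g in stim_groups
        }
    calls = pd.DataFrame(
        {
            g: call_changes(ratios[g], up_cutoff, down_cutoff, ses[g], min_z)
            for g in stim_groups
        }
    )
    result = ContrastResult(
        level=level, ratios=ratios, calls=calls, cutoffs=(up_cutoff, down_cutoff)
    )
    if set(stim_groups) == {"immediate_shock", "cfc"}:
        result.sets = contrast_sets(calls["cfc"], calls["immediate_shock"])
    return result


def contrast_sets(calls_cfc: pd.Series, calls_shock: pd.Series) -> dict:
    """Direction-aware Venn regions between the two stimulated groups.

    ``shared`` requires the same-direction call in both groups; ``cfc_only``
    is the "CFC minus immediate shock" list (called in CFC, not called in
    that direction in shock), and symmetrically for ``shock_only``.
    Gene lists are sorted for determinism.
    """
    if not calls_cfc.index.equals(calls_shock.index):
        raise DataError("call series cover different gene universes")
    out = {}
    for direction in ("up", "down"):
        cfc = set(calls_cfc.index[calls_cfc == direction])
        shock = set(calls_shock.index[calls_shock == direction])
        out[direction] = {
            "cfc_only": sorted(cfc - shock),
            "shock_only": sorted(shock - cfc),
            "shared": sorted(cfc & shock),
        }
    out["counts"] = {
        d: {k: len(v) for k, v in out[d].items()} for d in ("up", "down")
    }
    return out


def cross_condition_correlation(
    ratios_cfc: pd.Series, ratios_shock: pd.Series
) -> tuple[float, pd.DataFrame]:
    """Squared Pearson correlation of log2 ratios over jointly defined genes,
    plus the scatter table used for plotting."""
    ok = ratios_cfc.notna() & ratios_shock.notna() & (ratios_cfc > 0) & (ratios_shock > 0)
    if ok.sum() < 3:
        raise DataError("need >= 3 genes with both ratios defined")
    x = np.log2(ratios_cfc[ok])
    y = np.log2(ratios_shock[ok])
    table = pd.DataFrame(
        {"gene_id": x.index, "log2_ratio_cfc": x.to_numpy(), "log2_ratio_shock": y.to_numpy()}
    )
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance in log2 ratios: R^2 undefined", stacklevel=2)
        return float("nan"), table
    r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return r2, table


def recovery_statistics(
    result: ContrastResult, truth: pd.DataFrame
) -> pd.DataFrame:
    """Sensitivity/precision of calling against the planted truth, per class.

    A planted gene is a true positive when called in the planted direction
    in the group(s) carrying its effect; precision is measured over all
    calls in that group/direction against genes planted accordingly.
    """
    level_cols = {
        "transcription": ("mrna_lfc_immediate_shock", "mrna_lfc_cfc"),
        "translation": ("te_lfc_immediate_shock", "te_lfc_cfc"),
    }[result.level]
    truth = truth.loc[result.calls.index]
    rows = []
    for group, col in zip(("immediate_shock", "cfc"), level_cols):
        lfc = truth[col]
        calls = result.calls[group]
        for direction, sign in (("up", 1), ("down", -1)):
            planted = set(truth.index[np.sign(lfc) == sign])
            called = set(calls.index[calls == direction])
            tp = len(planted & called)
            rows.append(
                {
                    "group": group,
                    "direction": direction,
                    "n_planted": len(planted),
                    "n_called": len(called),
                    "sensitivity": tp / len(planted) if planted else np.nan,
                    "precision": tp / len(called) if called else np.nan,
                }
            )
    return pd.DataFrame(rows)
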