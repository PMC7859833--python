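"""5'/3' UTR characterization: basic statistics, secondary-structure minimum
free energy, and motif scanning (uORF, TOP, and a configurable pattern
registry), plus the group-comparison statistics used on DTG lists.

The folding energy is a deliberately simple base-pair model (Nussinov-style
dynamic programming over nested structures with per-pair energies and a
minimum hairpin loop), not a full nearest-neighbour thermodynamic model:
the pipeline compares groups of UTRs against each other, for which a
monotone structure-propensity score suffices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .datamodel import DataError, GeneModel, RNA_ALPHABET, STOP_CODONS

# pair energies, kcal/mol
PAIR_ENERGY = {("G", "C"): -3.0, ("A", "U"): -2.0, ("G", "U"): -1.0}
MIN_HAIRPIN_LOOP = 3  # unpaired nt enclosed by a pair
FOLD_LENGTH_CAP = 4000

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
# energy matrix indexed by base codes (symmetric)
_EMAT = np.zeros((4, 4))
for (b1, b2), e in PAIR_ENERGY.items():
    _EMAT[_BASE_CODE[b1], _BASE_CODE[b2]] = e
    _EMAT[_BASE_CODE[b2], _BASE_CODE[b1]] = e


@njit(cache=True)
def _nussinov_min_energy(codes, emat, min_loop):  # pragma: no cover - numba
    n = len(codes)
    W = np.zeros((n, n))
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            best = W[i + 1, j]
            if W[i, j - 1] < best:
                best = W[i, j - 1]
            if j - i - 1 >= min_loop:
                e = emat[codes[i], codes[j]]
                if e < 0.0:
                    v = e + (W[i + 1, j - 1] if j - i >= 2 else 0.0)
                    if v < best:
                        best = v
            for k in range(i, j):
                v = W[i, k] + W[k + 1, j]
                if v < best:
                    best = v
            W[i, j] = best
    return W[0, n - 1]


def fold_min_energy(sequence: str) -> float:
    """Minimum free energy (kcal/mol, <= 0) over nested secondary structures.

    Pair energies G-C = -3, A-U = -2, G-U = -1 kcal/mol; hairpin loops must
    enclose at least 3 unpaired nucleotides. Deterministic O(n^3) dynamic
    program.
    """
    if len(sequence) == 0:
        raise DataError("cannot fold an empty sequence")
    bad = set(sequence) - RNA_ALPHABET
    if bad:
        raise DataError(f"non-RNA characters in sequence: {sorted(bad)}")
    if len(sequence) > FOLD_LENGTH_CAP:
        import warnings

        warnings.warn(
            f"sequence length {len(sequence)} exceeds fold cap {FOLD_LENGTH_CAP}; "
            "folding full length",
            stacklevel=2,
        )
    if len(sequence) == 1:
        return 0.0
    codes = np.array([_BASE_CODE[b] for b in sequence], dtype=np.int8)
    return float(_nussinov_min_energy(codes, _EMAT, MIN_HAIRPIN_LOOP))


# ---------------------------------------------------------------------------
# Basic statistics
# ---------------------------------------------------------------------------


def utr_basic_stats(gene: GeneModel) -> dict:
    """Length and GC% per UTR region; empty regions get GC = None."""
    out = {}
    for region in ("utr5", "utr3"):
        seq = getattr(gene, region)
        gc = (
            100.0 * (seq.count("G") + seq.count("C")) / len(seq) if seq else None
        )
        out[region] = {"length": len(seq), "gc_percent": gc}
    return out


# ---------------------------------------------------------------------------
# uORF and TOP scanners
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Uorf:
    start: int  # 0-based offset of the AUG within the 5'UTR
    end: int  # 0-based half-open end (last nt of the stop codon + 1)

    @property
    def n_codons(self) -> int:
        return (self.end - self.start) // 3


def detect_uorfs(utr5: str, min_codons: int = 2) -> list[Uorf]:
    """All upstream ORFs entirely inside the 5'UTR.

    A uORF is an AUG followed by an in-frame stop codon whose last
    nucleotide lies within the UTR; minimum length ``min_codons`` including
    the stop (default 2 codons = 6 nt). Each AUG yields at most one uORF
    (its first in-frame stop); overlapping and nested uORFs from distinct
    AUGs are all reported.
    """
    hits = []
    for m in re.finditer("AUG", utr5):
        s = m.start()
        for p in range(s + 3, len(utr5) - 2, 3):
            if utr5[p : p + 3] in STOP_CODONS:
                if (p + 3 - s) // 3 >= min_codons:
                    hits.append(Uorf(s, p + 3))
                break
    return hits


def detect_top(leader: str, min_tract: int = 4) -> tuple[bool, int]:
    """TOP (terminal oligopyrimidine) test on a transcript 5' end.

    Positive iff the first nucleotide is C and it is followed by an
    uninterrupted pyrimidine (C/U) run of length >= ``min_tract``. Returns
    (is_top, tract_length) where tract length counts the leading C plus the
    run (0 if the first base is not C).
    """
    if not leader or leader[0] != "C":
        return False, 0
    run = 0
    for b in leader[1:]:
        if b in "CU":
            run += 1
        else:
            break
    return run >= min_tract, 1 + run


# ---------------------------------------------------------------------------
# Motif registry
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "[AG]", "Y": "[CU]", "S": "[CG]", "W": "[AU]",
    "K": "[GU]", "M": "[AC]", "B": "[CGU]", "D": "[AGU]",
    "H": "[ACU]", "V": "[ACG]", "N": "[ACGU]",
}


def iupac_to_regex(pattern: str) -> str:
    out = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch in _IUPAC:
            out.append(_IUPAC[ch])
            i += 1
        elif ch in "{}0123456789,|()":
            out.append(ch)
            i += 1
        else:
            raise DataError(f"unsupported IUPAC/pattern character {ch!r}")
    return "".join(out)


@dataclass(frozen=True)
class MotifDefinition:
    """A named UTR motif: either a sequence pattern (IUPAC, with {m,n}
    repetition and alternation allowed) or a named algorithmic rule."""

    name: str
    region: str  # "utr5" or "utr3"
    pattern: str | None = None  # IUPAC-style pattern
    rule: str | None = None  # "uorf" | "top"
    min_copies: int = 1

    def __post_init__(self):
        if (self.pattern is None) == (self.rule is None):
            raise DataError(f"motif {self.name}: exactly one of pattern/rule required")
        if self.region not in ("utr5", "utr3"):
            raise DataError(f"motif {self.name}: region must be utr5 or utr3")


#: default 5'UTR registry: 4 motif types
DEFAULT_UTR5_REGISTRY = (
    MotifDefinition("uORF", "utr5", rule="uorf"),
    MotifDefinition("TOP", "utr5", rule="top"),
    MotifDefinition("PAS-like", "utr5", pattern="AAUAAA"),
    MotifDefinition("pyrimidine-rich", "utr5", pattern="Y{8,}"),
)

#: default 3'UTR registry: 9 motif types
DEFAULT_UTR3_REGISTRY = (
    MotifDefinition("PAS", "utr3", pattern="AAUAAA|AUUAAA"),
    MotifDefinition("ARE", "utr3", pattern="AUUUA", min_copies=2),
    MotifDefinition("CPE", "utr3", pattern="UUUUUAU"),
    MotifDefinition("Musashi", "utr3", pattern="AUAGU"),
    MotifDefinition("Brd-box", "utr3", pattern="AGCUUUA"),
    MotifDefinition("K-box", "utr3", pattern="UGUGAU"),
    MotifDefinition("GY-box", "utr3", pattern="GUCUUCC"),
    MotifDefinition("15-LOX-DICE", "utr3", pattern="CCCCRCCCUCUUCCCCAAG"),
    MotifDefinition("UA-rich", "utr3", pattern="W{6,}"),
)

DEFAULT_REGISTRY = DEFAULT_UTR5_REGISTRY + DEFAULT_UTR3_REGISTRY


def scan_motifs(
    gene: GeneModel, registry=DEFAULT_REGISTRY
) -> list[dict]:
    """Scan one gene's UTRs against a motif registry.

    Returns one record per hit: motif name, region, 0-based half-open
    coordinates within the region, and a detail string. Presence is
    governed by ``min_copies`` (e.g. AU-rich elements require >= 2 copies).
    """
    names = [m.name for m in registry]
    if len(set(names)) != len(names):
        raise DataError("motif registry names must be unique")
    hits = []
    for motif in registry:
        seq = getattr(gene, motif.region)
        if motif.rule == "uorf":
            if motif.region != "utr5":
                raise DataError("uORF rule applies to utr5 only")
            for u in detect_uorfs(seq):
                hits.append(
                    {
                        "gene_id": gene.gene_id,
                        "motif": motif.name,
                        "region": motif.region,
                        "start": u.start,
                        "end": u.end,
                        "detail": f"{u.n_codons} codons",
                    }
                )
        elif motif.rule == "top":
            if motif.region != "utr5":
                raise DataError("TOP rule applies to utr5 only")
            is_top, tract = detect_top(seq)
            if is_top:
                hits.append(
                    {
                        "gene_id": gene.gene_id,
                        "motif": motif.name,
                        "region": motif.region,
                        "start": 0,
                        "end": tract,
                        "detail": f"tract {tract} nt",
                    }
                )
        else:
            regex = iupac_to_regex(motif.pattern)
            matches = list(re.finditer(regex, seq))
            if len(matches) >= motif.min_copies:
                for m in matches:
                    hits.append(
                        {
                            "gene_id": gene.gene_id,
                            "motif": motif.name,
                            "region": motif.region,
                            "start": m.start(),
                            "end": m.end(),
                            "detail": m.group(0),
                        }
                    )
    return hits


def utr_feature_table(
    genes: list[GeneModel],
    registry=DEFAULT_REGISTRY,
    with_mfe: bool = True,
) -> pd.DataFrame:
    """Per-gene, per-region feature table: length, GC%, MFE, motif presence."""
    motif_names = {(m.region, m.name) for m in registry}
    rows = []
    for g in genes:
        basics = utr_basic_stats(g)
        hits = scan_motifs(g, registry)
        present = {(h["region"], h["motif"]) for h in hits}
        for region in ("utr5", "utr3"):
            seq = getattr(g, region)
            row = {
                "gene_id": g.gene_id,
                "region": region,
                "length": basics[region]["length"],
                "gc_percent": basics[region]["gc_percent"],
                "mfe": fold_min_energy(seq) if (with_mfe and seq) else (0.0 if not with_mfe else None),
            }
            for reg, name in sorted(motif_names):
                if reg == region:
                    row[f"has_{name}"] = (reg, name) in present
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------


def twoway_anova_noreplication(table: pd.DataFrame) -> dict:
    """Two-way ANOVA without replication on a motif x group table of
    percentages (one observation per cell).

    Rows are motif types, columns are experimental groups. Returns F and
    degrees of freedom for both factors against the residual mean square.
    """
    x = table.to_numpy(dtype=float)
    r, c = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_row = c * np.sum((row_means - grand) ** 2)
    ss_col = r * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_res = ss_tot - ss_row - ss_col
    df_row, df_col = r - 1, c - 1
    df_res = df_row * df_col
    ms_res = ss_res / df_res if df_res > 0 else np.nan

    def _f(ss: float, df: int) -> float:
        if ms_res > 0:
            return (ss / df) / ms_res
        # degenerate perfect-additive fit: a factor with no sum of squares
        # explains nothing (F = 0); one with positive SS dominates (F = inf)
        return 0.0 if np.isclose(ss, 0.0) else np.inf

    f_row = _f(ss_row, df_row)
    f_col = _f(ss_col, df_col)
    return {
        "row_factor": {
            "F": f_row,
            "df": (df_row, df_res),
            "p": float(stats.f.sf(f_row, df_row, df_res)),
        },
        "col_factor": {
            "F": f_col,
            "df": (df_col, df_res),
            "p": float(stats.f.sf(f_col, df_col, df_res)),
        },
        "ms_residual": ms_res,
    }


def compare_utr_features(
    features: pd.DataFrame,
    group_assignments: dict[str, str],
    registry=DEFAULT_REGISTRY,
) -> dict:
    """Between-group statistics on UTR features of called gene lists.

    ``group_assignments`` maps gene_id -> group label (e.g. cfc_up,
    cfc_down, shock_up, shock_down). Per region and per scalar feature
    (length, GC%, MFE), two-sided Student's t-tests between all group
    pairs; per region, a two-way ANOVA (motif type x experimental group)
    on motif-presence percentages with Bonferroni-adjusted post-hoc
    contrasts between groups.
    """
    feats = features[features["gene_id"].isin(group_assignments)].copy()
    feats["group"] = feats["gene_id"].map(group_assignments)
    groups = sorted(feats["group"].unique())
    report: dict = {"t_tests": [], "anova": {}, "skipped": []}

    for region in ("utr5", "utr3"):
        sub = feats[feats["region"] == region]
        for feature in ("length", "gc_percent", "mfe"):
            for g1, g2 in combinations(groups, 2):
                x = sub.loc[sub["group"] == g1, feature].dropna().to_numpy(float)
                y = sub.loc[sub["group"] == g2, feature].dropna().to_numpy(float)
                if len(x) < 2 or len(y) < 2:
                    report["skipped"].append((region, feature, g1, g2))
                    continue
                t, p = stats.ttest_ind(x, y)
                report["t_tests"].append(
                    {
                        "region": region,
                        "feature": feature,
                        "group1": g1,
                        "group2": g2,
                        "t": float(t),
                        "p": float(p),
                        "df": len(x) + len(y) - 2,
                    }
                )

        motif_cols = sorted(
            c for c in sub.columns if c.startswith("has_") and sub[c].notna().any()
        )
        if not motif_cols or len(groups) < 2:
            continue
        pct = pd.DataFrame(
            {
                g: [
                    100.0 * sub.loc[sub["group"] == g, c].mean()
                    for c in motif_cols
                ]
                for g in groups
            },
            index=[c[4:] for c in motif_cols],
        )
        anova = twoway_anova_noreplication(pct)
        n_pairs = len(list(combinations(groups, 2)))
        posthoc = []
        for g1, g2 in combinations(groups, 2):
            # group-mean contrast using the residual MS, Bonferroni-adjusted
            diff = pct[g1].mean() - pct[g2].mean()
            se = np.sqrt(2 * anova["ms_residual"] / len(pct))
            df_res = anova["col_factor"]["df"][1]
            t = diff / se if se > 0 else np.inf
            p = min(1.0, 2 * stats.t.sf(abs(t), df_res) * n_pairs)
            posthoc.append(
                {"group1": g1, "group2": g2, "diff_percent": diff, "t": t, "p_bonferroni": p}
            )
        report["anova"][region] = {
            "motif_type": anova["row_factor"],
            "experimental_group": anova["col_factor"],
            "percent_table": pct,
            "posthoc": posthoc,
        }
    return report
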