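"""RPKM / translational-efficiency quantification and library QC.

Covers: RPKM from counts, cross-library normalization (quantile or
median-ratio), per-replicate TE = footprint RPKM / total RPKM, footprint
length and reading-frame diagnostics, P-site offset estimation, metagene
periodicity, replicate correlation, PCA + complete-linkage clustering, and
TE comparisons between gene classes (with length matching against
ribosomal-protein transcripts).

Undefined values (RPKM 0 or TE with a zero in the pair) are carried as an
explicit defined-mask; such genes are excluded from every log2-based
analysis downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .datamodel import CountMatrix, DataError, GeneModel, LibraryDesign, ReadSet

PSITE_SEARCH_RANGE = (10, 15)
PSITE_DEFAULT = 12
PSITE_MIN_READS = 100


@dataclass
class ExpressionTable:
    """Per-library RPKM values with design metadata and defined-value masks.

    ``te`` (per replicate pair) and ``group_te`` are populated by
    :func:`compute_te`; TE is undefined wherever either RPKM of the pair
    is zero.
    """

    rpkm: pd.DataFrame  # genes x library_id
    design: list[LibraryDesign]
    defined: pd.DataFrame  # boolean, same shape as rpkm
    lengths: pd.Series  # transcript length per gene (nt)
    te: pd.DataFrame | None = None  # genes x "group/rep"
    te_defined: pd.DataFrame | None = None
    group_te: pd.DataFrame | None = None  # genes x group
    meta: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.rpkm.index)

    def libraries(self, assay: str | None = None) -> list[LibraryDesign]:
        return [l for l in self.design if assay is None or l.assay == assay]

    def group_mean_rpkm(self, assay: str) -> pd.DataFrame:
        """Mean RPKM per group for one assay (NaN where any replicate is
        undefined is NOT applied here; zeros simply average in)."""
        groups = sorted({l.group for l in self.design})
        out = {}
        for g in groups:
            cols = [l.library_id for l in self.design if l.assay == assay and l.group == g]
            out[g] = self.rpkm[cols].mean(axis=1)
        return pd.DataFrame(out)


def compute_rpkm(counts: CountMatrix, genes: list[GeneModel]) -> ExpressionTable:
    """RPKM(g, lib) = count * 1e9 / (length_nt * library_size)."""
    lengths = pd.Series(
        {g.gene_id: g.length for g in genes}, name="length"
    ).loc[counts.genes]
    sizes = counts.library_sizes
    if np.any(sizes <= 0):
        bad = [counts.libraries[j].library_id for j in np.where(sizes <= 0)[0]]
        raise DataError(f"zero library size for {bad}")
    rpkm = counts.counts * 1e9 / (lengths.to_numpy()[:, None] * sizes[None, :])
    df = pd.DataFrame(rpkm, index=counts.genes, columns=counts.library_ids)
    return ExpressionTable(
        rpkm=df,
        design=list(counts.libraries),
        defined=df > 0,
        lengths=lengths,
    )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def _quantile_normalize(mat: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization: each column's sorted values replaced
    by the mean sorted vector (ties get the mean of their rank values)."""
    ranks = mat.rank(method="average")
    mean_sorted = np.sort(mat.to_numpy(), axis=0).mean(axis=1)
    # interpolate mean_sorted at fractional (tied) ranks
    grid = np.arange(1, len(mat) + 1, dtype=float)
    out = mat.copy()
    for col in mat.columns:
        out[col] = np.interp(ranks[col].to_numpy(), grid, mean_sorted)
    return out


def normalize_libraries(expr: ExpressionTable, method: str = "quantile") -> ExpressionTable:
    """Cross-library normalization of RPKM, applied within each assay.

    ``quantile``: quantile normalization on the log2 scale (zeros kept at
    zero and excluded from the reference distribution's support by working
    on log2(RPKM) of expressed entries only is not attempted; the standard
    all-rows transform is used, which maps zeros to the pooled minimum).
    ``median-ratio``: per-library scale factor = median of ratios to the
    per-gene geometric mean across libraries, computed over genes expressed
    everywhere. Both are rank-preserving within a library.
    """
    if method not in ("quantile", "median-ratio"):
        raise DataError(f"unknown normalization method {method!r}")
    assays = sorted({l.assay for l in expr.design})
    rpkm = expr.rpkm.copy()
    for assay in assays:
        cols = [l.library_id for l in expr.design if l.assay == assay]
        if len(cols) < 2:
            warnings.warn(
                f"single {assay} library: normalization is the identity", stacklevel=2
            )
            continue
        block = rpkm[cols]
        if method == "quantile":
            log2 = np.log2(block.where(block > 0))
            filled = log2.fillna(log2.min().min() - 1.0)
            normed = _quantile_normalize(filled)
            normed = normed.where(block > 0, 0.0)
            rpkm[cols] = np.where(block > 0, 2.0 ** normed, 0.0)
        else:
            expressed = (block > 0).all(axis=1)
            geo = np.exp(np.log(block[expressed]).mean(axis=1))
            factors = block[expressed].div(geo, axis=0).median(axis=0)
            rpkm[cols] = block.div(factors, axis=1)
    return ExpressionTable(
        rpkm=rpkm,
        design=list(expr.design),
        defined=rpkm > 0,
        lengths=expr.lengths,
        meta={**expr.meta, "normalization": method},
    )


# ---------------------------------------------------------------------------
# Translational efficiency
# ---------------------------------------------------------------------------


def compute_te(expr: ExpressionTable, log_scale_mean: bool = False) -> ExpressionTable:
    """Per-replicate TE = footprint RPKM / total RPKM, then group means.

    TE is undefined (masked) for a (gene, group, replicate) where either
    RPKM is zero; the group TE is the mean over replicates with defined
    values on the natural scale (geometric mean if ``log_scale_mean``).
    Genes with no defined replicate in a group stay undefined there.
    """
    fp = {(l.group, l.replicate): l.library_id for l in expr.design if l.assay == "footprint"}
    tot = {(l.group, l.replicate): l.library_id for l in expr.design if l.assay == "total_mrna"}
    orphans = set(fp).symmetric_difference(tot)
    if orphans:
        raise DataError(f"unpaired footprint/total libraries: {sorted(orphans)}")

    te_cols, te_def = {}, {}
    for key in sorted(fp):
        f = expr.rpkm[fp[key]]
        t = expr.rpkm[tot[key]]
        ok = (f > 0) & (t > 0)
        col = f"{key[0]}/r{key[1]}"
        te_cols[col] = (f / t).where(ok)
        te_def[col] = ok
    te = pd.DataFrame(te_cols)
    te_defined = pd.DataFrame(te_def)

    groups = sorted({g for g, _ in fp})
    group_te = {}
    for g in groups:
        cols = [c for c in te.columns if c.startswith(f"{g}/")]
        vals = te[cols]
        group_te[g] = (
            np.exp(np.log(vals).mean(axis=1)) if log_scale_mean else vals.mean(axis=1)
        )
    return ExpressionTable(
        rpkm=expr.rpkm,
        design=list(expr.design),
        defined=expr.defined,
        lengths=expr.lengths,
        te=te,
        te_defined=te_defined,
        group_te=pd.DataFrame(group_te),
        meta=dict(expr.meta),
    )


# ---------------------------------------------------------------------------
# Footprint QC
# ---------------------------------------------------------------------------


def footprint_length_distribution(reads: ReadSet) -> tuple[pd.Series, float]:
    """Integer length histogram plus the fraction of reads in [28, 32] nt."""
    if len(reads) == 0:
        raise DataError("empty read set")
    lengths, counts = np.unique(reads.length, return_counts=True)
    hist = pd.Series(counts, index=lengths).sort_index()
    frac = float(((reads.length >= 28) & (reads.length <= 32)).mean())
    return hist, frac


def _gene_arrays(genes: list[GeneModel], reads: ReadSet):
    lookup = {g.gene_id: g for g in genes}
    cds_start = np.array([lookup[g].cds_start for g in reads.genes])
    cds_end = np.array([lookup[g].cds_end for g in reads.genes])
    return cds_start[reads.gene_idx], cds_end[reads.gene_idx]


def estimate_psite_offsets(
    reads: ReadSet,
    genes: list[GeneModel],
    search_range: tuple = PSITE_SEARCH_RANGE,
    default: int = PSITE_DEFAULT,
) -> dict[int, int]:
    """Per-read-length P-site offset from metagene codon-start coverage.

    For each length, the offset in ``search_range`` maximizing the number
    of reads whose 5' end + offset lands on the first nucleotide of a CDS
    codon (codon-start meta-coverage, anchored at the start codon and
    every in-frame codon after it — the start-codon column alone carries
    too few reads per length to be a consistent estimator when footprints
    are spread along the CDS). Ties, including the inherent period-3 tie
    (e.g. 12 vs 15), go to the candidate closest to ``default``. Lengths
    with fewer than 100 reads fall back to the default with a warning.
    """
    cds_start, cds_end = _gene_arrays(genes, reads)
    candidates = list(range(search_range[0], search_range[1] + 1))
    offsets = {}
    for L in sorted(np.unique(reads.length)):
        mask = reads.length == L
        if mask.sum() < PSITE_MIN_READS:
            warnings.warn(
                f"length {L}: only {int(mask.sum())} reads; default offset {default}",
                stacklevel=2,
            )
            offsets[int(L)] = default
            continue
        start = reads.start[mask]
        cs, ce = cds_start[mask], cds_end[mask]
        scores = []
        for off in candidates:
            psite = start + off
            in_cds = (psite >= cs) & (psite < ce)
            scores.append(int(np.sum(in_cds & ((psite - cs) % 3 == 0))))
        best = max(scores)
        winners = [c for c, s in zip(candidates, scores) if s == best]
        offsets[int(L)] = min(winners, key=lambda c: (abs(c - default), c))
    return offsets


def _psites(reads: ReadSet, offsets: dict[int, int]) -> np.ndarray:
    off = np.array([offsets.get(int(l), PSITE_DEFAULT) for l in reads.length])
    return reads.start + off


def frame_distribution(
    reads: ReadSet, genes: list[GeneModel], offsets: dict[int, int]
) -> tuple[float, float, float]:
    """Fractions of P-sites in CDS frames 0/1/2 (P-sites outside the CDS are
    excluded from the denominator)."""
    cds_start, cds_end = _gene_arrays(genes, reads)
    psite = _psites(reads, offsets)
    in_cds = (psite >= cds_start) & (psite < cds_end)
    if not in_cds.any():
        raise DataError("no P-sites inside any CDS")
    frame = (psite[in_cds] - cds_start[in_cds]) % 3
    f = np.bincount(frame, minlength=3) / in_cds.sum()
    return float(f[0]), float(f[1]), float(f[2])


def metagene_periodicity(
    reads: ReadSet,
    genes: list[GeneModel],
    offsets: dict[int, int],
    window: tuple = (-20, 60),
) -> tuple[pd.Series, float]:
    """Metagene P-site coverage around CDS starts plus a periodicity score.

    The score is the spectral power at period 3 divided by the summed power
    at periods 2..6, computed on the mean-removed CDS-side profile
    (positions >= 0); it lies in [0, 1], with 1/5 the flat-spectrum
    expectation and values near 1 for strongly 3-periodic coverage.
    """
    lo, hi = window
    if hi <= lo:
        raise DataError("empty metagene window")
    cds_start, _ = _gene_arrays(genes, reads)
    rel = _psites(reads, offsets) - cds_start
    mask = (rel >= lo) & (rel < hi)
    if not mask.any():
        raise DataError("no P-sites fall inside the metagene window")
    profile = np.bincount(rel[mask] - lo, minlength=hi - lo).astype(float)
    series = pd.Series(profile, index=np.arange(lo, hi))
    score = periodicity_score(series[series.index >= 0].to_numpy())
    return series, score


def periodicity_score(profile: np.ndarray, periods=(2, 3, 4, 5, 6)) -> float:
    """Power at period 3 over total power at the candidate periods.

    Power at period p is |sum_n x_n exp(-2 pi i n / p)|^2 of the
    mean-removed profile.
    """
    x = np.asarray(profile, dtype=float)
    if len(x) == 0 or np.all(x == 0):
        raise DataError("cannot score an all-zero profile")
    x = x - x.mean()
    n = np.arange(len(x))
    powers = {
        p: np.abs(np.sum(x * np.exp(-2j * np.pi * n / p))) ** 2 for p in periods
    }
    total = sum(powers.values())
    if total <= 0:
        warnings.warn("flat profile: periodicity score undefined", stacklevel=2)
        return float("nan")
    return float(powers[3] / total)


# ---------------------------------------------------------------------------
# Replicate correlation, PCA, clustering
# ---------------------------------------------------------------------------


def replicate_correlation(expr: ExpressionTable) -> pd.DataFrame:
    """Pairwise R^2 (squared Pearson, log2 RPKM) between replicate libraries
    of the same assay and group; genes undefined in either member of a pair
    are excluded pairwise."""
    rows = []
    keys = sorted({(l.assay, l.group) for l in expr.design})
    for assay, group in keys:
        libs = sorted(
            [l for l in expr.design if l.assay == assay and l.group == group],
            key=lambda l: l.replicate,
        )
        for i in range(len(libs)):
            for j in range(i + 1, len(libs)):
                a, b = libs[i].library_id, libs[j].library_id
                ok = expr.defined[a] & expr.defined[b]
                if ok.sum() < 3:
                    warnings.warn(
                        f"<3 shared defined genes for {a} vs {b}", stacklevel=2
                    )
                    r2 = np.nan
                else:
                    x = np.log2(expr.rpkm.loc[ok, a])
                    y = np.log2(expr.rpkm.loc[ok, b])
                    if x.std() == 0 or y.std() == 0:
                        warnings.warn(
                            f"zero variance in {a} or {b}: R^2 undefined", stacklevel=2
                        )
                        r2 = np.nan
                    else:
                        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
                rows.append(
                    {"assay": assay, "group": group, "library1": a, "library2": b, "r2": r2}
                )
    return pd.DataFrame(rows)


def pca_cluster(values: pd.DataFrame, defined: pd.DataFrame | None = None) -> dict:
    """Sample PCA + complete-linkage clustering on per-gene standardized
    log2 values.

    ``values`` is genes x samples on the linear scale; genes undefined
    (zero) in any sample are excluded, remaining log2 values standardized
    per gene to mean 0 / SD 1, samples embedded by PCA and clustered by
    complete linkage on their Euclidean distance matrix.
    """
    if values.shape[1] < 3:
        raise DataError("need >= 3 samples for PCA/clustering")
    ok = (values > 0).all(axis=1)
    if defined is not None:
        ok &= defined.all(axis=1)
    log2 = np.log2(values[ok])
    sd = log2.std(axis=1, ddof=0)
    zero_var = int((sd == 0).sum())
    log2 = log2[sd > 0]
    z = log2.sub(log2.mean(axis=1), axis=0).div(log2.std(axis=1, ddof=0), axis=0)
    mat = z.to_numpy().T  # samples x genes

    n_comp = min(mat.shape[0], mat.shape[1], values.shape[1] - 1)
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(mat)
    dist = pdist(mat, metric="euclidean")
    merges = linkage(dist, method="complete")
    return {
        "samples": list(values.columns),
        "pca_coordinates": pd.DataFrame(
            coords, index=values.columns, columns=[f"PC{i+1}" for i in range(n_comp)]
        ),
        "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
        "linkage": merges,
        "n_genes_used": int(z.shape[0]),
        "n_zero_variance_excluded": zero_var,
    }


# ---------------------------------------------------------------------------
# Gene-class TE comparison
# ---------------------------------------------------------------------------


def te_by_gene_class(
    expr: ExpressionTable, genes: list[GeneModel], group: str | None = None
) -> pd.DataFrame:
    """TE distribution summaries for gene classes, with a length-matched set.

    Reports all protein-coding genes, ribosomal proteins, mitochondrial
    ribosomal proteins, and protein-coding genes length-matched to the
    ribosomal-protein transcript length range (ribosomal proteins excluded
    from the matched set). Summaries are median and quartiles of defined
    TE values.
    """
    if expr.group_te is None:
        raise DataError("run compute_te first")
    te = (
        expr.group_te[group]
        if group is not None
        else expr.group_te.mean(axis=1)
    )
    labels = pd.Series({g.gene_id: g.class_label for g in genes}).loc[te.index]
    lengths = expr.lengths.loc[te.index]

    rp = labels == "ribosomal_protein"
    if not rp.any():
        raise DataError("no ribosomal_protein genes in annotation")
    lo, hi = lengths[rp].min(), lengths[rp].max()
    matched = (~rp) & (labels != "mito_ribosomal_protein") & lengths.between(lo, hi)

    sets = {
        "all_protein_coding": labels.notna(),
        "ribosomal_protein": rp,
        "mito_ribosomal_protein": labels == "mito_ribosomal_protein",
        "length_matched": matched,
    }
    rows = []
    for name, mask in sets.items():
        vals = te[mask].dropna()
        rows.append(
            {
                "gene_class": name,
                "n": len(vals),
                "median_te": vals.median(),
                "q1_te": vals.quantile(0.25),
                "q3_te": vals.quantile(0.75),
                "length_min": lengths[mask].min() if mask.any() else np.nan,
                "length_max": lengths[mask].max() if mask.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)
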