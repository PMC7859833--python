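"""Synthetic-data generator with known planted truth.

Emulates the study design this pipeline targets: three behavioural groups
(homecage baseline, immediate shock, contextual fear conditioning) with two
biological replicates each, paired footprint and total-mRNA libraries, and
planted gene classes carrying mRNA-level (DEG) or translation-level (DTG)
fold changes of known sign and size. Footprints carry the canonical
28-32 nt length peak and reading-frame bias; 5'UTRs carry planted uORF and
TOP (terminal oligopyrimidine) motifs whose prevalence differs between
classes. Every output is a pure function of (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import (
    DataError,
    GeneModel,
    CountMatrix,
    LibraryDesign,
    PolysomeTrace,
    ReadSet,
    GROUPS,
    STOP_CODONS,
)
from .utr import detect_uorfs, detect_top

STIM_GROUPS = ("immediate_shock", "cfc")

#: planted gene classes and their default proportions
DEFAULT_CLASS_PROPORTIONS = {
    "ieg_shared": 0.04,
    "cfc_only_deg": 0.05,
    "cfc_only_dtg": 0.05,
    "shock_only_deg": 0.05,
    "shock_only_dtg": 0.05,
    "ribosomal_protein": 0.06,
    "mito_ribosomal_protein": 0.03,
    "null": 0.67,
}

#: classes whose planted contrast makes them callable at the 1.5x cutoff
EFFECT_CLASSES = ("ieg_shared", "cfc_only_deg", "cfc_only_dtg",
                  "shock_only_deg", "shock_only_dtg")


@dataclass
class SimConfig:
    """All knobs of the generator. Defaults are the package's standard study
    conditions; see docs/methods.md for the rationale behind each value."""

    n_genes: int = 1000
    seed: int = 0
    groups: tuple = GROUPS
    n_replicates: int = 2
    library_size: int = 1_000_000

    # baseline relative abundance ~ LogNormal(meanlog, sdlog)
    baseline_meanlog: float = 3.0
    baseline_sdlog: float = 1.0
    # negative-binomial dispersion alpha: var = mu + alpha mu^2 (0 => Poisson)
    dispersion: float = 0.005

    class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    # planted |log2 FC| per effect class (sign drawn per gene; IEGs always up)
    effect_log2: dict = field(
        default_factory=lambda: {c: 1.5 for c in EFFECT_CLASSES}
    )
    #: constitutive log2 TE offset for ribosomal-protein genes (all groups)
    rp_te_shift_log2: float = -0.5

    # transcript geometry (nt); ribosomal proteins are deliberately short so
    # length-matched comparisons are exercised
    utr5_mean: float = 150.0
    utr5_sd: float = 60.0
    utr3_mean: float = 450.0
    utr3_sd: float = 200.0
    cds_codon_range: tuple = (150, 900)
    rp_cds_codon_range: tuple = (60, 180)
    gc_content: dict = field(default_factory=lambda: {"default": 0.48})

    uorf_prob: dict = field(
        default_factory=lambda: {"cfc_only_dtg": 0.7, "default": 0.08}
    )
    top_prob: dict = field(
        default_factory=lambda: {
            "ribosomal_protein": 0.8,
            "shock_only_dtg": 0.5,
            "default": 0.02,
        }
    )

    # footprint geometry
    footprint_lengths: tuple = tuple(range(26, 35))
    footprint_length_probs: tuple = (
        0.01, 0.04, 0.18, 0.34, 0.22, 0.12, 0.05, 0.03, 0.01,
    )  # mode 29, support 26..34
    frame_fidelity: float = 0.85
    psite_offset: int = 12

    def __post_init__(self):
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"class proportions sum to {total}, expected 1")
        if not (1 / 3 <= self.frame_fidelity <= 1):
            raise DataError("frame_fidelity must lie in [1/3, 1]")
        for cls in EFFECT_CLASSES:
            if self.effect_log2.get(cls, 0.0) < np.log2(1.5):
                raise DataError(
                    f"effect for {cls} below log2(1.5); planted genes would "
                    "not be callable at the standard cutoff"
                )
        if abs(sum(self.footprint_length_probs) - 1.0) > 1e-9:
            raise DataError("footprint length probabilities must sum to 1")

    def to_dict(self) -> dict:
        return asdict(self)


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-component generator derived from the global seed."""
    ss = np.random.SeedSequence([seed, int.from_bytes(stream.encode(), "big") % (2**31)])
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGU"))


def _random_seq(rng, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _random_cds(rng, n_codons: int, gc: float) -> str:
    """AUG + random stop-free codons + stop codon."""
    body = []
    while len(body) < n_codons - 2:
        codon = _random_seq(rng, 3, gc)
        if codon not in STOP_CODONS:
            body.append(codon)
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return "AUG" + "".join(body) + stop


def _plant_uorf(rng, utr5: str, gc: float) -> str:
    """Overwrite a slice of utr5 with AUG + stop-free codons + stop."""
    n_codons = int(rng.integers(1, 4))  # 1-3 codons between AUG and stop
    cassette = "AUG"
    for _ in range(n_codons):
        codon = _random_seq(rng, 3, gc)
        while codon in STOP_CODONS:
            codon = _random_seq(rng, 3, gc)
        cassette += codon
    cassette += STOP_CODONS[rng.integers(len(STOP_CODONS))]
    lo, hi = 8, len(utr5) - len(cassette)
    pos = int(rng.integers(lo, hi + 1))
    return utr5[:pos] + cassette + utr5[pos + len(cassette):]


def _remove_uorfs(seq: str) -> str:
    """Destroy every uORF by mutating the G of its AUG to C.

    C cannot be part of a new AUG, so the repair terminates; it preserves
    length and leaves the rest of the sequence untouched.
    """
    while True:
        hits = detect_uorfs(seq)
        if not hits:
            return seq
        s = hits[0].start
        seq = seq[: s + 2] + "C" + seq[s + 3 :]


def _make_utr5(rng, length: int, gc: float, want_uorf: bool, want_top: bool) -> str:
    """Generate a 5'UTR honouring the planted uORF/TOP flags exactly.

    Planted motifs are embedded by construction; non-planted sequences are
    repaired to be motif-free, so planted flags and scanner output coincide
    on every generated gene.
    """
    length = max(length, 26 if want_uorf else 8)
    for _ in range(200):
        seq = _random_seq(rng, length, gc)
        if want_top:
            run = int(rng.integers(4, 9))
            tract = "C" + "".join(
                np.where(rng.random(run) < 0.5, "C", "U")
            )
            # purine terminator so the tract length is exactly 1 + run
            seq = tract + "A" + seq[len(tract) + 1:]
        if want_uorf:
            seq = _plant_uorf(rng, seq, gc)
        else:
            seq = _remove_uorfs(seq)
        top_found, _ = detect_top(seq)
        if top_found != want_top:
            continue
        if (len(detect_uorfs(seq)) > 0) != want_uorf:
            continue
        return seq
    raise DataError("could not satisfy UTR motif constraints after 200 tries")


def generate_transcriptome(config: SimConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    """Generate gene models plus the planted-truth table.

    The truth table has one row per gene: class label, per-group true mRNA
    and TE log2 fold changes vs homecage, constitutive TE offset, and
    uORF/TOP planting flags.
    """
    rng = child_rng(config.seed, "transcriptome")
    n = config.n_genes
    classes = sorted(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])
    labels = rng.choice(classes, size=n, p=probs)

    gc_default = config.gc_content.get("default", 0.48)
    rows = []
    genes = []
    for i in range(n):
        cls = str(labels[i])
        gene_id = f"g{i:05d}"
        gc = config.gc_content.get(cls, gc_default)

        if cls == "ribosomal_protein":
            n_codons = int(rng.integers(*config.rp_cds_codon_range))
        else:
            n_codons = int(rng.integers(*config.cds_codon_range))
        utr5_len = max(8, int(rng.normal(config.utr5_mean, config.utr5_sd)))
        utr3_len = max(10, int(rng.normal(config.utr3_mean, config.utr3_sd)))

        want_uorf = rng.random() < config.uorf_prob.get(
            cls, config.uorf_prob.get("default", 0.0)
        )
        want_top = rng.random() < config.top_prob.get(
            cls, config.top_prob.get("default", 0.0)
        )
        utr5 = _make_utr5(rng, utr5_len, gc, want_uorf, want_top)
        cds = _random_cds(rng, n_codons, gc)
        utr3 = _random_seq(rng, utr3_len, gc)

        genes.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=f"{gene_id}.t1",
                class_label=cls,
                utr5=utr5,
                cds=cds,
                utr3=utr3,
            )
        )

        eff = config.effect_log2.get(cls, 0.0)
        sign = 1.0 if cls == "ieg_shared" else (1.0 if rng.random() < 0.5 else -1.0)
        mrna = {g: 0.0 for g in STIM_GROUPS}
        te = {g: 0.0 for g in STIM_GROUPS}
        if cls == "ieg_shared":
            for g in STIM_GROUPS:
                mrna[g] = eff
        elif cls == "cfc_only_deg":
            mrna["cfc"] = sign * eff
        elif cls == "shock_only_deg":
            mrna["immediate_shock"] = sign * eff
        elif cls == "cfc_only_dtg":
            te["cfc"] = sign * eff
        elif cls == "shock_only_dtg":
            te["immediate_shock"] = sign * eff
        rows.append(
            {
                "gene_id": gene_id,
                "class_label": cls,
                "mrna_lfc_immediate_shock": mrna["immediate_shock"],
                "mrna_lfc_cfc": mrna["cfc"],
                "te_lfc_immediate_shock": te["immediate_shock"],
                "te_lfc_cfc": te["cfc"],
                "te_baseline_log2": (
                    config.rp_te_shift_log2 if cls == "ribosomal_protein" else 0.0
                ),
                "uorf_planted": want_uorf,
                "top_planted": want_top,
            }
        )
    truth = pd.DataFrame(rows).set_index("gene_id")
    return genes, truth


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def default_design(config: SimConfig) -> list[LibraryDesign]:
    libs = []
    for assay in ("footprint", "total_mrna"):
        for group in config.groups:
            for rep in range(1, config.n_replicates + 1):
                tag = "fp" if assay == "footprint" else "tot"
                libs.append(
                    LibraryDesign(f"{tag}_{group}_r{rep}", assay, group, rep)
                )
    return libs


def _nb_draw(rng, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_counts(
    genes: list[GeneModel], truth: pd.DataFrame, config: SimConfig
) -> tuple[CountMatrix, CountMatrix]:
    """Draw footprint and total-mRNA count matrices around the planted truth.

    Expected counts follow relative abundance x transcript length; footprint
    abundance multiplies in the TE effect, so footprint = mRNA x TE by
    construction and RPKM ratios recover the planted log2 effects.
    """
    if config.library_size <= 0:
        raise DataError("library size must be positive")
    rng = child_rng(config.seed, "counts")
    gene_ids = [g.gene_id for g in genes]
    if set(gene_ids) != set(truth.index):
        raise DataError("truth table does not cover the generated genes")
    truth = truth.loc[gene_ids]
    lengths = np.array([g.length for g in genes], dtype=float)
    baseline = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, len(genes))

    mrna_lfc = {
        "homecage": np.zeros(len(genes)),
        "immediate_shock": truth["mrna_lfc_immediate_shock"].to_numpy(),
        "cfc": truth["mrna_lfc_cfc"].to_numpy(),
    }
    te_lfc = {
        "homecage": np.zeros(len(genes)),
        "immediate_shock": truth["te_lfc_immediate_shock"].to_numpy(),
        "cfc": truth["te_lfc_cfc"].to_numpy(),
    }
    te_base = truth["te_baseline_log2"].to_numpy()

    libs = default_design(config)
    counts = np.zeros((len(genes), len(libs)), dtype=np.int64)
    for j, lib in enumerate(libs):
        w = baseline * 2.0 ** mrna_lfc[lib.group] * lengths
        if lib.assay == "footprint":
            w = w * 2.0 ** (te_lfc[lib.group] + te_base)
        mu = config.library_size * w / w.sum()
        counts[:, j] = _nb_draw(rng, mu, config.dispersion)

    fp_idx = [j for j, l in enumerate(libs) if l.assay == "footprint"]
    tot_idx = [j for j, l in enumerate(libs) if l.assay == "total_mrna"]
    fp = CountMatrix(gene_ids, [libs[j] for j in fp_idx], counts[:, fp_idx])
    tot = CountMatrix(gene_ids, [libs[j] for j in tot_idx], counts[:, tot_idx])
    return fp, tot


# ---------------------------------------------------------------------------
# Footprint reads
# ---------------------------------------------------------------------------


def simulate_footprint_reads(
    genes: list[GeneModel],
    counts: CountMatrix | np.ndarray,
    config: SimConfig,
) -> ReadSet:
    """Place one aligned footprint per counted read on its transcript.

    Lengths are drawn from the configured distribution; the P-site
    (5' end + offset) lands on CDS frame 0 with probability
    ``frame_fidelity`` and uniformly on the other two frames otherwise,
    uniformly positioned along the CDS.
    """
    rng = child_rng(config.seed, "reads")
    if isinstance(counts, CountMatrix):
        per_gene = counts.counts.sum(axis=1)
        if list(counts.genes) != [g.gene_id for g in genes]:
            raise DataError("count matrix gene order does not match gene models")
    else:
        per_gene = np.asarray(counts, dtype=np.int64)

    lengths_support = np.array(config.footprint_lengths)
    length_p = np.array(config.footprint_length_probs)
    off = config.psite_offset

    gene_idx_col, start_col, len_col = [], [], []
    for i, g in enumerate(genes):
        n = int(per_gene[i])
        if n == 0:
            continue
        L = lengths_support[rng.choice(len(lengths_support), size=n, p=length_p)]
        n_codons = len(g.cds) // 3
        if n_codons == 0 or g.length < int(L.min()):
            # degenerate transcript: clamp at the 5' end, flag via truncation
            warnings.warn(f"{g.gene_id}: CDS shorter than read length", stacklevel=2)
            start = np.zeros(n, dtype=np.int64)
            L = np.minimum(L, g.length)
        else:
            in_frame = rng.random(n) < config.frame_fidelity
            frame = np.where(
                in_frame, 0, rng.integers(1, 3, size=n)
            )
            codon = rng.integers(0, n_codons, size=n)
            psite = g.cds_start + 3 * codon + frame
            start = psite - off
            # keep reads on the transcript without disturbing the frame:
            # shift whole codons, which preserves position mod 3
            low = np.maximum(start, 0)
            shift = np.ceil((low - start) / 3).astype(np.int64) * 3
            start = start + shift
            over = start + L - g.length
            shift = np.ceil(np.maximum(over, 0) / 3).astype(np.int64) * 3
            start = np.maximum(start - shift, 0)
            L = np.minimum(L, g.length - start)
        gene_idx_col.append(np.full(n, i, dtype=np.int64))
        start_col.append(start)
        len_col.append(L)

    if not gene_idx_col:
        return ReadSet([g.gene_id for g in genes], [], [], [])
    return ReadSet(
        [g.gene_id for g in genes],
        np.concatenate(gene_idx_col),
        np.concatenate(start_col),
        np.concatenate(len_col),
    )


# ---------------------------------------------------------------------------
# Polysome traces
# ---------------------------------------------------------------------------

DEFAULT_PEAKS = {
    # name: (center, sigma, area)
    "40S": (10.0, 0.7, 0.8),
    "60S": (14.0, 0.7, 1.0),
    "80S": (18.0, 0.9, 2.0),
    "poly1": (24.0, 1.0, 1.2),
    "poly2": (28.0, 1.0, 1.0),
    "poly3": (32.0, 1.0, 0.8),
    "poly4": (36.0, 1.0, 0.6),
}

LIGHT_PEAKS = ("poly1", "poly2")
HEAVY_PEAKS = ("poly3", "poly4")


def simulate_polysome_trace(
    config: SimConfig,
    peaks: dict | None = None,
    noise_sd: float = 0.002,
    grid_step: float = 0.05,
    x_range: tuple = (5.0, 40.0),
) -> tuple[PolysomeTrace, dict]:
    """Sum-of-Gaussians A254 trace plus analytic per-peak areas as truth.

    Returns the trace and a truth dict with per-peak areas, the analytic
    polysome/monosome area ratio and the true inter-peak valley positions.
    """
    peaks = dict(DEFAULT_PEAKS if peaks is None else peaks)
    names = list(peaks)
    centers = [peaks[k][0] for k in names]
    if any(np.diff(centers) <= 0):
        raise DataError("peak centers must be strictly increasing")
    rng = child_rng(config.seed, "trace")
    x = np.arange(x_range[0], x_range[1] + grid_step / 2, grid_step)
    y0 = np.zeros_like(x)
    for c, s, area in peaks.values():
        y0 += area / (s * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - c) / s) ** 2)
    y = y0 + noise_sd * rng.standard_normal(len(x))

    def _true_valley(left: str, right: str) -> float:
        sel = (x >= peaks[left][0]) & (x <= peaks[right][0])
        return float(x[sel][np.argmin(y0[sel])])

    areas = {k: peaks[k][2] for k in names}
    mono = areas.get("80S", 0.0)
    poly = sum(areas[k] for k in names if k.startswith("poly"))
    # resolvability check: valley depth vs noise
    resolvable = True
    for (c1, s1, a1), (c2, s2, a2) in zip(
        list(peaks.values())[:-1], list(peaks.values())[1:]
    ):
        mid = 0.5 * (c1 + c2)
        valley = sum(
            a / (s * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((mid - c) / s) ** 2)
            for c, s, a in peaks.values()
        )
        flank = min(
            a1 / (s1 * np.sqrt(2 * np.pi)), a2 / (s2 * np.sqrt(2 * np.pi))
        )
        if flank - valley < 3 * noise_sd:
            resolvable = False
    truth = {
        "areas": areas,
        "pm_ratio": poly / mono if mono > 0 else np.nan,
        "valley_a": _true_valley("60S", "80S"),
        "valley_b": _true_valley("80S", "poly1"),
        "resolvable": resolvable,
    }
    trace = PolysomeTrace(positions=x, absorbance=y, annotations={"peaks": peaks})
    return trace, truth


# ---------------------------------------------------------------------------
# qPCR and behaviour
# ---------------------------------------------------------------------------


def simulate_qpcr(
    fold_changes: dict[str, dict[str, float]],
    config: SimConfig,
    ct_base: float = 24.0,
    ct_lc: float = 18.0,
    noise_sd: float = 0.0,
    baseline_condition: str = "homecage",
) -> pd.DataFrame:
    """Ct table with Ct = base - log2(relative abundance) + noise.

    ``fold_changes`` maps gene -> condition -> fold change vs the baseline
    condition; the loading control is constant across conditions up to noise.
    """
    rng = child_rng(config.seed, "qpcr")
    rows = []
    for gene in sorted(fold_changes):
        conds = fold_changes[gene]
        if any(fc <= 0 for fc in conds.values()):
            raise DataError(f"non-positive fold change for {gene}")
        all_conds = dict(conds)
        all_conds.setdefault(baseline_condition, 1.0)
        for cond in sorted(all_conds):
            fc = all_conds[cond]
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "ct_gene": ct_base - np.log2(fc) + noise_sd * rng.standard_normal(),
                    "ct_loading_control": ct_lc + noise_sd * rng.standard_normal(),
                }
            )
    return pd.DataFrame(rows)


def simulate_freezing(
    p_freeze: dict[str, float],
    n_intervals: int = 60,
    n_mice: int = 12,
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli per-5-s-interval freeze scores for each mouse and group.

    Default 60 intervals = 5 min test scored in 5 s bins.
    """
    for g, p in p_freeze.items():
        if not 0 <= p <= 1:
            raise DataError(f"p_freeze for {g} outside [0, 1]")
    rng = child_rng(seed, "freezing")
    rows = []
    for group in sorted(p_freeze):
        for m in range(1, n_mice + 1):
            scores = (rng.random(n_intervals) < p_freeze[group]).astype(int)
            rows.append(
                {
                    "mouse_id": f"{group}_m{m:02d}",
                    "group": group,
                    **{f"i{k:03d}": int(s) for k, s in enumerate(scores)},
                }
            )
    return pd.DataFrame(rows)
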