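"""Core domain types shared by all pipeline stages.

Conventions
-----------
* Internal coordinates are 0-based half-open; GTF input/output is 1-based
  inclusive at the boundary.
* Sequences are stored in the RNA alphabet (``ACGU``); DNA input is
  normalized with ``T -> U`` on read.
* A gene is represented by one representative transcript (no isoform
  deconvolution); its 5'UTR and 3'UTR are the longest observed across
  annotated transcripts of that gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RNA_ALPHABET = frozenset("ACGU")
STOP_CODONS = ("UAA", "UAG", "UGA")
START_CODON = "AUG"

ASSAYS = ("footprint", "total_mrna")
GROUPS = ("homecage", "immediate_shock", "cfc")


class DataError(ValueError):
    """Raised when an input file or table violates the format contract."""


def normalize_rna(seq: str) -> str:
    """Uppercase and map DNA T to RNA U."""
    return seq.upper().replace("T", "U")


def to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open."""
    return start_1based - 1, end_1based


def to_gtf(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open interval -> 1-based inclusive."""
    return start0 + 1, end0


@dataclass(frozen=True)
class GeneModel:
    """One gene's representative transcript: UTR5 / CDS / UTR3 sequences."""

    gene_id: str
    transcript_id: str
    class_label: str
    utr5: str
    cds: str
    utr3: str
    cds_frame_ok: bool = True

    def __post_init__(self):
        for name in ("utr5", "cds", "utr3"):
            seq = getattr(self, name)
            bad = set(seq) - RNA_ALPHABET
            if bad:
                raise DataError(
                    f"{self.gene_id}/{name}: non-RNA characters {sorted(bad)}"
                )
        if self.length == 0:
            raise DataError(f"{self.gene_id}: zero-length transcript")

    @property
    def sequence(self) -> str:
        return self.utr5 + self.cds + self.utr3

    @property
    def length(self) -> int:
        return len(self.utr5) + len(self.cds) + len(self.utr3)

    @property
    def cds_start(self) -> int:
        """0-based transcript offset of the first CDS nucleotide."""
        return len(self.utr5)

    @property
    def cds_end(self) -> int:
        return len(self.utr5) + len(self.cds)


@dataclass(frozen=True, order=True)
class LibraryDesign:
    """Identity of one sequencing library in the 3-group x 2-replicate design."""

    library_id: str
    assay: str
    group: str
    replicate: int

    def __post_init__(self):
        if self.assay not in ASSAYS:
            raise DataError(f"unknown assay {self.assay!r} for {self.library_id}")
        if self.replicate < 1:
            raise DataError(f"replicate must be >= 1 for {self.library_id}")


def validate_design(libraries: list[LibraryDesign], require_pairing: bool = True):
    """Check (assay, group, replicate) uniqueness and footprint/total pairing."""
    keys = [(l.assay, l.group, l.replicate) for l in libraries]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise DataError(f"duplicate (assay, group, replicate) triples: {dupes}")
    if require_pairing:
        fp = {(l.group, l.replicate) for l in libraries if l.assay == "footprint"}
        tot = {(l.group, l.replicate) for l in libraries if l.assay == "total_mrna"}
        orphans = fp.symmetric_difference(tot)
        if orphans:
            raise DataError(
                f"unpaired footprint/total libraries for (group, replicate): {sorted(orphans)}"
            )


@dataclass
class CountMatrix:
    """Genes x libraries integer read counts for one or both assays."""

    genes: list[str]
    libraries: list[LibraryDesign]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.libraries)):
            raise DataError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.libraries)} libraries"
            )
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise DataError(f"duplicate gene_id rows: {dupes}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                bad = np.argwhere(np.mod(self.counts, 1) != 0)[0]
                raise DataError(
                    f"non-integer count at row {bad[0]} ({self.genes[bad[0]]}), "
                    f"column {bad[1]} ({self.libraries[bad[1]].library_id})"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise DataError(
                f"negative count at row {bad[0]} ({self.genes[bad[0]]}), "
                f"column {bad[1]} ({self.libraries[bad[1]].library_id})"
            )
        validate_design(self.libraries, require_pairing=False)

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def library_ids(self) -> list[str]:
        return [l.library_id for l in self.libraries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.library_ids)

    def subset_assay(self, assay: str) -> "CountMatrix":
        idx = [i for i, l in enumerate(self.libraries) if l.assay == assay]
        return CountMatrix(
            genes=list(self.genes),
            libraries=[self.libraries[i] for i in idx],
            counts=self.counts[:, idx].copy(),
        )


@dataclass(frozen=True)
class AlignedRead:
    """A single footprint alignment in transcript coordinates (5' end, length)."""

    gene_id: str
    start: int
    length: int


class ReadSet:
    """Column-oriented container for large sets of aligned footprint reads.

    Stores parallel numpy arrays (gene index, start, length) plus the gene
    ordering, which is far cheaper than a list of per-read objects at the
    10^5..10^6 reads used for QC.
    """

    def __init__(self, genes: list[str], gene_idx, start, length):
        self.genes = list(genes)
        self.gene_idx = np.asarray(gene_idx, dtype=np.int64)
        self.start = np.asarray(start, dtype=np.int64)
        self.length = np.asarray(length, dtype=np.int64)
        if not (len(self.gene_idx) == len(self.start) == len(self.length)):
            raise DataError("ReadSet columns must have equal length")

    def __len__(self) -> int:
        return len(self.start)

    @classmethod
    def from_reads(cls, reads: list[AlignedRead]) -> "ReadSet":
        genes = sorted({r.gene_id for r in reads})
        lookup = {g: i for i, g in enumerate(genes)}
        return cls(
            genes,
            [lookup[r.gene_id] for r in reads],
            [r.start for r in reads],
            [r.length for r in reads],
        )

    def to_reads(self) -> list[AlignedRead]:
        return [
            AlignedRead(self.genes[g], int(s), int(l))
            for g, s, l in zip(self.gene_idx, self.start, self.length)
        ]


@dataclass
class PolysomeTrace:
    """An A254 absorbance trace over a sucrose gradient.

    ``positions`` are strictly increasing (arbitrary units along the
    gradient); boundary markers delimit the monosome region [a, b] and the
    polysome region [b, c].
    """

    positions: np.ndarray
    absorbance: np.ndarray
    a: float | None = None
    b: float | None = None
    c: float | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.absorbance.shape:
            raise DataError("trace positions/absorbance must be equal-length 1-D")
        if np.any(np.diff(self.positions) <= 0):
            raise DataError("trace positions must be strictly increasing")
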