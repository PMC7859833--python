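"""Readers and writers for the pipeline's file formats.

Formats: GTF annotation (features on transcript coordinates, 1-based
inclusive), FASTA transcript sequences, TSV count tables, CSV library
design, TSV result tables and a JSON run summary.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datamodel import (
    CountMatrix,
    DataError,
    GeneModel,
    LibraryDesign,
    normalize_rna,
    to_gtf,
    to_internal,
)

# ---------------------------------------------------------------------------
# Annotation + sequence
# ---------------------------------------------------------------------------


def read_annotation(annotation_path, fasta_path) -> list[GeneModel]:
    """Load a GTF + FASTA pair into one :class:`GeneModel` per gene.

    The GTF uses transcript identifiers as seqnames, with ``transcript``,
    ``CDS``, ``five_prime_utr`` and ``three_prime_utr`` features in 1-based
    inclusive transcript coordinates. When a gene has several transcripts,
    the representative carries the longest 5'UTR and the longest 3'UTR seen
    for that gene (ties broken toward the lexicographically smallest
    transcript_id); the CDS comes from the longest-5'UTR transcript.
    """
    seqs = {
        rec.id: normalize_rna(str(rec.seq))
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    db = gffutils.create_db(
        str(annotation_path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    per_tx: dict[str, dict] = {}
    for feat in db.all_features():
        tid = feat.attributes.get("transcript_id", [feat.seqid])[0]
        rec = per_tx.setdefault(
            tid,
            {
                "gene_id": feat.attributes.get("gene_id", [tid])[0],
                "class": feat.attributes.get("gene_class", ["protein_coding"])[0],
                "utr5": None,
                "cds": None,
                "utr3": None,
            },
        )
        key = {
            "five_prime_utr": "utr5",
            "CDS": "cds",
            "three_prime_utr": "utr3",
        }.get(feat.featuretype)
        if key is not None:
            rec[key] = to_internal(feat.start, feat.end)

    by_gene: dict[str, list[tuple[str, dict]]] = {}
    for tid in sorted(per_tx):
        info = per_tx[tid]
        if tid not in seqs:
            raise DataError(f"no FASTA sequence for annotated transcript {tid}")
        seq = seqs[tid]
        info["seq"] = seq
        info["tid"] = tid
        by_gene.setdefault(info["gene_id"], []).append((tid, info))

    def _slice(seq: str, iv) -> str:
        return "" if iv is None else seq[iv[0] : iv[1]]

    models: list[GeneModel] = []
    for gene_id in sorted(by_gene):
        txs = by_gene[gene_id]
        # longest UTRs per gene; ties toward smallest transcript_id (txs sorted)
        rep5 = max(txs, key=lambda t: len(_slice(t[1]["seq"], t[1]["utr5"])))[1]
        rep3 = max(txs, key=lambda t: len(_slice(t[1]["seq"], t[1]["utr3"])))[1]
        cds = _slice(rep5["seq"], rep5["cds"])
        frame_ok = len(cds) > 0 and len(cds) % 3 == 0
        if not frame_ok:
            warnings.warn(
                f"{gene_id}: CDS length {len(cds)} not a positive multiple of 3; "
                "excluded from reading-frame logic",
                stacklevel=2,
            )
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=rep5["tid"],
                class_label=rep5["class"],
                utr5=_slice(rep5["seq"], rep5["utr5"]),
                cds=cds,
                utr3=_slice(rep3["seq"], rep3["utr3"]),
                cds_frame_ok=frame_ok,
            )
        )
    return models


def write_annotation(genes: list[GeneModel], annotation_path, fasta_path) -> None:
    """Write GeneModels as a GTF + FASTA pair readable by :func:`read_annotation`."""
    records = []
    with open(annotation_path, "w") as gtf:
        for g in genes:
            tid = g.transcript_id
            attrs = (
                f'gene_id "{g.gene_id}"; transcript_id "{tid}"; '
                f'gene_class "{g.class_label}";'
            )
            feats = [("transcript", 0, g.length)]
            if g.utr5:
                feats.append(("five_prime_utr", 0, len(g.utr5)))
            feats.append(("CDS", g.cds_start, g.cds_end))
            if g.utr3:
                feats.append(("three_prime_utr", g.cds_end, g.length))
            for ftype, s0, e0 in feats:
                s1, e1 = to_gtf(s0, e0)
                gtf.write(
                    f"{tid}\tribocontrast\t{ftype}\t{s1}\t{e1}\t.\t+\t.\t{attrs}\n"
                )
            records.append(SeqRecord(Seq(g.sequence), id=tid, description=""))
    SeqIO.write(records, str(fasta_path), "fasta")


# ---------------------------------------------------------------------------
# Counts + design
# ---------------------------------------------------------------------------


def read_design(design_path) -> list[LibraryDesign]:
    df = pd.read_csv(design_path)
    required = {"library_id", "assay", "group", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"design file missing columns: {sorted(missing)}")
    return [
        LibraryDesign(
            library_id=str(r.library_id),
            assay=str(r.assay),
            group=str(r.group),
            replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]


def write_design(libraries: list[LibraryDesign], design_path) -> None:
    pd.DataFrame(
        {
            "library_id": [l.library_id for l in libraries],
            "assay": [l.assay for l in libraries],
            "group": [l.group for l in libraries],
            "replicate": [l.replicate for l in libraries],
        }
    ).to_csv(design_path, index=False)


def read_counts(tsv_path, design_path) -> CountMatrix:
    """Read a genes x libraries TSV count table plus its design CSV."""
    design = {l.library_id: l for l in read_design(design_path)}
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise DataError(f"duplicate gene_id rows: {dupes}")
    unknown = [c for c in df.columns if c not in design]
    if unknown:
        raise DataError(f"libraries in counts absent from design: {unknown}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals % 1 != 0) | (vals < 0)]
        if len(bad):
            raise DataError(
                f"invalid count (negative/non-integer) at row {bad[0]!r}, column {col!r}"
            )
    return CountMatrix(
        genes=[str(g) for g in df.index],
        libraries=[design[c] for c in df.columns],
        counts=df.to_numpy().astype(np.int64),
    )


def write_counts(cm: CountMatrix, tsv_path, design_path=None) -> None:
    df = cm.to_frame()
    df.index.name = "gene_id"
    df.to_csv(tsv_path, sep="\t")
    if design_path is not None:
        write_design(cm.libraries, design_path)


# ---------------------------------------------------------------------------
# Result tables + run summary
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic TSV: stable column order, undefined values as empty fields."""
    df.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.10g")


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(tables: dict[str, pd.DataFrame], out_dir, summary: dict | None = None) -> list[Path]:
    """Write stage output tables plus a JSON run summary.

    Identical tables + summary produce byte-identical files; the summary
    carries the package version, seed and config hash, never wall-clock
    state.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name in sorted(tables):
            path = out_dir / f"{name}.tsv"
            write_table(tables[name], path)
            written.append(path)
        if summary is not None:
            path = out_dir / "run_summary.json"
            with open(path, "w") as fh:
                json.dump(summary, fh, indent=2, sort_keys=True, default=str)
                fh.write("\n")
            written.append(path)
        return written
    except OSError as exc:
        raise DataError(f"cannot write results to {out_dir}: {exc}") from exc
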