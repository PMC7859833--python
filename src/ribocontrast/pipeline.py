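"""End-to-end orchestration: simulate -> quantify/QC -> differential ->
UTR analysis -> assay analytics, as one reproducible run.

Every stage reads and writes plain files in documented formats, so stages
can also be re-run independently on saved outputs. Identical config + seed
produce byte-identical outputs; timings go to the log, never into compared
files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import assays as assays_mod
from . import differential as diff_mod
from . import io as io_mod
from . import quant as quant_mod
from . import simulate as sim_mod
from . import utr as utr_mod
from .datamodel import DataError

log = logging.getLogger("ribocontrast")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str = "run"
    sim: dict = field(default_factory=dict)  # overrides for SimConfig
    up_cutoff: float = diff_mod.UP_CUTOFF
    down_cutoff: float = diff_mod.DOWN_CUTOFF
    normalization: str = "median-ratio"
    call_min_z: float = 3.0
    n_qc_reads: int = 100_000
    metagene_window: tuple = (-20, 60)
    p_freeze: dict = field(
        default_factory=lambda: {"homecage": 0.05, "immediate_shock": 0.1, "cfc": 0.7}
    )
    n_mice: int = 12

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sim_config(config: RunConfig) -> sim_mod.SimConfig:
    return sim_mod.SimConfig(seed=config.seed, **config.sim)


def simulate_stage(config: RunConfig, out: Path) -> dict:
    sim = _sim_config(config)
    genes, truth = sim_mod.generate_transcriptome(sim)
    fp, tot = sim_mod.simulate_counts(genes, truth, sim)
    io_mod.write_annotation(genes, out / "annotation.gtf", out / "transcripts.fasta")
    io_mod.write_counts(fp, out / "counts_footprint.tsv")
    io_mod.write_counts(tot, out / "counts_total.tsv")
    io_mod.write_design(fp.libraries + tot.libraries, out / "design.csv")
    truth.reset_index().to_csv(out / "truth.tsv", sep="\t", index=False)

    # QC reads: a fixed-size sample proportional to footprint counts
    per_gene = fp.counts.sum(axis=1)
    scale = config.n_qc_reads / per_gene.sum()
    reads = sim_mod.simulate_footprint_reads(
        genes, np.round(per_gene * scale).astype(np.int64), sim
    )
    pd.DataFrame(
        {
            "gene_id": [reads.genes[i] for i in reads.gene_idx],
            "start": reads.start,
            "length": reads.length,
        }
    ).to_csv(out / "footprint_reads.tsv", sep="\t", index=False)

    trace, trace_truth = sim_mod.simulate_polysome_trace(sim)
    pd.DataFrame(
        {"position": trace.positions, "a254": trace.absorbance}
    ).to_csv(out / "polysome_trace.csv", index=False)

    fcs = {"geneA": {"immediate_shock": 2.0, "cfc": 4.0},
           "geneB": {"immediate_shock": 1.0, "cfc": 2.0}}
    sim_mod.simulate_qpcr(fcs, sim).to_csv(out / "qpcr.csv", index=False)
    sim_mod.simulate_freezing(
        config.p_freeze, n_mice=config.n_mice, seed=config.seed
    ).to_csv(out / "freezing.csv", index=False)
    return {
        "genes": genes,
        "truth": truth,
        "fp": fp,
        "tot": tot,
        "reads": reads,
        "trace": trace,
        "trace_truth": trace_truth,
        "qpcr_truth": fcs,
    }


def quant_stage(config: RunConfig, data: dict, out: Path) -> dict:
    genes, fp, tot = data["genes"], data["fp"], data["tot"]
    from .datamodel import CountMatrix

    combined = CountMatrix(
        genes=list(fp.genes),
        libraries=fp.libraries + tot.libraries,
        counts=np.hstack([fp.counts, tot.counts]),
    )
    expr = quant_mod.compute_rpkm(combined, genes)
    expr = quant_mod.normalize_libraries(expr, config.normalization)
    expr = quant_mod.compute_te(expr)

    rpkm_out = expr.rpkm.copy()
    rpkm_out.insert(0, "gene_id", rpkm_out.index)
    io_mod.write_table(rpkm_out, out / "rpkm.tsv")
    te_out = expr.group_te.copy()
    te_out.insert(0, "gene_id", te_out.index)
    io_mod.write_table(te_out, out / "te.tsv")

    reads = data["reads"]
    hist, frac_28_32 = quant_mod.footprint_length_distribution(reads)
    offsets = quant_mod.estimate_psite_offsets(reads, genes)
    f0, f1, f2 = quant_mod.frame_distribution(reads, genes, offsets)
    profile, periodicity = quant_mod.metagene_periodicity(
        reads, genes, offsets, tuple(config.metagene_window)
    )
    rep_corr = quant_mod.replicate_correlation(expr)
    pca = quant_mod.pca_cluster(
        expr.rpkm[[l.library_id for l in expr.libraries("footprint")]
                  + [l.library_id for l in expr.libraries("total_mrna")]]
    )
    if any(g.class_label == "ribosomal_protein" for g in genes):
        class_te = quant_mod.te_by_gene_class(expr, genes)
    else:
        class_te = pd.DataFrame(
            columns=["gene_class", "n", "median_te", "q1_te", "q3_te",
                     "length_min", "length_max"]
        )
    io_mod.write_table(class_te, out / "te_by_class.tsv")

    qc = {
        "length_histogram": {int(k): int(v) for k, v in hist.items()},
        "fraction_28_32": frac_28_32,
        "psite_offsets": offsets,
        "frame_fractions": [f0, f1, f2],
        "periodicity_score": periodicity,
        "replicate_r2": rep_corr.to_dict(orient="records"),
        "pca_explained_variance_ratio": pca["explained_variance_ratio"],
        "n_genes_in_pca": pca["n_genes_used"],
    }
    with open(out / "qc_report.json", "w") as fh:
        json.dump(qc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"expr": expr, "qc": qc, "class_te": class_te}


def differential_stage(config: RunConfig, data: dict, out: Path) -> dict:
    expr = data["expr"]
    results = {}
    for level in ("transcription", "translation"):
        res = diff_mod.compute_contrasts(
            expr,
            level,
            up_cutoff=config.up_cutoff,
            down_cutoff=config.down_cutoff,
            fp_counts=data["fp"],
            tot_counts=data["tot"],
            min_z=config.call_min_z,
        )
        results[level] = res
        table = res.ratios.copy()
        table.columns = [f"ratio_{c}" for c in table.columns]
        for g in res.calls.columns:
            table[f"call_{g}"] = res.calls[g]
        table.insert(0, "gene_id", table.index)
        io_mod.write_table(table, out / f"contrast_{level}.tsv")
        for direction in ("up", "down"):
            for region, genes_list in res.sets[direction].items():
                path = out / f"{level}_{direction}_{region}.txt"
                path.write_text("".join(f"{g}\n" for g in genes_list))
    r2 = {}
    for level, res in results.items():
        r2[level], scatter = diff_mod.cross_condition_correlation(
            res.ratios["cfc"], res.ratios["immediate_shock"]
        )
        io_mod.write_table(scatter, out / f"scatter_{level}.tsv")
    venn = {
        level: {**res.sets["counts"], "cross_condition_r2": r2[level]}
        for level, res in results.items()
    }
    with open(out / "venn.json", "w") as fh:
        json.dump(venn, fh, indent=2, sort_keys=True)
        fh.write("\n")
    recovery = {
        level: diff_mod.recovery_statistics(res, data["truth"])
        for level, res in results.items()
    }
    for level, rec in recovery.items():
        io_mod.write_table(rec, out / f"recovery_{level}.tsv")
    return {"contrasts": results, "venn": venn, "recovery": recovery}


def utr_stage(config: RunConfig, data: dict, out: Path) -> dict:
    genes = data["genes"]
    features = utr_mod.utr_feature_table(genes)
    io_mod.write_table(features, out / "utr_features.tsv")

    res = data["contrasts"]["translation"]
    assignments = {}
    for direction in ("up", "down"):
        for g in res.sets[direction]["cfc_only"]:
            assignments[g] = f"cfc_{direction}"
        for g in res.sets[direction]["shock_only"]:
            assignments[g] = f"shock_{direction}"
    stats_report = (
        utr_mod.compare_utr_features(features, assignments)
        if len(set(assignments.values())) >= 2
        else {"t_tests": [], "anova": {}, "skipped": ["<2 DTG groups"]}
    )
    serializable = {
        "t_tests": stats_report["t_tests"],
        "skipped": [list(map(str, s)) for s in stats_report["skipped"]],
        "anova": {
            region: {
                "motif_type": rep["motif_type"],
                "experimental_group": rep["experimental_group"],
                "posthoc": rep["posthoc"],
            }
            for region, rep in stats_report.get("anova", {}).items()
        },
    }
    with open(out / "utr_statistics.json", "w") as fh:
        json.dump(serializable, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return {"features": features, "utr_stats": stats_report}


def assay_stage(config: RunConfig, data: dict, out: Path) -> dict:
    trace = data["trace"]
    a, b, c = assays_mod.detect_trace_boundaries(trace)
    pm = assays_mod.polysome_monosome_ratio(trace, a, b, c)

    sim = _sim_config(config)
    qpcr = sim_mod.simulate_qpcr(data["qpcr_truth"], sim)
    ddct = assays_mod.ddct_fold_change(qpcr)

    freezing = sim_mod.simulate_freezing(
        config.p_freeze, n_mice=config.n_mice, seed=config.seed
    )
    per_mouse = assays_mod.freezing_table(freezing)
    io_mod.write_table(per_mouse, out / "freezing_percent.tsv")
    anova = assays_mod.group_compare(
        per_mouse["freezing_percent"], per_mouse["group"], posthoc="tukey"
    )
    result = {
        "trace_boundaries": [a, b, c],
        "pm_ratio": pm,
        "pm_ratio_truth": data["trace_truth"]["pm_ratio"],
        "ddct": ddct.to_dict(orient="records"),
        "freezing_mean_percent": per_mouse.groupby("group")["freezing_percent"]
        .mean()
        .to_dict(),
        "freezing_anova": {
            "F": anova["F"],
            "df": list(anova["df"]),
            "p": anova["p"],
        },
    }
    with open(out / "assay_results.json", "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"assays": result}


STAGES = (
    ("simulate", simulate_stage),
    ("quant", quant_stage),
    ("differential", differential_stage),
    ("utr", utr_stage),
    ("assays", assay_stage),
)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the populated run directory.

    A failing stage aborts with its name; outputs of completed stages are
    preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data: dict = {}
    timings = {}
    for name, fn in STAGES:
        t0 = time.perf_counter()
        log.info("stage %s starting", name)
        try:
            data.update(fn(config, data, out) if fn is not simulate_stage else fn(config, out))
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            raise DataError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        log.info("stage %s done in %.2f s", name, timings[name])

    cfg_dict = config.to_dict()
    cfg_dict.pop("out_dir", None)  # a path, not part of the scientific config
    summary = {
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_hash": io_mod.config_hash(cfg_dict),
        "venn": data["venn"],
        "qc": {
            k: data["qc"][k]
            for k in ("fraction_28_32", "frame_fractions", "periodicity_score")
        },
        "recovery": {
            level: rec.to_dict(orient="records")
            for level, rec in data["recovery"].items()
        },
        "assays": data["assays"],
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run.log", "w") as fh:
        for name, dt in timings.items():
            fh.write(f"{name}\t{dt:.3f}s\n")
    return out
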