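"""RPKM/TE quantification, normalization, footprint QC, PCA/clustering."""

import numpy as np
import pandas as pd
import pytest

from ribocontrast.datamodel import CountMatrix, DataError, GeneModel, LibraryDesign, ReadSet
from ribocontrast.quant import (
    ExpressionTable,
    compute_rpkm,
    compute_te,
    estimate_psite_offsets,
    footprint_length_distribution,
    frame_distribution,
    metagene_periodicity,
    normalize_libraries,
    pca_cluster,
    periodicity_score,
    replicate_correlation,
    te_by_gene_class,
)
from ribocontrast.simulate import SimConfig, generate_transcriptome, simulate_footprint_reads


def _gene(gene_id, length, cls="protein_coding"):
    n_codons = max(2, length // 6)  # CDS covers roughly half; rest is 3'UTR
    cds = "AUG" + "GCA" * (n_codons - 2) + "UAA"
    return GeneModel(gene_id, f"{gene_id}.t", cls, "", cds, "A" * (length - len(cds)))


def _paired_libs():
    libs = []
    for assay, tag in (("footprint", "fp"), ("total_mrna", "tot")):
        for rep in (1, 2):
            libs.append(LibraryDesign(f"{tag}_r{rep}", assay, "homecage", rep))
    return libs


class TestRpkm:
    def test_closed_form(self):
        genes = [_gene("g1", 1000), _gene("g2", 1000)]
        cm = CountMatrix(
            ["g1", "g2"],
            [LibraryDesign("l1", "footprint", "cfc", 1)],
            np.array([[10], [10**6 - 10]]),
        )
        expr = compute_rpkm(cm, genes)
        assert expr.rpkm.loc["g1", "l1"] == pytest.approx(10.0)

    def test_zero_count_flagged_undefined(self):
        genes = [_gene("g1", 300), _gene("g2", 300)]
        cm = CountMatrix(
            ["g1", "g2"],
            [LibraryDesign("l1", "footprint", "cfc", 1)],
            np.array([[0], [5]]),
        )
        expr = compute_rpkm(cm, genes)
        assert not expr.defined.loc["g1", "l1"]
        assert expr.rpkm.loc["g1", "l1"] == 0.0

    def test_length_normalization_ratio(self):
        genes = [_gene("g1", 500), _gene("g2", 1000)]
        cm = CountMatrix(
            ["g1", "g2"],
            [LibraryDesign("l1", "footprint", "cfc", 1)],
            np.array([[100], [100]]),
        )
        expr = compute_rpkm(cm, genes)
        assert expr.rpkm.loc["g1", "l1"] / expr.rpkm.loc["g2", "l1"] == pytest.approx(2.0)


class TestNormalization:
    def _expr(self, mat, libs=None):
        libs = libs or [
            LibraryDesign(f"l{i+1}", "footprint", "homecage", i + 1)
            for i in range(mat.shape[1])
        ]
        df = pd.DataFrame(
            mat, index=[f"g{i}" for i in range(mat.shape[0])],
            columns=[l.library_id for l in libs],
        )
        return ExpressionTable(
            rpkm=df, design=libs, defined=df > 0,
            lengths=pd.Series(500, index=df.index),
        )

    def test_identical_libraries_are_fixed_point(self):
        mat = np.tile(np.array([[1.0], [4.0], [9.0]]), (1, 3))
        expr = self._expr(mat)
        for method in ("quantile", "median-ratio"):
            out = normalize_libraries(expr, method)
            np.testing.assert_allclose(out.rpkm.to_numpy(), mat)

    def test_median_ratio_removes_global_scaling(self):
        base = np.array([[1.0], [4.0], [9.0], [2.0]])
        mat = np.hstack([base, 2 * base])
        out = normalize_libraries(self._expr(mat), "median-ratio")
        np.testing.assert_allclose(out.rpkm["l1"], out.rpkm["l2"])

    def test_quantile_equalizes_sorted_vectors(self):
        rng = np.random.default_rng(0)
        mat = rng.lognormal(0, 1, (50, 4))
        out = normalize_libraries(self._expr(mat), "quantile")
        sorted_cols = np.sort(out.rpkm.to_numpy(), axis=0)
        for j in range(1, 4):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])

    def test_rank_preserving(self):
        rng = np.random.default_rng(1)
        mat = rng.lognormal(0, 1, (30, 3))
        expr = self._expr(mat)
        for method in ("quantile", "median-ratio"):
            out = normalize_libraries(expr, method)
            for col in out.rpkm:
                assert (
                    out.rpkm[col].rank().to_numpy()
                    == expr.rpkm[col].rank().to_numpy()
                ).all()

    def test_unknown_method_rejected(self, small_expr):
        with pytest.raises(DataError, match="unknown normalization"):
            normalize_libraries(small_expr, "loess")


class TestTe:
    def _expr(self, fp_vals, tot_vals):
        libs = _paired_libs()
        data = {
            "fp_r1": fp_vals, "fp_r2": fp_vals,
            "tot_r1": tot_vals, "tot_r2": tot_vals,
        }
        df = pd.DataFrame(data, index=[f"g{i}" for i in range(len(fp_vals))])
        return ExpressionTable(
            rpkm=df, design=libs, defined=df > 0,
            lengths=pd.Series(500, index=df.index),
        )

    def test_te_is_ratio(self):
        expr = compute_te(self._expr([20.0], [10.0]))
        assert expr.group_te.loc["g0", "homecage"] == pytest.approx(2.0)

    def test_zero_mrna_gives_undefined_flag_not_infinity(self):
        expr = compute_te(self._expr([20.0], [0.0]))
        assert not expr.te_defined.loc["g0"].any()
        assert np.isnan(expr.group_te.loc["g0", "homecage"])

    def test_identical_assays_give_unit_te(self, small_dataset):
        fp = small_dataset["fp"]
        tot_libs = [
            LibraryDesign(l.library_id.replace("fp", "tot"), "total_mrna", l.group, l.replicate)
            for l in fp.libraries
        ]
        cm = CountMatrix(
            list(fp.genes), fp.libraries + tot_libs, np.hstack([fp.counts, fp.counts])
        )
        expr = compute_te(compute_rpkm(cm, small_dataset["genes"]))
        vals = expr.group_te.to_numpy()
        np.testing.assert_allclose(vals[~np.isnan(vals)], 1.0)

    def test_missing_pair_is_hard_error(self):
        libs = _paired_libs()[:3]  # drop tot_r2
        df = pd.DataFrame(
            np.ones((2, 3)), index=["g0", "g1"], columns=[l.library_id for l in libs]
        )
        expr = ExpressionTable(
            rpkm=df, design=libs, defined=df > 0,
            lengths=pd.Series(500, index=df.index),
        )
        with pytest.raises(DataError, match="unpaired"):
            compute_te(expr)


class TestLengthDistribution:
    def test_all_canonical(self):
        reads = ReadSet(["g"], [0, 0], [0, 3], [29, 29])
        hist, frac = footprint_length_distribution(reads)
        assert frac == 1.0
        assert hist.sum() == 2

    def test_half_in_window(self):
        reads = ReadSet(["g"], [0] * 4, [0] * 4, [27, 28, 32, 33])
        _, frac = footprint_length_distribution(reads)
        assert frac == 0.5

    def test_empty_rejected(self):
        with pytest.raises(DataError, match="empty"):
            footprint_length_distribution(ReadSet(["g"], [], [], []))


@pytest.fixture(scope="module")
def qc_sim():
    cfg = SimConfig(n_genes=80, seed=17, frame_fidelity=0.85)
    genes, _ = generate_transcriptome(cfg)
    per_gene = np.full(len(genes), 100_000 // len(genes))
    reads = simulate_footprint_reads(genes, per_gene, cfg)
    return cfg, genes, reads


class TestPsiteOffsets:
    def test_recovers_true_offset(self, qc_sim):
        cfg, genes, reads = qc_sim
        offsets = estimate_psite_offsets(reads, genes)
        for L, off in offsets.items():
            if (reads.length == L).sum() >= 100:
                assert off == cfg.psite_offset

    def test_sparse_length_falls_back_to_default(self, qc_sim):
        _, genes, _ = qc_sim
        few = ReadSet([g.gene_id for g in genes], [0] * 5, [10] * 5, [26] * 5)
        with pytest.warns(UserWarning, match="default offset"):
            offsets = estimate_psite_offsets(few, genes)
        assert offsets[26] == 12

    def test_flat_placement_keeps_near_default(self, qc_sim):
        """With uniform placement there is no start-codon enrichment; the
        tie-break pulls the estimate toward the canonical offset."""
        cfg, genes, _ = qc_sim
        flat_cfg = SimConfig(n_genes=80, seed=18, frame_fidelity=1 / 3)
        flat_genes, _ = generate_transcriptome(flat_cfg)
        reads = simulate_footprint_reads(
            flat_genes, np.full(len(flat_genes), 500), flat_cfg
        )
        offsets = estimate_psite_offsets(reads, flat_genes)
        assert all(10 <= off <= 15 for off in offsets.values())


class TestFrameDistribution:
    def test_recovers_fidelity(self, qc_sim):
        cfg, genes, reads = qc_sim
        offsets = estimate_psite_offsets(reads, genes)
        f0, f1, f2 = frame_distribution(reads, genes, offsets)
        assert f0 == pytest.approx(0.85, abs=0.01)
        assert f0 + f1 + f2 == pytest.approx(1.0, abs=1e-12)

    def test_utr_psites_excluded(self):
        g = _gene("g1", 300)
        # P-site (start+12) in the 3'UTR for the second read
        reads = ReadSet(["g1"], [0, 0], [0, 280], [29, 20])
        f0, f1, f2 = frame_distribution(reads, [g], {29: 12, 20: 12})
        assert f0 + f1 + f2 == pytest.approx(1.0)

    def test_no_cds_psites_is_error(self):
        g = _gene("g1", 300)
        reads = ReadSet(["g1"], [0], [280], [20])
        with pytest.raises(DataError, match="P-site"):
            frame_distribution(reads, [g], {20: 12})


class TestPeriodicity:
    def test_perfect_impulse_train_scores_high(self):
        """Exact 3-periodic impulse train: nearly all candidate-period
        power sits at period 3 (checked against an FFT-bin oracle)."""
        profile = np.tile([30.0, 0.0, 0.0], 20)  # length 60
        score = periodicity_score(profile)
        x = profile - profile.mean()
        spec = np.abs(np.fft.fft(x)) ** 2
        oracle = spec[20] / (spec[30] + spec[20] + spec[15] + spec[12] + spec[10])
        assert score == pytest.approx(oracle)
        assert score >= 0.9

    def test_flat_spectrum_scores_one_fifth(self):
        """Noisy flat profiles have equal expected power at every period:
        score concentrates near 1/5."""
        rng = np.random.default_rng(23)
        scores = [
            periodicity_score(rng.poisson(50, 60).astype(float)) for _ in range(300)
        ]
        assert np.mean(scores) == pytest.approx(0.2, abs=0.05)

    def test_all_zero_profile_is_error(self):
        with pytest.raises(DataError, match="all-zero"):
            periodicity_score(np.zeros(60))

    def test_metagene_from_simulated_reads(self, qc_sim):
        cfg, genes, reads = qc_sim
        offsets = estimate_psite_offsets(reads, genes)
        profile, score = metagene_periodicity(reads, genes, offsets, (-20, 60))
        assert list(profile.index) == list(range(-20, 60))
        assert score > 0.5

    def test_empty_window_is_error(self, qc_sim):
        cfg, genes, reads = qc_sim
        with pytest.raises(DataError, match="window"):
            metagene_periodicity(reads, genes, {29: 12}, (10, 10))


class TestReplicateCorrelation:
    def test_identical_replicates_give_one(self):
        libs = _paired_libs()
        rng = np.random.default_rng(2)
        v = rng.lognormal(1, 1, 20)
        df = pd.DataFrame(
            {l.library_id: v for l in libs}, index=[f"g{i}" for i in range(20)]
        )
        expr = ExpressionTable(
            rpkm=df, design=libs, defined=df > 0,
            lengths=pd.Series(500, index=df.index),
        )
        out = replicate_correlation(expr)
        np.testing.assert_allclose(out["r2"], 1.0)

    def test_sign_blind(self):
        libs = _paired_libs()[:2]
        x = np.array([1.0, 2.0, 4.0, 8.0])
        df = pd.DataFrame({"fp_r1": x, "fp_r2": 1 / x}, index=[f"g{i}" for i in range(4)])
        expr = ExpressionTable(
            rpkm=df, design=libs, defined=df > 0,
            lengths=pd.Series(500, index=df.index),
        )
        out = replicate_correlation(expr)
        assert out["r2"].iloc[0] == pytest.approx(1.0)

    def test_constant_vector_undefined_with_warning(self):
        libs = _paired_libs()[:2]
        df = pd.DataFrame(
            {"fp_r1": [2.0] * 5, "fp_r2": [1, 2, 3, 4, 5.0]},
            index=[f"g{i}" for i in range(5)],
        )
        expr = ExpressionTable(
            rpkm=df, design=libs, defined=df > 0,
            lengths=pd.Series(500, index=df.index),
        )
        with pytest.warns(UserWarning, match="zero variance"):
            out = replicate_correlation(expr)
        assert np.isnan(out["r2"].iloc[0])


class TestPcaCluster:
    def test_duplicated_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(3)
        base = rng.lognormal(0, 1, 40)
        df = pd.DataFrame(
            {
                "s1": base,
                "s2": base,  # exact duplicate of s1
                "s3": base * rng.lognormal(0, 0.5, 40),
                "s4": base * rng.lognormal(0, 0.5, 40),
            },
            index=[f"g{i}" for i in range(40)],
        )
        out = pca_cluster(df)
        first = out["linkage"][0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-9)

    def test_explained_variance_ratios_bounded(self, small_expr):
        out = pca_cluster(small_expr.rpkm)
        assert sum(out["explained_variance_ratio"]) <= 1.0 + 1e-9

    def test_three_separated_groups_recovered_at_k3(self):
        """Complete-linkage cut at k=3 recovers strong group structure."""
        from scipy.cluster.hierarchy import fcluster

        rng = np.random.default_rng(4)
        base = rng.lognormal(2, 0.5, 60)
        cols = {}
        for gi, shift in enumerate([1.0, 8.0, 64.0]):
            mask = rng.random(60) < 0.5
            for rep in (1, 2):
                v = base.copy()
                v[mask] *= shift
                cols[f"grp{gi}_r{rep}"] = v * rng.lognormal(0, 0.05, 60)
        df = pd.DataFrame(cols, index=[f"g{i}" for i in range(60)])
        out = pca_cluster(df)
        labels = fcluster(out["linkage"], 3, criterion="maxclust")
        pairs = {tuple(labels[i : i + 2]) for i in (0, 2, 4)}
        assert all(a == b for a, b in pairs)
        assert len({a for a, _ in pairs}) == 3

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame(np.ones((5, 2)), columns=["a", "b"])
        with pytest.raises(DataError, match="3 samples"):
            pca_cluster(df)


class TestTeByGeneClass:
    def test_length_matched_set_definition(self, small_expr, small_dataset):
        genes = small_dataset["genes"]
        out = te_by_gene_class(small_expr, genes).set_index("gene_class")
        lo = out.loc["ribosomal_protein", "length_min"]
        hi = out.loc["ribosomal_protein", "length_max"]
        expected = [
            g.gene_id
            for g in genes
            if g.class_label not in ("ribosomal_protein", "mito_ribosomal_protein")
            and lo <= g.length <= hi
        ]
        assert out.loc["length_matched", "n"] <= len(expected)
        assert out.loc["length_matched", "length_min"] >= lo
        assert out.loc["length_matched", "length_max"] <= hi

    def test_planted_rp_shift_lowers_median(self, small_expr, small_dataset):
        """Ribosomal proteins carry a -0.5 log2 constitutive TE offset and
        should sit below the length-matched comparison set."""
        out = te_by_gene_class(small_expr, small_dataset["genes"]).set_index(
            "gene_class"
        )
        assert out.loc["ribosomal_protein", "median_te"] < out.loc[
            "length_matched", "median_te"
        ]

    def test_missing_rp_class_is_error(self, small_expr):
        genes = [_gene(g, 500) for g in small_expr.rpkm.index]
        with pytest.raises(DataError, match="ribosomal_protein"):
            te_by_gene_class(small_expr, genes)
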