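import numpy as np
import pandas as pd
import pytest
from scipy import stats

import _oracles as oracles
from emtrn.errors import IntegrityError, ParameterError
from emtrn.methylome import (
    MethylationMatrix,
    build_enhancer_regions,
    call_dmers,
    call_dpmgs,
    filter_probes_by_missingness,
    fit_group_difference,
    knn_impute,
    map_promoter_probes,
    summarize_promoter_methylation,
    summarize_region_methylation,
)


def _mm(values, groups=None):
    if groups is None:
        n = values.shape[1]
        groups = pd.Series(
            ["tumor"] * (n // 2) + ["normal"] * (n - n // 2), index=values.columns
        )
    return MethylationMatrix(values, groups)


def _manifest(rows):
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "is_enhancer"])


class TestMissingnessFilter:
    @pytest.mark.parametrize(
        "n_missing, kept", [(4, False), (3, True), (0, True)],
        ids=["0.40-removed", "0.30-boundary-retained", "complete-retained"],
    )
    def test_strict_30_percent_rule(self, n_missing, kept):
        values = pd.DataFrame(
            np.full((2, 10), 0.5), index=["probeA", "probeB"],
            columns=[f"s{i}" for i in range(10)],
        )
        values.iloc[0, :n_missing] = np.nan
        out, removed = filter_probes_by_missingness(_mm(values), 0.30)
        assert ("probeA" in out.values.index) is kept
        assert ("probeA" in removed) is not kept
        assert "probeB" in out.values.index

    def test_counts_conserved(self):
        gen = np.random.default_rng(3)
        values = pd.DataFrame(gen.random((30, 10)), columns=[f"s{i}" for i in range(10)])
        values[gen.random(values.shape) < 0.4] = np.nan
        out, removed = filter_probes_by_missingness(_mm(values), 0.30)
        assert len(out.values) + len(removed) == 30


class TestKnnImpute:
    def test_nearest_row_donates(self):
        values = pd.DataFrame(
            [[0.1, 0.2, np.nan], [0.1, 0.2, 0.3], [0.9, 0.9, 0.9]],
            index=["A", "B", "C"], columns=["s1", "s2", "s3"],
        )
        groups = pd.Series(["tumor", "tumor", "normal"], index=values.columns)
        out = knn_impute(_mm(values, groups), k=1)
        assert out.values.loc["A", "s3"] == pytest.approx(0.3)
        # observed cells untouched
        assert out.values.loc["B", "s1"] == 0.1

    def test_large_k_degenerates_to_column_mean(self):
        values = pd.DataFrame(
            [[0.2, np.nan], [0.4, 0.6], [0.6, 0.8]],
            index=["A", "B", "C"], columns=["s1", "s2"],
        )
        out = knn_impute(_mm(values), k=10)
        assert out.values.loc["A", "s2"] == pytest.approx(0.7)

    def test_complete_matrix_identity(self, beta_matrix):
        values, groups = beta_matrix
        out = knn_impute(_mm(values, groups), k=3)
        pd.testing.assert_frame_equal(out.values, values)

    def test_imputed_values_in_range(self, rng):
        values = pd.DataFrame(rng.random((20, 8)), columns=[f"s{i}" for i in range(8)])
        values[rng.random(values.shape) < 0.2] = np.nan
        out = knn_impute(_mm(values), k=4)
        assert not out.values.isna().any().any()
        assert ((out.values >= 0) & (out.values <= 1)).all().all()


class TestEnhancerRegions:
    def test_isolated_probe_gives_1000bp_region(self):
        regions = build_enhancer_regions(_manifest([("cg1", "chr1", 1000, True)]), 500)
        (r,) = regions
        assert (r.chrom, r.start, r.end) == ("chr1", 500, 1500)
        assert r.end - r.start == 1000 and r.probes == ["cg1"]

    def test_overlapping_windows_merge(self):
        regions = build_enhancer_regions(
            _manifest([("cg1", "chr1", 1000, True), ("cg2", "chr1", 1800, True)]), 500
        )
        (r,) = regions
        assert (r.start, r.end) == (500, 2300)
        assert sorted(r.probes) == ["cg1", "cg2"]

    def test_bookended_windows_stay_separate(self):
        regions = build_enhancer_regions(
            _manifest([("cg1", "chr1", 1000, True), ("cg2", "chr1", 2000, True)]), 500
        )
        assert [(r.start, r.end) for r in regions] == [(500, 1500), (1500, 2500)]

    def test_non_enhancer_probes_ignored(self):
        regions = build_enhancer_regions(
            _manifest([("cg1", "chr1", 1000, True), ("cg2", "chr1", 1100, False)]), 500
        )
        assert len(regions) == 1 and regions[0].probes == ["cg1"]

    def test_window_clipped_at_chromosome_start(self):
        with pytest.warns(UserWarning, match="clipped"):
            regions = build_enhancer_regions(_manifest([("cg1", "chr1", 100, True)]), 500)
        assert regions[0].start == 0

    def test_matches_bitmap_oracle_on_random_manifests(self, rng):
        for _ in range(150):
            n = int(rng.integers(1, 40))
            manifest = _manifest(
                [
                    (
                        f"cg{i}",
                        f"chr{rng.integers(1, 4)}",
                        int(rng.integers(500, 20_000)),
                        bool(rng.random() < 0.8),
                    )
                    for i in range(n)
                ]
            )
            manifest = manifest.drop_duplicates(subset=["chrom", "pos"])
            regions = build_enhancer_regions(manifest, 500)
            got = {
                (r.chrom, r.start, r.end, frozenset(r.probes)) for r in regions
            }
            assert got == oracles.bitmap_merge(manifest, 500)
            # pairwise disjoint within chromosomes, probes conserved
            by_chrom = {}
            for r in regions:
                by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
            for spans in by_chrom.values():
                spans.sort()
                assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))
            assert sum(len(r.probes) for r in regions) == manifest["is_enhancer"].sum()

    def test_order_invariant_and_idempotent(self, rng):
        manifest = _manifest(
            [(f"cg{i}", "chr1", int(rng.integers(500, 5000)), True) for i in range(20)]
        ).drop_duplicates(subset=["pos"])
        shuffled = manifest.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = build_enhancer_regions(manifest, 500)
        b = build_enhancer_regions(shuffled, 500)
        assert [(r.chrom, r.start, r.end, tuple(sorted(r.probes))) for r in a] == [
            (r.chrom, r.start, r.end, tuple(sorted(r.probes))) for r in b
        ]


class TestSummaries:
    def test_region_mean_and_symmetry(self, beta_matrix):
        values, groups = beta_matrix
        from emtrn.methylome import EnhancerRegion

        region = EnhancerRegion("R1", "chr1", 0, 10, ["cg000", "cg001"])
        out = summarize_region_methylation(_mm(values, groups), [region])
        expected = (values.loc["cg000"] + values.loc["cg001"]) / 2
        assert np.allclose(out.values.loc["R1"], expected)
        flipped = EnhancerRegion("R1", "chr1", 0, 10, ["cg001", "cg000"])
        out2 = summarize_region_methylation(_mm(values, groups), [flipped])
        pd.testing.assert_frame_equal(out.values, out2.values)

    def test_single_probe_region_is_identity(self, beta_matrix):
        values, groups = beta_matrix
        from emtrn.methylome import EnhancerRegion

        out = summarize_region_methylation(
            _mm(values, groups), [EnhancerRegion("R1", "chr1", 0, 10, ["cg003"])]
        )
        assert np.allclose(out.values.loc["R1"], values.loc["cg003"])

    def test_unknown_probe_is_integrity_error(self, beta_matrix):
        values, groups = beta_matrix
        from emtrn.methylome import EnhancerRegion

        with pytest.raises(IntegrityError):
            summarize_region_methylation(
                _mm(values, groups), [EnhancerRegion("R1", "chr1", 0, 10, ["nope"])]
            )

    def test_promoter_summary_mean_and_absence(self, beta_matrix):
        values, groups = beta_matrix
        out = summarize_promoter_methylation(
            _mm(values, groups), {"geneA": ["cg000", "cg002"], "geneB": []}
        )
        assert list(out.values.index) == ["geneA"]
        assert np.allclose(out.values.loc["geneA"], (values.loc["cg000"] + values.loc["cg002"]) / 2)


class TestPromoterMapping:
    GENES = pd.DataFrame(
        {
            "gene_id": ["gPlus", "gMinus"],
            "gene_type": ["mRNA", "lncRNA"],
            "chrom": ["chr1", "chr1"],
            "strand": ["+", "-"],
            "tss": [10_000, 50_000],
        }
    )

    def test_strand_aware_containment(self):
        manifest = _manifest(
            [
                ("p_up", "chr1", 9_500, False),     # inside [8000, 10000) of gPlus
                ("p_at_tss", "chr1", 10_000, False),  # at TSS: outside (half-open)
                ("m_down", "chr1", 50_400, False),    # inside [50000, 52000) of gMinus
                ("m_up", "chr1", 49_900, False),      # upstream of - strand TSS: outside
            ]
        )
        mapping = map_promoter_probes(manifest, self.GENES, 2000)
        assert mapping == {"gPlus": ["p_up"], "gMinus": ["m_down"]}

    def test_enhancer_probe_excluded(self):
        manifest = _manifest([("enh", "chr1", 9_500, True)])
        assert map_promoter_probes(manifest, self.GENES, 2000) == {}

    def test_multi_gene_probe_excluded_entirely(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "gene_type": ["mRNA", "mRNA"],
                "chrom": ["chr1", "chr1"],
                "strand": ["+", "-"],
                "tss": [10_000, 9_000],  # promoters [8000,10000) and [9000,11000)
            }
        )
        manifest = _manifest([("shared", "chr1", 9_500, False), ("solo", "chr1", 8_100, False)])
        mapping = map_promoter_probes(manifest, genes, 2000)
        assert mapping == {"g1": ["solo"]}


class TestGroupDifference:
    def test_equal_group_means_give_zero_t(self):
        gen = np.random.default_rng(0)
        noise = gen.normal(0, 0.05, size=5)
        row = np.concatenate([0.5 + noise, 0.5 + noise[:4]])
        extra = np.clip(gen.random((10, 9)), 0.01, 0.99)
        values = pd.DataFrame(
            np.vstack([np.clip(row, 0.01, 0.99), extra]),
            index=[f"f{i}" for i in range(11)],
            columns=[f"T{i}" for i in range(5)] + [f"N{i}" for i in range(4)],
        )
        values.iloc[0, :5] = 0.5
        values.iloc[0, 5:] = 0.5 + np.array([0.01, -0.01, 0.02, -0.02])
        groups = pd.Series(["tumor"] * 5 + ["normal"] * 4, index=values.columns)
        res = fit_group_difference(MethylationMatrix(values, groups))
        assert res.loc["f0", "log2fc"] == pytest.approx(0.0)
        assert res.loc["f0", "t"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["f0", "p"] == pytest.approx(1.0)

    def test_prior_df_zero_recovers_pooled_t(self, beta_matrix):
        values, groups = beta_matrix
        res = fit_group_difference(MethylationMatrix(values, groups), prior_df=0)
        for fid in values.index:
            t_ref = oracles.pooled_two_sample_t(
                values.loc[fid, groups == "tumor"], values.loc[fid, groups == "normal"]
            )
            assert res.loc[fid, "t"] == pytest.approx(t_ref, abs=1e-10)

    def test_bh_matches_stepup_oracle(self):
        # the textbook example: (0.01, 0.02, 0.03, 0.04) all adjust to 0.04
        assert np.allclose(oracles.bh_stepup([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        gen = np.random.default_rng(11)
        values = pd.DataFrame(
            np.clip(gen.random((25, 12)), 0.01, 0.99),
            columns=[f"T{i}" for i in range(6)] + [f"N{i}" for i in range(6)],
        )
        groups = pd.Series(["tumor"] * 6 + ["normal"] * 6, index=values.columns)
        res = fit_group_difference(MethylationMatrix(values, groups))
        assert np.allclose(res["adj_p"], oracles.bh_stepup(res["p"]), atol=1e-12)

    def test_matches_limma_on_frozen_fixture(self):
        """Moderated t agrees with the Bioconductor limma oracle (values
        computed once with limma 3.58.1 on this exact generated matrix)."""
        gen = np.random.default_rng(7)
        sds = gen.uniform(0.02, 0.3, 40)
        X = np.clip(0.5 + sds[:, None] * gen.normal(size=(40, 10)), 0.01, 0.99)
        values = pd.DataFrame(
            np.round(X, 6), index=[f"g{i:02d}" for i in range(40)],
            columns=[f"T{i}" for i in range(6)] + [f"N{i}" for i in range(4)],
        )
        groups = pd.Series(["tumor"] * 6 + ["normal"] * 4, index=values.columns)
        res = fit_group_difference(MethylationMatrix(values, groups))
        # limma: fit$df.prior, fit$s2.prior and selected moderated t / p
        expected = {
            "g00": (0.644245, 0.533989),
            "g02": (-1.169412, 0.269493),
            "g39": (-0.064514, 0.949839),
        }
        for gid, (t_exp, p_exp) in expected.items():
            assert res.loc[gid, "t"] == pytest.approx(t_exp, abs=5e-6)
            assert res.loc[gid, "p"] == pytest.approx(p_exp, abs=5e-6)

    def test_moderated_t_limits(self, beta_matrix):
        """d0 -> 0 gives the pooled t; d0 -> inf pins the variance at s0^2."""
        values, groups = beta_matrix
        mm = MethylationMatrix(values, groups)
        res0 = fit_group_difference(mm, prior_df=0)
        resinf = fit_group_difference(mm, prior_df=np.inf)
        n1, n2 = 6, 4
        for fid in values.index:
            t_ref = oracles.pooled_two_sample_t(
                values.loc[fid, groups == "tumor"], values.loc[fid, groups == "normal"]
            )
            assert res0.loc[fid, "t"] == pytest.approx(t_ref, abs=1e-10)
        # infinite prior: all features share one variance -> t proportional to coef
        ratio = resinf["t"] / resinf["log2fc"]
        assert np.allclose(ratio, ratio.iloc[0])

    def test_zero_variance_feature_flagged(self):
        values = pd.DataFrame(
            [[0.4] * 6 + [0.6] * 4, [0.3, 0.35, 0.4, 0.45, 0.5, 0.55, 0.2, 0.25, 0.3, 0.35]],
            index=["flat", "ok"],
            columns=[f"T{i}" for i in range(6)] + [f"N{i}" for i in range(4)],
        )
        groups = pd.Series(["tumor"] * 6 + ["normal"] * 4, index=values.columns)
        res = fit_group_difference(MethylationMatrix(values, groups))
        assert bool(res.loc["flat", "zero_variance"])
        assert res.loc["flat", "p"] == 1.0 and np.isnan(res.loc["flat", "t"])


class TestCalling:
    @pytest.mark.parametrize(
        "log2fc, adj_p, direction",
        [(0.05, 0.01, "hyper"), (0.005, 0.001, "ns"), (-0.20, 0.04, "hypo"),
         (0.05, 0.06, "ns")],
    )
    def test_dmer_thresholds(self, log2fc, adj_p, direction):
        results = pd.DataFrame({"log2fc": [log2fc], "adj_p": [adj_p]}, index=["R1"])
        assert call_dmers(results).loc["R1", "direction"] == direction

    @pytest.mark.parametrize(
        "delta, adj_p, direction",
        [(0.15, 0.01, "hyper"), (0.05, 0.0001, "ns"), (-0.30, 0.04, "hypo")],
    )
    def test_dpmg_thresholds(self, delta, adj_p, direction):
        results = pd.DataFrame({"delta_median": [delta], "adj_p": [adj_p]}, index=["g1"])
        assert call_dpmgs(results).loc["g1", "direction"] == direction
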