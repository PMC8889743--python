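import numpy as np
import pandas as pd
import pytest

from circsig.io_formats import ExpressionMatrix, PipelineConfig, SampleMeta
from circsig.diffexpr import (
    count_de,
    de_test,
    global_abundance_test,
    prevalence_filter,
    size_factors,
)


def _paired_samples(n_pairs, tissue="brain"):
    out = []
    for i in range(n_pairs):
        out.append(SampleMeta(f"p{i}T", tissue, "tumor", f"p{i}", 10_000_000))
        out.append(SampleMeta(f"p{i}N", tissue, "normal", f"p{i}", 10_000_000))
    return out


def _nb_counts(rng, mean, shape, alpha=0.1):
    n = 1 / alpha
    return rng.negative_binomial(n, n / (n + mean), size=shape)


class TestDeTest:
    def test_identical_tumor_and_normal_gives_zero_fc(self):
        rng = np.random.default_rng(0)
        samples = _paired_samples(5)
        half = _nb_counts(rng, 50, (40, 5))
        counts = np.empty((40, 10), dtype=int)
        counts[:, 0::2] = half  # tumors
        counts[:, 1::2] = half  # normals identical per pair
        res = de_test(counts, [f"f{i}" for i in range(40)], samples)
        assert np.allclose(res["log2fc"], 0.0, atol=1e-6)
        assert (res["direction"] == "ns").all()

    def test_swapping_condition_labels_negates_log2fc(self):
        rng = np.random.default_rng(1)
        samples = _paired_samples(6)
        counts = _nb_counts(rng, 30, (50, 12))
        res = de_test(counts, [f"f{i}" for i in range(50)], samples)
        flipped = [
            SampleMeta(s.sample_id, s.tissue,
                       "normal" if s.condition == "tumor" else "tumor",
                       s.patient_id, s.mapped_reads)
            for s in samples
        ]
        res2 = de_test(counts, [f"f{i}" for i in range(50)], flipped)
        np.testing.assert_allclose(res2["log2fc"], -res["log2fc"], atol=1e-6)
        np.testing.assert_allclose(res2["p_value"], res["p_value"], atol=1e-6)

    def test_all_zero_feature_reported_ns_with_nan_stats(self):
        rng = np.random.default_rng(2)
        samples = _paired_samples(4)
        counts = _nb_counts(rng, 20, (10, 8))
        counts[3, :] = 0
        res = de_test(counts, [f"f{i}" for i in range(10)], samples)
        assert res.loc[3, "direction"] == "ns"
        assert np.isnan(res.loc[3, "p_value"])

    def test_non_integer_counts_rejected(self):
        samples = _paired_samples(3)
        with pytest.raises(ValueError, match="integer"):
            de_test(np.full((4, 6), 1.5), list("abcd"), samples)

    def test_fewer_than_three_pairs_rejected(self):
        samples = _paired_samples(2)
        with pytest.raises(ValueError, match="pairs"):
            de_test(np.ones((4, 4), dtype=int), list("abcd"), samples)

    def test_direction_requires_both_significance_and_fold_change(self):
        """A significant feature below the fold-change gate stays ns."""
        rng = np.random.default_rng(3)
        samples = _paired_samples(10)
        counts = _nb_counts(rng, 100, (80, 20), alpha=0.05)
        counts[0, 0::2] = _nb_counts(rng, 400, (10,), alpha=0.05)  # 4x up
        strict = PipelineConfig(de_min_fold_change=16)
        res = de_test(counts, [f"f{i}" for i in range(80)], samples, config=strict)
        assert res.loc[0, "padj"] < 0.05
        assert abs(res.loc[0, "log2fc"]) < 4
        assert res.loc[0, "direction"] == "ns"

    def test_bh_adjustment_is_monotone_and_bounded(self):
        rng = np.random.default_rng(4)
        samples = _paired_samples(5)
        counts = _nb_counts(rng, 25, (120, 10))
        res = de_test(counts, [f"f{i}" for i in range(120)], samples).dropna()
        assert (res["padj"] <= 1.0).all()
        assert (res["padj"] >= res["p_value"] - 1e-12).all()
        ordered = res.sort_values("p_value")
        assert ordered["padj"].cummax().equals(ordered["padj"])


def test_size_factors_recover_depth_ratios():
    rng = np.random.default_rng(5)
    base = rng.lognormal(3, 1, size=200)
    depth = np.array([0.5, 1.0, 2.0])
    counts = rng.poisson(base[:, None] * depth[None, :])
    sf = size_factors(counts)
    np.testing.assert_allclose(sf / sf[1], depth, rtol=0.1)


class TestPrevalenceFilter:
    def _rpm(self, values):
        n = values.shape[1]
        samples = _paired_samples(n // 2)
        return ExpressionMatrix(
            [f"f{i}" for i in range(len(values))],
            [s.sample_id for s in samples], values, "RPM", samples=samples,
        )

    def test_two_of_twenty_meets_ten_percent(self):
        values = np.zeros((1, 20))
        values[0, :2] = 0.1
        assert prevalence_filter(self._rpm(values)) == ["f0"]

    def test_one_of_twenty_fails(self):
        values = np.zeros((1, 20))
        values[0, 0] = 5.0
        assert prevalence_filter(self._rpm(values)) == []

    def test_matches_bruteforce_on_random_fixture(self):
        rng = np.random.default_rng(6)
        values = rng.uniform(0, 0.3, size=(50, 20))
        kept = prevalence_filter(self._rpm(values))
        need = int(np.ceil(0.1 * 20))
        expected = [
            f"f{i}" for i in range(50) if (values[i] >= 0.1).sum() >= need
        ]
        assert kept == expected


class TestGlobalAbundance:
    def _rpm_matrix(self, tumor_totals, normal_totals, tissue="brain"):
        samples, cols = [], []
        for i, (t, n) in enumerate(zip(tumor_totals, normal_totals)):
            samples.append(SampleMeta(f"p{i}T", tissue, "tumor", f"p{i}", 10**6))
            samples.append(SampleMeta(f"p{i}N", tissue, "normal", f"p{i}", 10**6))
            cols += [t, n]
        return ExpressionMatrix(
            ["f0"], [s.sample_id for s in samples],
            np.array([cols], dtype=float), "RPM", samples=samples,
        )

    def test_identical_totals_give_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = global_abundance_test(self._rpm_matrix(vals, vals))
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_complete_separation_gives_extreme_p(self):
        tumor = [1, 2, 3, 4, 5, 6, 7, 8]
        normal = [101, 102, 103, 104, 105, 106, 107, 108]
        res = global_abundance_test(self._rpm_matrix(tumor, normal))
        assert res.loc[0, "p_value"] < 1e-3
        assert res.loc[0, "tumor_median_total_rpm"] < res.loc[0, "normal_median_total_rpm"]

    def test_too_few_pairs_reports_nan(self):
        res = global_abundance_test(self._rpm_matrix([1, 2], [3, 4]))
        assert np.isnan(res.loc[0, "p_value"])


class TestCountDe:
    def test_simple_aggregation(self):
        table = pd.DataFrame(
            {
                "feature_id": list("abcde"),
                "cancer": ["GBM"] * 5,
                "direction": ["up", "up", "up", "down", "down"],
            }
        )
        out = count_de(table)
        assert out.loc[0, ["n_up", "n_down", "n_total"]].tolist() == [3, 2, 5]

    def test_empty_table_gives_zero_rows(self):
        assert count_de(pd.DataFrame(columns=["feature_id", "cancer", "direction"])).empty


def test_deseq2_cross_check_on_small_instance():
    """Independent oracle: pydeseq2 on the same counts ranks the same features.

    Exact parity is not expected (different dispersion/shrinkage choices);
    planted 4x features must be the top hits with matching sign in both.
    """
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    rng = np.random.default_rng(7)
    samples = _paired_samples(8)
    counts = _nb_counts(rng, 60, (60, 16), alpha=0.05)
    planted = [0, 1, 2]
    for i, sign in zip(planted, (1, 1, -1)):
        factor = 4.0 if sign > 0 else 0.25
        counts[i, 0::2] = _nb_counts(rng, 60 * factor, (8,), alpha=0.05)
    ours = de_test(counts, [f"f{i}" for i in range(60)], samples)

    meta = pd.DataFrame(
        {
            "condition": ["tumor" if s.condition == "tumor" else "normal"
                           for s in samples],
            "patient": [s.patient_id for s in samples],
        },
        index=[s.sample_id for s in samples],
    )
    dds = DeseqDataSet(
        counts=pd.DataFrame(counts.T, index=meta.index),
        metadata=meta,
        design="~patient + condition",
        quiet=True,
    )
    dds.deseq2()
    stats = DeseqStats(dds, contrast=["condition", "tumor", "normal"], quiet=True)
    stats.summary()
    theirs = stats.results_df.reset_index(drop=True)
    for i in planted:
        assert np.sign(ours.loc[i, "log2fc"]) == np.sign(
            theirs.loc[i, "log2FoldChange"]
        )
        assert ours.loc[i, "padj"] < 0.05 and theirs.loc[i, "padj"] < 0.05
    # fold-change estimates agree to within a third of a log2 unit
    np.testing.assert_allclose(
        ours.loc[planted, "log2fc"],
        theirs.loc[planted, "log2FoldChange"],
        atol=0.35,
    )
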