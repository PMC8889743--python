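import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from circsig.io_formats import CircRNARecord, GenomicIntervals, PipelineConfig, TranscriptModel
from circsig.attribution import (
    attribute_dysregulated_circ,
    attribute_specific_circ,
    best_rbp_correlation,
    flanking_intron_peak_overlap,
    fold_change_quadrant,
    pearson_profile,
)


class TestPearson:
    def test_affine_relation_is_perfect(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert pearson_profile(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_profile(x, -x) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert pearson_profile([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_symmetry_and_self_correlation(self):
        x, y = [1.0, 4.0, 2.0, 8.0], [3.0, 1.0, 5.0, 2.0]
        assert pearson_profile(x, x) == pytest.approx(1.0)
        assert pearson_profile(x, y) == pearson_profile(y, x)

    def test_affine_rescaling_invariance(self):
        x, y = np.array([1.0, 4.0, 2.0, 8.0]), np.array([3.0, 1.0, 5.0, 2.0])
        assert pearson_profile(3 * x + 7, y) == pytest.approx(pearson_profile(x, y))

    def test_constant_vector_is_flagged_undefined(self):
        assert np.isnan(pearson_profile([1, 1, 1], [1, 2, 3]))

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            pearson_profile([1, 2, 3], [1, 2])

    def test_best_rbp_matches_exhaustive_scan(self):
        """Vectorised best-RBP search equals a brute-force pairwise scan."""
        rng = np.random.default_rng(0)
        circ = rng.uniform(0, 10, size=7)
        panel = pd.DataFrame(
            rng.uniform(0, 10, size=(20, 7)),
            index=[f"RBP{i:02d}" for i in range(20)],
        )
        best_id, best_r = best_rbp_correlation(circ, panel)
        brute = {
            rid: sps.pearsonr(circ, panel.loc[rid]).statistic for rid in panel.index
        }
        expected_id = max(brute, key=brute.get)
        assert best_id == expected_id
        assert best_r == pytest.approx(brute[expected_id])


def _tsi_like(index, categories, argmax):
    return pd.DataFrame(
        {"tsi": [0.9 if c == "tissue_specific" else 0.1 for c in categories],
         "argmax_tissue": argmax, "category": categories},
        index=index,
    )


class TestSpecificAttribution:
    tissues = ["brain", "lung", "liver"]

    def test_threshold_logic_on_constructed_profiles(self):
        """Host-driven, RBP-driven and orphan circRNAs get the right calls."""
        circ_prof = pd.DataFrame(
            [[50.0, 0.1, 0.2], [0.3, 40.0, 0.2], [9.0, 0.0, 1.0]],
            index=["circH", "circR", "circU"], columns=self.tissues,
        )
        circ_tsi = _tsi_like(
            ["circH", "circR", "circU"],
            ["tissue_specific"] * 3, ["brain", "lung", "brain"],
        )
        gene_tsi = _tsi_like(
            ["GH", "GR", "GU"],
            ["tissue_specific", "ubiquitous", "ubiquitous"],
            ["brain", "brain", "brain"],
        )
        # one lung-specific RBP strongly matching circR; nothing matches circU
        rbp_prof = pd.DataFrame(
            [[0.2, 30.0, 0.1]], index=["RBPX"], columns=self.tissues
        )
        rbp_tsi = _tsi_like(["RBPX"], ["tissue_specific"], ["lung"])
        res = attribute_specific_circ(
            circ_tsi, circ_prof, gene_tsi, rbp_tsi, rbp_prof,
            {"circH": "GH", "circR": "GR", "circU": "GU"},
        )
        assert res.loc["circH", "driver_call"] == "host_gene"
        assert res.loc["circR", "driver_call"] == "rbp_associated"
        assert res.loc["circR", "best_rbp"] == "RBPX"
        assert res.loc["circU", "driver_call"] == "unexplained"

    def test_circ_without_host_gene_is_skipped_with_flag(self):
        circ_prof = pd.DataFrame([[5.0, 0.0, 0.0]], index=["c"], columns=self.tissues)
        circ_tsi = _tsi_like(["c"], ["tissue_specific"], ["brain"])
        empty = _tsi_like([], [], [])
        res = attribute_specific_circ(
            circ_tsi, circ_prof, empty, empty, pd.DataFrame(columns=self.tissues), {}
        )
        assert res.loc["c", "driver_call"] == "skipped_no_host"

    def test_driver_partition_is_exhaustive_on_simulation(self, cohort):
        from circsig.quantify import rpm_matrix
        from circsig.specificity import categorize, filter_abundant, median_by_tissue, tsi_table

        cfg = PipelineConfig()
        rpm = rpm_matrix(cohort.junctions)
        circ_prof = filter_abundant(median_by_tissue(rpm), cfg.circ_abundance_median_rpm)
        gene_prof_all = median_by_tissue(cohort.gene_fpkm)
        gene_prof = filter_abundant(gene_prof_all, cfg.gene_abundance_median_fpkm)
        circ_tsi = categorize(tsi_table(circ_prof), cfg)
        gene_tsi = categorize(tsi_table(gene_prof), cfg)
        rbp_prof = gene_prof_all.loc[cohort.rbp_panel]
        rbp_tsi = categorize(tsi_table(rbp_prof), cfg)
        res = attribute_specific_circ(
            circ_tsi, circ_prof, gene_tsi, rbp_tsi, rbp_prof,
            cohort.host_gene_map, gene_profiles=gene_prof_all, config=cfg,
        )
        assert res["driver_call"].isin(
            ["host_gene", "rbp_associated", "both", "unexplained", "skipped_no_host"]
        ).all()
        n_specific = (circ_tsi["category"] == "tissue_specific").sum()
        assert len(res) == n_specific


class TestDysregulatedAttribution:
    def _de(self, rows):
        return pd.DataFrame(
            rows, columns=["feature_id", "cancer", "log2fc", "padj", "direction"]
        )

    def test_host_explained_and_quadrant(self):
        circ_de = self._de([["c1", "GBM", -2.1, 0.001, "down"]])
        gene_de = self._de([["G1", "GBM", -1.8, 0.004, "down"]])
        att, quad = attribute_dysregulated_circ(
            circ_de, gene_de, self._de([]), pd.DataFrame(), pd.DataFrame(),
            {"c1": "G1"},
        )
        assert att.loc[0, "driver_call"] == "host_gene"
        assert quad.loc[0, "quadrant"] == "both_down" and quad.loc[0, "concordant"]

    def test_rbp_fallback_when_host_not_significant(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(1, 10, size=10)
        circ_expr = pd.DataFrame([base * 2.0], index=["c1"])
        rbp_expr = pd.DataFrame([base + rng.normal(0, 0.01, 10)], index=["R1"])
        circ_de = self._de([["c1", "GBM", -2.0, 0.01, "down"]])
        gene_de = self._de([["G1", "GBM", -0.1, 0.9, "ns"]])
        rbp_de = self._de([["R1", "GBM", -1.5, 0.02, "down"]])
        att, _ = attribute_dysregulated_circ(
            circ_de, gene_de, rbp_de, circ_expr, rbp_expr, {"c1": "G1"}
        )
        assert att.loc[0, "driver_call"] == "rbp_associated"
        assert att.loc[0, "best_rbp_r"] >= 0.7

    def test_direction_discordant_host_falls_to_quadrant(self):
        circ_de = self._de([["c1", "GBM", -2.0, 0.01, "down"]])
        gene_de = self._de([["G1", "GBM", 1.9, 0.01, "up"]])
        att, quad = attribute_dysregulated_circ(
            circ_de, gene_de, self._de([]), pd.DataFrame(), pd.DataFrame(),
            {"c1": "G1"},
        )
        assert att.loc[0, "driver_call"] == "unexplained"
        assert att.loc[0, "host_de_any_direction"]
        assert quad.loc[0, "quadrant"] == "circ_down_gene_up"

    def test_quadrant_partition_concordant_plus_discordant(self):
        rng = np.random.default_rng(2)
        lfc = rng.normal(0, 2, size=(30, 2))
        quads = [fold_change_quadrant(a, b) for a, b in lfc]
        concordant = sum(1 for _, c in quads if c)
        assert concordant + sum(1 for _, c in quads if not c) == 30
        for (q, c), (a, b) in zip(quads, lfc):
            assert c == ((a >= 0) == (b >= 0))


class TestPeakOverlap:
    tx = TranscriptModel(
        "t1", "G1", "chr1", "+",
        exons=((0, 100), (1100, 1200), (2200, 2300), (3300, 3400)),
        cds=(10, 3390),
    )
    rec = CircRNARecord("chr1", 1100, 2300, "+", "c",
                        exon_blocks=((1100, 1200), (2200, 2300)))

    def test_peak_in_upstream_intron(self):
        peaks = GenomicIntervals()
        peaks.add("chr1", 500, 550)
        out = flanking_intron_peak_overlap(self.rec, self.tx, peaks)
        assert out["any_overlap"] and out["upstream_peaks"] == 1

    def test_distal_peaks_do_not_count(self):
        peaks = GenomicIntervals()
        peaks.add("chr1", 5000, 5100)
        out = flanking_intron_peak_overlap(self.rec, self.tx, peaks)
        assert not out["any_overlap"]

    def test_counts_per_side(self):
        peaks = GenomicIntervals()
        peaks.add("chr1", 200, 260)
        peaks.add("chr1", 700, 760)
        peaks.add("chr1", 2500, 2560)
        out = flanking_intron_peak_overlap(self.rec, self.tx, peaks)
        assert (out["upstream_peaks"], out["downstream_peaks"]) == (2, 1)
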