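"""Divergence parameters: exhaustive-enumeration oracles and recovery."""

import math

import numpy as np
import pytest

from barcode_eval.distances import distance_matrix
from barcode_eval.divergence import (
    gap_histograms,
    interspecific_stats,
    intraspecific_stats,
    nearest_congener_distances,
    ratio_gap_index,
    summarize_divergence,
)
from barcode_eval.simdata import SimulationConfig, simulate_dataset

from conftest import make_dataset, make_record, matrix_from_pairs


def dataset_of(species_by_id):
    return make_dataset(
        [make_record(i, sp, "ACGT") for i, sp in species_by_id.items()]
    )


class TestIntraspecific:
    def test_two_records(self):
        ds = dataset_of({"a1": "Genus alpha", "a2": "Genus alpha"})
        m = matrix_from_pairs(["a1", "a2"], {("a1", "a2"): 0.04})
        table = intraspecific_stats(m, ds).set_index("species")
        assert table.loc["Genus alpha", "theta"] == pytest.approx(0.04)
        assert table.loc["Genus alpha", "depth"] == pytest.approx(0.04)

    def test_three_records_mean_and_max(self):
        ds = dataset_of({f"a{i}": "Genus alpha" for i in range(3)})
        m = matrix_from_pairs(
            ["a0", "a1", "a2"],
            {("a0", "a1"): 0.01, ("a0", "a2"): 0.02, ("a1", "a2"): 0.03},
        )
        table = intraspecific_stats(m, ds).set_index("species")
        assert table.loc["Genus alpha", "theta"] == pytest.approx(0.02)
        assert table.loc["Genus alpha", "depth"] == pytest.approx(0.03)

    def test_singletons_excluded(self):
        ds = dataset_of({"a1": "Genus alpha", "b1": "Genus beta"})
        m = matrix_from_pairs(["a1", "b1"], {("a1", "b1"): 0.2})
        assert intraspecific_stats(m, ds).empty

    def test_undefined_pairs_skipped(self):
        ds = dataset_of({f"a{i}": "Genus alpha" for i in range(3)})
        m = matrix_from_pairs(
            ["a0", "a1", "a2"],
            {("a0", "a1"): 0.01, ("a0", "a2"): None, ("a1", "a2"): 0.03},
        )
        row = intraspecific_stats(m, ds).iloc[0]
        assert row["n_undefined"] == 1
        assert row["theta"] == pytest.approx(0.02)


class TestInterspecific:
    def test_two_singleton_species(self):
        ds = dataset_of({"a1": "Genus alpha", "b1": "Genus beta2"})
        ds = dataset_of({"a1": "Genus alpha", "b1": "Genus beta"})
        m = matrix_from_pairs(["a1", "b1"], {("a1", "b1"): 0.15})
        row = interspecific_stats(m, ds).iloc[0]
        assert row["theta_prime"] == pytest.approx(0.15)
        assert row["min_inter"] == pytest.approx(0.15)

    def test_mean_and_min_over_heterospecific_pairs(self):
        ds = dataset_of({"a1": "Genus alpha", "a2": "Genus alpha", "b1": "Genus beta"})
        m = matrix_from_pairs(
            ["a1", "a2", "b1"],
            {("a1", "a2"): 0.01, ("a1", "b1"): 0.10, ("a2", "b1"): 0.20},
        )
        row = interspecific_stats(m, ds).iloc[0]
        assert row["theta_prime"] == pytest.approx(0.15)
        assert row["min_inter"] == pytest.approx(0.10)
        assert row["n_pairs"] == 2  # the conspecific pair is not counted

    def test_cross_genus_pairs_never_counted(self):
        ds = dataset_of({"a1": "GenusA alpha", "b1": "GenusA beta",
                         "c1": "GenusB gamma", "c2": "GenusB delta"})
        m = matrix_from_pairs(
            ["a1", "b1", "c1", "c2"],
            {("a1", "b1"): 0.10, ("c1", "c2"): 0.30,
             ("a1", "c1"): 0.9, ("a1", "c2"): 0.9, ("b1", "c1"): 0.9, ("b1", "c2"): 0.9},
        )
        table = interspecific_stats(m, ds).set_index("genus")
        assert table.loc["GenusA", "theta_prime"] == pytest.approx(0.10)
        assert table.loc["GenusB", "theta_prime"] == pytest.approx(0.30)


class TestSummaryAndGap:
    def test_theta_never_exceeds_depth(self, sim_default, sim_default_matrix):
        _, dataset, _ = sim_default
        table = intraspecific_stats(sim_default_matrix, dataset)
        assert (table["theta"] <= table["depth"] + 1e-12).all()

    def test_duplicate_record_never_increases_depth(self):
        ds = dataset_of({f"a{i}": "Genus alpha" for i in range(3)})
        m = matrix_from_pairs(
            ["a0", "a1", "a2"],
            {("a0", "a1"): 0.02, ("a0", "a2"): 0.0, ("a1", "a2"): 0.02},
        )  # a2 duplicates a0
        base = matrix_from_pairs(["a0", "a1"], {("a0", "a1"): 0.02})
        ds_base = dataset_of({"a0": "Genus alpha", "a1": "Genus alpha"})
        depth_base = intraspecific_stats(base, ds_base).iloc[0]["depth"]
        depth_dup = intraspecific_stats(m, ds).iloc[0]["depth"]
        assert depth_dup <= depth_base + 1e-12

    def test_recovery_on_simulated_targets(self):
        """Recovered theta and inter-divergence hit the generator targets."""
        config = SimulationConfig(seed=11)
        thetas, inters = [], []
        for seed in range(11, 17):
            ds, _ = simulate_dataset(SimulationConfig(seed=seed))
            s = summarize_divergence(distance_matrix(ds), ds)
            thetas.append(s.theta[0])
            inters.append(s.avg_interspecific[0])
        for values, target in ((thetas, config.intra_divergence),
                               (inters, config.inter_divergence)):
            arr = np.array(values)
            se = arr.std(ddof=1) / math.sqrt(arr.size)
            assert abs(arr.mean() - target) <= 3 * se

    def test_gap_histograms_disjoint_on_gapped_data(self, sim_default, sim_default_matrix):
        _, dataset, _ = sim_default
        s = summarize_divergence(sim_default_matrix, dataset)
        hist = gap_histograms(s.per_species, s.per_genus, bin_width=0.05)
        assert not hist.overlap
        assert hist.min_interspecific_counts.sum() == len(s.per_species)

    def test_gap_histograms_overlap_when_species_collide(self, sim_overlap):
        _, dataset, _ = sim_overlap
        m = distance_matrix(dataset)
        s = summarize_divergence(m, dataset)
        hist = gap_histograms(s.per_species, s.per_genus, bin_width=0.05)
        assert hist.overlap

    def test_single_value_lands_in_right_bin(self):
        ds = dataset_of({"a1": "Genus alpha", "a2": "Genus alpha", "b1": "Genus beta"})
        m = matrix_from_pairs(
            ["a1", "a2", "b1"],
            {("a1", "a2"): 0.01, ("a1", "b1"): 0.17, ("a2", "b1"): 0.18},
        )
        s = summarize_divergence(m, ds)
        hist = gap_histograms(s.per_species, s.per_genus, bin_width=0.05)
        bin_idx = np.digitize(0.17, hist.bin_edges) - 1
        assert hist.min_interspecific_counts[bin_idx] == 1

    def test_nonpositive_bin_width_rejected(self, sim_default, sim_default_matrix):
        _, dataset, _ = sim_default
        s = summarize_divergence(sim_default_matrix, dataset)
        with pytest.raises(ValueError):
            gap_histograms(s.per_species, s.per_genus, bin_width=0.0)


class TestRatio:
    def _summary_with(self, min_inter, depth):
        ds = dataset_of({"a1": "Genus alpha", "a2": "Genus alpha", "b1": "Genus beta"})
        m = matrix_from_pairs(
            ["a1", "a2", "b1"],
            {("a1", "a2"): depth, ("a1", "b1"): min_inter, ("a2", "b1"): min_inter},
        )
        return summarize_divergence(m, ds)

    def test_wide_gap_ratio(self):
        # mean minimum inter 35.1% over mean depth 2.1% -> about 16.7
        assert ratio_gap_index(self._summary_with(0.351, 0.021)) == pytest.approx(
            16.71, abs=0.01
        )

    def test_equal_means_give_one(self):
        assert ratio_gap_index(self._summary_with(0.05, 0.05)) == pytest.approx(1.0)

    def test_division(self):
        assert ratio_gap_index(self._summary_with(0.178, 0.038)) == pytest.approx(
            0.178 / 0.038
        )

    def test_zero_depth_undefined(self):
        assert math.isnan(ratio_gap_index(self._summary_with(0.1, 0.0)))

    def test_nearest_congener_is_min_over_pairs(self):
        ds = dataset_of({"a1": "Genus alpha", "b1": "Genus beta", "c1": "Genus gamma"})
        m = matrix_from_pairs(
            ["a1", "b1", "c1"],
            {("a1", "b1"): 0.10, ("a1", "c1"): 0.30, ("b1", "c1"): 0.20},
        )
        near = nearest_congener_distances(m, ds)
        assert near["Genus alpha"] == pytest.approx(0.10)
        assert near["Genus gamma"] == pytest.approx(0.20)
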