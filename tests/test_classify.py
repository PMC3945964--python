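"""Identification decision rules and reference-library screening."""

import math

import numpy as np
import pytest

from barcode_eval.classify import (
    best_hit_identify,
    liberal_tree_identify,
    liberal_tree_threshold_identify,
    nj_tree,
    nn_identify,
    screen_unpublished,
)
from barcode_eval.datasets import build_evaluation_sets
from barcode_eval.distances import distance_matrix
from barcode_eval.simdata import SimulationConfig, simulate_dataset
from barcode_eval.tree import PhyloTree

from conftest import make_dataset, make_record, matrix_from_pairs


def panel(sim):
    _, dataset, _ = sim
    return dataset


class TestNearestNeighbour:
    def _setup(self):
        species = {"q": "Genus query", "a1": "Genus alpha", "a2": "Genus alpha",
                   "b1": "Genus beta"}
        ids = list(species)
        matrix = matrix_from_pairs(ids, {
            ("q", "a1"): 0.01, ("q", "a2"): 0.03, ("q", "b1"): 0.10,
            ("a1", "a2"): 0.02, ("a1", "b1"): 0.1, ("a2", "b1"): 0.1,
        })
        ref = make_dataset([make_record(i, s, "ACGT")
                            for i, s in species.items() if i != "q"])
        return matrix, ref

    def test_assigns_closest_species(self):
        matrix, ref = self._setup()
        call = nn_identify("q", matrix, ref)
        assert call.state == "assigned"
        assert call.assigned_species == "Genus alpha"
        assert call.support == pytest.approx(0.01)

    def test_equidistant_species_are_uncertain(self):
        matrix = matrix_from_pairs(
            ["q", "a1", "b1"],
            {("q", "a1"): 0.05, ("q", "b1"): 0.05, ("a1", "b1"): 0.1},
        )
        ref = make_dataset([make_record("a1", "Genus alpha", "ACGT"),
                            make_record("b1", "Genus beta", "ACGT")])
        call = nn_identify("q", matrix, ref)
        assert call.state == "uncertain"
        assert call.tied_species == ("Genus alpha", "Genus beta")

    def test_all_undefined_is_no_hit(self):
        matrix = matrix_from_pairs(
            ["q", "a1"], {("q", "a1"): None, }
        )
        ref = make_dataset([make_record("a1", "Genus alpha", "ACGT")])
        assert nn_identify("q", matrix, ref).state == "no-hit"

    def test_duplicated_reference_assigns_its_species(self, sim_default, sim_default_matrix):
        dataset = panel(sim_default)
        rec = dataset.records[0]
        call = nn_identify(rec.id, sim_default_matrix, dataset)
        assert call.state == "assigned"
        assert call.assigned_species == rec.species

    def test_matches_row_argmin_oracle(self, sim_default, sim_default_matrix):
        dataset = panel(sim_default)
        m = sim_default_matrix
        species = dataset.species_of()
        for rec in dataset.records[:40]:
            call = nn_identify(rec.id, m, dataset)
            qi = m.index_of(rec.id)
            row = [
                (round(m.values[qi, m.index_of(r.id)], 10), r.id)
                for r in dataset
                if r.id != rec.id and not math.isnan(m.values[qi, m.index_of(r.id)])
            ]
            best = min(d for d, _ in row)
            expected = {species[rid] for d, rid in row if d == best}
            if len(expected) == 1:
                assert call.assigned_species in expected
            else:
                assert call.state == "uncertain"


class TestBestHit:
    def _refs(self):
        seq_a = "ACGTTGCAAGGCTTACGGAT" * 4
        seq_b = "TTGGCCAAGGTTCCGGAATC" * 4
        return make_dataset([
            make_record("a1", "Genus alpha", seq_a),
            make_record("b1", "Genus beta", seq_b),
        ]), seq_a, seq_b

    def test_identical_to_one_reference(self):
        ref, seq_a, _ = self._refs()
        query = make_record("q", "Genus alpha", seq_a)
        call = best_hit_identify(query, ref)
        assert call.state == "assigned"
        assert call.assigned_species == "Genus alpha"

    def test_two_identical_references_uncertain(self):
        seq = "ACGTTGCAAGGCTTACGGAT" * 4
        ref = make_dataset([
            make_record("a1", "Genus alpha", seq),
            make_record("b1", "Genus beta", seq),
        ])
        call = best_hit_identify(make_record("q", "Genus alpha", seq), ref)
        assert call.state == "uncertain"
        assert set(call.tied_species) == {"Genus alpha", "Genus beta"}

    def test_identity_floor_produces_no_hit(self):
        ref, seq_a, _ = self._refs()
        rng = np.random.default_rng(0)
        bases = "ACGT"
        noisy = "".join(
            bases[(bases.index(c) + 1 + rng.integers(0, 3)) % 4]
            if rng.random() < 0.35 else c
            for c in seq_a
        )
        call = best_hit_identify(make_record("q", "Genus alpha", noisy), ref,
                                 identity_floor=0.95)
        assert call.state == "no-hit"

    def test_consistent_with_nn_on_clean_panels(self):
        dataset, _ = simulate_dataset(
            SimulationConfig(seed=6, n_genera=2, species_per_genus=3,
                             records_per_species=2, seq_length=200)
        )
        matrix = distance_matrix(dataset)
        for query in dataset.records[:6]:
            nn = nn_identify(query.id, matrix, dataset)
            bh = best_hit_identify(query, dataset, identity_floor=0.0,
                                   evalue_cutoff=float("inf"))
            if nn.state == "assigned" and bh.state == "assigned":
                assert nn.assigned_species == bh.assigned_species


class TestLiberalTree:
    def test_sister_to_monospecific_pair(self):
        tree = PhyloTree.from_newick("((x1:0.01,x2:0.01):0.05,q:0.05);")
        smap = {"x1": "Genus ex", "x2": "Genus ex"}
        call = liberal_tree_identify(tree, "q", smap)
        assert call.state == "assigned"
        assert call.assigned_species == "Genus ex"

    def test_nested_within_monospecific_clade(self):
        tree = PhyloTree.from_newick("((x1:0.01,q:0.01):0.05,x2:0.02);")
        smap = {"x1": "Genus ex", "x2": "Genus ex"}
        assert liberal_tree_identify(tree, "q", smap).state == "assigned"

    def test_mixed_sibling_clade_uncertain(self):
        tree = PhyloTree.from_newick("((x1:0.01,y1:0.01):0.05,q:0.05);")
        smap = {"x1": "Genus ex", "y1": "Genus why"}
        call = liberal_tree_identify(tree, "q", smap)
        assert call.state == "uncertain"

    def test_conflicting_monospecific_directions_uncertain(self):
        tree = PhyloTree.from_newick("((x1:0.01,q:0.01):0.05,y1:0.02);")
        smap = {"x1": "Genus ex", "y1": "Genus why"}
        call = liberal_tree_identify(tree, "q", smap)
        assert call.state == "uncertain"
        assert call.tied_species == ("Genus ex", "Genus why")

    def test_missing_query_rejected(self):
        tree = PhyloTree.from_newick("((x1:0.01,x2:0.01):0.05,x3:0.05);")
        with pytest.raises(KeyError):
            liberal_tree_identify(tree, "nope", {"x1": "A a", "x2": "A a"})

    def test_full_assignment_on_monophyletic_references(self, sim_default, sim_default_matrix):
        dataset = panel(sim_default)
        tree = nj_tree(sim_default_matrix)
        species = dataset.species_of()
        for rec in dataset:
            smap = {k: v for k, v in species.items() if k != rec.id}
            call = liberal_tree_identify(tree, rec.id, smap)
            assert call.state == "assigned"
            assert call.assigned_species == rec.species


class TestTreeThreshold:
    def _fixture(self):
        tree = PhyloTree.from_newick("((x1:0.01,x2:0.01):0.05,q:0.05);")
        smap = {"x1": "Genus ex", "x2": "Genus ex"}
        return tree, smap

    def test_threshold_veto(self):
        tree, smap = self._fixture()
        matrix = matrix_from_pairs(
            ["q", "x1", "x2"],
            {("q", "x1"): 0.20, ("q", "x2"): 0.22, ("x1", "x2"): 0.01},
        )
        call = liberal_tree_threshold_identify(tree, "q", smap, matrix, 0.0613)
        assert call.state == "uncertain"

    def test_within_threshold_assigned(self):
        tree, smap = self._fixture()
        matrix = matrix_from_pairs(
            ["q", "x1", "x2"],
            {("q", "x1"): 0.01, ("q", "x2"): 0.02, ("x1", "x2"): 0.01},
        )
        call = liberal_tree_threshold_identify(tree, "q", smap, matrix, 0.0613)
        assert call.state == "assigned"

    def test_composition_of_tree_and_distance_rules(self, sim_default, sim_default_matrix):
        dataset = panel(sim_default)
        tree = nj_tree(sim_default_matrix)
        m = sim_default_matrix
        species = dataset.species_of()
        threshold = 0.05
        for rec in dataset.records[:20]:
            smap = {k: v for k, v in species.items() if k != rec.id}
            plain = liberal_tree_identify(tree, rec.id, smap)
            combo = liberal_tree_threshold_identify(tree, rec.id, smap, m, threshold)
            qi = m.index_of(rec.id)
            nearest = min(
                m.values[qi, m.index_of(r)] for r in smap if r in m.ids
            )
            if plain.state == "assigned" and nearest < threshold:
                assert combo.state == "assigned"
                assert combo.assigned_species == plain.assigned_species
            else:
                assert combo.state != "assigned"


class TestScreening:
    def _dataset(self, statuses_species):
        seq = "ACGT" * 10
        return make_dataset([
            make_record(i, sp, seq, status=st)
            for i, (sp, st) in statuses_species.items()
        ])

    def test_sister_to_published_conspecific_screened_in(self):
        tree = PhyloTree.from_newick("((u:0.01,p1:0.01):0.05,p2:0.05);")
        ds = self._dataset({
            "u": ("Genus ex", "unpublished"),
            "p1": ("Genus ex", "published"),
            "p2": ("Genus why", "published"),
        })
        screened, report = screen_unpublished(tree, ds)
        assert screened.get("u").status == "screened-in"
        assert report.iloc[0]["status"] == "screened-in"

    def test_nested_among_other_species_screened_out(self):
        tree = PhyloTree.from_newick("((u:0.01,p2:0.01):0.05,p1:0.05);")
        ds = self._dataset({
            "u": ("Genus ex", "unpublished"),
            "p1": ("Genus ex", "published"),
            "p2": ("Genus why", "published"),
        })
        screened, _ = screen_unpublished(tree, ds)
        assert screened.get("u").status == "screened-out"

    def test_no_reliable_conspecific_screened_out_with_reason(self):
        tree = PhyloTree.from_newick("((u:0.01,p1:0.01):0.05,p2:0.05);")
        ds = self._dataset({
            "u": ("Genus lost", "unpublished"),
            "p1": ("Genus ex", "published"),
            "p2": ("Genus why", "published"),
        })
        screened, report = screen_unpublished(tree, ds)
        assert screened.get("u").status == "screened-out"
        assert report.iloc[0]["reason"] == "no reliable conspecific"

    def test_reliable_statuses_never_change(self):
        dataset, truth = simulate_dataset(
            SimulationConfig(seed=8, mislabel_fraction=0.1)
        )
        tree = nj_tree(distance_matrix(dataset))
        screened, _ = screen_unpublished(tree, dataset)
        for before, after in zip(dataset, screened):
            if before.status != "unpublished":
                assert after.status == before.status

    def test_mislabels_rejected_on_simulated_data(self):
        dataset, truth = simulate_dataset(
            SimulationConfig(seed=12, mislabel_fraction=0.1)
        )
        tree = nj_tree(distance_matrix(dataset))
        screened, _ = screen_unpublished(tree, dataset)
        mislabeled = set(truth.loc[truth.mislabeled, "id"])
        flagged = {r.id for r in screened if r.status == "screened-out"}
        assert len(mislabeled & flagged) >= 0.8 * len(mislabeled)


class TestNJWrapper:
    def test_undefined_distances_imputed_as_max(self):
        matrix = matrix_from_pairs(
            ["a", "b", "c", "d"],
            {("a", "b"): 0.1, ("a", "c"): 0.4, ("a", "d"): None,
             ("b", "c"): 0.4, ("b", "d"): 0.45, ("c", "d"): 0.2},
        )
        tree = nj_tree(matrix)
        assert tree.leaf_names == {"a", "b", "c", "d"}

    def test_too_few_records_rejected(self):
        matrix = matrix_from_pairs(["a", "b"], {("a", "b"): 0.1})
        with pytest.raises(ValueError):
            nj_tree(matrix)
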