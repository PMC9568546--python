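"""Colony genotyping, mutation grouping, clone relations, and fractions."""

import numpy as np
import pytest

from clonoscope import (
    GenotypeCallConfig,
    estimate_fractions,
    genotype_colonies,
    group_mutations,
    infer_relations,
    render_composition,
    simulate_colonies_from_tree,
)
from clonoscope.model import ABSENT, AMBIGUOUS, PRESENT, ColonyGenotypeMatrix, Variant
from clonoscope.simulate import random_clone_tree


def _matrix(vafs, depths, variants=None, animal="m"):
    vafs = np.asarray(vafs, dtype=float)
    n, m = vafs.shape
    if variants is None:
        variants = [Variant("chr1", 1000 * (j + 1), "A", "G") for j in range(m)]
    colonies = [(f"c{i + 1}", "HSC" if i % 2 == 0 else "MPP") for i in range(n)]
    return ColonyGenotypeMatrix(
        animal_id=animal, colonies=colonies, variants=variants,
        vaf=vafs, depth=np.asarray(depths, dtype=int),
    )


class TestGenotypeColonies:
    @pytest.mark.parametrize(
        "vaf,depth,expected",
        [
            (0.48, 1000, PRESENT),
            (0.01, 1000, ABSENT),
            (0.45, 5, AMBIGUOUS),  # below min_depth
            (0.85, 1000, AMBIGUOUS),  # above het_high
            (0.30, 20, PRESENT),  # inclusive boundaries
            (0.70, 20, PRESENT),
        ],
    )
    def test_call_rules(self, vaf, depth, expected):
        mat = _matrix([[vaf]], [[depth]])
        genotype_colonies(mat)
        assert mat.calls[0, 0] == expected

    def test_missing_vaf_is_ambiguous(self):
        mat = _matrix([[np.nan]], [[1000]])
        genotype_colonies(mat)
        assert mat.calls[0, 0] == AMBIGUOUS


class TestGroupMutations:
    def test_mouse33_pattern_groups(self, reference_fixtures):
        mat = genotype_colonies(reference_fixtures.mouse33_colonies)
        groups = group_mutations(mat)
        partitions = {frozenset(v.pos for v in g.mutations) for g in groups}
        assert partitions == {
            frozenset({95_432_868}),
            frozenset({79_076_783}),
            frozenset({48_036_757}),
        }

    def test_mouse85_four_clones(self, reference_fixtures):
        mat = genotype_colonies(reference_fixtures.mouse85_colonies)
        groups = group_mutations(mat)
        sizes = sorted(len(g.mutations) for g in groups)
        assert sizes == [1, 2, 3, 4]

    def test_no_presence_keeps_singleton_groups(self):
        mat = _matrix(np.zeros((5, 3)), np.full((5, 3), 100))
        genotype_colonies(mat)
        groups = group_mutations(mat)
        assert len(groups) == 3
        assert all(g.support == frozenset() for g in groups)

    def test_partition_property(self, reference_fixtures):
        mat = genotype_colonies(reference_fixtures.mouse85_colonies)
        groups = group_mutations(mat)
        all_mutations = [v.key for g in groups for v in g.mutations]
        assert sorted(all_mutations) == sorted(v.key for v in mat.variants)


class TestInferRelations:
    def test_mouse33_nesting_and_exclusion(self, reference_fixtures):
        mat = genotype_colonies(reference_fixtures.mouse33_colonies)
        groups = group_mutations(mat)
        model = infer_relations(groups, mat)
        by_pos = {g.mutations[0].pos: g.group_id for g in groups}
        nell2, eif3i, rik = by_pos[95_432_868], by_pos[79_076_783], by_pos[48_036_757]
        assert (eif3i, nell2) in model.nested
        assert (rik, nell2) in model.nested
        assert frozenset((eif3i, rik)) in model.exclusive
        assert model.conflicts == []

    def test_mouse85_all_exclusive(self, reference_fixtures):
        mat = genotype_colonies(reference_fixtures.mouse85_colonies)
        groups = group_mutations(mat)
        model = infer_relations(groups, mat)
        assert model.nested == set()
        assert len(model.exclusive) == 6  # all 4-choose-2 pairs
        assert model.conflicts == []

    def test_crossing_supports_recorded_as_conflict(self):
        # supports {c1,c2} and {c2,c3} violate the tree assumption
        vafs = [[0.5, 0.0], [0.5, 0.5], [0.0, 0.5], [0.0, 0.0]]
        mat = _matrix(vafs, np.full((4, 2), 100))
        genotype_colonies(mat)
        groups = group_mutations(mat)
        model = infer_relations(groups, mat)
        assert len(model.conflicts) == 1

    def test_recovers_random_trees_noise_free(self, rng):
        """Exact partition and relation recovery on 100 random clone trees."""
        ok = 0
        for _ in range(100):
            tree = random_clone_tree(rng, int(rng.integers(1, 6)))
            mat = simulate_colonies_from_tree(tree, rng, n_colonies=60)
            genotype_colonies(mat)
            groups = group_mutations(mat)
            part = {frozenset(v.key for v in g.mutations) for g in groups}
            if part != set(tree.expected_partition()):
                continue
            model = infer_relations(groups, mat)
            gid_to_clone = {}
            for g in groups:
                keys = frozenset(v.key for v in g.mutations)
                for cid, node in tree.nodes.items():
                    if keys == frozenset(v.key for v in node.mutations):
                        gid_to_clone[g.group_id] = cid
            nested = {(gid_to_clone[a], gid_to_clone[b]) for a, b in model.nested}
            excl = {
                frozenset(gid_to_clone[x] for x in pair) for pair in model.exclusive
            }
            if (
                nested == tree.expected_nested()
                and excl == tree.expected_exclusive()
                and not model.conflicts
            ):
                ok += 1
        assert ok == 100

    def test_nesting_is_a_forest(self, rng):
        """On conflict-free input each group has at most one minimal parent."""
        for _ in range(20):
            tree = random_clone_tree(rng, int(rng.integers(2, 7)))
            mat = simulate_colonies_from_tree(tree, rng, n_colonies=80)
            genotype_colonies(mat)
            groups = group_mutations(mat)
            model = infer_relations(groups, mat)
            assert not model.conflicts
            # no cycles: nested is a strict partial order on supports
            for child, parent in model.nested:
                assert (parent, child) not in model.nested
            for g in groups:
                model.minimal_parent(g.group_id)  # must not raise


class TestEstimateFractions:
    def test_mouse33_fractions_and_tree(self, reference_fixtures):
        fx = reference_fixtures
        mat = genotype_colonies(fx.mouse33_colonies)
        groups = group_mutations(mat)
        model = infer_relations(groups, mat)
        estimate_fractions(model, fx.mouse33_bulk_bm)
        fracs = sorted(round(f, 3) for f in model.fractions.values())
        assert fracs == [0.24, 0.28, 0.58]
        report = render_composition(model)
        assert report["delivered_fraction"] == pytest.approx(0.58)
        assert report["remainder"] == pytest.approx(0.42)
        (root,) = report["clones"]
        assert root["fraction_bm"] == pytest.approx(0.58)
        child_fracs = sorted(c["fraction_bm"] for c in root["children"])
        assert child_fracs == pytest.approx([0.24, 0.28])

    def test_mouse85_delivered_fraction(self, reference_fixtures):
        fx = reference_fixtures
        mat = genotype_colonies(fx.mouse85_colonies)
        groups = group_mutations(mat)
        model = infer_relations(groups, mat)
        estimate_fractions(model, fx.mouse85_bulk_bm)
        report = render_composition(model)
        assert report["delivered_fraction"] == pytest.approx(0.80)
        assert report["remainder"] == pytest.approx(0.20)
        assert len(report["clones"]) == 4

    def test_single_clone_full_marrow_boundary(self):
        vafs = [[0.5]] * 4
        mat = _matrix(vafs, np.full((4, 1), 100))
        genotype_colonies(mat)
        groups = group_mutations(mat)
        model = infer_relations(groups, mat)
        estimate_fractions(model, {"chr1:1000:A>G": 0.5})
        assert model.fractions["G1"] == pytest.approx(1.0)
        assert render_composition(model)["remainder"] == pytest.approx(0.0)

    def test_missing_bm_observation_flagged(self):
        mat = _matrix([[0.5]] * 4, np.full((4, 1), 100))
        genotype_colonies(mat)
        groups = group_mutations(mat)
        model = infer_relations(groups, mat)
        estimate_fractions(model, {})
        assert model.fractions["G1"] is None

    def test_empty_model_remainder_one(self):
        mat = _matrix(np.zeros((0, 0)), np.zeros((0, 0)))
        genotype_colonies(mat)
        model = infer_relations(group_mutations(mat), mat)
        estimate_fractions(model, {})
        assert render_composition(model)["remainder"] == pytest.approx(1.0)

    def test_fraction_consistency_under_read_resampling(self, reference_fixtures, rng):
        """Binomial resampling at 30,000x keeps fractions within 0.02 of truth."""
        fx = reference_fixtures
        mat = genotype_colonies(fx.mouse33_colonies)
        groups = group_mutations(mat)
        depth = 30_000
        ok = total = 0
        for _ in range(200):
            noisy = {
                k: rng.binomial(depth, v) / depth
                for k, v in fx.mouse33_bulk_bm.items()
            }
            model = infer_relations(groups, mat)
            estimate_fractions(model, noisy)
            truth = infer_relations(groups, mat)
            estimate_fractions(truth, fx.mouse33_bulk_bm)
            for gid, f in model.fractions.items():
                total += 1
                ok += abs(f - truth.fractions[gid]) <= 0.02
        assert ok / total >= 0.95
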