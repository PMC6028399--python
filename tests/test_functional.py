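"""Gower distance, UPGMA dendrogram, and occupancy-weighted FD."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scalediv as sd
from scalediv.synthetic import DIET_AXES, FORAGING_AXES


def _trait_row(species_id, mass, diet_axis=0, forage_axis=0):
    row = {"species_id": species_id, "body_mass_g": mass}
    for i, ax in enumerate(DIET_AXES):
        row[ax] = 1.0 if i == diet_axis else 0.0
    for i, ax in enumerate(FORAGING_AXES):
        row[ax] = 1.0 if i == forage_axis else 0.0
    return row


class TestGower:
    def test_identical_rows_distance_zero(self):
        t = pd.DataFrame([_trait_row("A", 10), _trait_row("B", 10), _trait_row("C", 20)])
        d = sd.gower_distance(t)
        assert d.loc["A", "B"] == 0.0
        assert np.allclose(np.diag(d), 0)
        assert np.allclose(d, d.T)

    def test_maximally_different_distance_one(self):
        # differ by the full range on every informative axis
        t = pd.DataFrame([_trait_row("A", 1, 0, 0), _trait_row("B", 1000, 1, 1)])
        d = sd.gower_distance(t)
        assert d.loc["A", "B"] == pytest.approx(1.0)

    def test_hand_weighted_formula(self):
        # masses differ by half the pool range, diet/foraging identical between
        # A and B (C keeps every axis informative):
        # d = (1 * 0.5) / (1 + 7/7 + 7/7) = 0.5 / 3
        simplex_ab = [0.3, 0.1, 0.1, 0.1, 0.1, 0.2, 0.1]
        simplex_c = [0.2, 0.2, 0.05, 0.15, 0.05, 0.3, 0.05]
        rows = []
        for sp, mass, simplex in (("A", 10, simplex_ab), ("B", 20, simplex_ab), ("C", 30, simplex_c)):
            row = {"species_id": sp, "body_mass_g": mass}
            row.update(dict(zip(DIET_AXES, simplex)))
            row.update(dict(zip(FORAGING_AXES, simplex)))
            rows.append(row)
        d = sd.gower_distance(pd.DataFrame(rows), log_mass=False)
        assert d.loc["A", "B"] == pytest.approx(0.5 / 3)

    def test_zero_range_axis_dropped_with_warning(self):
        t = pd.DataFrame([_trait_row("A", 10, 0, 0), _trait_row("B", 20, 1, 0)])
        # all foraging axes identical -> those axes have zero range
        with pytest.warns(UserWarning, match="zero range"):
            d = sd.gower_distance(t, log_mass=False)
        assert 0 <= d.loc["A", "B"] <= 1

    def test_entries_in_unit_interval(self, small_traits):
        d = sd.gower_distance(small_traits)
        assert ((d.values >= 0) & (d.values <= 1 + 1e-12)).all()


class TestUpgma:
    def test_two_leaves(self):
        d = pd.DataFrame([[0, 3], [3, 0]], index=list("AB"), columns=list("AB"))
        tree = sd.upgma_tree(d)
        # single merge at ultrametric height 1.5, terminal branches 1.5
        assert tree.heights.max() == pytest.approx(1.5)
        assert sorted(tree.length[:-1]) == pytest.approx([1.5, 1.5])

    def test_three_leaf_hand_case(self):
        d = pd.DataFrame(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]], index=list("ABC"), columns=list("ABC")
        )
        tree = sd.upgma_tree(d)
        internal = sorted(tree.heights[tree.heights > 0])
        assert internal == pytest.approx([1.0, 2.0])
        assert tree.is_ultrametric()
        # internal branch (AB) length = 2 - 1 = 1
        ab = [i for i in range(len(tree.parent)) if len(tree.leafsets[i]) == 2][0]
        assert tree.length[ab] == pytest.approx(1.0)

    def test_ultrametric_fixed_point(self):
        d = pd.DataFrame(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]], index=list("ABC"), columns=list("ABC")
        )
        tree = sd.upgma_tree(d)
        coph = tree.cophenetic_matrix().loc[list("ABC"), list("ABC")]
        np.testing.assert_allclose(coph.values, d.values, atol=1e-12)

    def test_nan_rejected(self):
        d = pd.DataFrame([[0, np.nan], [np.nan, 0]], index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError):
            sd.upgma_tree(d)

    def test_newick_round_trip(self, small_traits):
        tree = sd.upgma_tree(sd.gower_distance(small_traits))
        tree2 = sd.FunctionalDendrogram.from_newick(tree.to_newick())
        assert sorted(tree2.leaf_names) == sorted(tree.leaf_names)
        c1 = tree.cophenetic_matrix().loc[tree.leaf_names, tree.leaf_names]
        c2 = tree2.cophenetic_matrix().loc[tree.leaf_names, tree.leaf_names]
        np.testing.assert_allclose(c1.values, c2.values, rtol=1e-6)


class TestCopheneticCorrelation:
    def test_ultrametric_input_gives_one(self):
        d = pd.DataFrame(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]], index=list("ABC"), columns=list("ABC")
        )
        tree = sd.upgma_tree(d)
        assert sd.cophenetic_correlation(tree, d) == pytest.approx(1.0)

    def test_matches_brute_force_on_four_species(self):
        rng = np.random.default_rng(3)
        m = rng.uniform(0.1, 1.0, size=(4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        d = pd.DataFrame(m, index=list("ABCD"), columns=list("ABCD"))
        tree = sd.upgma_tree(d)
        coph = tree.cophenetic_matrix().loc[list("ABCD"), list("ABCD")].values
        pairs = list(itertools.combinations(range(4), 2))
        x = np.array([m[i, j] for i, j in pairs])
        y = np.array([coph[i, j] for i, j in pairs])
        expected = np.corrcoef(x, y)[0, 1]
        assert sd.cophenetic_correlation(tree, d) == pytest.approx(expected)
        assert -1 <= expected <= 1

    def test_too_few_species(self, toy_tree):
        d = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError):
            sd.cophenetic_correlation(toy_tree, d)


class TestFunctionalDiversity:
    def test_all_present_equals_total_branch_length(self, toy_tree):
        assert sd.functional_diversity(toy_tree, {"A": 1, "B": 1, "C": 1}) == pytest.approx(5.0)
        assert toy_tree.total_branch_length == pytest.approx(5.0)

    def test_hand_weighted_case(self, toy_tree):
        # 0.5 + 0.5 + 1*(1 - 0.25) + 2 = 3.75
        assert sd.functional_diversity(toy_tree, {"A": 0.5, "B": 0.5, "C": 1}) == pytest.approx(3.75)

    def test_pruning_collapse(self, toy_tree):
        assert sd.functional_diversity(toy_tree, {"A": 0, "B": 0, "C": 1}) == pytest.approx(2.0)

    def test_all_zero_warns(self, toy_tree):
        with pytest.warns(UserWarning):
            assert sd.functional_diversity(toy_tree, {"A": 0, "B": 0, "C": 0}) == 0.0

    def test_invalid_psi(self, toy_tree):
        with pytest.raises(ValueError):
            sd.functional_diversity(toy_tree, {"A": 1.2, "B": 0, "C": 0})

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        psi=st.lists(st.floats(0, 1), min_size=3, max_size=3),
        bump=st.floats(0.01, 1.0),
        which=st.integers(0, 2),
    )
    def test_monotone_in_each_psi(self, toy_tree, psi, bump, which):
        before = sd.functional_diversity(toy_tree, np.array(psi)) if any(psi) else 0.0
        psi2 = list(psi)
        psi2[which] = min(1.0, psi2[which] + bump)
        after = sd.functional_diversity(toy_tree, np.array(psi2))
        assert after >= before - 1e-12
        assert after <= toy_tree.total_branch_length + 1e-12

    def test_internal_weight_bounds(self, small_traits):
        tree = sd.upgma_tree(sd.gower_distance(small_traits))
        rng = np.random.default_rng(0)
        psi = rng.uniform(0, 1, tree.n_leaves)
        for i in range(len(tree.parent)):
            ls = tree.leafsets[i]
            if len(ls) < 2 or tree.parent[i] == -1:
                continue
            w = 1 - np.prod(1 - psi[ls])
            assert psi[ls].max() - 1e-12 <= w <= min(1.0, psi[ls].sum()) + 1e-12

    def test_binary_psi_equals_spanned_branch_length(self, small_traits):
        # classic dendrogram FD: sum of branch lengths on root-to-leaf paths of
        # present species, computed by brute-force path union
        traits = small_traits.iloc[:6]
        tree = sd.upgma_tree(sd.gower_distance(traits))
        name_to_leaf = {n: i for i, n in enumerate(tree.leaf_names)}
        for mask in itertools.product([0, 1], repeat=6):
            present = {tree.leaf_names[i] for i in range(6) if mask[i]}
            if not present:
                continue
            spanned = 0.0
            for i in range(len(tree.parent)):
                if tree.parent[i] == -1:
                    continue
                leaves = {tree.leaf_names[j] for j in tree.leafsets[i]}
                if leaves & present:
                    spanned += tree.length[i]
            psi = np.array([1.0 if tree.leaf_names[i] in present else 0.0 for i in range(6)])
            assert sd.functional_diversity(tree, psi) == pytest.approx(spanned)
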