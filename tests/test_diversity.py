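"""TD, the persistence/colonization/extinction calculus, and the Sorensen partition."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scalediv as sd


class TestTaxonomicDiversity:
    def test_sum(self):
        assert sd.taxonomic_diversity([0.2, 0.3, 0.5]) == pytest.approx(1.0)
        assert sd.taxonomic_diversity(np.ones(7)) == 7
        assert sd.taxonomic_diversity(np.zeros(3)) == 0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            sd.taxonomic_diversity([0.5, 1.2])


class TestComponents:
    def test_persistence(self):
        a, ai = sd.persistence_component([1, 1, 1], [1, 1, 1])
        assert a == 3
        a, ai = sd.persistence_component([1, 0.5], [1, 0.4])
        assert a == pytest.approx(1.2)
        assert ai == pytest.approx([1.0, 0.2])
        a, _ = sd.persistence_component([0.0], [0.9])
        assert a == 0

    def test_colonization_single_step(self):
        series = np.array([[0.1, 0.9]])
        b, bi = sd.colonization_component(series, 1)
        assert b == pytest.approx(0.9 * 0.9)

    def test_colonization_eligibility(self):
        # psi at base 0.9 > 0.8 -> not a first colonization
        series = np.array([[0.9, 0.95]])
        b, _ = sd.colonization_component(series, 1)
        assert b == 0.0

    def test_colonization_two_terms(self):
        series = np.array([[0.1, 0.5, 0.9]])
        b, _ = sd.colonization_component(series, 2)
        assert b == pytest.approx(0.5 * 0.9 + 0.9 * 0.5)

    def test_extinction_single_step(self):
        series = np.array([[0.9, 0.1]])
        c, _ = sd.extinction_component(series, 1)
        assert c == pytest.approx(0.9 * 0.9)

    def test_extinction_recolonizer_excluded(self):
        # psi = 0.95 after m -> the species recolonized; not counted
        series = np.array([[0.9, 0.1, 0.95]])
        c, _ = sd.extinction_component(series, 1)
        assert c == 0.0

    def test_extinction_two_terms(self):
        series = np.array([[0.9, 0.5, 0.1]])
        c, _ = sd.extinction_component(series, 2)
        assert c == pytest.approx(0.9 * 0.5 + 0.5 * 0.9)

    def test_bad_m_index(self):
        series = np.array([[0.1, 0.2]])
        with pytest.raises(ValueError):
            sd.colonization_component(series, 0)
        with pytest.raises(ValueError):
            sd.extinction_component(series, 2)


class TestSorensenPartition:
    def test_hand_arithmetic(self):
        assert sd.sorensen_dissimilarity(2, 1, 1) == pytest.approx(1 / 3)
        assert sd.nestedness_component(1, 2, 0) == pytest.approx(0.5)
        assert sd.turnover_component(1, 1, 1) == pytest.approx(0.5)

    def test_edge_cases(self):
        assert sd.sorensen_dissimilarity(3, 0, 0) == 0.0
        assert sd.sorensen_dissimilarity(0, 1, 1) == 1.0
        assert sd.nestedness_component(1, 2, 2) == 0.0  # b == c
        assert sd.nestedness_component(0, 2, 1) == 0.0  # a == 0
        assert sd.turnover_component(5, 2, 0) == 0.0  # min(b, c) == 0
        with pytest.warns(UserWarning):
            assert np.isnan(sd.sorensen_dissimilarity(0, 0, 0))

    def test_partition_identity_example(self):
        dis = sd.sorensen_dissimilarity(1, 2, 0)
        assert sd.nestedness_component(1, 2, 0) + sd.turnover_component(1, 2, 0) == pytest.approx(dis)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        a=st.floats(0, 100), b=st.floats(0, 100), c=st.floats(0, 100)
    )
    def test_partition_identity_property(self, a, b, c):
        if 2 * a + b + c == 0:
            return
        dis = sd.sorensen_dissimilarity(a, b, c)
        nes = sd.nestedness_component(a, b, c)
        tur = sd.turnover_component(a, b, c)
        assert 0 <= dis <= 1 and 0 <= nes <= 1 and 0 <= tur <= 1
        assert nes + tur == pytest.approx(dis, abs=1e-12)

    def test_contributions(self):
        assert sd.component_contributions(0.5, 0.5, 0.0) == pytest.approx((1.0, 0.0))
        assert sd.component_contributions(0.5, 0.0, 0.5) == pytest.approx((0.0, 1.0))
        assert sd.component_contributions(0.4, 0.1, 0.3) == pytest.approx((0.25, 0.75))
        with pytest.warns(UserWarning):
            nesc, turc = sd.component_contributions(0.0, 0.0, 0.0)
        assert np.isnan(nesc) and np.isnan(turc)


class TestBinaryReduction:
    """With psi in {0,1} and thresholds inactive, the calculus is set arithmetic."""

    def test_two_year_binary_equals_set_sorensen(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            n = rng.integers(2, 9)
            base = rng.integers(0, 2, n).astype(float)
            late = rng.integers(0, 2, n).astype(float)
            series = np.column_stack([base, late])
            a, _ = sd.persistence_component(base, late)
            b, _ = sd.colonization_component(series, 1, threshold=1.0)
            c, _ = sd.extinction_component(series, 1, threshold=1.0)
            s_base = {i for i in range(n) if base[i]}
            s_late = {i for i in range(n) if late[i]}
            assert a == len(s_base & s_late)
            assert b == len(s_late - s_base)
            assert c == len(s_base - s_late)
            if s_base | s_late:
                expected = (b + c) / (2 * a + b + c)
                assert sd.sorensen_dissimilarity(a, b, c) == pytest.approx(expected)


class TestFunctionalComponents:
    def test_all_persist(self, toy_tree):
        d, e, f = sd.functional_components(toy_tree, np.ones(3), np.zeros(3), np.zeros(3))
        assert d == pytest.approx(toy_tree.total_branch_length)
        assert e == 0.0 and f == 0.0

    def test_single_colonizer_path_length(self, toy_tree):
        # only C colonizes: e = C's root-to-leaf path = 2
        b_i = np.array([0.0, 0.0, 1.0])
        _, e, _ = sd.functional_components(toy_tree, np.zeros(3), b_i, np.zeros(3))
        assert e == pytest.approx(2.0)

    def test_reuses_weighted_fd(self, toy_tree):
        d, _, _ = sd.functional_components(
            toy_tree, np.array([0.5, 0.5, 1.0]), np.zeros(3), np.zeros(3)
        )
        assert d == pytest.approx(3.75)

    def test_clipping_logged(self, toy_tree):
        with pytest.warns(UserWarning, match="clipped"):
            sd.functional_components(toy_tree, np.array([0.5, 0.5, 1.3]), np.zeros(3), np.zeros(3))


class TestTraitSummaries:
    def test_weighted_mass(self):
        assert sd.weighted_mean_body_mass([1, 1], [10, 30]) == 20
        assert sd.weighted_mean_body_mass([1, 0], [10, 30]) == 10
        assert sd.weighted_mean_body_mass([0.5, 1], [10, 30]) == pytest.approx(35 / 1.5)
        with pytest.warns(UserWarning):
            assert np.isnan(sd.weighted_mean_body_mass([0, 0], [10, 30]))

    def test_guild_prevalence(self):
        block = np.array([[1.0] + [0.0] * 6, [0.0, 1.0] + [0.0] * 5])
        prev = sd.guild_prevalence([1, 1], block)
        assert prev[0] == pytest.approx(0.5)
        assert prev.sum() == pytest.approx(1.0)
        prev = sd.guild_prevalence([1, 0], block)
        np.testing.assert_allclose(prev, block[0])
        prev = sd.guild_prevalence([0.5, 1], block)
        assert prev[0] == pytest.approx(0.5 / 1.5)


class TestGlobalSeries:
    def test_counting(self):
        ext = pd.DataFrame({"species_id": ["a", "b"], "status": ["Extinct"] * 2,
                            "extinction_year": [1975, 1980]})
        s = sd.global_td_series(ext, 100, range(1969, 1990))
        td = s.set_index("year")["TD"]
        assert td[1969] == 100 and td[1976] == 99 and td[1981] == 98

    def test_no_extinctions_constant(self):
        s = sd.global_td_series(pd.DataFrame(columns=["species_id", "status", "extinction_year"]),
                                50, range(1969, 1980))
        assert (s["TD"] == 50).all()

    def test_non_increasing(self):
        ext = sd.generate_global_extinction_fixture(100, 21, (1969, 2013), seed=4)
        s = sd.global_td_series(ext, 494, range(1969, 2014))
        assert (np.diff(s["TD"]) <= 0).all()


class TestDissimilaritySeries:
    def test_full_table_consistency(self, toy_tree):
        rng = np.random.default_rng(5)
        panel = {t: rng.uniform(0, 1, 3) for t in range(2000, 2006)}
        out = sd.dissimilarity_series(panel, tree=toy_tree)
        assert len(out) == 5
        np.testing.assert_allclose(out["TD_NES"] + out["TD_TUR"], out["TD_DIS"], atol=1e-12)
        np.testing.assert_allclose(out["FD_NES"] + out["FD_TUR"], out["FD_DIS"], atol=1e-12)
        valid = out["TD_DIS"] > 0
        np.testing.assert_allclose(out.loc[valid, "TD_NESc"] + out.loc[valid, "TD_TURc"], 1.0)
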