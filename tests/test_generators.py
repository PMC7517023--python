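"""Matrix-family generators: invariants, closed-form totals, reproducibility."""
import numpy as np
import pytest

from bipmi import (
    TopologySpec,
    compound_nested,
    decompose,
    generate,
    margins,
    modular_increasing,
    modular_isometric,
    modular_rect,
    nested_general,
    nested_packed,
    random_fill,
    s_nested_packed,
    s_uniform,
    uniform_regular,
)


def assert_perfectly_nested(values):
    """Rows left-packed with non-increasing lengths: subset-structured."""
    lens = values.sum(axis=1)
    assert (lens[:-1] >= lens[1:]).all()
    for row, ln in zip(values, lens):
        assert row[:ln].all() and not row[ln:].any()


class TestUniformRegular:
    def test_all_margins_equal_k(self):
        m = uniform_regular(12, 0.5, seed=3)
        ms = margins(m)
        assert (ms.kx == 6).all() and (ms.ky == 6).all()

    def test_k1_is_a_permutation_matrix(self):
        m = uniform_regular(4, 0.25, seed=0)
        assert (m.values.sum(axis=0) == 1).all() and (m.values.sum(axis=1) == 1).all()

    def test_saturated(self):
        m = uniform_regular(4, 1.0)
        assert m.values.all()
        assert decompose(m).s == pytest.approx(0.0, abs=1e-12)

    def test_s_matches_closed_form_for_any_arrangement(self):
        for seed in (None, 1, 2):
            m = uniform_regular(10, 0.5, seed=seed)
            assert decompose(m).s == pytest.approx(s_uniform(10, 10, 0.5).s, abs=1e-12)

    def test_infeasible_occupancy_names_grid(self):
        with pytest.raises(ValueError, match="multiples of 1/10"):
            uniform_regular(10, 0.55)


class TestRandomFill:
    def test_exact_cell_count_and_determinism(self):
        m1 = random_fill(15, 9, 0.4, seed=7)
        m2 = random_fill(15, 9, 0.4, seed=7)
        m3 = random_fill(15, 9, 0.4, seed=8)
        assert m1.values.sum() == round(0.4 * 15 * 9)
        assert np.array_equal(m1.values, m2.values)
        assert not np.array_equal(m1.values, m3.values)

    def test_saturated(self):
        assert random_fill(2, 2, 1.0, seed=0).values.all()

    def test_empty_fill_rejected(self):
        with pytest.raises(ValueError):
            random_fill(3, 3, 0.01, seed=0)


class TestNestedPacked:
    def test_smallest_case(self):
        ms = margins(nested_packed(2))
        assert sorted(ms.kx.tolist()) == [1, 2]
        assert sorted(ms.ky.tolist()) == [1, 2]
        assert ms.nm == 3

    def test_totals_n20(self):
        ms = margins(nested_packed(20))
        assert ms.nm == 210
        assert ms.rho == pytest.approx(0.525, abs=0)

    def test_matches_analytic(self):
        assert decompose(nested_packed(20)).s == pytest.approx(s_nested_packed(20).s, abs=1e-12)

    def test_packed_above_antidiagonal(self):
        assert_perfectly_nested(nested_packed(6).values)


class TestNestedGeneral:
    @pytest.mark.parametrize("rho", [0.2, 0.35, 0.525, 0.8])
    def test_hits_target_occupancy_and_is_nested(self, rho):
        m = nested_general(20, 20, rho, seed=1)
        assert m.values.sum() == round(rho * 400)
        assert_perfectly_nested(m.values)
        assert m.values.sum(axis=0).min() >= 1 and m.values.sum(axis=1).min() >= 1

    def test_rectangular_shapes(self):
        m = nested_general(8, 25, 0.4, seed=5)
        assert m.shape == (8, 25)
        assert_perfectly_nested(m.values)

    def test_saturated_limit(self):
        m = nested_general(20, 20, 1.0, seed=0)
        assert m.values.all()
        assert decompose(m).s == pytest.approx(0.0, abs=1e-12)

    def test_consistent_with_packed_at_half_occupancy(self):
        m = nested_general(20, 20, 0.525, seed=2)
        assert m.values.sum() == nested_packed(20).values.sum()

    def test_infeasible_occupancy_rejected(self):
        with pytest.raises(ValueError, match="feasible rho"):
            nested_general(20, 20, 0.05)

    def test_seed_reproducibility(self):
        a = nested_general(17, 11, 0.5, seed=42)
        b = nested_general(17, 11, 0.5, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_always_below_uniform_at_matched_occupancy(self, rng):
        # non-flat nested margins lower H(X)+H(Y) at the same NM
        for _ in range(40):
            rho = rng.uniform(39 / 400 + 0.01, 0.99)
            s_nested = decompose(nested_general(20, 20, rho, seed=int(rng.integers(2**31)))).s
            nm = round(rho * 400)
            assert s_nested < s_uniform(20, 20, nm / 400).s


class TestModularFamilies:
    @pytest.mark.parametrize("m,t", [(1, 4), (2, 60), (3, 40), (5, 3)])
    def test_isometric_block_structure(self, m, t):
        mx = modular_isometric(m, t)
        ms = margins(mx)
        assert mx.shape == (m * t, m * t)
        assert ms.nm == m * t * t
        assert ms.rho == pytest.approx(1 / m, abs=1e-15)

    def test_isometric_diagonal_limit(self):
        assert np.array_equal(modular_isometric(5, 1).values, np.eye(5, dtype=int))

    def test_rect_reduces_to_isometric(self):
        assert np.array_equal(modular_rect(3, 4, 4).values, modular_isometric(3, 4).values)

    def test_rect_shape(self):
        mx = modular_rect(4, 2, 3)
        assert mx.shape == (8, 12)
        assert margins(mx).nm == 4 * 2 * 3

    @pytest.mark.parametrize("m,n", [(3, 6), (5, 15)])
    def test_increasing_matrix_size(self, m, n):
        assert modular_increasing(m).shape == (n, n)

    def test_increasing_totals_m3(self):
        ms = margins(modular_increasing(3))
        assert ms.nm == 14
        assert ms.rho == pytest.approx(14 / 36, abs=1e-15)

    def test_compound_reduces_to_packed_nested(self):
        assert np.array_equal(compound_nested(1, 6).values, nested_packed(6).values)

    def test_compound_totals(self):
        assert margins(compound_nested(4, 5)).nm == 60
        assert decompose(compound_nested(4, 5)).s == pytest.approx(0.404886, abs=1e-6)


class TestTopologySpec:
    def test_dispatch_matches_direct_call(self):
        spec = TopologySpec(family="compound_nested", m=3, t=5)
        assert generate(spec) == compound_nested(3, 5)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown family"):
            TopologySpec(family="smallworld")

    def test_missing_parameter_named(self):
        with pytest.raises(ValueError, match="rho"):
            generate(TopologySpec(family="random_fill", nx=5, ny=5))
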