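"""Three-body equilibrium: closed forms, exact solver vs oracle, hook effect."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ternary_sar.equilibrium import (
    EquilibriumError,
    EquilibriumParams,
    beta_factor,
    binary_complex_conc,
    cooperativity,
    hook_curve,
    max_ternary_fraction,
    solve_ternary_equilibrium,
    spr_occupancy,
)

from conftest import brute_force_equilibrium

positive_k = st.floats(min_value=1e-3, max_value=1e6)


class TestCooperativity:
    @pytest.mark.parametrize(
        "k_lp, k_lpt, printed",
        [(60, 4.7, 12.8), (20.5, 1.5, 13.7)],
    )
    def test_matches_printed_table_values(self, k_lp, k_lpt, printed):
        assert round(cooperativity(k_lp, k_lpt), 1) == printed

    @given(positive_k)
    @settings(deadline=None)
    def test_identity_case(self, k):
        assert cooperativity(k, k) == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [(-1, 5), (5, 0), (0, 0)])
    def test_rejects_non_positive(self, bad):
        with pytest.raises(EquilibriumError):
            cooperativity(*bad)


class TestBetaFactor:
    @pytest.mark.parametrize(
        "ratio, expected", [(1, 4 / 25), (9, 16 / 25), (100, 121 / 25)]
    )
    def test_closed_form(self, ratio, expected):
        assert beta_factor(ratio * 7.0, 7.0) == pytest.approx(expected)

    def test_configurable_target_excess(self):
        assert beta_factor(5.0, 5.0, target_excess=4.0) == pytest.approx(1.0)

    def test_rejects_non_positive(self):
        with pytest.raises(EquilibriumError):
            beta_factor(-1, 1)


class TestSprOccupancy:
    @pytest.mark.parametrize(
        "p, k, expected", [(20, 20, 0.5), (0, 20, 0.0), (180, 20, 0.9)]
    )
    def test_isotherm(self, p, k, expected):
        assert spr_occupancy(p, k) == pytest.approx(expected)

    def test_rejects_negative_dose(self):
        with pytest.raises(EquilibriumError):
            spr_occupancy(-1, 20)


class TestMaxTernaryFraction:
    def test_landmark_alpha_two(self):
        # the maximal fraction crosses 0.9 already at cooperativity 2
        # when the binary-affinity factor is 0.2
        assert max_ternary_fraction(2, 0.2) == pytest.approx(0.9091, abs=1e-4)

    def test_symmetry_and_limit(self):
        assert max_ternary_fraction(1, 1) == pytest.approx(0.5)
        assert max_ternary_fraction(1e6, 0.2) == pytest.approx(1.0, abs=1e-5)

    @given(st.floats(1e-2, 1e2), st.floats(1e-2, 1e2))
    @settings(deadline=None)
    def test_monotone_in_alpha(self, alpha, beta):
        assert max_ternary_fraction(2 * alpha, beta) > max_ternary_fraction(
            alpha, beta
        )


class TestBinaryComplex:
    def test_weak_binding_limit(self):
        # quadratic root ~ weak-binding approximation P*T/(T+K)
        val = binary_complex_conc(0.01, 100, 100)
        assert val == pytest.approx(0.0049995, rel=1e-4)
        assert val <= min(0.01, 100)

    def test_tight_binding_limit(self):
        assert binary_complex_conc(3.0, 7.0, 1e-9) == pytest.approx(3.0, rel=1e-6)
        assert binary_complex_conc(7.0, 3.0, 1e-9) == pytest.approx(3.0, rel=1e-6)

    def test_zero_dose(self):
        assert binary_complex_conc(0, 50, 10) == 0.0


class TestSolver:
    def test_zero_protac_short_circuit(self):
        params = EquilibriumParams(k_lp=50, k_tp=80, alpha=2)
        st_ = solve_ternary_equilibrium(10, 20, 0, params)
        assert st_.lpt == 0 and st_.l_free == 10 and st_.t_free == 20

    def test_matches_bisection_oracle_at_symmetric_point(self):
        params = EquilibriumParams(k_lp=100, k_tp=100, alpha=1)
        got = solve_ternary_equilibrium(100, 100, 100, params)
        oracle = brute_force_equilibrium(100, 100, 100, params)
        assert got.lpt == pytest.approx(oracle["LPT"], rel=1e-8)

    def test_oracle_agreement_random_systems(self, rng):
        for _ in range(100):
            params = EquilibriumParams(
                k_lp=10 ** rng.uniform(-1, 4),
                k_tp=10 ** rng.uniform(-1, 4),
                alpha=10 ** rng.uniform(-1.5, 1.5),
            )
            totals = 10 ** rng.uniform(-1, 3, size=3)
            got = solve_ternary_equilibrium(*totals, params)
            oracle = brute_force_equilibrium(*totals, params)
            assert got.lpt == pytest.approx(oracle["LPT"], rel=1e-8, abs=1e-12)
            assert got.p_free == pytest.approx(oracle["P"], rel=1e-8, abs=1e-12)

    def test_hook_collapse_at_huge_dose(self):
        params = EquilibriumParams(k_lp=100, k_tp=100, alpha=1)
        grid = np.logspace(-1, 7, 40)
        lpt = hook_curve(100, 100, grid, params)
        assert lpt[-1] < 0.01 * lpt.max()

    def test_conservation_and_nonnegativity_random_sweep(self, rng):
        # 1000 random systems: every species non-negative, mass conserved
        for _ in range(1000):
            params = EquilibriumParams(
                k_lp=10 ** rng.uniform(-2, 5),
                k_tp=10 ** rng.uniform(-2, 5),
                alpha=10 ** rng.uniform(-2, 2),
            )
            l_t, t_t, p_t = 10 ** rng.uniform(-2, 4, size=3)
            s = solve_ternary_equilibrium(l_t, t_t, p_t, params)
            for v in (s.l_free, s.t_free, s.p_free, s.lp, s.tp, s.lpt):
                assert v >= 0
            s.check_conservation(rtol=1e-8)


class TestHookCurve:
    def test_no_target_means_no_ternary(self):
        params = EquilibriumParams(k_lp=50, k_tp=50, alpha=5)
        lpt = hook_curve(10, 0, np.logspace(-1, 4, 10), params)
        assert np.all(lpt == 0)

    def test_surface_limit_max_matches_closed_form(self):
        # [L]_t tiny, [T]_t = 25*K_TP: the numeric hook-curve maximum
        # reproduces alpha/(alpha+beta) within 5%
        params = EquilibriumParams(k_lp=100, k_tp=100, alpha=2)
        grid = np.logspace(-2, 6, 120)
        lpt = hook_curve(0.01, 25 * params.k_tp, grid, params)
        frac = lpt.max() / 0.01
        assert frac == pytest.approx(params.max_ternary_fraction(), rel=0.05)

    def test_surface_limit_sweep(self):
        # closed-form accuracy across cooperativity and affinity-ratio space
        grid = np.logspace(-3, 7, 140)
        for alpha in (0.1, 1.0, 10.0, 100.0):
            for ratio in (0.1, 1.0, 10.0):
                params = EquilibriumParams(k_lp=100 * ratio, k_tp=100, alpha=alpha)
                lpt = hook_curve(1e-3, 25 * params.k_tp, grid, params)
                frac = lpt.max() / 1e-3
                assert frac == pytest.approx(
                    params.max_ternary_fraction(), rel=0.05
                ), (alpha, ratio)

    def test_max_increases_with_cooperativity(self):
        grid = np.logspace(-2, 5, 60)
        low = hook_curve(1, 200, grid, EquilibriumParams(k_lp=50, k_tp=50, alpha=1))
        high = hook_curve(1, 200, grid, EquilibriumParams(k_lp=50, k_tp=50, alpha=2))
        assert high.max() > low.max()

    def test_unimodal_over_spanning_grid(self):
        params = EquilibriumParams(k_lp=100, k_tp=100, alpha=5)
        lpt = hook_curve(10, 100, np.logspace(-2, 6, 80), params)
        peak = int(np.argmax(lpt))
        assert np.all(np.diff(lpt[: peak + 1]) >= -1e-12)
        assert np.all(np.diff(lpt[peak:]) <= 1e-12)


class TestParams:
    def test_alpha_k_lpt_consistency_enforced(self):
        with pytest.raises(EquilibriumError):
            EquilibriumParams(k_lp=100, k_tp=100, k_lpt=10, alpha=5)

    def test_derivations(self):
        p = EquilibriumParams(k_lp=60, k_tp=30, k_lpt=4.7)
        assert p.alpha == pytest.approx(60 / 4.7)
        assert p.beta == pytest.approx((math.sqrt(2) + 1) ** 2 / 25)
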