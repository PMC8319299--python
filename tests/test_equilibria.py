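"""Model-layer checks: closed forms, mass balance, limiting cases."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from titrofit.equilibria import (
    AffinityParams,
    DomainError,
    HillParams,
    MixtureComposition,
    MMParams,
    cubic_coefficients,
    hill_signal,
    mm_rate,
    oracle_solve,
    predicted_anisotropy,
    solve_competitive,
    solve_direct,
)

uM = 1e-6
nM = 1e-9


def assert_state_consistent(state, comp, params, rtol=1e-9):
    """Mass conservation and mass action at equilibrium."""
    scale = max(comp.P0, comp.L0, comp.N0, 1e-30)
    atol = rtol * scale
    assert state.P_free >= 0 and state.L_free >= 0 and state.N_free >= 0
    assert state.PL >= 0 and state.PN >= 0
    np.testing.assert_allclose(state.P_free + state.PL + state.PN, comp.P0,
                               rtol=rtol, atol=atol)
    np.testing.assert_allclose(state.L_free + state.PL, comp.L0,
                               rtol=rtol, atol=atol)
    np.testing.assert_allclose(state.N_free + state.PN, comp.N0,
                               rtol=rtol, atol=atol)
    np.testing.assert_allclose(state.PL * params.K_L, state.P_free * state.L_free,
                               rtol=1e-6, atol=1e-6 * scale**2)
    if params.K_N is not None:
        np.testing.assert_allclose(state.PN * params.K_N,
                                   state.P_free * state.N_free,
                                   rtol=1e-6, atol=1e-6 * scale**2)


class TestDirect:
    def test_no_protein_means_no_complex(self):
        st_ = solve_direct(MixtureComposition(0.0, 3 * uM), AffinityParams(K_L=1 * uM))
        assert st_.PL == 0.0
        assert st_.L_free == 3 * uM

    def test_symmetric_unit_case_matches_quadratic_closed_form(self):
        # P0 = L0 = K_L -> PL = (3 - sqrt(5))/2 * K_L
        st_ = solve_direct(MixtureComposition(1 * uM, 1 * uM), AffinityParams(K_L=1 * uM))
        np.testing.assert_allclose(st_.PL, (3 - np.sqrt(5)) / 2 * uM, rtol=1e-12)

    def test_half_bound_at_protein_equal_kd_for_trace_probe(self):
        # trace probe: bound fraction is 1/2 when P0 = K_L
        st_ = solve_direct(MixtureComposition(8.07 * uM, 0.04 * uM),
                           AffinityParams(K_L=8.07 * uM))
        assert st_.PL / 0.04 / uM == pytest.approx(0.5, abs=2e-3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DomainError):
            AffinityParams(K_L=0.0)
        with pytest.raises(DomainError):
            MixtureComposition(-1.0, 0.0)
        with pytest.raises(DomainError):
            solve_direct(MixtureComposition(1 * uM, 1 * uM, N0=1 * uM),
                         AffinityParams(K_L=1 * uM))


class TestAnisotropyObservable:
    def test_algebraic_identities(self):
        from titrofit.equilibria import SpeciesState

        assert predicted_anisotropy(SpeciesState(1, 1, 0, 0, 0), 0.1) == 0.0
        assert predicted_anisotropy(SpeciesState(1, 0, 0, 2 * uM, 0), 0.1) == pytest.approx(0.1)
        half = predicted_anisotropy(SpeciesState(1, 5 * nM, 0, 5 * nM, 0), 0.1)
        assert half == pytest.approx(0.05)

    def test_zero_probe_is_undefined(self):
        from titrofit.equilibria import SpeciesState

        with pytest.raises(DomainError):
            predicted_anisotropy(SpeciesState(1, 0, 0, 0, 0), 0.1)


class TestCubic:
    def test_coefficients_direct_substitution(self):
        # K_L = K_N = 1, P0 = 1, L0 = 0, N0 = 1 (uM): both dialects identical
        comp = MixtureComposition(1 * uM, 0.0, 1 * uM)
        params = AffinityParams(K_L=1 * uM, K_N=1 * uM)
        for dialect in ("paper", "complete"):
            c = cubic_coefficients(comp, params, dialect)
            np.testing.assert_allclose(c.c2, 2 * uM, rtol=1e-12)
            assert c.c1 == pytest.approx(0.0, abs=1e-24)
            np.testing.assert_allclose(c.c0, -1 * uM**3, rtol=1e-12)
        assert c.c0 <= 0

    def test_golden_ratio_root(self):
        # cubic factors as (P^2 + P - 1)(P + 1) in uM units
        comp = MixtureComposition(1 * uM, 0.0, 1 * uM)
        params = AffinityParams(K_L=3 * uM, K_N=1 * uM)
        st_ = solve_competitive(comp, params)
        np.testing.assert_allclose(st_.P_free, (np.sqrt(5) - 1) / 2 * uM, rtol=1e-10)
        np.testing.assert_allclose(st_.PN, (3 - np.sqrt(5)) / 2 * uM, rtol=1e-9)

    def test_zero_protein_root(self):
        comp = MixtureComposition(0.0, 1 * uM, 1 * uM)
        params = AffinityParams(K_L=1 * uM, K_N=1 * uM)
        assert cubic_coefficients(comp, params).c0 == 0.0
        assert solve_competitive(comp, params).P_free == 0.0

    def test_no_ligands_factorisation(self):
        # with N0 = L0 = 0 the physical root solves the direct-binding quadratic
        comp = MixtureComposition(2 * uM, 0.0, 0.0)
        params = AffinityParams(K_L=1 * uM, K_N=5 * uM)
        st_ = solve_competitive(comp, params)
        np.testing.assert_allclose(st_.P_free, 2 * uM, rtol=1e-10)

    @pytest.mark.parametrize("n0_zero", [True, False])
    def test_reduces_to_direct_without_competitor(self, n0_zero):
        comp = MixtureComposition(10 * uM, 40 * nM, 0.0 if n0_zero else 0.0)
        params = AffinityParams(K_L=8.07 * uM, K_N=41.7 * uM)
        a = solve_competitive(comp, params, dialect="complete")
        b = solve_direct(MixtureComposition(comp.P0, comp.L0),
                         AffinityParams(K_L=params.K_L))
        np.testing.assert_allclose(a.PL, b.PL, rtol=1e-9)
        np.testing.assert_allclose(a.P_free, b.P_free, rtol=1e-9)

    def test_infinitely_weak_competitor_limit(self):
        comp = MixtureComposition(10 * uM, 40 * nM, 100 * uM)
        params = AffinityParams(K_L=8.07 * uM, K_N=1e9 * 8.07 * uM)
        a = solve_competitive(comp, params, dialect="complete")
        b = solve_direct(MixtureComposition(comp.P0, comp.L0),
                         AffinityParams(K_L=params.K_L))
        np.testing.assert_allclose(a.PL, b.PL, rtol=1e-6)


conc = st.floats(min_value=-9.0, max_value=-3.0).map(lambda u: 10.0**u)


class TestOracleEquivalence:
    @settings(max_examples=250, derandomize=True, deadline=None)
    @given(P0=conc, L0=conc, N0=conc, K_L=conc, K_N=conc)
    def test_cubic_matches_mass_balance_oracle(self, P0, L0, N0, K_L, K_N):
        comp = MixtureComposition(P0, L0, N0)
        params = AffinityParams(K_L=K_L, K_N=K_N)
        a = solve_competitive(comp, params, dialect="complete")
        b = oracle_solve(comp, params)
        scale = max(P0, L0, N0)
        for x, y in [(a.P_free, b.P_free), (a.PL, b.PL), (a.PN, b.PN)]:
            np.testing.assert_allclose(x, y, rtol=1e-9, atol=1e-15 * scale)
        assert_state_consistent(a, comp, params)
        assert_state_consistent(b, comp, params)

    def test_all_zero_composition(self):
        st_ = oracle_solve(MixtureComposition(0, 0, 0),
                           AffinityParams(K_L=1 * uM, K_N=1 * uM))
        assert st_.P_free == st_.PL == st_.PN == 0.0


class TestMonotonicity:
    def test_complex_monotone_in_totals_and_affinity(self):
        P0 = np.geomspace(0.01 * uM, 100 * uM, 40)
        pl_p = [solve_direct(MixtureComposition(p, 40 * nM),
                             AffinityParams(K_L=8 * uM)).PL for p in P0]
        assert np.all(np.diff(pl_p) >= -1e-18)
        L0 = np.geomspace(1 * nM, 10 * uM, 40)
        pl_l = [solve_direct(MixtureComposition(5 * uM, l),
                             AffinityParams(K_L=8 * uM)).PL for l in L0]
        assert np.all(np.diff(pl_l) >= -1e-18)
        KL = np.geomspace(0.1 * uM, 1000 * uM, 40)
        pl_k = [solve_direct(MixtureComposition(5 * uM, 40 * nM),
                             AffinityParams(K_L=k)).PL for k in KL]
        assert np.all(np.diff(pl_k) <= 1e-18)

    def test_competitor_displaces_label(self):
        dr = 0.1
        params = AffinityParams(K_L=8.07 * uM, K_N=7.49 * uM, delta_r=dr)
        robs = []
        for n0 in np.geomspace(1 * nM, 1000 * uM, 60):
            st_ = solve_competitive(MixtureComposition(10 * uM, 40 * nM, n0), params)
            r = predicted_anisotropy(st_, dr)
            assert 0.0 <= r <= dr
            robs.append(r)
        assert np.all(np.diff(robs) <= 1e-15)


class TestDialects:
    def test_trace_probe_regime_agreement(self):
        # L0 <= 1e-3 * min(K_L, K_N, P0): dialects agree to 1% in all species
        K_L, K_N, P0 = 8.07 * uM, 41.7 * uM, 10 * uM
        L0 = 1e-3 * min(K_L, K_N, P0)
        for n0 in np.geomspace(0.1 * uM, 1000 * uM, 20):
            comp = MixtureComposition(P0, L0, n0)
            params = AffinityParams(K_L=K_L, K_N=K_N)
            a = solve_competitive(comp, params, dialect="complete")
            b = solve_competitive(comp, params, dialect="paper")
            np.testing.assert_allclose(b.PL, a.PL, rtol=1e-2)
            np.testing.assert_allclose(b.P_free, a.P_free, rtol=1e-2)


class TestEmpiricalModels:
    def test_hill_midpoint_and_floor(self):
        for h in (0.5, 1.0, 2.7):
            p = HillParams(K_d=155 * nM, h=h, B_max=1.0, floor=0.2)
            assert hill_signal(155 * nM, p) == pytest.approx(0.6)
            assert hill_signal(0.0, p) == pytest.approx(0.2)

    def test_hyperbola_quartile_point(self):
        # h = 1: signal at 3*K_d is 0.75 * B_max
        p = HillParams(K_d=155 * nM, h=1.0, B_max=1.0)
        assert hill_signal(465 * nM, p) == pytest.approx(0.75)

    def test_hill_h1_equals_hyperbola_and_mm(self):
        x = np.geomspace(1 * nM, 10 * uM, 30)
        hp = HillParams(K_d=224 * nM, h=1.0, B_max=1.5e-9)
        mp = MMParams(k_cat=0.1, K_M=224 * nM, E0=15 * nM)
        np.testing.assert_allclose(hill_signal(x, hp),
                                   hp.B_max * x / (hp.K_d + x), rtol=1e-12)
        np.testing.assert_allclose(mm_rate(x, mp),
                                   hill_signal(x, HillParams(K_d=mp.K_M, h=1.0,
                                                             B_max=mp.k_cat * mp.E0)),
                                   rtol=1e-12)

    def test_mm_half_saturation_and_limits(self):
        p = MMParams(k_cat=0.1, K_M=224 * nM, E0=15 * nM)
        assert mm_rate(224 * nM, p) == pytest.approx(0.1 * 15 * nM / 2, rel=1e-12)
        assert mm_rate(0.0, p) == 0.0
        assert mm_rate(100 * 224 * nM, p) == pytest.approx(0.1 * 15 * nM, rel=0.01)
        with pytest.raises(DomainError):
            mm_rate(-1.0, p)
        with pytest.raises(DomainError):
            hill_signal(-1.0, HillParams(K_d=1.0, h=1.0, B_max=1.0))
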