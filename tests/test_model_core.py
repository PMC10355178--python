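"""Unit tests for the rate functions, ODE right-hand sides and equilibria."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from defsym import (
    ModelParameters,
    MonomorphicState,
    PolymorphicState,
    ResidentTraits,
    birth_rate,
    coinfection_virulence,
    ode_rhs_monomorphic,
    ode_rhs_polymorphic,
    parasite_virulence,
    protection_cost,
    solve_equilibrium,
    symbiont_transmission,
)


class TestRateFunctions:
    @pytest.mark.parametrize("y, c1, c2, expected", [
        (0.0, 0.25, 2.0, 0.0),
        (0.0, 0.9, -3.0, 0.0),
        (1.0, 0.25, 2.0, 0.25),
        (1.0, 0.9, -2.0, 0.9),
        # direct evaluation of the exponential cost at the default shape
        (0.5, 0.25, 2.0, 0.06723535534249878),
    ])
    def test_protection_cost_values(self, y, c1, c2, expected):
        assert protection_cost(y, c1, c2) == pytest.approx(expected, abs=1e-12)

    def test_protection_cost_monotone_and_bounded(self):
        for c2 in (-3.0, -0.5, 0.0, 0.5, 3.0):
            vals = [protection_cost(y, 0.7, c2) for y in np.linspace(0, 1, 41)]
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
            assert all(0.0 <= v <= 0.7 + 1e-12 for v in vals)

    def test_protection_cost_linear_limit_continuity(self):
        # the c2 -> 0 branch switch must be seamless
        for y in np.linspace(0, 1, 21):
            for c2 in (1e-8, -1e-8):
                assert protection_cost(y, 0.25, c2) == pytest.approx(
                    0.25 * y, abs=1e-6)

    @pytest.mark.parametrize("y, c1", [(-0.1, 0.5), (1.1, 0.5), (0.5, 1.5)])
    def test_protection_cost_domain_errors(self, y, c1):
        with pytest.raises(ValueError):
            protection_cost(y, c1, 2.0)

    def test_symbiont_transmission(self, params):
        assert symbiont_transmission(0.0, params) == pytest.approx(2.0)
        full = ModelParameters(c1=0.25)
        assert symbiont_transmission(1.0, full) == pytest.approx(1.5)
        assert symbiont_transmission(0.5, params) == pytest.approx(
            2.0 * (1 - 0.06723535534249878))

    def test_parasite_virulence(self, params):
        assert parasite_virulence(0.0, params) == pytest.approx(0.1)
        assert parasite_virulence(2.0, params) == pytest.approx(0.5)
        assert parasite_virulence(1.0, params) == pytest.approx(0.2)
        with pytest.raises(ValueError):
            parasite_virulence(-1.0, params)

    def test_coinfection_virulence(self, params):
        # full tolerance leaves only the symbiont-induced mortality
        assert coinfection_virulence(1.0, 3.7, params) == pytest.approx(0.1)
        assert coinfection_virulence(0.0, 2.0, params) == pytest.approx(0.6)
        assert coinfection_virulence(0.5, 2.0, params) == pytest.approx(0.35)

    def test_coinfection_virulence_bounded_by_additive_case(self, params):
        for y in np.linspace(0, 1, 21):
            for beta in (0.0, 1.0, 2.5, 6.0):
                assert coinfection_virulence(y, beta, params) <= (
                    parasite_virulence(beta, params) + params.alpha_D + 1e-12)

    def test_birth_rate(self, params):
        assert birth_rate(0.0, params) == 0.0
        assert birth_rate(4.0, params) == 0.0  # carrying-capacity zero
        assert birth_rate(3.0, ModelParameters(a=1.0, q=0.25)) == pytest.approx(0.75)
        assert birth_rate(10.0, params) == 0.0  # clamped above a/q
        with pytest.raises(ValueError):
            birth_rate(-1.0, params)


class TestParameterValidation:
    def test_c1_out_of_range(self):
        with pytest.raises(ValueError, match="c1"):
            ModelParameters(c1=1.5)

    def test_d_must_exceed_one(self):
        with pytest.raises(ValueError, match="d"):
            ModelParameters(d=1.0)

    def test_birth_must_exceed_death(self):
        with pytest.raises(ValueError):
            ModelParameters(a=0.2, b=0.25)


class TestMonomorphicRHS:
    def test_extinction_is_equilibrium(self, params):
        rhs = ode_rhs_monomorphic(MonomorphicState(0, 0, 0, 0),
                                  ResidentTraits(y=0.5, beta_P=2.0), params)
        assert np.all(rhs == 0.0)

    def test_disease_free_equilibrium(self, params):
        H = (params.a - params.b) / params.q  # = 3 with defaults
        rhs = ode_rhs_monomorphic(MonomorphicState(H, 0, 0, 0),
                                  ResidentTraits(y=0.5, beta_P=2.0), params)
        assert np.allclose(rhs, 0.0, atol=1e-14)

    def test_matches_hand_transcription(self, params):
        # independent hand evaluation of the four equations at
        # H=D=P=B=1, y=0.5, beta_P=2, default parameters
        rhs = ode_rhs_monomorphic(MonomorphicState(1, 1, 1, 1),
                                  ResidentTraits(y=0.5, beta_P=2.0), params)
        expected = [-7.88105857863, -0.61894142137, -0.48105857863,
                    7.03105857863]
        assert np.allclose(rhs, expected, atol=1e-10)

    @given(st.lists(st.floats(0.0, 3.0), min_size=4, max_size=4),
           st.floats(0.0, 1.0), st.floats(0.1, 5.0))
    @hyp_settings(max_examples=50, deadline=None)
    def test_total_population_identity(self, comps, y, beta):
        """dN/dt must equal births minus natural and disease mortality."""
        p = ModelParameters()
        state = MonomorphicState(*comps)
        traits = ResidentTraits(y=y, beta_P=beta)
        rhs = ode_rhs_monomorphic(state, traits, p)
        expected = (birth_rate(state.N, p) - p.b * state.N
                    - p.alpha_D * state.D
                    - parasite_virulence(beta, p) * state.P
                    - coinfection_virulence(y, beta, p) * state.B)
        assert rhs.sum() == pytest.approx(expected, abs=1e-12)


def _brute_force_poly_rhs(state: PolymorphicState, p: ModelParameters):
    """Independent arrow-by-arrow bookkeeping of the strain-structured
    model, written with explicit loops over every transition."""
    nD, nP = state.n_symbiont, state.n_parasite
    H, D, P, B = state.H, state.D, state.P, state.B
    N = H + D.sum() + P.sum() + B.sum()
    bD = [symbiont_transmission(y, p) for y in state.y_strains]
    bP = list(state.beta_strains)
    dH, dD, dP = 0.0, np.zeros(nD), np.zeros(nP)
    dB = np.zeros((nP, nD))
    dH += birth_rate(N, p)                       # births enter H
    dH -= p.b * H                                 # natural death
    for j in range(nD):
        lam = bD[j] * (D[j] + B[:, j].sum())
        dH -= lam * H                             # H -> D_j
        dD[j] += lam * H
        dD[j] -= (p.b + p.alpha_D) * D[j]         # death of D_j hosts
        dD[j] -= p.gamma_D * D[j]                 # clearance D_j -> H
        dH += p.gamma_D * D[j]
        for i in range(nP):
            dP[i] -= lam * P[i]                   # P_i -> B_ij
            dB[i, j] += lam * P[i]
    for i in range(nP):
        lam = bP[i] * (P[i] + B[i, :].sum())
        dH -= lam * H                             # H -> P_i
        dP[i] += lam * H
        aP = parasite_virulence(bP[i], p)
        dP[i] -= (p.b + aP) * P[i]                # death of P_i hosts
        dP[i] -= p.gamma_P * P[i]                 # clearance P_i -> H
        dH += p.gamma_P * P[i]
        for j in range(nD):
            dD[j] -= lam * D[j]                   # D_j -> B_ij
            dB[i, j] += lam * D[j]
    for i in range(nP):
        for j in range(nD):
            aB = coinfection_virulence(state.y_strains[j], bP[i], p)
            dB[i, j] -= (p.b + aB) * B[i, j]      # death of coinfected
            dB[i, j] -= p.gamma_D * B[i, j]       # clear symbiont: -> P_i
            dP[i] += p.gamma_D * B[i, j]
            dB[i, j] -= p.gamma_P * B[i, j]       # clear parasite: -> D_j
            dD[j] += p.gamma_P * B[i, j]
    return dH, dD, dP, dB


class TestPolymorphicRHS:
    def test_reduces_to_monomorphic(self, params, rng):
        for _ in range(5):
            mono = MonomorphicState(*rng.uniform(0.01, 2.0, size=4))
            traits = ResidentTraits(y=float(rng.uniform(0, 1)),
                                    beta_P=float(rng.uniform(0.1, 4)))
            poly = PolymorphicState.from_monomorphic(mono, traits)
            d_poly = ode_rhs_polymorphic(poly, params)
            d_mono = ode_rhs_monomorphic(mono, traits, params)
            got = np.array([d_poly.H, d_poly.D[0], d_poly.P[0],
                            d_poly.B[0, 0]])
            assert np.allclose(got, d_mono, atol=0, rtol=0)

    def test_neutral_strain_splitting(self, params):
        """Two identical parasite strains at half density must jointly
        reproduce the monomorphic dynamics."""
        mono = MonomorphicState(1.2, 0.8, 0.6, 0.4)
        traits = ResidentTraits(y=0.3, beta_P=2.5)
        d_mono = ode_rhs_monomorphic(mono, traits, params)
        # strictly-sorted trait lists: give the twin a numerically
        # negligible offset
        split = PolymorphicState(
            np.array([0.3]), np.array([2.5, 2.5 + 1e-12]), mono.H,
            np.array([mono.D]), np.array([mono.P / 2, mono.P / 2]),
            np.array([[mono.B / 2], [mono.B / 2]]))
        d = ode_rhs_polymorphic(split, params)
        assert d.H == pytest.approx(d_mono[0], rel=1e-9)
        assert d.D[0] == pytest.approx(d_mono[1], rel=1e-9)
        assert d.P.sum() == pytest.approx(d_mono[2], rel=1e-9)
        assert d.B.sum() == pytest.approx(d_mono[3], rel=1e-9)

    def test_matches_bookkeeping_oracle(self, params, rng):
        state = PolymorphicState(
            np.array([0.4]), np.array([1.5, 3.0]),
            float(rng.uniform(0.1, 2)),
            rng.uniform(0.1, 2, size=1), rng.uniform(0.1, 2, size=2),
            rng.uniform(0.1, 2, size=(2, 1)))
        d = ode_rhs_polymorphic(state, params)
        dH, dD, dP, dB = _brute_force_poly_rhs(state, params)
        assert d.H == pytest.approx(dH, abs=1e-12)
        assert np.allclose(d.D, dD, atol=1e-12)
        assert np.allclose(d.P, dP, atol=1e-12)
        assert np.allclose(d.B, dB, atol=1e-12)


class TestSolveEquilibrium:
    def test_disease_free_start_stays(self, params):
        init = MonomorphicState(3.0, 0.0, 0.0, 0.0)
        eq = solve_equilibrium(init, params,
                               traits=ResidentTraits(y=0.5, beta_P=2.0))
        assert eq.converged
        assert eq.residual <= 1e-9
        assert eq.state.H == pytest.approx(3.0, abs=1e-8)
        assert eq.state.D == eq.state.P == eq.state.B == 0.0

    def test_parasite_only_endemic(self, params):
        init = MonomorphicState(2.0, 0.0, 0.1, 0.0)
        eq = solve_equilibrium(init, params,
                               traits=ResidentTraits(y=None, beta_P=2.0))
        assert eq.converged and eq.residual <= 1e-9
        assert eq.state.P > 0.05
        # the parasite depresses the host population below its
        # disease-free density (a - b)/q = 3
        assert eq.state.N < 3.0

    def test_full_system_all_classes_positive(self, params):
        init = MonomorphicState(2.0, 0.1, 0.1, 0.0)
        eq = solve_equilibrium(init, params,
                               traits=ResidentTraits(y=0.5, beta_P=2.0))
        assert eq.converged and eq.residual <= 1e-9
        st = eq.state
        assert min(st.H, st.D, st.P, st.B) > 1e-4
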