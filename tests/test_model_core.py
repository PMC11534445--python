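"""Unit and property tests for the flux equations and assembled RHS."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import scavsim as sv
from scavsim.model_core import (
    boar_carrion_portion,
    boar_intake_capacity,
    boar_realized_intake,
    carrion_pool_boar,
    carrion_pool_deer,
    holling2,
    hunting_flux,
    natural_mortality_prey,
    predation_fluxes,
    rhs_array,
    scavenger_carrion_growth,
    scavenger_intake_capacity,
    vegetation_growth,
)

DENSITY = st.floats(min_value=0.0, max_value=20.0, allow_nan=False)
POSITIVE = st.floats(min_value=1e-6, max_value=20.0, allow_nan=False)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class TestDomainTypes:
    def test_state_rejects_negative_and_nonfinite(self):
        with pytest.raises(ValueError):
            sv.StateVector(V=-0.1)
        with pytest.raises(ValueError):
            sv.StateVector(D=float("nan"))

    def test_state_roundtrip(self):
        s = sv.StateVector(V=1, D=2, B=3, S=4, W=5)
        assert sv.StateVector.from_array(s.as_array()) == s

    @pytest.mark.parametrize(
        "bad",
        [
            {"C_VD": 1.5},        # fraction above 1
            {"u_a": 0.3},         # exceeds u = 0.2
            {"M_D": -0.1},        # negative rate
            {"B_u": 0.0},         # half-saturation must be positive
            {"carrion_dialect": "other"},
        ],
    )
    def test_parameter_validation(self, bad):
        with pytest.raises(ValueError):
            sv.ParameterSet(**bad)

    def test_defaults_match_calibrated_values(self, params):
        # spot-check the three parameters revised during calibration
        assert params.C_VD == 0.025
        assert params.C_XS == 0.1
        assert params.M_W == 0.2


# ---------------------------------------------------------------------------
# individual flux operations (frozen examples)
# ---------------------------------------------------------------------------

class TestFluxOperations:
    def test_vegetation_growth(self, params):
        assert vegetation_growth(sv.StateVector(V=10.0), params) == 0.0
        assert vegetation_growth(sv.StateVector(V=0.0), params) == 0.0
        assert vegetation_growth(sv.StateVector(V=5.0), params) == pytest.approx(10.0)
        # overshoot damping is the only admissible negative growth
        assert vegetation_growth(sv.StateVector(V=12.0), params) < 0.0

    def test_holling2(self):
        assert holling2(0.0, 23.5, 10.0) == 0.0
        assert holling2(10.0, 23.5, 10.0) == pytest.approx(11.75)
        with pytest.raises(ValueError):
            holling2(1.0, 23.5, 0.0)

    @given(resource=DENSITY, bigger=POSITIVE)
    def test_holling2_monotone_and_bounded(self, resource, bigger):
        lo = holling2(resource, 23.5, 10.0)
        hi = holling2(resource + bigger, 23.5, 10.0)
        assert lo <= hi <= 23.5

    def test_boar_carrion_portion(self, params):
        assert boar_carrion_portion(1.0, 0.0, params) == 0.0
        assert boar_carrion_portion(0.0, 1.0, params) == 0.0
        # per-capita supply x = 2.015/20.15 = 0.1 -> u/2
        assert boar_carrion_portion(2.015, 1.0, params) == pytest.approx(0.1)

    @given(K_D=DENSITY, B=POSITIVE)
    def test_boar_carrion_portion_below_max(self, K_D, B, params):
        assert 0.0 <= boar_carrion_portion(K_D, B, params) < params.u

    def test_boar_intake_capacity(self, params):
        assert boar_intake_capacity(params.u_a, params) == pytest.approx(20.15)
        assert boar_intake_capacity(0.0, params) == pytest.approx(20.9706545, rel=1e-6)
        # decreasing in the carrion portion (carrion converts better)
        assert boar_intake_capacity(params.u, params) < 20.15 < boar_intake_capacity(0.0, params)

    def test_boar_realized_intake(self, params):
        cap = 20.0
        assert boar_realized_intake(0.0, 0.0, 0.0, cap, params) == 0.0
        assert boar_realized_intake(10.0, 0.0, 0.0, cap, params) == pytest.approx(cap / 2)
        # mixed resource m = 9*0.9 + 19*0.1 = 10 -> half-saturation again
        assert boar_realized_intake(9.0, 19.0, 0.1, cap, params) == pytest.approx(cap / 2)

    def test_carrion_pools(self, params):
        assert carrion_pool_deer(0.0, 0.0, 0.0, params) == 0.0
        assert carrion_pool_deer(0.1, 0.2, 0.5, params) == pytest.approx(0.36)
        everything = params.replace(L_D=1.0, L_B=1.0, v=1.0)
        assert carrion_pool_boar(0.1, 0.2, 0.5, everything) == pytest.approx(0.8)

    @given(death=DENSITY, hunt=DENSITY, pred=DENSITY, delta=st.floats(0, 0.5))
    def test_carrion_pool_monotone_in_leftovers(self, death, hunt, pred, delta, params):
        base = carrion_pool_deer(death, hunt, pred, params)
        more_left = carrion_pool_deer(death, hunt, pred, params.replace(L_D=min(params.L_D + delta, 1.0)))
        more_uncons = carrion_pool_deer(death, hunt, pred, params.replace(v=min(params.v + delta, 1.0)))
        assert more_left >= base and more_uncons >= base

    def test_scavenger_intake_capacity(self, params):
        assert scavenger_intake_capacity(0.0, 0.0, 0.0, params) == 0.0
        assert scavenger_intake_capacity(10.0, 0.0, 0.0, params) == pytest.approx(10.0)
        # depends only on the total resource
        assert scavenger_intake_capacity(5.0, 3.0, 2.0, params) == pytest.approx(10.0)

    def test_predation_fluxes(self, params):
        assert predation_fluxes(sv.StateVector(D=1, B=1), params) == (0.0, 0.0)
        d, b = predation_fluxes(sv.StateVector(D=2, B=2, W=0.5), params)
        assert d == pytest.approx(b)
        d, b = predation_fluxes(sv.StateVector(D=10, B=0, W=0.1), params)
        assert (d, b) == (pytest.approx(4.83), 0.0)

    @given(D=POSITIVE, B=POSITIVE, W=POSITIVE)
    def test_predation_conserves_total(self, D, B, W, params):
        state = sv.StateVector(D=D, B=B, W=W)
        d, b = predation_fluxes(state, params)
        total = params.r * (D + B) / (params.B_XX + D + B) * W
        assert d + b == pytest.approx(total, rel=1e-12)

    def test_hunting_flux(self):
        assert hunting_flux(0.4, 0.5, 1.0) == 0.0
        assert hunting_flux(0.5, 0.5, 1.0) == 0.0
        assert hunting_flux(2.0, 0.0, 0.7) == pytest.approx(1.4)  # proportional when T=0
        assert hunting_flux(1.0, 0.5, 1.0) == pytest.approx(0.25)

    @given(X=st.floats(0.5, 20.0), eps=st.floats(1e-9, 1e-6))
    def test_hunting_continuity_at_target(self, X, eps):
        T = 0.5
        assert hunting_flux(T + eps, T, 1.0) < 1e-5
        assert hunting_flux(X + eps, T, 1.0) >= hunting_flux(X, T, 1.0)

    def test_natural_mortality(self, params):
        assert natural_mortality_prey(1.0, 1.0, 0.0, 0.125, 10.0) == pytest.approx(0.125)
        assert natural_mortality_prey(0.0, 0.0, 1.0, 0.125, 10.0) == 0.0
        # D=1, B=0, W=0.1: share 1, exponent -1
        assert natural_mortality_prey(1.0, 1.0, 0.1, 0.125, 10.0) == pytest.approx(
            0.125 * math.exp(-1.0)
        )

    @given(X=DENSITY, share=st.floats(0, 1), W=DENSITY)
    def test_mortality_never_exceeds_baseline(self, X, share, W):
        assert natural_mortality_prey(X, share, W, 0.125, 10.0) <= 0.125 * X + 1e-15

    def test_scavenger_carrion_growth_caps(self):
        assert scavenger_carrion_growth(5.0, 1.0, 0.0, 0.1) == 0.0
        assert scavenger_carrion_growth(5.0, 1.0, 2.0, 0.1) == pytest.approx(0.2)  # pool binds
        assert scavenger_carrion_growth(1.0, 1.0, 2.0, 0.1) == pytest.approx(0.1)  # demand binds

    def test_scavenger_carrion_growth_proportional_dialect(self):
        # demand 10 apportioned by pool share 2/8 -> 2.5, capped at pool 2
        value = scavenger_carrion_growth(10.0, 1.0, 2.0, 0.1, "proportional", 8.0)
        assert value == pytest.approx(0.2)
        # small demand: apportioned 1*2/8 = 0.25 below the pool
        value = scavenger_carrion_growth(1.0, 1.0, 2.0, 0.1, "proportional", 8.0)
        assert value == pytest.approx(0.025)


class TestRateDerivation:
    @pytest.mark.parametrize(
        "food,weight,unconsumed,expected,digits",
        [
            (986.0, 42.0, 0.0, 23.5, 1),     # deer intake
            (1209.0, 60.0, 0.0, 20.15, 2),   # boar intake
            (1642.5, 25.0, 0.32, 96.6, 1),   # wolf predation, corrected for leftovers
        ],
    )
    def test_printed_rates(self, food, weight, unconsumed, expected, digits):
        rate = sv.derive_rate_from_life_history(food, weight, unconsumed)
        assert round(rate, digits) == expected

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            sv.derive_rate_from_life_history(100.0, 0.0)
        with pytest.raises(ValueError):
            sv.derive_rate_from_life_history(100.0, 10.0, 1.0)


# ---------------------------------------------------------------------------
# assembled right-hand side
# ---------------------------------------------------------------------------

def naive_rhs(y, p):
    """Independent single-expression transcription of the five rate equations.

    Deliberately written as one flat block (no shared helpers with the
    package) to serve as an oracle for the assembled RHS.
    """
    V, D, B, S, W = y
    sq = D * D + B * B
    shareD = D * D / sq if sq > 0 else 0.0
    shareB = B * B / sq if sq > 0 else 0.0
    Dpred = p.r * (D + B) / (p.B_XX + D + B) * shareD * W if sq > 0 else 0.0
    Bpred = p.r * (D + B) / (p.B_XX + D + B) * shareB * W if sq > 0 else 0.0
    Dhunt = 0.0 if D <= p.T_D else (1 - p.T_D / D) * p.H_D * (D - p.T_D)
    Bhunt = 0.0 if B <= p.T_B else (1 - p.T_B / B) * p.H_B * (B - p.T_B)
    Ddeath = math.exp(-p.q * W * shareD) * p.M_D * D
    Bdeath = math.exp(-p.q * W * shareB) * p.M_B * B
    KD = Ddeath + Dhunt * p.L_D + Dpred * p.v
    KB = Bdeath + Bhunt * p.L_B + Bpred * p.v
    if B > 0 and KD > 0:
        x = KD / (p.A_XB * B)
        u_dd = p.u * x / (p.B_u + x)
    else:
        u_dd = 0.0
    A_dd = p.A_XB * (p.C_VB * (1 - p.u_a) + p.C_DB * p.u_a) / (
        p.C_VB * (1 - u_dd) + p.C_DB * u_dd
    )
    m = V * (1 - u_dd) + KD * u_dd
    A_td = A_dd * m / (p.B_XX + m) if m > 0 else 0.0
    VconsB = B * A_td * (1 - u_dd)
    BgrowthD = A_td * u_dd * B * p.C_DB
    KD_avail = max(KD - A_td * u_dd * B, 0.0)
    total = V + KD_avail + KB
    A_ds = p.A_XS * total / (p.B_XX + total) if total > 0 else 0.0
    VconsS = S * A_ds * V / total if total > 0 else 0.0
    SgrowthD = min(A_ds * S, KD_avail) * p.C_XS if KD_avail > 0 else 0.0
    SgrowthB = min(A_ds * S, KB) * p.C_XS if KB > 0 else 0.0
    VconsD = D * p.A_VD * V / (p.B_XX + V)
    return [
        p.R0 * V * (1 - V / p.k0) - VconsD - VconsB - VconsS,
        VconsD * p.C_VD - Dpred - Dhunt - Ddeath,
        VconsB * p.C_VB + BgrowthD - Bpred - Bhunt - Bdeath,
        VconsS * p.C_VS + SgrowthD + SgrowthB - p.M_S * S,
        (Dpred + Bpred) * p.C_XW * (1 - p.v) - p.M_W * W,
    ]


class TestAssembledRHS:
    def test_extinction_is_absorbing(self, params):
        deriv, fl = sv.rhs(0.0, sv.StateVector(), params)
        assert np.all(deriv == 0.0)
        # all true fluxes vanish; per-capita intake capacities are rates,
        # and the boar capacity is legitimately nonzero at an empty state
        per_capita = {"A_ddot_XB", "A_tdot_XB", "A_ddot_XS"}
        assert all(
            value == 0.0 for name, value in fl.as_dict().items() if name not in per_capita
        )

    def test_vegetation_only_reduces_to_logistic(self, params):
        deriv, _ = sv.rhs(0.0, sv.StateVector(V=5.0), params)
        assert deriv[0] == pytest.approx(10.0)
        assert np.all(deriv[1:] == 0.0)

    def test_rhs_matches_naive_transcription(self, params, random_states):
        for state in random_states:
            got = rhs_array(0.0, state.as_array(), params)
            want = naive_rhs(state.as_array(), params)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-14)

    def test_rhs_matches_flux_breakdown(self, params, random_states):
        for state in random_states[:50]:
            deriv, fl = sv.rhs(0.0, state, params)
            np.testing.assert_array_equal(deriv, fl.derivatives())

    def test_rhs_rejects_nonfinite_state(self, params):
        with pytest.raises(ValueError):
            rhs_array(0.0, [1.0, float("nan"), 0.0, 0.0, 0.0], params)

    def test_flux_nonnegativity_closure(self, params, random_states):
        for state in random_states[:200]:
            fl = sv.evaluate_fluxes(state, params)
            for name, value in fl.as_dict().items():
                if name == "Vgrowth" and state.V > params.k0:
                    continue
                assert value >= 0.0, f"{name} < 0 at {state}"
            assert fl.u_dd < params.u
            assert fl.K_D_avail == pytest.approx(
                max(fl.K_D - fl.A_tdot_XB * fl.u_dd * state.B, 0.0)
            )

    def test_carrion_caps(self, params, random_states):
        for state in random_states[:200]:
            fl = sv.evaluate_fluxes(state, params)
            assert fl.SgrowthD <= fl.K_D_avail * params.C_XS + 1e-15
            assert fl.SgrowthB <= fl.K_B * params.C_XS + 1e-15
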