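"""Five-state trophic-web model: vegetation, deer, boar, facultative scavengers, wolf.

The model tracks biomass densities (ton ha^-1) of a shared vegetation pool
(V), two hunted ungulate guilds — deer (D) and wild boar (B) — an aggregated
facultative-scavenger guild (S), and the wolf (W).  Time is in years and all
rates in yr^-1.  Consumption follows Holling type-II functional responses
with a single shared half-saturation density ``B_XX``; scavenger carrion
uptake is a capped (type-I) response on the instantaneous carrion flux.

Carrion is bookkept as a *flux* (ton ha^-1 yr^-1), not a standing stock:
the deer pool ``K_D`` and boar pool ``K_B`` collect, at each instant,
natural mortality, the fraction of hunted biomass left in the field, and
the fraction of wolf kills not consumed by the wolf.  Boar scavenge deer
carrion first; only the remainder (``K_D_avail``) is available to the
scavenger guild.  Wolves do not scavenge and nobody scavenges wolf carrion;
boar do not scavenge conspecifics.

Every named flux of the right-hand side is exposed in :class:`FluxBreakdown`
so that trajectories carry a full audit trail of where each guild's growth
and loss came from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable

import numpy as np

__all__ = [
    "StateVector",
    "ParameterSet",
    "FluxBreakdown",
    "STATE_NAMES",
    "FLUX_NAMES",
    "FRACTION_PARAMS",
    "vegetation_growth",
    "holling2",
    "boar_carrion_portion",
    "boar_intake_capacity",
    "boar_realized_intake",
    "carrion_pool",
    "scavenger_intake_capacity",
    "scavenger_carrion_growth",
    "predation_fluxes",
    "hunting_flux",
    "natural_mortality_prey",
    "evaluate_fluxes",
    "rhs",
    "rhs_array",
    "derive_rate_from_life_history",
]

STATE_NAMES = ("V", "D", "B", "S", "W")


@dataclass(frozen=True)
class StateVector:
    """Instantaneous biomass densities (ton ha^-1) of the five guilds."""

    V: float = 0.0
    D: float = 0.0
    B: float = 0.0
    S: float = 0.0
    W: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_NAMES:
            x = float(getattr(self, name))
            if not math.isfinite(x):
                raise ValueError(f"state component {name} must be finite, got {x!r}")
            if x < 0:
                raise ValueError(f"state component {name} must be >= 0, got {x}")
            object.__setattr__(self, name, x)

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.D, self.B, self.S, self.W], dtype=float)

    @classmethod
    def from_array(cls, y: Iterable[float]) -> "StateVector":
        v, d, b, s, w = (float(x) for x in y)
        return cls(V=v, D=d, B=b, S=s, W=w)

    def replace(self, **kwargs: float) -> "StateVector":
        return replace(self, **kwargs)


#: parameters that are fractions/conversion efficiencies, bounded in [0, 1]
FRACTION_PARAMS = frozenset(
    {"C_VD", "C_VB", "C_DB", "C_XS", "C_XW", "C_VS", "u_a", "u", "L_D", "L_B", "v"}
)

#: dialects for the scavenger carrion-uptake cap (see scavenger_carrion_growth)
CARRION_DIALECTS = ("literal", "proportional")


@dataclass(frozen=True)
class ParameterSet:
    """Model parameters with field defaults at their calibrated values.

    Units: densities in ton ha^-1, rates in yr^-1, conversion factors and
    diet fractions dimensionless.  The hunting regime (``T_*``, ``H_*``,
    ``L_*``) defaults to a medium-target policy and is normally overridden
    per scenario.
    """

    R0: float = 4.0          # vegetation regrowth rate (yr^-1)
    k0: float = 10.0         # vegetation carrying capacity (ton ha^-1)
    A_VD: float = 23.5       # max vegetation ingestion per unit deer (yr^-1)
    B_XX: float = 10.0       # shared half-saturation density (ton ha^-1)
    C_VD: float = 0.025      # vegetation -> deer conversion
    M_D: float = 0.125       # deer baseline death rate (yr^-1)
    A_XB: float = 20.15      # max total ingestion per unit boar (yr^-1)
    C_VB: float = 0.055      # vegetation -> boar conversion
    M_B: float = 0.08        # boar baseline death rate (yr^-1)
    u_a: float = 0.16        # average deer-carrion diet portion of boar
    u: float = 0.2           # maximum deer-carrion diet portion of boar
    B_u: float = 0.1         # half-saturation of the boar carrion-portion response
    C_DB: float = 0.069      # deer carrion -> boar conversion
    q: float = 10.0          # decay of natural prey mortality with predation pressure
    T_D: float = 0.5         # deer hunting target (ton ha^-1)
    H_D: float = 1.0         # deer hunting rate (yr^-1)
    L_D: float = 0.5         # fraction of hunted deer left in the field
    T_B: float = 0.5         # boar hunting target (ton ha^-1)
    H_B: float = 1.0         # boar hunting rate (yr^-1)
    L_B: float = 0.5         # fraction of hunted boar left in the field
    M_S: float = 0.2         # scavenger death rate (yr^-1)
    C_XS: float = 0.1        # carrion -> scavenger conversion
    M_W: float = 0.2         # wolf death rate (yr^-1)
    r: float = 96.6          # max predation rate per unit wolf (yr^-1)
    v: float = 0.32          # fraction of kills not consumed by the wolf
    C_XW: float = 0.038      # prey -> wolf conversion
    A_XS: float = 20.0       # max ingestion per unit scavenger (yr^-1)
    C_VS: float = 0.036      # vegetation -> scavenger conversion
    carrion_dialect: str = "literal"  # scavenger carrion-cap dialect

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "carrion_dialect":
                continue
            x = float(getattr(self, f.name))
            if not math.isfinite(x) or x < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0, got {x!r}")
            if f.name in FRACTION_PARAMS and x > 1:
                raise ValueError(f"parameter {f.name} is a fraction, must be <= 1, got {x}")
            object.__setattr__(self, f.name, x)
        if self.u_a > self.u:
            raise ValueError(f"u_a ({self.u_a}) must not exceed u ({self.u})")
        if self.B_u <= 0 or self.B_XX <= 0 or self.k0 <= 0:
            raise ValueError("B_u, B_XX and k0 must be strictly positive")
        if self.carrion_dialect not in CARRION_DIALECTS:
            raise ValueError(
                f"carrion_dialect must be one of {CARRION_DIALECTS}, got {self.carrion_dialect!r}"
            )

    @classmethod
    def numeric_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls) if f.name != "carrion_dialect")

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in self.numeric_names()}
        d["carrion_dialect"] = self.carrion_dialect
        return d

    def replace(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)


FLUX_NAMES = (
    "Vgrowth", "VconsD", "VconsB", "VconsS",
    "u_dd", "A_ddot_XB", "A_tdot_XB", "A_ddot_XS",
    "K_D", "K_B", "K_D_avail",
    "Dpred", "Bpred", "Dhunt", "Bhunt",
    "Ddeath", "Bdeath", "Sdeath", "Wdeath",
    "DgrowthV", "BgrowthV", "BgrowthD",
    "SgrowthV", "SgrowthD", "SgrowthB",
    "WgrowthD", "WgrowthB",
)


@dataclass(frozen=True, slots=True)
class FluxBreakdown:
    """Every named flux of the right-hand side, evaluated at one state.

    All entries are fluxes in ton ha^-1 yr^-1 except the three per-capita
    intake capacities (``A_ddot_XB``, ``A_tdot_XB``, ``A_ddot_XS``, yr^-1)
    and the realized boar carrion diet portion ``u_dd`` (dimensionless).
    """

    Vgrowth: float
    VconsD: float
    VconsB: float
    VconsS: float
    u_dd: float
    A_ddot_XB: float
    A_tdot_XB: float
    A_ddot_XS: float
    K_D: float
    K_B: float
    K_D_avail: float
    Dpred: float
    Bpred: float
    Dhunt: float
    Bhunt: float
    Ddeath: float
    Bdeath: float
    Sdeath: float
    Wdeath: float
    DgrowthV: float
    BgrowthV: float
    BgrowthD: float
    SgrowthV: float
    SgrowthD: float
    SgrowthB: float
    WgrowthD: float
    WgrowthB: float

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FLUX_NAMES}

    def derivatives(self) -> np.ndarray:
        """Assemble (dV/dt, dD/dt, dB/dt, dS/dt, dW/dt) from the fluxes."""
        return np.array(
            [
                self.Vgrowth - self.VconsD - self.VconsB - self.VconsS,
                self.DgrowthV - self.Dpred - self.Dhunt - self.Ddeath,
                self.BgrowthV + self.BgrowthD - self.Bpred - self.Bhunt - self.Bdeath,
                self.SgrowthV + self.SgrowthD + self.SgrowthB - self.Sdeath,
                self.WgrowthD + self.WgrowthB - self.Wdeath,
            ]
        )


# ---------------------------------------------------------------------------
# individual flux operations
# ---------------------------------------------------------------------------

def vegetation_growth(state: StateVector, params: ParameterSet) -> float:
    """Logistic vegetation regrowth R0*V*(1 - V/k0).

    Negative only on overshoot (V > k0), which damps the excursion back to
    the carrying capacity.
    """
    return params.R0 * state.V * (1.0 - state.V / params.k0)


def holling2(resource: float, rate: float, half_sat: float) -> float:
    """Holling type-II per-capita intake: rate*resource/(half_sat + resource)."""
    if half_sat <= 0:
        raise ValueError(f"half_sat must be > 0, got {half_sat}")
    if resource < 0:
        raise ValueError(f"resource must be >= 0, got {resource}")
    return rate * resource / (half_sat + resource)


def boar_carrion_portion(K_D: float, B: float, params: ParameterSet) -> float:
    """Realized deer-carrion portion of the boar diet.

    A saturating response of the per-capita carrion supply x = K_D/(A_XB*B):
    u*x/(B_u + x), strictly below the maximum portion u.  Defined as 0 when
    boar are absent or no deer carrion is produced (the mathematical limit).
    """
    if B <= 0.0 or K_D <= 0.0:
        return 0.0
    x = K_D / (params.A_XB * B)
    return params.u * x / (params.B_u + x)


def boar_intake_capacity(u_dd: float, params: ParameterSet) -> float:
    """Diet-corrected maximum boar intake.

    Boar aim at a fixed biomass gain: because deer carrion converts better
    than vegetation (C_DB > C_VB), total intake shrinks as the carrion
    portion of the diet rises above its average u_a.
    """
    denom = params.C_VB * (1.0 - u_dd) + params.C_DB * u_dd
    if denom <= 0:
        raise ValueError("degenerate diet conversion: C_VB(1-u)+C_DB*u must be > 0")
    num = params.C_VB * (1.0 - params.u_a) + params.C_DB * params.u_a
    return params.A_XB * num / denom


def boar_realized_intake(
    V: float, K_D: float, u_dd: float, A_ddot_XB: float, params: ParameterSet
) -> float:
    """Realized total boar intake: type-II response on the diet-mixed resource.

    The effective resource is m = V*(1-u_dd) + K_D*u_dd.
    """
    m = V * (1.0 - u_dd) + K_D * u_dd
    if m <= 0.0:
        return 0.0
    return A_ddot_XB * m / (params.B_XX + m)


def carrion_pool(
    death: float, hunt: float, leftover_fraction: float, pred: float, unconsumed_fraction: float
) -> float:
    """Instantaneous carrion flux: natural death + hunting leftovers + kill leftovers."""
    return death + hunt * leftover_fraction + pred * unconsumed_fraction


def carrion_pool_deer(
    Ddeath: float, Dhunt: float, Dpred: float, params: ParameterSet
) -> float:
    """Deer carrion flux K_D = Ddeath + Dhunt*L_D + Dpred*v."""
    return carrion_pool(Ddeath, Dhunt, params.L_D, Dpred, params.v)


def carrion_pool_boar(
    Bdeath: float, Bhunt: float, Bpred: float, params: ParameterSet
) -> float:
    """Boar carrion flux K_B = Bdeath + Bhunt*L_B + Bpred*v."""
    return carrion_pool(Bdeath, Bhunt, params.L_B, Bpred, params.v)


def scavenger_intake_capacity(
    V: float, K_D_avail: float, K_B: float, params: ParameterSet
) -> float:
    """Scavenger per-capita intake: type-II response on V + available carrion.

    ``K_D_avail`` is the deer carrion flux net of boar consumption — boar
    scavenge deer carcasses first, so only the remainder reaches the guild.
    """
    total = V + K_D_avail + K_B
    if total <= 0.0:
        return 0.0
    return params.A_XS * total / (params.B_XX + total)


def scavenger_carrion_growth(
    A_ddot_XS: float,
    S: float,
    pool_avail: float,
    C_XS: float,
    dialect: str = "literal",
    resource_total: float | None = None,
) -> float:
    """Scavenger growth from one carrion pool: capped (type-I) uptake.

    The ``literal`` dialect caps total demand ``A_ddot_XS*S`` at the pool
    itself; the ``proportional`` dialect first apportions demand to the
    pool by its share of the total resource (vegetation + both carrion
    pools), mirroring how vegetation consumption is apportioned.
    """
    if pool_avail <= 0.0:
        return 0.0
    demand = A_ddot_XS * S
    if dialect == "proportional":
        if resource_total is None or resource_total <= 0.0:
            return 0.0
        demand *= pool_avail / resource_total
    elif dialect != "literal":
        raise ValueError(f"unknown carrion dialect {dialect!r}")
    return min(demand, pool_avail) * C_XS


def predation_fluxes(state: StateVector, params: ParameterSet) -> tuple[float, float]:
    """Wolf predation on deer and boar with squared prey preference.

    Total offtake is a type-II response on combined prey density; it is
    split in proportion to the squared biomasses D^2 : B^2, sharpening the
    wolf's selection for the more abundant prey.  Both fluxes are 0 when
    no prey is present.
    """
    D, B, W = state.D, state.B, state.W
    prey = D + B
    sq = D * D + B * B
    if sq <= 0.0 or W <= 0.0:
        return 0.0, 0.0
    total = params.r * prey / (params.B_XX + prey) * W
    return total * D * D / sq, total * B * B / sq


def hunting_flux(X: float, T: float, H: float) -> float:
    """Quota hunting: nothing below the target T, H*(X-T)^2/X above it.

    The (1 - T/X) efficiency factor models the increasing difficulty of
    finding animals as density approaches the target; the flux is
    continuous at X = T.
    """
    if X <= T or X <= 0.0:
        return 0.0
    return (1.0 - T / X) * H * (X - T)


def natural_mortality_prey(
    X: float, own_sq_share: float, W: float, M: float, q: float
) -> float:
    """Background prey mortality, suppressed by predation pressure.

    Wolves preferentially take old and weak animals, lowering natural
    mortality: exp(-q*W*share)*M*X, where share = X^2/(D^2+B^2) is the same
    squared preference weight used to split predation.
    """
    return math.exp(-q * W * own_sq_share) * M * X


# ---------------------------------------------------------------------------
# assembled right-hand side
# ---------------------------------------------------------------------------

def _compute_fluxes(
    V: float, D: float, B: float, S: float, W: float, p: ParameterSet
) -> tuple:
    """Evaluate every flux at one (clamped non-negative) state.

    Returns the values in FLUX_NAMES order.  Evaluation follows the flux
    dependency chain: predation/hunting/mortality -> deer carrion pool ->
    boar diet correction -> boar carrion consumption -> boar carrion pool ->
    residual deer carrion -> scavenger intake -> growth conversions.
    """
    if V < 0.0:
        V = 0.0
    if D < 0.0:
        D = 0.0
    if B < 0.0:
        B = 0.0
    if S < 0.0:
        S = 0.0
    if W < 0.0:
        W = 0.0

    Vgrowth = p.R0 * V * (1.0 - V / p.k0)

    # predation, hunting, natural mortality of the two prey guilds
    prey = D + B
    sq = D * D + B * B
    if sq > 0.0:
        shareD = D * D / sq
        shareB = B * B / sq
    else:
        shareD = shareB = 0.0
    if sq > 0.0 and W > 0.0:
        total_pred = p.r * prey / (p.B_XX + prey) * W
        Dpred = total_pred * shareD
        Bpred = total_pred * shareB
    else:
        Dpred = Bpred = 0.0

    Dhunt = hunting_flux(D, p.T_D, p.H_D)
    Bhunt = hunting_flux(B, p.T_B, p.H_B)
    Ddeath = math.exp(-p.q * W * shareD) * p.M_D * D
    Bdeath = math.exp(-p.q * W * shareB) * p.M_B * B

    # deer carrion pool, boar diet correction and realized intake
    K_D = Ddeath + Dhunt * p.L_D + Dpred * p.v
    u_dd = boar_carrion_portion(K_D, B, p)
    A_ddot_XB = boar_intake_capacity(u_dd, p)
    A_tdot_XB = boar_realized_intake(V, K_D, u_dd, A_ddot_XB, p)
    VconsB = B * A_tdot_XB * (1.0 - u_dd)
    BgrowthD = A_tdot_XB * u_dd * B * p.C_DB

    K_B = Bdeath + Bhunt * p.L_B + Bpred * p.v
    K_D_avail = K_D - A_tdot_XB * u_dd * B
    if K_D_avail < 0.0:
        K_D_avail = 0.0

    # scavenger intake over vegetation + residual carrion
    A_ddot_XS = scavenger_intake_capacity(V, K_D_avail, K_B, p)
    resource_total = V + K_D_avail + K_B
    if resource_total > 0.0:
        VconsS = S * A_ddot_XS * V / resource_total
    else:
        VconsS = 0.0
    SgrowthD = scavenger_carrion_growth(
        A_ddot_XS, S, K_D_avail, p.C_XS, p.carrion_dialect, resource_total
    )
    SgrowthB = scavenger_carrion_growth(
        A_ddot_XS, S, K_B, p.C_XS, p.carrion_dialect, resource_total
    )

    # vegetation consumption by deer, growth conversions, static mortality
    VconsD = D * p.A_VD * V / (p.B_XX + V)
    DgrowthV = VconsD * p.C_VD
    BgrowthV = VconsB * p.C_VB
    SgrowthV = VconsS * p.C_VS
    one_minus_v = 1.0 - p.v
    WgrowthD = Dpred * p.C_XW * one_minus_v
    WgrowthB = Bpred * p.C_XW * one_minus_v
    Sdeath = p.M_S * S
    Wdeath = p.M_W * W

    return (
        Vgrowth, VconsD, VconsB, VconsS,
        u_dd, A_ddot_XB, A_tdot_XB, A_ddot_XS,
        K_D, K_B, K_D_avail,
        Dpred, Bpred, Dhunt, Bhunt,
        Ddeath, Bdeath, Sdeath, Wdeath,
        DgrowthV, BgrowthV, BgrowthD,
        SgrowthV, SgrowthD, SgrowthB,
        WgrowthD, WgrowthB,
    )


def evaluate_fluxes(state: StateVector, params: ParameterSet) -> FluxBreakdown:
    """Full flux audit trail at one state."""
    return FluxBreakdown(*_compute_fluxes(state.V, state.D, state.B, state.S, state.W, params))


def rhs(t: float, state: StateVector, params: ParameterSet) -> tuple[np.ndarray, FluxBreakdown]:
    """Time derivative of the five states plus the flux breakdown behind it.

    The system is autonomous; ``t`` is accepted for solver compatibility.
    """
    fl = evaluate_fluxes(state, params)
    return fl.derivatives(), fl


def rhs_array(t: float, y, params: ParameterSet) -> list[float]:
    """Solver-facing derivative: plain sequence in, plain list out.

    Components are clamped at 0 before evaluation, so small negative
    excursions of the integrator cannot feed back into the dynamics.
    """
    V, D, B, S, W = (float(x) for x in y)
    if not (
        math.isfinite(V) and math.isfinite(D) and math.isfinite(B)
        and math.isfinite(S) and math.isfinite(W)
    ):
        raise ValueError(f"non-finite state at t={t}: {(V, D, B, S, W)}")
    f = _compute_fluxes(V, D, B, S, W, params)
    (Vgrowth, VconsD, VconsB, VconsS, _u_dd, _axb, _atxb, _axs,
     _kd, _kb, _kda, Dpred, Bpred, Dhunt, Bhunt, Ddeath, Bdeath,
     Sdeath, Wdeath, DgrowthV, BgrowthV, BgrowthD,
     SgrowthV, SgrowthD, SgrowthB, WgrowthD, WgrowthB) = f
    return [
        Vgrowth - VconsD - VconsB - VconsS,
        DgrowthV - Dpred - Dhunt - Ddeath,
        BgrowthV + BgrowthD - Bpred - Bhunt - Bdeath,
        SgrowthV + SgrowthD + SgrowthB - Sdeath,
        WgrowthD + WgrowthB - Wdeath,
    ]


def derive_rate_from_life_history(
    annual_food_req: float, mean_weight: float, unconsumed_fraction: float = 0.0
) -> float:
    """Per-unit-biomass intake rate from individual life-history numbers.

    Divides the annual individual food requirement (kg yr^-1) by the mean
    individual weight (kg); when a fraction of the acquired biomass is not
    consumed (e.g. wolf kills left in the field), the rate is inflated by
    1/(1 - unconsumed_fraction) so the consumed amount still meets the
    requirement.
    """
    if mean_weight <= 0:
        raise ValueError(f"mean_weight must be > 0, got {mean_weight}")
    if not 0.0 <= unconsumed_fraction < 1.0:
        raise ValueError(
            f"unconsumed_fraction must be in [0, 1), got {unconsumed_fraction}"
        )
    return (annual_food_req / mean_weight) / (1.0 - unconsumed_fraction)
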