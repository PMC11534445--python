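"""Scenario construction: presence/absence grids and incremental model building.

A scenario fixes which guilds are present (absence is encoded by a zero
initial biomass — the dynamics then never create the guild) and the human
hunting regime (targets T, rates H, leftover fractions L for deer and
boar).  The default factorial grid crosses the four presence combinations
(boar and wolf each present/absent) with hunting-target and leftover
levels, varying T_D = T_B and L_D = L_B jointly as single "hunting target"
and "fraction left" factors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import Iterable, Sequence

from .integrator import RunSettings, Trajectory, solve
from .model_core import ParameterSet, StateVector

__all__ = [
    "ScenarioConfig",
    "DEFAULT_INITIAL",
    "DEFAULT_TARGETS",
    "DEFAULT_LEFTOVERS",
    "ALL_PRESENCE",
    "build_scenario_grid",
    "incremental_build_sequence",
    "apply_scenario",
    "run_scenarios",
]

#: default initial biomasses (ton ha^-1) for guilds that are present
DEFAULT_INITIAL = StateVector(V=5.0, D=0.5, B=0.5, S=0.1, W=0.05)

#: hunting-target levels: zero (maximal hunting), medium, high target
DEFAULT_TARGETS = (0.0, 0.5, 1.0)
#: leftover-fraction levels: carcasses removed, half left, all left
DEFAULT_LEFTOVERS = (0.0, 0.5, 1.0)
#: (boar_present, wolf_present) combinations
ALL_PRESENCE = ((True, True), (True, False), (False, True), (False, False))


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: guild presence, hunting regime, initial state."""

    boar_present: bool = True
    wolf_present: bool = True
    T_D: float = 0.5
    T_B: float = 0.5
    H_D: float = 1.0
    H_B: float = 1.0
    L_D: float = 0.5
    L_B: float = 0.5
    initial: StateVector = DEFAULT_INITIAL
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("T_D", "T_B", "H_D", "H_B", "L_D", "L_B"):
            x = float(getattr(self, name))
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {x}")
        init = self.initial
        if not self.boar_present and init.B != 0.0:
            init = init.replace(B=0.0)
        if not self.wolf_present and init.W != 0.0:
            init = init.replace(W=0.0)
        object.__setattr__(self, "initial", init)
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        boar = "boar" if self.boar_present else "noboar"
        wolf = "wolf" if self.wolf_present else "nowolf"
        return f"{boar}-{wolf}_T{self.T_D:g}_L{self.L_D:g}"

    def with_initial(self, initial: StateVector) -> "ScenarioConfig":
        cfg = replace(self, initial=initial, label=self.label)
        return cfg


def apply_scenario(params: ParameterSet, config: ScenarioConfig) -> ParameterSet:
    """Overlay the scenario's hunting regime on a parameter set."""
    return params.replace(
        T_D=config.T_D,
        T_B=config.T_B,
        H_D=config.H_D,
        H_B=config.H_B,
        L_D=config.L_D,
        L_B=config.L_B,
    )


def build_scenario_grid(
    targets: Sequence[float] = DEFAULT_TARGETS,
    leftovers: Sequence[float] = DEFAULT_LEFTOVERS,
    presence: Sequence[tuple[bool, bool]] = ALL_PRESENCE,
    hunting_rate: float = 1.0,
    initial: StateVector = DEFAULT_INITIAL,
) -> list[ScenarioConfig]:
    """Cartesian product presence x targets x leftovers.

    Targets and leftover fractions are varied jointly for deer and boar
    (T_D = T_B, L_D = L_B); the hunting rate is shared.  Labels encode all
    three factors.
    """
    if not targets or not leftovers or not presence:
        raise ValueError("targets, leftovers and presence must be non-empty")
    for name, values in (("target", targets), ("leftover", leftovers)):
        for x in values:
            if not 0.0 <= float(x) <= 1.0:
                raise ValueError(f"{name} level {x} outside [0, 1]")
    if not 0.0 <= hunting_rate <= 1.0:
        raise ValueError(f"hunting_rate must lie in [0, 1], got {hunting_rate}")

    grid = []
    for (boar, wolf), target, leftover in product(presence, targets, leftovers):
        grid.append(
            ScenarioConfig(
                boar_present=boar,
                wolf_present=wolf,
                T_D=float(target),
                T_B=float(target),
                H_D=hunting_rate,
                H_B=hunting_rate,
                L_D=float(leftover),
                L_B=float(leftover),
                initial=initial,
            )
        )
    return grid


def incremental_build_sequence(
    params: ParameterSet, initial: StateVector = DEFAULT_INITIAL
) -> list[ScenarioConfig]:
    """Step-wise model-building sequence, from vegetation-only to the full web.

    Each step zeroes the initial biomass of the guilds not yet introduced:
    V; V+D; V+B; V+D+B; V+D+B+S; V+D+B+S+W.
    """
    zero = {"D": 0.0, "B": 0.0, "S": 0.0, "W": 0.0}
    steps = [
        ("V", zero),
        ("V+D", {"B": 0.0, "S": 0.0, "W": 0.0}),
        ("V+B", {"D": 0.0, "S": 0.0, "W": 0.0}),
        ("V+D+B", {"S": 0.0, "W": 0.0}),
        ("V+D+B+S", {"W": 0.0}),
        ("V+D+B+S+W", {}),
    ]
    configs = []
    for label, zeroed in steps:
        configs.append(
            ScenarioConfig(
                boar_present="B" not in zeroed,
                wolf_present="W" not in zeroed,
                T_D=params.T_D,
                T_B=params.T_B,
                H_D=params.H_D,
                H_B=params.H_B,
                L_D=params.L_D,
                L_B=params.L_B,
                initial=initial.replace(**zeroed),
                label=label,
            )
        )
    return configs


def run_scenarios(
    configs: Iterable[ScenarioConfig],
    params: ParameterSet,
    settings: RunSettings | None = None,
) -> list[Trajectory]:
    """Integrate every scenario; deterministic and order-independent.

    Integration failures are re-raised with the scenario label attached.
    """
    settings = settings or RunSettings()
    out = []
    for config in configs:
        scenario_params = apply_scenario(params, config)
        try:
            out.append(
                solve(config.initial, scenario_params, settings, scenario_id=config.label)
            )
        except Exception as exc:
            raise type(exc)(f"scenario {config.label!r}: {exc}") from exc
    return out
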