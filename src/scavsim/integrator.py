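"""Numerical integration of the trophic-web ODE system.

Uses SciPy's LSODA (stiffness-switching Adams/BDF) via ``solve_ivp``, which
adapts its step size and switches between stiff and non-stiff methods as
the dynamics demand — predator-prey cycles near extinction boundaries are
stiff, the vegetation-only limit is not.

Biomasses are physically non-negative: the right-hand side clamps each
component at 0 before evaluation, and output states below the extinction
floor are snapped to exactly 0.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import (
    FLUX_NAMES,
    STATE_NAMES,
    FluxBreakdown,
    ParameterSet,
    StateVector,
    evaluate_fluxes,
    rhs_array,
)

__all__ = ["RunSettings", "Trajectory", "IntegrationError", "solve", "equilibrium_summary"]


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failing time and state."""

    def __init__(self, message: str, t: float | None = None, state=None):
        super().__init__(message)
        self.t = t
        self.state = state


@dataclass(frozen=True)
class RunSettings:
    """Integration horizon, output grid and solver tolerances.

    ``extinction_floor`` is the density below which a state is treated as
    extinct and reported as exactly 0 on the output grid.
    """

    t_end: float = 250.0
    output_step: float = 1.0
    rtol: float = 1e-8
    atol: float = 1e-10
    extinction_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError(f"t_end must be > 0, got {self.t_end}")
        if self.output_step <= 0:
            raise ValueError(f"output_step must be > 0, got {self.output_step}")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.extinction_floor < 0:
            raise ValueError("extinction_floor must be >= 0")

    def grid(self) -> np.ndarray:
        n = int(round(self.t_end / self.output_step))
        t = np.arange(n + 1, dtype=float) * self.output_step
        if t[-1] < self.t_end - 1e-12:
            t = np.append(t, self.t_end)
        else:
            t[-1] = self.t_end
        return t

    def as_dict(self) -> dict:
        return {
            "t_end": self.t_end,
            "output_step": self.output_step,
            "rtol": self.rtol,
            "atol": self.atol,
            "extinction_floor": self.extinction_floor,
        }


def _hash_inputs(initial: StateVector, params: ParameterSet, settings: RunSettings) -> str:
    payload = json.dumps(
        {
            "initial": list(initial.as_array()),
            "params": params.as_dict(),
            "settings": settings.as_dict(),
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class Trajectory:
    """One simulation run: output times, states and the flux audit trail.

    ``states`` has shape (n_times, 5) in V, D, B, S, W order; ``fluxes``
    has shape (n_times, len(FLUX_NAMES)), recomputed from the integrated
    state at each output time.
    """

    times: np.ndarray
    states: np.ndarray
    fluxes: np.ndarray
    scenario_id: str = "run"
    params_hash: str = ""
    params: ParameterSet | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.times[0] != 0.0:
            raise ValueError("output grid must start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("output times must be strictly increasing")
        if np.any(self.states < 0):
            raise ValueError("trajectory states must be non-negative")

    def state_at(self, index: int) -> StateVector:
        return StateVector.from_array(self.states[index])

    def flux_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fluxes, columns=list(FLUX_NAMES), index=self.times)

    def state_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.states, columns=list(STATE_NAMES), index=self.times)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format frame: (scenario_id, time, variable, value)."""
        wide = pd.concat([self.state_frame(), self.flux_frame()], axis=1)
        tidy = wide.reset_index(names="time").melt(id_vars="time", var_name="variable")
        tidy.insert(0, "scenario_id", self.scenario_id)
        return tidy

    def window_mean(self, name: str, window: float) -> float:
        """Mean of one state or flux over the final ``window`` years."""
        mask = self.times >= self.times[-1] - window
        if name in STATE_NAMES:
            col = self.states[:, STATE_NAMES.index(name)]
        elif name in FLUX_NAMES:
            col = self.fluxes[:, FLUX_NAMES.index(name)]
        else:
            raise KeyError(f"unknown variable {name!r}")
        return float(col[mask].mean())


def solve(
    initial: StateVector,
    params: ParameterSet,
    settings: RunSettings | None = None,
    scenario_id: str = "run",
) -> Trajectory:
    """Integrate the system from ``initial`` and return the trajectory.

    The flux breakdown at each output time is recomputed from the
    integrated (clamped) state, so the audit trail is exactly consistent
    with the reported states.
    """
    settings = settings or RunSettings()
    t_eval = settings.grid()
    y0 = initial.as_array()

    # Integrate one output interval at a time, snapping sub-floor components
    # to exactly 0 between intervals.  A truly absent guild then stays absent:
    # integrator round-off (~atol) can otherwise seed a structurally extinct
    # state and let it regrow.
    states = np.empty((t_eval.size, y0.size))
    states[0] = np.clip(y0, 0.0, None)
    y = states[0].copy()
    for i in range(1, t_eval.size):
        sol = solve_ivp(
            rhs_array,
            (t_eval[i - 1], t_eval[i]),
            y,
            method="LSODA",
            rtol=settings.rtol,
            atol=settings.atol,
            args=(params,),
        )
        if not sol.success:
            t_fail = float(sol.t[-1]) if sol.t.size else t_eval[i - 1]
            y_fail = sol.y[:, -1] if sol.t.size else y
            raise IntegrationError(
                f"integration failed at t={t_fail:.6g} "
                f"(state={np.array2string(np.asarray(y_fail), precision=6)}): {sol.message}",
                t=t_fail,
                state=y_fail,
            )
        y = np.clip(sol.y[:, -1], 0.0, None)
        y[y < settings.extinction_floor] = 0.0
        states[i] = y
    fluxes = np.empty((states.shape[0], len(FLUX_NAMES)))
    for i, row in enumerate(states):
        fl = evaluate_fluxes(StateVector.from_array(row), params)
        fluxes[i] = [getattr(fl, name) for name in FLUX_NAMES]

    return Trajectory(
        times=t_eval,
        states=states,
        fluxes=fluxes,
        scenario_id=scenario_id,
        params_hash=_hash_inputs(initial, params, settings),
        params=params,
    )


def equilibrium_summary(traj: Trajectory, window: float) -> pd.DataFrame:
    """Mean and amplitude (max - min) of each state over the final window.

    A near-zero amplitude indicates convergence to a point equilibrium;
    a persistent amplitude indicates cycling around it.
    """
    if window <= 0 or window > traj.times[-1]:
        raise ValueError(f"window must lie in (0, t_end], got {window}")
    mask = traj.times >= traj.times[-1] - window
    if not mask.any():
        raise ValueError("window contains no output points")
    block = traj.states[mask]
    return pd.DataFrame(
        {
            "mean": block.mean(axis=0),
            "amplitude": block.max(axis=0) - block.min(axis=0),
        },
        index=list(STATE_NAMES),
    )
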