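"""Numerical integration of the biofilm model and closed-form steady states.

Integration is segmented: a growth phase, an optional treatment pulse with
hard agent resets at its boundaries (protocol events, not dynamics), and a
recovery phase.  Internal time unit is seconds; reporting unit is days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    CLIP_TOL,
    BiofilmState,
    ModelParameters,
    StateError,
    _derivs,
    hill,
)

__all__ = [
    "DAY",
    "STATE_COLUMNS",
    "IntegrationError",
    "Trajectory",
    "SteadyState",
    "integrate",
    "steady_state_closed_form",
    "apply_treatment_pulse",
    "live_ratio",
]

DAY = 86400.0
STATE_COLUMNS = ("L", "D", "E", "T", "A", "H", "Q")

# rates span ~1e-7 to ~1e-2 1/s over horizons up to ~1e7 s
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-12


class IntegrationError(RuntimeError):
    """The ODE solver failed inside a named protocol segment."""


@dataclass
class Trajectory:
    """Time grid (s) plus one state row per time, with phase labels.

    ``states`` has columns ``L, D, E, T, A, H, Q``; ``T`` is recomputed
    from the closure at every point.
    """

    times: np.ndarray
    states: np.ndarray
    phases: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        self.phases = np.asarray(self.phases, dtype=object)
        if self.states.shape != (self.times.size, 7):
            raise ValueError("states must be (n_times, 7)")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def times_days(self) -> np.ndarray:
        return self.times / DAY

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_COLUMNS.index(name)]

    def state_at(self, index: int) -> BiofilmState:
        L, D, E, T, A, H, Q = self.states[index]
        return BiofilmState(L=L, D=D, E=E, A=A, H=H, Q=Q)

    @property
    def final_state(self) -> BiofilmState:
        return self.state_at(-1)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.states, columns=list(STATE_COLUMNS))
        frame.insert(0, "time_days", self.times_days)
        frame["live_ratio"] = live_ratio(self)
        frame["phase"] = self.phases
        return frame

    @classmethod
    def concatenate(cls, segments: list["Trajectory"]) -> "Trajectory":
        """Join contiguous segments, dropping duplicate boundary points."""
        times, states, phases = [segments[0].times], [segments[0].states], [segments[0].phases]
        for seg in segments[1:]:
            keep = seg.times > times[-1][-1]
            times.append(seg.times[keep])
            states.append(seg.states[keep])
            phases.append(seg.phases[keep])
        return cls(np.concatenate(times), np.vstack(states), np.concatenate(phases))


def _clip_rows(y: np.ndarray, phase: str) -> np.ndarray:
    """Clip roundoff negatives to zero; reject anything worse."""
    if np.any(y < -CLIP_TOL):
        worst = float(y.min())
        raise StateError(f"segment {phase!r}: component reached {worst!r} < -{CLIP_TOL}")
    return np.where(y < 0.0, 0.0, y)


def integrate(
    params: ModelParameters,
    initial: BiofilmState,
    duration: float,
    output_grid: np.ndarray | None = None,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    phase: str = "growth",
    t_start: float = 0.0,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model for ``duration`` seconds from ``initial``.

    ``output_grid`` (seconds, within ``[0, duration]``) selects the reported
    time points; the solution itself is controlled only by the tolerances,
    so the final state does not depend on the grid density.  Times in the
    returned trajectory are offset by ``t_start``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    y0 = initial.clipped().as_vector()
    if output_grid is None:
        t_eval = np.linspace(0.0, duration, 201)
    else:
        t_eval = np.asarray(output_grid, dtype=float)
        if t_eval.size == 0 or t_eval[0] < 0 or t_eval[-1] > duration * (1 + 1e-12):
            raise ValueError("output_grid must lie within [0, duration]")
        t_eval = np.minimum(t_eval, duration)
    sol = solve_ivp(
        _derivs,
        (0.0, float(duration)),
        y0,
        args=(params,),
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(
            f"segment {phase!r} failed: {sol.message}; last state {sol.y[:, -1] if sol.y.size else y0}"
        )
    y = _clip_rows(sol.y.T, phase)
    L, D, E = y[:, 0], y[:, 1], y[:, 2]
    T = 1.0 - L - D - E
    states = np.column_stack([L, D, E, T, y[:, 3], y[:, 4], y[:, 5]])
    return Trajectory(
        times=t_start + sol.t,
        states=states,
        phases=np.full(sol.t.size, phase, dtype=object),
    )


@dataclass(frozen=True)
class SteadyState:
    """Untreated (A = 0) steady state with saturated H, Q and EPS."""

    L_ss: float
    D_ss: float
    E_ss: float
    H_ss: float
    Q_ss: float
    live_ratio_ss: float

    def as_state(self) -> BiofilmState:
        return BiofilmState(
            L=self.L_ss, D=self.D_ss, E=self.E_ss, A=0.0, H=self.H_ss, Q=self.Q_ss
        )


def steady_state_closed_form(params: ModelParameters) -> SteadyState:
    """Closed-form untreated steady state.

    With the agent absent and H, Q, E at their capacities, the logistic
    live-cell balance gives ``L_ss = L_max (1 - r_bs / (c2 h(Q_max)))``
    with ``h`` the squared Hill response, the dead pool balances at
    ``D_ss = (r_bs / r_dp) L_ss``, and the live ratio is
    ``r_dp / (r_dp + r_bs)`` independent of L.  If natural death outpaces
    saturated growth the only steady state is extinction (``L_ss = 0``).
    """
    growth = params.c2 * hill(params.Q_max, params.k_q)
    if growth > params.r_bs:
        L_ss = params.L_max * (1.0 - params.r_bs / growth)
    else:
        L_ss = 0.0
    D_ss = (params.r_bs / params.r_dp) * L_ss
    return SteadyState(
        L_ss=L_ss,
        D_ss=D_ss,
        E_ss=params.E_max,
        H_ss=params.H_max,
        Q_ss=params.Q_max,
        live_ratio_ss=params.r_dp / (params.r_dp + params.r_bs),
    )


def apply_treatment_pulse(
    state: BiofilmState,
    params: ModelParameters,
    agent_level: float,
    duration: float,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> BiofilmState:
    """Immerse the biofilm in agent at ``agent_level`` for ``duration`` s.

    The agent concentration is reset hard to ``agent_level`` at the start
    and to ``params.A_residual`` (the post-rinse leaked-agent level) at the
    end — the immersion and rinse are protocol events, not dynamics.  A
    zero-length pulse applies only the two resets.
    """
    if duration < 0 or agent_level < 0:
        raise ValueError("duration and agent_level must be >= 0")
    dosed = BiofilmState(
        L=state.L, D=state.D, E=state.E, A=float(agent_level), H=state.H, Q=state.Q
    )
    if duration > 0:
        traj = integrate(
            params, dosed, duration, np.array([0.0, duration]),
            rtol=rtol, atol=atol, phase="pulse",
        )
        dosed = traj.final_state
    return BiofilmState(
        L=dosed.L, D=dosed.D, E=dosed.E, A=params.A_residual, H=dosed.H, Q=dosed.Q
    )


def live_ratio(traj: Trajectory) -> np.ndarray:
    """Viable fraction of bacterial volume, ``L / (L + D)``, per time point."""
    L, D = traj.column("L"), traj.column("D")
    total = L + D
    if np.any(total <= 0):
        raise StateError("live ratio undefined where L + D = 0")
    return L / total
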