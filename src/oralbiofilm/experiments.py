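"""Drivers for the three simulated studies.

* recovery study — grow 21 days from a 5% inoculum, immerse 10 min in
  irrigant at the working concentration, follow the live-cell ratio over a
  105-day recovery with the residual leaked agent;
* component study — paired treated/untreated trajectories of L, D, E, H, Q;
* aged-biofilm study — post-pulse live ratio as a function of biofilm age
  for 1- and 3-minute pulses.

Time 0 of a recovery trajectory is the moment right after the pulse (the
"immediately" sample of the viability-staining schedule).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .model import BiofilmState, ModelParameters, ScaleConstants
from .simulate import (
    DAY,
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    Trajectory,
    apply_treatment_pulse,
    integrate,
    live_ratio,
    steady_state_closed_form,
)

__all__ = [
    "INOCULUM",
    "WEEK_TIMEPOINTS_DAYS",
    "DEFAULT_AGE_GRID_DAYS",
    "ProtocolSpec",
    "RecoveryResult",
    "ComponentResult",
    "simulate_recovery",
    "simulate_ratio_at",
    "run_recovery_study",
    "run_age_response_study",
    "run_component_study",
    "maturation_week",
    "grown_state",
]

#: standard inoculum: 5% live bacteria in fresh medium, no signal yet.
INOCULUM = BiofilmState(L=0.05, D=0.0, E=0.0, A=0.0, H=0.0, Q=0.0)

#: viability sampling schedule: immediately, then 1, 3, 8, 11, 15 weeks.
WEEK_TIMEPOINTS_DAYS = (0.0, 7.0, 21.0, 56.0, 77.0, 105.0)

#: default age grid of the aged-biofilm study (0-8 weeks of growth).
DEFAULT_AGE_GRID_DAYS = (1.0, 4.0, 7.0, 14.0, 21.0, 28.0, 42.0, 56.0)


@dataclass(frozen=True)
class ProtocolSpec:
    """One simulated treatment protocol.

    ``pulse_level`` is the agent concentration during immersion (kg/m^3);
    level 0 is the saline control and skips the agent resets entirely.
    ``start_at_steady_state`` replaces the 21-day growth phase by the exact
    closed-form steady state (used by calibration identity checks).
    """

    kind: str = "recovery"
    group: str = ""
    growth_days: float = 21.0
    pulse_s: float = 600.0
    pulse_level: float = ScaleConstants().C
    recovery_days: float = 105.0
    age_grid_days: tuple[float, ...] = DEFAULT_AGE_GRID_DAYS
    start_at_steady_state: bool = False
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL

    def __post_init__(self) -> None:
        if min(self.growth_days, self.pulse_s, self.recovery_days) < 0:
            raise ValueError("durations must be >= 0")
        if self.pulse_level < 0:
            raise ValueError("pulse_level must be >= 0")
        if list(self.age_grid_days) != sorted(self.age_grid_days):
            raise ValueError("age grid must be increasing")

    def replace(self, **changes) -> "ProtocolSpec":
        return _dc_replace(self, **changes)


@dataclass
class RecoveryResult:
    """A recovery run: pre/post-pulse states plus the recovery trajectory."""

    group: str
    pretreat_state: BiofilmState
    post_pulse_state: BiofilmState
    trajectory: Trajectory  # times measured from the end of the pulse
    pretreat_ratio: float

    def ratio_at_days(self, days) -> np.ndarray:
        days = np.atleast_1d(np.asarray(days, dtype=float))
        return np.interp(days, self.trajectory.times_days, live_ratio(self.trajectory))

    def week_ratios(self, max_week: int = 15) -> pd.Series:
        weeks = np.arange(0, max_week + 1)
        return pd.Series(self.ratio_at_days(7.0 * weeks), index=weeks, name="live_ratio")

    def nadir_week(self) -> int:
        """Week (nearest whole) of the live-ratio minimum."""
        ratios = live_ratio(self.trajectory)
        t_min = self.trajectory.times_days[int(np.argmin(ratios))]
        return int(round(t_min / 7.0))

    def recovery_week(self, rel_tol: float = 0.02, max_week: int = 15) -> int | None:
        """First whole week back within ``rel_tol`` of the pretreatment ratio."""
        for week, ratio in self.week_ratios(max_week).items():
            if abs(ratio - self.pretreat_ratio) <= rel_tol * self.pretreat_ratio:
                return int(week)
        return None


def _growth_key(params: ModelParameters, protocol: ProtocolSpec) -> tuple:
    # agent-specific (class III) parameters cannot influence the agent-free
    # growth phase, so the grown state is cached on everything else
    names = ("c2", "c5", "c_a", "c_q", "r_bs", "r_dp", "k_q", "k_9",
             "L_max", "E_max", "H_max", "Q_max")
    return tuple(getattr(params, n) for n in names) + (
        protocol.growth_days, protocol.start_at_steady_state,
        protocol.rtol, protocol.atol,
    )


_GROWN_CACHE: dict[tuple, BiofilmState] = {}


def grown_state(params: ModelParameters, protocol: ProtocolSpec) -> BiofilmState:
    """State at the end of the growth phase (cached across agent refits)."""
    if protocol.start_at_steady_state:
        return steady_state_closed_form(params).as_state()
    key = _growth_key(params, protocol)
    state = _GROWN_CACHE.get(key)
    if state is None:
        traj = integrate(
            params, INOCULUM, protocol.growth_days * DAY,
            np.array([0.0, protocol.growth_days * DAY]),
            rtol=protocol.rtol, atol=protocol.atol, phase="growth",
        )
        state = traj.final_state
        if len(_GROWN_CACHE) > 256:
            _GROWN_CACHE.clear()
        _GROWN_CACHE[key] = state
    return state


def _recovery_grid_days(protocol: ProtocolSpec, extra_days=()) -> np.ndarray:
    base = np.arange(0.0, protocol.recovery_days + 1e-9, 0.25)
    grid = np.unique(np.concatenate([base, np.asarray(extra_days, dtype=float),
                                     [protocol.recovery_days]]))
    return grid[grid <= protocol.recovery_days + 1e-9]


def simulate_recovery(
    params: ModelParameters,
    protocol: ProtocolSpec = ProtocolSpec(),
    output_grid_days: np.ndarray | None = None,
) -> RecoveryResult:
    """Growth -> pulse -> recovery for one (donor, agent) group."""
    pre = grown_state(params, protocol)
    pre_ratio = pre.L / (pre.L + pre.D)
    if protocol.pulse_level > 0:
        post = apply_treatment_pulse(
            pre, params, protocol.pulse_level, protocol.pulse_s,
            rtol=protocol.rtol, atol=protocol.atol,
        )
    else:
        post = pre  # saline control: no agent, no residual
    grid_days = (
        _recovery_grid_days(protocol, WEEK_TIMEPOINTS_DAYS)
        if output_grid_days is None
        else np.asarray(output_grid_days, dtype=float)
    )
    traj = integrate(
        params, post, protocol.recovery_days * DAY, grid_days * DAY,
        rtol=protocol.rtol, atol=protocol.atol, phase="recovery",
    )
    return RecoveryResult(
        group=protocol.group,
        pretreat_state=pre,
        post_pulse_state=post,
        trajectory=traj,
        pretreat_ratio=pre_ratio,
    )


def simulate_ratio_at(
    params: ModelParameters,
    protocol: ProtocolSpec,
    times_days,
) -> np.ndarray:
    """Live ratio at post-pulse times (days) — the calibration observable."""
    times_days = np.atleast_1d(np.asarray(times_days, dtype=float))
    grid = np.unique(np.concatenate([[0.0], times_days]))
    horizon = max(float(grid[-1]), 1e-6 / DAY)
    result = simulate_recovery(
        params, protocol.replace(recovery_days=horizon), output_grid_days=grid
    )
    return result.ratio_at_days(times_days)


def run_recovery_study(
    param_sets: dict[str, ModelParameters],
    protocol: ProtocolSpec = ProtocolSpec(),
) -> dict[str, RecoveryResult]:
    """Recovery run per group (e.g. ``donor1/CHX`` ... 2 donors x 3 agents)."""
    return {
        group: simulate_recovery(params, protocol.replace(group=group))
        for group, params in param_sets.items()
    }


def run_age_response_study(
    param_sets: dict[str, ModelParameters],
    age_grid_days=DEFAULT_AGE_GRID_DAYS,
    pulse_durations_s=(60.0, 180.0),
    pulse_level: float = ScaleConstants().C,
    protocol: ProtocolSpec = ProtocolSpec(kind="age_response"),
) -> pd.DataFrame:
    """Post-pulse state vs biofilm age for each agent and pulse duration.

    Grows once per agent to the oldest age, then pulses the stored state at
    each age.  Returns one row per (agent, age, duration) with the
    immediately-post-pulse live ratio and component values, plus matched
    untreated controls (duration 0).
    """
    ages = np.asarray(sorted(age_grid_days), dtype=float)
    rows = []
    for agent, params in param_sets.items():
        traj = integrate(
            params, INOCULUM, float(ages[-1]) * DAY, ages * DAY,
            rtol=protocol.rtol, atol=protocol.atol, phase="growth",
        )
        for i, age in enumerate(ages):
            control = traj.state_at(i)
            for duration in (0.0, *pulse_durations_s):
                if duration == 0.0:
                    state = control
                else:
                    state = apply_treatment_pulse(
                        control, params, pulse_level, duration,
                        rtol=protocol.rtol, atol=protocol.atol,
                    )
                rows.append({
                    "agent": agent,
                    "age_days": float(age),
                    "pulse_s": float(duration),
                    "live_ratio": state.L / (state.L + state.D),
                    "L": state.L, "D": state.D, "E": state.E,
                    "H": state.H, "Q": state.Q,
                })
    return pd.DataFrame(rows)


def maturation_week(
    age_response: pd.DataFrame,
    agent: str,
    pulse_s: float = 180.0,
    rel_change: float = 0.05,
    max_week: int = 8,
) -> int | None:
    """First whole-week age where the post-pulse ratio changes by less than
    ``rel_change`` relative to the next weekly age — the maturation age
    beyond which susceptibility is age-insensitive."""
    sel = age_response[(age_response.agent == agent) & (age_response.pulse_s == pulse_s)]
    ratios = {}
    for week in range(1, max_week + 1):
        match = sel[np.isclose(sel.age_days, 7.0 * week)]
        if len(match):
            ratios[week] = float(match.live_ratio.iloc[0])
    for week in sorted(ratios):
        if week + 1 in ratios:
            if abs(ratios[week + 1] - ratios[week]) < rel_change * ratios[week]:
                return week
    return None


@dataclass
class ComponentResult:
    """Paired treated/untreated component trajectories on a shared grid."""

    treated: Trajectory
    untreated: Trajectory

    def frame(self) -> pd.DataFrame:
        t = self.treated.to_frame().assign(arm="treated")
        u = self.untreated.to_frame().assign(arm="untreated")
        return pd.concat([t, u], ignore_index=True)


def run_component_study(
    params: ModelParameters,
    protocol: ProtocolSpec = ProtocolSpec(kind="components"),
) -> ComponentResult:
    """L, D, E, H, Q with and without treatment, aligned at treatment time.

    Both arms share the growth phase; the untreated arm then simply keeps
    growing over the same post-treatment time axis.
    """
    treated = simulate_recovery(params, protocol)
    grid_days = treated.trajectory.times_days
    control_start = treated.pretreat_state
    if protocol.pulse_s > 0:
        # keep the arms on the same absolute clock: the control also ages
        # through the immersion interval, just without agent
        control_start = integrate(
            params, control_start, protocol.pulse_s,
            np.array([0.0, protocol.pulse_s]),
            rtol=protocol.rtol, atol=protocol.atol, phase="pulse",
        ).final_state
    untreated_traj = integrate(
        params, control_start, protocol.recovery_days * DAY,
        grid_days * DAY, rtol=protocol.rtol, atol=protocol.atol,
        phase="recovery",
    )
    return ComponentResult(treated=treated.trajectory, untreated=untreated_traj)
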