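"""Steady-state-constrained sequential interval-search calibration.

The protocol mirrors how the model is fitted in practice:

1. the natural death rate ``r_bs`` is pinned from the saline control group
   through the steady-state balance ``r_bs L_ss = r_dp D_ss``, i.e. from
   the measured control live ratio alone;
2. the remaining free parameters are refined one at a time by an
   interval-halving (golden-section) line search on the sum-of-squares
   misfit of the simulated live ratio to the observations, sweeping the
   fit order repeatedly so earlier parameters re-adjust as later ones
   move; agent-specific (class III) parameters are always fitted last.

Golden-section reduction is used for the one-dimensional search because a
best-fit problem has no sign change to bisect on; it is the
interval-halving analogue for a minimum and terminates deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelParameters, PARAM_CLASS, DomainError
from .experiments import ProtocolSpec, simulate_ratio_at

__all__ = [
    "ObservationSet",
    "CalibrationConfig",
    "FitResult",
    "CalibrationError",
    "infer_rbs_from_control",
    "objective",
    "bisection_fit_parameter",
    "sequential_calibrate",
    "order_by_sensitivity",
    "default_config",
]

_OBS_COLUMNS = ["group", "time_days", "live_ratio", "replicate"]

#: golden-ratio interval reduction factor per probe
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


class CalibrationError(RuntimeError):
    """Simulation or search failure during calibration, with the offending
    parameter set attached in the message."""


@dataclass
class ObservationSet:
    """Live-ratio observations: (group, time_days, live_ratio, replicate).

    The statistical unit is one biofilm disc (replicate) imaged at one
    time; replicates enter the objective individually.
    """

    records: pd.DataFrame
    truncation_flagged: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in _OBS_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"observation table missing columns {missing}")
        self.records = self.records[_OBS_COLUMNS].reset_index(drop=True)
        if len(self.records):
            r = self.records.live_ratio
            if r.min() < 0 or r.max() > 1:
                raise ValueError("live ratios must lie in [0, 1]")
            if self.records.time_days.min() < 0:
                raise ValueError("times must be >= 0")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_records(cls, rows, **kw) -> "ObservationSet":
        return cls(pd.DataFrame(rows, columns=_OBS_COLUMNS), **kw)

    @classmethod
    def empty(cls) -> "ObservationSet":
        return cls(pd.DataFrame(columns=_OBS_COLUMNS))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.records.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservationSet":
        return cls(pd.read_csv(path, sep="\t"))


def infer_rbs_from_control(live_ratio_ss: float, r_dp: float) -> float:
    """Natural death rate from the control-group steady-state live ratio.

    At the untreated steady state ``r_bs L_ss = r_dp D_ss``, so
    ``r_bs = r_dp (1/ratio - 1)`` with ``ratio = L_ss / (L_ss + D_ss)``.
    """
    if r_dp <= 0:
        raise DomainError("r_dp must be > 0")
    if not 0 < live_ratio_ss <= 1:
        raise DomainError(
            f"control live ratio must be in (0, 1], got {live_ratio_ss!r}"
        )
    return r_dp * (1.0 / live_ratio_ss - 1.0)


def objective(
    params: ModelParameters,
    obs: ObservationSet,
    protocol: ProtocolSpec,
) -> float:
    """Sum of squared live-ratio residuals over all observation records."""
    if len(obs) == 0:
        return 0.0
    times = np.unique(obs.records.time_days.to_numpy(dtype=float))
    try:
        simulated = simulate_ratio_at(params, protocol, times)
    except Exception as exc:
        raise CalibrationError(
            f"simulation failed at parameters {params.to_dict()}: {exc}"
        ) from exc
    lookup = dict(zip(times, simulated))
    resid = obs.records.live_ratio.to_numpy(dtype=float) - np.array(
        [lookup[t] for t in obs.records.time_days.to_numpy(dtype=float)]
    )
    return float(resid @ resid)


def bisection_fit_parameter(
    name: str,
    interval: tuple[float, float],
    params: ModelParameters,
    obs: ObservationSet,
    protocol: ProtocolSpec,
    depth: int = 24,
) -> float:
    """Golden-section line search for one parameter on ``interval``.

    Returns the midpoint of the final interval, whose width shrinks by the
    golden factor (~0.618) per probe.  On a strictly monotone objective
    slice the search collapses onto the better endpoint.
    """
    lo, hi = float(interval[0]), float(interval[1])
    if not (0 < lo <= hi) or not np.isfinite(hi):
        raise ValueError(f"interval for {name!r} must satisfy 0 < lo <= hi < inf")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if lo == hi:
        return lo

    def f(value: float) -> float:
        out = objective(params.replace(**{name: value}), obs, protocol)
        if not np.isfinite(out):
            raise CalibrationError(
                f"non-finite objective at {name}={value!r}"
            )
        return out

    a, b = lo, hi
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(depth):
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


@dataclass
class CalibrationConfig:
    """Fit order, per-parameter search intervals and stopping rules."""

    order: list[str]
    intervals: dict[str, tuple[float, float]]
    depth: int = 24
    passes: int = 3
    tol: float = 1e-8

    def __post_init__(self) -> None:
        for name in self.order:
            lo, hi = self.intervals[name]
            if not (0 < lo <= hi) or not np.isfinite(hi):
                raise ValueError(f"interval for {name!r} must be positive and finite")
        classes = [PARAM_CLASS[name] for name in self.order]
        seen_iii = False
        for cls in classes:
            if cls == "III":
                seen_iii = True
            elif seen_iii:
                raise ValueError("agent-specific (class III) parameters must be fitted last")


@dataclass
class FitResult:
    """Calibrated parameters, final objective and per-parameter trace."""

    params: ModelParameters
    objective: float
    trace: pd.DataFrame
    converged: bool


def order_by_sensitivity(
    names: list[str],
    params: ModelParameters,
    obs: ObservationSet,
    protocol: ProtocolSpec,
    rel_step: float = 0.05,
) -> list[str]:
    """Sort ``names`` by finite-difference objective sensitivity (largest
    first), keeping non-agent parameters ahead of agent-specific ones."""
    base = objective(params, obs, protocol)
    sens = {}
    for name in names:
        value = getattr(params, name)
        bumped = objective(params.replace(**{name: value * (1 + rel_step)}), obs, protocol)
        sens[name] = abs(bumped - base)
    return sorted(names, key=lambda n: (PARAM_CLASS[n] == "III", -sens[n]))


def default_config(
    reference: ModelParameters,
    names: list[str],
    *,
    upper_factor: float = 10.0,
    lower_factor: float = 1e-3,
    depth: int = 24,
    passes: int = 3,
    tol: float = 1e-8,
) -> CalibrationConfig:
    """Search intervals ``(lower_factor, upper_factor) x reference value``.

    The upper limit defaults to 10x the shipped value for the matching
    agent — the prescribed-range convention when no tighter physical bound
    is known.
    """
    intervals = {
        name: (lower_factor * getattr(reference, name), upper_factor * getattr(reference, name))
        for name in names
    }
    order = sorted(names, key=lambda n: PARAM_CLASS[n] == "III")
    return CalibrationConfig(order=order, intervals=intervals, depth=depth,
                             passes=passes, tol=tol)


def sequential_calibrate(
    config: CalibrationConfig,
    params: ModelParameters,
    obs: ObservationSet,
    protocol: ProtocolSpec,
) -> FitResult:
    """Outer passes of per-parameter golden-section refinement.

    Each parameter is refined with the others held at their current
    values; a refined value is kept only if it does not worsen the
    objective, so the objective is non-increasing along the trace.  The
    search stops when a full pass improves the objective by less than
    ``config.tol`` or the pass budget is exhausted.  Stalling on the very
    first pass with the objective still above tolerance sets
    ``converged=False`` instead of raising.
    """
    best = objective(params, obs, protocol)
    rows = [{"pass": 0, "parameter": "<initial>", "value": np.nan, "objective": best}]
    converged = True
    for pass_idx in range(1, config.passes + 1):
        pass_start = best
        for name in config.order:
            value = bisection_fit_parameter(
                name, config.intervals[name], params, obs, protocol, config.depth
            )
            candidate = params.replace(**{name: value})
            cand_obj = objective(candidate, obs, protocol)
            if cand_obj <= best:
                params, best = candidate, cand_obj
            rows.append({
                "pass": pass_idx,
                "parameter": name,
                "value": getattr(params, name),
                "objective": best,
            })
        improvement = pass_start - best
        if improvement < config.tol:
            converged = not (pass_idx == 1 and best > config.tol)
            break
    return FitResult(
        params=params,
        objective=best,
        trace=pd.DataFrame(rows),
        converged=converged,
    )
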