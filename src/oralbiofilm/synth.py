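"""Synthetic observation sets with the structure of the CLSM measurements.

Emulates the study design: live ratio ``L/(L+D)`` sampled immediately and
1, 3, 8, 11, 15 weeks post-treatment, two discs per group and time, with
additive Gaussian noise on the ratio truncated to [0, 1].  One shared seed
drives every replicate through a counter-based stream keyed on (group,
time, replicate), so insertion order cannot change the draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import ObservationSet
from .experiments import ProtocolSpec, WEEK_TIMEPOINTS_DAYS, simulate_ratio_at
from .model import ModelParameters

__all__ = ["NoiseModel", "generate_observations", "generate_control_observations"]


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian ratio noise, replicate count and master seed."""

    sd: float = 0.03
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def _draw(seed: int, group: str, time_days: float, replicate: int,
          mean: float, sd: float) -> tuple[float, bool]:
    """One truncated-Gaussian ratio draw from the counter-based stream."""
    if sd == 0:
        return mean, False
    entropy = [
        int(seed) & 0x7FFFFFFF,
        zlib.crc32(group.encode()),
        int(round(time_days * 1000.0)),
        int(replicate),
    ]
    rng = np.random.default_rng(np.random.SeedSequence(entropy))
    raw = mean + sd * rng.standard_normal()
    truncated = raw < 0.0 or raw > 1.0
    return float(np.clip(raw, 0.0, 1.0)), truncated


def generate_observations(
    params: ModelParameters,
    protocol: ProtocolSpec,
    noise: NoiseModel = NoiseModel(),
    timepoints_days=WEEK_TIMEPOINTS_DAYS,
    group: str = "group",
) -> ObservationSet:
    """Simulate ``protocol`` and sample noisy live ratios at ``timepoints_days``.

    If more than half the draws had to be truncated back into [0, 1] the
    returned set carries ``truncation_flagged=True``.
    """
    times = np.asarray(timepoints_days, dtype=float)
    ratios = simulate_ratio_at(params, protocol, times)
    rows, n_truncated = [], 0
    for t, ratio in zip(times, ratios):
        for rep in range(1, noise.replicates + 1):
            value, truncated = _draw(noise.seed, group, float(t), rep, float(ratio), noise.sd)
            n_truncated += truncated
            rows.append({
                "group": group,
                "time_days": float(t),
                "live_ratio": value,
                "replicate": rep,
            })
    flagged = n_truncated > 0.5 * len(rows)
    return ObservationSet(pd.DataFrame(rows), truncation_flagged=flagged)


def generate_control_observations(
    params: ModelParameters,
    timepoints_days=WEEK_TIMEPOINTS_DAYS,
    noise: NoiseModel = NoiseModel(sd=0.0),
    protocol: ProtocolSpec = ProtocolSpec(),
    group: str = "control",
) -> ObservationSet:
    """Saline-control observations: zero pulse level, no residual agent."""
    control_protocol = protocol.replace(pulse_level=0.0, group=group)
    control_params = params.replace(A_residual=0.0)
    return generate_observations(
        control_params, control_protocol, noise, timepoints_days, group=group
    )
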