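"""Deterministic tabular output of study results.

Everything written here is a pure function of (fixture, protocol,
tolerances): two identical runs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .experiments import RecoveryResult
from .fixtures import fixture_checksums
from .simulate import DEFAULT_ATOL, DEFAULT_RTOL, Trajectory

__all__ = ["write_trajectory", "write_report"]

_FLOAT_FMT = "%.10g"


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """One row per time point: time_days, L, D, E, T, A, H, Q, live_ratio."""
    path = Path(path)
    traj.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def summarize_recovery(results: dict[str, RecoveryResult]) -> pd.DataFrame:
    rows = []
    for group, res in results.items():
        week0 = float(res.ratio_at_days(0.0)[0])
        rows.append({
            "group": group,
            "pretreat_live_ratio": res.pretreat_ratio,
            "week0_live_ratio": week0,
            "kill_fraction": 1.0 - week0 / res.pretreat_ratio,
            "nadir_week": res.nadir_week(),
            "recovery_week": res.recovery_week(),
        })
    return pd.DataFrame(rows).sort_values("group").reset_index(drop=True)


def write_report(
    results: dict[str, RecoveryResult],
    destination: str | Path,
    *,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write per-group trajectories, a summary table and run metadata."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for group, res in sorted(results.items()):
        name = group.replace("/", "_") or "run"
        written[group] = write_trajectory(res.trajectory, dest / f"trajectory_{name}.tsv")
    summary = summarize_recovery(results)
    summary_path = dest / "summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    written["summary"] = summary_path
    metadata = {
        "seed": seed,
        "solver": {"method": "LSODA", "rtol": DEFAULT_RTOL, "atol": DEFAULT_ATOL},
        "fixture_sha256": fixture_checksums(),
        "groups": sorted(results),
    }
    meta_path = dest / "run_metadata.yaml"
    meta_path.write_text(yaml.safe_dump(metadata, sort_keys=True))
    written["metadata"] = meta_path
    return written
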