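"""Packaged parameter sets and their plain-text serialization.

Two fixture files ship with the package, one per study:

* ``recovery`` — 2 donors x 3 irrigants (CHX, IPI, NaOCl), the 15-week
  kill-and-recovery experiment;
* ``aged`` — 3 irrigants, the 0-8-week aged-biofilm susceptibility
  experiment.

Registry keys look like ``"recovery/donor1/CHX"`` or ``"aged/NaOCl"``.
Shipped bytes are frozen by sha256 so silent edits fail loudly.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import yaml

from .model import ModelParameters, ParameterError, ScaleConstants

__all__ = [
    "FixtureError",
    "available_keys",
    "load_parameters",
    "load_scale",
    "save_parameters",
    "fixture_checksums",
    "verify_fixture_integrity",
]


class FixtureError(ValueError):
    """A fixture file is missing, malformed or has been tampered with."""


_FILES = {
    "recovery": "recovery_parameters.yaml",
    "aged": "aged_parameters.yaml",
}

#: sha256 of the shipped fixture files, frozen at release.
EXPECTED_SHA256 = {
    "recovery": "1ab31c0f39ca0e35533a4c3413bc44e5e09afbe71e340ed19f044116f7132e39",
    "aged": "cab0e4bd0aed959ef0132b01779d6e7feb73e49f5feea82be50da72217e9cce6",
}


def _read_fixture(study: str) -> dict:
    try:
        name = _FILES[study]
    except KeyError:
        raise FixtureError(f"unknown study {study!r}; expected one of {sorted(_FILES)}") from None
    text = resources.files("oralbiofilm.data").joinpath(name).read_text()
    return yaml.safe_load(text)


def _coerce_parameters(mapping: dict, origin: str) -> ModelParameters:
    expected = set(ModelParameters.field_names())
    got = set(mapping)
    if got != expected:
        missing, extra = expected - got, got - expected
        raise FixtureError(
            f"{origin}: missing fields {sorted(missing)}, unknown fields {sorted(extra)}"
        )
    try:
        return ModelParameters(**{k: float(v) for k, v in mapping.items()})
    except (TypeError, ValueError, ParameterError) as exc:
        raise FixtureError(f"{origin}: {exc}") from exc


def available_keys() -> list[str]:
    """All registry keys, e.g. ``recovery/donor1/CHX``, ``aged/NaOCl``."""
    keys = []
    for study in _FILES:
        doc = _read_fixture(study)
        for group, agents in doc["groups"].items():
            for agent in agents:
                if study == "aged":
                    keys.append(f"{study}/{agent}")
                else:
                    keys.append(f"{study}/{group}/{agent}")
    return keys


def load_parameters(key: str | Path) -> ModelParameters:
    """Load a parameter set from a registry key or a YAML file path.

    Registry keys: ``recovery/<donor>/<agent>`` or ``aged/<agent>``.
    A path must point at a flat ``field: value`` YAML mapping (the format
    :func:`save_parameters` writes).
    """
    key = str(key)
    if "/" in key and key.split("/", 1)[0] in _FILES:
        parts = key.split("/")
        study = parts[0]
        doc = _read_fixture(study)
        if study == "aged" and len(parts) == 2:
            parts = [study, "aged", parts[1]]
        if len(parts) != 3:
            raise FixtureError(f"malformed registry key {key!r}")
        _, group, agent = parts
        try:
            mapping = doc["groups"][group][agent]
        except KeyError:
            raise FixtureError(f"no fixture entry for {key!r}") from None
        return _coerce_parameters(mapping, key)
    path = Path(key)
    if not path.exists():
        raise FixtureError(f"{key!r} is neither a registry key nor an existing file")
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise FixtureError(f"{path}: expected a flat field/value mapping")
    return _coerce_parameters(doc, str(path))


def load_scale(study: str = "recovery") -> ScaleConstants:
    doc = _read_fixture(study)
    scale = doc.get("scale", {})
    return ScaleConstants(t0=float(scale.get("t0", 1.0)), C=float(scale.get("C", 8.24e-3)))


def save_parameters(params: ModelParameters, path: str | Path) -> Path:
    """Write a flat YAML mapping round-trippable through :func:`load_parameters`."""
    path = Path(path)
    lines = [f"{name}: {getattr(params, name)!r}" for name in params.field_names()]
    path.write_text("\n".join(lines) + "\n")
    return path


def fixture_checksums() -> dict[str, str]:
    out = {}
    for study, name in _FILES.items():
        data = resources.files("oralbiofilm.data").joinpath(name).read_bytes()
        out[study] = hashlib.sha256(data).hexdigest()
    return out


def verify_fixture_integrity() -> None:
    """Raise :class:`FixtureError` if any shipped fixture byte changed."""
    actual = fixture_checksums()
    for study, expected in EXPECTED_SHA256.items():
        if actual[study] != expected:
            raise FixtureError(
                f"fixture {study!r} checksum mismatch: {actual[study]} != {expected}"
            )
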