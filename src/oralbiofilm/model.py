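"""Core kinetic model of a coarse-grained oral multispecies biofilm.

The biofilm is described by four volume fractions — live bacteria ``L``,
dead bacteria ``D``, extracellular polymeric substance (EPS) ``E`` and
solvent ``T`` — closed by ``L + D + E + T = 1``, together with three
dissolved concentrations (kg/m^3): an antibacterial agent ``A``, a
quorum-sensing signal ``H`` and a growth-factor proxy ``Q``.

Mechanisms, all spatially homogeneous:

* live cells proliferate logistically toward ``L_max`` at a rate gated by a
  squared Hill function of the growth factor, die naturally at rate
  ``r_bs`` and are killed by the agent at rate ``c3 * gamma * A``;
* dead cells degrade into EPS and solvent at rate ``r_dp`` slowed by the
  agent through the factor ``k_13 / (k_13 + A)``;
* EPS is produced by live cells under quorum-sensing control and by
  dead-cell degradation, saturating at ``E_max``;
* the agent is consumed by live cells (``c8``) and self-degrades (``r_a``);
* the signal ``H`` and growth factor ``Q`` are produced by live cells and
  saturate at their carrying capacities.

Spatial diffusion of the agent is replaced by the dimensionless relaxation
factor ``gamma`` which decreases as cells and EPS crowd the film — the
EPS-shielding mechanism that makes mature biofilms hard to kill.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "CLIP_TOL",
    "PARAM_CLASS",
    "BiofilmState",
    "ModelParameters",
    "ScaleConstants",
    "DomainError",
    "StateError",
    "ParameterError",
    "hill",
    "gamma_factor",
    "dead_degradation_slowdown",
    "rhs",
]

#: magnitude below which a negative component is treated as integrator
#: roundoff and clipped to zero; anything more negative is a genuine
#: violation and raises.
CLIP_TOL = 1e-12


class DomainError(ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class StateError(ValueError):
    """A biofilm state violates its physical invariants."""


class ParameterError(ValueError):
    """A parameter set violates its physical invariants."""


#: Parameter classes: I — independent of donor and agent; II — donor
#: dependent; III — antibacterial-agent specific.  The residual ("leaked")
#: agent level is agent specific.
PARAM_CLASS: dict[str, str] = {
    "H_max": "I",
    "Q_max": "I",
    "c5": "I",
    "c_a": "I",
    "k_9": "I",
    "k_q": "I",
    "E_max": "I",
    "c2": "II",
    "c_q": "II",
    "r_bs": "II",
    "r_dp": "II",
    "L_max": "II",
    "c3": "III",
    "c8": "III",
    "r_a": "III",
    "k_13": "III",
    "D_pr": "III",
    "A_residual": "III",
}


@dataclass(frozen=True)
class ScaleConstants:
    """Characteristic scales: time ``t0`` (s) and concentration ``C`` (kg/m^3).

    ``C`` is the working irrigant concentration; a treatment pulse at
    dimensionless level 1 means ``A = C``.
    """

    t0: float = 1.0
    C: float = 8.24e-3

    def __post_init__(self) -> None:
        if self.t0 <= 0 or self.C <= 0:
            raise ParameterError("scale constants must be strictly positive")


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants, Hill constants and carrying capacities.

    Units: first-order rates in 1/s; ``c3`` in 1/s per kg/m^3 (it multiplies
    the agent concentration); ``c_a``/``c_q`` in kg/m^3/s; Hill constants
    and concentration capacities in kg/m^3; ``L_max``, ``E_max`` and
    ``D_pr`` dimensionless.  ``A_residual`` is the post-rinse "leaked"
    agent concentration (kg/m^3) carried into the recovery phase.
    """

    c2: float
    c3: float
    c5: float
    c8: float
    c_a: float
    c_q: float
    r_bs: float
    r_dp: float
    r_a: float
    k_q: float
    k_9: float
    k_13: float
    L_max: float
    E_max: float
    H_max: float
    Q_max: float
    D_pr: float
    A_residual: float = 0.0

    def __post_init__(self) -> None:
        for name in self.field_names():
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ParameterError(f"{name} must be finite, got {value!r}")
            if name == "A_residual":
                if value < 0:
                    raise ParameterError(f"A_residual must be >= 0, got {value!r}")
            elif value <= 0:
                raise ParameterError(f"{name} must be > 0, got {value!r}")
        if self.L_max + self.E_max >= 1.0:
            raise ParameterError(
                "L_max + E_max must be < 1 so dead cells and solvent retain volume"
            )

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    @staticmethod
    def param_class(name: str) -> str:
        """Class tag of a parameter: donor/agent (in)dependence."""
        try:
            return PARAM_CLASS[name]
        except KeyError:
            raise ParameterError(f"unknown parameter {name!r}") from None

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.field_names()}


#: order of the integrated components in the state vector
VECTOR_FIELDS = ("L", "D", "E", "A", "H", "Q")


@dataclass(frozen=True)
class BiofilmState:
    """The seven dynamical quantities at one instant.

    ``T`` is the solvent closure ``1 - L - D - E``; it is derived, never
    integrated.  Pass ``T`` explicitly only when re-hydrating a stored
    state (it is then checked against the closure).
    """

    L: float
    D: float
    E: float
    A: float = 0.0
    H: float = 0.0
    Q: float = 0.0
    T: float | None = None

    def __post_init__(self) -> None:
        closure = 1.0 - self.L - self.D - self.E
        if self.T is None:
            object.__setattr__(self, "T", closure)
        elif abs(self.T - closure) > 1e-9:
            raise StateError(
                f"T={self.T!r} violates the volume closure (expected {closure!r})"
            )

    def clipped(self) -> "BiofilmState":
        """Zero out roundoff-scale negatives; reject genuine violations."""
        values = {}
        for name in VECTOR_FIELDS:
            v = getattr(self, name)
            if v < -CLIP_TOL:
                raise StateError(f"{name}={v!r} is negative beyond roundoff")
            values[name] = 0.0 if v < 0.0 else v
        return BiofilmState(**values)

    def validate(self, params: ModelParameters | None = None, tol: float = 1e-9) -> None:
        for name in ("L", "D", "E", "T"):
            v = getattr(self, name)
            if v < -tol or v > 1.0 + tol:
                raise StateError(f"volume fraction {name}={v!r} outside [0, 1]")
        for name in ("A", "H", "Q"):
            if getattr(self, name) < -tol:
                raise StateError(f"concentration {name} is negative")
        if params is not None:
            for name, cap in (("L", params.L_max), ("E", params.E_max),
                              ("H", params.H_max), ("Q", params.Q_max)):
                if getattr(self, name) > cap * (1.0 + 1e-6) + tol:
                    raise StateError(f"{name} exceeds its carrying capacity {cap!r}")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in VECTOR_FIELDS], dtype=float)

    @classmethod
    def from_vector(cls, y: Iterable[float], clip: bool = True) -> "BiofilmState":
        L, D, E, A, H, Q = (float(v) for v in y)
        state = cls(L=L, D=D, E=E, A=A, H=H, Q=Q)
        return state.clipped() if clip else state


def hill(x, k: float):
    """Squared Hill response ``x^2 / (x^2 + k^2)`` in ``[0, 1)``.

    Shared by growth-factor gating of proliferation and signal production
    and by quorum-sensing gating of EPS production.  Accepts scalars or
    arrays in ``x``.
    """
    if k <= 0:
        raise DomainError(f"Hill constant must be > 0, got {k!r}")
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0):
        raise DomainError("Hill argument must be >= 0")
    out = xa * xa / (xa * xa + k * k)
    return out if xa.ndim else float(out)


def gamma_factor(state: BiofilmState, D_pr: float) -> float:
    """Diffusion-proxy relaxation factor.

    ``gamma = [1 / (T + E/D_pr)] * [2 (T + E) / (2 + (L + D))]`` — equal to 1
    in pure solvent and shrinking as cells and EPS accumulate, which is how
    EPS shielding of the embedded cells enters the kill term.
    """
    return _gamma(state.L, state.D, state.E, state.T, D_pr)


def _gamma(L: float, D: float, E: float, T: float, D_pr: float) -> float:
    denom = T + E / D_pr
    if denom <= 0.0:
        raise StateError(
            "degenerate state: T + E/D_pr = 0 (fully cellular biofilm)"
        )
    return (1.0 / denom) * (2.0 * (T + E) / (2.0 + (L + D)))


def dead_degradation_slowdown(A: float, k_13: float) -> float:
    """Agent-induced slowdown ``k_13 / (k_13 + A)`` of dead-cell degradation.

    Equals 1 with no agent and decreases strictly in ``A`` — treatment
    stress delays disintegration of dead cells, the mechanism behind the
    post-treatment dip of the live-cell ratio.
    """
    if A < 0 or k_13 <= 0:
        raise DomainError("require A >= 0 and k_13 > 0")
    return k_13 / (k_13 + A)


def _derivs(t: float, y, p: ModelParameters):
    """Right-hand side on the raw vector (L, D, E, A, H, Q); solver-facing."""
    L, D, E, A, H, Q = y
    T = 1.0 - L - D - E
    gq = Q * Q / (Q * Q + p.k_q * p.k_q)
    gh = H * H / (H * H + p.k_9 * p.k_9)
    gamma = _gamma(L, D, E, T, p.D_pr)
    slow = p.k_13 / (p.k_13 + A)
    kill = p.c3 * gamma * A * L
    degrade = p.r_dp * slow * D
    dL = p.c2 * gq * (1.0 - L / p.L_max) * L - p.r_bs * L - kill
    dD = p.r_bs * L + kill - degrade
    dE = (p.c5 * L * gh + degrade) * (1.0 - E / p.E_max)
    dA = -p.c8 * A * L - p.r_a * A
    dH = p.c_a * gq * L * (1.0 - H / p.H_max)
    dQ = p.c_q * L * (1.0 - Q / p.Q_max)
    return (dL, dD, dE, dA, dH, dQ)


def rhs(state: BiofilmState, params: ModelParameters) -> np.ndarray:
    """Time derivatives of ``(L, D, E, A, H, Q)`` for a validated state.

    ``dT/dt`` is implied by the closure and never integrated.  The state
    must satisfy its invariants (clip or reject before calling).
    """
    state = state.clipped()
    state.validate()
    return np.array(_derivs(0.0, state.as_vector(), params), dtype=float)
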