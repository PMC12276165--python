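"""Core state/parameter data model and right-hand side of the rejection ODEs.

The model tracks six populations in a liver-transplant recipient roughly one
year after transplant, once immunosuppression is withdrawn and T cell-mediated
rejection begins:

* ``L``   — healthy allograft hepatocytes (absolute cells, whole liver),
* ``A``   — alloantigen-presenting APCs (cells/µL blood),
* ``T_H`` — activated alloreactive helper T cells (cells/µL),
* ``T_C`` — activated alloreactive cytotoxic T cells (cells/µL),
* ``T_R`` — regulatory T cells (cells/µL),
* ``I``   — interleukin-2 (ng/µL).

Every bounded interaction uses the Michaelis–Menten form ``alpha*x/(beta+x)``
so that effects saturate at ``alpha`` with half-maximum at ``x = beta``.
Hepatocytes are assumed to be in production/death homeostasis, so the only
net change in ``L`` is the cytotoxic killing term and ``dL/dt <= 0`` always.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, fields, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "PARAM_UNITS",
    "PARAM_SYMBOLS",
    "STATE_NAMES",
    "ImmuneState",
    "ModelParameters",
    "StateDerivative",
    "ConstraintReport",
    "ConstraintError",
    "DomainError",
    "saturating_effect",
    "derivative",
    "decompose_pathways",
    "recombine_pathways",
    "check_constraints",
]

SCHEMA_VERSION = 1

#: Parameter storage keys in Table-3 row order.  ASCII names map one-to-one to
#: the conventional Greek symbols: ``alpha_CL`` <-> α_CL, ``beta_IRA`` <->
#: β_IRA, ``gamma_H`` <-> γ_H, ``delta_I`` <-> δ_I, ``lambda_L`` <-> λ_L,
#: ``s_R`` <-> s_R, ``K_C`` <-> K_C.
PARAM_NAMES: tuple[str, ...] = (
    "delta_L", "alpha_CL", "beta_CL", "lambda_L", "delta_A",
    "alpha_AH", "beta_AH", "alpha_RA", "beta_RA", "alpha_IRA", "beta_IRA",
    "gamma_H", "K_H", "alpha_IH", "beta_IH", "delta_H",
    "alpha_HC", "beta_HC", "gamma_C", "K_C", "alpha_IC", "beta_IC", "delta_C",
    "s_R", "delta_R", "alpha_IR", "beta_IR",
    "alpha_CI", "beta_CI", "alpha_HI", "beta_HI",
    "lambda_C", "lambda_H", "lambda_R", "delta_I",
)

PARAM_UNITS: dict[str, str] = {
    "delta_L": "1/day", "alpha_CL": "-", "beta_CL": "cells/uL",
    "lambda_L": "1/uL", "delta_A": "1/day",
    "alpha_AH": "cells/uL*day", "beta_AH": "cells/uL",
    "alpha_RA": "-", "beta_RA": "cells/uL",
    "alpha_IRA": "-", "beta_IRA": "ng/uL",
    "gamma_H": "1/day", "K_H": "cells/uL", "alpha_IH": "-", "beta_IH": "ng/uL",
    "delta_H": "1/day",
    "alpha_HC": "cells/uL*day", "beta_HC": "cells/uL",
    "gamma_C": "1/day", "K_C": "cells/uL", "alpha_IC": "-", "beta_IC": "ng/uL",
    "delta_C": "1/day",
    "s_R": "cells/uL*day", "delta_R": "1/day", "alpha_IR": "-",
    "beta_IR": "ng/uL",
    "alpha_CI": "ng/uL*day", "beta_CI": "cells/uL",
    "alpha_HI": "ng/uL*day", "beta_HI": "cells/uL",
    "lambda_C": "ng/cell", "lambda_H": "ng/cell", "lambda_R": "ng/cell",
    "delta_I": "1/day",
}

PARAM_SYMBOLS: dict[str, str] = {
    name: (name.replace("alpha_", "α_").replace("beta_", "β_")
           .replace("gamma_", "γ_").replace("delta_", "δ_")
           .replace("lambda_", "λ_"))
    for name in PARAM_NAMES
}

STATE_NAMES: tuple[str, ...] = ("L", "A", "T_H", "T_C", "T_R", "I")

STATE_UNITS: dict[str, str] = {
    "L": "cells", "A": "cells/uL", "T_H": "cells/uL", "T_C": "cells/uL",
    "T_R": "cells/uL", "I": "ng/uL",
}


class DomainError(ValueError):
    """An input violates a mathematical precondition (e.g. negative state)."""


class ConstraintError(ValueError):
    """A parameter set violates a hard model constraint."""


@dataclass(frozen=True)
class ImmuneState:
    """One point of the six-dimensional model state.

    ``L`` is an absolute whole-liver cell count; the other populations are
    blood concentrations.  The unit conversion between the two happens in the
    APC source term through ``lambda_L`` (units 1/µL).
    """

    L: float
    A: float
    T_H: float
    T_C: float
    T_R: float
    I: float

    def to_array(self) -> np.ndarray:
        return np.array([self.L, self.A, self.T_H, self.T_C, self.T_R, self.I],
                        dtype=float)

    @classmethod
    def from_array(cls, y: Iterable[float]) -> "ImmuneState":
        L, A, T_H, T_C, T_R, I = (float(v) for v in y)
        return cls(L=L, A=A, T_H=T_H, T_C=T_C, T_R=T_R, I=I)

    def validate_nonnegative(self) -> None:
        for name, value in zip(STATE_NAMES, self.to_array()):
            if not np.isfinite(value) or value < 0:
                raise DomainError(
                    f"state variable {name} = {value!r} must be finite and >= 0")

    def replace(self, **kw: float) -> "ImmuneState":
        return replace(self, **kw)


@dataclass(frozen=True)
class StateDerivative:
    """Time derivatives (per day) of the six state variables."""

    dL: float
    dA: float
    dT_H: float
    dT_C: float
    dT_R: float
    dI: float

    def to_array(self) -> np.ndarray:
        return np.array([self.dL, self.dA, self.dT_H, self.dT_C,
                         self.dT_R, self.dI], dtype=float)


@dataclass(frozen=True)
class ModelParameters:
    """All 35 rate constants, thresholds and proportionality constants.

    The hepatocyte source rate ``s_L`` is not stored: homeostasis sets
    ``s_L = delta_L`` and it cancels out of the hepatocyte equation.
    """

    delta_L: float
    alpha_CL: float
    beta_CL: float
    lambda_L: float
    delta_A: float
    alpha_AH: float
    beta_AH: float
    alpha_RA: float
    beta_RA: float
    alpha_IRA: float
    beta_IRA: float
    gamma_H: float
    K_H: float
    alpha_IH: float
    beta_IH: float
    delta_H: float
    alpha_HC: float
    beta_HC: float
    gamma_C: float
    K_C: float
    alpha_IC: float
    beta_IC: float
    delta_C: float
    s_R: float
    delta_R: float
    alpha_IR: float
    beta_IR: float
    alpha_CI: float
    beta_CI: float
    alpha_HI: float
    beta_HI: float
    lambda_C: float
    lambda_H: float
    lambda_R: float
    delta_I: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "ModelParameters":
        values = list(values)
        if len(values) != len(PARAM_NAMES):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got {len(values)}")
        return cls(**{n: float(v) for n, v in zip(PARAM_NAMES, values)})

    def to_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelParameters":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter names: {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(d)
        if missing:
            raise KeyError(f"missing parameter names: {sorted(missing)}")
        return cls(**{n: float(d[n]) for n in PARAM_NAMES})

    def replace(self, **overrides: float) -> "ModelParameters":
        unknown = set(overrides) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter names: {sorted(unknown)}")
        return replace(self, **overrides)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "parameters": self.to_dict(),
            "units": {n: PARAM_UNITS[n] for n in PARAM_NAMES},
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelParameters":
        doc = json.loads(text)
        if "schema_version" not in doc:
            raise ValueError("parameter document lacks a schema_version field")
        if doc["schema_version"] != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema_version {doc['schema_version']!r}")
        return cls.from_dict(doc["parameters"])

    def digest(self) -> str:
        """Short SHA-256 of the parameter vector, for output provenance."""
        payload = ",".join(f"{v:.17g}" for v in self.to_array())
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# constraint checks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstraintReport:
    """Outcome of the parameter-constraint checks.

    ``errors`` are hard violations (non-positive parameter, ``alpha_IR > 1``)
    that make the equations physically meaningless; ``warnings`` flag the
    soft Treg-suppression bound ``alpha_RA*(1 + alpha_IRA) <= 1``, which the
    nominal values themselves exceed (0.4 * 3 = 1.2) and which is therefore
    reported but never enforced.
    """

    errors: tuple[str, ...]
    warnings: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.errors


def check_constraints(params: ModelParameters) -> ConstraintReport:
    errors: list[str] = []
    warnings: list[str] = []
    for name in PARAM_NAMES:
        v = getattr(params, name)
        if not (np.isfinite(v) and v >= 0):
            errors.append(f"{name} = {v!r} must be finite and >= 0")
        elif v == 0:
            warnings.append(
                f"{name} = 0 switches its pathway off entirely "
                "(admissible as a diagnostic limit, not a physiological value)")
    if params.alpha_IR > 1:
        errors.append(
            f"alpha_IR = {params.alpha_IR} > 1 would turn Treg loss into gain")
    bound = params.alpha_RA * (1.0 + params.alpha_IRA)
    if bound > 1:
        warnings.append(
            "alpha_RA*(1 + alpha_IRA) = "
            f"{bound:g} > 1: the helper-activation bracket can go negative "
            "when T_R and I are large (evaluated as written, not floored)")
    return ConstraintReport(errors=tuple(errors), warnings=tuple(warnings))


def _require_valid(params: ModelParameters) -> None:
    report = check_constraints(params)
    if not report.ok:
        raise ConstraintError("; ".join(report.errors))


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def saturating_effect(x: float, alpha: float, beta: float) -> float:
    """Michaelis–Menten style bounded effect ``alpha*x/(beta + x)``.

    Monotone non-decreasing in ``x``, zero at ``x = 0``, ``alpha/2`` at
    ``x = beta``, and bounded above by ``alpha``.
    """
    if beta <= 0:
        raise DomainError(f"beta = {beta!r} must be > 0")
    if x < 0:
        raise DomainError(f"x = {x!r} must be >= 0")
    return alpha * x / (beta + x)


def decompose_pathways(state: ImmuneState, params: ModelParameters,
                       validate: bool = True) -> dict[str, float]:
    """Evaluate every labelled interaction pathway at ``state``.

    Keys are the pathway letters of the model diagram that appear in the
    equations; ``"g,m"`` (APC-driven helper activation) and ``"k,l"``
    (helper-driven cytotoxic activation) are fused labels for single terms.
    :func:`recombine_pathways` documents how the derivatives are rebuilt
    from these factors.
    """
    if validate:
        _require_valid(params)
        state.validate_nonnegative()
    p = params
    L, A, T_H, T_C, T_R, I = state.to_array()
    return {
        # hepatocyte / APC equations
        "h": p.delta_L * L,                                # natural hepatocyte loss
        "e": p.alpha_CL * T_C / (p.beta_CL + T_C),         # T_C killing boost
        "b": p.lambda_L,                                   # alloantigen shedding
        "i": p.delta_A * A,                                # APC natural loss
        # helper T cell equation
        "g,m": p.alpha_AH * A / (p.beta_AH + A),           # APC-driven activation
        "j": p.alpha_RA * T_R / (p.beta_RA + T_R),         # Treg suppression
        "x": 1.0 + p.alpha_IRA * I / (p.beta_IRA + I),     # IL-2 suppression boost
        "s": p.gamma_H * T_H * (1.0 - T_H / p.K_H),        # logistic T_H growth
        "r": p.alpha_IH * I / (p.beta_IH + I),             # IL-2 gate on T_H growth
        "y": p.delta_H * T_H,                              # T_H natural loss
        # cytotoxic T cell equation
        "k,l": p.alpha_HC * T_H / (p.beta_HC + T_H),       # T_H-driven activation
        "p": p.gamma_C * T_C * (1.0 - T_C / p.K_C),        # logistic T_C growth
        "q": p.alpha_IC * I / (p.beta_IC + I),             # IL-2 gate on T_C growth
        "t": p.delta_C * T_C,                              # T_C natural loss
        # Treg equation
        "v": p.s_R,                                        # constant Treg source
        "z": p.delta_R * T_R,                              # Treg natural loss
        "u": 1.0 - p.alpha_IR * I / (p.beta_IR + I),       # IL-2 lifespan extension
        # IL-2 equation
        "n": p.alpha_CI * T_C / (p.beta_CI + T_C),         # IL-2 from T_C
        "o": p.alpha_HI * T_H / (p.beta_HI + T_H),         # IL-2 from T_H
        "w": p.delta_I * I,                                # IL-2 natural decay
    }


def recombine_pathways(pw: Mapping[str, float],
                       params: ModelParameters) -> StateDerivative:
    """Rebuild the six derivatives from labelled pathway factors.

    Recombination rule::

        dL   = -h * e
        dA   = b * h * (1 + e) - i
        dT_H = (g,m) * [1 - j * x] + s * r - y
        dT_C = (k,l) + p * q - t
        dT_R = v - z * u
        dI   = n + o - lambda_C * p * q - lambda_H * s * r - lambda_R * z * u - w

    The three IL-2 internalization losses are, by construction, exactly the
    ``lambda``-weighted proliferation/survival terms of the T cell equations.
    """
    return StateDerivative(
        dL=-pw["h"] * pw["e"],
        dA=pw["b"] * pw["h"] * (1.0 + pw["e"]) - pw["i"],
        dT_H=pw["g,m"] * (1.0 - pw["j"] * pw["x"]) + pw["s"] * pw["r"] - pw["y"],
        dT_C=pw["k,l"] + pw["p"] * pw["q"] - pw["t"],
        dT_R=pw["v"] - pw["z"] * pw["u"],
        dI=(pw["n"] + pw["o"]
            - params.lambda_C * pw["p"] * pw["q"]
            - params.lambda_H * pw["s"] * pw["r"]
            - params.lambda_R * pw["z"] * pw["u"]
            - pw["w"]),
    )


def derivative(state: ImmuneState, params: ModelParameters,
               validate: bool = True) -> StateDerivative:
    """Evaluate the model right-hand side at ``state``.

    The equations are evaluated exactly as displayed; in particular the
    helper-activation bracket ``[1 - j*x]`` is not floored at zero and the
    logistic terms may be negative above carrying capacity.
    """
    if validate:
        _require_valid(params)
        state.validate_nonnegative()
    dy = _rhs(0.0, state.to_array(), params.to_array())
    return StateDerivative(*dy)


def _rhs(t: float, y: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Fast array right-hand side; ``theta`` is in :data:`PARAM_NAMES` order.

    Shared by the adaptive solver, the fixed-step reference integrator and
    (broadcast over a trailing sample axis) the vectorized GSA evaluator.
    """
    L, A, T_H, T_C, T_R, I = y
    (delta_L, alpha_CL, beta_CL, lambda_L, delta_A,
     alpha_AH, beta_AH, alpha_RA, beta_RA, alpha_IRA, beta_IRA,
     gamma_H, K_H, alpha_IH, beta_IH, delta_H,
     alpha_HC, beta_HC, gamma_C, K_C, alpha_IC, beta_IC, delta_C,
     s_R, delta_R, alpha_IR, beta_IR,
     alpha_CI, beta_CI, alpha_HI, beta_HI,
     lambda_C, lambda_H, lambda_R, delta_I) = theta

    e = alpha_CL * T_C / (beta_CL + T_C)
    h = delta_L * L
    act_H = alpha_AH * A / (beta_AH + A)
    j = alpha_RA * T_R / (beta_RA + T_R)
    x = 1.0 + alpha_IRA * I / (beta_IRA + I)
    s = gamma_H * T_H * (1.0 - T_H / K_H)
    r = alpha_IH * I / (beta_IH + I)
    act_C = alpha_HC * T_H / (beta_HC + T_H)
    pr = gamma_C * T_C * (1.0 - T_C / K_C)
    q = alpha_IC * I / (beta_IC + I)
    u = 1.0 - alpha_IR * I / (beta_IR + I)
    z = delta_R * T_R

    dL = -h * e
    dA = lambda_L * h * (1.0 + e) - delta_A * A
    dT_H = act_H * (1.0 - j * x) + s * r - delta_H * T_H
    dT_C = act_C + pr * q - delta_C * T_C
    dT_R = s_R - z * u
    dI = (alpha_CI * T_C / (beta_CI + T_C)
          + alpha_HI * T_H / (beta_HI + T_H)
          - lambda_C * pr * q - lambda_H * s * r - lambda_R * z * u
          - delta_I * I)
    return np.array([dL, dA, dT_H, dT_C, dT_R, dI])
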