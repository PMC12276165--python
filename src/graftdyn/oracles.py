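"""Closed-form test functions that validate the Sobol' index estimators.

Two standard benchmarks whose variance decompositions are known exactly:

* an additive linear function of independent uniforms, where first-order and
  total indices coincide at ``c_i^2 var(x_i) / sum_j c_j^2 var(x_j)``;
* the Ishigami function ``sin(x1) + a sin(x2)^2 + b x3^4 sin(x1)`` on
  ``[-pi, pi]^3``, which has a pure x1–x3 interaction, a zero first-order
  index for x3, and fully analytic indices.

The analytic values here are derived independently of the estimators (plain
integrals of the ANOVA decomposition), so agreement is evidence about the
estimator implementation, not a self-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sensitivity import SobolIndices, design_from_bounds, estimate_indices, evaluate_design

__all__ = [
    "linear_analytic_indices",
    "ishigami",
    "ishigami_analytic_indices",
    "OracleReport",
    "linear_report",
    "ishigami_report",
]


def linear_analytic_indices(coeffs: np.ndarray, lo: np.ndarray,
                            hi: np.ndarray) -> np.ndarray:
    """S1 = ST for y = sum c_i x_i with independent uniform x_i."""
    contributions = np.asarray(coeffs) ** 2 * (np.asarray(hi) - np.asarray(lo)) ** 2 / 12.0
    return contributions / contributions.sum()


def ishigami(x: np.ndarray, a: float = 7.0, b: float = 0.1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return (np.sin(x[:, 0]) + a * np.sin(x[:, 1]) ** 2
            + b * x[:, 2] ** 4 * np.sin(x[:, 0]))


def ishigami_analytic_indices(a: float = 7.0, b: float = 0.1
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Exact (S1, ST) of the Ishigami function on [-pi, pi]^3.

    From the ANOVA decomposition: V1 = b*pi^4/5 + b^2*pi^8/50 + 1/2,
    V2 = a^2/8, V3 = 0, V13 = b^2*pi^8*(1/18 - 1/50), all other interaction
    terms zero, and V = V1 + V2 + V13.
    """
    pi = np.pi
    V1 = b * pi ** 4 / 5.0 + b ** 2 * pi ** 8 / 50.0 + 0.5
    V2 = a ** 2 / 8.0
    V13 = b ** 2 * pi ** 8 * (1.0 / 18.0 - 1.0 / 50.0)
    V = V1 + V2 + V13
    S1 = np.array([V1 / V, V2 / V, 0.0])
    ST = np.array([(V1 + V13) / V, V2 / V, V13 / V])
    return S1, ST


@dataclass(frozen=True)
class OracleReport:
    """Estimated vs analytic indices with the 3-standard-error verdict."""

    name: str
    indices: SobolIndices
    S1_true: np.ndarray
    ST_true: np.ndarray

    @property
    def ok(self) -> bool:
        s1_ok = np.all(np.abs(self.indices.S1 - self.S1_true)
                       <= 3.0 * np.maximum(self.indices.S1_err, 1e-12))
        st_ok = np.all(np.abs(self.indices.ST - self.ST_true)
                       <= 3.0 * np.maximum(self.indices.ST_err, 1e-12))
        return bool(s1_ok and st_ok)

    def describe(self) -> str:
        lines = [f"{self.name}: {'OK' if self.ok else 'DISAGREES'} "
                 f"(N={self.indices.N})"]
        for i, nm in enumerate(self.indices.names):
            lines.append(
                f"  {nm}: S1 {self.indices.S1[i]:+.4f} (true {self.S1_true[i]:+.4f}"
                f" +/- {3 * self.indices.S1_err[i]:.4f})  "
                f"ST {self.indices.ST[i]:+.4f} (true {self.ST_true[i]:+.4f}"
                f" +/- {3 * self.indices.ST_err[i]:.4f})")
        return "\n".join(lines)


def linear_report(N: int = 8192, seed: int = 0,
                  coeffs: tuple[float, ...] = (4.0, 2.0, 1.0, 0.5),
                  ) -> OracleReport:
    """Estimate indices of an additive linear function and compare exactly."""
    c = np.asarray(coeffs)
    lo = np.zeros_like(c)
    hi = np.ones_like(c)
    design = design_from_bounds(lo, hi, N, seed=seed,
                                names=[f"c{ci:g}" for ci in c])
    y = evaluate_design(design, lambda X: X @ c)
    idx = estimate_indices(design, y)
    S = linear_analytic_indices(c, lo, hi)
    return OracleReport("additive-linear", idx, S, S)


def ishigami_report(N: int = 8192, seed: int = 0,
                    a: float = 7.0, b: float = 0.1) -> OracleReport:
    """Estimate indices of the Ishigami function and compare with closed form."""
    lo = np.full(3, -np.pi)
    hi = np.full(3, np.pi)
    design = design_from_bounds(lo, hi, N, seed=seed,
                                names=["x1", "x2", "x3"])
    y = evaluate_design(design, lambda X: ishigami(X, a, b))
    idx = estimate_indices(design, y)
    S1, ST = ishigami_analytic_indices(a, b)
    return OracleReport("ishigami", idx, S1, ST)
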