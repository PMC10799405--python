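"""Classical growth families, the allometric disturbance term, and their sum.

A light-response phenotype trajectory y(l) over log light intensity l is
decomposed additively into an autogenic (genetically regulated) sigmoid
φ(l) drawn from one of seven classical growth families and an environmental
disturbance term ω(l) = c·l^d following an allometric scaling law:

    y(l) = φ(l) + ω(l)   [+ ε, an optional population-structure offset]

Trait-specific default forms: the electron transport rate (ETR) rises
sigmoidally (logistic), photochemical quenching (qP) falls monotonically
(Mitscherlich with a < 0), and nonphotochemical quenching (qN) follows a
Korf curve that stays near zero at low light.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "HDEEParams",
    "GROWTH_FAMILIES",
    "TRAIT_FORMS",
    "eval_growth",
    "eval_disturbance",
    "eval_hdee",
    "n_growth_params",
    "growth_jacobian",
    "hdee_jacobian",
]


@dataclass(frozen=True)
class HDEEParams:
    """Parameters of one composite light-response curve.

    K : upper asymptote of the autogenic term (trait units).
    a : initial-value / shape parameter of the growth family.
    b : intrinsic rate (all families); inflection-related for Korf.
    m : Richards shape parameter (only used by the Richards family; m ≠ 1).
    c : disturbance rate (trait units per l^d); sign free.
    d : disturbance scale exponent (dimensionless).
    """

    K: float
    a: float
    b: float
    m: Optional[float] = None
    c: float = 0.0
    d: float = 0.0

    def with_(self, **kw) -> "HDEEParams":
        return replace(self, **kw)

    def as_vector(self, family: str, disturbance: bool) -> np.ndarray:
        v = [self.K, self.a, self.b]
        if family == "richards":
            v.append(1.5 if self.m is None else self.m)
        if disturbance:
            v += [self.c, self.d]
        return np.asarray(v, dtype=float)

    @staticmethod
    def from_vector(x, family: str, disturbance: bool) -> "HDEEParams":
        x = np.asarray(x, dtype=float)
        K, a, b = x[:3]
        i = 3
        m = None
        if family == "richards":
            m = float(x[i])
            i += 1
        c = d = 0.0
        if disturbance:
            c, d = float(x[i]), float(x[i + 1])
        return HDEEParams(K=float(K), a=float(a), b=float(b), m=m, c=c, d=d)


def _gompertz(p: HDEEParams, l: np.ndarray) -> np.ndarray:
    return p.K * np.exp(-p.a * np.exp(-p.b * l))


def _logistic(p: HDEEParams, l: np.ndarray) -> np.ndarray:
    return p.K / (1.0 + p.a * np.exp(-p.b * l))


def _mitscherlich(p: HDEEParams, l: np.ndarray) -> np.ndarray:
    return p.K * (1.0 - p.a * np.exp(-p.b * l))


def _bertalanffy(p: HDEEParams, l: np.ndarray) -> np.ndarray:
    return p.K * (1.0 - p.a * np.exp(-p.b * l)) ** 3


def _richards(p: HDEEParams, l: np.ndarray) -> np.ndarray:
    if p.m is None or p.m == 1.0:
        raise ValueError("richards family requires shape parameter m != 1")
    base = 1.0 - p.a * np.exp(-p.b * l)
    return p.K * np.sign(base) * np.abs(base) ** (1.0 / (1.0 - p.m))


def _korf(p: HDEEParams, l: np.ndarray) -> np.ndarray:
    if np.any(np.asarray(l) <= 0):
        raise ValueError("korf family is defined for l > 0")
    return p.K * np.exp(-p.a / np.asarray(l, dtype=float) ** p.b)


def _weibull(p: HDEEParams, l: np.ndarray) -> np.ndarray:
    # Standard Weibull growth K(1 - e^{-(l/a)^b}); evaluated for l > 0.
    if np.any(np.asarray(l) <= 0):
        raise ValueError("weibull family is defined for l > 0")
    return p.K * (1.0 - np.exp(-((np.asarray(l, dtype=float) / p.a) ** p.b)))


GROWTH_FAMILIES = {
    "gompertz": _gompertz,
    "logistic": _logistic,
    "mitscherlich": _mitscherlich,
    "bertalanffy": _bertalanffy,
    "richards": _richards,
    "korf": _korf,
    "weibull": _weibull,
}

#: Trait-specific default autogenic forms (composite with c·l^d in each case).
TRAIT_FORMS = {"ETR": "logistic", "qP": "mitscherlich", "qN": "korf"}


def n_growth_params(family: str) -> int:
    """Number of autogenic parameters: 4 for Richards, 3 otherwise."""
    if family not in GROWTH_FAMILIES:
        raise ValueError(f"unknown growth family {family!r}")
    return 4 if family == "richards" else 3


def eval_growth(family: str, params: HDEEParams, l) -> np.ndarray:
    """Evaluate the autogenic growth term φ(l) of the given family."""
    if family not in GROWTH_FAMILIES:
        raise ValueError(f"unknown growth family {family!r}")
    l = np.asarray(l, dtype=float)
    return GROWTH_FAMILIES[family](params, l)


def eval_disturbance(c: float, d: float, l) -> np.ndarray:
    """Allometric environmental disturbance ω(l) = c·l^d (l > 0)."""
    l = np.asarray(l, dtype=float)
    if np.any(l <= 0):
        raise ValueError("disturbance term is defined for l > 0")
    return c * l**d


def eval_hdee(family: str, params: HDEEParams, l, epsilon: float = 0.0) -> np.ndarray:
    """Composite curve φ(l) + ω(l) (+ ε when a group offset is supplied)."""
    return eval_growth(family, params, l) + eval_disturbance(params.c, params.d, l) + epsilon


def growth_jacobian(family: str, params: HDEEParams, l) -> np.ndarray:
    """Analytic Jacobian of φ(l) w.r.t. the family's parameters (L × p).

    Column order matches :meth:`HDEEParams.as_vector`.  Rows where the
    family's domain is violated (e.g. a non-positive Richards base) come
    back non-finite and are handled by the caller.
    """
    l = np.asarray(l, dtype=float)
    K, a, b, m = params.K, params.a, params.b, params.m
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        if family == "gompertz":
            E = np.exp(-b * l)
            core = np.exp(-a * E)
            return np.column_stack([core, -K * E * core, K * a * l * E * core])
        if family == "logistic":
            E = np.exp(-b * l)
            D = 1.0 + a * E
            return np.column_stack([1.0 / D, -K * E / D**2, K * a * l * E / D**2])
        if family == "mitscherlich":
            E = np.exp(-b * l)
            return np.column_stack([1.0 - a * E, -K * E, K * a * l * E])
        if family == "bertalanffy":
            E = np.exp(-b * l)
            B = 1.0 - a * E
            return np.column_stack([B**3, -3 * K * B**2 * E, 3 * K * B**2 * a * l * E])
        if family == "richards":
            if m is None or m == 1.0:
                raise ValueError("richards family requires shape parameter m != 1")
            E = np.exp(-b * l)
            B = 1.0 - a * E
            r = 1.0 / (1.0 - m)
            Br = B**r  # non-finite where B <= 0; caller guards
            return np.column_stack([
                Br, -K * r * B ** (r - 1) * E, K * r * B ** (r - 1) * a * l * E,
                K * Br * np.log(B) / (1.0 - m) ** 2,
            ])
        if family == "korf":
            u = l ** (-b)
            core = np.exp(-a * u)
            return np.column_stack([core, -K * u * core, K * a * np.log(l) * u * core])
        if family == "weibull":
            v = (l / a) ** b
            ev = np.exp(-v)
            return np.column_stack([1.0 - ev, -K * ev * b * v / a, K * ev * v * np.log(l / a)])
    raise ValueError(f"unknown growth family {family!r}")


def hdee_jacobian(family: str, params: HDEEParams, l, disturbance: bool) -> np.ndarray:
    """Jacobian of the composite curve; appends the c·l^d columns if present."""
    l = np.asarray(l, dtype=float)
    J = growth_jacobian(family, params, l)
    if disturbance:
        with np.errstate(over="ignore", invalid="ignore"):
            ld = l**params.d
            J = np.column_stack([J, ld, params.c * ld * np.log(l)])
    return J
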