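"""Candidate curve families for relative-NDVI dynamics on the RAGDD clock.

The headline family is the double logistic,

    y(x) = 1/(1 + exp(-a (x - b))) - 1/(1 + exp(-c (x - d))),

a rising logistic limb (steepness a, inflection timing b) minus a
senescence limb (steepness c, timing d), producing the rise - plateau -
decline shape of a rice canopy over the season. a and c control how
steeply the canopy greens up and senesces; b and d are the RAGDD
locations of the two inflection points. Four alternatives from the same
model-selection exercise are shipped alongside it: a cubic polynomial,
two rational forms, and a three-parameter logistic.

The registry is extensible; ``relationship`` families (linear,
saturating exponential, power) used for NDVI-vs-growth-index
regressions are registered here too so a single evaluator serves both.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

#: evaluation/fitting domain of the RAGDD clock, slightly past harvest
#: so peaks near the end of the season are not edge artifacts
RAGDD_DOMAIN = (0.0, 1.1)

_DENOM_EPS = 1e-12


def _double_logistic(p, x):
    a, b, c, d = p
    return 1.0 / (1.0 + np.exp(-a * (x - b))) - 1.0 / (1.0 + np.exp(-c * (x - d)))


def _cubic(p, x):
    a, b, c, d = p
    return a + b * x + c * x**2 + d * x**3


def _rational_quad(p, x):
    a, b, c, d = p
    den = c * x + d * x**2 + 1.0
    if np.any(np.abs(den) < _DENOM_EPS):
        raise ValueError("rational_quad denominator vanishes at requested x")
    return (a + b * x) / den


def _rational_power(p, x):
    a, b, c, d = p
    if np.any(np.asarray(x) < 0):
        raise ValueError("rational_power requires x >= 0")
    xd = np.power(x, d)
    den = b + xd
    if np.any(np.abs(den) < _DENOM_EPS):
        raise ValueError("rational_power denominator vanishes at requested x")
    return (a * b + c * xd) / den


def _logistic3(p, x):
    a, b, c = p
    return a / (1.0 + b * np.exp(-c * x))


def _linear(p, x):
    a, b = p
    return a + b * x


def _exp_saturating(p, x):
    a, b, c = p
    return a - b * np.exp(-c * x)


def _power(p, x):
    a, b = p
    if np.any(np.asarray(x) <= 0):
        raise ValueError("power family requires x > 0")
    return a * np.power(x, b)


@dataclass(frozen=True)
class Family:
    name: str
    arity: int
    fn: Callable
    param_names: tuple[str, ...]


FAMILIES: dict[str, Family] = {
    f.name: f
    for f in [
        Family("double_logistic", 4, _double_logistic, ("a", "b", "c", "d")),
        Family("cubic", 4, _cubic, ("a", "b", "c", "d")),
        Family("rational_quad", 4, _rational_quad, ("a", "b", "c", "d")),
        Family("rational_power", 4, _rational_power, ("a", "b", "c", "d")),
        Family("logistic3", 3, _logistic3, ("a", "b", "c")),
        Family("linear", 2, _linear, ("a", "b")),
        Family("exponential_saturating", 3, _exp_saturating, ("a", "b", "c")),
        Family("power", 2, _power, ("a", "b")),
    ]
}

#: the five candidate families entered in the RNDVI model-selection stage
CANDIDATE_FAMILIES = (
    "double_logistic",
    "cubic",
    "rational_quad",
    "rational_power",
    "logistic3",
)


@dataclass(frozen=True)
class CurveSpec:
    """A curve family plus a concrete parameter vector."""

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        fam = FAMILIES.get(self.family)
        if fam is None:
            raise ValueError(f"unknown curve family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if len(self.params) != fam.arity:
            raise ValueError(
                f"{self.family} takes {fam.arity} parameters, got {len(self.params)}"
            )
        if self.family == "double_logistic":
            a, b, c, d = self.params
            if not (a > 0 and c > 0 and b < d):
                warnings.warn(
                    "double_logistic parameters do not describe a physical "
                    f"rise-then-fall canopy curve (a={a}, b={b}, c={c}, d={d})",
                    stacklevel=2,
                )

    @property
    def named_params(self) -> dict[str, float]:
        return dict(zip(FAMILIES[self.family].param_names, self.params))

    def to_json(self) -> str:
        return json.dumps({"family": self.family, "params": self.named_params})

    @classmethod
    def from_json(cls, text: str) -> "CurveSpec":
        obj = json.loads(text)
        fam = FAMILIES[obj["family"]]
        params = tuple(obj["params"][name] for name in fam.param_names)
        return cls(obj["family"], params)


def eval_curve(spec: CurveSpec, x):
    """Evaluate a curve spec at scalar or array ``x``.

    Raises a domain error when a rational family's denominator comes
    within 1e-12 of zero, or when x is outside the family's domain.
    """
    xv = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(xv)):
        raise ValueError("x must be finite")
    y = FAMILIES[spec.family].fn(spec.params, xv)
    if np.ndim(x) == 0:
        return float(y)
    return np.asarray(y, dtype=float)


def curve_peak(
    spec: CurveSpec, lo: float = RAGDD_DOMAIN[0], hi: float = RAGDD_DOMAIN[1]
) -> tuple[float, float]:
    """Locate the maximum of a curve over [lo, hi].

    Dense-grid scan followed by golden-section refinement around the
    best grid point; x is resolved to well under 1e-4.
    """
    from scipy.optimize import minimize_scalar

    grid = np.linspace(lo, hi, 2201)
    yg = eval_curve(spec, grid)
    k = int(np.argmax(yg))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    if a == b:
        return float(grid[k]), float(yg[k])
    res = minimize_scalar(
        lambda t: -eval_curve(spec, float(t)),
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-7},
    )
    x_at_max, y_max = float(res.x), float(-res.fun)
    if yg[k] > y_max:  # refinement can only improve on the grid point
        return float(grid[k]), float(yg[k])
    return x_at_max, y_max
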