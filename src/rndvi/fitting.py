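"""Nonlinear least-squares fitting, goodness of fit, model ranking, and
per-group model construction.

Candidate curves are fitted to the pooled (RAGDD, RNDVI) point clouds
by trust-region least squares (scipy's trust-region reflective solver);
linear-in-parameter families (cubic, linear) are solved exactly by
ordinary least squares. Goodness of fit is the coefficient of
determination about the observed mean and the root mean squared error

    RMSE = sqrt( (1/n) * sum_i (P_i - O_i)^2 ),

with P the simulated and O the observed values. Candidate families are
ranked by R^2 (descending), with RMSE and then parameter count breaking
ties. Parameter standard errors come from the linearized covariance at
the solution and feed a Wald z-test for comparing parameters between
two fitted models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .curves import CANDIDATE_FAMILIES, FAMILIES, CurveSpec, eval_curve
from .normalize import NormalizedSeries
from .types import CultivarType, YieldLevel

# physically motivated box constraints for the double logistic on the
# [0, 1.1] RAGDD clock: steepness positive and bounded, green-up timing
# in the first half of the season, senescence timing near harvest
_BOUNDS: dict[str, tuple[list[float], list[float]]] = {
    "double_logistic": ([1e-8, -0.5, 1e-8, 0.5], [100.0, 1.0, 100.0, 1.6]),
    "logistic3": ([1e-8, 1e-8, 1e-8], [10.0, 1e6, 200.0]),
    "rational_power": ([-10.0, 1e-8, -10.0, 0.05], [10.0, 1e6, 10.0, 20.0]),
    "exponential_saturating": ([-np.inf, -np.inf, 1e-8], [np.inf, np.inf, np.inf]),
}

_DEFAULT_START: dict[str, tuple[float, ...]] = {
    "double_logistic": (10.0, 0.2, 10.0, 1.0),
    "logistic3": (1.0, 50.0, 10.0),
    "rational_power": (0.0, 0.5, 1.0, 3.0),
}

# scattered alternates tried when the default start fails to converge
_MULTI_STARTS: dict[str, list[tuple[float, ...]]] = {
    "double_logistic": [
        (5.0, 0.1, 5.0, 0.9),
        (20.0, 0.25, 12.0, 1.0),
        (40.0, 0.15, 8.0, 1.05),
        (15.0, 0.3, 15.0, 0.95),
        (8.0, 0.2, 20.0, 1.1),
        (30.0, 0.1, 30.0, 1.0),
        (12.0, 0.35, 6.0, 1.2),
        (50.0, 0.2, 10.0, 1.0),
    ],
    "logistic3": [
        (0.9, 100.0, 27.0),
        (1.0, 10.0, 5.0),
        (0.8, 1000.0, 50.0),
        (1.2, 5.0, 2.0),
        (0.5, 50.0, 15.0),
        (2.0, 200.0, 30.0),
        (1.0, 1.0, 1.0),
        (0.7, 20.0, 8.0),
    ],
    "rational_power": [
        (-0.2, 0.001, 0.9, 3.5),
        (0.0, 0.01, 1.0, 2.0),
        (-0.5, 0.1, 1.2, 5.0),
        (0.1, 1.0, 0.8, 1.0),
        (0.0, 0.0001, 1.0, 4.0),
        (-1.0, 0.05, 2.0, 2.5),
        (0.2, 0.5, 0.5, 6.0),
        (0.0, 0.002, 0.9, 3.0),
    ],
}


class FitError(RuntimeError):
    """A fit that cannot even be attempted (e.g. underdetermined)."""


@dataclass
class ModelFit:
    """A fitted curve with goodness of fit and parameter uncertainty."""

    spec: CurveSpec
    r2: float
    rmse: float
    n: int
    param_se: tuple[float, ...] = ()
    converged: bool = True
    residual_variance: float = field(default=float("nan"), repr=False)

    @property
    def arity(self) -> int:
        return FAMILIES[self.spec.family].arity

    def predict(self, x):
        return eval_curve(self.spec, x)


def goodness(y_obs, y_hat) -> tuple[float, float]:
    """Coefficient of determination and RMSE of predictions vs observations.

    R^2 = 1 - SSE/SST with SST about the mean of ``y_obs`` (not squared
    Pearson r — the distinction matters for nonlinear fits). When the
    observations have zero variance R^2 is undefined; it is reported as
    0.0 for a perfect fit (the model adds nothing beyond the mean) and
    NaN, with a warning, otherwise.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y_obs.shape != y_hat.shape:
        raise ValueError("y_obs and y_hat must have equal length")
    n = y_obs.size
    if n < 2:
        raise ValueError("need at least 2 points")
    resid = y_hat - y_obs
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y_obs - y_obs.mean()) ** 2))
    rmse = float(np.sqrt(sse / n))
    # numerically-zero sums of squares (constant inputs) count as zero
    tol = n * (1e-12 * max(1.0, float(np.abs(y_obs).max()))) ** 2
    if sst <= tol:
        if sse <= tol:
            return 0.0, rmse
        warnings.warn("zero variance in y_obs: R^2 undefined", stacklevel=2)
        return float("nan"), rmse
    return 1.0 - sse / sst, rmse


def _as_xy(points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, NormalizedSeries):
        return points.ragdd, points.rndvi
    x, y = points
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def _linear_fit(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact OLS solve returning coefficients and their standard errors."""
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = len(y) - design.shape[1]
    s2 = float(resid @ resid) / dof if dof > 0 else float("nan")
    cov = s2 * np.linalg.pinv(design.T @ design)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return beta, se


def _rational_quad_init(x: np.ndarray, y: np.ndarray) -> tuple[float, ...]:
    # y (1 + c x + d x^2) = a + b x is linear in (a, b, c, d)
    design = np.column_stack([np.ones_like(x), x, -x * y, -(x**2) * y])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return tuple(beta)


def _nls(
    family: str,
    x: np.ndarray,
    y: np.ndarray,
    start: Sequence[float],
    bounds,
) -> "least_squares":
    fn = FAMILIES[family].fn

    def residuals(p):
        with np.errstate(over="ignore", invalid="ignore"):
            try:
                pred = fn(tuple(p), x)
            except ValueError:
                return np.full_like(y, 1e6)
        pred = np.nan_to_num(pred, nan=1e6, posinf=1e6, neginf=-1e6)
        return pred - y

    lo, hi = bounds
    start = np.clip(np.asarray(start, dtype=float), lo, hi)
    return least_squares(
        residuals, start, bounds=bounds, method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000,
    )


def fit_curve(
    family: str,
    points,
    init: Sequence[float] | None = None,
    bounds=None,
) -> ModelFit:
    """Least-squares fit of one curve family to (x, y) points.

    ``points`` is a NormalizedSeries or an (x, y) pair of arrays. The
    fit is deterministic given identical inputs and starting values.
    Linear-in-parameter families are solved exactly; nonlinear families
    use a trust-region solver from a physically motivated default start,
    falling back to eight scattered starts when the first attempt fails
    to converge. A fit that never converges is returned flagged with
    ``converged=False`` rather than raised.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown curve family {family!r}")
    x, y = _as_xy(points)
    arity = FAMILIES[family].arity
    n = x.size
    if n < arity + 1:
        raise FitError(
            f"{family}: {n} points cannot determine {arity} parameters"
        )

    if family in ("cubic", "linear"):
        degree = 3 if family == "cubic" else 1
        design = np.column_stack([x**k for k in range(degree + 1)])
        beta, se = _linear_fit(design, y)
        spec = CurveSpec(family, tuple(beta))
        r2, rmse = goodness(y, design @ beta)
        return ModelFit(spec, r2, rmse, n, tuple(se), True)
    if family == "power":
        if np.any(x <= 0):
            raise FitError("power family requires x > 0")
        start = _power_init(x, y)
        return _fit_nonlinear(family, x, y, [start], bounds)

    if bounds is None:
        bounds = _BOUNDS.get(family, (-np.inf, np.inf))
    starts: list[Sequence[float]] = []
    if init is not None:
        starts.append(tuple(init))
    elif family == "rational_quad":
        starts.append(_rational_quad_init(x, y))
    elif family == "exponential_saturating":
        span = float(y.max() - y.min()) or 1.0
        xscale = float(np.mean(np.abs(x))) or 1.0
        starts.append((float(y.max()), span, 1.0 / xscale))
    else:
        starts.append(_DEFAULT_START[family])
    starts.extend(_MULTI_STARTS.get(family, []))
    return _fit_nonlinear(family, x, y, starts, bounds)


def _power_init(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pos = y > 0
    if pos.sum() >= 2:
        b, loga = np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)
        return (float(np.exp(loga)), float(b))
    return (1.0, 1.0)


def _fit_nonlinear(family, x, y, starts, bounds) -> ModelFit:
    if bounds is None:
        bounds = _BOUNDS.get(family, (-np.inf, np.inf))
    best = None
    for i, start in enumerate(starts):
        res = _nls(family, x, y, start, bounds)
        if (
            best is None
            or (res.success and not best.success)
            or (res.success == best.success and res.cost < best.cost)
        ):
            best = res
        if i == 0 and res.success:
            break  # default start converged: deterministic single-start path
    converged = bool(best is not None and best.success)
    spec = CurveSpec(family, tuple(best.x))
    n, p = x.size, len(best.x)
    sse = float(np.sum(best.fun**2))
    dof = n - p
    s2 = sse / dof if dof > 0 else float("nan")
    jtj = best.jac.T @ best.jac
    cov = s2 * np.linalg.pinv(jtj)
    se = tuple(np.sqrt(np.clip(np.diag(cov), 0.0, None)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = eval_curve(spec, x)
    r2, rmse = goodness(y, pred)
    return ModelFit(spec, r2, rmse, n, se, converged, s2)


def rank_models(fits: Iterable[ModelFit]) -> list[ModelFit]:
    """Order fits best-first: by R^2 descending, then RMSE ascending,
    then fewer parameters. Unconverged fits are dropped; if none
    converged that is an error."""
    usable = [f for f in fits if f.converged]
    if not usable:
        raise FitError("no converged fits to rank")
    return sorted(usable, key=lambda f: (-f.r2, f.rmse, f.arity))


def fit_candidates(
    points, families: Sequence[str] = CANDIDATE_FAMILIES
) -> list[ModelFit]:
    """Fit every candidate family to the same point cloud and rank them."""
    fits = []
    for family in families:
        try:
            fits.append(fit_curve(family, points))
        except FitError as exc:
            warnings.warn(f"{family}: {exc}", stacklevel=2)
    return rank_models(fits)


GroupKey = tuple[CultivarType, YieldLevel]


def fit_group_models(
    datasets: Iterable[NormalizedSeries],
    family: str = "double_logistic",
) -> dict[GroupKey, ModelFit]:
    """Fit one curve per (cultivar type, yield level) group.

    A group whose fit fails is skipped with a warning; the remaining
    groups are unaffected. Absent groups are simply absent from the
    result, never null-filled.
    """
    out: dict[GroupKey, ModelFit] = {}
    for ds in datasets:
        try:
            out[ds.group_key] = fit_curve(family, ds)
        except (FitError, ValueError) as exc:
            warnings.warn(
                f"group {ds.group_key!r}: fit failed ({exc})", stacklevel=2
            )
    return out


def compare_parameters(
    fit_a: ModelFit, fit_b: ModelFit
) -> dict[str, tuple[float, float]]:
    """Wald z-test for each parameter of two fits of the same family.

    z = (theta_a - theta_b) / sqrt(se_a^2 + se_b^2), with a two-sided
    normal-approximation p-value. Identical fits give z = 0, p = 1;
    vanishing standard errors with different estimates drive p to 0.
    """
    if fit_a.spec.family != fit_b.spec.family:
        raise ValueError("fits must share a curve family")
    if not fit_a.param_se or not fit_b.param_se:
        raise ValueError("both fits need parameter standard errors")
    names = FAMILIES[fit_a.spec.family].param_names
    out: dict[str, tuple[float, float]] = {}
    for name, ta, tb, sa, sb in zip(
        names, fit_a.spec.params, fit_b.spec.params, fit_a.param_se, fit_b.param_se
    ):
        denom = float(np.hypot(sa, sb))
        diff = ta - tb
        if denom == 0.0:
            z = 0.0 if diff == 0.0 else float(np.sign(diff)) * float("inf")
        else:
            z = diff / denom
        p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
        if z == 0.0:
            p = 1.0
        out[name] = (float(z), p)
    return out


RELATIONSHIP_FAMILIES = ("linear", "exponential_saturating", "power")


def relationship_fit(x, y, family: str = "linear") -> ModelFit:
    """Regression of canopy NDVI on a growth index (LAI, dry matter, or
    grain yield), per growth stage.

    Offers a small family menu — linear, saturating exponential
    a - b*exp(-c*x), and power a*x^b — since NDVI saturates against
    dense canopies; the chosen family is recorded on the returned fit.
    """
    if family not in RELATIONSHIP_FAMILIES:
        raise ValueError(
            f"family {family!r} not in {RELATIONSHIP_FAMILIES}"
        )
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise FitError("need at least 3 points")
    return fit_curve(family, (x, y))
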