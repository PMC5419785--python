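"""Back-transform of relative NDVI and stage-wise validation scoring.

A fitted RNDVI(RAGDD) model is turned back into NDVI via

    NDVI_s(i) = NDVI_max * RNDVI_s(i),

then simulated values are scored against independent observations per
growth stage with three statistics: the accuracy slope k (through-origin
regression of simulated on observed — k near 1 means the simulation
tracks the 1:1 line), the precision R^2, and RMSE. Growth stages are
binned on the RAGDD clock so the same bins transfer across seasons and
sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fitting import goodness

#: default stage windows on the RAGDD clock, half-open [lo, hi)
DEFAULT_STAGE_BINS: dict[str, tuple[float, float]] = {
    "active_tillering": (0.10, 0.20),
    "middle_tillering": (0.20, 0.30),
    "jointing": (0.30, 0.45),
    "booting": (0.45, 0.60),
    "heading": (0.60, 0.70),
    "flowering": (0.70, 0.80),
}

OVERALL = "overall"


def reconstruct_ndvi(rndvi_s, ndvi_max: float):
    """Scale simulated relative NDVI back to NDVI by the group maximum."""
    if ndvi_max <= 0:
        raise ValueError(f"ndvi_max must be positive, got {ndvi_max}")
    out = np.asarray(rndvi_s, dtype=float) * ndvi_max
    if np.ndim(rndvi_s) == 0:
        return float(out)
    return out


def slope_k(obs, sim, through_origin: bool = True) -> float:
    """Accuracy slope of simulated on observed values.

    Default is the through-origin least-squares slope
    sum(obs*sim)/sum(obs^2), matching the 1:1-line reading of a
    validation scatter; ``through_origin=False`` gives the ordinary
    slope with intercept instead.
    """
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 points")
    if not np.any(obs != 0):
        raise ValueError("observed values are all zero; slope undefined")
    if through_origin:
        return float(np.dot(obs, sim) / np.dot(obs, obs))
    slope, _ = np.polyfit(obs, sim, 1)
    return float(slope)


@dataclass(frozen=True)
class ValidationReport:
    """Accuracy (k), precision (R^2) and RMSE for one growth stage."""

    stage: str
    k: float
    r2: float
    rmse: float
    n: int


def validate_stagewise(
    pairs,
    stage_bins: dict[str, tuple[float, float]] | None = None,
    through_origin: bool = True,
) -> list[ValidationReport]:
    """Score observed vs simulated NDVI per growth stage.

    ``pairs`` is a sequence of (ragdd, observed, simulated) triples (or
    a 3-column array). Each point is assigned to the half-open stage
    bin [lo, hi) containing its RAGDD; points outside every bin are
    excluded with a warning, as are stages with fewer than 2 points. An
    ``overall`` row pooling all binned points is appended last.
    """
    bins = DEFAULT_STAGE_BINS if stage_bins is None else stage_bins
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("pairs must be (ragdd, obs, sim) triples")
    ragdd, obs, sim = arr.T

    for (s1, (lo1, hi1)) in bins.items():
        for (s2, (lo2, hi2)) in bins.items():
            if s1 < s2 and lo1 < hi2 and lo2 < hi1:
                raise ValueError(f"stage bins {s1!r} and {s2!r} overlap")

    reports: list[ValidationReport] = []
    pooled = np.zeros(len(ragdd), dtype=bool)
    for stage, (lo, hi) in bins.items():
        mask = (ragdd >= lo) & (ragdd < hi)
        pooled |= mask
        if mask.sum() < 2:
            warnings.warn(
                f"stage {stage!r}: {int(mask.sum())} point(s); omitted",
                stacklevel=2,
            )
            continue
        k = slope_k(obs[mask], sim[mask], through_origin)
        r2, rmse = goodness(obs[mask], sim[mask])
        reports.append(ValidationReport(stage, k, r2, rmse, int(mask.sum())))
    n_out = int(len(ragdd) - pooled.sum())
    if n_out:
        warnings.warn(
            f"{n_out} point(s) fall outside every stage bin; excluded",
            stacklevel=2,
        )
    if pooled.sum() >= 2:
        k = slope_k(obs[pooled], sim[pooled], through_origin)
        r2, rmse = goodness(obs[pooled], sim[pooled])
        reports.append(ValidationReport(OVERALL, k, r2, rmse, int(pooled.sum())))
    return reports


def reports_to_frame(reports: list[ValidationReport]):
    """Validation reports as a DataFrame (one row per stage)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"stage": r.stage, "k": r.k, "r2": r.r2, "rmse": r.rmse, "n": r.n}
            for r in reports
        ]
    )


def plot_validation(obs, sim, path, title: str = "Observed vs simulated NDVI"):
    """Scatter of observed vs simulated NDVI with the 45-degree line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    obs = np.asarray(obs, float)
    sim = np.asarray(sim, float)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(obs, sim, s=12, alpha=0.6, edgecolors="none")
    lim = [0.0, max(1.0, obs.max(), sim.max())]
    ax.plot(lim, lim, "k-", lw=1)
    ax.set_xlabel("Observed NDVI")
    ax.set_ylabel("Simulated NDVI")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
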