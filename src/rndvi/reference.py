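"""Published rice RNDVI model parameters and experimental constants.

These are the printed results of the multi-site Jiangsu rice field
study this package reimplements: double-logistic RNDVI(RAGDD)
parameter sets for the pooled high-yield population and for each
cultivar type x yield level, the candidate-model coefficients from the
model-selection stage, and the per-cultivar seasonal NDVI maxima and
grain yields by nitrogen rate. They serve as generating truths for the
synthetic experiment generator and as recovery targets in tests.
"""

from __future__ import annotations

from .curves import CurveSpec
from .types import CultivarType, YieldLevel

#: pooled high-yield (>= 10.5 t/ha) double-logistic RNDVI model
HIGH_YIELD_POOLED = CurveSpec(
    "double_logistic", (15.2829, 0.1944, 11.6517, 1.0267)
)

#: per cultivar-type, per yield-level double-logistic parameter sets
GROUP_PARAMS: dict[tuple[CultivarType, YieldLevel], CurveSpec] = {
    (CultivarType.JAPONICA, YieldLevel.LOW): CurveSpec(
        "double_logistic", (16.4599, 0.3090, 12.3144, 0.9851)
    ),
    (CultivarType.JAPONICA, YieldLevel.MIDDLE): CurveSpec(
        "double_logistic", (19.0544, 0.2629, 11.4756, 1.0022)
    ),
    (CultivarType.JAPONICA, YieldLevel.HIGH): CurveSpec(
        "double_logistic", (20.0313, 0.2370, 10.9741, 1.0195)
    ),
    (CultivarType.INDICA, YieldLevel.LOW): CurveSpec(
        "double_logistic", (14.3656, 0.2196, 14.0343, 0.9972)
    ),
    (CultivarType.INDICA, YieldLevel.MIDDLE): CurveSpec(
        "double_logistic", (17.1028, 0.1749, 13.2413, 1.0192)
    ),
    (CultivarType.INDICA, YieldLevel.HIGH): CurveSpec(
        "double_logistic", (23.8261, 0.1489, 12.0923, 1.0361)
    ),
}

INDICA_HIGH = GROUP_PARAMS[(CultivarType.INDICA, YieldLevel.HIGH)]
JAPONICA_HIGH = GROUP_PARAMS[(CultivarType.JAPONICA, YieldLevel.HIGH)]

#: published coefficients of the five candidate families on the pooled
#: high-yield data (family -> (spec, r2, rmse))
CANDIDATE_RESULTS: dict[str, tuple[CurveSpec, float, float]] = {
    "double_logistic": (HIGH_YIELD_POOLED, 0.8577, 0.1161),
    "cubic": (
        CurveSpec("cubic", (-0.3796, 5.7851, -7.4437, 2.7004)),
        0.8357,
        0.1357,
    ),
    "rational_quad": (
        CurveSpec("rational_quad", (-0.4319, 5.3826, -0.3948, 6.1176)),
        0.8319,
        0.1373,
    ),
    "rational_power": (
        CurveSpec("rational_power", (-0.1741, 0.0010, 0.8720, 3.5469)),
        0.7671,
        0.1616,
    ),
    "logistic3": (
        CurveSpec("logistic3", (0.8635, 97.9447, 27.3641)),
        0.7549,
        0.1674,
    ),
}

#: seasonal NDVI maxima by cultivar and N rate (kg/ha), from the two
#: model-building experiments (2013: WXJ14/SY63; 2014: WYJ24/YLY1)
NDVI_MAX_BY_CULTIVAR_N: dict[str, dict[int, float]] = {
    "WXJ14": {0: 0.489, 75: 0.632, 150: 0.645, 225: 0.659, 300: 0.660, 375: 0.691},
    "SY63": {0: 0.689, 75: 0.759, 150: 0.870, 225: 0.880, 300: 0.886, 375: 0.888},
    "WYJ24": {0: 0.663, 75: 0.737, 150: 0.746, 225: 0.769, 300: 0.777, 375: 0.784},
    "YLY1": {0: 0.688, 75: 0.736, 150: 0.754, 225: 0.769, 300: 0.787, 375: 0.790},
}

#: grain yields (t/ha) by cultivar and N rate from the same experiments
YIELD_BY_CULTIVAR_N: dict[str, dict[int, float]] = {
    "WXJ14": {0: 6.08, 75: 7.75, 150: 8.78, 225: 9.08, 300: 10.53, 375: 10.61},
    "WYJ24": {0: 6.70, 75: 7.87, 150: 8.98, 225: 9.62, 300: 10.54, 375: 10.63},
    "SY63": {0: 6.16, 75: 8.17, 150: 9.04, 225: 9.86, 300: 10.61, 375: 11.02},
    "YLY1": {0: 7.01, 75: 8.20, 150: 9.25, 225: 10.13, 300: 10.83, 375: 11.26},
}

CULTIVAR_TYPE: dict[str, CultivarType] = {
    "WXJ14": CultivarType.JAPONICA,
    "WYJ24": CultivarType.JAPONICA,
    "SY63": CultivarType.INDICA,
    "YLY1": CultivarType.INDICA,
}

#: whole-season lengths in days (transplanting to harvest)
SEASON_LENGTH: dict[str, int] = {
    "WXJ14": 150,
    "WYJ24": 156,
    "SY63": 153,
    "YLY1": 133,
}
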