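"""End-to-end pipeline stages: simulate, normalize, fit, validate.

These functions are what the CLI subcommands wrap; they are equally
usable directly from Python. Each writes its outputs plus a manifest
(config hash, seed, version) into the configured output directory.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .config import RunConfig, write_manifest
from .curves import FAMILIES, CurveSpec
from .fitting import ModelFit, fit_candidates, fit_group_models
from .normalize import NormalizedSeries, build_group_dataset
from .synthetic import default_design, gen_experiment
from .thermal import accumulate
from .types import CultivarType, YieldLevel, assign_yield_level
from .validation import DEFAULT_STAGE_BINS, reports_to_frame, validate_stagewise

log = logging.getLogger("rndvi")


def _design_from_config(config: RunConfig):
    from dataclasses import replace

    design = default_design(seed=config.seed)
    block = dict(config.design)
    if "cultivars" in block:
        from .reference import (
            CULTIVAR_TYPE,
            NDVI_MAX_BY_CULTIVAR_N,
            SEASON_LENGTH,
            YIELD_BY_CULTIVAR_N,
        )
        from .synthetic import CultivarDesign

        block["cultivars"] = tuple(
            CultivarDesign(
                name=name,
                cultivar_type=CULTIVAR_TYPE[name],
                season_length=SEASON_LENGTH[name],
                ndvi_max=dict(NDVI_MAX_BY_CULTIVAR_N[name]),
                grain_yield=dict(YIELD_BY_CULTIVAR_N[name]),
            )
            for name in block["cultivars"]
        )
    if "n_rates" in block:
        block["n_rates"] = tuple(block["n_rates"])
    return replace(design, **block)


def run_simulate(config: RunConfig) -> Path:
    """Generate a synthetic experiment into the output directory."""
    outdir = Path(config.outdir)
    design = _design_from_config(config)
    gen_experiment(design, outdir)
    write_manifest(outdir, config, "simulate")
    log.info("simulated experiment written to %s", outdir)
    return outdir


def _load_dataset(config: RunConfig):
    config.require_paths()
    weather = rio.read_weather(config.weather)
    series_list = rio.read_sensor_log(config.sensor, config.metadata)
    thermal = {
        s.plot.plot_id: accumulate(
            weather,
            s.plot,
            tbase=config.tbase_c,
            include_transplant_day=config.include_transplant_day,
        )
        for s in series_list
    }
    return weather, series_list, thermal


def run_normalize(config: RunConfig) -> Path:
    """Write the pooled normalized (RAGDD, RNDVI) point clouds per group."""
    _, series_list, thermal = _load_dataset(config)
    datasets = build_group_dataset(
        series_list,
        thermal,
        grouping=config.grouping,
        per_cultivar_norm=config.per_cultivar_norm,
        ndvi_max_override=_parse_override(config),
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        {"group": _key_str(ds.group_key), "ragdd": x, "rndvi": y}
        for ds in datasets
        for x, y in zip(ds.ragdd, ds.rndvi)
    ]
    pd.DataFrame(rows).to_csv(
        outdir / "normalized.csv", index=False, float_format="%.6f"
    )
    write_manifest(outdir, config, "normalize")
    return outdir


def _key_str(key) -> str:
    if isinstance(key, tuple):
        return "|".join(getattr(k, "value", str(k)) for k in key)
    return str(key)


def _parse_override(config: RunConfig):
    if not config.ndvi_max_override:
        return None
    out = {}
    for key, val in config.ndvi_max_override.items():
        parts = str(key).split("|")
        if config.grouping == "by_yield_level_and_type" and len(parts) == 2:
            out[(CultivarType(parts[0]), YieldLevel(parts[1]))] = float(val)
        elif config.grouping == "by_treatment" and len(parts) == 2:
            out[(parts[0], float(parts[1]))] = float(val)
        else:
            out[key] = float(val)
    return out


def _fit_row(key, fit: ModelFit, ndvi_max) -> dict:
    row = {
        "group": _key_str(key),
        "family": fit.spec.family,
        "r2": fit.r2,
        "rmse": fit.rmse,
        "n": fit.n,
        "converged": fit.converged,
        "ndvi_max": ndvi_max,
    }
    row.update({f"param_{k}": v for k, v in fit.spec.named_params.items()})
    return row


def run_fit(config: RunConfig) -> Path:
    """Thermal time -> normalization -> candidate ranking + group models.

    Writes ranking.csv (all candidate families on the pooled high-yield
    point cloud, best first), group_models.csv (one double-logistic fit
    per cultivar type x yield level), and fits.json consumed by the
    validate stage.
    """
    _, series_list, thermal = _load_dataset(config)
    if not series_list:
        raise ValueError("dataset contains no observation series")
    datasets = build_group_dataset(
        series_list,
        thermal,
        grouping="by_yield_level_and_type",
        per_cultivar_norm=config.per_cultivar_norm,
        ndvi_max_override=_parse_override(config),
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # model selection on the pooled high-yield point cloud
    high = [ds for ds in datasets if ds.group_key[1] == YieldLevel.HIGH]
    ranking_rows = []
    if high:
        pooled = NormalizedSeries(
            group_key="high_yield_pooled",
            ragdd=np.concatenate([ds.ragdd for ds in high]),
            rndvi=np.concatenate([ds.rndvi for ds in high]),
            ndvi_max=1.0,
        )
        ranked = fit_candidates(pooled, config.families)
        ranking_rows = [
            _fit_row("high_yield_pooled", f, None) for f in ranked
        ]
        pd.DataFrame(ranking_rows).to_csv(
            outdir / "ranking.csv", index=False, float_format="%.6f"
        )
    else:
        warnings.warn("no high-yield plots: candidate ranking skipped")

    group_fits = fit_group_models(datasets, family="double_logistic")
    ndvi_max_by_group = {ds.group_key: ds.ndvi_max for ds in datasets}
    rows = [
        _fit_row(key, fit, ndvi_max_by_group.get(key))
        for key, fit in group_fits.items()
    ]
    pd.DataFrame(rows).to_csv(
        outdir / "group_models.csv", index=False, float_format="%.6f"
    )

    payload = {
        "groups": [
            {
                "cultivar_type": key[0].value,
                "yield_level": key[1].value,
                "family": fit.spec.family,
                "params": fit.spec.named_params,
                "param_se": list(fit.param_se),
                "r2": fit.r2,
                "rmse": fit.rmse,
                "n": fit.n,
                "converged": fit.converged,
                "ndvi_max": ndvi_max_by_group.get(key),
            }
            for key, fit in group_fits.items()
        ],
        "ranking": ranking_rows,
    }
    (outdir / "fits.json").write_text(json.dumps(payload, indent=2))
    write_manifest(outdir, config, "fit")
    return outdir


def load_model_specs(path) -> dict[tuple[CultivarType, YieldLevel], dict]:
    """Read a fits.json produced by run_fit into model specs per group."""
    payload = json.loads(Path(path).read_text())
    out = {}
    for grp in payload["groups"]:
        key = (CultivarType(grp["cultivar_type"]), YieldLevel(grp["yield_level"]))
        fam = FAMILIES[grp["family"]]
        spec = CurveSpec(
            grp["family"], tuple(grp["params"][n] for n in fam.param_names)
        )
        out[key] = {"spec": spec, "ndvi_max": grp.get("ndvi_max")}
    return out


def run_validate(config: RunConfig, models_path) -> Path:
    """Reconstruct NDVI from the fitted models and score it stage-wise.

    The dataset named in the config plays the role of the independent
    validation experiments: observations are grouped by cultivar type x
    yield level, simulated as NDVI_max * model(RAGDD), and scored per
    growth stage (k, R^2, RMSE) separately for each cultivar type, plus
    a pooled overall row per type.
    """
    models = load_model_specs(models_path)
    _, series_list, thermal = _load_dataset(config)
    stage_bins = (
        {k: tuple(v) for k, v in config.stage_bins.items()}
        if config.stage_bins
        else DEFAULT_STAGE_BINS
    )
    # NDVI_max per group from this dataset's own pooled observations
    datasets = build_group_dataset(
        series_list,
        thermal,
        grouping="by_yield_level_and_type",
        ndvi_max_override=_parse_override(config),
    )
    ndvi_max_by_group = {ds.group_key: ds.ndvi_max for ds in datasets}

    pairs_by_type: dict[CultivarType, list[tuple[float, float, float]]] = {}
    skipped = set()
    for s in series_list:
        key = (s.plot.cultivar_type, assign_yield_level(s.plot.grain_yield))
        model = models.get(key)
        if model is None:
            skipped.add(key)
            continue
        ndvi_max = ndvi_max_by_group.get(key, model["ndvi_max"])
        th = thermal[s.plot.plot_id]
        for obs in s.observations:
            ragdd = th.ragdd_at(obs.dat)
            from .curves import eval_curve

            sim = ndvi_max * eval_curve(model["spec"], ragdd)
            pairs_by_type.setdefault(key[0], []).append((ragdd, obs.ndvi, sim))
    for key in sorted(skipped, key=repr):
        warnings.warn(f"no fitted model for group {key!r}; its plots skipped")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    for ctype in sorted(pairs_by_type, key=lambda c: c.value):
        reports = validate_stagewise(pairs_by_type[ctype], stage_bins)
        frame = reports_to_frame(reports)
        frame.insert(0, "cultivar_type", ctype.value)
        frames.append(frame)
    if not frames:
        raise ValueError("no plots matched any fitted model; nothing to validate")
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(outdir / "validation.csv", index=False, float_format="%.6f")
    write_manifest(outdir, config, "validate", models=str(models_path))
    return outdir
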