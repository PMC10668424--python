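"""End-to-end experiment orchestration.

Runs the full comparison on a pair of cohorts (synthetic or loaded from
disk): impute missing CA125 (development and validation separately), tune
and fit every requested algorithm with and without CA125, average validation
predictions over imputation pairs, and evaluate discrimination (PDI with
meta-analyzed CI/PI, binary AUROC), calibration (center-averaged flexible
curves, rescaled ECI), clinical utility (meta-analyzed Net Benefit, decision
curves, referrals avoided) and inter-model prediction uncertainty
(probability ranges, decision reversal, pairwise scatter data).

All randomness descends from a single root seed through named sub-seeds
recorded in the output manifest, so a rerun with the same config produces
byte-identical metric outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import multiclass_eci, per_center_curves, pooled_calibration_curves
from .cohort import (GeneratorConfig, OUTCOME_LEVELS, generate_cohort,
                     outcome_codes, read_cohort, write_cohort)
from .comparison import pairwise_prediction_export, probability_range_table
from .discrimination import binary_cstat_any_malignancy, pdi
from .imputation import impute_ca125
from .meta import center_statistics, random_effects_pool
from .models import DEFAULT_GRIDS, SMALL_GRIDS, ModelSpec, fit_model, tune_hyperparameters
from .utility import (DEFAULT_THRESHOLDS, HEADLINE_THRESHOLD, decision_curve,
                      malignancy_risk, referrals_avoided, reversal_matrix)

logger = logging.getLogger(__name__)

VARIANTS = ("with_ca125", "without_ca125")

DEFAULT_CONFIG = {
    "seed": 1,
    "development": {"synthetic": {"n_patients": 1500, "n_centers": 5,
                                  "ca125_missing_rate": 0.30}},
    "validation": {"synthetic": {"n_patients": 800, "n_centers": 5,
                                 "ca125_missing_rate": 0.30}},
    "algorithms": ["mlr", "ridge_mlr", "rf", "xgboost", "nn", "svm"],
    "variants": ["with_ca125", "without_ca125"],
    "m_imputations": 2,
    "grids": "small",
    "calibration_span": 0.75,
    "bootstrap": 200,
    "thresholds": {"min": 0.05, "max": 0.40, "step": 0.01},
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(path_or_dict)
    merged = dict(DEFAULT_CONFIG)
    merged.update(cfg or {})
    unknown_variants = set(merged["variants"]) - set(VARIANTS)
    if unknown_variants:
        raise ValueError(f"unknown variants: {sorted(unknown_variants)}")
    return merged


def validate_cohort_schema(path) -> pd.DataFrame:
    """Read a cohort CSV, failing fast with located schema errors."""
    return read_cohort(path)


def _named_seeds(root_seed: int, names: tuple[str, ...]) -> dict[str, int]:
    children = np.random.SeedSequence(root_seed).spawn(len(names))
    return {name: int(ss.generate_state(1)[0] % 2**31)
            for name, ss in zip(names, children)}


def _resolve_cohort(section: dict, seed: int) -> pd.DataFrame:
    if "path" in section:
        return validate_cohort_schema(section["path"])
    if "synthetic" in section:
        params = dict(section["synthetic"])
        params.setdefault("seed", seed)
        if "class_prevalences" in params:
            params["class_prevalences"] = tuple(params["class_prevalences"])
        return generate_cohort(GeneratorConfig(**params))
    raise ValueError("cohort section needs a 'path' or a 'synthetic' block")


def _resolve_grids(cfg) -> dict:
    g = cfg["grids"]
    if g == "default":
        return DEFAULT_GRIDS
    if g == "small":
        return SMALL_GRIDS
    if isinstance(g, dict):
        merged = {k: list(v) for k, v in SMALL_GRIDS.items()}
        merged.update(g)
        return merged
    raise ValueError(f"grids must be 'default', 'small' or a mapping, got {g!r}")


def _threshold_grid(cfg) -> np.ndarray:
    t = cfg["thresholds"]
    if isinstance(t, dict):
        return np.round(np.arange(t["min"], t["max"] + t["step"] / 2, t["step"]), 6)
    return np.asarray(t, dtype=float)


def _averaged_validation_predictions(model_fits, val_tables) -> np.ndarray:
    """Average predictions over all development x validation imputation pairs."""
    preds = [fit.predict_probabilities(vt)
             for fit in model_fits for vt in val_tables]
    P = np.mean(preds, axis=0)
    return P / P.sum(axis=1, keepdims=True)


def fit_variant_models(algorithms, dev_tables, grids, seeds, variant: str):
    """Tune (on the first completed dataset) and fit each algorithm on every
    completed development dataset; returns {algorithm: [FittedModel, ...]}."""
    with_ca125 = variant == "with_ca125"
    fitted = {}
    for algo in algorithms:
        spec = ModelSpec(algorithm=algo, with_ca125=with_ca125,
                         grid=grids[algo],
                         seed=seeds[f"model_{algo}_{variant}"])
        tuned = tune_hyperparameters(spec, dev_tables[0])
        logger.info("%s/%s tuned: %s", algo, variant, tuned.hyperparameters)
        fitted[algo] = [fit_model(tuned, t) for t in dev_tables]
    return fitted


def evaluate_models(model_predictions: dict[str, np.ndarray], outcomes, centers,
                    span: float, boot_seed: int, n_boot: int,
                    thresholds: np.ndarray):
    """Performance table (Table-2 layout) plus curve/decision-curve exports."""
    codes = outcome_codes(outcomes)
    centers = np.asarray(centers)
    rows = []
    calib_export = []
    risk_by_model = {name: malignancy_risk(P)
                     for name, P in model_predictions.items()}
    dc = decision_curve(risk_by_model, codes, centers, thresholds)
    nb_all_10 = dc.query("strategy == 'treat_all' and abs(threshold - @HEADLINE_THRESHOLD) < 1e-9")["nb"].iloc[0]

    for name, P in model_predictions.items():
        def pdi_metric(Pc, yc):
            return pdi(Pc, yc, estimator="auto").overall_pdi

        try:
            ests = center_statistics(P, codes, centers, pdi_metric,
                                     n_boot=n_boot, seed=boot_seed)
            if len(ests) >= 2:
                pooled = random_effects_pool(ests, scale="logit")
                pdi_mu, pdi_ci, pdi_pi = pooled.mu, pooled.ci95, pooled.pi95
            else:
                raise ValueError("fewer than 2 eligible centers")
        except ValueError as exc:
            logger.warning("PDI meta-analysis unavailable for %s (%s); "
                           "reporting whole-data PDI", name, exc)
            pdi_mu = pdi(P, codes, estimator="auto").overall_pdi
            pdi_ci = (np.nan, np.nan)
            pdi_pi = None

        curves = pooled_calibration_curves(P, codes, centers, span=span)
        eci = multiclass_eci(P, codes, curves)
        for level, curve in curves.items():
            for center_curve in per_center_curves(P, codes, centers,
                                                  OUTCOME_LEVELS.index(level),
                                                  span=span):
                calib_export.extend(
                    {"model": name, "category": level,
                     "center": center_curve.center_id, "grid": g,
                     "observed": o, "weight": center_curve.weight}
                    for g, o in zip(center_curve.grid, center_curve.observed))
            calib_export.extend(
                {"model": name, "category": level, "center": "pooled",
                 "grid": g, "observed": o, "weight": curve.weight}
                for g, o in zip(curve.grid, curve.observed))

        nb_10 = dc.query("strategy == @name and abs(threshold - @HEADLINE_THRESHOLD) < 1e-9")["nb"].iloc[0]
        auroc = binary_cstat_any_malignancy(P, codes)
        row = {
            "model": name,
            "pdi": pdi_mu,
            "pdi_ci_low": pdi_ci[0], "pdi_ci_high": pdi_ci[1],
            "pdi_pi_low": pdi_pi[0] if pdi_pi else np.nan,
            "pdi_pi_high": pdi_pi[1] if pdi_pi else np.nan,
            "auroc_any_malignancy": auroc,
        }
        for k, level in enumerate(OUTCOME_LEVELS):
            row[f"eci_{level}"] = eci.per_category_eci[k]
        row["eci_mean"] = eci.mean_eci
        row["nb_10"] = nb_10
        row["referrals_avoided_10"] = referrals_avoided(
            nb_10, nb_all_10, HEADLINE_THRESHOLD)
        rows.append(row)
    return pd.DataFrame(rows), dc, pd.DataFrame(calib_export)


def run_experiment(config, out_dir) -> Path:
    """Run the full experiment; returns the artifact directory path."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    seed_names = (
        ["generator_dev", "generator_val", "imputation_dev", "imputation_val",
         "bootstrap"]
        + [f"model_{a}_{v}" for a in cfg["algorithms"] for v in VARIANTS]
    )
    seeds = _named_seeds(cfg["seed"], tuple(seed_names))
    grids = _resolve_grids(cfg)
    thresholds = _threshold_grid(cfg)

    dev = _resolve_cohort(cfg["development"], seeds["generator_dev"])
    val = _resolve_cohort(cfg["validation"], seeds["generator_val"])
    write_cohort(dev, out / "development.csv")
    write_cohort(val, out / "validation.csv")
    y_val = val["outcome"].to_numpy()
    centers_val = val["center_id"].to_numpy()

    m = cfg["m_imputations"]
    need_imputation = "with_ca125" in cfg["variants"] and dev["ca125"].isna().any()
    if "with_ca125" in cfg["variants"]:
        dev_imp = (impute_ca125(dev, m=m, seed=seeds["imputation_dev"]).completed_tables
                   if need_imputation else [dev])
        val_imp = (impute_ca125(val, m=m, seed=seeds["imputation_val"]).completed_tables
                   if val["ca125"].isna().any() else [val])

    all_tables = {}
    all_dc = {}
    all_calib = {}
    predictions = {}
    for variant in cfg["variants"]:
        if variant == "with_ca125":
            dev_tables, val_tables = dev_imp, val_imp
        else:
            # without-CA125 models ignore CA125 entirely: single non-imputed path
            dev_tables, val_tables = [dev], [val]
        fitted = fit_variant_models(cfg["algorithms"], dev_tables, grids,
                                    seeds, variant)
        preds = {algo: _averaged_validation_predictions(fits, val_tables)
                 for algo, fits in fitted.items()}
        predictions[variant] = preds

        table2, dc, calib = evaluate_models(
            preds, y_val, centers_val, cfg["calibration_span"],
            seeds["bootstrap"], cfg["bootstrap"], thresholds)
        table2.insert(1, "variant", variant)
        all_tables[variant] = table2
        all_dc[variant] = dc.assign(variant=variant)
        all_calib[variant] = calib.assign(variant=variant)

        # prediction-uncertainty outputs per variant
        probability_range_table(list(preds.values())).to_csv(
            out / f"table3_probability_ranges_{variant}.csv", index=False)
        reversal_matrix(preds).to_csv(
            out / f"tableS5_decision_reversal_{variant}.csv")
        for level in OUTCOME_LEVELS:
            pairwise_prediction_export(
                preds, level, patient_ids=val["patient_id"].to_numpy()
            ).to_csv(out / f"scatter_{level}_{variant}.csv", index=False)

    pd.concat(all_tables.values(), ignore_index=True).to_csv(
        out / "table2_performance.csv", index=False)
    pd.concat(all_dc.values(), ignore_index=True).to_csv(
        out / "decision_curves.csv", index=False)
    pd.concat(all_calib.values(), ignore_index=True).to_csv(
        out / "calibration_curves.csv", index=False)

    manifest = {
        "ovarisk_version": __version__,
        "config": {k: v for k, v in cfg.items()},
        "seeds": seeds,
        "n_development": int(len(dev)),
        "n_validation": int(len(val)),
        "outcome_levels": list(OUTCOME_LEVELS),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
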