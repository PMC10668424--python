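"""Six-algorithm model zoo emitting five-class probability estimates.

Each algorithm is fitted with and/or without CA125 on a complete
(post-imputation) development cohort and exposes ``predict_probabilities``
returning an n x 5 row-stochastic matrix in the canonical outcome order.

Feature handling by family:

* ``mlr`` / ``ridge_mlr`` — restricted cubic splines (3 knots) on age,
  log CA125, proportion of solid tissue and lesion diameter; papillation
  count as an ordinal score. CA125 is log-transformed before spline
  expansion because of its heavy right skew. Ridge standardizes the design
  and penalizes all non-intercept coefficients.
* ``rf`` / ``xgboost`` — raw predictors, papillation count one-hot encoded.
* ``nn`` / ``svm`` — raw predictors with ordinal papillation score,
  standardized inputs. SVM probabilities come from libsvm's per-pair Platt
  scaling combined by pairwise coupling.

Hyperparameters are tuned by seeded stratified 10-fold cross-validation,
maximizing the mean out-of-fold multinomial log-likelihood (a proper scoring
rule, consistent with the calibration focus of the evaluation); the full
tuning record is retained on the spec. Standard MLR is fitted by full
maximum likelihood (statsmodels), so coefficient standard errors are
available for parameter-recovery checks.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .cohort import (OUTCOME_LEVELS, PAPILLATION_LEVELS, PAPILLATION_SCORE,
                     outcome_codes)
from .splines import SplineBasis, build_spline_basis

logger = logging.getLogger(__name__)

ALGORITHMS = ("mlr", "ridge_mlr", "rf", "xgboost", "nn", "svm")
SPLINE_VARIABLES = ("age", "log_ca125", "prop_solid", "max_diameter")
N_FOLDS = 10
PROB_FLOOR = 1e-12
XGB_MAX_ROUNDS = 500
XGB_PATIENCE = 50

DEFAULT_GRIDS: dict[str, list[dict[str, Any]]] = {
    "mlr": [{}],
    "ridge_mlr": [{"ridge_lambda": float(l)} for l in np.logspace(-4, 4, 25)],
    "rf": [
        {"n_estimators": 500, "max_features": m, "min_samples_leaf": s}
        for m in (2, 3, 4, 6) for s in (1, 5, 10)
    ],
    "xgboost": [
        {"max_depth": d, "learning_rate": e, "subsample": s}
        for d in (2, 3, 4, 6) for e in (0.01, 0.05, 0.1) for s in (0.7, 1.0)
    ],
    "nn": [
        {"hidden_units": h, "weight_decay": a}
        for h in (2, 3, 5, 8) for a in (0.001, 0.01, 0.1)
    ],
    "svm": [
        {"svm_c": 2.0 ** c, "svm_gamma": 2.0 ** g}
        for c in range(-2, 7) for g in range(-6, 1)
    ],
}

#: reduced grids for desk-scale experiments; override via config
SMALL_GRIDS: dict[str, list[dict[str, Any]]] = {
    "mlr": [{}],
    "ridge_mlr": [{"ridge_lambda": l} for l in (1e-3, 1e-1, 1e1)],
    "rf": [
        {"n_estimators": 200, "max_features": m, "min_samples_leaf": 5}
        for m in (2, 4)
    ],
    "xgboost": [
        {"max_depth": d, "learning_rate": 0.1, "subsample": 0.7}
        for d in (2, 4)
    ],
    "nn": [{"hidden_units": h, "weight_decay": 0.01} for h in (3, 5)],
    "svm": [{"svm_c": 1.0, "svm_gamma": 0.1},
            {"svm_c": 4.0, "svm_gamma": 2.0 ** -5}],
}


@dataclass
class ModelSpec:
    """Algorithm choice, predictor variant, hyperparameters and tuning record."""

    algorithm: str
    with_ca125: bool = True
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    grid: list[dict[str, Any]] | None = None
    seed: int = 0
    use_splines: bool = True  # MLR variants only
    tuning_record: list[dict[str, Any]] | None = None

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


# ---------------------------------------------------------------------------
# feature mapping
# ---------------------------------------------------------------------------

class FeatureMapper:
    """Cohort -> design matrix, fitted on development data.

    Spline knots (MLR family) and the input scaler (ridge/NN/SVM) are
    learned from the development cohort and reused at prediction time.
    """

    def __init__(self, algorithm: str, with_ca125: bool, use_splines: bool = True):
        self.algorithm = algorithm
        self.with_ca125 = with_ca125
        self.family = ("mlr" if algorithm in ("mlr", "ridge_mlr")
                       else "tree" if algorithm in ("rf", "xgboost")
                       else "scaled")
        self.use_splines = use_splines and self.family == "mlr"
        self.spline_bases: dict[str, SplineBasis] = {}
        self.scaler: StandardScaler | None = None

    def _continuous(self, cohort: pd.DataFrame) -> dict[str, np.ndarray]:
        cols = {
            "age": cohort["age"].to_numpy(float),
            "prop_solid": cohort["prop_solid"].to_numpy(float),
            "max_diameter": cohort["max_diameter"].to_numpy(float),
        }
        if self.with_ca125:
            ca = cohort["ca125"].to_numpy(float)
            if np.isnan(ca).any():
                raise ValueError(
                    "CA125 is missing for some patients; impute first "
                    "(ovarisk.imputation.impute_ca125) or use a without-CA125 model"
                )
            if self.family == "mlr":
                cols["log_ca125"] = np.log(ca)
            else:
                cols["ca125"] = ca
        return cols

    def _raw_design(self, cohort: pd.DataFrame) -> np.ndarray:
        cont = self._continuous(cohort)
        pap = cohort["papillations"].map(PAPILLATION_SCORE).to_numpy(float)
        binaries = [cohort[c].to_numpy(float)
                    for c in ("center_oncology", "shadows", "ascites", "gt10_locules")]
        if self.family == "mlr":
            blocks = [binaries[0][:, None]]
            for name in SPLINE_VARIABLES:
                if name not in cont:
                    continue
                x = cont[name]
                if self.use_splines and name in self.spline_bases:
                    blocks.append(self.spline_bases[name].transform(x))
                else:
                    blocks.append(x[:, None])
            blocks += [b[:, None] for b in binaries[1:]]
            blocks.append(pap[:, None])
            return np.column_stack(blocks)
        if self.family == "tree":
            pap_onehot = np.column_stack(
                [(cohort["papillations"] == lvl).to_numpy(float)
                 for lvl in PAPILLATION_LEVELS]
            )
            return np.column_stack(
                [binaries[0]] + [cont[c] for c in cont]
                + binaries[1:] + [pap_onehot]
            )
        # scaled family: ordinal papillation score
        return np.column_stack(
            [binaries[0]] + [cont[c] for c in cont] + binaries[1:] + [pap]
        )

    def fit(self, development: pd.DataFrame) -> "FeatureMapper":
        if self.use_splines:
            cont = self._continuous(development)
            for name in SPLINE_VARIABLES:
                if name not in cont:
                    continue
                try:
                    self.spline_bases[name] = build_spline_basis(cont[name], name)
                except ValueError as exc:
                    logger.warning("spline basis for %s unavailable (%s); "
                                   "entering linearly", name, exc)
        if self.algorithm in ("ridge_mlr", "nn", "svm"):
            self.scaler = StandardScaler().fit(self._raw_design(development))
        return self

    def transform(self, cohort: pd.DataFrame) -> np.ndarray:
        X = self._raw_design(cohort)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return X


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class _MnlogitEstimator:
    """Standard multinomial logit by full ML (benign reference)."""

    def __init__(self):
        self.result = None

    def fit(self, X, y):
        Xc = sm.add_constant(X, has_constant="add")
        model = sm.MNLogit(y, Xc)

        def _ok(res):
            # Newton can diverge to NaN while still flagging convergence
            return (res.mle_retvals.get("converged", False)
                    and np.isfinite(np.asarray(res.params)).all()
                    and np.isfinite(res.llf))

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(method="newton", maxiter=200, disp=0)
            if not _ok(result):
                result = model.fit(method="lbfgs", maxiter=2000, disp=0)
            if not _ok(result):
                result = model.fit(method="bfgs", maxiter=2000, disp=0)
        if not _ok(result):
            raise RuntimeError(
                "multinomial logit did not converge "
                f"(llf={result.llf!r}); check for separation or rescale predictors"
            )
        self.result = result
        return self

    def predict_proba(self, X):
        Xc = sm.add_constant(X, has_constant="add")
        return np.asarray(self.result.predict(Xc))

    @property
    def coefficients(self) -> np.ndarray:
        """(p+1) x 4 coefficient matrix, intercept row first."""
        return np.asarray(self.result.params)

    @property
    def standard_errors(self) -> np.ndarray:
        return np.asarray(self.result.bse)


def _build_estimator(algorithm: str, hp: dict[str, Any], seed: int,
                     n_rounds: int | None = None, early_stopping: bool = False):
    if algorithm == "mlr":
        return _MnlogitEstimator()
    if algorithm == "ridge_mlr":
        lam = hp.get("ridge_lambda", 1.0)
        return LogisticRegression(penalty="l2", C=1.0 / lam, solver="lbfgs",
                                  max_iter=5000)
    if algorithm == "rf":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 500),
            max_features=hp.get("max_features", 3),
            min_samples_leaf=hp.get("min_samples_leaf", 1),
            random_state=seed, n_jobs=1,
        )
    if algorithm == "xgboost":
        kwargs = dict(
            objective="multi:softprob", num_class=len(OUTCOME_LEVELS),
            max_depth=hp.get("max_depth", 3),
            learning_rate=hp.get("learning_rate", 0.1),
            subsample=hp.get("subsample", 1.0),
            n_estimators=n_rounds or hp.get("n_estimators", XGB_MAX_ROUNDS),
            tree_method="hist", n_jobs=1, random_state=seed, verbosity=0,
        )
        if early_stopping:
            kwargs["early_stopping_rounds"] = XGB_PATIENCE
            kwargs["eval_metric"] = "mlogloss"
        return XGBClassifier(**kwargs)
    if algorithm == "nn":
        return MLPClassifier(
            hidden_layer_sizes=(hp.get("hidden_units", 5),),
            alpha=hp.get("weight_decay", 0.01),
            max_iter=500, random_state=seed,
        )
    if algorithm == "svm":
        return SVC(C=hp.get("svm_c", 1.0), gamma=hp.get("svm_gamma", 0.1),
                   kernel="rbf", probability=True, random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _fit_estimator(est, X, y, X_val=None, y_val=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", FutureWarning)  # SVC(probability=True)
        if isinstance(est, XGBClassifier) and est.get_params().get(
                "early_stopping_rounds"):
            est.fit(X, y, eval_set=[(X_val, y_val)], verbose=False)
        else:
            est.fit(X, y)
    return est


def _align_proba(est, X, n_classes: int = len(OUTCOME_LEVELS)) -> np.ndarray:
    """predict_proba with columns forced into canonical class order."""
    raw = est.predict_proba(X)
    if isinstance(est, _MnlogitEstimator):
        return raw
    classes = np.asarray(est.classes_, dtype=int)
    out = np.zeros((raw.shape[0], n_classes))
    out[:, classes] = raw
    return out


def _multinomial_loglik(P: np.ndarray, y: np.ndarray) -> float:
    p_true = np.clip(P[np.arange(y.size), y], PROB_FLOOR, 1.0)
    return float(np.log(p_true).mean())


# ---------------------------------------------------------------------------
# tuning and fitting
# ---------------------------------------------------------------------------

def tune_hyperparameters(spec: ModelSpec, development: pd.DataFrame) -> ModelSpec:
    """Select hyperparameters by stratified 10-fold cross-validation.

    The criterion is the mean out-of-fold multinomial log-likelihood.
    Classes with fewer members than folds trigger a reduced-fold fallback
    (logged). XGBoost additionally early-stops on each fold's held-out data;
    the selected candidate's round count is the mean best iteration.
    Returns a new spec carrying the winning hyperparameters and the full
    tuning record.
    """
    y = outcome_codes(development["outcome"].to_numpy())
    counts = np.bincount(y, minlength=len(OUTCOME_LEVELS))
    if counts.min() == 0:
        missing = OUTCOME_LEVELS[int(np.argmin(counts))]
        raise ValueError(f"development data lacks outcome class {missing!r}")
    n_folds = N_FOLDS
    if counts.min() < N_FOLDS:
        n_folds = max(2, int(counts.min()))
        logger.warning("smallest class has %d members; using %d-fold CV",
                       counts.min(), n_folds)
    grid = spec.grid if spec.grid is not None else DEFAULT_GRIDS[spec.algorithm]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=spec.seed)
    folds = list(skf.split(np.zeros(y.size), y))

    record = []
    for hp in grid:
        logliks, best_rounds = [], []
        for fold_i, (tr, te) in enumerate(folds):
            dev_tr = development.iloc[tr]
            dev_te = development.iloc[te]
            mapper = FeatureMapper(spec.algorithm, spec.with_ca125,
                                   spec.use_splines).fit(dev_tr)
            Xtr, Xte = mapper.transform(dev_tr), mapper.transform(dev_te)
            est = _build_estimator(spec.algorithm, hp, spec.seed,
                                   early_stopping=spec.algorithm == "xgboost")
            try:
                _fit_estimator(est, Xtr, y[tr], Xte, y[te])
            except (RuntimeError, np.linalg.LinAlgError) as exc:
                logger.warning("%s fold %d failed for %s: %s",
                               spec.algorithm, fold_i, hp, exc)
                logliks.append(-np.inf)
                continue
            if spec.algorithm == "xgboost":
                best_rounds.append(int(est.best_iteration) + 1)
            logliks.append(_multinomial_loglik(_align_proba(est, Xte), y[te]))
        entry = {"params": dict(hp), "cv_loglik": float(np.mean(logliks)),
                 "fold_logliks": [float(v) for v in logliks]}
        if best_rounds:
            entry["mean_best_rounds"] = int(round(np.mean(best_rounds)))
        record.append(entry)

    best = max(record, key=lambda e: e["cv_loglik"])
    chosen = dict(best["params"])
    if spec.algorithm == "xgboost":
        chosen["n_estimators"] = max(best.get("mean_best_rounds", 100), 10)
    return replace(spec, hyperparameters=chosen, tuning_record=record)


@dataclass
class FittedModel:
    """Fitted model handle: feature mapper + estimator + provenance."""

    spec: ModelSpec
    mapper: FeatureMapper
    estimator: Any
    n_train: int

    def predict_probabilities(self, cohort: pd.DataFrame) -> np.ndarray:
        """n x 5 row-stochastic class-probability matrix for a cohort."""
        X = self.mapper.transform(cohort)
        P = _align_proba(self.estimator, X)
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)

    @property
    def coefficients(self):
        if not isinstance(self.estimator, _MnlogitEstimator):
            raise AttributeError("coefficients available for standard MLR only")
        return self.estimator.coefficients

    @property
    def coefficient_standard_errors(self):
        if not isinstance(self.estimator, _MnlogitEstimator):
            raise AttributeError("standard errors available for standard MLR only")
        return self.estimator.standard_errors


def fit_model(spec: ModelSpec, development: pd.DataFrame) -> FittedModel:
    """Train on the full development data with the spec's hyperparameters."""
    y = outcome_codes(development["outcome"].to_numpy())
    if np.bincount(y, minlength=len(OUTCOME_LEVELS)).min() == 0:
        raise ValueError("development data must contain all five outcome classes")
    mapper = FeatureMapper(spec.algorithm, spec.with_ca125,
                           spec.use_splines).fit(development)
    X = mapper.transform(development)
    n_rounds = (spec.hyperparameters.get("n_estimators")
                if spec.algorithm == "xgboost" else None)
    est = _build_estimator(spec.algorithm, spec.hyperparameters, spec.seed,
                           n_rounds=n_rounds)
    _fit_estimator(est, X, y)
    return FittedModel(spec, mapper, est, len(development))


def save_model(model: FittedModel, path, sidecar_path=None) -> None:
    """Serialize a fitted model (pickle) with a JSON sidecar of its spec."""
    import json
    import pickle
    from pathlib import Path

    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump({"format_version": 1, "model": model}, fh)
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "format_version": 1,
        "algorithm": model.spec.algorithm,
        "with_ca125": model.spec.with_ca125,
        "hyperparameters": model.spec.hyperparameters,
        "seed": model.spec.seed,
        "n_train": model.n_train,
        "tuning_record": model.spec.tuning_record,
    }, indent=2, default=float))


def load_model(path) -> FittedModel:
    import pickle

    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != 1:
        raise ValueError("unsupported model artifact version")
    return payload["model"]
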