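"""Synthetic multicenter cohorts of patients with an adnexal mass.

Generates patient-level tables with the structure the downstream analysis
assumes: nine clinical/ultrasound predictors, a center identifier with an
oncology-center flag, and a five-level histological outcome (benign,
borderline, stage I invasive, stage II-IV invasive, secondary metastatic).
Two generating mechanisms are provided:

* :func:`generate_cohort` — class-conditional predictor distributions around
  configurable marginals, with between-center outcome-prevalence
  heterogeneity (Dirichlet) and higher malignancy rates in oncology centers.
* :func:`generate_from_latent_mlr` — predictors first, outcome drawn from a
  known multinomial-logistic mechanism, so that every patient's true
  class-probability vector is available in closed form (for
  parameter-recovery and oracle tests).

CA125 missingness is injected separately (:func:`inject_ca125_missingness`)
with the probability of being *measured* increasing in a malignancy-suspicion
score, mimicking clinical practice where suspicious tumors get the marker
measured more often.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

OUTCOME_LEVELS = ("benign", "borderline", "stage_I", "stage_II_IV", "sec_met")
PAPILLATION_LEVELS = ("0", "1", "2", "3", ">3")
PAPILLATION_SCORE = {lvl: i for i, lvl in enumerate(PAPILLATION_LEVELS)}

#: column order of the on-disk cohort CSV dialect
COHORT_COLUMNS = (
    "patient_id",
    "center_id",
    "center_oncology",
    "age",
    "ca125",
    "prop_solid",
    "max_diameter",
    "shadows",
    "ascites",
    "gt10_locules",
    "papillations",
    "outcome",
)

PREDICTOR_COLUMNS = COHORT_COLUMNS[2:11]
BINARY_COLUMNS = ("center_oncology", "shadows", "ascites", "gt10_locules")


@dataclass(frozen=True)
class ClassParams:
    """Class-conditional predictor distribution parameters.

    Continuous predictors are Normal (age) or log-normal (CA125, diameter);
    the solid-tissue proportion is zero-inflated Beta (many purely cystic
    tumors have no solid component at all); binaries are Bernoulli and the
    papillation count is categorical over its five levels.
    """

    age_mean: float
    age_sd: float
    ca125_median: float
    ca125_log_sd: float
    diam_median: float
    diam_log_sd: float
    psolid_zero_prob: float
    psolid_beta_a: float
    psolid_beta_b: float
    shadows_p: float
    ascites_p: float
    locules_p: float
    papillation_probs: tuple[float, ...]


# Defaults calibrated once to the validation-cohort descriptive statistics
# (median age 49, median CA125 25 U/mL, median diameter 71 mm, prop_solid
# lower quartile 0, ascites 10%, shadows 14%, >10 locules 12%).
DEFAULT_CLASS_PARAMS: dict[str, ClassParams] = {
    "benign": ClassParams(44.0, 14.0, 14.0, 1.1, 62.0, 0.55, 0.52, 0.9, 2.8,
                          0.19, 0.025, 0.10, (0.88, 0.05, 0.02, 0.015, 0.035)),
    "borderline": ClassParams(48.0, 14.0, 35.0, 1.0, 80.0, 0.50, 0.15, 1.2, 2.2,
                              0.06, 0.07, 0.22, (0.55, 0.15, 0.07, 0.06, 0.17)),
    "stage_I": ClassParams(54.0, 14.0, 80.0, 1.2, 95.0, 0.50, 0.05, 1.6, 1.4,
                           0.04, 0.12, 0.16, (0.70, 0.09, 0.05, 0.04, 0.12)),
    "stage_II_IV": ClassParams(58.0, 14.0, 300.0, 1.2, 90.0, 0.50, 0.02, 2.5, 1.2,
                               0.03, 0.38, 0.12, (0.78, 0.07, 0.04, 0.03, 0.08)),
    "sec_met": ClassParams(55.0, 14.0, 120.0, 1.3, 85.0, 0.55, 0.05, 2.2, 1.3,
                           0.04, 0.30, 0.14, (0.85, 0.05, 0.03, 0.02, 0.05)),
}

#: validation-cohort outcome mix: 62% benign, 8% borderline, 7% stage I,
#: 18% stage II-IV, 5% secondary metastatic
DEFAULT_PREVALENCES = (0.62, 0.08, 0.07, 0.18, 0.05)


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic multicenter cohort generator."""

    n_patients: int = 3199
    n_centers: int = 25
    class_prevalences: tuple[float, ...] = DEFAULT_PREVALENCES
    dirichlet_concentration: float = 80.0
    oncology_center_fraction: float = 0.6
    oncology_malignancy_tilt: float = 1.3
    class_params: dict[str, ClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS)
    )
    latent_mlr_coefficients: np.ndarray | None = None
    ca125_missing_rate: float = 0.0
    suspicion_slope: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        prev = np.asarray(self.class_prevalences, dtype=float)
        if prev.shape != (5,):
            raise ValueError("class_prevalences must have exactly 5 entries")
        if abs(prev.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"class_prevalences must sum to 1 (got {prev.sum()!r})"
            )
        if (prev < 0).any():
            raise ValueError("class_prevalences must be non-negative")
        if self.n_centers < 2:
            raise ValueError("n_centers must be at least 2")
        if self.n_patients < self.n_centers:
            raise ValueError("n_patients must be >= n_centers")
        if not 0.0 <= self.ca125_missing_rate < 1.0:
            raise ValueError("ca125_missing_rate must be in [0, 1)")


def _center_layout(config: GeneratorConfig, rng: np.random.Generator):
    """Center sizes, oncology flags and center-level prevalence vectors."""
    k = config.n_centers
    # uneven but non-degenerate center sizes
    raw = rng.lognormal(mean=0.0, sigma=0.6, size=k)
    sizes = np.maximum(1, np.round(raw / raw.sum() * config.n_patients)).astype(int)
    # fix rounding so sizes sum exactly to n_patients
    diff = config.n_patients - sizes.sum()
    order = np.argsort(-sizes)
    i = 0
    while diff != 0:
        j = order[i % k]
        step = 1 if diff > 0 else -1
        if sizes[j] + step >= 1:
            sizes[j] += step
            diff -= step
        i += 1

    n_onc = int(round(config.oncology_center_fraction * k))
    oncology = np.zeros(k, dtype=bool)
    oncology[rng.permutation(k)[:n_onc]] = True

    prev = np.asarray(config.class_prevalences, dtype=float)
    f_onc = sizes[oncology].sum() / sizes.sum() if n_onc else 0.0
    base = np.tile(prev, (k, 1))
    if 0.0 < f_onc < 1.0 and config.oncology_malignancy_tilt != 1.0:
        t = config.oncology_malignancy_tilt
        mal = prev[1:].sum()
        t_non = max((mal - f_onc * t * mal) / ((1.0 - f_onc) * mal), 0.0) if mal else 1.0
        for c in range(k):
            scale = t if oncology[c] else t_non
            v = prev.copy()
            v[1:] *= scale
            v[0] = 1.0 - v[1:].sum()
            if v[0] < 0:  # extreme tilt: renormalize instead
                v = np.clip(v, 0, None)
                v /= v.sum()
            base[c] = v
    conc = config.dirichlet_concentration
    center_prev = np.vstack(
        [rng.dirichlet(np.maximum(conc * base[c], 1e-3)) for c in range(k)]
    )
    return sizes, oncology, center_prev


def _draw_predictors(classes: np.ndarray, params: dict[str, ClassParams],
                     rng: np.random.Generator) -> pd.DataFrame:
    """Draw class-conditional predictors for an integer class-code vector."""
    n = classes.size
    out = {
        "age": np.empty(n), "ca125": np.empty(n), "prop_solid": np.empty(n),
        "max_diameter": np.empty(n),
        "shadows": np.empty(n, dtype=int), "ascites": np.empty(n, dtype=int),
        "gt10_locules": np.empty(n, dtype=int),
        "papillations": np.empty(n, dtype=object),
    }
    pap_levels = np.array(PAPILLATION_LEVELS, dtype=object)
    for code, level in enumerate(OUTCOME_LEVELS):
        idx = np.flatnonzero(classes == code)
        if idx.size == 0:
            continue
        p = params[level]
        m = idx.size
        out["age"][idx] = np.clip(rng.normal(p.age_mean, p.age_sd, m), 16.0, 95.0)
        out["ca125"][idx] = np.exp(rng.normal(np.log(p.ca125_median), p.ca125_log_sd, m))
        out["max_diameter"][idx] = np.exp(
            rng.normal(np.log(p.diam_median), p.diam_log_sd, m)
        )
        solid = rng.beta(p.psolid_beta_a, p.psolid_beta_b, m)
        solid[rng.random(m) < p.psolid_zero_prob] = 0.0
        out["prop_solid"][idx] = solid
        out["shadows"][idx] = rng.random(m) < p.shadows_p
        out["ascites"][idx] = rng.random(m) < p.ascites_p
        out["gt10_locules"][idx] = rng.random(m) < p.locules_p
        out["papillations"][idx] = pap_levels[
            rng.choice(5, size=m, p=np.asarray(p.papillation_probs))
        ]
    return pd.DataFrame(out)


def _assemble(center_ids, oncology_flags, predictors, outcomes) -> pd.DataFrame:
    n = len(predictors)
    df = pd.DataFrame({
        "patient_id": np.arange(1, n + 1),
        "center_id": center_ids,
        "center_oncology": oncology_flags.astype(int),
    })
    df = pd.concat([df, predictors.reset_index(drop=True)], axis=1)
    df["outcome"] = outcomes
    df["ca125_missing"] = False
    return df[list(COHORT_COLUMNS) + ["ca125_missing"]]


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a multicenter cohort from class-conditional marginals.

    Outcomes are drawn per center from Dirichlet-perturbed prevalence
    vectors; predictors are then drawn conditional on the outcome class.
    Fully reproducible for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sizes, oncology, center_prev = _center_layout(config, rng)

    center_ids, onc_flags, class_codes = [], [], []
    for c in range(config.n_centers):
        m = sizes[c]
        center_ids.append(np.full(m, c + 1))
        onc_flags.append(np.full(m, oncology[c]))
        class_codes.append(rng.choice(5, size=m, p=center_prev[c]))
    center_ids = np.concatenate(center_ids)
    onc_flags = np.concatenate(onc_flags)
    class_codes = np.concatenate(class_codes)

    predictors = _draw_predictors(class_codes, config.class_params, rng)
    outcomes = np.array(OUTCOME_LEVELS, dtype=object)[class_codes]
    table = _assemble(center_ids, onc_flags, predictors, outcomes)

    present = set(table["outcome"].unique())
    absent = [lvl for lvl in OUTCOME_LEVELS if lvl not in present]
    if absent:
        warnings.warn(
            f"generated cohort lacks outcome classes: {absent}; "
            "multiclass discrimination metrics will not be computable",
            UserWarning,
            stacklevel=2,
        )
    if config.ca125_missing_rate > 0:
        table = inject_ca125_missingness(
            table, config.ca125_missing_rate, config.suspicion_slope,
            seed=int(rng.integers(2**31)),
        )
    return table


# ---------------------------------------------------------------------------
# known-truth latent multinomial-logistic mechanism
# ---------------------------------------------------------------------------

#: design-column order of the latent linear predictor (intercept first)
LATENT_FEATURES = (
    "center_oncology", "age", "log_ca125", "prop_solid", "max_diameter",
    "shadows", "ascites", "gt10_locules", "papillation_score",
)


def default_latent_coefficients() -> np.ndarray:
    """A plausible (intercept + 9 features) x 4 coefficient matrix.

    Columns are the four malignant classes (benign is the reference).
    Intercepts were calibrated once by simulation so the implied outcome mix
    is roughly the default prevalence vector; slopes encode the clinical
    direction of each predictor (solid tissue, ascites, CA125 and papillation
    count push toward malignancy; acoustic shadows toward benign).
    """
    #               borderline  stage_I  stage_II_IV  sec_met
    return np.array([
        [-4.24,      -6.28,     -8.15,      -6.70],   # intercept
        [0.30,        0.30,      0.60,       0.50],   # center_oncology
        [0.00,        0.02,      0.03,       0.02],   # age (years)
        [0.30,        0.50,      0.90,       0.60],   # log CA125
        [1.50,        2.50,      3.00,       2.50],   # prop_solid
        [0.004,       0.004,     0.002,      0.000],  # max_diameter (mm)
        [-1.00,      -1.00,     -1.50,      -1.00],   # shadows
        [0.30,        0.80,      2.00,       1.50],   # ascites
        [0.80,        0.30,      0.00,       0.20],   # >10 locules
        [0.60,        0.40,      0.20,       0.00],   # papillation score 0..4
    ])


def latent_design(table: pd.DataFrame) -> np.ndarray:
    """n x 10 design matrix (leading intercept) of the latent mechanism."""
    pap = table["papillations"].map(PAPILLATION_SCORE).to_numpy(float)
    return np.column_stack([
        np.ones(len(table)),
        table["center_oncology"].to_numpy(float),
        table["age"].to_numpy(float),
        np.log(table["ca125"].to_numpy(float)),
        table["prop_solid"].to_numpy(float),
        table["max_diameter"].to_numpy(float),
        table["shadows"].to_numpy(float),
        table["ascites"].to_numpy(float),
        table["gt10_locules"].to_numpy(float),
        pap,
    ])


def softmax_probabilities(design: np.ndarray, coefficients: np.ndarray) -> np.ndarray:
    """Row-stochastic n x 5 matrix implied by a benign-reference MLR."""
    eta = np.column_stack([np.zeros(len(design)), design @ coefficients])
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    return p / p.sum(axis=1, keepdims=True)


def generate_from_latent_mlr(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate a cohort whose outcome follows a known MLR mechanism.

    Predictors are drawn from the configured class-conditional marginals
    mixed over the global prevalences (the mixing label is discarded), then
    the outcome is drawn from the softmax of the latent linear predictors.
    Returns the cohort together with the true n x 5 probability matrix.
    """
    config.validate()
    if config.latent_mlr_coefficients is None:
        raise ValueError("latent_mlr_coefficients must be provided")
    coef = np.asarray(config.latent_mlr_coefficients, dtype=float)
    if coef.shape != (len(LATENT_FEATURES) + 1, 4):
        raise ValueError(
            f"coefficient matrix must be {(len(LATENT_FEATURES) + 1, 4)} "
            f"(intercept + features x 4 non-reference classes), got {coef.shape}"
        )
    rng = np.random.default_rng(config.seed)
    sizes, oncology, _ = _center_layout(config, rng)

    center_ids = np.concatenate(
        [np.full(m, c + 1) for c, m in enumerate(sizes)]
    )
    onc_flags = np.concatenate(
        [np.full(m, oncology[c]) for c, m in enumerate(sizes)]
    )
    mix = rng.choice(5, size=config.n_patients,
                     p=np.asarray(config.class_prevalences, dtype=float))
    predictors = _draw_predictors(mix, config.class_params, rng)
    # oncology flag comes from the center, not the mixing class
    table = _assemble(center_ids, onc_flags, predictors,
                      np.full(config.n_patients, "benign", dtype=object))
    true_p = softmax_probabilities(latent_design(table), coef)
    u = rng.random(config.n_patients)
    codes = (true_p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    table["outcome"] = np.array(OUTCOME_LEVELS, dtype=object)[codes]
    return table, true_p


# ---------------------------------------------------------------------------
# CA125 missingness
# ---------------------------------------------------------------------------

def suspicion_score(table: pd.DataFrame) -> np.ndarray:
    """Crude malignancy-suspicion score: monotone in solid tissue, ascites
    and papillation count (the features that prompt CA125 measurement)."""
    pap = table["papillations"].map(PAPILLATION_SCORE).to_numpy(float)
    return (
        table["prop_solid"].to_numpy(float)
        + table["ascites"].to_numpy(float)
        + pap / 4.0
    )


def inject_ca125_missingness(
    cohort: pd.DataFrame, rate: float, suspicion_slope: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Blank CA125 values with measurement probability rising in suspicion.

    The probability of being *measured* is logistic in the centered
    suspicion score; the intercept is solved so the expected overall
    missingness equals ``rate``.
    """
    if rate >= 1.0 or rate < 0.0:
        raise ValueError("missingness rate must be in [0, 1)")
    if cohort["ca125"].isna().any():
        raise ValueError("cohort must have complete CA125 before injection")
    out = cohort.copy()
    if rate == 0.0:
        return out
    s = suspicion_score(cohort)
    s = s - s.mean()

    def mean_measured(a: float) -> float:
        return expit(a + suspicion_slope * s).mean() - (1.0 - rate)

    a = brentq(mean_measured, -40.0, 40.0)
    rng = np.random.default_rng(seed)
    measured = rng.random(len(cohort)) < expit(a + suspicion_slope * s)
    out.loc[~measured, "ca125"] = np.nan
    out["ca125_missing"] = ~measured
    return out


# ---------------------------------------------------------------------------
# delimited-text I/O and schema validation
# ---------------------------------------------------------------------------

def write_cohort(table: pd.DataFrame, path) -> None:
    """Write the cohort in the package CSV dialect (header, NA for missing)."""
    out = table[list(COHORT_COLUMNS)].copy()
    out.to_csv(path, index=False, na_rep="NA", float_format="%.10g")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; see :func:`validate_cohort_frame`."""
    df = pd.read_csv(
        path, na_values=["NA"], keep_default_na=False,
        dtype={"papillations": str},
    )
    return validate_cohort_frame(df)


def validate_cohort_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and ranges; returns a typed copy with missing flags.

    Missing values are permitted in CA125 only. Errors name the offending
    column and row (0-based position in the file body).
    """
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")
    df = df[list(COHORT_COLUMNS)].copy()

    for col in COHORT_COLUMNS:
        if col == "ca125":
            continue
        na = df[col].isna()
        if na.any():
            raise ValueError(
                f"column '{col}' has missing values at rows "
                f"{np.flatnonzero(na)[:5].tolist()} (only ca125 may be missing)"
            )
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"duplicate patient_id: {dup!r}")

    bad = ~df["outcome"].isin(OUTCOME_LEVELS)
    if bad.any():
        r = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"unknown outcome level {df['outcome'].iloc[r]!r} at row {r}"
        )
    df["papillations"] = df["papillations"].astype(str)
    bad = ~df["papillations"].isin(PAPILLATION_LEVELS)
    if bad.any():
        r = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"unknown papillations level {df['papillations'].iloc[r]!r} at row {r}"
        )
    for col, lo, hi in (("prop_solid", 0.0, 1.0), ("age", 0.0, np.inf),
                        ("max_diameter", 0.0, np.inf)):
        v = pd.to_numeric(df[col])
        out_of_range = (v < lo) | (v > hi) | ((v <= 0) & (lo == 0.0) & (col != "prop_solid"))
        if out_of_range.any():
            r = int(np.flatnonzero(out_of_range)[0])
            raise ValueError(
                f"column '{col}' out of range at row {r}: {v.iloc[r]!r}"
            )
        df[col] = v
    v = pd.to_numeric(df["ca125"])
    if (v[v.notna()] <= 0).any():
        r = int(np.flatnonzero(v.notna() & (v <= 0))[0])
        raise ValueError(f"ca125 must be positive at row {r}: {v.iloc[r]!r}")
    df["ca125"] = v
    for col in BINARY_COLUMNS:
        v = pd.to_numeric(df[col]).astype(int)
        if not np.isin(v, (0, 1)).all():
            r = int(np.flatnonzero(~np.isin(v, (0, 1)))[0])
            raise ValueError(f"column '{col}' must be 0/1, row {r}: {v.iloc[r]!r}")
        df[col] = v
    df["ca125_missing"] = df["ca125"].isna()
    return df.reset_index(drop=True)


def outcome_codes(outcomes) -> np.ndarray:
    """Map outcome labels (or 0-4 codes) to integer codes 0..4."""
    arr = np.asarray(outcomes)
    if arr.dtype.kind in "iu":
        if arr.size and (arr.min() < 0 or arr.max() > 4):
            raise ValueError("integer outcome codes must lie in 0..4")
        return arr.astype(int)
    lut = {lvl: i for i, lvl in enumerate(OUTCOME_LEVELS)}
    try:
        return np.array([lut[x] for x in arr], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown outcome label: {exc.args[0]!r}") from None
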