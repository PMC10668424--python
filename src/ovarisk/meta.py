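"""Random-effects meta-analysis of center-specific performance statistics.

Pooling uses the DerSimonian-Laird moment estimator of the between-center
variance tau^2, inverse-variance weights 1/(v_c + tau^2), a Wald 95%
confidence interval for the pooled mean, and a Higgins-Thompson 95%
prediction interval mu +/- t_{k-2, 0.975} * sqrt(tau^2 + SE(mu)^2) telling a
user what to expect in a new center. Proportions and c-statistics can be
pooled on the logit scale (variances carried over by the delta method).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class CenterEstimate:
    center_id: str
    value: float
    variance: float
    n: int


@dataclass(frozen=True)
class PooledEstimate:
    mu: float
    ci95: tuple[float, float]
    pi95: tuple[float, float] | None
    tau2: float
    k: int
    scale: str = "identity"
    method: str = "DerSimonian-Laird"


def random_effects_pool(estimates: list[CenterEstimate],
                        scale: str = "identity") -> PooledEstimate:
    """DerSimonian-Laird random-effects pool of center estimates.

    ``scale='logit'`` transforms values in (0,1) to the logit scale before
    pooling (appropriate for proportions and c-statistics) and transforms
    the pooled mean and intervals back. The 95% prediction interval needs
    k >= 3 centers and is None (flagged in logs) for k = 2.
    """
    if len(estimates) < 2:
        raise ValueError("meta-analysis requires at least 2 centers")
    y = np.array([e.value for e in estimates], dtype=float)
    v = np.array([e.variance for e in estimates], dtype=float)
    if not (np.isfinite(y).all() and np.isfinite(v).all()) or (v < 0).any():
        raise ValueError("non-finite values or negative variances in estimates")

    if scale == "logit":
        if (y <= 0).any() or (y >= 1).any():
            raise ValueError("logit-scale pooling requires values strictly in (0,1)")
        v = v / (y * (1.0 - y)) ** 2  # delta method
        y = logit(y)
    elif scale != "identity":
        raise ValueError(f"unknown scale {scale!r}")

    k = y.size
    v = np.maximum(v, 1e-12)
    w = 1.0 / v
    mu_fixed = (w * y).sum() / w.sum()
    q = float((w * (y - mu_fixed) ** 2).sum())
    denom = w.sum() - (w ** 2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0

    w_star = 1.0 / (v + tau2)
    mu = float((w_star * y).sum() / w_star.sum())
    se = float(np.sqrt(1.0 / w_star.sum()))
    ci = (mu - Z975 * se, mu + Z975 * se)

    if k >= 3:
        t = stats.t.ppf(0.975, k - 2)
        half = t * np.sqrt(tau2 + se ** 2)
        pi = (mu - half, mu + half)
    else:
        logger.info("prediction interval undefined for k=2 centers")
        pi = None

    if scale == "logit":
        mu_out = float(expit(mu))
        ci = (float(expit(ci[0])), float(expit(ci[1])))
        pi = (float(expit(pi[0])), float(expit(pi[1]))) if pi is not None else None
    else:
        mu_out = mu
    return PooledEstimate(mu_out, ci, pi, float(tau2), k, scale=scale)


def center_statistics(probabilities, outcomes, centers, metric_fn,
                      variance_fn=None, n_boot: int = 200,
                      seed: int = 0, min_n: int = 2) -> list[CenterEstimate]:
    """Evaluate a metric per center with a within-center variance.

    ``metric_fn(P, y) -> float`` is applied to each center's rows; centers
    where it raises (metric preconditions unmet, e.g. a missing outcome
    class) are excluded with a logged reason. The variance comes from
    ``variance_fn(P, y)`` when supplied (closed form), otherwise from a
    seeded nonparametric bootstrap of the center's rows (B = ``n_boot``).
    """
    P = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes)
    centers = np.asarray(centers)
    root = np.random.SeedSequence(seed)
    out = []
    unique_centers = np.unique(centers)
    child_seeds = root.spawn(len(unique_centers))
    for c, ss in zip(unique_centers, child_seeds):
        mask = centers == c
        n_c = int(mask.sum())
        if n_c < min_n:
            logger.info("center %s excluded (n=%d < %d)", c, n_c, min_n)
            continue
        Pc, yc = P[mask], y[mask]
        try:
            value = float(metric_fn(Pc, yc))
        except ValueError as exc:
            logger.info("center %s excluded: %s", c, exc)
            continue
        if variance_fn is not None:
            variance = float(variance_fn(Pc, yc))
        else:
            rng = np.random.default_rng(ss)
            reps = []
            for _ in range(n_boot):
                idx = rng.integers(n_c, size=n_c)
                try:
                    reps.append(metric_fn(Pc[idx], yc[idx]))
                except ValueError:
                    continue  # resample lost a class; skip replicate
            if len(reps) < 2:
                logger.info("center %s excluded: bootstrap variance unavailable", c)
                continue
            variance = float(np.var(reps, ddof=1))
        out.append(CenterEstimate(str(c), value, variance, n_c))
    if not out:
        raise ValueError("no center satisfied the metric's preconditions")
    return out
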