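"""Net Benefit, decision curves, referrals avoided and decision reversal.

Clinical utility is assessed for the binary decision "refer to a gynecologic
oncology center when the estimated risk of any malignancy is at least t".
The risk of any malignancy is 1 - p_benign. At threshold t,

    NB = TP/n - (FP/n) * t / (1 - t)

counts true positives net of harm-weighted false positives per patient and
is compared with the default strategies: refer everyone ("treat all", NB =
prevalence - (1-prevalence) * t/(1-t)) and refer no-one ("treat none", NB =
0). Net Benefit is pooled across centers with the random-effects
meta-analysis of :mod:`ovarisk.meta`; within-center variances come from a
multinomial delta method.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import outcome_codes
from .meta import CenterEstimate, random_effects_pool

logger = logging.getLogger(__name__)

#: paper-style threshold grid: 5% to 40% by 1 percentage point
DEFAULT_THRESHOLDS = np.round(np.arange(0.05, 0.401, 0.01), 4)
HEADLINE_THRESHOLD = 0.10


def _check_threshold(threshold: float) -> None:
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")


def net_benefit(risk, malignant, threshold: float) -> float:
    """Net Benefit of referring patients with risk >= threshold."""
    _check_threshold(threshold)
    r = np.asarray(risk, dtype=float)
    m = np.asarray(malignant, dtype=bool)
    if r.size == 0:
        raise ValueError("empty input")
    pos = r >= threshold
    n = r.size
    tp = np.count_nonzero(pos & m) / n
    fp = np.count_nonzero(pos & ~m) / n
    return tp - fp * threshold / (1.0 - threshold)


def net_benefit_variance(risk, malignant, threshold: float) -> float:
    """Delta-method variance of NB from the multinomial (TP, FP) counts."""
    _check_threshold(threshold)
    r = np.asarray(risk, dtype=float)
    m = np.asarray(malignant, dtype=bool)
    n = r.size
    pos = r >= threshold
    p1 = np.count_nonzero(pos & m) / n
    p2 = np.count_nonzero(pos & ~m) / n
    w = threshold / (1.0 - threshold)
    return (p1 * (1 - p1) + w ** 2 * p2 * (1 - p2) + 2 * w * p1 * p2) / n


def treat_all_nb(prevalence: float, threshold: float) -> float:
    """Net Benefit of referring everyone."""
    _check_threshold(threshold)
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    return prevalence - (1.0 - prevalence) * threshold / (1.0 - threshold)


def referrals_avoided(nb_model: float, nb_all: float, threshold: float) -> float:
    """Net proportion of unnecessary referrals avoided relative to treat-all.

    (NB_model - NB_all) * (1 - t) / t: the false positives avoided per
    patient, net of any true positives missed, at threshold t.
    """
    _check_threshold(threshold)
    return (nb_model - nb_all) * (1.0 - threshold) / threshold


def malignancy_risk(probabilities) -> np.ndarray:
    """Risk of any malignancy: 1 - estimated benign probability."""
    return 1.0 - np.asarray(probabilities, dtype=float)[:, 0]


def decision_curve(model_risks: dict[str, np.ndarray], outcomes, centers,
                   thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Meta-analyzed decision curve for each model plus default strategies.

    ``model_risks`` maps strategy name -> per-patient malignancy risk.
    Center-specific Net Benefit values are pooled per threshold with the
    DerSimonian-Laird random-effects model (identity scale, delta-method
    within-center variances); with a single center, plain NB is reported
    with a warning. Returns a long-format table (threshold, strategy, nb,
    nb_ci_low, nb_ci_high, k_centers).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("thresholds must lie in (0, 1)")
    codes = outcome_codes(outcomes)
    malignant = codes != 0
    centers = np.asarray(centers)
    unique_centers = np.unique(centers)
    if unique_centers.size < 2:
        logger.warning("single center: decision curve uses plain (unpooled) NB")

    strategies = dict(model_risks)
    strategies["treat_all"] = np.ones(malignant.size)
    strategies["treat_none"] = np.zeros(malignant.size)

    rows = []
    for t in thresholds:
        for name, risk in strategies.items():
            risk = np.asarray(risk, dtype=float)
            if name == "treat_none":
                rows.append((t, name, 0.0, 0.0, 0.0, unique_centers.size))
                continue
            if unique_centers.size < 2:
                nb = net_benefit(risk, malignant, t)
                rows.append((t, name, nb, np.nan, np.nan, 1))
                continue
            ests = []
            for c in unique_centers:
                mask = centers == c
                nb_c = net_benefit(risk[mask], malignant[mask], t)
                v_c = net_benefit_variance(risk[mask], malignant[mask], t)
                ests.append(CenterEstimate(str(c), nb_c, v_c, int(mask.sum())))
            pooled = random_effects_pool(ests, scale="identity")
            rows.append((t, name, pooled.mu, pooled.ci95[0], pooled.ci95[1],
                         pooled.k))
    return pd.DataFrame(
        rows, columns=["threshold", "strategy", "nb", "nb_ci_low",
                       "nb_ci_high", "k_centers"],
    )


def decision_reversal(probabilities_a, probabilities_b,
                      threshold: float = HEADLINE_THRESHOLD) -> float:
    """Percentage of patients on opposite sides of the risk threshold.

    Risks are 1 - p_benign for each model; the comparison uses the closed
    rule risk >= t. Symmetric in its two arguments.
    """
    _check_threshold(threshold)
    ra = malignancy_risk(probabilities_a)
    rb = malignancy_risk(probabilities_b)
    if ra.size != rb.size:
        raise ValueError("probability matrices are not aligned")
    return float(np.mean((ra >= threshold) != (rb >= threshold)) * 100.0)


def reversal_matrix(model_probabilities: dict[str, np.ndarray],
                    threshold: float = HEADLINE_THRESHOLD) -> pd.DataFrame:
    """Square matrix of pairwise decision-reversal percentages."""
    names = list(model_probabilities)
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r = decision_reversal(model_probabilities[a],
                                  model_probabilities[b], threshold)
            out.loc[a, b] = r
            out.loc[b, a] = r
    return out
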