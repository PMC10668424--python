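"""Inter-model prediction-uncertainty descriptives.

Even when models have similar population-level performance, the probability
they assign to the same patient can differ materially. This module computes
the per-patient, per-category probability range (max minus min across
models) and tabulates how many patients exceed range thresholds, plus a
long-format export of all pairwise prediction scatter data.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .cohort import OUTCOME_LEVELS

RANGE_THRESHOLDS = (0.05, 0.10, 0.20, 0.30)


def probability_range_table(probability_matrices,
                            thresholds=RANGE_THRESHOLDS) -> pd.DataFrame:
    """Counts and percentages of patients whose across-model probability
    range reaches each threshold, per outcome category.

    Rows are thresholds; for each category there is an ``n`` and a ``pct``
    column. Counts are necessarily non-increasing in the threshold.
    """
    mats = [np.asarray(P, dtype=float) for P in probability_matrices]
    if len(mats) < 2:
        raise ValueError("at least 2 probability matrices are required")
    shape = mats[0].shape
    if any(P.shape != shape for P in mats):
        raise ValueError("probability matrices are not aligned")
    stack = np.stack(mats)  # models x n x K
    rng = stack.max(axis=0) - stack.min(axis=0)  # n x K
    n = shape[0]
    rows = []
    for t in thresholds:
        row = {"range_threshold": t}
        for k, level in enumerate(OUTCOME_LEVELS[: shape[1]]):
            count = int((rng[:, k] >= t).sum())
            row[f"{level}_n"] = count
            row[f"{level}_pct"] = 100.0 * count / n
        rows.append(row)
    return pd.DataFrame(rows)


def pairwise_prediction_export(model_probabilities: dict[str, np.ndarray],
                               category: str,
                               patient_ids=None) -> pd.DataFrame:
    """Long table of per-patient predictions for every unordered model pair.

    One row per (patient, model pair) with both models' estimated
    probabilities for ``category`` — the data behind pairwise scatter plots.
    """
    if category not in OUTCOME_LEVELS:
        raise ValueError(f"unknown category {category!r}")
    if len(model_probabilities) < 2:
        raise ValueError("at least 2 models are required")
    k = OUTCOME_LEVELS.index(category)
    names = list(model_probabilities)
    n = np.asarray(model_probabilities[names[0]]).shape[0]
    if patient_ids is None:
        patient_ids = np.arange(1, n + 1)
    frames = []
    for a, b in itertools.combinations(names, 2):
        frames.append(pd.DataFrame({
            "patient_id": patient_ids,
            "model_a": a,
            "model_b": b,
            "p_a": np.asarray(model_probabilities[a], float)[:, k],
            "p_b": np.asarray(model_probabilities[b], float)[:, k],
        }))
    return pd.concat(frames, ignore_index=True)
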