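"""Multiclass and pairwise discrimination metrics.

The Polytomous Discrimination Index (PDI) generalizes the binary c-statistic
to K classes: draw one patient from each class and pick a class k at random;
the PDI is the probability that the patient truly from class k has the
highest estimated probability for class k within the drawn K-tuple. Ties at
the maximum receive fractional credit 1/m (m patients tied including the
class-k patient), so a model that outputs the same vector for everyone
scores exactly 1/K and an indicator-probability model scores exactly 1.

Three estimators are provided: ``exhaustive`` enumerates every tuple (used
as the oracle at small n), ``sorted_exact`` computes the identical value by
per-class rank counting in O(n log n), and ``monte_carlo`` samples tuples.

Pairwise c-statistics use the conditional-risk construction: among patients
truly in classes k or l, the AUROC of p_l / (p_k + p_l) for membership of
class l, with ties counted 1/2 (Mann-Whitney convention).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .cohort import OUTCOME_LEVELS, outcome_codes

EXHAUSTIVE_TUPLE_LIMIT = 10**6
#: `auto` enumerates tuples only below this count; the rank-counting path
#: computes the identical value, so enumeration is kept for tiny inputs and
#: as the test oracle
AUTO_EXHAUSTIVE_LIMIT = 2000


@dataclass(frozen=True)
class PdiResult:
    overall_pdi: float
    category_pdi: np.ndarray
    estimator: str
    n_tuples_evaluated: int
    mc_se: float | None = None


def _class_indices(codes: np.ndarray, n_classes: int) -> list[np.ndarray]:
    groups = [np.flatnonzero(codes == k) for k in range(n_classes)]
    for k, g in enumerate(groups):
        if g.size == 0:
            name = OUTCOME_LEVELS[k] if n_classes == len(OUTCOME_LEVELS) else str(k)
            raise ValueError(f"outcome class {name!r} has no patients; PDI undefined")
    return groups


def _tuple_credit(block: np.ndarray, k: int) -> float:
    """Credit of one tuple for class k: block is K x K (row j = patient from
    class j), column k holds the relevant probabilities."""
    col = block[:, k]
    mx = col.max()
    if col[k] < mx:
        return 0.0
    return 1.0 / np.count_nonzero(col == mx)


def pdi(probabilities, outcomes, estimator: str = "auto", seed: int | None = None,
        n_samples: int = 100_000) -> PdiResult:
    """Polytomous Discrimination Index with fractional tie credit.

    ``outcomes`` may be the five outcome labels or integer codes 0..4;
    the probability columns must follow the same class order.
    """
    P = np.asarray(probabilities, dtype=float)
    K = P.shape[1]
    codes = outcome_codes(outcomes) if K == len(OUTCOME_LEVELS) else np.asarray(outcomes, int)
    if codes.size != P.shape[0]:
        raise ValueError("probabilities and outcomes are not aligned")
    groups = _class_indices(codes, K)
    sizes = np.array([g.size for g in groups])
    n_tuples = int(np.prod(sizes.astype(object)))

    if estimator == "auto":
        estimator = "exhaustive" if n_tuples <= AUTO_EXHAUSTIVE_LIMIT else "sorted_exact"

    if estimator == "exhaustive":
        if n_tuples > EXHAUSTIVE_TUPLE_LIMIT:
            raise ValueError(
                f"{n_tuples} tuples exceed the exhaustive limit; use sorted_exact"
            )
        cat = np.zeros(K)
        for tup in itertools.product(*groups):
            block = P[list(tup)]
            for k in range(K):
                cat[k] += _tuple_credit(block, k)
        cat /= n_tuples
        return PdiResult(float(cat.mean()), cat, "exhaustive", n_tuples)

    if estimator == "sorted_exact":
        cat = np.zeros(K)
        others_cache = {}
        for k in range(K):
            # sorted class-j values of the class-k probability column
            sorted_cols = [np.sort(P[groups[j], k]) for j in range(K)]
            v = P[groups[k], k]
            # a[j] = # class-j patients strictly below v, t[j] = # tied at v
            credit = None
            # polynomial in u: prod_j (a_j + t_j u); coefficient of u^s is the
            # number of ways to pick s tied classes; credit weight 1/(1+s)
            coeffs = np.zeros((v.size, K))  # degrees 0..K-1
            coeffs[:, 0] = 1.0
            for j in range(K):
                if j == k:
                    continue
                a = np.searchsorted(sorted_cols[j], v, side="left").astype(float)
                t = np.searchsorted(sorted_cols[j], v, side="right") - a
                new = np.zeros_like(coeffs)
                new += coeffs * a[:, None]
                new[:, 1:] += coeffs[:, :-1] * t[:, None]
                coeffs = new
            weights = 1.0 / (1.0 + np.arange(K))
            credit = coeffs @ weights
            cat[k] = credit.sum() / n_tuples
        return PdiResult(float(cat.mean()), cat, "sorted_exact", n_tuples)

    if estimator == "monte_carlo":
        rng = np.random.default_rng(seed)
        idx = np.column_stack([
            g[rng.integers(g.size, size=n_samples)] for g in groups
        ])  # n_samples x K patient indices, column j from class j
        per_tuple = np.empty((n_samples, K))
        # block values: for tuple i, B[i, j, k] = P[idx[i, j], k]
        B = P[idx]  # n_samples x K x K
        for k in range(K):
            col = B[:, :, k]
            mx = col.max(axis=1)
            own = col[:, k]
            ties = (col == mx[:, None]).sum(axis=1)
            per_tuple[:, k] = np.where(own >= mx, 1.0 / ties, 0.0)
        cat = per_tuple.mean(axis=0)
        overall = per_tuple.mean(axis=1)
        mc_se = float(overall.std(ddof=1) / np.sqrt(n_samples))
        return PdiResult(float(cat.mean()), cat, "monte_carlo", n_samples, mc_se)

    raise ValueError(f"unknown estimator {estimator!r}")


def conditional_risk(probabilities, class_k: int, class_l: int) -> np.ndarray:
    """Per-patient conditional risk p_l / (p_k + p_l); 0.5 when p_k+p_l = 0.

    The degenerate zero-sum case is mapped to the no-information value 0.5
    rather than dropping the patient, keeping n fixed.
    """
    if class_k == class_l:
        raise ValueError("class_k and class_l must differ")
    P = np.asarray(probabilities, dtype=float)
    num = P[:, class_l]
    den = P[:, class_k] + P[:, class_l]
    out = np.full(P.shape[0], 0.5)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def pairwise_cstat(probabilities, outcomes, class_k: int, class_l: int) -> float:
    """Conditional-risk pairwise c-statistic for classes k vs l.

    AUROC of the conditional risk for class l over patients truly in
    {k, l}; ties credited 1/2.
    """
    P = np.asarray(probabilities, dtype=float)
    codes = outcome_codes(outcomes)
    mask = (codes == class_k) | (codes == class_l)
    sub = codes[mask]
    for c in (class_k, class_l):
        if not (sub == c).any():
            name = OUTCOME_LEVELS[c] if P.shape[1] == len(OUTCOME_LEVELS) else str(c)
            raise ValueError(f"class {name!r} has no patients in the pair subset")
    risk = conditional_risk(P[mask], class_k, class_l)
    return float(roc_auc_score(sub == class_l, risk))


def pairwise_cstat_matrix(probabilities, outcomes) -> np.ndarray:
    """Upper-triangle matrix of conditional-risk pairwise c-statistics."""
    P = np.asarray(probabilities, dtype=float)
    K = P.shape[1]
    out = np.full((K, K), np.nan)
    for k in range(K):
        for l in range(k + 1, K):
            out[k, l] = pairwise_cstat(P, outcomes, k, l)
    return out


def binary_cstat_any_malignancy(probabilities, outcomes) -> float:
    """AUROC of (1 - p_benign) for benign vs any malignant tumor.

    The estimated risk of any malignancy is one minus the estimated benign
    probability; the four malignant classes are merged.
    """
    P = np.asarray(probabilities, dtype=float)
    codes = outcome_codes(outcomes)
    malignant = codes != 0
    if malignant.all() or not malignant.any():
        raise ValueError("both benign and malignant patients are required")
    return float(roc_auc_score(malignant, 1.0 - P[:, 0]))
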