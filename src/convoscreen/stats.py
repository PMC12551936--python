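"""Statistical machinery: permutation tests, 1-D Gaussian mixtures with
AIC/BIC selection, inter-rater agreement, and ROC/PR threshold analysis.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import comb, logsumexp
from scipy.stats import norm
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import average_precision_score, roc_curve

__all__ = [
    "PermutationResult",
    "permutation_test_mean_diff",
    "GMMFit",
    "fit_gmm_1d",
    "select_gmm_components",
    "AgreementReport",
    "agreement",
    "RocResult",
    "roc_analysis",
]


# --- permutation test --------------------------------------------------------

@dataclass(frozen=True)
class PermutationResult:
    observed_diff: float
    p_value: float
    n_permutations: int
    seed: int
    alternative: str
    exhaustive: bool


def permutation_test_mean_diff(
    x, y, n_permutations: int = 9999, seed: int = 0, alternative: str = "two_sided"
) -> PermutationResult:
    """Permutation test for a difference of group means.

    The observed statistic is mean(x) − mean(y). The null distribution is
    built by relabeling the pooled sample at fixed group sizes. When the
    number of distinct relabelings C(n, n_x) is at most ``n_permutations``
    the test enumerates all of them and the p-value is the exact tail
    proportion (the identity relabeling counts itself). Otherwise
    ``n_permutations`` random relabelings are drawn and the add-one
    estimator p = (1 + #extreme) / (n_permutations + 1) is used, so p is
    never zero.

    ``alternative``: ``two_sided`` (|null| ≥ |observed|), ``greater``
    (null ≥ observed) or ``less`` (null ≤ observed).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in {"two_sided", "greater", "less"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    observed = float(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    total = comb(n, nx, exact=True)
    exhaustive = total <= n_permutations

    if exhaustive:
        null = np.empty(total)
        pooled_sum = pooled.sum()
        for j, idx in enumerate(itertools.combinations(range(n), nx)):
            sx = pooled[list(idx)].sum()
            null[j] = sx / nx - (pooled_sum - sx) / (n - nx)
        denom = total
        n_used = total
        count = _tail_count(null, observed, alternative)
        p = count / denom
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_permutations)
        pooled_sum = pooled.sum()
        for j in range(n_permutations):
            idx = rng.permutation(n)[:nx]
            sx = pooled[idx].sum()
            null[j] = sx / nx - (pooled_sum - sx) / (n - nx)
        count = _tail_count(null, observed, alternative)
        p = (1 + count) / (n_permutations + 1)
        n_used = n_permutations

    return PermutationResult(
        observed_diff=observed,
        p_value=float(p),
        n_permutations=n_used,
        seed=seed,
        alternative=alternative,
        exhaustive=exhaustive,
    )


def _tail_count(null: np.ndarray, observed: float, alternative: str) -> int:
    if alternative == "two_sided":
        return int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    if alternative == "greater":
        return int(np.sum(null >= observed - 1e-12))
    return int(np.sum(null <= observed + 1e-12))


# --- 1-D Gaussian mixture ----------------------------------------------------

@dataclass
class GMMFit:
    """EM fit of a k-component univariate Gaussian mixture.

    AIC = 2p − 2·loglik and BIC = p·ln(n) − 2·loglik with p = 3k − 1 free
    parameters (k−1 weights, k means, k variances).
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    aic: float
    bic: float
    n_iter: int
    converged: bool


def _gmm_loglik(x: np.ndarray, weights, means, variances) -> tuple[float, np.ndarray]:
    # log densities per (component, observation)
    log_dens = (
        np.log(weights)[:, None]
        + norm.logpdf(x[None, :], loc=np.asarray(means)[:, None],
                      scale=np.sqrt(np.asarray(variances))[:, None])
    )
    per_obs = logsumexp(log_dens, axis=0)
    return float(per_obs.sum()), log_dens - per_obs[None, :]


def fit_gmm_1d(
    values,
    k: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> GMMFit:
    """Expectation-maximization for a 1-D Gaussian mixture.

    Means are initialized at quantile-spaced points of the data with a small
    seed-controlled jitter, weights equal, variances at the sample variance.
    The log-likelihood is checked to be non-decreasing at every iteration
    and variances are floored at 1e-6 times the sample variance to keep the
    likelihood bounded.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 3 * k:
        raise ValueError(f"need n >= 3k observations (n={n}, k={k})")
    rng = np.random.default_rng(seed)
    sample_var = float(x.var())
    floor = max(1e-6 * sample_var, 1e-12)
    qs = (np.arange(k) + 0.5) / k
    means = np.quantile(x, qs)
    spread = math.sqrt(sample_var) if sample_var > 0 else 1.0
    means = means + rng.normal(0.0, 0.01 * spread / max(k, 1), size=k)
    variances = np.full(k, max(sample_var, floor))
    weights = np.full(k, 1.0 / k)

    loglik, log_resp = _gmm_loglik(x, weights, means, variances)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resp = np.exp(log_resp)  # (k, n)
        nk = resp.sum(axis=1)
        weights = nk / n
        means = (resp @ x) / nk
        variances = (resp @ (x**2)) / nk - means**2
        variances = np.maximum(variances, floor)
        new_loglik, log_resp = _gmm_loglik(x, weights, means, variances)
        assert new_loglik >= loglik - 1e-8 * (1 + abs(loglik)), (
            f"EM log-likelihood decreased: {loglik} -> {new_loglik}"
        )
        if abs(new_loglik - loglik) < tol * (1 + abs(loglik)):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

    p = 3 * k - 1
    return GMMFit(
        k=k,
        weights=weights,
        means=means,
        variances=variances,
        loglik=loglik,
        aic=2 * p - 2 * loglik,
        bic=p * math.log(n) - 2 * loglik,
        n_iter=it,
        converged=converged,
    )


def select_gmm_components(
    values, k_range, criterion: str = "bic", seed: int = 0, **fit_kwargs
) -> tuple[int, list[GMMFit]]:
    """Fit a mixture for every k and pick the criterion-minimizing one."""
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    if criterion not in {"aic", "bic"}:
        raise ValueError(f"criterion must be 'aic' or 'bic', got {criterion!r}")
    fits = [fit_gmm_1d(values, k, seed=seed, **fit_kwargs) for k in k_range]
    best = min(fits, key=lambda f: getattr(f, criterion))
    return best.k, fits


# --- inter-rater agreement ---------------------------------------------------

@dataclass
class AgreementReport:
    """Contingency table, percent agreement, and Cohen's kappa.

    kappa = (p_o − p_e) / (1 − p_e) where p_o is the observed agreement
    (table trace over total) and p_e the chance agreement from the raters'
    marginal label distributions. kappa > 0.61 is conventionally read as
    substantial agreement.
    """

    labels: list
    table: np.ndarray
    percent_agreement: float
    kappa: float


def agreement(labels_a, labels_b) -> AgreementReport:
    """Agreement statistics between two equal-length label vectors."""
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("need at least one label pair")
    labels = sorted(set(a) | set(b), key=str)
    index = {lab: i for i, lab in enumerate(labels)}
    r = len(labels)
    table = np.zeros((r, r), dtype=int)
    for la, lb in zip(a, b):
        table[index[la], index[lb]] += 1
    total = table.sum()
    p_o = float(np.trace(table)) / total
    p_e = float((table.sum(axis=1) / total) @ (table.sum(axis=0) / total))
    if p_e >= 1.0:
        kappa = 1.0 if p_o == 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1 - p_e)
    return AgreementReport(labels=labels, table=table, percent_agreement=p_o, kappa=float(kappa))


# --- ROC / precision-recall --------------------------------------------------

@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    roc_auc: float
    pr_auc: float
    best_threshold: float
    precision_at_best: float
    recall_at_best: float


def roc_analysis(scores, labels, positive_is_high: bool = True) -> RocResult:
    """ROC and precision-recall analysis with a TPR−FPR-optimal threshold.

    ``labels`` are binary (1 = positive class). When ``positive_is_high``
    the classifier predicts positive for scores at or above the threshold;
    otherwise scores are negated internally and the reported threshold is
    mapped back. ROC AUC is the trapezoidal area; PR AUC uses step
    interpolation over recall (average precision). The operating threshold
    maximizes TPR − FPR, ties broken toward the lowest threshold, and
    precision/recall are reported at that threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.size != y.size:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    s_eff = s if positive_is_high else -s
    fpr, tpr, thresholds = roc_curve(y, s_eff)
    roc_auc = float(_trapezoid_auc(fpr, tpr))
    pr_auc = float(average_precision_score(y, s_eff))

    j = tpr - fpr
    best_j = j.max()
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    finite = candidates[np.isfinite(thresholds[candidates])]
    pick = (finite if finite.size else candidates)[
        np.argmin(thresholds[finite if finite.size else candidates])
    ]
    best_thr_eff = float(thresholds[pick])

    pred = s_eff >= best_thr_eff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0

    best_threshold = best_thr_eff if positive_is_high else -best_thr_eff
    return RocResult(
        thresholds=thresholds if positive_is_high else -thresholds,
        tpr=tpr,
        fpr=fpr,
        roc_auc=roc_auc,
        pr_auc=pr_auc,
        best_threshold=best_threshold,
        precision_at_best=float(precision),
        recall_at_best=float(recall),
    )
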