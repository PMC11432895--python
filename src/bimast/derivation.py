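"""Score derivation and validation statistics.

The machinery behind deriving a screening score from a cohort and judging
it: a seeded 2:1 derivation/validation split, Mann-Whitney / chi-square
univariate screening, a hand-rolled IRLS logistic fit (the convergence
contract — score max-norm < 1e-8 within 100 iterations, perfect separation
flagged rather than fatal — is part of this module's interface), Brier score
and Hosmer-Lemeshow calibration, non-parametric AUROC with DeLong variance
and confidence intervals, the paired DeLong test, and Youden-J cut-off
selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .exceptions import ConvergenceWarning, DerivationError
from .scores import ConfusionSummary

__all__ = [
    "split_cohort",
    "univariate_screen",
    "LogisticFit",
    "fit_logistic",
    "brier_score",
    "hosmer_lemeshow",
    "RocResult",
    "roc_auroc",
    "delong_test",
    "optimal_cutoff",
    "diagnostic_metrics",
]


def split_cohort(cohort: pd.DataFrame, seed: int = 0,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded 2:1 random split into (derivation, validation) subsets.

    The derivation subset holds round(2n/3) subjects; the two subsets are
    disjoint and exhaustive, and the membership is reproducible from the
    seed.
    """
    n = len(cohort)
    if n < 3:
        raise DerivationError(f"cohort: needs at least 3 records to split, got {n}")
    n_deriv = round(2 * n / 3)
    perm = np.random.default_rng([int(seed) & 0x7FFFFFFF, 11]).permutation(n)
    deriv = cohort.iloc[np.sort(perm[:n_deriv])]
    valid = cohort.iloc[np.sort(perm[n_deriv:])]
    return deriv, valid


def univariate_screen(cohort: pd.DataFrame, outcome: np.ndarray,
                      variables: Sequence[str],
                      categorical: Sequence[str] = ()) -> pd.Series:
    """Two-sided p-value per candidate predictor.

    Continuous variables: Mann-Whitney U with the tie-corrected normal
    approximation.  Categorical variables (listed in ``categorical``):
    Pearson chi-square on the contingency table with the outcome.
    """
    outcome = np.asarray(outcome, dtype=bool)
    if outcome.all() or not outcome.any():
        raise DerivationError("outcome: both outcome groups must be non-empty")
    pvalues = {}
    for var in variables:
        x = cohort[var]
        if var in categorical:
            table = pd.crosstab(x, outcome)
            pvalues[var] = float(stats.chi2_contingency(table.to_numpy())[1])
        else:
            v = x.to_numpy(dtype=float)
            res = stats.mannwhitneyu(v[outcome], v[~outcome],
                                     alternative="two-sided", method="asymptotic")
            pvalues[var] = float(res.pvalue)
    return pd.Series(pvalues, name="p_value")


# ---------------------------------------------------------------------------
# Logistic regression (IRLS)


@dataclass
class LogisticFit:
    """Fitted logistic model: coefficients, uncertainty, fit diagnostics."""

    params: pd.Series  # index: ["intercept", *predictors]
    bse: pd.Series  # asymptotic standard errors from (X'WX)^-1
    log_likelihood: float
    converged: bool
    n_iterations: int
    cov_params: pd.DataFrame = field(repr=False, default=None)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Predicted event probabilities for new records."""
        eta = np.full(len(data), self.params["intercept"], dtype=float)
        for name, beta in self.params.items():
            if name != "intercept":
                eta += beta * data[name].to_numpy(dtype=float)
        return expit(eta)


def _bernoulli_ll(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def fit_logistic(data: pd.DataFrame, predictors: Sequence[str],
                 outcome, tol: float = 1e-8, max_iter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton/IRLS.

    Converged when the score vector's max-norm drops below ``tol``.  Under
    perfect separation the likelihood has no finite maximiser; the fit is
    flagged non-converged, a ConvergenceWarning is issued, and the last
    iterate is returned so callers can still inspect it.
    """
    if isinstance(outcome, str):
        y = data[outcome].to_numpy(dtype=float)
    else:
        y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise DerivationError("outcome: must be binary 0/1")
    if y.all() or not y.any():
        raise DerivationError("outcome: both classes must be present")
    x = np.column_stack([np.ones(len(data))]
                        + [data[p].to_numpy(dtype=float) for p in predictors])
    for j, p in enumerate(predictors):
        if np.ptp(x[:, j + 1]) == 0:
            raise DerivationError(f"predictor {p!r}: constant column")

    names = ["intercept", *predictors]
    beta = np.zeros(x.shape[1])
    converged = False
    n_iter = 0
    xtwx = np.eye(x.shape[1])
    for n_iter in range(1, max_iter + 1):
        mu = expit(x @ beta)
        score = x.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = np.clip(mu * (1 - mu), 1e-10, None)
        xtwx = x.T @ (x * w[:, None])
        try:
            step = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(xtwx, score, rcond=None)[0]
        # dampen huge Newton steps (separation sends coefficients to infinity)
        norm = np.max(np.abs(step))
        if norm > 50.0:
            step *= 50.0 / norm
        beta = beta + step

    mu = expit(x @ beta)
    # perfect separation: every response fitted exactly, MLE at infinity
    if converged and np.all(np.abs(y - mu) < 1e-4):
        converged = False
    if not converged:
        warnings.warn(
            "logistic fit did not converge (possible perfect separation); "
            "coefficients are the last iterate", ConvergenceWarning)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    xtwx = x.T @ (x * w[:, None])
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(xtwx)
    return LogisticFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(np.sqrt(np.clip(np.diag(cov), 0, None)), index=names),
        log_likelihood=_bernoulli_ll(y, mu),
        converged=converged,
        n_iterations=n_iter,
        cov_params=pd.DataFrame(cov, index=names, columns=names),
    )


# ---------------------------------------------------------------------------
# Calibration


def brier_score(probabilities, outcomes) -> float:
    """Mean squared difference between predicted probability and 0/1 outcome."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.size == 0:
        raise DerivationError("probabilities: empty input")
    if np.any((p < 0) | (p > 1)):
        raise DerivationError("probabilities: values outside [0, 1]")
    return float(np.mean((p - y) ** 2))


def hosmer_lemeshow(probabilities, outcomes, groups: int = 10,
                    ) -> tuple[float, float]:
    """Hosmer-Lemeshow goodness of fit over equal-count risk deciles.

    Statistic: sum over groups of (O - E)^2 / (E (1 - E/n_g)) where O and E
    are observed and expected event counts.  Groups whose variance term
    degenerates (expected count 0 or n_g) are merged with their neighbour.
    p-value from chi-square with (groups used - 2) degrees of freedom.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n = p.size
    if n < groups:
        raise DerivationError(f"probabilities: need n >= {groups} records, got {n}")
    if y.all() or not y.any():
        raise DerivationError("outcomes: both classes must be present")
    order = np.argsort(p, kind="mergesort")
    bins = [idx for idx in np.array_split(order, groups) if idx.size]

    # merge degenerate bins (E == 0 or E == n_g gives a zero variance term)
    merged: list[np.ndarray] = []
    for idx in bins:
        e = p[idx].sum()
        if (e <= 0 or e >= idx.size) and merged:
            merged[-1] = np.concatenate([merged[-1], idx])
        else:
            merged.append(idx)
    # a degenerate first bin merges forward
    while len(merged) > 1:
        e = p[merged[0]].sum()
        if e <= 0 or e >= merged[0].size:
            merged[1] = np.concatenate([merged[0], merged[1]])
            merged.pop(0)
        else:
            break

    stat = 0.0
    for idx in merged:
        n_g = idx.size
        e = p[idx].sum()
        o = y[idx].sum()
        denom = e * (1 - e / n_g)
        if denom <= 0:
            continue  # fully degenerate even after merging
        stat += (o - e) ** 2 / denom
    df = max(len(merged) - 2, 1)
    return float(stat), float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# ROC / AUROC / DeLong


@dataclass
class RocResult:
    """AUROC with DeLong variance, 95% CI and the empirical ROC curve."""

    auroc: float
    variance: float
    ci_low: float
    ci_high: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray


def _placements(cases: np.ndarray, controls: np.ndarray,
                ) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components.

    v10[i] = P-hat(control < case_i) with ties counted 1/2; v01[j] the dual.
    Their means both equal the Mann-Whitney AUROC.
    """
    sorted_controls = np.sort(controls)
    less = np.searchsorted(sorted_controls, cases, side="left")
    leq = np.searchsorted(sorted_controls, cases, side="right")
    v10 = (less + 0.5 * (leq - less)) / controls.size
    sorted_cases = np.sort(cases)
    below = np.searchsorted(sorted_cases, controls, side="left")
    at = np.searchsorted(sorted_cases, controls, side="right")
    greater = cases.size - at
    v01 = (greater + 0.5 * (at - below)) / cases.size
    return v10, v01


def _split_classes(scores, outcomes) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if s.shape != y.shape:
        raise DerivationError("scores and outcomes: length mismatch")
    cases, controls = s[y], s[~y]
    if cases.size == 0 or controls.size == 0:
        raise DerivationError("outcomes: both classes must be present")
    return cases, controls


def roc_auroc(scores, outcomes, ci_level: float = 0.95) -> RocResult:
    """Non-parametric AUROC (ties count 1/2) with DeLong variance and CI.

    The AUROC is the Mann-Whitney concordance probability; the variance is
    var(v10)/m + var(v01)/n from the DeLong structural components; the CI is
    asymptotic normal, clipped to [0, 1].
    """
    cases, controls = _split_classes(scores, outcomes)
    v10, v01 = _placements(cases, controls)
    auc = float(np.mean(v10))
    m, n = cases.size, controls.size
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) \
        + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    half = z * np.sqrt(var)

    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    # one ROC point per distinct threshold value ("positive if score >= t")
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(~y_sorted)[distinct]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    sens = np.r_[0.0, tp / m]
    spec = np.r_[1.0, 1 - fp / n]
    return RocResult(auroc=auc, variance=float(var),
                     ci_low=float(max(0.0, auc - half)),
                     ci_high=float(min(1.0, auc + half)),
                     thresholds=thresholds, sensitivity=sens, specificity=spec)


def delong_test(scores_a, scores_b, outcomes,
                ) -> tuple[float, float, float, float]:
    """Paired DeLong comparison of two AUROCs on the same subjects.

    Returns (auroc_a, auroc_b, z, two-sided p) using the DeLong covariance
    of the paired empirical AUROCs and a normal approximation.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise DerivationError("scores: paired score vectors must have equal length")
    cases_a, controls_a = _split_classes(a, outcomes)
    cases_b, controls_b = _split_classes(b, outcomes)
    v10 = np.vstack(
        [_placements(cases_a, controls_a)[0], _placements(cases_b, controls_b)[0]])
    v01 = np.vstack(
        [_placements(cases_a, controls_a)[1], _placements(cases_b, controls_b)[1]])
    auc = v10.mean(axis=1)
    m, n = cases_a.size, controls_a.size
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        z = 0.0
    else:
        z = float((auc[0] - auc[1]) / np.sqrt(var_diff))
    p = float(2 * stats.norm.sf(abs(z)))
    return float(auc[0]), float(auc[1]), z, p


def optimal_cutoff(roc: RocResult) -> float:
    """Threshold maximising Youden's J = sens + spec - 1.

    Ties are broken toward the higher-sensitivity point — a screening test
    prefers fewer missed cases at equal J.
    """
    finite = np.isfinite(roc.thresholds)
    if finite.sum() < 2:
        raise DerivationError("roc: degenerate curve with fewer than 2 points")
    j = roc.sensitivity + roc.specificity - 1.0
    best_j = j[finite].max()
    tied = finite & (j >= best_j - 1e-12)
    best = np.flatnonzero(tied)[np.argmax(roc.sensitivity[tied])]
    return float(roc.thresholds[best])


def diagnostic_metrics(summary: ConfusionSummary,
                       ) -> dict[str, float]:
    """Sens/spec/PPV/NPV from counts; undefined ratios become NaN flags."""
    return {
        "sensitivity": summary.sensitivity,
        "specificity": summary.specificity,
        "ppv": summary.ppv,
        "npv": summary.npv,
    }
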