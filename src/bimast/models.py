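"""Model/Results front-ends over the derivation and cost-utility engines.

Two statsmodels-style pairs:

``FibrosisScoreModel`` fits a logistic screening score to a cohort and its
``FibrosisScoreResults`` carries coefficients, standard errors, calibration
(Brier, Hosmer-Lemeshow), discrimination (AUROC with DeLong CI), the
Youden-optimal cut-off and a text ``summary()``; ``evaluate()`` scores a
held-out cohort.

``CostUtilityModel`` wraps the decision-tree + Markov engine; ``run()``
returns ``CostUtilityResults`` with the per-strategy base-case table,
``psa()``/``ceac()``/``one_way()`` sensitivity analyses and ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import derivation as dv
from . import health_econ as he
from .exceptions import DerivationError

__all__ = [
    "FibrosisScoreModel",
    "FibrosisScoreResults",
    "CostUtilityModel",
    "CostUtilityResults",
]


class FibrosisScoreModel:
    """Logistic screening-score model for a stiffness-defined endpoint.

    Parameters
    ----------
    data : cohort DataFrame (canonical columns; see `bimast.cohort`).
    predictors : biomarker columns entering the linear score.
    endpoint : LSM threshold (kPa) defining the outcome, 8.1 or 12.1.
    """

    def __init__(self, data: pd.DataFrame, predictors: Sequence[str] = ("bmi", "ast"),
                 endpoint: float = 8.1):
        if len(data) == 0:
            raise DerivationError("data: empty cohort")
        self.data = data
        self.predictors = tuple(predictors)
        self.endpoint = float(endpoint)
        self.outcome = (data["lsm"].to_numpy(dtype=float) >= self.endpoint).astype(int)
        if self.outcome.all() or not self.outcome.any():
            raise DerivationError(
                f"data: no outcome variation at the {endpoint} kPa endpoint")

    @classmethod
    def from_csv(cls, path, **kwargs) -> "FibrosisScoreModel":
        from .cohort import read_cohort
        return cls(read_cohort(path), **kwargs)

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> "FibrosisScoreResults":
        fit = dv.fit_logistic(self.data, self.predictors, self.outcome,
                              tol=tol, max_iter=max_iter)
        return FibrosisScoreResults(model=self, fit=fit)


@dataclass
class FibrosisScoreResults:
    """Fitted score with calibration/discrimination diagnostics."""

    model: FibrosisScoreModel
    fit: dv.LogisticFit
    _roc: Optional[dv.RocResult] = field(default=None, repr=False)

    @property
    def params(self) -> pd.Series:
        return self.fit.params

    @property
    def bse(self) -> pd.Series:
        return self.fit.bse

    def predict(self, data: Optional[pd.DataFrame] = None) -> np.ndarray:
        return self.fit.predict(self.model.data if data is None else data)

    def linear_score(self, data: Optional[pd.DataFrame] = None) -> np.ndarray:
        """The fitted linear predictor (the screening score itself)."""
        frame = self.model.data if data is None else data
        eta = np.full(len(frame), self.params["intercept"], dtype=float)
        for name in self.model.predictors:
            eta += self.params[name] * frame[name].to_numpy(dtype=float)
        return eta

    def roc(self) -> dv.RocResult:
        if self._roc is None:
            self._roc = dv.roc_auroc(self.linear_score(), self.model.outcome)
        return self._roc

    def brier(self) -> float:
        return dv.brier_score(self.predict(), self.model.outcome)

    def hosmer_lemeshow(self, groups: int = 10) -> tuple[float, float]:
        return dv.hosmer_lemeshow(self.predict(), self.model.outcome, groups)

    def optimal_cutoff(self) -> float:
        return dv.optimal_cutoff(self.roc())

    def evaluate(self, data: pd.DataFrame, cutoff: Optional[float] = None,
                 ) -> dict[str, float]:
        """Score a held-out cohort at a cut-off (default: Youden-optimal).

        Returns AUROC with CI, Brier, Hosmer-Lemeshow p and the confusion
        metrics at the cut-off (positivity is strict >, matching the
        screening rule convention for derived scores).
        """
        outcome = (data["lsm"].to_numpy(dtype=float) >= self.model.endpoint)
        if outcome.all() or not outcome.any():
            raise DerivationError("data: single-class outcome in evaluation cohort")
        score = self.linear_score(data)
        prob = self.predict(data)
        roc = dv.roc_auroc(score, outcome)
        cut = self.optimal_cutoff() if cutoff is None else float(cutoff)
        positive = score > cut
        tp = int(np.sum(positive & outcome))
        fp = int(np.sum(positive & ~outcome))
        fn = int(np.sum(~positive & outcome))
        tn = int(np.sum(~positive & ~outcome))
        from .scores import ConfusionSummary
        summary = ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)
        hl_stat, hl_p = dv.hosmer_lemeshow(prob, outcome) \
            if len(data) >= 10 else (float("nan"), float("nan"))
        return {
            "auroc": roc.auroc, "auroc_ci_low": roc.ci_low,
            "auroc_ci_high": roc.ci_high,
            "brier": dv.brier_score(prob, outcome),
            "hl_stat": hl_stat, "hl_p": hl_p, "cutoff": cut,
            "sensitivity": summary.sensitivity, "specificity": summary.specificity,
            "ppv": summary.ppv, "npv": summary.npv,
            "fn_rate": summary.fn_rate,
        }

    def summary(self) -> str:
        roc = self.roc()
        hl_stat, hl_p = self.hosmer_lemeshow()
        lines = [
            "Fibrosis screening score (logistic regression)",
            "=" * 54,
            f"Endpoint: LSM >= {self.model.endpoint} kPa   "
            f"n = {len(self.model.data)}   events = {int(self.model.outcome.sum())}",
            f"Converged: {self.fit.converged} "
            f"({self.fit.n_iterations} iterations)   "
            f"logL = {self.fit.log_likelihood:.3f}",
            "-" * 54,
            f"{'term':<12}{'coef':>12}{'std err':>12}",
        ]
        for name in self.params.index:
            lines.append(f"{name:<12}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}")
        lines += [
            "-" * 54,
            f"AUROC = {roc.auroc:.3f} (95% CI {roc.ci_low:.3f}-{roc.ci_high:.3f})",
            f"Brier = {self.brier():.4f}   Hosmer-Lemeshow p = {hl_p:.3f}",
            f"Youden-optimal cut-off = {self.optimal_cutoff():.4f}",
        ]
        return "\n".join(lines)


class CostUtilityModel:
    """Decision-tree + Markov cohort cost-utility model over strategies."""

    def __init__(self, config: Optional[he.EconConfig] = None):
        self.config = config if config is not None else he.load_default_config()
        self.config.validate()

    @classmethod
    def from_yaml(cls, path) -> "CostUtilityModel":
        return cls(he.EconConfig.from_yaml(path))

    def run(self, strategies: Optional[Sequence[str]] = None) -> "CostUtilityResults":
        table = he.evaluate_strategies(self.config, strategies)
        return CostUtilityResults(model=self, table=table)


@dataclass
class CostUtilityResults:
    """Base-case table plus sensitivity-analysis entry points."""

    model: CostUtilityModel
    table: pd.DataFrame

    def psa(self, n_draws: int = 1000, seed: int = 0) -> he.PsaResult:
        return he.psa(self.model.config, n_draws, seed)

    def ceac(self, psa_result: he.PsaResult,
             thresholds: Optional[Sequence[float]] = None) -> pd.DataFrame:
        if thresholds is None:
            thresholds = np.linspace(0.0, 2 * self.model.config.cet, 41)
        return he.ceac(psa_result, thresholds)

    def one_way(self, path: str, values: Sequence[float]) -> pd.DataFrame:
        return he.one_way_sensitivity(self.model.config, path, values)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Cost-utility analysis of screening strategies",
            "=" * 72,
            f"Horizon {cfg.horizon} y   discount {cfg.discount_rate:.1%}   "
            f"cohort {cfg.cohort_size}   CET {cfg.cet:,.0f} GBP/QALY",
            "-" * 72,
            f"{'strategy':<10}{'LY (cohort)':>13}{'dQALY':>10}"
            f"{'cost/pp':>12}{'ICER':>12}  flag",
        ]
        for _, row in self.table.iterrows():
            icer_txt = f"{row.icer_vs_soc:,.0f}" if np.isfinite(row.icer_vs_soc) else "-"
            lines.append(
                f"{row.strategy:<10}{row.discounted_life_years:>13,.1f}"
                f"{row.qalys_gained_vs_soc:>10.1f}{row.cost_per_person:>12,.0f}"
                f"{icer_txt:>12}  {row.icer_flag}")
        return "\n".join(lines)
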