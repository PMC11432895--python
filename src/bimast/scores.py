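"""Fibrosis screening scores and strategy-level classification.

Implements the BIMAST score (0.17*BMI + 0.054*AST - 8.771) together with the
comparator indices used in primary-care fibrosis screening — FIB-4, the NAFLD
fibrosis score (NFS), ELF and transient elastography — and the machinery that
turns a screening strategy (a score with a threshold, or a test with fixed
sensitivity/specificity) into a confusion summary against the stiffness-based
reference standard.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .exceptions import DomainError, StrategyError

__all__ = [
    "ScoreCoefficients",
    "DEFAULT_BIMAST_COEFFICIENTS",
    "NFS_COEFFICIENTS",
    "bimast_score",
    "fib4",
    "nfs",
    "classify",
    "compute_score",
    "StrategyDefinition",
    "default_strategies",
    "ConfusionSummary",
    "apply_strategy",
    "false_negative_rate",
]


@dataclass(frozen=True)
class ScoreCoefficients:
    """Linear BIMAST coefficients: score = intercept + b_bmi*BMI + b_ast*AST."""

    intercept: float = -8.771
    beta_bmi: float = 0.17  # per kg/m2
    beta_ast: float = 0.054  # per IU/L


DEFAULT_BIMAST_COEFFICIENTS = ScoreCoefficients()

#: Standard published NFS coefficients (the formula predates this package and
#: is pinned here so it can be overridden): -1.675 + 0.037*age + 0.094*BMI
#: + 1.13*IFG/diabetes + 0.99*AST/ALT - 0.013*platelets - 0.66*albumin[g/dL].
NFS_COEFFICIENTS = {
    "intercept": -1.675,
    "age": 0.037,
    "bmi": 0.094,
    "diabetes": 1.13,
    "ast_alt_ratio": 0.99,
    "platelets": -0.013,
    "albumin": -0.66,
}


def _require_positive(**values) -> None:
    for name, v in values.items():
        arr = np.asarray(v, dtype=float)
        if not np.all(arr > 0):
            raise DomainError(f"{name}: must be strictly positive")


def bimast_score(bmi, ast, coefficients: ScoreCoefficients = DEFAULT_BIMAST_COEFFICIENTS):
    """BIMAST = intercept + beta_bmi*BMI(kg/m2) + beta_ast*AST(IU/L).

    Strictly increasing in both inputs; vectorised over array inputs.
    """
    _require_positive(bmi=bmi, ast=ast)
    return (coefficients.intercept
            + coefficients.beta_bmi * np.asarray(bmi, dtype=float)
            + coefficients.beta_ast * np.asarray(ast, dtype=float))


def fib4(age, ast, alt, platelets):
    """FIB-4 = age * AST / (platelets[1e9/L] * sqrt(ALT))."""
    _require_positive(age=age, ast=ast, alt=alt, platelets=platelets)
    age = np.asarray(age, dtype=float)
    ast = np.asarray(ast, dtype=float)
    alt = np.asarray(alt, dtype=float)
    platelets = np.asarray(platelets, dtype=float)
    return age * ast / (platelets * np.sqrt(alt))


def nfs(age, bmi, ast, alt, platelets, albumin_g_dl, diabetes=True,
        coefficients: Mapping[str, float] = NFS_COEFFICIENTS):
    """NAFLD fibrosis score; albumin is in g/dL (convert from g/L upstream)."""
    _require_positive(age=age, bmi=bmi, ast=ast, alt=alt,
                      platelets=platelets, albumin_g_dl=albumin_g_dl)
    c = coefficients
    return (c["intercept"]
            + c["age"] * np.asarray(age, dtype=float)
            + c["bmi"] * np.asarray(bmi, dtype=float)
            + c["diabetes"] * np.asarray(diabetes, dtype=float)
            + c["ast_alt_ratio"] * np.asarray(ast, dtype=float) / np.asarray(alt, dtype=float)
            + c["platelets"] * np.asarray(platelets, dtype=float)
            + c["albumin"] * np.asarray(albumin_g_dl, dtype=float))


def classify(value, threshold: float, direction: str):
    """Screening positivity: "greater" is strict (>), "greater_equal" is >=.

    BIMAST/FIB-4/NFS thresholds are strict; ELF and stiffness cut-offs are
    inclusive.
    """
    value = np.asarray(value, dtype=float)
    if direction == "greater":
        return value > threshold
    if direction == "greater_equal":
        return value >= threshold
    raise StrategyError(f"direction: unknown comparison {direction!r}")


def compute_score(cohort: pd.DataFrame, score_name: str,
                  coefficients: Optional[ScoreCoefficients] = None) -> np.ndarray:
    """Evaluate a named score column-wise on a cohort frame.

    The cohort stores albumin in g/L; NFS takes g/dL, converted here.  All
    subjects are diabetic by study inclusion, so the NFS diabetes term is 1.
    """
    if score_name == "bimast":
        return np.asarray(bimast_score(
            cohort["bmi"], cohort["ast"],
            coefficients or DEFAULT_BIMAST_COEFFICIENTS))
    if score_name == "fib4":
        return np.asarray(fib4(cohort["age"], cohort["ast"],
                               cohort["alt"], cohort["platelets"]))
    if score_name == "nfs":
        return np.asarray(nfs(cohort["age"], cohort["bmi"], cohort["ast"],
                              cohort["alt"], cohort["platelets"],
                              cohort["albumin"] / 10.0, diabetes=True))
    if score_name in ("elf", "lsm"):
        return cohort[score_name].to_numpy(dtype=float)
    raise StrategyError(f"score: unknown score {score_name!r}")


@dataclass(frozen=True)
class StrategyDefinition:
    """One screening rule: either a score+threshold or fixed sens/spec.

    Exactly one rule form must be populated.  test_cost is the per-person
    cost (GBP) of administering the first-tier test.
    """

    name: str
    score: Optional[str] = None
    threshold: Optional[float] = None
    direction: str = "greater"
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    test_cost: float = 0.0

    def validate(self) -> None:
        score_form = self.score is not None
        prob_form = self.sensitivity is not None or self.specificity is not None
        if score_form == prob_form:
            raise StrategyError(
                f"strategy {self.name!r}: exactly one of score-rule or "
                f"fixed sens/spec must be given")
        if score_form:
            if self.threshold is None or not np.isfinite(self.threshold):
                raise StrategyError(f"strategy {self.name!r}: threshold must be finite")
            if self.direction not in ("greater", "greater_equal"):
                raise StrategyError(
                    f"strategy {self.name!r}: direction {self.direction!r} unknown")
        else:
            for label, v in (("sensitivity", self.sensitivity),
                             ("specificity", self.specificity)):
                if v is None or not (0.0 <= v <= 1.0):
                    raise StrategyError(
                        f"strategy {self.name!r}: {label} must be in [0, 1], got {v!r}")

    @property
    def is_probabilistic(self) -> bool:
        return self.score is None


def default_strategies() -> dict[str, StrategyDefinition]:
    """The six screening strategies plus standard of care (SOC).

    Score thresholds are the published primary-care cut-offs (FIB-4 > 1.3,
    NFS > -1.45, BIMAST > 0.063 strict; ELF >= 9.8 and LSM >= 8.1 inclusive).
    US+LFTs is a probabilistic proxy at 35% sensitivity / 65% specificity;
    SOC (abnormal-LFTs-or-nothing) is a placeholder half-uptake mix of that
    proxy.  Test costs are placeholder GBP values.
    """
    return {
        "US_LFTS": StrategyDefinition("US_LFTS", sensitivity=0.35, specificity=0.65,
                                      test_cost=60.0),
        "FIB4": StrategyDefinition("FIB4", score="fib4", threshold=1.3,
                                   direction="greater", test_cost=5.0),
        "NFS": StrategyDefinition("NFS", score="nfs", threshold=-1.45,
                                  direction="greater", test_cost=5.0),
        "BIMAST": StrategyDefinition("BIMAST", score="bimast", threshold=0.063,
                                     direction="greater", test_cost=2.0),
        "ELF": StrategyDefinition("ELF", score="elf", threshold=9.8,
                                  direction="greater_equal", test_cost=50.0),
        "TE": StrategyDefinition("TE", score="lsm", threshold=8.1,
                                 direction="greater_equal", test_cost=70.0),
        "SOC": StrategyDefinition("SOC", sensitivity=0.175, specificity=0.825,
                                  test_cost=0.0),
    }


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 screening outcome against the stiffness reference standard."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def ppv(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def npv(self) -> float:
        d = self.tn + self.fn
        return self.tn / d if d else float("nan")

    @property
    def fn_rate(self) -> float:
        d = self.tp + self.fn
        return self.fn / d if d else float("nan")


def apply_strategy(cohort: pd.DataFrame, strategy: StrategyDefinition,
                   truth_threshold: float = 8.1, seed: int = 0) -> ConfusionSummary:
    """Classify every subject under a strategy; truth is LSM >= threshold.

    Score rules are deterministic (seed ignored); fixed-sens/spec rules draw
    one Bernoulli per subject with the stated probabilities, independent of
    biomarkers given disease status.
    """
    strategy.validate()
    if len(cohort) == 0:
        raise StrategyError("cohort: empty cohort cannot be classified")
    if truth_threshold not in (8.1, 12.1):
        raise StrategyError(
            f"truth_threshold: must be 8.1 or 12.1 kPa, got {truth_threshold}")
    truth = cohort["lsm"].to_numpy(dtype=float) >= truth_threshold
    if strategy.is_probabilistic:
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 101])
        u = rng.random(len(cohort))
        positive = np.where(truth, u < strategy.sensitivity,
                            u >= strategy.specificity)
    else:
        values = compute_score(cohort, strategy.score)
        positive = classify(values, strategy.threshold, strategy.direction)
    tp = int(np.sum(positive & truth))
    fp = int(np.sum(positive & ~truth))
    fn = int(np.sum(~positive & truth))
    tn = int(np.sum(~positive & ~truth))
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def false_negative_rate(summary: ConfusionSummary) -> float:
    """Fraction of truly diseased subjects missed at screening: fn/(tp+fn)."""
    if summary.tp + summary.fn == 0:
        raise StrategyError("false_negative_rate: no diseased subjects in summary")
    return summary.fn / (summary.tp + summary.fn)
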