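"""Decision-tree + Markov cohort cost-utility model for fibrosis screening.

A one-off screening test stratifies a diabetic primary-care cohort into
mild/no disease (MLD), significant/advanced liver disease (SLD) and
compensated cirrhosis (CC); diseased subjects missed at screening (false
negatives, `_fn` states) progress faster than diagnosed ones (`_dx`), and
advanced disease can decompensate (DC), develop hepatocellular carcinoma
(HCC), be transplanted (LT) or die.  Annual-cycle Markov dynamics accrue
discounted life-years, QALYs and costs over the horizon; strategies are
compared with incremental cost-effectiveness ratios (ICER) against standard
of care, one-way sensitivity analysis, probabilistic sensitivity analysis
(PSA) and cost-effectiveness acceptability curves (CEAC).

The packaged default parameter set (data/default_econ.yaml) holds clearly
labelled PLACEHOLDER transition/cost/utility values that satisfy every
structural invariant; study-specific values can be transcribed over them.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import EconConfigError

__all__ = [
    "STATES",
    "ALIVE_STATES",
    "EconConfig",
    "StrategyPerformance",
    "load_default_config",
    "build_decision_tree",
    "MarkovResult",
    "run_markov",
    "EconOutcome",
    "evaluate_strategy",
    "evaluate_strategies",
    "IcerResult",
    "icer",
    "one_way_sensitivity",
    "PsaResult",
    "psa",
    "ceac",
]

#: Markov states.  SLD/CC are split by diagnosis status so that slower
#: progression under management is a parameter, not a special case.
STATES = ("MLD", "SLD_dx", "SLD_fn", "CC_dx", "CC_fn", "DC", "HCC", "LT", "DEAD")
ALIVE_STATES = STATES[:-1]
_IDX = {s: i for i, s in enumerate(STATES)}

#: (fn, dx) state pairs whose outgoing progression probabilities must obey
#: fn >= dx (undiagnosed disease progresses at least as fast).
_FN_DX_PAIRS = (("SLD_fn", "SLD_dx"), ("CC_fn", "CC_dx"))


@dataclass(frozen=True)
class StrategyPerformance:
    """Decision-tree inputs for one strategy: operating point and test cost."""

    name: str
    sensitivity: float
    specificity: float
    test_cost: float  # GBP per person screened


@dataclass
class EconConfig:
    """All health-economic model parameters, units in field names or docs.

    transitions: annual disease transition probabilities per state; each
    row's residual mass is the stay-probability.  Background (non-liver)
    mortality is applied multiplicatively on top: effective row =
    (1 - p_bg) * disease_row + p_bg * DEAD.
    """

    prevalence: dict[str, float] = field(default_factory=lambda: {
        "MLD": 0.83, "SLD": 0.14, "CC": 0.03})
    transitions: dict[str, dict[str, float]] = field(default_factory=dict)
    state_costs: dict[str, float] = field(default_factory=dict)  # GBP/year
    state_utilities: dict[str, float] = field(default_factory=dict)  # QALY-weight/year
    strategies: dict[str, StrategyPerformance] = field(default_factory=dict)
    referral_cost: float = 400.0  # GBP per screen-positive referral work-up
    background_mortality: float = 0.015  # annual probability, all alive states
    discount_rate: float = 0.035  # per year
    horizon: int = 40  # years
    cohort_size: int = 287  # persons
    cet: float = 20_000.0  # GBP/QALY
    half_cycle_correction: bool = False
    psa_distributions: dict[str, dict] = field(default_factory=dict)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if abs(sum(self.prevalence.values()) - 1.0) > 1e-12:
            raise EconConfigError(
                f"prevalence: sums to {sum(self.prevalence.values())!r}, not 1")
        for grp in ("MLD", "SLD", "CC"):
            p = self.prevalence.get(grp)
            if p is None or not (0.0 <= p <= 1.0):
                raise EconConfigError(f"prevalence[{grp}]: missing or outside [0, 1]")
        for state in ALIVE_STATES:
            row = self.transitions.get(state, {})
            total = 0.0
            for dest, p in row.items():
                if dest not in _IDX:
                    raise EconConfigError(f"transitions[{state}][{dest}]: unknown state")
                if not (0.0 <= p <= 1.0):
                    raise EconConfigError(
                        f"transitions[{state}][{dest}]: {p} outside [0, 1]")
                total += p
            if total > 1.0 + 1e-12:
                raise EconConfigError(
                    f"transitions[{state}]: outgoing mass {total} exceeds 1")
        for fn_state, dx_state in _FN_DX_PAIRS:
            fn_row = self.transitions.get(fn_state, {})
            dx_row = self.transitions.get(dx_state, {})
            for dest in set(dx_row) | set(fn_row):
                dest_generic = dest.replace("_fn", "").replace("_dx", "")
                fn_p = sum(p for d, p in fn_row.items()
                           if d.replace("_fn", "").replace("_dx", "") == dest_generic)
                dx_p = sum(p for d, p in dx_row.items()
                           if d.replace("_fn", "").replace("_dx", "") == dest_generic)
                if fn_p < dx_p - 1e-12:
                    raise EconConfigError(
                        f"transitions[{fn_state}]: progression to {dest_generic} "
                        f"({fn_p}) slower than diagnosed counterpart ({dx_p})")
        for state in STATES:
            u = self.state_utilities.get(state)
            if u is None or not (0.0 <= u <= 1.0):
                raise EconConfigError(
                    f"state_utilities[{state}]: missing or outside [0, 1]")
            c = self.state_costs.get(state)
            if c is None or c < 0:
                raise EconConfigError(f"state_costs[{state}]: missing or negative")
        if not (0.0 <= self.background_mortality <= 1.0):
            raise EconConfigError(
                f"background_mortality: {self.background_mortality} outside [0, 1]")
        if self.discount_rate < 0:
            raise EconConfigError(f"discount_rate: {self.discount_rate} negative")
        if self.horizon < 1:
            raise EconConfigError(f"horizon: {self.horizon} < 1")
        if self.cohort_size < 1:
            raise EconConfigError(f"cohort_size: {self.cohort_size} < 1")
        if "SOC" not in self.strategies:
            raise EconConfigError("strategies: must include SOC (the comparator)")
        for name, s in self.strategies.items():
            for label, v in (("sensitivity", s.sensitivity),
                             ("specificity", s.specificity)):
                if not (0.0 <= v <= 1.0):
                    raise EconConfigError(
                        f"strategies[{name}].{label}: {v} outside [0, 1]")
            if s.test_cost < 0:
                raise EconConfigError(f"strategies[{name}].test_cost: negative")
        for path, dist in self.psa_distributions.items():
            self._check_psa_entry(path, dist)

    @staticmethod
    def _check_psa_entry(path: str, dist: Mapping) -> None:
        family = dist.get("dist")
        if family == "beta":
            a, b = dist.get("alpha"), dist.get("beta")
            if not (a and b and a > 0 and b > 0):
                raise EconConfigError(
                    f"psa_distributions[{path}]: beta needs alpha, beta > 0")
        elif family == "gamma":
            k, s = dist.get("shape"), dist.get("scale")
            if not (k and s and k > 0 and s > 0):
                raise EconConfigError(
                    f"psa_distributions[{path}]: gamma needs shape, scale > 0")
        elif family == "fixed":
            if "value" not in dist:
                raise EconConfigError(f"psa_distributions[{path}]: fixed needs value")
        else:
            raise EconConfigError(
                f"psa_distributions[{path}]: unknown family {family!r}")

    # -- parameter paths ---------------------------------------------------

    def get_param(self, path: str) -> float:
        obj = self
        parts = path.split(".")
        for i, part in enumerate(parts):
            if isinstance(obj, Mapping):
                if part not in obj:
                    raise EconConfigError(f"parameter path {path!r}: {part!r} not found")
                obj = obj[part]
            elif dataclasses.is_dataclass(obj):
                if not hasattr(obj, part):
                    raise EconConfigError(f"parameter path {path!r}: {part!r} not found")
                obj = getattr(obj, part)
            else:
                raise EconConfigError(f"parameter path {path!r}: cannot descend into {part!r}")
        return obj

    def set_param(self, path: str, value: float) -> None:
        parts = path.split(".")
        obj = self
        for part in parts[:-1]:
            if isinstance(obj, Mapping):
                if part not in obj:
                    raise EconConfigError(f"parameter path {path!r}: {part!r} not found")
                obj = obj[part]
            elif dataclasses.is_dataclass(obj):
                if not hasattr(obj, part):
                    raise EconConfigError(f"parameter path {path!r}: {part!r} not found")
                obj = getattr(obj, part)
            else:
                raise EconConfigError(f"parameter path {path!r}: cannot descend into {part!r}")
        leaf = parts[-1]
        if isinstance(obj, dict):
            obj[leaf] = value
        elif dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            if isinstance(obj, StrategyPerformance):
                # frozen dataclass: replace in the parent strategies dict
                raise EconConfigError(
                    f"parameter path {path!r}: set strategy fields via "
                    f"'strategies.<name>.<field>'")
            if not hasattr(obj, leaf):
                raise EconConfigError(f"parameter path {path!r}: {leaf!r} not found")
            setattr(obj, leaf, value)
        else:
            raise EconConfigError(f"parameter path {path!r}: cannot set {leaf!r}")

    # -- serialisation -----------------------------------------------------

    @classmethod
    def from_dict(cls, doc: Mapping) -> "EconConfig":
        cfg = cls()
        simple = ("prevalence", "transitions", "state_costs", "state_utilities",
                  "referral_cost", "background_mortality", "discount_rate",
                  "horizon", "cohort_size", "cet", "half_cycle_correction",
                  "psa_distributions")
        for key in simple:
            if key in doc:
                setattr(cfg, key, copy.deepcopy(doc[key]))
        if "strategies" in doc:
            cfg.strategies = {}
            for name, s in doc["strategies"].items():
                try:
                    cfg.strategies[name] = StrategyPerformance(
                        name=name, sensitivity=float(s["sensitivity"]),
                        specificity=float(s["specificity"]),
                        test_cost=float(s["test_cost"]))
                except KeyError as err:
                    raise EconConfigError(
                        f"strategies[{name}]: missing field {err.args[0]!r}") from None
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "EconConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise EconConfigError(f"{path}: config is not a mapping")
        return cls.from_dict(doc)

    def to_yaml(self, path) -> None:
        doc = {
            "prevalence": self.prevalence,
            "transitions": self.transitions,
            "state_costs": self.state_costs,
            "state_utilities": self.state_utilities,
            "strategies": {
                n: {"sensitivity": s.sensitivity, "specificity": s.specificity,
                    "test_cost": s.test_cost}
                for n, s in self.strategies.items()},
            "referral_cost": self.referral_cost,
            "background_mortality": self.background_mortality,
            "discount_rate": self.discount_rate,
            "horizon": self.horizon,
            "cohort_size": self.cohort_size,
            "cet": self.cet,
            "half_cycle_correction": self.half_cycle_correction,
            "psa_distributions": self.psa_distributions,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic annual matrix including background mortality."""
        k = len(STATES)
        mat = np.zeros((k, k))
        for state in ALIVE_STATES:
            i = _IDX[state]
            row = self.transitions.get(state, {})
            out = 0.0
            for dest, p in row.items():
                mat[i, _IDX[dest]] = p
                out += p
            mat[i, i] += 1.0 - out  # stay-probability is the residual
            bg = self.background_mortality
            mat[i] *= (1.0 - bg)
            mat[i, _IDX["DEAD"]] += bg
        mat[_IDX["DEAD"], _IDX["DEAD"]] = 1.0
        return mat


def load_default_config() -> EconConfig:
    """The packaged placeholder parameter set."""
    ref = resources.files("bimast").joinpath("data/default_econ.yaml")
    with resources.as_file(ref) as path:
        return EconConfig.from_yaml(path)


# ---------------------------------------------------------------------------
# Decision tree


def build_decision_tree(performance: StrategyPerformance,
                        prevalence: Mapping[str, float],
                        referral_cost: float,
                        ) -> tuple[np.ndarray, float]:
    """Screening-stage split into the initial Markov distribution.

    Diseased & test-positive subjects enter the diagnosed states, diseased &
    test-negative the false-negative states; non-diseased subjects stay in
    MLD, with false positives (1 - specificity of the MLD mass) incurring a
    one-off referral cost.  Returns (initial distribution over STATES,
    upfront cost per person = test cost + referral cost x positive fraction).
    """
    total = sum(prevalence.get(g, 0.0) for g in ("MLD", "SLD", "CC"))
    if abs(total - 1.0) > 1e-9:
        raise EconConfigError(f"prevalence: sums to {total!r}, not 1")
    sens, spec = performance.sensitivity, performance.specificity
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise EconConfigError("sensitivity/specificity must lie in [0, 1]")
    init = np.zeros(len(STATES))
    init[_IDX["MLD"]] = prevalence["MLD"]
    init[_IDX["SLD_dx"]] = prevalence["SLD"] * sens
    init[_IDX["SLD_fn"]] = prevalence["SLD"] * (1.0 - sens)
    init[_IDX["CC_dx"]] = prevalence["CC"] * sens
    init[_IDX["CC_fn"]] = prevalence["CC"] * (1.0 - sens)
    positives = sens * (prevalence["SLD"] + prevalence["CC"]) \
        + (1.0 - spec) * prevalence["MLD"]
    upfront = performance.test_cost + referral_cost * positives
    return init, upfront


# ---------------------------------------------------------------------------
# Markov engine


@dataclass
class MarkovResult:
    """Per-person discounted accruals plus the occupancy trace."""

    life_years: float
    qalys: float
    cost: float  # state-occupancy cost only; upfront cost added by caller
    trace: np.ndarray  # (horizon + 1, n_states) occupancy at cycle starts


def run_markov(initial: np.ndarray, config: EconConfig) -> MarkovResult:
    """Iterate annual cycles, accruing discounted life-years, QALYs, costs.

    Accrual happens at each cycle start (discount factor (1+r)^-t, t = 0, 1,
    ...), then the cohort transitions; with half_cycle_correction the accrual
    uses the mean of the cycle-start and cycle-end occupancies instead.
    Occupancy is conserved to 1e-10 every cycle by construction of the
    row-stochastic matrix.
    """
    init = np.asarray(initial, dtype=float)
    if init.shape != (len(STATES),):
        raise EconConfigError(f"initial distribution: expected {len(STATES)} states")
    if abs(init.sum() - 1.0) > 1e-9 or (init < -1e-12).any():
        raise EconConfigError("initial distribution: not a probability vector")
    mat = config.transition_matrix()
    rowsums = mat.sum(axis=1)
    if np.max(np.abs(rowsums - 1.0)) > 1e-12:
        raise EconConfigError("transitions: matrix is not row-stochastic")

    utilities = np.array([config.state_utilities[s] for s in STATES])
    costs = np.array([config.state_costs[s] for s in STATES])
    alive = np.array([s != "DEAD" for s in STATES], dtype=float)

    occ = init.copy()
    trace = np.empty((config.horizon + 1, len(STATES)))
    ly = qaly = cost = 0.0
    for t in range(config.horizon):
        trace[t] = occ
        nxt = occ @ mat
        exposure = 0.5 * (occ + nxt) if config.half_cycle_correction else occ
        d = (1.0 + config.discount_rate) ** (-t)
        ly += d * float(exposure @ alive)
        qaly += d * float(exposure @ utilities)
        cost += d * float(exposure @ costs)
        occ = nxt
    trace[config.horizon] = occ
    return MarkovResult(life_years=ly, qalys=qaly, cost=cost, trace=trace)


# ---------------------------------------------------------------------------
# Strategy evaluation and ICER


@dataclass
class EconOutcome:
    """One strategy's discounted totals (cohort scale unless noted)."""

    strategy: str
    life_years: float  # cohort total, discounted
    qalys: float  # cohort total, discounted
    cost_per_person: float  # lifetime discounted, incl. upfront screening
    correct_diagnosis_rate: float  # (tp + tn) / n at screening
    cohort_size: int = 287


def evaluate_strategy(name: str, config: EconConfig) -> EconOutcome:
    perf = config.strategies.get(name)
    if perf is None:
        raise EconConfigError(f"strategies[{name}]: not in config")
    init, upfront = build_decision_tree(perf, config.prevalence,
                                        config.referral_cost)
    res = run_markov(init, config)
    prev_diseased = config.prevalence["SLD"] + config.prevalence["CC"]
    correct = perf.sensitivity * prev_diseased \
        + perf.specificity * (1.0 - prev_diseased)
    return EconOutcome(
        strategy=name,
        life_years=res.life_years * config.cohort_size,
        qalys=res.qalys * config.cohort_size,
        cost_per_person=res.cost + upfront,
        correct_diagnosis_rate=correct,
        cohort_size=config.cohort_size,
    )


@dataclass(frozen=True)
class IcerResult:
    """ICER vs comparator, or a dominance/undefined flag instead of a ratio."""

    value: Optional[float]
    flag: Optional[str] = None  # "dominant" | "dominated" | "undefined" | None


def icer(strategy_outcome: EconOutcome, soc_outcome: EconOutcome) -> IcerResult:
    """Incremental cost-effectiveness ratio vs standard of care.

    Dominant (more QALYs, cheaper) and dominated (fewer QALYs, dearer)
    strategies get flags, not ratios; a zero QALY difference is undefined.
    """
    d_cost = strategy_outcome.cost_per_person - soc_outcome.cost_per_person
    d_qaly = strategy_outcome.qalys - soc_outcome.qalys
    if d_qaly == 0:
        return IcerResult(value=None, flag="undefined")
    if d_qaly > 0 and d_cost < 0:
        return IcerResult(value=None, flag="dominant")
    if d_qaly < 0 and d_cost > 0:
        return IcerResult(value=None, flag="dominated")
    # Δcost is per person; scale to the cohort to match cohort-level ΔQALY
    return IcerResult(value=float(d_cost * strategy_outcome.cohort_size / d_qaly),
                      flag=None)


def evaluate_strategies(config: EconConfig,
                        strategies: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Base-case table: one row per strategy with SOC comparisons."""
    config.validate()
    names = list(strategies) if strategies is not None else list(config.strategies)
    if "SOC" not in names:
        names.append("SOC")
    outcomes = {n: evaluate_strategy(n, config) for n in names}
    soc = outcomes["SOC"]
    rows = []
    for n in names:
        o = outcomes[n]
        res = icer(o, soc) if n != "SOC" else IcerResult(None, "undefined")
        rows.append({
            "strategy": n,
            "discounted_life_years": o.life_years,
            "qalys": o.qalys,
            "qalys_gained_vs_soc": o.qalys - soc.qalys,
            "correct_diagnosis_increase_pp":
                (o.correct_diagnosis_rate - soc.correct_diagnosis_rate) * 100.0,
            "cost_per_person": o.cost_per_person,
            "icer_vs_soc": res.value if res.value is not None else np.nan,
            "icer_flag": res.flag or "",
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sensitivity analyses


def one_way_sensitivity(config: EconConfig, path: str,
                        values: Sequence[float]) -> pd.DataFrame:
    """Re-run the full pipeline per grid value of one parameter.

    Returns sorted (value, strategy, icer, flag) rows; grid values violating
    an invariant raise the loader's validation error naming the bound.
    """
    frames = []
    for v in sorted(values):
        cfg = copy.deepcopy(config)
        cfg.set_param(path, v)
        cfg.validate()
        table = evaluate_strategies(cfg)
        table.insert(0, "value", v)
        frames.append(table[["value", "strategy", "icer_vs_soc", "icer_flag"]])
    return pd.concat(frames, ignore_index=True)


@dataclass
class PsaResult:
    """Joint PSA draws: per-draw cohort cost and QALY totals per strategy."""

    strategies: list[str]
    costs: np.ndarray  # (n_draws, n_strategies), cohort totals
    qalys: np.ndarray  # (n_draws, n_strategies), cohort totals
    seed: int


def _draw_psa_params(config: EconConfig, rng: np.random.Generator) -> list[tuple[str, float]]:
    drawn = []
    for path, dist in config.psa_distributions.items():
        family = dist["dist"]
        if family == "beta":
            v = float(rng.beta(dist["alpha"], dist["beta"]))
        elif family == "gamma":
            v = float(rng.gamma(dist["shape"], dist["scale"]))
        else:  # fixed
            v = float(dist["value"])
        drawn.append((path, v))
    return drawn


def psa(config: EconConfig, n_draws: int, seed: int = 0) -> PsaResult:
    """Probabilistic sensitivity analysis with common random numbers.

    Each draw samples every uncertain input from its configured family
    (beta for probabilities/utilities, gamma for costs), rebuilds the
    config, and re-runs decision tree + Markov for every strategy, so all
    strategies see the same parameter draw.
    """
    if n_draws < 1:
        raise EconConfigError(f"n_draws: must be >= 1, got {n_draws}")
    config.validate()
    names = list(config.strategies)
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 202])
    costs = np.empty((n_draws, len(names)))
    qalys = np.empty((n_draws, len(names)))
    for d in range(n_draws):
        cfg = copy.deepcopy(config)
        for path, v in _draw_psa_params(config, rng):
            cfg.set_param(path, v)
        cfg.validate()
        for j, n in enumerate(names):
            o = evaluate_strategy(n, cfg)
            costs[d, j] = o.cost_per_person * cfg.cohort_size
            qalys[d, j] = o.qalys
    return PsaResult(strategies=names, costs=costs, qalys=qalys, seed=seed)


def ceac(result: PsaResult, thresholds: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability: P(strategy maximises NMB) per λ.

    NMB = λ·QALY − cost per draw; at each threshold the probabilities over
    the compared strategies sum to 1.
    """
    grid = np.asarray(thresholds, dtype=float)
    if grid.size == 0:
        raise EconConfigError("thresholds: empty grid")
    if np.any(np.diff(grid) < 0):
        raise EconConfigError("thresholds: grid must be sorted ascending")
    rows = []
    for lam in grid:
        nmb = lam * result.qalys - result.costs
        winner = np.argmax(nmb, axis=1)
        for j, name in enumerate(result.strategies):
            rows.append({"threshold": float(lam), "strategy": name,
                         "probability": float(np.mean(winner == j))})
    return pd.DataFrame(rows)
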