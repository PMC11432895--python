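"""Synthetic diabetic primary-care cohorts with liver-fibrosis structure.

The generator draws patients from a Gaussian copula whose marginals are
conditioned on a latent fibrosis state.  Defaults are calibrated to a
primary-care type-2-diabetes screening population: 17% of subjects have a
liver-stiffness measurement (LSM) >= 8.1 kPa (significant fibrosis), 11%
have LSM >= 12.1 kPa (advanced fibrosis) and 3% are cirrhotic, and the
high-stiffness group carries the higher BMI (36.8 vs 30.3 kg/m2), waist
(120 vs 105 cm) and AST (37 vs 26 IU/L) medians reported for such cohorts.

LSM is drawn from disjoint per-state ranges so the stiffness value and the
fibrosis label can never disagree.  A `spectrum_shift` transform enriches a
spec toward the higher-prevalence, higher-LFT case mix of secondary and
tertiary referral centres.
"""

from __future__ import annotations

import copy
import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import expit

from .exceptions import CohortCSVError, CohortSpecError

__all__ = [
    "FIBROSIS_STATES",
    "FIBROTIC_STATES",
    "LSM_RANGES",
    "BIOMARKERS",
    "COHORT_COLUMNS",
    "Marginal",
    "PatientRecord",
    "CohortSpec",
    "default_spec",
    "generate_cohort",
    "spectrum_shift",
    "spectrum_factor_for_prevalence",
    "simulate_score_outcomes",
    "write_cohort",
    "read_cohort",
]

#: Ordered fibrosis states; "significant" means significant-but-not-advanced.
FIBROSIS_STATES = ("none_or_mild", "significant", "advanced", "cirrhosis")
FIBROTIC_STATES = ("significant", "advanced", "cirrhosis")

#: Disjoint LSM (kPa) support per state: labels and thresholds cannot disagree.
LSM_RANGES = {
    "none_or_mild": (2.0, 8.0),
    "significant": (8.1, 12.0),
    "advanced": (12.1, 25.0),
    "cirrhosis": (25.1, 75.0),
}

#: Continuous biomarkers drawn from the copula, in column order.
BIOMARKERS = ("age", "bmi", "waist", "ast", "alt", "platelets", "albumin", "elf", "lsm")

#: Canonical cohort CSV header.
COHORT_COLUMNS = [
    "id", "age", "sex", "bmi", "waist", "ast", "alt",
    "platelets", "albumin", "elf", "lsm", "fibrosis_state", "has_masld",
]

_THRESHOLD_SIGNIFICANT = 8.1  # kPa
_THRESHOLD_ADVANCED = 12.1  # kPa


@dataclass(frozen=True)
class Marginal:
    """One biomarker's per-state marginal distribution.

    family "normal" is a truncated normal with location `median`; family
    "lognormal" is a truncated normal on the log scale with exp(location)
    = `median` (a right-skewed lab).  `low`/`high` truncate the support.
    """

    family: str  # "normal" | "lognormal"
    median: float
    sigma: float
    low: float = -math.inf
    high: float = math.inf

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.family == "normal":
            a = (self.low - self.median) / self.sigma
            b = (self.high - self.median) / self.sigma
            return stats.truncnorm.ppf(u, a, b, loc=self.median, scale=self.sigma)
        if self.family == "lognormal":
            mu = math.log(self.median)
            lo = math.log(self.low) if self.low > 0 else -math.inf
            hi = math.log(self.high) if math.isfinite(self.high) else math.inf
            a = (lo - mu) / self.sigma
            b = (hi - mu) / self.sigma
            return np.exp(stats.truncnorm.ppf(u, a, b, loc=mu, scale=self.sigma))
        raise CohortSpecError(f"group_params: unknown marginal family {self.family!r}")


@dataclass(frozen=True)
class PatientRecord:
    """One simulated subject: demographics, labs, stiffness, labels."""

    id: str
    age: float
    sex: str
    bmi: float
    waist: float
    ast: float
    alt: float
    platelets: float
    albumin: float  # g/L
    elf: float
    lsm: float  # kPa
    fibrosis_state: str
    has_masld: bool


def _default_group_params() -> dict[str, dict[str, Marginal]]:
    """Per-state marginals.

    Fibrotic states share the printed high-stiffness-group locations for
    BMI/waist/AST so the pooled LSM>=8.1 medians land on the targets;
    platelets/albumin/ELF grade with severity as they do clinically.
    Scales are chosen to give plausible IQRs (medians are the only printed
    summaries for this population).
    """
    none = {
        "age": Marginal("normal", 62.0, 11.0, 25.0, 90.0),
        "bmi": Marginal("normal", 30.3, 5.5, 16.0, 70.0),
        "waist": Marginal("normal", 105.0, 13.0, 60.0, 200.0),
        "ast": Marginal("lognormal", 26.0, 0.35),
        "alt": Marginal("lognormal", 28.0, 0.40),
        "platelets": Marginal("normal", 255.0, 60.0, 30.0, 700.0),
        "albumin": Marginal("normal", 44.0, 3.0, 20.0, 60.0),
        "elf": Marginal("lognormal", 8.8, 0.07),
        "lsm": Marginal("lognormal", 5.0, 0.35, *LSM_RANGES["none_or_mild"]),
    }

    def fibrotic(state: str, platelets: float, albumin: float, elf: float,
                 lsm_median: float, lsm_sigma: float) -> dict[str, Marginal]:
        return {
            "age": Marginal("normal", 63.0, 10.0, 25.0, 90.0),
            "bmi": Marginal("normal", 36.8, 6.0, 16.0, 70.0),
            "waist": Marginal("normal", 120.0, 14.0, 60.0, 200.0),
            "ast": Marginal("lognormal", 37.0, 0.40),
            "alt": Marginal("lognormal", 40.0, 0.45),
            "platelets": Marginal("normal", platelets, 60.0, 30.0, 700.0),
            "albumin": Marginal("normal", albumin, 3.5, 20.0, 60.0),
            "elf": Marginal("lognormal", elf, 0.07),
            "lsm": Marginal("lognormal", lsm_median, lsm_sigma, *LSM_RANGES[state]),
        }

    return {
        "none_or_mild": none,
        "significant": fibrotic("significant", 245.0, 43.0, 9.6, 9.5, 0.12),
        "advanced": fibrotic("advanced", 225.0, 42.0, 10.2, 15.0, 0.20),
        "cirrhosis": fibrotic("cirrhosis", 165.0, 38.0, 11.2, 33.0, 0.25),
    }


#: Spearman rank-correlation targets between biomarkers (within state).
_DEFAULT_CORRELATION = {
    ("bmi", "waist"): 0.80,
    ("ast", "alt"): 0.70,
    ("bmi", "ast"): 0.25,
    ("bmi", "lsm"): 0.30,
    ("ast", "lsm"): 0.35,
    ("elf", "lsm"): 0.40,
    ("platelets", "lsm"): -0.25,
    ("albumin", "lsm"): -0.20,
    ("age", "elf"): 0.30,
}


@dataclass
class CohortSpec:
    """Generative parameters for one synthetic cohort.

    prevalence maps every fibrosis state to its probability (sums to 1);
    spectrum_shift records how far the spec has been pushed from the
    primary-care case mix (0 = primary care).
    """

    n: int = 287
    prevalence: dict[str, float] = field(default_factory=lambda: {
        "none_or_mild": 0.83, "significant": 0.06, "advanced": 0.08, "cirrhosis": 0.03,
    })
    masld_prevalence: float = 0.64
    male_fraction: float = 0.55
    group_params: dict[str, dict[str, Marginal]] = field(default_factory=_default_group_params)
    correlation: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_CORRELATION))
    spectrum_shift: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.n, (int, np.integer)) or self.n < 0:
            raise CohortSpecError(f"n: must be a non-negative integer, got {self.n!r}")
        if set(self.prevalence) != set(FIBROSIS_STATES):
            raise CohortSpecError(
                f"prevalence: must have exactly the states {FIBROSIS_STATES}")
        for state, p in self.prevalence.items():
            if not (0.0 <= p <= 1.0):
                raise CohortSpecError(f"prevalence[{state}]: {p} outside [0, 1]")
        if abs(sum(self.prevalence.values()) - 1.0) > 1e-12:
            raise CohortSpecError(
                f"prevalence: entries sum to {sum(self.prevalence.values())!r}, not 1")
        if not (0.0 <= self.masld_prevalence <= 1.0):
            raise CohortSpecError(f"masld_prevalence: {self.masld_prevalence} outside [0, 1]")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise CohortSpecError(f"male_fraction: {self.male_fraction} outside [0, 1]")
        if self.spectrum_shift < 0:
            raise CohortSpecError(f"spectrum_shift: {self.spectrum_shift} is negative")
        for state in FIBROSIS_STATES:
            if state not in self.group_params:
                raise CohortSpecError(f"group_params: missing state {state!r}")
            for var in BIOMARKERS:
                m = self.group_params[state].get(var)
                if m is None:
                    raise CohortSpecError(f"group_params[{state}]: missing biomarker {var!r}")
                if not (m.sigma > 0):
                    raise CohortSpecError(
                        f"group_params[{state}][{var}].sigma: must be > 0, got {m.sigma}")
        for (a, b), rho in self.correlation.items():
            if a not in BIOMARKERS or b not in BIOMARKERS:
                raise CohortSpecError(f"correlation[{a},{b}]: unknown biomarker")
            if not (-1.0 < rho < 1.0):
                raise CohortSpecError(f"correlation[{a},{b}]: {rho} outside (-1, 1)")

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "n": int(self.n),
            "prevalence": {k: float(v) for k, v in self.prevalence.items()},
            "masld_prevalence": float(self.masld_prevalence),
            "male_fraction": float(self.male_fraction),
            "spectrum_shift": float(self.spectrum_shift),
            "seed": int(self.seed),
            "correlation": {f"{a}:{b}": float(r) for (a, b), r in self.correlation.items()},
            "group_params": {
                s: {v: dataclasses.asdict(m) for v, m in ps.items()}
                for s, ps in self.group_params.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise CohortSpecError("spec file: not a mapping")
        spec = cls()
        for key in ("n", "masld_prevalence", "male_fraction", "spectrum_shift", "seed"):
            if key in doc:
                setattr(spec, key, doc[key])
        if "prevalence" in doc:
            spec.prevalence = {k: float(v) for k, v in doc["prevalence"].items()}
        if "correlation" in doc:
            spec.correlation = {
                tuple(k.split(":")): float(v) for k, v in doc["correlation"].items()}
        if "group_params" in doc:
            spec.group_params = {
                s: {v: Marginal(**m) for v, m in ps.items()}
                for s, ps in doc["group_params"].items()
            }
        spec.validate()
        return spec


def default_spec(n: int = 287, seed: int = 0) -> CohortSpec:
    """The primary-care base case."""
    return CohortSpec(n=n, seed=seed)


# ---------------------------------------------------------------------------
# Copula machinery


def _corr_matrix(spec: CohortSpec) -> np.ndarray:
    """Pearson copula correlation from Spearman targets (2 sin(pi rho / 6))."""
    k = len(BIOMARKERS)
    idx = {v: i for i, v in enumerate(BIOMARKERS)}
    r = np.eye(k)
    for (a, b), rho in spec.correlation.items():
        pearson = 2.0 * math.sin(math.pi * rho / 6.0)
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = pearson
    # nearest-PD repair: clip eigenvalues, restore unit diagonal
    w, v = np.linalg.eigh(r)
    if w.min() < 1e-8:
        w = np.clip(w, 1e-8, None)
        r = (v * w) @ v.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
    return r


def _rng(seed: int, *stream: int) -> np.random.Generator:
    """Deterministic sub-stream of the cohort RNG."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw exactly ``spec.n`` patients; identical spec => identical frame.

    Returns a DataFrame with the canonical cohort columns.  State labels are
    assigned first, then biomarkers are drawn from the state-conditional
    Gaussian copula; the MASLD flag is 1 for every fibrotic subject and
    Bernoulli(masld_prevalence) otherwise.
    """
    spec.validate()
    n = int(spec.n)
    if n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS).astype({"id": str})

    p = np.array([spec.prevalence[s] for s in FIBROSIS_STATES])
    states = _rng(spec.seed, 0).choice(len(FIBROSIS_STATES), size=n, p=p)
    sex = np.where(_rng(spec.seed, 1).random(n) < spec.male_fraction, "male", "female")

    corr = _corr_matrix(spec)
    chol = np.linalg.cholesky(corr)
    x = np.empty((n, len(BIOMARKERS)))
    for si, state in enumerate(FIBROSIS_STATES):
        mask = states == si
        m = int(mask.sum())
        if m == 0:
            continue
        z = _rng(spec.seed, 2, si).standard_normal((m, len(BIOMARKERS))) @ chol.T
        u = stats.norm.cdf(z)
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
        params = spec.group_params[state]
        for vi, var in enumerate(BIOMARKERS):
            x[mask, vi] = params[var].ppf(u[:, vi])

    fibrotic = states > 0
    masld = np.where(
        fibrotic, True, _rng(spec.seed, 3).random(n) < spec.masld_prevalence)

    frame = pd.DataFrame(x, columns=list(BIOMARKERS))
    frame.insert(0, "id", [f"P{i:06d}" for i in range(n)])
    frame.insert(2, "sex", sex)
    frame["fibrosis_state"] = [FIBROSIS_STATES[s] for s in states]
    frame["has_masld"] = masld
    return frame[COHORT_COLUMNS]


# ---------------------------------------------------------------------------
# Spectrum shift


def spectrum_shift(spec: CohortSpec, factor: float) -> CohortSpec:
    """Push a primary-care spec toward a referral-centre case mix.

    Fibrotic prevalences are up-weighted by (1 + factor) and renormalised,
    and AST/ALT/LSM locations move upward (LSM medians slide toward the top
    of each state's band so the disjoint-range invariant is preserved).
    factor = 0 is the identity.
    """
    if factor < 0:
        raise CohortSpecError(f"spectrum_shift factor: {factor} is negative")
    out = copy.deepcopy(spec)
    if factor == 0:
        return out

    w = 1.0 + float(factor)
    prev = {s: spec.prevalence[s] * (w if s in FIBROTIC_STATES else 1.0)
            for s in FIBROSIS_STATES}
    total = sum(prev.values())
    out.prevalence = {s: v / total for s, v in prev.items()}

    lft_scale = 1.0 + 0.10 * factor
    for state in FIBROSIS_STATES:
        params = dict(out.group_params[state])
        for var in ("ast", "alt"):
            m = params[var]
            params[var] = dataclasses.replace(m, median=m.median * lft_scale)
        m = params["lsm"]
        lo, hi = LSM_RANGES[state]
        shifted = hi - (hi - m.median) / (1.0 + 0.20 * factor)
        params["lsm"] = dataclasses.replace(m, median=min(shifted, hi * 0.999))
        out.group_params[state] = params
    out.spectrum_shift = spec.spectrum_shift + float(factor)
    return out


def spectrum_factor_for_prevalence(spec: CohortSpec, target: float,
                                   tol: float = 1e-10) -> float:
    """Bisect the shift factor so P(fibrotic) hits ``target`` exactly.

    Works on the analytic prevalence map (no simulation): with base fibrotic
    mass q, the shifted mass is q(1+f) / (q(1+f) + 1 - q), monotone in f.
    """
    q = sum(spec.prevalence[s] for s in FIBROTIC_STATES)
    if not (q < target < 1.0):
        raise CohortSpecError(
            f"target prevalence {target} not reachable from base {q} by enrichment")
    lo, hi = 0.0, 1.0
    def mass(f: float) -> float:
        return q * (1 + f) / (q * (1 + f) + (1 - q))
    while mass(hi) < target:
        hi *= 2.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mass(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Planted-coefficient simulator (for parameter-recovery experiments)


def simulate_score_outcomes(n: int, coefficients: Sequence[float],
                            seed: int = 0) -> pd.DataFrame:
    """Simulate (bmi, ast, outcome) with outcome ~ Bernoulli(expit(linear)).

    coefficients = (intercept, beta_bmi, beta_ast).  BMI is truncated normal
    around 33 kg/m2, AST log-normal around 30 IU/L, independently drawn —
    a stylised diabetic population with a planted logistic truth, used to
    check that the fitting machinery recovers known coefficients.
    """
    if n < 0:
        raise CohortSpecError(f"n: must be non-negative, got {n}")
    b0, b_bmi, b_ast = (float(c) for c in coefficients)
    rng = _rng(seed, 9)
    u = rng.random((n, 2))
    bmi = Marginal("normal", 33.0, 6.0, 16.0, 70.0).ppf(u[:, 0])
    ast = Marginal("lognormal", 30.0, 0.45).ppf(u[:, 1])
    prob = expit(b0 + b_bmi * bmi + b_ast * ast)
    y = rng.random(n) < prob
    return pd.DataFrame({"bmi": bmi, "ast": ast, "outcome": y.astype(int)})


# ---------------------------------------------------------------------------
# CSV IO

_NUMERIC_COLUMNS = ["age", "bmi", "waist", "ast", "alt", "platelets", "albumin", "elf", "lsm"]
_POSITIVE_LABS = ["bmi", "waist", "ast", "alt", "platelets", "albumin", "elf", "lsm"]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Serialise a cohort to UTF-8 CSV with the canonical header.

    Floats keep 6 significant digits; booleans are written 0/1.
    """
    out = cohort.loc[:, COHORT_COLUMNS].copy()
    out["has_masld"] = out["has_masld"].astype(int)
    out.to_csv(path, index=False, float_format="%.6g", encoding="utf-8")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; errors carry the 1-based data row."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    extra = [c for c in raw.columns if c not in COHORT_COLUMNS]
    if missing:
        raise CohortCSVError(f"{path}: missing columns {missing}")
    if extra:
        raise CohortCSVError(f"{path}: unexpected columns {extra}")
    if raw.empty:
        return pd.DataFrame(columns=COHORT_COLUMNS).astype({"id": str})

    frame = raw.copy()
    for col in _NUMERIC_COLUMNS:
        values = pd.to_numeric(raw[col], errors="coerce")
        bad = values.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise CohortCSVError(
                f"{path}: row {row}: non-numeric value {raw[col].iloc[row - 1]!r} "
                f"in column {col!r}")
        frame[col] = values.astype(float)
    frame["has_masld"] = raw["has_masld"].isin(["1", "True", "true"])

    def _first_bad(mask: np.ndarray, message: str) -> None:
        if mask.any():
            row = int(np.flatnonzero(mask)[0])
            raise CohortCSVError(f"{path}: row {row + 1}: " + message.format(row=row))

    for col in _POSITIVE_LABS:
        _first_bad(~(frame[col].to_numpy() > 0),
                   f"{col} is not strictly positive")
    state = frame["fibrosis_state"]
    _first_bad(~state.isin(FIBROSIS_STATES).to_numpy(),
               "unknown fibrosis_state")
    lsm = frame["lsm"].to_numpy()
    fibrotic = state.isin(FIBROTIC_STATES).to_numpy()
    advanced = state.isin(["advanced", "cirrhosis"]).to_numpy()
    _first_bad((lsm >= _THRESHOLD_SIGNIFICANT) != fibrotic,
               "lsm inconsistent with fibrosis_state at the 8.1 kPa threshold")
    _first_bad((lsm >= _THRESHOLD_ADVANCED) != advanced,
               "lsm inconsistent with fibrosis_state at the 12.1 kPa threshold")
    return frame[COHORT_COLUMNS]
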