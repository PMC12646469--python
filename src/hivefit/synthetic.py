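"""Synthetic cohort generation.

The study cohort (n = 162 women undergoing IVF) is private, so every
downstream stage of the package is exercised on synthetic cohorts that
reproduce the published marginal summary statistics: Bernoulli prevalences
for the 20 binary indicators, an integer age drawn from a truncated normal
on [24, 43] with mean 34.36 and SD 4.58, and an over-dispersed oocyte count
(mean 7.58, SD 9.81, range [0, 58]) modelled as a truncated negative
binomial whose post-truncation moments are calibrated to the printed values.

The binary outcome carries a configurable planted logistic signal:
P(success) = sigmoid(b0 + z'beta) where z are predictors standardized under
the marginal specification, so effect sizes are comparable across binary and
count features. With beta = 0 and a calibrated intercept the generator is an
exact null model at the published 0.38 outcome prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .cohort import BINARY_FEATURES, FEATURE_ORDER, OUTCOME_NAME, CohortTable, RDIEntry

#: Published prevalences of the binary predictors, in canonical feature order.
PUBLISHED_PREVALENCES: dict[str, float] = {
    "working_status": 0.72,
    "diagnosed_illness": 0.35,
    "dha": 0.72,
    "omega3": 0.39,
    "folic_acid": 0.10,
    "coq10": 0.30,
    "vit_b12": 0.03,
    "ferritin": 0.04,
    "vit_c": 0.03,
    "vit_b6": 0.03,
    "vit_b5": 0.006,
    "vit_d": 0.09,
    "phytoalexin": 0.02,
    "magnesium": 0.04,
    "selenium": 0.03,
    "zinc": 0.02,
    "melatonin": 0.006,
    "exercise": 0.24,
    "embryo_quality": 0.44,
    "dietician_support": 0.25,
}

PUBLISHED_AGE = {"mean": 34.36, "sd": 4.58, "lo": 24, "hi": 43}
PUBLISHED_OOCYTE = {"mean": 7.58, "sd": 9.81, "hi": 58}
PUBLISHED_OUTCOME_PREVALENCE = 0.38


@dataclass(frozen=True)
class MarginalSpec:
    """Per-feature marginal distributions for the generator."""

    binary_prevalence: dict[str, float]
    age_mean: float
    age_sd: float
    age_lo: int
    age_hi: int
    oocyte_mean: float
    oocyte_sd: float
    oocyte_hi: int

    def __post_init__(self) -> None:
        for name, p in self.binary_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {name!r} outside [0, 1]: {p}")
        if self.age_sd <= 0 or self.oocyte_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if self.age_lo > self.age_hi:
            raise ValueError("age_lo > age_hi")
        if self.oocyte_sd**2 <= self.oocyte_mean:
            raise ValueError(
                "oocyte variance must exceed the mean for a negative binomial"
            )


@dataclass(frozen=True)
class OutcomeModelSpec:
    """Planted logistic outcome model over standardized predictors."""

    beta: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    target_prevalence: float | None = None

    def __post_init__(self) -> None:
        for name, b in self.beta.items():
            if name not in FEATURE_ORDER:
                raise ValueError(f"unknown predictor {name!r} in outcome beta")
            if not np.isfinite(b):
                raise ValueError(f"non-finite coefficient for {name!r}")

    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta.get(f, 0.0) for f in FEATURE_ORDER])


@dataclass(frozen=True)
class SyntheticConfig:
    n: int
    seed: int
    marginals: MarginalSpec
    outcome: OutcomeModelSpec = field(default_factory=OutcomeModelSpec)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("cohort size n must be non-negative")


def default_marginals() -> MarginalSpec:
    """Marginal specification matching the published cohort summary table."""
    return MarginalSpec(
        binary_prevalence=dict(PUBLISHED_PREVALENCES),
        age_mean=PUBLISHED_AGE["mean"],
        age_sd=PUBLISHED_AGE["sd"],
        age_lo=PUBLISHED_AGE["lo"],
        age_hi=PUBLISHED_AGE["hi"],
        oocyte_mean=PUBLISHED_OOCYTE["mean"],
        oocyte_sd=PUBLISHED_OOCYTE["sd"],
        oocyte_hi=PUBLISHED_OOCYTE["hi"],
    )


def default_config(
    n: int = 162,
    seed: int = 0,
    beta: dict[str, float] | None = None,
    target_prevalence: float = PUBLISHED_OUTCOME_PREVALENCE,
) -> SyntheticConfig:
    """Convenience constructor for study-condition cohorts."""
    return SyntheticConfig(
        n=n,
        seed=seed,
        marginals=default_marginals(),
        outcome=OutcomeModelSpec(
            beta=beta or {}, target_prevalence=target_prevalence
        ),
    )


# ----------------------------------------------------------------------
# Truncated negative binomial for the oocyte count
# ----------------------------------------------------------------------

def _nb_params(mean: float, var: float) -> tuple[float, float]:
    """scipy (n, p) parameterization from (mean, variance), variance > mean."""
    p = mean / var
    n = mean * p / (1.0 - p)
    return n, p


def _truncated_nb_pmf(mean: float, var: float, hi: int) -> np.ndarray:
    n, p = _nb_params(mean, var)
    k = np.arange(hi + 1)
    pmf = stats.nbinom.pmf(k, n, p)
    return pmf / pmf.sum()


@lru_cache(maxsize=32)
def calibrate_truncated_nb(
    target_mean: float, target_sd: float, hi: int
) -> tuple[float, float]:
    """Untruncated (mean, variance) whose [0, hi]-truncated pmf matches the
    target post-truncation moments.

    Solved as a 2-D least-squares problem on the exact truncated pmf moments
    (truncation pulls both moments down, so both untruncated parameters must
    be free).
    """

    def resid(x):
        m, extra = np.exp(x)
        var = m + extra
        pmf = _truncated_nb_pmf(m, var, hi)
        k = np.arange(hi + 1)
        mu = float(pmf @ k)
        sd = float(np.sqrt(pmf @ (k - mu) ** 2))
        return [mu - target_mean, sd - target_sd]

    x0 = np.log([target_mean, target_sd**2 - target_mean])
    sol = optimize.least_squares(resid, x0, xtol=1e-12, ftol=1e-12)
    if not sol.success or float(np.abs(sol.fun).max()) > 1e-6:
        raise RuntimeError(f"truncated NB calibration failed: {sol.message}")
    m, extra = np.exp(sol.x)
    return float(m), float(m + extra)


# ----------------------------------------------------------------------
# Standardization moments implied by the marginals
# ----------------------------------------------------------------------

def marginal_moments(spec: MarginalSpec) -> tuple[np.ndarray, np.ndarray]:
    """(mean, sd) per predictor under the spec, in canonical order.

    Binary features use the exact Bernoulli moments; age and oocyte count use
    the calibrated post-truncation targets. Used to standardize predictors in
    the planted outcome model.
    """
    means, sds = [], []
    for f in FEATURE_ORDER:
        if f in spec.binary_prevalence:
            p = spec.binary_prevalence[f]
            means.append(p)
            sds.append(max(np.sqrt(p * (1 - p)), 1e-12))
        elif f == "age":
            means.append(spec.age_mean)
            sds.append(spec.age_sd)
        elif f == "oocyte_count":
            means.append(spec.oocyte_mean)
            sds.append(spec.oocyte_sd)
        else:  # pragma: no cover - schema guard
            raise KeyError(f)
    return np.array(means), np.array(sds)


# ----------------------------------------------------------------------
# Sampling
# ----------------------------------------------------------------------

def _draw_predictors(
    spec: MarginalSpec, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for f in BINARY_FEATURES:
        cols[f] = (rng.random(n) < spec.binary_prevalence[f]).astype(int)

    a = (spec.age_lo - 0.5 - spec.age_mean) / spec.age_sd
    b = (spec.age_hi + 0.5 - spec.age_mean) / spec.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=spec.age_mean, scale=spec.age_sd, size=n, random_state=rng
    )
    cols["age"] = np.clip(np.rint(age), spec.age_lo, spec.age_hi).astype(int)

    m0, v0 = calibrate_truncated_nb(spec.oocyte_mean, spec.oocyte_sd, spec.oocyte_hi)
    pmf = _truncated_nb_pmf(m0, v0, spec.oocyte_hi)
    cols["oocyte_count"] = rng.choice(spec.oocyte_hi + 1, size=n, p=pmf)

    return pd.DataFrame({f: cols[f] for f in FEATURE_ORDER})


def _linear_predictor(
    X: pd.DataFrame, spec: MarginalSpec, outcome: OutcomeModelSpec
) -> np.ndarray:
    means, sds = marginal_moments(spec)
    Z = (X.to_numpy(dtype=float) - means) / sds
    return Z @ outcome.beta_vector()


def calibrate_intercept(
    config: SyntheticConfig,
    target_prevalence: float | None = None,
    mc_n: int = 100_000,
    seed: int | None = None,
    tol: float = 1e-4,
) -> float:
    """Intercept b0 such that the population outcome prevalence matches the target.

    With a null signal (beta = 0) this is the closed form logit(target). With
    a planted signal the marginal prevalence is the expectation of
    sigmoid(b0 + z'beta) over the predictor distribution, estimated by Monte
    Carlo on a fixed draw and solved by bracketing root search (monotone in
    b0, so the result is deterministic for a fixed seed).
    """
    target = (
        target_prevalence
        if target_prevalence is not None
        else config.outcome.target_prevalence
    )
    if target is None or not 0.0 < target < 1.0:
        raise ValueError(f"target prevalence must be in (0, 1), got {target}")

    beta = config.outcome.beta_vector()
    if not np.any(beta):
        return float(logit(target))

    rng = np.random.default_rng(config.seed if seed is None else seed)
    X = _draw_predictors(config.marginals, mc_n, rng)
    s = _linear_predictor(X, config.marginals, config.outcome)

    def g(b0: float) -> float:
        return float(expit(b0 + s).mean()) - target

    lo, hi = -20.0, 20.0
    if g(lo) > 0 or g(hi) < 0:
        raise RuntimeError(
            f"intercept bracket [-20, 20] does not enclose the root: "
            f"g(-20)={g(lo):.4g}, g(20)={g(hi):.4g}"
        )
    b0 = optimize.brentq(g, lo, hi, xtol=tol / 10)
    return float(b0)


def generate_cohort(config: SyntheticConfig) -> CohortTable:
    """Draw a cohort under the marginal spec and planted outcome model.

    The outcome is Bernoulli(sigmoid(b0 + z'beta)); if the outcome spec sets a
    target prevalence the intercept is calibrated first (overriding any stored
    intercept). Fixed seed implies a byte-identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    X = _draw_predictors(config.marginals, config.n, rng)

    if config.outcome.target_prevalence is not None:
        b0 = calibrate_intercept(config)
    else:
        b0 = config.outcome.intercept

    s = _linear_predictor(X, config.marginals, config.outcome) if config.n else np.array([])
    prob = expit(b0 + s)
    y = (rng.random(config.n) < prob).astype(int)

    frame = X.copy()
    frame[OUTCOME_NAME] = y
    return CohortTable(
        frame,
        provenance=f"synthetic(n={config.n}, seed={config.seed})",
    )


def null_config(n: int, seed: int) -> SyntheticConfig:
    """Null-signal study-condition cohort config (beta = 0, prevalence 0.38)."""
    return default_config(n=n, seed=seed, beta=None)


def planted_config(
    n: int, seed: int, beta: dict[str, float]
) -> SyntheticConfig:
    """Study-condition config with a planted signal on named predictors."""
    return default_config(n=n, seed=seed, beta=beta)


# ----------------------------------------------------------------------
# Intake fixtures for the binarization stage
# ----------------------------------------------------------------------

def generate_intake_fixture(
    flags: pd.DataFrame,
    rdi: list[RDIEntry],
    seed: int = 0,
):
    """Construct intake records whose binarization reproduces ``flags`` exactly.

    ``flags`` is a patients-by-ingredients {0,1} frame (index = patient ids).
    For a 1 the total amount is drawn in [100%, 300%] of the requirement; for
    a 0 either no record is emitted or a sub-threshold one in [0%, 99%].
    """
    from .cohort import IntakeRecord

    if not flags.isin([0, 1]).all().all():
        raise ValueError("requested flags must be binary")
    rdi_map = {e.ingredient: e for e in rdi}
    unknown = [c for c in flags.columns if c not in rdi_map]
    if unknown:
        raise ValueError(f"flags reference ingredients without an RDI entry: {unknown}")

    rng = np.random.default_rng(seed)
    records: list[IntakeRecord] = []
    for pid, row in flags.iterrows():
        amounts: dict[str, float] = {}
        units: dict[str, str] = {}
        for ing, flag in row.items():
            entry = rdi_map[ing]
            if flag == 1:
                frac = rng.uniform(1.0, 3.0)
            else:
                if rng.random() < 0.5:
                    continue  # no record at all
                frac = rng.uniform(0.0, 0.99)
            amounts[ing] = frac * entry.daily_requirement
            units[ing] = entry.unit
        if amounts:
            records.append(
                IntakeRecord(str(pid), f"product_{pid}", amounts, units)
            )
    return records


def write_intake_records(records, path) -> None:
    rows = []
    for rec in records:
        for ing, amt in rec.ingredient_amounts.items():
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "product": rec.product,
                    "ingredient": ing,
                    "amount": amt,
                    "unit": rec.unit.get(ing, ""),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


__all__ = [
    "MarginalSpec",
    "OutcomeModelSpec",
    "SyntheticConfig",
    "PUBLISHED_PREVALENCES",
    "PUBLISHED_OUTCOME_PREVALENCE",
    "default_marginals",
    "default_config",
    "null_config",
    "planted_config",
    "calibrate_intercept",
    "calibrate_truncated_nb",
    "marginal_moments",
    "generate_cohort",
    "generate_intake_fixture",
    "write_intake_records",
]
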