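"""Local surrogate explanations.

For one patient, the fitted model's probability surface is probed in a
neighborhood of the instance: binary features are resampled uniformly from
{0, 1} (prevalence-based resampling available by flag), continuous features
are jittered by the cohort SD, and each perturbed row is weighted by an RBF
proximity kernel exp(-d^2 / width^2) on normalized Euclidean distance. A
ridge-stabilized weighted linear model on the top-K screened features is
then fit to the model's probabilities; its signed coefficients are the
per-feature contributions and its weighted R^2 the local fidelity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort import BINARY_FEATURES, FEATURE_ORDER

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExplainConfig:
    n_perturbations: int = 2000
    kernel_width: float | None = None  # default 0.75 * sqrt(p)
    max_features: int = 10
    seed: int = 0
    binary_sampling: str = "uniform"  # or "prevalence"
    ridge: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_perturbations < 10:
            raise ValueError("n_perturbations must be >= 10")
        if self.kernel_width is not None and self.kernel_width <= 0:
            raise ValueError("kernel width must be positive")

    def width(self, p: int) -> float:
        return self.kernel_width if self.kernel_width is not None else 0.75 * np.sqrt(p)


@dataclass
class Explanation:
    instance_id: str
    predicted_class: int
    predicted_probability: float
    contributions: list[tuple[str, float]]
    intercept: float
    fidelity: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "instance": self.instance_id,
                "predicted_class": self.predicted_class,
                "predicted_probability": self.predicted_probability,
                "contributions": [[f, w] for f, w in self.contributions],
                "intercept": self.intercept,
                "fidelity": self.fidelity,
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [
            f"Instance {self.instance_id}: predicted class "
            f"{self.predicted_class} with probability "
            f"{self.predicted_probability:.2f} (local fidelity R^2 = "
            f"{self.fidelity:.3f})"
        ]
        for feat, w in self.contributions:
            lines.append(f"  {feat}: {w:+.3f}")
        return "\n".join(lines)


@dataclass
class CohortStats:
    """Per-feature means/SDs and binary prevalences used for perturbation."""

    means: np.ndarray
    sds: np.ndarray
    is_binary: np.ndarray
    prevalences: np.ndarray

    @classmethod
    def from_matrix(cls, X: np.ndarray, feature_names=FEATURE_ORDER) -> "CohortStats":
        X = np.asarray(X, dtype=float)
        is_binary = np.array([f in BINARY_FEATURES for f in feature_names])
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1) if len(X) > 1 else np.zeros(X.shape[1])
        return cls(means, sds, is_binary, np.where(is_binary, means, 0.0))


def perturb_samples(
    instance: np.ndarray, stats: CohortStats, config: ExplainConfig, p: int | None = None
):
    """Perturbed design around the instance plus proximity weights.

    The first row is the unperturbed instance itself (weight exactly 1).
    Binary features are flipped with probability 0.5 relative to the
    instance (uniform resampling); continuous features receive Gaussian
    jitter scaled by the cohort SD, with zero-SD features left unperturbed.
    """
    instance = np.asarray(instance, dtype=float)
    p = len(instance)
    rng = np.random.default_rng(config.seed)
    n = config.n_perturbations

    Z = np.tile(instance, (n, 1))
    for j in range(p):
        if stats.is_binary[j]:
            if config.binary_sampling == "prevalence":
                Z[1:, j] = (rng.random(n - 1) < stats.prevalences[j]).astype(float)
            else:
                Z[1:, j] = rng.integers(0, 2, size=n - 1).astype(float)
        else:
            if stats.sds[j] == 0:
                logger.debug("feature %d has zero SD; left unperturbed", j)
                continue
            Z[1:, j] = instance[j] + rng.normal(0.0, stats.sds[j], size=n - 1)

    scale = np.where(stats.sds > 0, stats.sds, 1.0)
    d = np.sqrt(np.sum(((Z - instance) / scale) ** 2, axis=1))
    width = config.width(p)
    weights = np.exp(-(d**2) / width**2)
    return Z, weights


def fit_surrogate(
    Z: np.ndarray,
    probs: np.ndarray,
    weights: np.ndarray,
    config: ExplainConfig,
    candidate_features: np.ndarray | None = None,
):
    """Ridge-stabilized weighted least squares on the top-K screened features.

    K = ``max_features`` columns are chosen by largest absolute weighted
    univariate covariance with the model probabilities (deterministic);
    fidelity is the weighted R^2 of the surrogate. Fewer than two distinct
    probability values trigger the constant-model shortcut (all weights 0,
    fidelity 1).
    """
    Z = np.asarray(Z, dtype=float)
    probs = np.asarray(probs, dtype=float)
    weights = np.asarray(weights, dtype=float)
    p = Z.shape[1]
    coefs = np.zeros(p)

    if len(np.unique(probs)) < 2:
        return coefs, float(probs.mean()), 1.0

    w = weights / weights.sum()
    mu_y = float(w @ probs)
    mu_z = w @ Z
    cov = (w * (probs - mu_y)) @ (Z - mu_z)

    candidates = (
        np.arange(p) if candidate_features is None else np.asarray(candidate_features)
    )
    order = candidates[np.argsort(-np.abs(cov[candidates]), kind="stable")]
    selected = np.sort(order[: config.max_features])

    A = np.column_stack([np.ones(len(Z)), Z[:, selected]])
    sw = np.sqrt(weights)
    Aw = A * sw[:, None]
    yw = probs * sw
    # ridge on the slope block only (not the intercept)
    k = A.shape[1]
    reg = np.sqrt(config.ridge) * np.eye(k)
    reg[0, 0] = 0.0
    A_aug = np.vstack([Aw, reg])
    y_aug = np.concatenate([yw, np.zeros(k)])
    beta, *_ = np.linalg.lstsq(A_aug, y_aug, rcond=None)

    intercept = float(beta[0])
    coefs[selected] = beta[1:]

    fitted = A @ beta
    ss_res = float(weights @ (probs - fitted) ** 2)
    ss_tot = float(weights @ (probs - mu_y) ** 2)
    fidelity = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return coefs, intercept, fidelity


def explain_instance(
    model,
    instance: np.ndarray,
    stats: CohortStats,
    config: ExplainConfig | None = None,
    feature_names=FEATURE_ORDER,
    instance_id: str = "0",
) -> Explanation:
    """End-to-end local explanation of one fitted model prediction.

    Features outside the model's applied mask cannot influence the
    prediction and are excluded from the surrogate, so their reported weight
    is exactly 0. The contribution list is ranked by |weight| descending,
    ties broken by feature order, and truncated to ``max_features``.
    """
    config = config or ExplainConfig()
    instance = np.asarray(instance, dtype=float)
    Z, weights = perturb_samples(instance, stats, config)
    probs = np.asarray(model.predict_proba(Z), dtype=float)

    candidates = None
    mask = getattr(model, "mask_", None)
    if mask is not None:
        candidates = mask.indices

    coefs, intercept, fidelity = fit_surrogate(Z, probs, weights, config, candidates)

    nonzero = np.flatnonzero(coefs)
    order = nonzero[np.argsort(-np.abs(coefs[nonzero]), kind="stable")]
    contributions = [(feature_names[j], float(coefs[j])) for j in order]
    contributions = contributions[: config.max_features]

    prob1 = float(probs[0])
    return Explanation(
        instance_id=instance_id,
        predicted_class=int(prob1 >= 0.5),
        predicted_probability=prob1 if prob1 >= 0.5 else 1 - prob1,
        contributions=contributions,
        intercept=intercept,
        fidelity=fidelity,
    )
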