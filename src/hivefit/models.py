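"""Hybrid classifier stages.

Three model stages behind one fit/predict contract:

* ``simple`` — a base learner (KNN, CART, SVM or RF) on all predictors;
* ``lr_hybrid`` — L1-penalized logistic regression selects a feature subset,
  then the base learner is trained on the masked predictors;
* ``abc_lr_hybrid`` — an artificial-bee-colony search over binary feature
  masks, scored by inner stratified cross-validation of the base learner
  (with minority oversampling applied inside inner training folds), picks
  the mask; the base learner is then trained on it.

All stages accept the original predictor matrix at predict time and apply
their mask internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .abc_opt import (
    ABCConfig,
    ArtificialBeeColony,
    INFEASIBLE_OBJECTIVE,
    OptimizeResult,
    SearchSpace,
    decode_mask,
)
from .cohort import FEATURE_ORDER

STAGES = ("simple", "lr_hybrid", "abc_lr_hybrid")
BASE_LEARNERS = ("knn", "cart", "svm", "rf")

#: Feature subset reported by the study's L1 logistic selection stage,
#: shipped as a named fixture mask for downstream tests and warm starts.
L1_FIXTURE_FEATURES: tuple[str, ...] = (
    "omega3",
    "folic_acid",
    "coq10",
    "vit_b12",
    "vit_c",
    "vit_b6",
    "vit_d",
    "phytoalexin",
    "selenium",
    "zinc",
    "dietician_support",
)


class ConfigurationError(ValueError):
    pass


class NotFittedError(RuntimeError):
    pass


@dataclass
class FeatureMask:
    """Binary inclusion vector aligned to the cohort feature order."""

    values: np.ndarray
    provenance: str = "manual"  # l1_selection | abc_search | manual

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if not np.isin(self.values, [0, 1]).all():
            raise ValueError("mask values must be binary")

    @property
    def feasible(self) -> bool:
        return bool(self.values.any())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.values)

    @property
    def n_selected(self) -> int:
        return int(self.values.sum())

    def feature_names(self, names=FEATURE_ORDER) -> list[str]:
        return [names[i] for i in self.indices]


def l1_fixture_mask() -> FeatureMask:
    values = np.array(
        [1 if f in L1_FIXTURE_FEATURES else 0 for f in FEATURE_ORDER]
    )
    return FeatureMask(values, provenance="l1_selection")


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one (stage, base learner) cell of the comparison grid."""

    stage: str = "simple"
    base_learner: str = "rf"
    base_params: dict = field(default_factory=dict)
    l1_strength: float = 1.0
    abc: ABCConfig = field(default_factory=ABCConfig)
    inner_cv: int = 3
    fitness_metric: str = "f1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ConfigurationError(f"unknown stage {self.stage!r}")
        if self.base_learner not in BASE_LEARNERS:
            raise ConfigurationError(f"unknown base learner {self.base_learner!r}")
        if self.inner_cv < 2:
            raise ConfigurationError("inner_cv must be >= 2")

    @property
    def name(self) -> str:
        base = self.base_learner.upper()
        if self.stage == "simple":
            return base
        if self.stage == "lr_hybrid":
            return f"LR-{base}"
        return f"ABC-LR-{base}"


def model_grid(
    stages=STAGES, bases=BASE_LEARNERS, seed: int = 0, **kwargs
) -> list[ModelSpec]:
    """The full stage-by-base comparison grid (12 specs at defaults)."""
    return [
        ModelSpec(stage=s, base_learner=b, seed=seed, **kwargs)
        for s in stages
        for b in bases
    ]


# ----------------------------------------------------------------------
# Base learners
# ----------------------------------------------------------------------

def make_base_learner(name: str, seed: int = 0, params: dict | None = None):
    params = dict(params or {})
    if name == "knn":
        return KNeighborsClassifier(**params)
    if name == "cart":
        return DecisionTreeClassifier(random_state=seed, **params)
    if name == "rf":
        return RandomForestClassifier(random_state=seed, **params)
    if name == "svm":
        return SVC(random_state=seed, **params)
    raise ConfigurationError(f"unknown base learner {name!r}")


class _PlattScaledSVM:
    """SVM with probabilities via a logistic link fitted on training
    decision-function scores, so calibration metrics are computable."""

    def __init__(self, seed: int = 0, params: dict | None = None) -> None:
        self.svm = SVC(random_state=seed, **(params or {}))
        self.link = LogisticRegression()

    def fit(self, X, y):
        self.svm.fit(X, y)
        scores = self.svm.decision_function(X).reshape(-1, 1)
        if len(np.unique(y)) < 2:
            raise ValueError("single-class training labels")
        self.link.fit(scores, y)
        return self

    def predict_proba(self, X):
        scores = self.svm.decision_function(X).reshape(-1, 1)
        return self.link.predict_proba(scores)

    def predict(self, X):
        return self.svm.predict(X)


def _make_estimator(spec: ModelSpec):
    if spec.base_learner == "svm":
        return _PlattScaledSVM(seed=spec.seed, params=spec.base_params)
    return make_base_learner(spec.base_learner, seed=spec.seed, params=spec.base_params)


# ----------------------------------------------------------------------
# L1 selection
# ----------------------------------------------------------------------

def l1_select(
    X: np.ndarray, y: np.ndarray, strength: float = 1.0, seed: int = 0
) -> FeatureMask:
    """Feature mask from the nonzero coefficients of an L1-penalized
    logistic regression at regularization strength ``strength`` (C = 1/strength).

    An empty mask (everything shrunk to zero) is returned with its
    infeasible flag so the caller decides the fallback.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("l1_select requires both outcome classes")
    lr = LogisticRegression(
        l1_ratio=1,
        C=1.0 / strength,
        solver="liblinear",
        random_state=seed,
        max_iter=2000,
    )
    lr.fit(X, y)
    mask = (np.abs(lr.coef_[0]) > 0).astype(int)
    return FeatureMask(mask, provenance="l1_selection")


# ----------------------------------------------------------------------
# Inner-CV fitness and the ABC mask search
# ----------------------------------------------------------------------

_METRICS = {
    "f1": f1_score,
    "accuracy": accuracy_score,
    "recall": recall_score,
    "precision": precision_score,
}


def _inner_cv_score(
    X, y, mask: np.ndarray, spec: ModelSpec, folds, resample: bool
) -> float:
    """Mean inner-CV score of the base learner on the masked predictors.

    Minority oversampling (when enabled) happens strictly inside each inner
    training fold; inner test folds stay untouched.
    """
    from .evaluation import smote_oversample

    cols = np.flatnonzero(mask)
    scorer = _METRICS[spec.fitness_metric]
    scores = []
    for f, (tr, te) in enumerate(folds):
        X_tr, y_tr = X[np.ix_(tr, cols)], y[tr]
        if resample:
            X_tr, y_tr = smote_oversample(
                X_tr, y_tr, seed=spec.seed * 1000 + f
            )
        est = _make_estimator(spec)
        est.fit(X_tr, y_tr)
        pred = est.predict(X[np.ix_(te, cols)])
        if spec.fitness_metric == "accuracy":
            scores.append(scorer(y[te], pred))
        else:
            scores.append(scorer(y[te], pred, zero_division=0))
    return float(np.mean(scores))


def abc_feature_search(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    warm_start: FeatureMask | None = None,
    resample: bool = True,
) -> tuple[FeatureMask, OptimizeResult]:
    """ABC search over binary feature masks, minimizing 1 - mean inner-CV score.

    Inner folds are fixed once (stratified, seeded) so every mask is scored
    on identical partitions; mask objectives are memoized, since one-coordinate
    moves often leave the decoded mask unchanged.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("abc_feature_search requires both outcome classes")
    p = X.shape[1]
    skf = StratifiedKFold(n_splits=spec.inner_cv, shuffle=True, random_state=spec.seed)
    folds = list(skf.split(X, y))

    cache: dict[bytes, float] = {}

    def objective(mask: np.ndarray) -> float:
        key = mask.astype(np.int8).tobytes()
        if key not in cache:
            cache[key] = 1.0 - _inner_cv_score(X, y, mask, spec, folds, resample)
        return cache[key]

    space = SearchSpace(dimension=p, encoding="binary-mask")
    colony = ArtificialBeeColony(objective, space, spec.abc)

    init = None
    if warm_start is not None and len(warm_start.values) == p:
        # place the warm-start mask well inside its decoding cell
        init = np.where(warm_start.values == 1, 0.75, 0.25)[None, :]

    result = colony.optimize(init_positions=init)
    if result.best.objective >= INFEASIBLE_OBJECTIVE:
        raise RuntimeError("no feasible mask found within the evaluation budget")
    mask, _ = decode_mask(result.best.position, space)
    return FeatureMask(mask, provenance="abc_search"), result


# ----------------------------------------------------------------------
# The fit/predict contract
# ----------------------------------------------------------------------

class HybridClassifier:
    """One comparison-grid model honoring fit/predict/predict_proba.

    ``fit`` may be given ``resample="smote"`` to balance the training data
    (used by the leakage-safe evaluation harness: resampling then stays
    inside the training fold). Stage-specific behavior:

    * stage ``lr_hybrid`` runs L1 selection on the (possibly resampled)
      training data; if selection empties the mask it falls back to all-ones
      with a warning;
    * stage ``abc_lr_hybrid`` runs the ABC mask search on the raw training
      data with oversampling inside its inner folds, warm-starting one food
      source from the L1 selection.
    """

    def __init__(self, spec: ModelSpec) -> None:
        self.spec = spec
        self.mask_: FeatureMask | None = None
        self.trace_: OptimizeResult | None = None
        self.estimator_ = None
        self._p: int | None = None

    # ------------------------------------------------------------------
    def fit(self, X, y, resample: str | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("fit requires both outcome classes")
        self._p = X.shape[1]
        do_resample = resample == "smote"

        from .evaluation import smote_oversample

        X_bal, y_bal = (
            smote_oversample(X, y, seed=self.spec.seed) if do_resample else (X, y)
        )

        if self.spec.stage == "simple":
            self.mask_ = FeatureMask(np.ones(self._p, dtype=int), provenance="manual")
        elif self.spec.stage == "lr_hybrid":
            mask = l1_select(
                X_bal, y_bal, strength=self.spec.l1_strength, seed=self.spec.seed
            )
            if not mask.feasible:
                warnings.warn(
                    "L1 selection removed every feature; falling back to all-ones",
                    stacklevel=2,
                )
                mask = FeatureMask(np.ones(self._p, dtype=int), provenance="manual")
            self.mask_ = mask
        else:  # abc_lr_hybrid
            try:
                warm = l1_select(
                    X_bal, y_bal, strength=self.spec.l1_strength, seed=self.spec.seed
                )
                warm = warm if warm.feasible else None
            except ValueError:  # pragma: no cover - guarded above
                warm = None
            self.mask_, self.trace_ = abc_feature_search(
                X, y, self.spec, warm_start=warm, resample=do_resample
            )

        cols = self.mask_.indices
        self.estimator_ = _make_estimator(self.spec)
        self.estimator_.fit(X_bal[:, cols], y_bal)
        return self

    # ------------------------------------------------------------------
    def _check(self, X) -> np.ndarray:
        if self.estimator_ is None:
            raise NotFittedError("call fit before predict")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self._p:
            raise ValueError(
                f"predict expects {self._p} features in training order, got {X.shape[1]}"
            )
        return X

    def predict_proba(self, X) -> np.ndarray:
        """Class-1 probability for each row."""
        X = self._check(X)
        cols = self.mask_.indices
        proba = self.estimator_.predict_proba(X[:, cols])
        # classifiers order classes ascending; both classes are present at fit
        return proba[:, -1]

    def predict(self, X) -> np.ndarray:
        """Labels thresholded at probability 0.5."""
        return (self.predict_proba(X) >= 0.5).astype(int)


def build_model(spec: ModelSpec) -> HybridClassifier:
    """Construct an unfitted model for one grid cell."""
    return HybridClassifier(spec)
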