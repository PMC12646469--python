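"""Model-object facade over the hybrid pipeline.

``TransferOutcomeModel`` is built from data (arrays, a DataFrame, or a
:class:`~hivefit.cohort.CohortTable`) plus a :class:`~hivefit.models.ModelSpec`;
``fit()`` returns a :class:`TransferOutcomeResults` carrying the applied
feature mask, the ABC fitness trace (stage 3), prediction methods, local
explanations, cross-validated metrics and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from .cohort import FEATURE_ORDER, OUTCOME_NAME, CohortTable
from .evaluation import CVConfig, MetricsReport, cross_validate, format_percent
from .explain import CohortStats, ExplainConfig, Explanation, explain_instance
from .models import HybridClassifier, ModelSpec, build_model


class TransferOutcomeModel:
    """Embryo-transfer outcome model over a patient cohort.

    Parameters
    ----------
    endog : binary outcome vector (1 = successful transfer).
    exog : n x p predictor matrix in a fixed column order.
    spec : which comparison-grid cell to fit (stage and base learner).
    feature_names : optional column names; defaults to the canonical order
        when p matches, positional names otherwise.
    """

    def __init__(
        self,
        endog,
        exog,
        spec: ModelSpec | None = None,
        feature_names: tuple[str, ...] | None = None,
        cohort: CohortTable | None = None,
    ) -> None:
        self.endog = np.asarray(endog, dtype=int)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or len(self.endog) != len(self.exog):
            raise ValueError("endog and exog must align (n rows)")
        self.spec = spec or ModelSpec()
        if feature_names is not None:
            self.feature_names = tuple(feature_names)
        elif self.exog.shape[1] == len(FEATURE_ORDER):
            self.feature_names = FEATURE_ORDER
        else:
            self.feature_names = tuple(
                f"x{j}" for j in range(self.exog.shape[1])
            )
        self._cohort = cohort

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str = OUTCOME_NAME,
        spec: ModelSpec | None = None,
    ) -> "TransferOutcomeModel":
        if outcome not in df.columns:
            raise ValueError(f"outcome column {outcome!r} not in frame")
        features = [c for c in df.columns if c != outcome]
        return cls(
            df[outcome].to_numpy(),
            df[features].to_numpy(dtype=float),
            spec=spec,
            feature_names=tuple(features),
        )

    @classmethod
    def from_cohort(
        cls, cohort: CohortTable, spec: ModelSpec | None = None
    ) -> "TransferOutcomeModel":
        return cls(cohort.y, cohort.X, spec=spec, cohort=cohort)

    # ------------------------------------------------------------------
    def fit(self, resample: str | None = None) -> "TransferOutcomeResults":
        clf = build_model(self.spec)
        clf.fit(self.exog, self.endog, resample=resample)
        return TransferOutcomeResults(self, clf)

    def cross_validate(self, cv: CVConfig | None = None) -> MetricsReport:
        cohort = self._cohort or _cohort_like(self)
        return cross_validate(self.spec, cohort, cv)


def _cohort_like(model: TransferOutcomeModel) -> CohortTable:
    """Wrap arbitrary endog/exog in a cohort-shaped container for the
    evaluation harness (works only for canonical 22-feature layouts)."""
    if model.feature_names != FEATURE_ORDER:
        raise ValueError(
            "cross-validation via the facade requires the canonical feature "
            "schema; use hivefit.evaluation.cross_validate on a CohortTable"
        )
    frame = pd.DataFrame(model.exog, columns=list(FEATURE_ORDER))
    frame[OUTCOME_NAME] = model.endog
    return CohortTable(frame, provenance="facade")


class TransferOutcomeResults:
    """Fitted-model results: mask, trace, predictions, explanations, summary."""

    def __init__(self, model: TransferOutcomeModel, classifier: HybridClassifier):
        self.model = model
        self.classifier = classifier
        self.mask = classifier.mask_
        self.trace = classifier.trace_
        self._cv_report: MetricsReport | None = None

    # ------------------------------------------------------------------
    def predict(self, exog=None) -> np.ndarray:
        X = self.model.exog if exog is None else np.asarray(exog, dtype=float)
        return self.classifier.predict(X)

    def predict_proba(self, exog=None) -> np.ndarray:
        X = self.model.exog if exog is None else np.asarray(exog, dtype=float)
        return self.classifier.predict_proba(X)

    @property
    def selected_features(self) -> list[str]:
        return self.mask.feature_names(self.model.feature_names)

    def cross_validate(self, cv: CVConfig | None = None) -> MetricsReport:
        self._cv_report = self.model.cross_validate(cv)
        return self._cv_report

    def explain(
        self,
        instance,
        config: ExplainConfig | None = None,
        instance_id: str = "0",
    ) -> Explanation:
        stats = CohortStats.from_matrix(self.model.exog, self.model.feature_names)
        return explain_instance(
            self.classifier,
            instance,
            stats,
            config,
            feature_names=self.model.feature_names,
            instance_id=instance_id,
        )

    # ------------------------------------------------------------------
    def summary(self) -> SimpleTable:
        spec = self.model.spec
        rows = [
            ("Model", spec.name),
            ("Stage", spec.stage),
            ("Base learner", spec.base_learner),
            ("No. observations", str(len(self.model.endog))),
            ("No. predictors", str(self.model.exog.shape[1])),
            ("Selected features", str(self.mask.n_selected)),
            ("Mask provenance", self.mask.provenance),
        ]
        if self.trace is not None:
            rows.append(
                ("ABC best objective", f"{self.trace.best.objective:.4f}")
            )
            rows.append(("ABC evaluations", str(self.trace.n_evaluations)))
        if self._cv_report is not None:
            rep = self._cv_report
            rows.extend(
                [
                    ("CV accuracy (%)", format_percent(rep.mean_fold("accuracy"))),
                    ("CV F1 (%)", format_percent(rep.mean_fold("f1"))),
                    ("CV recall (%)", format_percent(rep.mean_fold("sensitivity"))),
                    ("CV precision (%)", format_percent(rep.mean_fold("precision"))),
                    ("Brier score", f"{rep.probability.brier:.3f}"),
                ]
            )
        import textwrap

        wrapped = textwrap.wrap(", ".join(self.selected_features), width=48)
        for i, line in enumerate(wrapped):
            rows.append(("Features" if i == 0 else "", line))
        return SimpleTable(
            [[k, v] for k, v in rows],
            headers=["", ""],
            title="Embryo-transfer outcome model",
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<TransferOutcomeResults {self.model.spec.name}: "
            f"{self.mask.n_selected} features>"
        )
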