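"""Model/Results facade over the weighting-and-scoring pipeline.

``DriverMutationModel`` bundles the inputs a study needs — labelled
variant catalogues, domain assignments, a profile-HMM registry and a
background composition. ``fit()`` maps the variants onto models and
estimates the pathogenicity weight table; the returned
``DriverMutationResults`` carries the table, exposes ``predict`` for
new substitutions, ``cross_validate`` for k-fold re-estimation, and a
``summary()`` in the familiar fitted-model style.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .evaluation import (
    ConfusionCounts,
    CrossValidationResult,
    MetricSet,
    compute_metrics,
    confusion_from_predictions,
    kfold_weights_cv,
)
from .profilehmm import (
    AssignmentStore,
    BackgroundComposition,
    ModelRegistry,
    read_assignments_tsv,
)
from .scoring import ClassifierConfig, predict_batch
from .weights import (
    PathogenicityWeightTable,
    VariantLabel,
    VariantRecord,
    WeightTableBuilder,
    assign_variants_to_models,
    read_variants_tsv,
)


class DriverMutationModel:
    """Cancer-weighted substitution classifier, before estimation.

    Parameters
    ----------
    variants : sequence of VariantRecord
        Labelled catalogue (CANCER / NEUTRAL) used to estimate weights.
    assignments : AssignmentStore
        Protein -> domain-model alignments.
    registry : ModelRegistry
        The profile HMMs referenced by the assignments.
    background : BackgroundComposition, optional
        Null composition for information-gain model selection
        (SwissProt-like default).
    config : ClassifierConfig, optional
        Threshold, pseudo-count, weight mode and e-value cutoff.
    """

    def __init__(
        self,
        variants: Sequence[VariantRecord],
        assignments: AssignmentStore,
        registry: ModelRegistry,
        background: BackgroundComposition | None = None,
        config: ClassifierConfig | None = None,
    ) -> None:
        self.variants = list(variants)
        self.assignments = assignments
        self.registry = registry
        self.background = background or BackgroundComposition.default()
        self.config = config or ClassifierConfig()

    @classmethod
    def from_files(
        cls,
        variants_tsv: str | Path,
        assignments_tsv: str | Path,
        hmm_dir: str | Path,
        background: BackgroundComposition | None = None,
        config: ClassifierConfig | None = None,
    ) -> "DriverMutationModel":
        return cls(
            variants=read_variants_tsv(variants_tsv),
            assignments=read_assignments_tsv(assignments_tsv),
            registry=ModelRegistry.from_directory(hmm_dir),
            background=background,
            config=config,
        )

    def fit(self) -> "DriverMutationResults":
        """Map variants onto models and estimate the weight table."""
        mapped = assign_variants_to_models(
            self.variants, self.assignments, self.registry, self.background, self.config.e_max
        )
        builder = WeightTableBuilder(
            mapped, self.config.pseudo_count, self.config.weight_mode
        )
        return DriverMutationResults(self, builder, builder.build(), mapped)


@dataclass
class DriverMutationResults:
    """A fitted cancer-weighted classifier."""

    model: DriverMutationModel
    _builder: WeightTableBuilder
    weight_table: PathogenicityWeightTable
    mapped: dict[VariantRecord, str | None]

    @property
    def params(self) -> pd.DataFrame:
        """Estimated weights, one row per model (w_c, w_p and counts)."""
        rows = self.weight_table.rows
        return pd.DataFrame(
            {
                "model_id": list(rows),
                "cancer_count": [r.cancer_count for r in rows.values()],
                "neutral_count": [r.neutral_count for r in rows.values()],
                "w_c": [r.w_c for r in rows.values()],
                "w_p": [r.w_p for r in rows.values()],
            }
        ).set_index("model_id")

    @property
    def n_mapped(self) -> int:
        return sum(1 for m in self.mapped.values() if m is not None)

    def predict(
        self, substitutions: Sequence[tuple[str, str]] | pd.DataFrame
    ) -> pd.DataFrame:
        """Score (protein_id, substitution) pairs with the fitted weights."""
        return predict_batch(
            substitutions,
            self.model.assignments,
            self.model.registry,
            self.weight_table,
            self.model.background,
            self.model.config,
        )

    def training_confusion(self) -> ConfusionCounts:
        """Confusion of the training catalogue scored with the full table
        (no held-out re-estimation; see ``cross_validate`` for that)."""
        df = self.predict([(v.protein_id, v.substitution) for v in self.variant_list])
        scored = df[df["score"].notna()]
        truth = [
            v.label is VariantLabel.CANCER
            for v, has in zip(self.variant_list, df["score"].notna())
            if has
        ]
        return confusion_from_predictions(
            scored["score"].to_numpy(dtype=float), truth, self.model.config.threshold
        )

    def training_metrics(self, normalized: bool = True) -> MetricSet:
        return compute_metrics(self.training_confusion(), normalized=normalized)

    @property
    def variant_list(self) -> list[VariantRecord]:
        return self.model.variants

    def cross_validate(self, k: int, seed: int = 0) -> CrossValidationResult:
        """k-fold (k = n for leave-one-out) re-estimation of the weights."""
        return kfold_weights_cv(
            self.model.variants,
            k,
            seed,
            self.model.assignments,
            self.model.registry,
            self.model.background,
            self.model.config,
        )

    def summary(self) -> str:
        """Human-readable account of the fit."""
        cfg = self.model.config
        lines = [
            "Cancer-weighted substitution classifier",
            "=" * 54,
            f"variants in catalogue:     {len(self.model.variants)}",
            f"variants mapped to models: {self.n_mapped}",
            f"models with weights:       {len(self.weight_table)}",
            f"total cancer mapped:       {self.weight_table.total_cancer}",
            f"total neutral mapped:      {self.weight_table.total_neutral}",
            f"threshold (tau):           {cfg.threshold:g}",
            f"pseudo-count (delta):      {cfg.pseudo_count:g}",
            f"weight mode:               {cfg.weight_mode.value}",
            f"e-value cutoff:            {cfg.e_max:g}",
            "",
            "Pathogenicity weights",
            "-" * 54,
            f"{'model':<12}{'n_cancer':>9}{'n_neutral':>10}{'w_c':>9}{'w_p':>9}",
        ]
        for model_id in sorted(self.weight_table.rows):
            r = self.weight_table.rows[model_id]
            lines.append(
                f"{r.model_id:<12}{r.cancer_count:>9d}{r.neutral_count:>10d}"
                f"{r.w_c:>9.3f}{r.w_p:>9.3f}"
            )
        return "\n".join(lines)
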