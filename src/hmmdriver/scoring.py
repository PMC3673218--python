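"""The weighted magnitude-of-effect score and driver classification.

The score for a substitution at a match state with wild-type emission
probability P_w and mutant emission probability P_m, under model weights
W_c (cancer) and W_p (neutral) with pseudo-count delta, is

    score = ln( P_m * (W_p + delta) / ( P_w * (W_c + delta) ) )

A reduction in emission probability from wild-type to mutant drives the
score negative; cancer-enriched weights (large W_c) push it further
down. With W_c = W_p the score reduces to the plain log-ratio
ln(P_m/P_w). Scores at or below the decision threshold tau (default
-0.75) are labelled CANCER; the inclusive boundary is deliberate so an
exact-threshold score is never silently neutral.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import pandas as pd

from .alphabet import AA_INDEX
from .errors import HmmdriverError, ValidationError
from .profilehmm import (
    AssignmentStore,
    BackgroundComposition,
    ModelRegistry,
    select_model,
)
from .weights import (
    PathogenicityWeightTable,
    WeightMode,
    parse_substitution,
)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = -0.75
DEFAULT_PSEUDO_COUNT = 1.0
DEFAULT_E_MAX = 0.01


class PredictionLabel(Enum):
    CANCER = "CANCER"
    PASSENGER_OR_NEUTRAL = "PASSENGER_OR_NEUTRAL"
    NO_PREDICTION = "NO_PREDICTION"


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision parameters: threshold tau, pseudo-count delta, e-value cutoff."""

    threshold: float = DEFAULT_THRESHOLD
    pseudo_count: float = DEFAULT_PSEUDO_COUNT
    weight_mode: WeightMode = WeightMode.RELATIVE
    e_max: float = DEFAULT_E_MAX

    def __post_init__(self) -> None:
        if self.pseudo_count <= 0:
            raise ValidationError(f"pseudo_count must be > 0, got {self.pseudo_count}")
        if not math.isfinite(self.threshold):
            raise ValidationError("threshold must be finite")


@dataclass(frozen=True)
class Prediction:
    """A scored substitution with full provenance."""

    protein_id: str
    substitution: str
    score: float | None
    label: PredictionLabel
    model_id: str | None = None
    match_state: int | None = None
    p_w: float | None = None
    p_m: float | None = None
    w_c: float | None = None
    w_p: float | None = None

    def __post_init__(self) -> None:
        if (self.score is None) != (self.label is PredictionLabel.NO_PREDICTION):
            raise ValidationError("label is NO_PREDICTION iff score is None")


def weighted_score(p_w: float, p_m: float, w_c: float, w_p: float, pseudo_count: float = 1.0) -> float:
    """ln(p_m*(w_p+delta) / (p_w*(w_c+delta))).

    Strictly increasing in p_m and w_p, strictly decreasing in p_w and
    w_c; equals ln(p_m/p_w) whenever w_c == w_p.
    """
    if not (0.0 < p_w <= 1.0) or not (0.0 < p_m <= 1.0):
        raise ValidationError(f"probabilities must lie in (0, 1]; got p_w={p_w}, p_m={p_m}")
    if w_c < 0 or w_p < 0:
        raise ValidationError(f"weights must be >= 0; got w_c={w_c}, w_p={w_p}")
    if pseudo_count <= 0:
        raise ValidationError(f"pseudo_count must be > 0, got {pseudo_count}")
    return math.log((p_m * (w_p + pseudo_count)) / (p_w * (w_c + pseudo_count)))


def classify(score: float, config: ClassifierConfig) -> PredictionLabel:
    """CANCER iff score <= tau (inclusive boundary), else neutral/passenger."""
    if not math.isfinite(score):
        raise ValidationError(f"score must be finite, got {score}")
    return (
        PredictionLabel.CANCER
        if score <= config.threshold
        else PredictionLabel.PASSENGER_OR_NEUTRAL
    )


def predict(
    protein_id: str,
    substitution: str,
    assignments: AssignmentStore,
    registry: ModelRegistry,
    weight_table: PathogenicityWeightTable,
    bg: BackgroundComposition,
    config: ClassifierConfig = ClassifierConfig(),
) -> Prediction:
    """Score one substitution end to end.

    Selects the most informative significant model at the substituted
    position, reads P_w/P_m off the mapped match state, applies the
    model's weights (absent weight row -> 0/0, degrading gracefully to
    the unweighted log-ratio) and classifies against the threshold.
    Returns a NO_PREDICTION result when no model covers the position.
    """
    wt, pos, mut = parse_substitution(substitution)
    hit = select_model(
        assignments.for_protein(protein_id), pos, registry, bg, e_max=config.e_max
    )
    if hit is None:
        return Prediction(protein_id, f"{wt}{pos}{mut}", None, PredictionLabel.NO_PREDICTION)
    model, match_state = hit
    vector = model.emission_vector(match_state)
    p_w = float(vector[AA_INDEX[wt]])
    p_m = float(vector[AA_INDEX[mut]])
    # advisory only: homolog alignments routinely differ from the query residue
    modal = vector.argmax()
    if AA_INDEX[wt] != modal:
        logger.debug(
            "%s %s: declared wild-type %s is not the modal residue of %s state %d",
            protein_id, substitution, wt, model.model_id, match_state,
        )
    w_c, w_p = weight_table.weights_for(model.model_id)
    score = weighted_score(p_w, p_m, w_c, w_p, config.pseudo_count)
    return Prediction(
        protein_id=protein_id,
        substitution=f"{wt}{pos}{mut}",
        score=score,
        label=classify(score, config),
        model_id=model.model_id,
        match_state=match_state,
        p_w=p_w,
        p_m=p_m,
        w_c=w_c,
        w_p=w_p,
    )


PREDICTION_COLUMNS = (
    "protein_id", "substitution", "score", "label", "model_id",
    "match_state", "p_w", "p_m", "w_c", "w_p", "error",
)


def prediction_to_row(p: Prediction, error: str = "") -> dict:
    return {
        "protein_id": p.protein_id,
        "substitution": p.substitution,
        "score": p.score,
        "label": p.label.value,
        "model_id": p.model_id,
        "match_state": p.match_state,
        "p_w": p.p_w,
        "p_m": p.p_m,
        "w_c": p.w_c,
        "w_p": p.w_p,
        "error": error,
    }


def predict_batch(
    rows: Sequence[tuple[str, str]] | pd.DataFrame,
    assignments: AssignmentStore,
    registry: ModelRegistry,
    weight_table: PathogenicityWeightTable,
    bg: BackgroundComposition,
    config: ClassifierConfig = ClassifierConfig(),
) -> pd.DataFrame:
    """Score many (protein_id, substitution) rows, preserving input order.

    Per-row failures (parse errors, registry misses) are recorded in the
    ``error`` column and never abort the batch.
    """
    if isinstance(rows, pd.DataFrame):
        pairs = list(zip(rows["protein_id"], rows["substitution"]))
    else:
        pairs = list(rows)
    out = []
    for pid, sub in pairs:
        try:
            p = predict(pid, sub, assignments, registry, weight_table, bg, config)
            out.append(prediction_to_row(p))
        except (HmmdriverError, ValueError) as exc:
            out.append(
                {
                    "protein_id": pid, "substitution": sub, "score": None,
                    "label": PredictionLabel.NO_PREDICTION.value, "model_id": None,
                    "match_state": None, "p_w": None, "p_m": None, "w_c": None,
                    "w_p": None, "error": str(exc),
                }
            )
    df = pd.DataFrame(out, columns=PREDICTION_COLUMNS)
    counts = df["label"].value_counts().to_dict()
    logger.info("predict_batch: %d rows; labels: %s", len(df), counts)
    return df


def write_predictions_tsv(df: pd.DataFrame, path: str | Path, decimals: int = 2) -> None:
    """Write a prediction table; scores rounded for the report format."""
    report = df.copy()
    for col in ("score", "p_w", "p_m", "w_c", "w_p"):
        report[col] = report[col].map(
            lambda x: "" if pd.isna(x) else f"{x:.{decimals}f}"  # noqa: B023
        )
    report["match_state"] = report["match_state"].map(
        lambda x: "" if pd.isna(x) else str(int(x))
    )
    report = report.fillna("")
    report.to_csv(path, sep="\t", index=False, lineterminator="\n")
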