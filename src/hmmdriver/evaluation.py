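"""Performance evaluation: normalized metrics, cumulative ROC, threshold
derivation, cross-validation of the weight tables, and odds ratios.

Six performance parameters summarise a 2x2 confusion table. In the
*normalized* form, each class is first reduced to rates — sensitivity
s = tp/(tp+fn), specificity e = tn/(tn+fp), false-positive rate
f = fp/(tn+fp), miss rate m = fn/(tp+fn) — and the ratio metrics are
computed from those rates, so class imbalance cannot inflate them:

    accuracy  = (s + e) / 2
    precision = s / (s + f)
    npv       = e / (e + m)
    mcc       = (s*e - f*m) / sqrt((s+f)(s+m)(e+f)(e+m))

The raw-count textbook formulas are available with ``normalized=False``;
the two agree exactly on balanced classes. Zero denominators yield
``None`` markers, never silent zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, StratificationError, ValidationError
from .profilehmm import AssignmentStore, BackgroundComposition, ModelRegistry
from .scoring import ClassifierConfig, predict_batch
from .weights import (
    VariantLabel,
    VariantRecord,
    WeightTableBuilder,
    assign_variants_to_models,
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricSet:
    """The six performance parameters; None marks an undefined ratio."""

    accuracy: float | None
    precision: float | None
    specificity: float | None
    sensitivity: float | None
    npv: float | None
    mcc: float | None
    normalized: bool

    def as_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "npv": self.npv,
            "mcc": self.mcc,
        }


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(c: ConfusionCounts, normalized: bool = True) -> MetricSet:
    """Six performance parameters from a confusion table.

    With ``normalized=True`` (the default) the per-class rates are used,
    making accuracy the mean of sensitivity and specificity.
    """
    if c.positives == 0 or c.negatives == 0:
        raise ValidationError(
            "metrics need at least one positive (tp+fn) and one negative (tn+fp)"
        )
    s = c.tp / c.positives
    e = c.tn / c.negatives
    if normalized:
        f = c.fp / c.negatives
        m = c.fn / c.positives
        accuracy = (s + e) / 2
        precision = _safe_div(s, s + f)
        npv = _safe_div(e, e + m)
        denom2 = (s + f) * (s + m) * (e + f) * (e + m)
        mcc = ((s * e) - (f * m)) / math.sqrt(denom2) if denom2 > 0 else None
    else:
        total = c.tp + c.fp + c.tn + c.fn
        accuracy = (c.tp + c.tn) / total
        precision = _safe_div(c.tp, c.tp + c.fp)
        npv = _safe_div(c.tn, c.tn + c.fn)
        denom2 = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
        mcc = ((c.tp * c.tn) - (c.fp * c.fn)) / math.sqrt(denom2) if denom2 > 0 else None
    return MetricSet(
        accuracy=accuracy,
        precision=precision,
        specificity=e,
        sensitivity=s,
        npv=npv,
        mcc=mcc,
        normalized=normalized,
    )


def confusion_from_predictions(
    scores: Sequence[float], labels: Sequence[bool], threshold: float
) -> ConfusionCounts:
    """Count tp/fp/tn/fn under the "score <= tau predicts positive" rule.

    `labels` is True for the positive (driver) class.
    """
    if len(scores) != len(labels):
        raise DimensionError(f"{len(scores)} scores but {len(labels)} labels")
    tp = fp = tn = fn = 0
    for score, is_positive in zip(scores, labels):
        predicted_positive = bool(score <= threshold)
        if is_positive:
            tp += predicted_positive
            fn += not predicted_positive
        else:
            fp += predicted_positive
            tn += not predicted_positive
    return ConfusionCounts(int(tp), int(fp), int(tn), int(fn))


# ---------------------------------------------------------------------------
# Cumulative ROC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CumulativeROC:
    """Cumulative (false positives, true positives) as the threshold sweeps
    from most to least damaging. Tie blocks are emitted as single points.
    """

    fp: np.ndarray  # cumulative false-positive counts, starting at 0
    tp: np.ndarray  # cumulative true-positive counts, starting at 0
    n_positives: int
    n_negatives: int

    def rates(self) -> tuple[np.ndarray, np.ndarray]:
        return self.fp / self.n_negatives, self.tp / self.n_positives

    def auc(self) -> float:
        """Trapezoidal area on the rate scale (only meaningful untruncated)."""
        fpr, tpr = self.rates()
        return float(np.trapezoid(tpr, fpr))

    def to_frame(self) -> pd.DataFrame:
        fpr, tpr = self.rates()
        return pd.DataFrame(
            {"cum_fp": self.fp, "cum_tp": self.tp, "fpr": fpr, "tpr": tpr}
        )


def cumulative_roc(
    scores: Sequence[float],
    labels: Sequence[bool],
    fp_fraction_cap: float | None = None,
) -> CumulativeROC:
    """Build the cumulative ROC curve (most-damaging-first sweep).

    Scores are sorted ascending (most negative = most damaging first);
    tied scores are processed as one block so the curve is independent
    of input order. An optional cap truncates the curve once cumulative
    false positives exceed ``cap * total negatives`` (the conservative
    low-error-rate regime).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise DimensionError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs at least one positive and one negative")
    order = np.argsort(scores, kind="stable")
    fp_points = [0]
    tp_points = [0]
    cum_fp = cum_tp = 0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            j += 1
        block = order[i:j]
        cum_tp += int(labels[block].sum())
        cum_fp += int((~labels[block]).sum())
        fp_points.append(cum_fp)
        tp_points.append(cum_tp)
        if fp_fraction_cap is not None and cum_fp > fp_fraction_cap * n_neg:
            break
        i = j
    return CumulativeROC(
        fp=np.array(fp_points), tp=np.array(tp_points), n_positives=n_pos, n_negatives=n_neg
    )


# ---------------------------------------------------------------------------
# Threshold derivation
# ---------------------------------------------------------------------------


def derive_threshold(
    datasets: Sequence[tuple[Sequence[float], Sequence[bool]]],
    grid_step: float = 0.05,
) -> float:
    """Grid-search the threshold maximising summed sensitivity + specificity.

    Candidates run over [min score, max score] across all datasets in
    steps of `grid_step`; the objective is the sum over datasets of
    (sensitivity + specificity) at the candidate (Youden-style
    scalarisation). Ties break to the candidate closest to the median of
    the tied set, then to the most negative.
    """
    if not datasets:
        raise ValidationError("derive_threshold needs at least one dataset")
    cleaned = []
    lo = math.inf
    hi = -math.inf
    for scores, labels in datasets:
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=bool)
        if labels.all() or (~labels).all():
            raise ValidationError("each dataset must contain both classes")
        cleaned.append((scores, labels))
        lo = min(lo, float(scores.min()))
        hi = max(hi, float(scores.max()))
    n_steps = int(math.floor((hi - lo) / grid_step)) + 1
    candidates = lo + grid_step * np.arange(n_steps)
    if candidates[-1] < hi:
        candidates = np.append(candidates, hi)

    objective = np.zeros(len(candidates))
    for scores, labels in cleaned:
        pos = scores[labels]
        neg = scores[~labels]
        # sensitivity + specificity at each candidate tau
        sens = (pos[None, :] <= candidates[:, None]).mean(axis=1)
        spec = (neg[None, :] > candidates[:, None]).mean(axis=1)
        objective += sens + spec
    best = objective.max()
    tied = candidates[np.isclose(objective, best, rtol=0, atol=1e-12)]
    median = float(np.median(tied))
    dist = np.abs(tied - median)
    closest = tied[np.isclose(dist, dist.min(), rtol=0, atol=1e-12)]
    return float(closest.min())


# ---------------------------------------------------------------------------
# Cross-validation of the weighting scheme
# ---------------------------------------------------------------------------


def stratified_folds(
    variants: Sequence[VariantRecord], k: int, seed: int
) -> list[list[VariantRecord]]:
    """Deterministic label-stratified folds.

    Variants are canonically sorted before the seeded shuffle, so fold
    membership depends only on the variant set and the seed, not on
    input order. ``k == len(variants)`` gives leave-one-out.
    """
    n = len(variants)
    if k < 2 or k > n:
        raise ValidationError(f"k must be in [2, {n}], got {k}")
    rng = np.random.default_rng(seed)
    folds: list[list[VariantRecord]] = [[] for _ in range(k)]
    if k == n:
        for i, v in enumerate(sorted(variants, key=lambda v: (v.key, v.label.value))):
            folds[i].append(v)
        return folds
    for label in (VariantLabel.CANCER, VariantLabel.NEUTRAL):
        group = sorted(
            (v for v in variants if v.label is label), key=lambda v: v.key
        )
        idx = rng.permutation(len(group))
        if group and len(group) < k:
            raise StratificationError(
                f"class {label.value} has {len(group)} variants, fewer than k={k}"
            )
        for slot, i in enumerate(idx):
            folds[slot % k].append(group[i])
    for fold in folds:
        if len({v.label for v in fold}) < 2:
            raise StratificationError("a fold ended up single-class; lower k")
    return folds


@dataclass(frozen=True)
class CrossValidationResult:
    predictions: pd.DataFrame  # one row per held-out variant
    pooled_confusion: ConfusionCounts
    pooled_metrics: MetricSet
    k: int
    seed: int


def kfold_weights_cv(
    variants: Sequence[VariantRecord],
    k: int,
    seed: int,
    assignments: AssignmentStore,
    registry: ModelRegistry,
    bg: BackgroundComposition,
    config: ClassifierConfig = ClassifierConfig(),
) -> CrossValidationResult:
    """k-fold (or leave-one-out, k=n) cross-validation of the weights.

    For each fold the pathogenicity weight table is rebuilt from the
    complement only, the held-out variants are scored against it, and
    the fold confusions are pooled. This removes the circularity of
    scoring a variant with weights it contributed to.
    """
    variants = list(variants)
    mapped = assign_variants_to_models(variants, assignments, registry, bg, config.e_max)
    builder = WeightTableBuilder(mapped, config.pseudo_count, config.weight_mode)
    loo = k == len(variants)
    folds = (
        [[v] for v in sorted(variants, key=lambda v: (v.key, v.label.value))]
        if loo
        else stratified_folds(variants, k, seed)
    )
    frames = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for fold_id, fold in enumerate(folds):
        table = builder.build(exclude=fold)
        df = predict_batch(
            [(v.protein_id, v.substitution) for v in fold],
            assignments, registry, table, bg, config,
        )
        df.insert(0, "fold", fold_id)
        df["true_label"] = [v.label.value for v in fold]
        frames.append(df)
        scored = df[df["score"].notna()]
        if len(scored):
            pooled = pooled + confusion_from_predictions(
                scored["score"].to_numpy(dtype=float),
                (scored["true_label"] == VariantLabel.CANCER.value).to_numpy(),
                config.threshold,
            )
    predictions = pd.concat(frames, ignore_index=True)
    metrics = compute_metrics(pooled, normalized=True)
    return CrossValidationResult(predictions, pooled, metrics, k, seed)


# ---------------------------------------------------------------------------
# Odds ratio
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OddsRatio:
    odds_ratio: float
    ci_low: float
    ci_high: float
    haldane_corrected: bool

    def __iter__(self):
        return iter((self.odds_ratio, self.ci_low, self.ci_high))


def odds_ratio(
    correct_a: int, wrong_a: int, correct_b: int, wrong_b: int
) -> OddsRatio:
    """Odds ratio of scheme A's correct:wrong odds over scheme B's.

    OR = (correct_a * wrong_b) / (wrong_a * correct_b), with a 95%
    Woolf confidence interval exp(ln OR +- 1.96*sqrt(sum of 1/cell)).
    Any zero cell triggers the Haldane-Anscombe +0.5 correction, which
    is flagged in the result.
    """
    cells = [correct_a, wrong_a, correct_b, wrong_b]
    if min(cells) < 0:
        raise ValidationError("odds-ratio cells must be non-negative")
    corrected = 0 in cells
    a, b, c, d = ((x + 0.5 for x in cells) if corrected else cells)
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    return OddsRatio(
        odds_ratio=or_,
        ci_low=math.exp(log_or - 1.96 * se),
        ci_high=math.exp(log_or + 1.96 * se),
        haldane_corrected=corrected,
    )


def plot_cumulative_roc(curves: Mapping[str, CumulativeROC], path: str) -> None:
    """Plot cumulative ROC curves (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, roc in curves.items():
        fpr, tpr = roc.rates()
        ax.plot(fpr, tpr, label=name)
    ax.set_xlabel("cumulative false positive rate")
    ax.set_ylabel("cumulative true positive rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
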