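"""Published benchmark confusion counts, kept as metric-code fixtures.

These are printed tp/fp/tn/fn counts from published evaluations of
substitution-effect predictors on the three CHASM-derived benchmark
datasets — cancer vs neutral only (CNO), cancer vs neutral and other
disease (CND), and the synthetic driver/passenger set. They exercise the
normalized-metric code against independently published values; the
package does not re-run any of those predictors.

``HMM_WEIGHTED`` rows are the cancer-weighted HMM method this package
implements; ``SPF_CANCER`` is an independent support-vector predictor
included as a cross-tool fixture.
"""

from __future__ import annotations

from .evaluation import ConfusionCounts

#: (method, dataset) -> printed confusion counts
BENCHMARK_COUNTS: dict[tuple[str, str], ConfusionCounts] = {
    ("HMM_WEIGHTED", "CNO"): ConfusionCounts(tp=2858, fp=77, tn=3077, fn=300),
    ("HMM_WEIGHTED", "CND"): ConfusionCounts(tp=2858, fp=161, tn=2933, fn=300),
    ("HMM_WEIGHTED", "SYNTHETIC"): ConfusionCounts(tp=2858, fp=362, tn=2710, fn=300),
    ("SPF_CANCER", "CNO"): ConfusionCounts(tp=2876, fp=196, tn=2967, fn=287),
    ("SPF_CANCER", "CND"): ConfusionCounts(tp=2876, fp=418, tn=2745, fn=287),
    ("SPF_CANCER", "SYNTHETIC"): ConfusionCounts(tp=2859, fp=297, tn=2866, fn=304),
}

#: the metrics printed alongside those counts (normalized, 2 dp)
PUBLISHED_METRICS: dict[tuple[str, str], dict[str, float]] = {
    ("HMM_WEIGHTED", "CNO"): {
        "accuracy": 0.94, "precision": 0.97, "specificity": 0.98,
        "sensitivity": 0.91, "npv": 0.91, "mcc": 0.88,
    },
    ("HMM_WEIGHTED", "CND"): {
        "accuracy": 0.93, "precision": 0.95, "specificity": 0.95,
        "sensitivity": 0.91, "npv": 0.91, "mcc": 0.85,
    },
    ("HMM_WEIGHTED", "SYNTHETIC"): {
        "accuracy": 0.89, "precision": 0.88, "specificity": 0.88,
        "sensitivity": 0.91, "npv": 0.90, "mcc": 0.79,
    },
    ("SPF_CANCER", "CNO"): {
        "accuracy": 0.92, "precision": 0.94, "specificity": 0.94,
        "sensitivity": 0.91, "npv": 0.91, "mcc": 0.85,
    },
}


def round2(x: float) -> float:
    """Round to the 2-dp precision the published tables use."""
    return float(f"{x:.2f}")
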