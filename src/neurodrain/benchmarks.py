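"""Seeded phantom benchmarks exercising the full pipeline.

These drive the validation suite and the reproduction script: a
distractor benchmark for the detection sweep (cylindrical drain with
near-saturated probabilities plus bone-fragment-like blobs at
sub-threshold amplitudes) and a labeled phantom cohort for the
malposition classifier (embedded fraction drawn uniformly, label from
the transparent distal-coverage rule).

Per-case seeds are derived from a single master seed so every benchmark
is reproducible end to end.
"""

from __future__ import annotations

import numpy as np

from .classifier import PenalizedLogisticRegression, tune_loocv
from .detection import ComponentSet, DetectionOutcome
from .metrics import confusion_metrics, roc_auc
from .phantom import Distractor, PhantomSpec, make_phantom
from .pipeline import analyze_scan, phantom_features

__all__ = [
    "detection_benchmark_outcome",
    "classifier_cohort",
    "classifier_benchmark",
]


def _case_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def detection_benchmark_outcome(n_cases: int = 100, seed: int = 20240101,
                                amplitude_range: tuple[float, float] = (0.5, 0.85),
                                ) -> DetectionOutcome:
    """Pool the baseline object universes of ``n_cases`` distractor
    phantoms into one detection outcome.

    Each case holds one drain (probability ~ 1 in its core) and two
    distractor blobs whose maximum probability is drawn uniformly from
    ``amplitude_range``; objects are labeled against the phantom's GT
    drain mask, so the pooled universe has n drains and 2n noise
    objects.
    """
    rng = np.random.default_rng(seed)
    max_probs: list[float] = []
    is_drain: list[bool] = []
    for _ in range(n_cases):
        amps = rng.uniform(*amplitude_range, size=2)
        spec = PhantomSpec(
            embedded_fraction=float(rng.uniform(0.2, 0.9)),
            distractors=[Distractor(center=(10.0, 10.0, 48.0),
                                    amplitude=float(amps[0])),
                         Distractor(center=(38.0, 36.0, 10.0),
                                    amplitude=float(amps[1]))],
            seed=_case_seed(rng))
        case = make_phantom(spec)
        # retention threshold above 1 collects the baseline universe
        # without profiling anything (only detection is benchmarked here)
        analysis = analyze_scan(case.drain_prob, case.ich_prob,
                                gt_drain=case.gt_drain, t_detect=1.1)
        out = analysis.outcome
        max_probs.extend(out.components.max_prob.tolist())
        is_drain.extend(out.is_drain.tolist())
    comps = ComponentSet(np.zeros((1, 1, 1), int),
                         np.ones(len(max_probs), int),
                         np.asarray(max_probs), np.eye(4))
    return DetectionOutcome(comps, np.asarray(is_drain))


def classifier_cohort(n_cases: int, seed: int):
    """Generate ``n_cases`` labeled phantoms with embedded fraction
    f ~ Uniform[0, 1] and return pipeline features + rule labels."""
    rng = np.random.default_rng(seed)
    X = np.empty((n_cases, 15))
    y = np.empty(n_cases, object)
    for i in range(n_cases):
        spec = PhantomSpec(embedded_fraction=float(rng.uniform(0, 1)),
                           seed=_case_seed(rng))
        case = make_phantom(spec)
        X[i] = phantom_features(case)
        y[i] = case.truth_label
    return X, np.asarray(y, dtype=str)


def classifier_benchmark(n_train: int = 200, n_test: int = 100,
                         seed: int = 20240101, n_candidates: int = 60):
    """Train a LOOCV-tuned penalized logistic regression on phantom
    features and evaluate on a fresh phantom cohort.

    Returns (tuning, model, auc, confusion) where auc is the test ROC-AUC
    for detecting the "not correct" class.
    """
    X_tr, y_tr = classifier_cohort(n_train, seed)
    X_te, y_te = classifier_cohort(n_test, seed + 1)
    tuning = tune_loocv(X_tr, y_tr, n_candidates=n_candidates, seed=seed)
    model = PenalizedLogisticRegression(lam=tuning.selected_lam).fit(X_tr, y_tr)
    pos = model.classes_[1]          # "not correct"
    probs = model.predict_proba(X_te)[:, 1]
    auc, auc_ci = roc_auc(probs, y_te == pos)
    cm = confusion_metrics(model.predict(X_te) == pos, y_te == pos)
    return tuning, model, (auc, auc_ci), cm
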