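"""Drain detection as discrete connected objects.

The drain probability map is binarized at a baseline threshold (0.5),
its connected components form a fixed *object universe*, each object is
labelled "drain" or "noise" by overlap with the ground-truth drain mask,
and an object is *retained* at a higher threshold t iff its maximum
probability is >= t.  Accuracy / sensitivity / specificity of retaining
drains while suppressing noise are then swept over t in [0.5, 0.99].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .metrics import BinomialProportion, confusion_metrics
from .volumes import BinaryMask, ProbabilityVolume

__all__ = [
    "ComponentSet",
    "DetectionOutcome",
    "DetectionMetrics",
    "label_components",
    "assign_gt_labels",
    "evaluate_threshold",
    "detection_sweep",
    "full_accuracy_intervals",
]

BASELINE_THRESHOLD = 0.5   # defines the object universe
DETECT_THRESHOLD = 0.9     # operating point for drain detection

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ComponentSet:
    """Discrete objects of a binary mask.

    ``labels`` holds 0 for background and 1..K for objects; ``sizes`` and
    ``max_prob`` are per-object (index k-1 for object k).
    """

    labels: np.ndarray
    sizes: np.ndarray
    max_prob: np.ndarray
    affine: np.ndarray
    connectivity: int = 26

    @property
    def n_objects(self) -> int:
        return len(self.sizes)

    def object_mask(self, k: int) -> BinaryMask:
        """Binary mask of object ``k`` (1-based label)."""
        if not 1 <= k <= self.n_objects:
            raise ValueError(f"object id {k} out of range 1..{self.n_objects}")
        return BinaryMask(self.labels == k, self.affine)


@dataclass
class DetectionOutcome:
    """Object universe with ground-truth drain/noise labels.

    ``is_drain[k-1]`` is True when object k shares at least one voxel with
    the GT drain mask.  ``multi_drain_flags`` marks objects that two or
    more distinct GT drains map onto (touching drains merge into a single
    component — a known failure mode reported rather than resolved).
    """

    components: ComponentSet
    is_drain: np.ndarray
    multi_drain_flags: np.ndarray = field(default=None)

    @property
    def n_objects(self) -> int:
        return self.components.n_objects

    def retained_at(self, t: float) -> np.ndarray:
        """Boolean retention per object: max probability >= t."""
        return self.components.max_prob >= t


@dataclass
class DetectionMetrics:
    threshold: float
    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: BinomialProportion
    sensitivity: BinomialProportion
    specificity: BinomialProportion


def label_components(mask: BinaryMask, connectivity: int = 26,
                     prob: ProbabilityVolume | None = None) -> ComponentSet:
    """Label 26- (default), 18- or 6-connected objects of a binary mask.

    When the source probability volume is supplied, the per-object maximum
    probability is recorded (needed to judge retention at higher
    thresholds); otherwise max_prob is 1 for every object.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    labels, k = ndimage.label(mask.data, structure=_STRUCTURES[connectivity])
    if k == 0:
        return ComponentSet(labels, np.zeros(0, int), np.zeros(0), mask.affine,
                            connectivity)
    idx = np.arange(1, k + 1)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, idx).astype(int)
    if prob is not None:
        if prob.shape != mask.shape:
            raise ValueError("probability volume and mask grids differ")
        max_prob = ndimage.maximum(prob.data, labels, idx)
    else:
        max_prob = np.ones(k)
    return ComponentSet(labels, sizes, np.asarray(max_prob), mask.affine,
                        connectivity)


def assign_gt_labels(components: ComponentSet,
                     gt_drain: BinaryMask) -> DetectionOutcome:
    """Label each object drain/noise by ground-truth overlap.

    An object is a "drain" iff it shares at least one voxel with the GT
    drain mask.  Objects touched by >= 2 distinct GT drain components are
    flagged (merged touching drains).
    """
    if components.labels.shape != gt_drain.shape:
        raise ValueError("component grid and GT mask grids differ")
    k = components.n_objects
    is_drain = np.zeros(k, bool)
    multi = np.zeros(k, bool)
    if k:
        idx = np.arange(1, k + 1)
        overlap = ndimage.sum_labels(gt_drain.data.astype(float),
                                     components.labels, idx)
        is_drain = overlap >= 1
        gt_labels, n_gt = ndimage.label(gt_drain.data,
                                        structure=_STRUCTURES[26])
        if n_gt > 1:
            for i in range(k):
                gl = gt_labels[(components.labels == i + 1) & gt_drain.data]
                multi[i] = len(np.unique(gl)) >= 2
    return DetectionOutcome(components, is_drain, multi)


def evaluate_threshold(outcome: DetectionOutcome, t: float) -> DetectionMetrics:
    """2x2 table of retained/suppressed vs drain/noise at threshold ``t``.

    TP: drains retained; FN: drains suppressed; TN: noise suppressed;
    FP: noise retained.  Proportions come with exact Clopper-Pearson 95%
    confidence intervals.
    """
    if outcome.n_objects == 0:
        raise ValueError("empty object universe")
    kept = outcome.retained_at(t)
    drain = outcome.is_drain
    tp = int(np.sum(kept & drain))
    fn = int(np.sum(~kept & drain))
    fp = int(np.sum(kept & ~drain))
    tn = int(np.sum(~kept & ~drain))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-class universes are legitimate here
        cm = confusion_metrics(pred=kept, truth=drain)
    return DetectionMetrics(t, tp, fn, tn, fp, cm.accuracy, cm.sensitivity,
                            cm.specificity)


def detection_sweep(outcome: DetectionOutcome,
                    t_min: float = 0.5, t_max: float = 0.99,
                    step: float = 0.01) -> list[DetectionMetrics]:
    """Evaluate retention at every threshold in [t_min, t_max] (default
    0.50..0.99, step 0.01)."""
    n = int(round((t_max - t_min) / step))
    thresholds = t_min + step * np.arange(n + 1)
    return [evaluate_threshold(outcome, float(t)) for t in thresholds]


def full_accuracy_intervals(sweep: list[DetectionMetrics],
                            tol: float = 1e-12) -> list[tuple[float, float]]:
    """Maximal runs [low, high] of consecutive thresholds with accuracy 1."""
    intervals: list[tuple[float, float]] = []
    run_start = None
    for m in sweep:
        perfect = m.accuracy.value >= 1 - tol
        if perfect and run_start is None:
            run_start = m.threshold
        elif not perfect and run_start is not None:
            intervals.append((run_start, prev_t))
            run_start = None
        prev_t = m.threshold
    if run_start is not None:
        intervals.append((run_start, prev_t))
    return intervals
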