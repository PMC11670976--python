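"""Synthetic drain/ICH phantoms with analytic ground truth.

Every stage of the pipeline can be validated without patient data on
phantoms: a cylindrical drain (default radius 1.5 mm, the caliber of a
typical external drainage catheter) rasterized into a 3-D grid, and a
hemorrhage modeled as either a half-space (for a controlled embedded
fraction f of the drain) or an ellipsoid (fully-embedded and disjoint
scenarios).  Probability maps are Gaussian-blurred rasterizations with
clipped additive Gaussian noise; optional small high-probability
distractor blobs emulate bone fragments / calcifications that a
segmentation model mistakes for drains.  The analytic coverage profile
(1 on the embedded segment, 0 elsewhere) and the true tip position are
stored with each case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .coverage import DISTAL_MM, PROFILE_STEP_MM, CoverageProfile
from .volumes import BinaryMask, ProbabilityVolume

__all__ = [
    "Distractor",
    "PhantomSpec",
    "PhantomCase",
    "make_phantom",
    "analytic_profile",
]

DEFAULT_SEED = 20240101


@dataclass
class Distractor:
    """Small high-probability blob (bone fragment surrogate) added to the
    drain probability map only."""

    center: tuple[float, float, float]
    radius: float = 2.5
    amplitude: float = 0.7


@dataclass
class PhantomSpec:
    """Geometry and noise description of one synthetic case.

    The drain is the cylinder {tip + t*direction, 0 <= t <= length,
    radial distance <= radius}; ``direction`` points from the tip toward
    the entry (skull) end.  ``ich_kind`` selects the hemorrhage model:

    - "half_space": ICH fills the half-space containing the tip, with the
      bounding plane orthogonal to the drain at ``embedded_fraction`` of
      its length from the tip;
    - "ellipsoid": ellipsoid at ``ich_center`` with ``ich_semi_axes``;
    - "none": no hemorrhage.
    """

    shape: tuple[int, int, int] = (48, 48, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tip: tuple[float, float, float] = (23.0, 23.0, 20.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    radius: float = 1.5
    length: float = 40.0
    ich_kind: str = "half_space"
    embedded_fraction: float = 0.5
    ich_center: tuple[float, float, float] | None = None
    ich_semi_axes: tuple[float, float, float] | None = None
    blur_sigma: float = 0.5
    noise_sd: float = 0.02
    distractors: list[Distractor] = field(default_factory=list)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, float)
        self.direction = tuple(d / np.linalg.norm(d))
        if not 0.0 <= self.embedded_fraction <= 1.0:
            raise ValueError("embedded_fraction must lie in [0, 1]")
        if self.radius >= self.length / 4:
            raise ValueError("radius must be < length/4 (thin cylinder)")
        extent = np.asarray(self.shape) * np.asarray(self.spacing)
        tip = np.asarray(self.tip)
        entry = tip + self.length * np.asarray(self.direction)
        if np.any(tip < 2.0 - 1e-9) or np.any(tip > extent - 2.0 + 1e-9):
            raise ValueError("drain tip needs >= 2 mm margin inside the grid")
        if np.any(entry < -1e-9) or np.any(entry > extent + 1e-9):
            raise ValueError("drain entry end leaves the grid")

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0], a[1, 1], a[2, 2] = self.spacing
        return a


@dataclass
class PhantomCase:
    drain_prob: ProbabilityVolume
    ich_prob: ProbabilityVolume
    gt_drain: BinaryMask
    gt_ich: BinaryMask
    truth_profile: CoverageProfile
    truth_tip: np.ndarray
    truth_label: str
    spec: PhantomSpec


def _world_grid(spec: PhantomSpec) -> tuple[np.ndarray, ...]:
    idx = [np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)]
    return np.meshgrid(*idx, indexing="ij")


def _rasterize(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    X, Y, Z = _world_grid(spec)
    tip = np.asarray(spec.tip)
    d = np.asarray(spec.direction)
    dx, dy, dz = X - tip[0], Y - tip[1], Z - tip[2]
    t = dx * d[0] + dy * d[1] + dz * d[2]
    r2 = dx ** 2 + dy ** 2 + dz ** 2 - t ** 2
    drain = (t >= 0) & (t <= spec.length) & (r2 <= spec.radius ** 2)

    if spec.ich_kind == "half_space":
        plane = tip + spec.embedded_fraction * spec.length * d
        ich = ((X - plane[0]) * d[0] + (Y - plane[1]) * d[1]
               + (Z - plane[2]) * d[2]) <= 0
    elif spec.ich_kind == "ellipsoid":
        c = np.asarray(spec.ich_center, float)
        s = np.asarray(spec.ich_semi_axes, float)
        ich = (((X - c[0]) / s[0]) ** 2 + ((Y - c[1]) / s[1]) ** 2
               + ((Z - c[2]) / s[2]) ** 2) <= 1.0
    elif spec.ich_kind == "none":
        ich = np.zeros(spec.shape, bool)
    else:
        raise ValueError(f"unknown ich_kind {spec.ich_kind!r}")
    return drain, ich


def _prob_map(mask: np.ndarray, spec: PhantomSpec,
              rng: np.random.Generator) -> np.ndarray:
    out = mask.astype(float)
    if spec.blur_sigma > 0:
        sig = [spec.blur_sigma / s for s in spec.spacing]
        out = ndimage.gaussian_filter(out, sigma=sig, mode="nearest")
    if spec.noise_sd > 0:
        out = out + rng.normal(0.0, spec.noise_sd, size=out.shape)
    return np.clip(out, 0.0, 1.0)


def analytic_profile(spec: PhantomSpec) -> CoverageProfile:
    """Closed-form coverage profile for the supported geometries.

    Half-space: 1 on the embedded segment [0, f*length] from the tip, 0
    beyond; ellipsoid: 1 everywhere when the cylinder lies fully inside,
    0 everywhere when drain and ellipsoid are disjoint (anything in
    between is unsupported); no ICH: all zeros.
    """
    n = int(round(spec.length / PROFILE_STEP_MM))
    positions = PROFILE_STEP_MM * np.arange(n)
    centers = positions + PROFILE_STEP_MM / 2
    if spec.ich_kind == "none":
        values = np.zeros(n)
    elif spec.ich_kind == "half_space":
        values = (centers <= spec.embedded_fraction * spec.length).astype(float)
    elif spec.ich_kind == "ellipsoid":
        tip = np.asarray(spec.tip)
        d = np.asarray(spec.direction)
        c = np.asarray(spec.ich_center, float)
        s = np.asarray(spec.ich_semi_axes, float)
        pts = tip[None, :] + centers[:, None] * d[None, :]
        margin = spec.radius / s.min()
        q = np.sqrt((((pts - c) / s) ** 2).sum(axis=1))
        if np.all(q <= 1.0 - margin):
            values = np.ones(n)
        elif np.all(q >= 1.0 + margin):
            values = np.zeros(n)
        else:
            raise ValueError("ellipsoid geometry must fully contain or be "
                             "disjoint from the cylinder for an analytic "
                             "profile")
    else:
        raise ValueError(f"unknown ich_kind {spec.ich_kind!r}")
    tip = np.asarray(spec.tip, float)
    return CoverageProfile(positions, values, tip,
                           np.asarray(spec.direction, float),
                           drain_id=1, frame_source="analytic")


def make_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one synthetic case: GT masks, probability maps (seeded),
    analytic truth profile, true tip and a transparent position label.

    The label rule — "correct" iff the mean analytic coverage over the
    distal 15 mm is >= 0.5 — is a documented synthetic convention for
    producing labeled training sets, not a claim about radiologists'
    judgment.  On drain/ICH overlap the ground-truth ICH mask excludes
    drain voxels ("drain wins"), matching the geometry convention used in
    quantification.
    """
    drain, ich = _rasterize(spec)
    gt_drain = BinaryMask(drain, spec.affine)
    gt_ich = BinaryMask(ich & ~drain, spec.affine)

    rng = np.random.default_rng(spec.seed)
    drain_prob = _prob_map(drain, spec, rng)
    ich_prob = _prob_map(gt_ich.data, spec, rng)
    if spec.distractors:
        X, Y, Z = _world_grid(spec)
        for blob in spec.distractors:
            c = np.asarray(blob.center, float)
            sphere = ((X - c[0]) ** 2 + (Y - c[1]) ** 2
                      + (Z - c[2]) ** 2) <= blob.radius ** 2
            drain_prob = np.maximum(drain_prob, blob.amplitude * sphere)

    truth = analytic_profile(spec)
    distal = truth.values[truth.positions < DISTAL_MM]
    label = "correct" if float(distal.mean()) >= 0.5 else "not correct"
    return PhantomCase(
        ProbabilityVolume(drain_prob, spec.affine),
        ProbabilityVolume(ich_prob, spec.affine),
        gt_drain, gt_ich, truth,
        np.asarray(spec.tip, float), label, spec,
    )
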