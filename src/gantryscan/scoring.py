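"""Tumor-presence scoring and saliency-mask validation.

In the physical system a trained classifier assigns each B-mode frame a
probability of tumor presence, and class-activation maps are compared to
expert masks via Dice/IoU.  Here the classifier's role is played by a
deterministic analytic surrogate — a saturating function of the lesion area
fraction visible in the slice — behind a black-box scoring interface, so a
learned scorer can be plugged in without touching the search.  Saliency for
a black-box scorer comes from occlusion sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._util import ValidationError
from .bmode import BModeImage, occlude

__all__ = [
    "SliceScore",
    "ScorerSpec",
    "AnalyticScorer",
    "analytic_score",
    "occlusion_saliency",
    "saliency_to_mask",
    "dice_iou",
]


@dataclass
class SliceScore:
    """Probability of tumor presence for one slice, an optional saliency
    map, and the per-lesion visible-area fractions used for attribution."""

    probability: float
    saliency: np.ndarray | None = None
    lesion_area_fractions: dict[int, float] | None = None
    lesion_probabilities: dict[int, float] | None = None

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError("probability must lie in [0, 1]")


@dataclass(frozen=True)
class ScorerSpec:
    """Scorer configuration: ``analytic`` (area-fraction surrogate) or
    ``blackbox`` (externally supplied callable).  ``calibration_halfsat`` is
    the area fraction at which the analytic score reaches 0.5;
    ``detection_threshold`` is the probability above which a lesion counts
    as detected."""

    kind: str = "analytic"
    calibration_halfsat: float = 0.02
    detection_threshold: float = 0.5

    def __post_init__(self):
        if self.kind not in ("analytic", "blackbox"):
            raise ValidationError(f"unknown scorer kind {self.kind!r}")
        if self.calibration_halfsat <= 0:
            raise ValidationError("calibration_halfsat must be positive")
        if not 0.0 < self.detection_threshold < 1.0:
            raise ValidationError("detection_threshold must lie in (0, 1)")


def _saturating(a: float, a0: float) -> float:
    return a / (a + a0) if a > 0 else 0.0


def analytic_score(image: BModeImage, halfsat: float = 0.02) -> SliceScore:
    """Deterministic tumor-presence score from the slice's ground truth.

    Let ``a`` be the lesion-mask area fraction among in-volume pixels; the
    score is ``a / (a + a0)`` with half-saturation ``a0``: zero when the
    plane misses every lesion, 0.5 when lesions fill ``a0`` of the slice,
    approaching 1 for large cross-sections.  It is strictly increasing in
    ``a``, which is exactly the monotonicity the pose search needs.  The
    returned saliency is the ground-truth mask (an ideal activation map).
    """
    in_vol = ~image.out_of_volume
    n = int(in_vol.sum())
    if n == 0:
        warnings.warn("slice lies entirely outside the phantom; score 0")
        return SliceScore(0.0, saliency=np.zeros_like(image.pixels, dtype=float),
                          lesion_area_fractions={}, lesion_probabilities={})
    labels = image.labels[in_vol]
    counts = np.bincount(labels.ravel())
    fractions = {
        int(k): float(counts[k]) / n
        for k in range(1, counts.size)
        if counts[k] > 0
    }
    a = float((counts[1:].sum() if counts.size > 1 else 0)) / n
    return SliceScore(
        probability=_saturating(a, halfsat),
        saliency=image.mask.astype(float),
        lesion_area_fractions=fractions,
        lesion_probabilities={k: _saturating(f, halfsat) for k, f in fractions.items()},
    )


class AnalyticScorer:
    """Callable wrapper around :func:`analytic_score` with a fixed
    calibration, usable wherever a black-box scorer is expected."""

    def __init__(self, halfsat: float = 0.02):
        if halfsat <= 0:
            raise ValidationError("halfsat must be positive")
        self.halfsat = float(halfsat)

    def __call__(self, image: BModeImage) -> SliceScore:
        return analytic_score(image, self.halfsat)


def occlusion_saliency(
    image: BModeImage,
    score_fn,
    patch: int = 8,
    stride: int = 4,
    background_intensity: float | None = None,
) -> np.ndarray:
    """Occlusion-sensitivity saliency map for a black-box scorer.

    Each ``patch x patch`` window (slid with the given stride) is replaced by
    a background intensity — and stripped of lesion content, emulating the
    tissue simply not being there — and the induced score drop
    ``max(0, score(image) - score(occluded))`` is accumulated over the
    window.  The accumulated map is normalized to [0, 1] (all-zero maps stay
    zero).  Model-agnostic and deterministic: a drop-in for gradient-based
    class-activation maps when the scorer exposes no gradients.
    """
    if patch < 1 or stride < 1:
        raise ValidationError("patch and stride must be >= 1")
    h, w = image.pixels.shape
    if patch > h or patch > w:
        raise ValidationError(f"patch {patch} exceeds image shape {(h, w)}")
    if background_intensity is None:
        background_intensity = float(np.median(image.pixels))

    def _prob(img):
        out = score_fn(img)
        return out.probability if isinstance(out, SliceScore) else float(out)

    base = _prob(image)
    sal = np.zeros((h, w), dtype=float)
    for top in range(0, h - patch + 1, stride):
        for left in range(0, w - patch + 1, stride):
            rows = slice(top, top + patch)
            cols = slice(left, left + patch)
            drop = max(0.0, base - _prob(occlude(image, rows, cols, background_intensity)))
            if drop > 0:
                sal[rows, cols] += drop
    peak = sal.max()
    if peak > 0:
        sal /= peak
    return sal


def saliency_to_mask(saliency: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize a saliency map at ``threshold * max`` and keep the largest
    connected component (ties broken by lowest component label, i.e. first
    in scan order).  An all-zero saliency yields an empty mask."""
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must lie in (0, 1)")
    sal = np.asarray(saliency, dtype=float)
    peak = sal.max() if sal.size else 0.0
    if peak <= 0:
        return np.zeros(sal.shape, dtype=bool)
    binary = sal >= threshold * peak
    labeled, ncomp = ndimage.label(binary)
    if ncomp == 0:
        return np.zeros(sal.shape, dtype=bool)
    sizes = ndimage.sum_labels(binary, labeled, index=np.arange(1, ncomp + 1))
    keep = 1 + int(np.argmax(sizes))
    return labeled == keep


def dice_iou(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[float, float]:
    """Dice coefficient and intersection-over-union of two binary masks.

    ``dice = 2|A∩B|/(|A|+|B|)``, ``iou = |A∩B|/|A∪B|``; both are defined as
    1.0 when both masks are empty (correct prediction of absence).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0, 1.0
    inter = int(np.logical_and(a, b).sum())
    union = na + nb - inter
    return 2.0 * inter / (na + nb), inter / union
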