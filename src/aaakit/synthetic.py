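"""Seeded generator of synthetic aortic pixel-count profiles.

Real profiles come from tracking the aorta through a CTA stack and
counting segmented pixels per axial slice.  The generator emulates the
shape of that signal so every detector in the toolkit can be exercised
without imaging data:

* a roughly constant baseline cross-sectional area with multiplicative
  noise (area noise scales with area);
* an optional smooth aneurysmal enlargement modeled as a raised-cosine
  bump rising above the baseline and returning;
* an optional mild linear distal taper toward the iliac bifurcation;
* optional "segmentation dropout", where counts collapse to near zero
  inside the aneurysm, emulating a segmentation network trained only on
  normal anatomy that stops producing masks on pathological slices.

The ground-truth annotation is the contiguous set of slices where the
noiseless bump multiplier exceeds ``annotation_threshold`` (default 1.2,
the same relative-enlargement level the boundary rule uses for the start),
which has a closed form for the raised cosine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .profiles import BoundaryAnnotation, Cohort, MaskStack, SliceProfile

__all__ = [
    "SyntheticParams",
    "generate_profile",
    "generate_failure_profile",
    "generate_cohort",
    "render_mask_stack",
    "COHORT_HALFWIDTH_RANGE",
    "COHORT_AMPLITUDE_RANGE",
]

#: Bump geometry sampled by :func:`generate_cohort`.  The half-width range
#: (slices) and peak amplitude range (fraction of baseline area) describe
#: abrupt-onset aneurysms whose area roughly doubles to triples over a
#: couple of centimetres — the regime in which a relative-threshold
#: sliding-window rule is an appropriate detector.
COHORT_HALFWIDTH_RANGE = (7, 11)
COHORT_AMPLITUDE_RANGE = (1.2, 1.8)


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of one synthetic profile.

    Attributes
    ----------
    n_slices : total number of axial slices.
    baseline : mean normal-aorta pixel count per slice.
    noise_sd_frac : sd of multiplicative Gaussian noise, as a fraction of
        the local noiseless mean.
    bump_amplitude_frac : peak excess over baseline as a fraction of
        baseline (0 disables the aneurysm).
    bump_center, bump_halfwidth : center slice and half-support of the
        raised-cosine bump.
    taper_frac : total linear decline of the baseline across the scan.
    dropout : emit near-zero counts inside the aneurysm (segmentation
        failure) instead of the enlarged counts.
    annotation_threshold : bump multiplier above which slices are
        annotated aneurysmal.
    """

    n_slices: int = 200
    baseline: float = 300.0
    noise_sd_frac: float = 0.03
    bump_amplitude_frac: float = 1.0
    bump_center: int = 100
    bump_halfwidth: int = 25
    taper_frac: float = 0.1
    dropout: bool = False
    annotation_threshold: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 10:
            raise ValueError("n_slices must be >= 10")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be >= 0")
        if self.bump_halfwidth < 1:
            raise ValueError("bump_halfwidth must be >= 1")
        if self.annotation_threshold <= 1.0:
            raise ValueError("annotation_threshold must exceed 1")


def _bump_multiplier(params: SyntheticParams) -> np.ndarray:
    """Noiseless enlargement multiplier 1 + A * raised_cosine(i)."""
    i = np.arange(params.n_slices)
    d = i - params.bump_center
    rc = np.where(
        np.abs(d) <= params.bump_halfwidth,
        0.5 * (1.0 + np.cos(np.pi * d / params.bump_halfwidth)),
        0.0,
    )
    return 1.0 + params.bump_amplitude_frac * rc


def _annotation(params: SyntheticParams, patient_id: str) -> BoundaryAnnotation:
    mult = _bump_multiplier(params)
    idx = np.nonzero(mult > params.annotation_threshold)[0]
    if idx.size == 0:
        return BoundaryAnnotation(patient_id=patient_id, present=False)
    return BoundaryAnnotation(
        patient_id=patient_id, present=True, start=int(idx[0]), end=int(idx[-1])
    )


def generate_profile(
    params: SyntheticParams, patient_id: str = "P000"
) -> tuple[SliceProfile, BoundaryAnnotation]:
    """Generate one profile and its ground-truth aneurysm annotation.

    The noiseless signal is
    ``baseline * (1 - taper_frac * i / n_slices) * multiplier(i)``;
    counts are the signal times multiplicative Gaussian noise, rounded and
    floored at zero.  Identical parameters (including seed) always yield
    identical output.
    """
    if params.bump_amplitude_frac > 0:
        if not (0 <= params.bump_center < params.n_slices):
            raise ValueError("bump_center outside the profile")
        if (
            params.bump_center - params.bump_halfwidth < 0
            or params.bump_center + params.bump_halfwidth >= params.n_slices
        ):
            raise ValueError("bump support extends outside the profile")

    rng = np.random.default_rng(params.seed)
    i = np.arange(params.n_slices)
    signal = (
        params.baseline
        * (1.0 - params.taper_frac * i / params.n_slices)
        * _bump_multiplier(params)
    )
    noisy = signal * (1.0 + params.noise_sd_frac * rng.standard_normal(params.n_slices))
    counts = np.maximum(0, np.rint(noisy)).astype(int)
    ann = _annotation(params, patient_id)

    if params.dropout and ann.present:
        lo, hi = ann.start, ann.end
        ceiling = int(math.floor(0.05 * params.baseline))
        counts[lo : hi + 1] = rng.integers(0, ceiling + 1, size=hi - lo + 1)

    profile = SliceProfile(patient_id=patient_id, counts=tuple(int(c) for c in counts))
    return profile, ann


def generate_failure_profile(
    params: SyntheticParams, patient_id: str = "P000"
) -> tuple[SliceProfile, BoundaryAnnotation]:
    """Generate a segmentation-dropout profile (counts collapse in the bump).

    Convenience wrapper forcing ``dropout=True``; with zero amplitude there
    is no annotated interval and the profile equals the normal one.
    """
    return generate_profile(replace(params, dropout=True), patient_id=patient_id)


def generate_cohort(
    n: int,
    aneurysm_fraction: float = 1.0,
    params: Optional[SyntheticParams] = None,
    seed: int = 0,
    halfwidth_range: tuple[int, int] = COHORT_HALFWIDTH_RANGE,
    amplitude_range: tuple[float, float] = COHORT_AMPLITUDE_RANGE,
) -> Cohort:
    """Generate a cohort with randomized aneurysm geometry.

    ``round(n * aneurysm_fraction)`` patients receive an aneurysm with
    center, half-width, and amplitude drawn uniformly from the stated
    ranges; the remainder are normal (zero amplitude).  Everything is
    deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= aneurysm_fraction <= 1.0:
        raise ValueError("aneurysm_fraction must lie in [0, 1]")
    template = params or SyntheticParams()
    rng = np.random.default_rng(seed)
    n_pos = int(round(n * aneurysm_fraction))
    width = max(4, len(str(n - 1)))

    profiles = {}
    annotations = {}
    for k in range(n):
        pid = f"P{k:0{width}d}"
        if k < n_pos:
            hw = int(rng.integers(halfwidth_range[0], halfwidth_range[1] + 1))
            amp = float(rng.uniform(*amplitude_range))
            margin = hw + 2 * max(4, hw // 2)
            center = int(rng.integers(margin, template.n_slices - margin))
            p = replace(
                template,
                bump_amplitude_frac=amp,
                bump_center=center,
                bump_halfwidth=hw,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        else:
            p = replace(
                template,
                bump_amplitude_frac=0.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        prof, ann = generate_profile(p, patient_id=pid)
        profiles[pid] = prof
        annotations[pid] = ann
    return Cohort(profiles=profiles, annotations=annotations)


def render_mask_stack(profile: SliceProfile, grid: int = 128) -> MaskStack:
    """Render a profile as a stack of centered quasi-disks with exact counts.

    Pixels are ranked by distance from the grid center (ties broken
    lexicographically by coordinate) and each slice sets exactly
    ``counts[i]`` of the closest pixels, so
    ``extract_profile(render_mask_stack(p))`` reproduces ``p`` exactly and
    the shape is as close to a disk as the count allows.
    """
    if max(profile.counts) > grid * grid:
        raise ValueError(
            f"profile {profile.patient_id!r}: count exceeds {grid}x{grid} grid"
        )
    yy, xx = np.mgrid[0:grid, 0:grid]
    center = (grid - 1) / 2.0
    d2 = (yy - center) ** 2 + (xx - center) ** 2
    order = np.lexsort((xx.ravel(), yy.ravel(), d2.ravel()))

    slices = []
    for c in profile.counts:
        flat = np.zeros(grid * grid, dtype=np.uint8)
        flat[order[:c]] = 1
        slices.append(flat.reshape(grid, grid))
    return MaskStack(patient_id=profile.patient_id, slices=tuple(slices))
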