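"""Sliding-window expert rules on pixel-count profiles.

Two rule systems share the same primitive — comparing each slice's count
with the rolling mean of the counts on the slices immediately before it:

* :func:`screen_failure` is a binary screen that exploits segmentation
  dropout: a network trained only on normal anatomy stops producing masks
  on aneurysmal slices, so a sustained collapse (or surge) of the count
  relative to a rolling baseline flags the scan as abnormal.  Its baseline
  tracks *normal* segmentation: anomalous slices are excluded from the
  rolling buffer, so a run of dropout slices is measured against the last
  normal-caliber level and the first/last flagged slices delimit the
  abnormal extent.
* :func:`detect_boundaries_expert` places aneurysm start/end boundaries on
  a continuous tracking profile: a sustained rise above ``upper`` times
  the rolling mean marks a candidate start, and a sustained drop below
  ``lower`` times the rolling mean marks a candidate end.  Here the
  rolling mean always covers the ``window`` slices immediately preceding
  each slice and keeps rolling through the aneurysm — it is never frozen
  at the pre-aneurysm level, so the end rule measures the drop relative
  to recent aneurysm-scale counts.  The largest resulting abnormality
  region is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .metrics import interval_dice
from .profiles import BoundaryAnnotation, Cohort, SliceProfile

__all__ = [
    "RuleConfig",
    "ScreenResult",
    "GridSpec",
    "DEFAULT_BOUNDARY_RULE",
    "DEFAULT_SCREEN_RULE",
    "DEFAULT_GRID",
    "screen_failure",
    "detect_boundaries_expert",
    "grid_search",
]


@dataclass(frozen=True)
class RuleConfig:
    """Parameters of a sliding-window rule.

    ``window`` is both the rolling-average length and, for the boundary
    detector, the number of consecutive qualifying slices required;
    ``persistence`` is the run length required by the binary screen.
    """

    window: int = 4
    upper: float = 1.2
    lower: float = 0.8
    persistence: int = 4

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.persistence < 1:
            raise ValueError("persistence must be >= 1")
        if not self.lower < 1.0 < self.upper:
            raise ValueError("need lower < 1 < upper")


#: Boundary-detector defaults: 120 % start / 80 % end of a 4-slice rolling mean.
DEFAULT_BOUNDARY_RULE = RuleConfig(window=4, upper=1.2, lower=0.8, persistence=4)
#: Failure-screen defaults: 140 % / 50 % of a 4-slice rolling mean, 4-slice runs.
DEFAULT_SCREEN_RULE = RuleConfig(window=4, upper=1.4, lower=0.5, persistence=4)


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the binary aneurysm screen for one patient."""

    patient_id: str
    label: str  # "normal" | "aneurysm"
    first_flagged: Optional[int] = None
    last_flagged: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label not in ("normal", "aneurysm"):
            raise ValueError("label must be 'normal' or 'aneurysm'")
        flagged = self.first_flagged is not None and self.last_flagged is not None
        if (self.label == "aneurysm") != flagged:
            raise ValueError("flagged indices must be set iff label is aneurysm")
        if flagged and self.first_flagged > self.last_flagged:
            raise ValueError("first_flagged must be <= last_flagged")


@dataclass(frozen=True)
class GridSpec:
    """Search space for the boundary rule's window and thresholds."""

    windows: tuple[int, ...] = tuple(range(2, 9))
    uppers: tuple[float, ...] = tuple(np.round(np.arange(1.05, 1.501, 0.05), 2))
    lowers: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))

    def __post_init__(self) -> None:
        if not (self.windows and self.uppers and self.lowers):
            raise ValueError("grid axes must be non-empty")
        if min(self.windows) < 1:
            raise ValueError("windows must be >= 1")
        if min(self.uppers) <= 1.0:
            raise ValueError("uppers must be > 1")
        if not all(0.0 < l < 1.0 for l in self.lowers):
            raise ValueError("lowers must lie in (0, 1)")

    def configs(self) -> Iterable[RuleConfig]:
        for w in self.windows:
            for u in self.uppers:
                for l in self.lowers:
                    yield RuleConfig(window=w, upper=u, lower=l, persistence=w)


DEFAULT_GRID = GridSpec()


# ---------------------------------------------------------------------------
# shared primitives
# ---------------------------------------------------------------------------

def _rolling_baseline(counts: np.ndarray, window: int) -> np.ndarray:
    """Mean of the ``window`` counts strictly preceding each slice.

    The first ``window`` slices have no full preceding window; their
    baseline is NaN and they can never be flagged.
    """
    n = counts.size
    base = np.full(n, np.nan)
    if n > window:
        csum = np.concatenate(([0.0], np.cumsum(counts, dtype=float)))
        base[window:] = (csum[window:n] - csum[: n - window]) / window
    return base


def _runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_len, as inclusive (start, end)."""
    runs: list[tuple[int, int]] = []
    start: Optional[int] = None
    for i in range(mask.size + 1):
        val = bool(mask[i]) if i < mask.size else False
        if val and start is None:
            start = i
        elif not val and start is not None:
            if i - start >= min_len:
                runs.append((start, i - 1))
            start = None
    return runs


# ---------------------------------------------------------------------------
# rule systems
# ---------------------------------------------------------------------------

def screen_failure(profile: SliceProfile, config: RuleConfig = DEFAULT_SCREEN_RULE) -> ScreenResult:
    """Label a profile normal/aneurysm from sustained baseline deviations.

    A slice is anomalous when its count falls below ``lower`` times or
    exceeds ``upper`` times the rolling mean of the last ``window``
    *normal* (non-anomalous) slices; anomalous slices do not enter the
    baseline, which therefore holds at the last normal-caliber level
    through an abnormal stretch.  The first ``window`` slices seed the
    baseline and are never flagged.  The scan is labeled aneurysm when
    some run of at least ``persistence`` consecutive anomalous slices
    exists; the first slice of the first qualifying run and the last
    slice of the last qualifying run are reported as the flagged extent.
    """
    if profile.slice_count < config.window + config.persistence:
        raise ValueError(
            f"profile {profile.patient_id!r}: needs at least "
            f"window+persistence={config.window + config.persistence} slices"
        )
    counts = profile.as_array()
    anomalous = np.zeros(profile.slice_count, dtype=bool)
    buffer = list(counts[: config.window])  # baseline-eligible counts
    for i in range(config.window, profile.slice_count):
        base = float(np.mean(buffer[-config.window :]))
        if counts[i] < config.lower * base or counts[i] > config.upper * base:
            anomalous[i] = True
        else:
            buffer.append(counts[i])

    runs = _runs(anomalous, config.persistence)
    if not runs:
        return ScreenResult(patient_id=profile.patient_id, label="normal")
    return ScreenResult(
        patient_id=profile.patient_id,
        label="aneurysm",
        first_flagged=runs[0][0],
        last_flagged=runs[-1][1],
    )


def detect_boundaries_expert(
    profile: SliceProfile, config: RuleConfig = DEFAULT_BOUNDARY_RULE
) -> BoundaryAnnotation:
    """Place aneurysm boundaries with the sliding-window rise/drop rule.

    A candidate start is the first slice of a run of ``window`` consecutive
    slices whose counts each exceed ``upper`` times their own rolling
    baseline; a candidate end is the last slice of a run of ``window``
    consecutive slices each below ``lower`` times theirs.  Candidate
    regions pair a start with a later end; the region of greatest slice
    extent wins (ties broken toward the earliest start).  With no
    qualifying region the annotation is returned with ``present=False``.
    """
    if profile.slice_count < config.window + config.persistence:
        raise ValueError(
            f"profile {profile.patient_id!r}: needs at least "
            f"window+persistence={config.window + config.persistence} slices"
        )
    counts = profile.as_array()
    base = _rolling_baseline(counts, config.window)
    with np.errstate(invalid="ignore"):
        above = counts > config.upper * base
        below = counts < config.lower * base
    valid = ~np.isnan(base)
    above &= valid
    below &= valid

    starts = [r[0] for r in _runs(above, config.window)]
    ends = [r[1] for r in _runs(below, config.window)]
    regions = [(s, e) for s in starts for e in ends if s < e]
    if not regions:
        return BoundaryAnnotation(patient_id=profile.patient_id, present=False)
    # greatest extent first, then earliest
    regions.sort(key=lambda r: (-(r[1] - r[0] + 1), r[0]))
    s, e = regions[0]
    return BoundaryAnnotation(patient_id=profile.patient_id, present=True, start=s, end=e)


def grid_search(
    cohort: Cohort,
    grid: GridSpec = DEFAULT_GRID,
    objective: str = "mean_dice",
) -> tuple[RuleConfig, float]:
    """Exhaustively search the rule grid for the best mean interval Dice.

    Every grid point is evaluated on all annotated profiles of the cohort;
    ties are broken by smaller window, then upper threshold closer to 1,
    then lower threshold closer to 1.
    """
    if objective != "mean_dice":
        raise ValueError(f"unsupported objective {objective!r}")
    ids = cohort.annotated_ids()
    if not ids:
        raise ValueError("grid search needs at least one annotated profile")

    best: Optional[tuple] = None
    for cfg in grid.configs():
        dices = []
        for pid in ids:
            pred = detect_boundaries_expert(cohort.profiles[pid], cfg)
            dices.append(interval_dice(pred, cohort.annotations[pid]))
        score = float(np.mean(dices))
        key = (-score, cfg.window, cfg.upper - 1.0, 1.0 - cfg.lower)
        if best is None or key < best[0]:
            best = (key, cfg, score)
    return best[1], best[2]
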