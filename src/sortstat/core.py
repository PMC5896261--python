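"""Median-based and mean-based effect sizes for two-group comparisons.

Two statistics are implemented for a pair of numeric samples ``x`` (size
``n``) and ``y`` (size ``m``):

* **Cohen's d** — ``(mean(x) - mean(y)) / sigma``, where ``sigma`` is, by
  default, the sample standard deviation of the concatenated values (the
  "joint distribution"); the classical pooled within-group standard
  deviation is available as an explicit mode for cross-checking against
  conventional usage.

* **The sorting statistic D_s** — a nonparametric effect size.  Orient the
  groups so the one with the larger median plays the role of ``x``; then

      D_s = (median(x) - median(y)) / (Zx - Zy)

  where ``Z`` is the concatenation of both groups sorted in descending
  order, ``Zx`` is the median of the first ``n`` entries of ``Z`` and
  ``Zy`` the median of the last ``m`` entries.  The denominator is the
  largest median gap achievable by reassigning the observed values to two
  groups of the same sizes, so D_s is normalised to [0, 1].  When the two
  group medians coincide, D_s is defined to be exactly 0.  No assumption
  is made about the shape of the underlying distributions, which makes
  D_s informative for skewed data where a mean-based statistic can sit
  near zero despite a real difference in tail mass.

Calibration anchors map values to descriptive effect-size classes:
0.2 / 0.5 / 0.8 for |d| and 0.2 / 0.45 / 0.7 for D_s correspond to
small / medium / large effects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "GroupedSample",
    "EffectSizeResult",
    "CalibrationBand",
    "COHEN_D_BAND",
    "SORTING_BAND",
    "EffectSizeError",
    "ZeroSpreadError",
    "median",
    "cohens_d",
    "sorting_statistic",
    "classify_effect",
    "effect_sizes",
]

logger = logging.getLogger(__name__)

SigmaMode = Literal["joint", "pooled"]
EffectClass = Literal["negligible", "small", "medium", "large"]


class EffectSizeError(ValueError):
    """Raised when an effect size cannot be computed from the input."""


class ZeroSpreadError(EffectSizeError):
    """Raised when the standard-deviation denominator of Cohen's d is zero."""


def _as_clean_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise EffectSizeError(f"no data: group '{name}' is empty")
    if not np.all(np.isfinite(arr)):
        raise EffectSizeError(
            f"group '{name}' contains non-finite values; "
            "drop or impute them before computing effect sizes"
        )
    return arr


@dataclass(frozen=True)
class GroupedSample:
    """Two labelled numeric samples to be compared on one measurement.

    Values must be finite; use :meth:`from_raw` to drop missing values
    (NaN/Inf) with a logged count first.
    """

    values_x: np.ndarray
    values_y: np.ndarray
    label_x: str = "x"
    label_y: str = "y"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values_x", _as_clean_array(self.values_x, self.label_x))
        object.__setattr__(self, "values_y", _as_clean_array(self.values_y, self.label_y))

    @classmethod
    def from_raw(
        cls,
        values_x: Sequence[float],
        values_y: Sequence[float],
        label_x: str = "x",
        label_y: str = "y",
    ) -> "GroupedSample":
        """Build a sample, silently-but-loggedly dropping non-finite values."""
        cleaned = []
        for vals, label in ((values_x, label_x), (values_y, label_y)):
            arr = np.asarray(vals, dtype=float).ravel()
            keep = np.isfinite(arr)
            n_dropped = int(arr.size - keep.sum())
            if n_dropped:
                logger.info("dropped %d non-finite value(s) from group '%s'", n_dropped, label)
            cleaned.append(arr[keep])
        return cls(cleaned[0], cleaned[1], label_x, label_y)

    @property
    def n(self) -> int:
        return self.values_x.size

    @property
    def m(self) -> int:
        return self.values_y.size

    def swapped(self) -> "GroupedSample":
        return GroupedSample(self.values_y, self.values_x, self.label_y, self.label_x)


@dataclass(frozen=True)
class EffectSizeResult:
    """Cohen's d and the sorting statistic with all component terms.

    ``d`` carries sign (positive when group x has the larger mean) and is
    NaN when the spread is zero.  ``ds`` is unsigned in [0, 1];
    ``ds_signed`` restores direction in the original label order.
    ``median_hi``/``median_lo`` and ``z_med_hi``/``z_med_lo`` are the
    numerator and denominator terms after orientation; ``swapped`` records
    whether the groups were reordered so that ``median_hi >= median_lo``.
    """

    d: float
    d_sigma: float
    mean_x: float
    mean_y: float
    ds: float
    median_hi: float
    median_lo: float
    z_med_hi: float
    z_med_lo: float
    swapped: bool
    n: int
    m: int
    sigma_mode: str = "joint"

    @property
    def d_defined(self) -> bool:
        return math.isfinite(self.d)

    @property
    def ds_signed(self) -> float:
        """D_s with the sign of (median of x - median of y) in label order."""
        return -self.ds if self.swapped else self.ds

    @property
    def n_hi(self) -> int:
        """Size of the larger-median group (the oriented x)."""
        return self.m if self.swapped else self.n

    @property
    def m_lo(self) -> int:
        """Size of the smaller-median group (the oriented y)."""
        return self.n if self.swapped else self.m

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in (
            "d", "d_sigma", "mean_x", "mean_y", "ds", "ds_signed",
            "median_hi", "median_lo", "z_med_hi", "z_med_lo",
            "swapped", "n", "m", "sigma_mode",
        )}
        return out


@dataclass(frozen=True)
class CalibrationBand:
    """Anchor thresholds mapping a statistic to small/medium/large classes.

    Intervals are half-open: a value at or above a threshold and below the
    next belongs to that class; below the small threshold is negligible.
    For ``cohen_d`` bands the absolute value is classified.
    """

    statistic_kind: Literal["cohen_d", "sorting"]
    thresholds: tuple[float, float, float]

    def __post_init__(self) -> None:
        s, mdm, lg = self.thresholds
        if not (0 < s < mdm < lg):
            raise ValueError("band thresholds must be positive and strictly increasing")


#: Cohen's conventional anchors for |d|.
COHEN_D_BAND = CalibrationBand("cohen_d", (0.2, 0.5, 0.8))
#: Empirically matched anchors for the sorting statistic.
SORTING_BAND = CalibrationBand("sorting", (0.2, 0.45, 0.7))


def median(values: Sequence[float]) -> float:
    """Median of a nonempty collection of finite reals.

    Middle order statistic for odd counts; mean of the two middle order
    statistics for even counts.
    """
    arr = _as_clean_array(values, "values")
    return float(np.median(arr))


def _sigma(sample: GroupedSample, sigma_mode: SigmaMode) -> float:
    if sigma_mode == "joint":
        joint = np.concatenate([sample.values_x, sample.values_y])
        if joint.size < 2:
            raise EffectSizeError("joint-mode sigma needs at least 2 values in total")
        return float(np.std(joint, ddof=1))
    if sigma_mode == "pooled":
        n, m = sample.n, sample.m
        if n < 2 or m < 2:
            raise EffectSizeError("pooled-mode sigma needs at least 2 values per group")
        vx = float(np.var(sample.values_x, ddof=1))
        vy = float(np.var(sample.values_y, ddof=1))
        return math.sqrt(((n - 1) * vx + (m - 1) * vy) / (n + m - 2))
    raise ValueError(f"unknown sigma_mode {sigma_mode!r}")


def cohens_d(sample: GroupedSample, sigma_mode: SigmaMode = "joint") -> tuple[float, float]:
    """Cohen's d and the sigma used.

    Returns ``(d, sigma)`` where ``d = (mean_x - mean_y) / sigma``.  In the
    default ``joint`` mode sigma is the sample standard deviation (ddof=1)
    of the concatenated values; ``pooled`` uses the classical pooled
    within-group standard deviation.

    Raises
    ------
    ZeroSpreadError
        If sigma is zero (all values identical).
    """
    sigma = _sigma(sample, sigma_mode)
    if sigma == 0.0:
        raise ZeroSpreadError("zero spread: all values identical, Cohen's d undefined")
    return (float(np.mean(sample.values_x)) - float(np.mean(sample.values_y))) / sigma, sigma


def _sorting_terms(sample: GroupedSample) -> tuple[float, float, float, float, bool]:
    """Oriented medians and sorted-joint medians (hi/lo), plus the swap flag."""
    med_x = float(np.median(sample.values_x))
    med_y = float(np.median(sample.values_y))
    swapped = med_x < med_y
    if swapped:
        sample = sample.swapped()
        med_x, med_y = med_y, med_x
    n, m = sample.n, sample.m
    z = np.sort(np.concatenate([sample.values_x, sample.values_y]))[::-1]
    z_med_hi = float(np.median(z[:n]))
    z_med_lo = float(np.median(z[n:]))
    return med_x, med_y, z_med_hi, z_med_lo, swapped


def sorting_statistic(sample: GroupedSample) -> "EffectSizeResult":
    """The sorting statistic D_s with its component terms.

    The result's mean/sigma fields are NaN; use :func:`effect_sizes` for
    the full record.  D_s is exactly 0 when the two group medians are
    equal (this also covers the all-identical degenerate case, where the
    denominator would be 0/0).
    """
    med_hi, med_lo, z_hi, z_lo, swapped = _sorting_terms(sample)
    if med_hi == med_lo:
        ds = 0.0
    else:
        ds = (med_hi - med_lo) / (z_hi - z_lo)
    return EffectSizeResult(
        d=math.nan, d_sigma=math.nan, mean_x=math.nan, mean_y=math.nan,
        ds=ds, median_hi=med_hi, median_lo=med_lo,
        z_med_hi=z_hi, z_med_lo=z_lo, swapped=swapped,
        n=sample.n, m=sample.m,
    )


def classify_effect(value: float, band: CalibrationBand) -> EffectClass:
    """Map a statistic value to negligible/small/medium/large via a band.

    Cohen-d bands classify the absolute value.  NaN maps to negligible is
    not meaningful, so NaN raises.
    """
    if not math.isfinite(value):
        raise EffectSizeError("cannot classify a non-finite effect size")
    v = abs(value) if band.statistic_kind == "cohen_d" else value
    small, medium, large = band.thresholds
    if v >= large:
        return "large"
    if v >= medium:
        return "medium"
    if v >= small:
        return "small"
    return "negligible"


def effect_sizes(sample: GroupedSample, sigma_mode: SigmaMode = "joint") -> EffectSizeResult:
    """Full two-group effect-size record: Cohen's d plus the sorting statistic.

    If the data is constant (sigma = 0) d is reported as NaN while D_s
    (which is 0 in that case by the equal-median rule) is still returned.
    """
    frag = sorting_statistic(sample)
    try:
        d, sigma = cohens_d(sample, sigma_mode)
    except ZeroSpreadError:
        logger.info("sigma = 0: Cohen's d undefined, reporting NaN")
        d, sigma = math.nan, 0.0
    return EffectSizeResult(
        d=d, d_sigma=sigma,
        mean_x=float(np.mean(sample.values_x)),
        mean_y=float(np.mean(sample.values_y)),
        ds=frag.ds, median_hi=frag.median_hi, median_lo=frag.median_lo,
        z_med_hi=frag.z_med_hi, z_med_lo=frag.z_med_lo,
        swapped=frag.swapped, n=sample.n, m=sample.m, sigma_mode=sigma_mode,
    )
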