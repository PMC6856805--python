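"""Statistics over censored (nondetect-containing) concentration data.

Monitoring datasets for trace contaminants routinely mix quantified values
with nondetects reported only as "below the limit of quantitation (LOQ)".
This module implements the substitution-based conventions used in
pharmaceutical exposure assessment:

* percent ranking with nondetects occupying the lowest ranks (they push
  the lowest quantified value up the rank axis);
* summary quantiles by the nearest-rank (ceiling) convention, reported as
  a censored marker when the selected rank is a nondetect;
* arithmetic means with nondetects substituted at half their LOQ;
* exceedance counting, which refuses to answer when a nondetect's LOQ
  lies above the threshold (the comparison is indeterminate).

Maximum-likelihood or Kaplan-Meier censored estimators are deliberately
out of scope: the conventions here mirror regulatory practice.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import (IndeterminateCensoringError, InvalidParameterError,
                     NoDataError)

__all__ = [
    "Matrix",
    "CensoredSample",
    "RankedDistribution",
    "ExceedanceResult",
    "BELOW_LOQ",
    "percent_rank",
    "censored_mean",
    "fraction_above",
]

#: Marker returned for a quantile that falls on a nondetect rank.
BELOW_LOQ = "<LOQ"

DEFAULT_PERCENTILES = (5.0, 25.0, 50.0, 75.0, 90.0, 95.0, 99.0)


class Matrix(str, enum.Enum):
    surface_water = "surface_water"
    effluent = "effluent"
    influent = "influent"
    sediment = "sediment"
    drinking_water = "drinking_water"


@dataclass(frozen=True)
class CensoredSample:
    """One concentration measurement that may be a nondetect.

    Detected samples carry a positive ``value``; trace values reported
    below their own LOQ are kept as detects. Nondetects carry
    ``value=None`` and are characterized by their LOQ alone.
    """

    value: float | None
    loq: float
    detected: bool
    matrix: Matrix = Matrix.surface_water
    site: str = ""
    source: str = ""

    def __post_init__(self):
        object.__setattr__(self, "matrix", Matrix(self.matrix))
        if not self.loq > 0:
            raise InvalidParameterError("LOQ must be > 0")
        if self.detected:
            if self.value is None or not self.value > 0:
                raise InvalidParameterError("detected sample needs value > 0")
        elif self.value is not None:
            raise InvalidParameterError("nondetect must not carry a value")

    def sort_key(self) -> tuple:
        # nondetects rank before the smallest detect at the same LOQ
        if self.detected:
            return (self.value, 1)
        return (self.loq, 0)


@dataclass(frozen=True)
class RankedDistribution:
    """A percent-ranked censored dataset.

    ``ordered_values`` holds the samples in rank order (nondetects first,
    by LOQ, then detects ascending). ``percentile_of`` maps each requested
    percentile to a concentration in ug/L or to :data:`BELOW_LOQ`.
    """

    ordered_values: tuple[CensoredSample, ...]
    percentile_of: dict[float, float | str]
    n_total: int
    n_nondetect: int

    def percentile(self, p: float) -> float | str:
        """Nearest-rank (ceiling) percentile of the censored-ordered list."""
        if not 0.0 < p <= 100.0:
            raise InvalidParameterError("percentile must be in (0, 100]")
        rank = max(1, math.ceil(p * self.n_total / 100.0))
        s = self.ordered_values[min(rank, self.n_total) - 1]
        return s.value if s.detected else BELOW_LOQ


def percent_rank(samples: Sequence[CensoredSample],
                 percentiles: Iterable[float] = DEFAULT_PERCENTILES) -> RankedDistribution:
    """Rank a censored dataset and evaluate the requested percentiles.

    With no nondetects every quantile equals the ordinary nearest-rank
    empirical quantile. The operation is idempotent and invariant under
    permutation of the input.
    """
    samples = list(samples)
    if not samples:
        raise NoDataError("percent_rank needs at least one sample")
    ordered = tuple(sorted(samples, key=CensoredSample.sort_key))
    n_nd = sum(1 for s in ordered if not s.detected)
    dist = RankedDistribution(ordered_values=ordered, percentile_of={},
                              n_total=len(ordered), n_nondetect=n_nd)
    dist.percentile_of.update({float(p): dist.percentile(p) for p in percentiles})
    return dist


def censored_mean(samples: Sequence[CensoredSample],
                  substitution: str = "half_loq") -> float:
    """Arithmetic mean with nondetects substituted.

    ``substitution`` is one of ``half_loq`` (default), ``loq`` or ``zero``;
    the half-LOQ mean is bounded by the zero- and full-LOQ substitutions.
    """
    if not samples:
        raise NoDataError("censored_mean needs at least one sample")
    subs = {"half_loq": 0.5, "loq": 1.0, "zero": 0.0}
    if substitution not in subs:
        raise InvalidParameterError(f"unknown substitution {substitution!r}")
    f = subs[substitution]
    total = sum(s.value if s.detected else f * s.loq for s in samples)
    return total / len(samples)


@dataclass(frozen=True)
class ExceedanceResult:
    count: int
    fraction: float
    n_total: int


def fraction_above(samples: Sequence[CensoredSample], threshold: float) -> ExceedanceResult:
    """Count and fraction of samples strictly above a threshold.

    Nondetects count as below the threshold when their LOQ does not exceed
    it; a nondetect with LOQ above the threshold makes the comparison
    indeterminate and raises.
    """
    if not threshold > 0:
        raise InvalidParameterError("threshold must be > 0")
    if not samples:
        raise NoDataError("fraction_above needs at least one sample")
    count = 0
    for s in samples:
        if s.detected:
            if s.value > threshold:
                count += 1
        elif s.loq > threshold:
            raise IndeterminateCensoringError(
                f"nondetect with LOQ {s.loq} ug/L cannot be compared with "
                f"threshold {threshold} ug/L")
    return ExceedanceResult(count=count, fraction=count / len(samples),
                            n_total=len(samples))
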