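"""Two-step trend interchangeability classification.

The trend interchangeability method (TIM) decides, for each change between
two consecutive paired measurements of a reference method (RM) and a test
method (TM), whether the change measured by the test method is
interchangeable with the change measured by the reference method, given the
reference method's repeatability.

Step 1 (interpretability screen): a change in the reference method is
*interpretable* only when the precision intervals of its two reference
values — ``value ± value * RC`` where RC is the repeatability coefficient —
do not overlap.  Overlapping intervals mean the apparent change cannot be
distinguished from measurement noise, and the change is classed
``UNINTERPRETABLE``.

Step 2 (interchangeability zone): an interpretable change is projected into
the (test, reference) plane of the second pair.  Two *interchangeability
lines* anchored at the first pair bound the region where the second
reference reading is consistent with the second test reading:

    X = Y * (1 + RC) + (1 + RC) * (RM1 - TM1)
    X = Y * (1 - RC) + (1 + RC) * (RM1 - TM1)

with X the reference-axis and Y the test-axis coordinate of the second
pair.  The second pair is ``INTERCHANGEABLE`` when its reference value lies
between the two line evaluations at Y = TM2, in the ``GRAY_ZONE`` when it
lies outside but its precision interval still reaches the zone, and
``NONINTERCHANGEABLE`` otherwise.

The headline statistic is the trend interchangeability rate: interchangeable
changes divided by interpretable changes (gray-zone changes count in the
denominator only).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RepeatabilitySpec",
    "PairedSeries",
    "ChangeObservation",
    "InterchangeabilityLines",
    "Category",
    "ChangeClassification",
    "TrendSummary",
    "RateCategory",
    "RegionStatus",
    "CATEGORY_COLORS",
    "NonPositiveMeasurementWarning",
    "precision_interval",
    "is_interpretable",
    "interchangeability_lines",
    "region_status",
    "classify_change",
    "iter_changes",
    "classify_series",
    "summarize",
    "rate_category",
    "compare_devices",
]

#: Relative tolerance for every boundary comparison (interval touching,
#: points exactly on a line).  Far below any physiological resolution.
REL_TOL = 1e-9


class NonPositiveMeasurementWarning(UserWarning):
    """A measurement is zero or negative.

    The multiplicative precision interval and the interchangeability-line
    geometry are motivated by strictly positive quantities (flows, volumes,
    concentrations); the arithmetic still goes through with ``|value|``
    interval half-widths, but results for non-positive readings should be
    read with care.
    """


def _tol(*values: float) -> float:
    return REL_TOL * max(1.0, *(abs(v) for v in values))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatabilitySpec:
    """Repeatability of the reference method as a multiplicative coefficient.

    A single reference reading ``v`` is trusted to ``v ± v * coefficient``.
    Values >= 1 passed to the constructor are interpreted as percent and
    converted to a fraction (``5`` becomes ``0.05``).
    """

    coefficient: float

    def __post_init__(self) -> None:
        c = float(self.coefficient)
        if not math.isfinite(c) or c <= 0:
            raise ValueError(f"repeatability coefficient must be positive, got {c!r}")
        if c >= 1.0:
            c /= 100.0
        if not 0.0 < c < 1.0:
            raise ValueError(
                f"repeatability coefficient must lie in (0, 1) after percent "
                f"conversion, got {c!r}"
            )
        object.__setattr__(self, "coefficient", c)

    @classmethod
    def from_percent(cls, percent: float) -> "RepeatabilitySpec":
        return cls(float(percent) / 100.0)


@dataclass(frozen=True)
class PairedSeries:
    """One subject's ordered (reference, test) measurement pairs for one device.

    ``values`` is a sequence of ``(rm, tm, time_index)`` tuples with strictly
    increasing integer time index.  Consecutive time indices (difference of
    exactly one) define the changes the method classifies; a gap left by an
    excluded pair breaks adjacency so no change bridges it.
    """

    subject_id: str
    device: str
    values: tuple[tuple[float, float, int], ...]

    def __post_init__(self) -> None:
        vals = tuple((float(r), float(t), int(i)) for r, t, i in self.values)
        idx = [i for _, _, i in vals]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"time_index must be strictly increasing, got {idx}")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ChangeObservation:
    """Two consecutive paired measurements: (rm1, tm1) -> (rm2, tm2)."""

    rm1: float
    tm1: float
    rm2: float
    tm2: float

    @property
    def delta_rm(self) -> float:
        return self.rm2 - self.rm1

    @property
    def delta_tm(self) -> float:
        return self.tm2 - self.tm1


@dataclass(frozen=True)
class InterchangeabilityLines:
    """The two lines bounding the interchangeability zone, as (slope, intercept).

    Lines live in the (Y, X) plane: Y is the test-method coordinate, X the
    reference-method coordinate, of the second pair.  ``upper`` carries slope
    1+RC and ``lower`` slope 1-RC; with the as-published convention both
    intercepts equal ``(1+RC) * (rm1 - tm1)``.
    """

    upper: tuple[float, float]
    lower: tuple[float, float]

    def bounds_at(self, y: float) -> tuple[float, float]:
        """Reference-axis interval [lo, hi] of the zone at test value ``y``."""
        a = self.upper[0] * y + self.upper[1]
        b = self.lower[0] * y + self.lower[1]
        return (a, b) if a <= b else (b, a)


class Category(enum.Enum):
    UNINTERPRETABLE = "uninterpretable"
    NONINTERCHANGEABLE = "noninterchangeable"
    GRAY_ZONE = "gray_zone"
    INTERCHANGEABLE = "interchangeable"


#: Fixed color code used in every diagnostic plot.
CATEGORY_COLORS: dict[Category, str] = {
    Category.UNINTERPRETABLE: "blue",
    Category.NONINTERCHANGEABLE: "red",
    Category.GRAY_ZONE: "orange",
    Category.INTERCHANGEABLE: "green",
}


class RegionStatus(enum.Enum):
    INSIDE = "inside"
    BOUNDARY_OVERLAP = "boundary_overlap"
    OUTSIDE = "outside"


@dataclass(frozen=True)
class ChangeClassification:
    """Outcome for one change: a category plus its fixed plot color."""

    category: Category
    color: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "color", CATEGORY_COLORS[self.category])


class RateCategory(enum.Enum):
    EXCELLENT = "excellent"
    GOOD = "good"
    POOR = "poor"
    NOT_CLINICALLY_RELEVANT = "not_clinically_relevant"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class TrendSummary:
    """Per-device category counts and the trend interchangeability rate."""

    n_total: int
    n_uninterpretable: int
    n_noninterchangeable: int
    n_gray: int
    n_interchangeable: int
    device: str = ""

    def __post_init__(self) -> None:
        parts = (
            self.n_uninterpretable
            + self.n_noninterchangeable
            + self.n_gray
            + self.n_interchangeable
        )
        if parts != self.n_total:
            raise ValueError(
                f"category counts sum to {parts}, expected n_total={self.n_total}"
            )

    @property
    def n_interpretable(self) -> int:
        return self.n_total - self.n_uninterpretable

    @property
    def tim_rate(self) -> float | None:
        """Interchangeable / interpretable; None when nothing is interpretable."""
        if self.n_interpretable == 0:
            return None
        return self.n_interchangeable / self.n_interpretable

    @property
    def category_label(self) -> RateCategory:
        return rate_category(self.tim_rate)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


def _warn_non_positive(*values: float) -> None:
    if any(v <= 0 for v in values):
        warnings.warn(
            "non-positive measurement: multiplicative precision intervals and "
            "the interchangeability-zone geometry assume positive quantities",
            NonPositiveMeasurementWarning,
            stacklevel=3,
        )


def precision_interval(
    value: float, rc: RepeatabilitySpec | float
) -> tuple[float, float]:
    """Precision interval ``value ± |value| * RC`` of a single reference reading.

    The absolute value keeps lo <= hi for negative readings (for which a
    :class:`NonPositiveMeasurementWarning` is emitted by the classifier).
    """
    value = _check_finite("value", value)
    rc = rc if isinstance(rc, RepeatabilitySpec) else RepeatabilitySpec(rc)
    half = abs(value) * rc.coefficient
    return (value - half, value + half)


def is_interpretable(
    rm1: float, rm2: float, rc: RepeatabilitySpec | float
) -> bool:
    """True when the precision intervals of two reference readings are disjoint.

    Intervals that merely touch at one point count as overlapping
    (uninterpretable): a measure-zero separation is no evidence of change.
    """
    lo1, hi1 = precision_interval(rm1, rc)
    lo2, hi2 = precision_interval(rm2, rc)
    tol = _tol(lo1, hi1, lo2, hi2)
    return hi1 < lo2 - tol or hi2 < lo1 - tol


def interchangeability_lines(
    rm1: float,
    tm1: float,
    rc: RepeatabilitySpec | float,
    *,
    symmetric_intercepts: bool = False,
) -> InterchangeabilityLines:
    """The two lines bounding the zone of interchangeable second pairs.

    As published, the lower line carries slope ``1-RC`` but the *same*
    intercept factor ``(1+RC)(rm1-tm1)`` as the upper line.
    ``symmetric_intercepts=True`` switches the lower intercept to the
    plausibly intended ``(1-RC)(rm1-tm1)``; the default reproduces the
    published equations.
    """
    rm1 = _check_finite("rm1", rm1)
    tm1 = _check_finite("tm1", tm1)
    rc = rc if isinstance(rc, RepeatabilitySpec) else RepeatabilitySpec(rc)
    c = rc.coefficient
    offset = rm1 - tm1
    upper = (1.0 + c, (1.0 + c) * offset)
    lower_intercept = (1.0 - c) * offset if symmetric_intercepts else (1.0 + c) * offset
    lower = (1.0 - c, lower_intercept)
    return InterchangeabilityLines(upper=upper, lower=lower)


def region_status(
    rm2: float,
    tm2: float,
    lines: InterchangeabilityLines,
    rc: RepeatabilitySpec | float,
) -> RegionStatus:
    """Locate the second pair relative to the interchangeability zone.

    ``INSIDE`` when the reference value rm2 lies between the two line
    evaluations at Y = tm2 (closed region: points exactly on a line are
    inside).  ``BOUNDARY_OVERLAP`` when it does not, but the precision
    interval of rm2 — a segment along the reference axis at fixed Y = tm2 —
    still intersects the closed zone.  ``OUTSIDE`` otherwise.
    """
    rm2 = _check_finite("rm2", rm2)
    tm2 = _check_finite("tm2", tm2)
    lo, hi = lines.bounds_at(tm2)
    tol = _tol(lo, hi, rm2)
    if lo - tol <= rm2 <= hi + tol:
        return RegionStatus.INSIDE
    plo, phi = precision_interval(rm2, rc)
    if plo <= hi + tol and phi >= lo - tol:
        return RegionStatus.BOUNDARY_OVERLAP
    return RegionStatus.OUTSIDE


_STATUS_TO_CATEGORY = {
    RegionStatus.INSIDE: Category.INTERCHANGEABLE,
    RegionStatus.BOUNDARY_OVERLAP: Category.GRAY_ZONE,
    RegionStatus.OUTSIDE: Category.NONINTERCHANGEABLE,
}


def classify_change(
    change: ChangeObservation,
    rc: RepeatabilitySpec | float,
    *,
    symmetric_intercepts: bool = False,
) -> ChangeClassification:
    """Classify one change through the two-step algorithm.

    Step 1 consults only the reference values: overlapping precision
    intervals make the change ``UNINTERPRETABLE`` regardless of the test
    readings.  Step 2 maps the region status of the second pair to
    ``INTERCHANGEABLE`` / ``GRAY_ZONE`` / ``NONINTERCHANGEABLE``.
    """
    rc = rc if isinstance(rc, RepeatabilitySpec) else RepeatabilitySpec(rc)
    _warn_non_positive(change.rm1, change.tm1, change.rm2, change.tm2)
    if not is_interpretable(change.rm1, change.rm2, rc):
        return ChangeClassification(Category.UNINTERPRETABLE)
    lines = interchangeability_lines(
        change.rm1, change.tm1, rc, symmetric_intercepts=symmetric_intercepts
    )
    status = region_status(change.rm2, change.tm2, lines, rc)
    return ChangeClassification(_STATUS_TO_CATEGORY[status])


def iter_changes(
    series: PairedSeries, *, adjacent_only: bool = True
) -> Iterator[tuple[int, int, ChangeObservation]]:
    """Yield ``(time_from, time_to, change)`` for consecutive pairs of a series.

    With ``adjacent_only`` (default) a change is formed only between pairs
    whose time indices differ by exactly one, so a gap left by an excluded
    pair yields no bridged change.
    """
    for (r1, t1, i1), (r2, t2, i2) in zip(series.values, series.values[1:]):
        if adjacent_only and i2 - i1 != 1:
            continue
        yield i1, i2, ChangeObservation(rm1=r1, tm1=t1, rm2=r2, tm2=t2)


def classify_series(
    series_list: Iterable[PairedSeries],
    rc: RepeatabilitySpec | float,
    *,
    symmetric_intercepts: bool = False,
    adjacent_only: bool = True,
):
    """Classify every change of every series into a long-format table.

    Returns a :class:`pandas.DataFrame` with one row per change: subject,
    device, time_from/time_to, the four raw values, the deltas, the category
    and its plot color.
    """
    import pandas as pd

    rc = rc if isinstance(rc, RepeatabilitySpec) else RepeatabilitySpec(rc)
    rows = []
    for series in series_list:
        for i1, i2, change in iter_changes(series, adjacent_only=adjacent_only):
            cls = classify_change(
                change, rc, symmetric_intercepts=symmetric_intercepts
            )
            rows.append(
                {
                    "subject": series.subject_id,
                    "device": series.device,
                    "time_from": i1,
                    "time_to": i2,
                    "rm1": change.rm1,
                    "tm1": change.tm1,
                    "rm2": change.rm2,
                    "tm2": change.tm2,
                    "delta_rm": change.delta_rm,
                    "delta_tm": change.delta_tm,
                    "category": cls.category.value,
                    "color": cls.color,
                }
            )
    columns = [
        "subject", "device", "time_from", "time_to",
        "rm1", "tm1", "rm2", "tm2", "delta_rm", "delta_tm",
        "category", "color",
    ]
    return pd.DataFrame(rows, columns=columns)


def summarize(
    classifications: Iterable[ChangeClassification | Category],
    device: str = "",
) -> TrendSummary:
    """Count categories and form the trend interchangeability rate.

    The denominator is the number of interpretable changes (total minus
    uninterpretable); gray-zone changes belong to the denominator but not
    the numerator.  With no interpretable change the rate is undefined
    (``None``), not zero.
    """
    counts = {cat: 0 for cat in Category}
    for item in classifications:
        cat = item.category if isinstance(item, ChangeClassification) else Category(item)
        counts[cat] += 1
    return TrendSummary(
        n_total=sum(counts.values()),
        n_uninterpretable=counts[Category.UNINTERPRETABLE],
        n_noninterchangeable=counts[Category.NONINTERCHANGEABLE],
        n_gray=counts[Category.GRAY_ZONE],
        n_interchangeable=counts[Category.INTERCHANGEABLE],
        device=device,
    )


def rate_category(tim_rate: float | None) -> RateCategory:
    """Qualitative label for a trend interchangeability rate.

    >=95% excellent, >=90% good, 75-90% poor, <75% not clinically relevant.
    An undefined rate maps to ``UNDEFINED``.
    """
    if tim_rate is None:
        return RateCategory.UNDEFINED
    if not 0.0 <= tim_rate <= 1.0:
        raise ValueError(f"tim_rate must lie in [0, 1], got {tim_rate!r}")
    if tim_rate >= 0.95:
        return RateCategory.EXCELLENT
    if tim_rate >= 0.90:
        return RateCategory.GOOD
    if tim_rate >= 0.75:
        return RateCategory.POOR
    return RateCategory.NOT_CLINICALLY_RELEVANT


def compare_devices(
    summaries: Sequence[TrendSummary],
) -> tuple[float, float]:
    """Pearson chi-square comparison of interchangeability rates across devices.

    Builds the devices x {interchangeable, interpretable-but-not} contingency
    table and returns ``(statistic, two-tailed p)``.  Devices with a zero
    interpretable denominator are excluded with a warning.
    """
    rows = []
    for s in summaries:
        if s.n_interpretable == 0:
            warnings.warn(
                f"device {s.device or '<unnamed>'!r} has no interpretable "
                "changes and is excluded from the chi-square comparison",
                UserWarning,
                stacklevel=2,
            )
            continue
        rows.append([s.n_interchangeable, s.n_interpretable - s.n_interchangeable])
    if len(rows) < 2:
        raise ValueError("need at least 2 devices with interpretable changes")
    table = np.asarray(rows, dtype=float)
    # drop all-zero columns (e.g. every device fully interchangeable): the
    # table is then trivially homogeneous
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return 0.0, 1.0
    result = stats.chi2_contingency(table, correction=False)
    return float(result.statistic), float(result.pvalue)
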