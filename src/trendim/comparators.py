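"""Legacy trending statistics: four-quadrant concordance and polar-plot agreement.

These are the two comparators the trend interchangeability method is meant
to improve on; they are provided for side-by-side reporting.

The four-quadrant analysis scatters paired changes (dRM, dTM), removes a
central exclusion zone of clinically insignificant changes, and reports the
fraction of remaining points in the two quadrants of agreement (both
changes in the same direction).

The polar analysis converts each paired change to a vector; the angle it
makes with the line of identity Y = X measures trend disagreement.  The
customary acceptance thresholds are an angular bias within +/-5 degrees and
radial limits of agreement within +/-30 degrees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ChangePair",
    "PolarPoint",
    "ExclusionZone",
    "concordance_rate",
    "to_polar",
    "polar_stats",
    "changes_to_pairs",
    "ANGULAR_BIAS_THRESHOLD_DEG",
    "RADIAL_LOA_THRESHOLD_DEG",
]

#: Customary polar-plot acceptance thresholds, degrees.
ANGULAR_BIAS_THRESHOLD_DEG = 5.0
RADIAL_LOA_THRESHOLD_DEG = 30.0


@dataclass(frozen=True)
class ChangePair:
    """One paired change: delta of the reference and of the test method."""

    delta_rm: float
    delta_tm: float


@dataclass(frozen=True)
class PolarPoint:
    """A change as a vector: magnitude and angle (degrees) from the identity line.

    Positive angle means the test method exceeded the reference method.
    """

    radius: float
    angle: float

    def __post_init__(self) -> None:
        if not -180.0 <= self.angle <= 180.0:
            raise ValueError(f"angle must lie in [-180, 180], got {self.angle}")


@dataclass(frozen=True)
class ExclusionZone:
    """Central exclusion zone for the concordance analysis.

    Published choices are arbitrary and unstandardized, so the zone must be
    opted into.  ``absolute`` is a half-width in measurement units;
    ``percent`` defines the half-width as a percentage of the mean change
    magnitude of the dataset (scale-invariant).  A change is excluded when
    both |delta_rm| and |delta_tm| fall inside the square zone.
    """

    absolute: float | None = None
    percent: float | None = None

    def __post_init__(self) -> None:
        if (self.absolute is None) == (self.percent is None):
            raise ValueError("specify exactly one of absolute= or percent=")
        v = self.absolute if self.absolute is not None else self.percent
        if v < 0:
            raise ValueError("exclusion threshold must be non-negative")

    def half_width(self, changes: Sequence[ChangePair]) -> float:
        if self.absolute is not None:
            return float(self.absolute)
        mags = [max(abs(c.delta_rm), abs(c.delta_tm)) for c in changes]
        scale = float(np.mean(mags)) if mags else 0.0
        return self.percent / 100.0 * scale


def changes_to_pairs(changes: Iterable) -> list[ChangePair]:
    """Build :class:`ChangePair` records from change observations.

    Accepts anything with ``delta_rm``/``delta_tm`` attributes (e.g.
    :class:`trendim.core.ChangeObservation`) or 2-tuples.
    """
    out = []
    for c in changes:
        if isinstance(c, ChangePair):
            out.append(c)
        elif hasattr(c, "delta_rm"):
            out.append(ChangePair(float(c.delta_rm), float(c.delta_tm)))
        else:
            d_rm, d_tm = c
            out.append(ChangePair(float(d_rm), float(d_tm)))
    return out


def concordance_rate(
    changes: Iterable[ChangePair | tuple],
    exclusion: ExclusionZone | None = None,
) -> float | None:
    """Fraction of changes in the two quadrants of agreement.

    After removing changes inside the central exclusion zone (if any), a
    change is concordant when ``delta_rm * delta_tm > 0`` — both methods saw
    movement in the same direction.  A change lying exactly on an axis
    (one delta zero) is retained and counted discordant.  Returns ``None``
    when every change is excluded.
    """
    pairs = changes_to_pairs(changes)
    if exclusion is not None:
        h = exclusion.half_width(pairs)
        pairs = [
            c for c in pairs
            if not (abs(c.delta_rm) < h and abs(c.delta_tm) < h)
        ]
    if not pairs:
        warnings.warn(
            "all changes fall inside the exclusion zone; concordance rate "
            "undefined",
            UserWarning,
            stacklevel=2,
        )
        return None
    concordant = sum(1 for c in pairs if c.delta_rm * c.delta_tm > 0)
    return concordant / len(pairs)


def to_polar(
    change: ChangePair | tuple, *, fold_half_plane: bool = True
) -> PolarPoint:
    """Convert a paired change to its polar representation.

    The angle is measured from the line of identity Y = X: the raw vector
    angle ``atan2(delta_tm, delta_rm)`` minus 45 degrees, wrapped to
    (-180, 180].  With ``fold_half_plane`` (default) a vector in the
    lower-left half-plane is folded onto its mirror image through the
    origin, so a concordant decrease (-d, -d) reads as perfect agreement
    (0 degrees) exactly like the concordant increase (d, d); disagreement
    angles then stay within (-90, 90].  The zero vector is undefined.
    """
    pair = changes_to_pairs([change])[0]
    d_rm, d_tm = pair.delta_rm, pair.delta_tm
    if d_rm == 0.0 and d_tm == 0.0:
        raise ValueError("zero change vector has no polar representation")
    radius = math.hypot(d_rm, d_tm)
    angle = math.degrees(math.atan2(d_tm, d_rm)) - 45.0
    if angle <= -180.0:
        angle += 360.0
    if fold_half_plane:
        if angle > 90.0:
            angle -= 180.0
        elif angle <= -90.0:
            angle += 180.0
    return PolarPoint(radius=radius, angle=angle)


def polar_stats(
    points: Iterable[PolarPoint],
    exclusion_radius: float = 0.0,
) -> tuple[float, float]:
    """Angular bias and radial limits of agreement of a polar point set.

    Points with radius below ``exclusion_radius`` are removed first (the
    customary choice for cardiac output is 0.5 L/min).  The bias is the
    arithmetic mean of the angles; the radial limits of agreement are
    ``1.96 * SD`` of the angles.  Plain (non-circular) statistics are used:
    trending angles of interest cluster near zero, which is what the
    +/-5 and +/-30 degree thresholds presuppose.  Raises when fewer than
    two points survive.
    """
    surviving = [p for p in points if p.radius >= exclusion_radius]
    if len(surviving) < 2:
        raise ValueError(
            f"need >=2 points beyond the exclusion radius, have {len(surviving)}"
        )
    angles = np.array([p.angle for p in surviving])
    bias = float(np.mean(angles))
    sd = float(np.std(angles, ddof=1))
    return bias, 1.96 * sd
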