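"""Synthetic paired-series generator for method-comparison studies.

The default design emulates a simulated validation dataset of 150 patients
with 3 paired cardiac-output-like values (hence 2 changes) each.  Patients
are split evenly over three value ranges centered at 2.5, 3.5 and 5 units;
within a range each (reference, test) pair is drawn from a bivariate normal
distribution whose variance decreases as the range center grows.  Pooled
over ranges the reference readings span roughly 0 to 8 units with mean near
3.67 units.

``generate_biased`` adds a controlled test-method bias/noise scenario on
top of a design's reference trajectory, for property tests and sensitivity
sweeps: with zero bias and zero noise the test method reproduces the
reference exactly, so every interpretable change must classify as
interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import PairedSeries

__all__ = ["SimulationDesign", "generate", "generate_biased", "default_covariances"]


def default_covariances(n_ranges: int = 3) -> tuple[np.ndarray, ...]:
    """Per-range 2x2 covariance matrices of one (rm, tm) draw.

    Reference-method SDs 1.3, 1.1, 0.9 units for the low, middle and high
    range (variance shrinking as the center grows); the test method is 15%
    noisier and correlates 0.8 with the reference.
    """
    sd_rm = (1.3, 1.1, 0.9)
    if n_ranges != 3:
        raise ValueError("default covariances are defined for 3 ranges")
    out = []
    for s in sd_rm:
        sr, st, rho = s, 1.15 * s, 0.8
        out.append(np.array([[sr**2, rho * sr * st], [rho * sr * st, st**2]]))
    return tuple(out)


@dataclass(frozen=True)
class SimulationDesign:
    """Balanced multi-range design for paired serial measurements.

    Patients are assigned wholly to one range (each contributes all of their
    ``values_per_patient`` values there), so with the defaults each range
    yields 50 patients x 2 changes = 100 changes.
    """

    n_patients: int = 150
    values_per_patient: int = 3
    range_centers: tuple[float, ...] = (2.5, 3.5, 5.0)
    covariances: tuple[np.ndarray, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients % len(self.range_centers):
            raise ValueError(
                f"n_patients={self.n_patients} must be divisible by the "
                f"number of ranges ({len(self.range_centers)})"
            )
        if self.values_per_patient < 2:
            raise ValueError("need at least 2 values per patient to form a change")
        covs = self.covariances
        if covs is None:
            covs = default_covariances(len(self.range_centers))
        covs = tuple(np.asarray(c, dtype=float) for c in covs)
        if len(covs) != len(self.range_centers):
            raise ValueError("one covariance matrix required per range")
        for c in covs:
            if c.shape != (2, 2) or not np.allclose(c, c.T):
                raise ValueError("each covariance must be a symmetric 2x2 matrix")
            if np.min(np.linalg.eigvalsh(c)) < -1e-12:
                raise ValueError("covariance matrix must be positive semi-definite")
        object.__setattr__(self, "covariances", covs)


def generate(design: SimulationDesign) -> list[PairedSeries]:
    """Draw one dataset from a design; fully reproducible from its seed.

    Each patient's paired values are independent draws from the bivariate
    normal of their range.  Returns one :class:`PairedSeries` per patient
    (device label ``"TM"``).
    """
    rng = np.random.default_rng(design.seed)
    per_range = design.n_patients // len(design.range_centers)
    series: list[PairedSeries] = []
    patient = 0
    for center, cov in zip(design.range_centers, design.covariances):
        mean = np.array([center, center])
        draws = rng.multivariate_normal(
            mean, cov, size=(per_range, design.values_per_patient),
            method="cholesky" if np.min(np.linalg.eigvalsh(cov)) > 1e-12 else "svd",
        )
        for p in range(per_range):
            patient += 1
            values = tuple(
                (float(draws[p, t, 0]), float(draws[p, t, 1]), t)
                for t in range(design.values_per_patient)
            )
            series.append(
                PairedSeries(subject_id=f"P{patient:03d}", device="TM", values=values)
            )
    return series


def generate_biased(
    base: SimulationDesign, bias: float = 0.0, noise_sd: float = 0.0
) -> list[PairedSeries]:
    """Controlled scenario: test method = reference + bias + noise.

    Keeps the reference trajectories of ``base`` (same seed, same draws)
    and replaces the test readings with ``rm + bias + N(0, noise_sd)``.
    With ``bias=0, noise_sd=0`` the test method is an exact copy of the
    reference, the identity scenario.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([base.seed, 2**16]))
    out = []
    for series in generate(base):
        values = tuple(
            (rm, rm + bias + (rng.normal(0.0, noise_sd) if noise_sd else 0.0), t)
            for rm, _, t in series.values
        )
        out.append(
            PairedSeries(subject_id=series.subject_id, device=series.device, values=values)
        )
    return out
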