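"""Intersection-based estimation of the sample's relative permittivity.

When a coupling liquid is applied between the probe tip and an irregular
sample, the measured spectrum lies between the liquid's and the sample's
own spectra.  At a frequency where the measured "medium + sample" curve
meets the medium's own (averaged) curve, medium and sample have similar
permittivity — so the measured value there estimates the sample's
permittivity with minimal air-gap distortion.  Applying several media
with different dispersion produces intersections spread across the band,
yielding a point-wise estimate of the sample's eps'(f).

Per combination, the procedure is:

1. average the three medium-only acquisitions point-wise;
2. for each of the nine with-medium acquisitions, find the intersection
   with the averaged medium curve — the sampled grid frequency where the
   difference curve is closest to zero, required to change sign (or hit
   zero exactly) for the intersection to exist;
3. take the median (by value, lower-middle on even counts) of the
   intersecting acquisitions' values; the estimate inherits the
   frequency at which that median value was registered;
4. flag the estimate as excluded when the spread (max - min) of all nine
   with-medium acquisitions at that frequency reaches 5% of the estimate.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence

import numpy as np

from .dielectric import PermittivitySpectrum
from .simulate import AcquisitionSet

__all__ = [
    "IntersectionPoint",
    "EstimatePoint",
    "EXCLUSION_FRACTION",
    "average_medium_spectrum",
    "find_intersection",
    "estimate_point",
    "estimate_curve",
    "interpolate_estimates",
]

#: Exclusion rule: an estimate is discarded when the nine-acquisition
#: spread at its frequency reaches this fraction of the estimate.
EXCLUSION_FRACTION = 0.05


@dataclasses.dataclass(frozen=True)
class IntersectionPoint:
    """The sampled-grid intersection of one acquisition with the medium curve."""

    acquisition_index: int
    freq_index: int
    frequency: float
    eps_value: float


@dataclasses.dataclass(frozen=True)
class EstimatePoint:
    """One estimated (frequency, eps') point for the sample.

    ``variability_abs`` is the max-min spread of all nine with-medium
    acquisitions at the estimate's frequency; ``excluded`` marks points
    failing the 5% rule.
    """

    frequency: float
    eps_estimate: float
    medium_label: str
    n_intersections: int
    variability_abs: float
    excluded: bool


def average_medium_spectrum(
    medium_only: Sequence[PermittivitySpectrum],
) -> PermittivitySpectrum:
    """Point-wise mean of the three medium-only acquisitions."""
    if len(medium_only) != 3:
        raise ValueError(f"expected 3 medium-only spectra, got {len(medium_only)}")
    first = medium_only[0]
    for spec in medium_only[1:]:
        first.assert_same_grid(spec)
    mean = np.mean([s.eps_real for s in medium_only], axis=0)
    return PermittivitySpectrum(
        grid=first.grid, eps_real=mean, label=f"mean({first.label})"
    )


def find_intersection(
    acquisition: PermittivitySpectrum,
    medium_avg: PermittivitySpectrum,
    acquisition_index: int = 0,
) -> Optional[IntersectionPoint]:
    """Intersection of one acquisition with the averaged medium curve.

    The curves intersect when their difference changes sign on the grid
    (or equals zero at some grid point); the intersection is reported at
    the sampled grid frequency where the absolute difference is
    smallest, ties broken toward the lowest frequency.  Returns None
    when the curves do not intersect.
    """
    acquisition.assert_same_grid(medium_avg)
    d = acquisition.eps_real - medium_avg.eps_real
    has_zero = bool(np.any(d == 0.0))
    if not has_zero and (np.all(d > 0.0) or np.all(d < 0.0)):
        return None
    k = int(np.argmin(np.abs(d)))  # argmin takes the first (lowest-f) minimiser
    return IntersectionPoint(
        acquisition_index=acquisition_index,
        freq_index=k,
        frequency=float(acquisition.grid.values[k]),
        eps_value=float(acquisition.eps_real[k]),
    )


def estimate_point(acq_set: AcquisitionSet) -> Optional[EstimatePoint]:
    """Estimate the sample permittivity from one combination.

    Returns None when no acquisition intersects the medium curve (the
    medium's permittivity never crosses the measured curves, e.g. a
    medium entirely below the sample across the band).
    """
    medium_avg = average_medium_spectrum(acq_set.spectra_medium_only)
    hits: List[IntersectionPoint] = []
    for i, acq in enumerate(acq_set.spectra_with_medium):
        point = find_intersection(acq, medium_avg, acquisition_index=i)
        if point is not None:
            hits.append(point)
    if not hits:
        return None

    # Median by value; the lower-middle element on even counts so the
    # estimate remains a realised acquisition value with a frequency.
    hits_sorted = sorted(hits, key=lambda p: p.eps_value)
    chosen = hits_sorted[(len(hits_sorted) - 1) // 2]

    at_freq = np.array(
        [s.eps_real[chosen.freq_index] for s in acq_set.spectra_with_medium]
    )
    variability = float(at_freq.max() - at_freq.min())
    return EstimatePoint(
        frequency=chosen.frequency,
        eps_estimate=chosen.eps_value,
        medium_label=acq_set.medium.label,
        n_intersections=len(hits),
        variability_abs=variability,
        excluded=variability >= EXCLUSION_FRACTION * chosen.eps_value,
    )


def estimate_curve(sets: Sequence[AcquisitionSet]) -> List[EstimatePoint]:
    """Estimate the sample's eps'(f) from several media applied to one sample.

    One point per intersecting medium, sorted by frequency; points
    failing the 5% variability rule are retained with ``excluded=True``
    for reporting.
    """
    if not sets:
        return []
    ref = sets[0]
    for s in sets[1:]:
        if not s.grid.isclose(ref.grid):
            raise ValueError("acquisition sets span different frequency grids")
        if s.tooth_label != ref.tooth_label:
            raise ValueError(
                f"acquisition sets span different samples: "
                f"{s.tooth_label!r} vs {ref.tooth_label!r}"
            )
    points = [p for p in (estimate_point(s) for s in sets) if p is not None]
    return sorted(points, key=lambda p: p.frequency)


def interpolate_estimates(
    points: Sequence[EstimatePoint], target_freqs: Sequence[float]
) -> np.ndarray:
    """Piecewise-linear interpolation of non-excluded estimates.

    Extrapolation is refused: every target frequency must lie within the
    frequency span of the non-excluded points, of which at least two are
    required.
    """
    kept = sorted(
        (p for p in points if not p.excluded), key=lambda p: p.frequency
    )
    if len(kept) < 2:
        raise ValueError(
            f"interpolation needs >= 2 non-excluded points, got {len(kept)}"
        )
    freqs = np.array([p.frequency for p in kept])
    eps = np.array([p.eps_estimate for p in kept])
    targets = np.asarray(target_freqs, dtype=float)
    if np.any(targets < freqs[0]) or np.any(targets > freqs[-1]):
        raise ValueError(
            f"target frequencies outside the covered range "
            f"[{freqs[0]:.4g}, {freqs[-1]:.4g}] Hz"
        )
    return np.interp(targets, freqs, eps)
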