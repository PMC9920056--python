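"""Percentage-variation statistics qualifying probe measurements.

Two statistics recur throughout the workflow.  The first is the
percentage variation between two spectra,

    d_eps(f) = |eps'_A(f) - eps'_B(f)| / eps'_A(f) * 100,

averaged over the frequency grid.  It is deliberately asymmetric: the
denominator is always the reference curve eps'_A — the model in a
calibration validation, the highest recorded value in a repeatability
range (the acquisition least affected by air), the better-contact site
in a site comparison.  The second is the mean relative deviation of the
eight non-median acquisitions from the median acquisition of a
nine-repeat block.
"""

from __future__ import annotations

import dataclasses
from typing import List, Sequence, Tuple

import numpy as np

from .dielectric import PermittivitySpectrum
from .estimate import EstimatePoint, interpolate_estimates

__all__ = [
    "VariationReport",
    "DEFAULT_GATE_PERCENT",
    "percent_variation",
    "repeatability_variation",
    "median_relative_deviation",
    "validate_calibration",
    "compare_sites",
]

#: The highest acceptable error for dielectric-property measurements.
DEFAULT_GATE_PERCENT = 5.0

_DENOM_FLOOR = 1e-9


@dataclasses.dataclass(frozen=True)
class VariationReport:
    """Per-frequency percentage variation and its frequency average.

    ``denominator_rule`` records which curve served as the denominator:
    ``reference_a`` (explicit reference), ``highest_of_set``
    (repeatability range) or ``median_acq`` (median-acquisition
    deviation).
    """

    per_frequency: np.ndarray
    average: float
    denominator_rule: str


def _report(per_frequency: np.ndarray, rule: str) -> VariationReport:
    per_frequency = np.asarray(per_frequency, dtype=float)
    return VariationReport(
        per_frequency=per_frequency,
        average=float(per_frequency.mean()),
        denominator_rule=rule,
    )


def _check_denominator(values: np.ndarray) -> None:
    if np.any(np.abs(values) < _DENOM_FLOOR):
        raise ValueError(
            "denominator spectrum contains near-zero values; eps' >= 1 is "
            "expected physically, so this indicates corrupt input"
        )


def percent_variation(
    eps_a: PermittivitySpectrum, eps_b: PermittivitySpectrum
) -> VariationReport:
    """Percentage variation of ``eps_b`` relative to the reference ``eps_a``."""
    eps_a.assert_same_grid(eps_b)
    _check_denominator(eps_a.eps_real)
    per_f = np.abs(eps_a.eps_real - eps_b.eps_real) / eps_a.eps_real * 100.0
    return _report(per_f, "reference_a")


def repeatability_variation(
    repeats: Sequence[PermittivitySpectrum],
) -> VariationReport:
    """Range-based variation across repeated acquisitions.

    Per frequency, the range (max - min) relative to the highest
    recorded value — the acquisition least affected by air — expressed
    in percent and averaged over frequency.
    """
    if len(repeats) < 2:
        raise ValueError(f"need >= 2 repeats, got {len(repeats)}")
    first = repeats[0]
    for spec in repeats[1:]:
        first.assert_same_grid(spec)
    stack = np.array([s.eps_real for s in repeats])
    upper = stack.max(axis=0)
    lower = stack.min(axis=0)
    _check_denominator(upper)
    per_f = (upper - lower) / upper * 100.0
    return _report(per_f, "highest_of_set")


def median_relative_deviation(
    acquisitions: Sequence[PermittivitySpectrum],
    median_acq: PermittivitySpectrum,
) -> VariationReport:
    """Mean relative deviation of the eight non-median acquisitions from
    the median acquisition of a nine-repeat block, in percent."""
    if len(acquisitions) != 9:
        raise ValueError(f"expected 9 acquisitions, got {len(acquisitions)}")
    median_acq.assert_same_grid(acquisitions[0])

    others: List[PermittivitySpectrum] = []
    removed = False
    for acq in acquisitions:
        if not removed and (
            acq is median_acq or np.array_equal(acq.eps_real, median_acq.eps_real)
        ):
            removed = True
            continue
        median_acq.assert_same_grid(acq)
        others.append(acq)
    if not removed:
        raise ValueError("median_acq is not a member of the nine acquisitions")

    _check_denominator(median_acq.eps_real)
    diffs = np.array(
        [np.abs(o.eps_real - median_acq.eps_real) for o in others]
    )
    per_f = 100.0 * diffs.mean(axis=0) / median_acq.eps_real
    return _report(per_f, "median_acq")


def validate_calibration(
    measured: PermittivitySpectrum,
    reference: PermittivitySpectrum,
    gate_percent: float = DEFAULT_GATE_PERCENT,
) -> Tuple[VariationReport, bool]:
    """Compare a validation acquisition against its modelled reference.

    Passes when the frequency-averaged percentage variation (reference
    in the denominator) stays below ``gate_percent``.
    """
    if not (gate_percent > 0):
        raise ValueError(f"gate_percent must be positive, got {gate_percent}")
    report = percent_variation(reference, measured)
    return report, report.average < gate_percent


def compare_sites(
    est_ref: Sequence[EstimatePoint], est_other: Sequence[EstimatePoint]
) -> float:
    """Average percentage change between site estimates.

    The reference site's estimates are interpolated to the other site's
    intersection frequencies; the percentage changes (interpolated
    reference in the denominator) are averaged.  The reference estimates
    must cover every frequency of the other site's non-excluded points.
    """
    other = sorted(
        (p for p in est_other if not p.excluded), key=lambda p: p.frequency
    )
    if not other:
        raise ValueError("no non-excluded points in est_other")
    targets = np.array([p.frequency for p in other])
    ref_vals = interpolate_estimates(est_ref, targets)
    _check_denominator(ref_vals)
    other_vals = np.array([p.eps_estimate for p in other])
    changes = np.abs(ref_vals - other_vals) / ref_vals * 100.0
    return float(changes.mean())
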