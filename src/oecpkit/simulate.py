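"""Forward simulator of probe acquisition sessions with contact contamination.

An open-ended coaxial probe pressed against an irregular solid senses a
mixture of whatever fills its sensing volume: the sample itself, any
coupling liquid applied to the tip, and residual air where the contact
is poor.  Measured properties of such a heterogeneous load lie between
the properties of its constituents, so the simulator uses the simplest
law with that bounding property — a convex (volume-weighted) combination

    eps'_meas(f) = w_m * eps'_medium(f) + w_t * eps'_tooth(f) + w_a * 1

with per-acquisition jitter of the weights (re-normalised, clipped at
zero) emulating acquisition-to-acquisition contact variability, plus
additive Gaussian noise per frequency point.  Every acquisition is
reproducible from ``(seed, draw_index)``.

A full "coupling medium + tooth" combination follows the measurement
protocol: 2 calibration-validation acquisitions of saline, 3 acquisitions
of the coupling medium alone (beginning, middle and end of the repeat
block), 9 acquisitions of the tooth with the medium and 9 of the bare
tooth — 23 counted acquisitions.  Air checks interleaved with the
repeats are scheduled but not counted.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .dielectric import (
    CouplingMedium,
    DebyeParams,
    FrequencyGrid,
    PermittivitySpectrum,
    eval_cole_cole,
)
from .materials import SALINE_0P1M_20C, saline_reference

__all__ = [
    "ContactModel",
    "AcquisitionSet",
    "PlanEntry",
    "SessionPlan",
    "ROLE_VALIDATION",
    "ROLE_MEDIUM_ONLY",
    "ROLE_TOOTH_WITH_MEDIUM",
    "ROLE_TOOTH_BARE",
    "ROLE_AIR_CHECK",
    "COUNTED_ROLES",
    "SCENARIOS",
    "default_contact",
    "default_bare_contact",
    "plan_session",
    "simulate_acquisition",
    "simulate_combination",
    "generate_study",
]

ROLE_VALIDATION = "validation"
ROLE_MEDIUM_ONLY = "medium_only"
ROLE_TOOTH_WITH_MEDIUM = "tooth_with_medium"
ROLE_TOOTH_BARE = "tooth_bare"
ROLE_AIR_CHECK = "air_check"

#: Roles that count toward the 23 acquisitions of a combination.
COUNTED_ROLES = (
    ROLE_VALIDATION,
    ROLE_MEDIUM_ONLY,
    ROLE_TOOTH_WITH_MEDIUM,
    ROLE_TOOTH_BARE,
)

#: Expected counted-role composition of one combination.
ROLE_COUNTS = {
    ROLE_VALIDATION: 2,
    ROLE_MEDIUM_ONLY: 3,
    ROLE_TOOTH_WITH_MEDIUM: 9,
    ROLE_TOOTH_BARE: 9,
}

# Draw-index offsets keep the RNG streams of the different roles disjoint.
_DRAW_WITH_MEDIUM = 0
_DRAW_BARE = 100
_DRAW_MEDIUM_ONLY = 200
_DRAW_VALIDATION = 300


@dataclasses.dataclass(frozen=True)
class ContactModel:
    """Stochastic probe-contact model: mean mixing weights for the
    coupling medium, the tooth and residual air, with per-acquisition
    weight jitter and additive measurement noise.

    ``weight_jitter_sd`` is the standard deviation of the Gaussian
    perturbation applied to each weight before clipping at zero and
    re-normalising; ``noise_sd`` is the per-frequency additive noise on
    eps' (dimensionless).
    """

    w_medium: float
    w_tooth: float
    w_air: float
    weight_jitter_sd: float = 0.03
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("w_medium", "w_tooth", "w_air"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        total = self.w_medium + self.w_tooth + self.w_air
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"mixing weights must sum to 1, got {total!r}")
        if self.weight_jitter_sd < 0 or self.noise_sd < 0:
            raise ValueError("jitter and noise standard deviations must be >= 0")
        if int(self.seed) != self.seed or self.seed < 0:
            raise ValueError("seed must be a non-negative integer")


def default_contact(seed: int = 0) -> ContactModel:
    """Contact with a coupling medium applied: the liquid wets the gap,
    so residual air is small."""
    return ContactModel(
        w_medium=0.35, w_tooth=0.63, w_air=0.02,
        weight_jitter_sd=0.01, noise_sd=0.05, seed=seed,
    )


def default_bare_contact(seed: int = 0) -> ContactModel:
    """Bare contact on an irregular surface: a large, highly variable air
    fraction in the sensing volume."""
    return ContactModel(
        w_medium=0.0, w_tooth=0.65, w_air=0.35,
        weight_jitter_sd=0.08, noise_sd=0.05, seed=seed,
    )


@dataclasses.dataclass(frozen=True)
class PlanEntry:
    role: str
    sequence_index: int


@dataclasses.dataclass(frozen=True)
class SessionPlan:
    """Ordered acquisition schedule for one combination."""

    combination_id: str
    entries: Sequence[PlanEntry]

    @property
    def counted(self) -> List[PlanEntry]:
        return [e for e in self.entries if e.role != ROLE_AIR_CHECK]

    def role_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for e in self.counted:
            counts[e.role] = counts.get(e.role, 0) + 1
        return counts


def plan_session(combination_id: str) -> SessionPlan:
    """Acquisition schedule for one "coupling medium + tooth" combination.

    Two validations bracket the session; the coupling medium alone is
    measured at the beginning, middle and end of the nine-repeat block;
    each repeat consists of an (uncounted) air check, a bare-tooth
    acquisition and a tooth-with-medium acquisition.  Counted
    acquisitions total 23: 2 + 3 + 9 + 9.
    """
    roles: List[str] = [ROLE_VALIDATION, ROLE_MEDIUM_ONLY]
    for repeat in range(9):
        roles += [ROLE_AIR_CHECK, ROLE_TOOTH_BARE, ROLE_TOOTH_WITH_MEDIUM]
        if repeat == 4:  # middle of the nine-repeat block
            roles.append(ROLE_MEDIUM_ONLY)
    roles += [ROLE_MEDIUM_ONLY, ROLE_VALIDATION]
    entries = tuple(PlanEntry(role=r, sequence_index=i) for i, r in enumerate(roles))
    return SessionPlan(combination_id=combination_id, entries=entries)


@dataclasses.dataclass
class AcquisitionSet:
    """All counted spectra of one "coupling medium + tooth" combination."""

    combination_id: str
    medium: CouplingMedium
    tooth_label: str
    spectra_with_medium: List[PermittivitySpectrum]
    spectra_bare: List[PermittivitySpectrum]
    spectra_medium_only: List[PermittivitySpectrum]
    spectra_validation: List[PermittivitySpectrum]
    truth_tooth: Optional[PermittivitySpectrum] = None

    def __post_init__(self) -> None:
        counts = (
            len(self.spectra_with_medium),
            len(self.spectra_bare),
            len(self.spectra_medium_only),
            len(self.spectra_validation),
        )
        if counts != (9, 9, 3, 2):
            raise ValueError(
                f"acquisition counts must be 9/9/3/2, got {counts}"
            )
        ref = self.spectra_with_medium[0]
        for spec in self.all_spectra():
            ref.assert_same_grid(spec)

    def all_spectra(self) -> List[PermittivitySpectrum]:
        return (
            self.spectra_with_medium
            + self.spectra_bare
            + self.spectra_medium_only
            + self.spectra_validation
        )

    @property
    def grid(self) -> FrequencyGrid:
        return self.spectra_with_medium[0].grid


def _rng(seed: int, draw_index: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(draw_index)])


def simulate_acquisition(
    tooth: PermittivitySpectrum,
    medium: Optional[PermittivitySpectrum],
    contact: ContactModel,
    draw_index: int,
) -> PermittivitySpectrum:
    """One probe acquisition: a jittered convex mix of medium, tooth and
    air permittivities plus additive noise.

    When ``medium`` is None (bare-tooth acquisition) the medium weight is
    reassigned to air: the gap the liquid would have filled is empty.
    """
    if medium is not None:
        tooth.assert_same_grid(medium)
        base = np.array([contact.w_medium, contact.w_tooth, contact.w_air])
        med_vals = medium.eps_real
    else:
        base = np.array([0.0, contact.w_tooth, contact.w_air + contact.w_medium])
        med_vals = np.ones(tooth.grid.n_points)

    rng = _rng(contact.seed, draw_index)
    w = np.clip(base + rng.normal(0.0, contact.weight_jitter_sd, size=3), 0.0, None)
    total = w.sum()
    w = base if total <= 0 else w / total

    eps = (
        w[0] * med_vals
        + w[1] * tooth.eps_real
        + w[2] * np.ones(tooth.grid.n_points)
    )
    eps = eps + rng.normal(0.0, contact.noise_sd, size=tooth.grid.n_points)
    return PermittivitySpectrum(
        grid=tooth.grid,
        eps_real=np.maximum(eps, 1e-6),
        label=f"acq[{draw_index}]",
        temperature_c=tooth.temperature_c,
    )


def simulate_combination(
    tooth_truth: PermittivitySpectrum,
    medium: CouplingMedium,
    contact: ContactModel,
    bare_contact: ContactModel,
    combination_id: str = "",
    saline: DebyeParams = SALINE_0P1M_20C,
) -> AcquisitionSet:
    """Simulate the full 23-acquisition protocol for one combination."""
    grid = tooth_truth.grid
    med_spec = eval_cole_cole(medium.params, grid, label=medium.label)
    saline_spec = saline_reference(grid, saline)
    combination_id = combination_id or f"{tooth_truth.label}+{medium.label}"

    with_medium = [
        simulate_acquisition(tooth_truth, med_spec, contact, _DRAW_WITH_MEDIUM + k)
        for k in range(9)
    ]
    bare = [
        simulate_acquisition(tooth_truth, None, bare_contact, _DRAW_BARE + k)
        for k in range(9)
    ]

    def _noisy(model: PermittivitySpectrum, draw: int, tag: str) -> PermittivitySpectrum:
        noise = _rng(contact.seed, draw).normal(
            0.0, contact.noise_sd, size=grid.n_points
        )
        return PermittivitySpectrum(
            grid=grid, eps_real=np.maximum(model.eps_real + noise, 1e-6), label=tag
        )

    medium_only = [
        _noisy(med_spec, _DRAW_MEDIUM_ONLY + k, f"{medium.label}[{k}]")
        for k in range(3)
    ]
    validation = [
        _noisy(saline_spec, _DRAW_VALIDATION + k, f"validation[{k}]") for k in range(2)
    ]
    return AcquisitionSet(
        combination_id=combination_id,
        medium=medium,
        tooth_label=tooth_truth.label,
        spectra_with_medium=with_medium,
        spectra_bare=bare,
        spectra_medium_only=medium_only,
        spectra_validation=validation,
        truth_tooth=tooth_truth,
    )


# ---------------------------------------------------------------------------
# Study scenarios

SCENARIOS = (
    "baseline",
    "test_A_large_amount",
    "test_A_small_amount",
    "test_B_delayed",
    "poor_contact_R2",
)

#: Weight shift applied by the amount-of-medium perturbation (Test A):
#: the probe is not moved between the two amounts, so the composition of
#: the sensing volume changes only slightly.
TEST_A_WEIGHT_SHIFT = 0.01
#: Fractional shrink of the medium relaxation strength after exposure to
#: ambient conditions (Test B, delayed measurement).
TEST_B_DELTA_EPS_DRIFT = 0.02
#: Poor-contact (concave-site) shifts: more pooled medium, more residual
#: air under the probe, at the expense of tooth contact.
POOR_CONTACT_D_MEDIUM = 0.10
POOR_CONTACT_D_AIR = 0.05
POOR_CONTACT_BARE_D_AIR = 0.20


def _shift_weights(
    contact: ContactModel, d_medium: float = 0.0, d_air: float = 0.0
) -> ContactModel:
    w_m = contact.w_medium + d_medium
    w_a = contact.w_air + d_air
    w_t = 1.0 - w_m - w_a
    if min(w_m, w_a, w_t) < 0:
        raise ValueError("weight shift drives a mixing weight negative")
    return dataclasses.replace(contact, w_medium=w_m, w_tooth=w_t, w_air=w_a)


def _drift_medium(medium: CouplingMedium, shrink: float) -> CouplingMedium:
    params = dataclasses.replace(
        medium.params, delta_eps=medium.params.delta_eps * (1.0 - shrink)
    )
    return dataclasses.replace(medium, params=params)


def generate_study(
    tooth_truths: Mapping[str, PermittivitySpectrum],
    media: Sequence[CouplingMedium],
    contact: ContactModel,
    bare_contact: Optional[ContactModel] = None,
    scenario: str = "baseline",
) -> List[AcquisitionSet]:
    """Simulate one AcquisitionSet per "medium + tooth" combination.

    Scenarios perturb the baseline study: Test A shifts the medium
    mixing weight up/down (amount of liquid applied), Test B shrinks the
    medium relaxation strength (liquid exposed to ambient conditions
    before the delayed measurement), and ``poor_contact_R2`` emulates a
    concave measurement site with more pooled medium and more residual
    air.  Each combination draws from its own seeded stream, derived
    deterministically from the contact seed.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if bare_contact is None:
        bare_contact = default_bare_contact(seed=contact.seed)

    if scenario == "test_A_large_amount":
        contact = _shift_weights(contact, d_medium=+TEST_A_WEIGHT_SHIFT)
    elif scenario == "test_A_small_amount":
        contact = _shift_weights(contact, d_medium=-TEST_A_WEIGHT_SHIFT)
    elif scenario == "poor_contact_R2":
        contact = _shift_weights(
            contact, d_medium=POOR_CONTACT_D_MEDIUM, d_air=POOR_CONTACT_D_AIR
        )
        bare_contact = _shift_weights(bare_contact, d_air=POOR_CONTACT_BARE_D_AIR)

    sets: List[AcquisitionSet] = []
    combo_index = 0
    for tooth_label, truth in tooth_truths.items():
        for medium in media:
            applied = medium
            if scenario == "test_B_delayed":
                applied = _drift_medium(medium, TEST_B_DELTA_EPS_DRIFT)
            seed_i = contact.seed + 1009 * combo_index
            sets.append(
                simulate_combination(
                    truth,
                    applied,
                    dataclasses.replace(contact, seed=seed_i),
                    dataclasses.replace(bare_contact, seed=seed_i),
                    combination_id=f"{tooth_label}+{medium.label}",
                )
            )
            combo_index += 1
    return sets
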