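"""Core dielectric types: frequency grids, permittivity spectra and
single-pole relaxation models.

Everything downstream — the forward simulator, the intersection-based
estimator and the variability statistics — operates on
:class:`PermittivitySpectrum` objects: a shared linearly spaced frequency
grid paired with the real part of the relative permittivity, ``eps'(f)``.
Materials (water, glycerin, saline, coupling media) are described by
single-pole Cole-Cole parameters (:class:`DebyeParams`); only the real
part of the complex permittivity is ever consumed, so the static ionic
conductivity ``sigma_s`` is carried but never enters any curve.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FrequencyGrid",
    "PermittivitySpectrum",
    "DebyeParams",
    "CouplingMedium",
    "make_frequency_grid",
    "default_grid",
    "eval_cole_cole",
    "air_spectrum",
    "DEFAULT_F_MIN_HZ",
    "DEFAULT_F_MAX_HZ",
    "DEFAULT_N_POINTS",
]

#: Default acquisition band: 101 linearly spaced points, 0.5-18 GHz.
DEFAULT_F_MIN_HZ = 0.5e9
DEFAULT_F_MAX_HZ = 18.0e9
DEFAULT_N_POINTS = 101


@dataclasses.dataclass(frozen=True)
class FrequencyGrid:
    """A linearly spaced frequency grid in Hz, endpoints included."""

    f_min: float
    f_max: float
    n_points: int

    def __post_init__(self) -> None:
        if not (self.f_min > 0):
            raise ValueError(f"f_min must be positive, got {self.f_min}")
        if not (self.f_max > self.f_min):
            raise ValueError(
                f"f_max ({self.f_max}) must exceed f_min ({self.f_min})"
            )
        if int(self.n_points) != self.n_points or self.n_points < 2:
            raise ValueError(f"n_points must be an integer >= 2, got {self.n_points}")

    @property
    def values(self) -> np.ndarray:
        """Grid frequencies in Hz (ascending, both endpoints included)."""
        return np.linspace(self.f_min, self.f_max, self.n_points)

    @property
    def step(self) -> float:
        """Constant spacing between consecutive grid frequencies, Hz."""
        return (self.f_max - self.f_min) / (self.n_points - 1)

    def isclose(self, other: "FrequencyGrid", rtol: float = 1e-9) -> bool:
        return (
            self.n_points == other.n_points
            and math.isclose(self.f_min, other.f_min, rel_tol=rtol)
            and math.isclose(self.f_max, other.f_max, rel_tol=rtol)
        )


def make_frequency_grid(
    f_min: float = DEFAULT_F_MIN_HZ,
    f_max: float = DEFAULT_F_MAX_HZ,
    n_points: int = DEFAULT_N_POINTS,
) -> FrequencyGrid:
    """Build a linear frequency grid; defaults to the 0.5-18 GHz, 101-point band."""
    return FrequencyGrid(float(f_min), float(f_max), int(n_points))


def default_grid() -> FrequencyGrid:
    return make_frequency_grid()


@dataclasses.dataclass
class PermittivitySpectrum:
    """Real relative permittivity ``eps'(f)`` sampled on a frequency grid.

    Parameters
    ----------
    grid : FrequencyGrid
        The shared frequency grid.
    eps_real : array-like
        Dimensionless real relative permittivity, one value per grid point,
        all strictly positive (air is exactly 1; liquids and tissues > 1).
    label : str
        Free-text provenance tag (material, acquisition role, ...).
    temperature_c : float, optional
        Acquisition temperature. Metadata only; never enters computation.
    """

    grid: FrequencyGrid
    eps_real: np.ndarray
    label: str = ""
    temperature_c: Optional[float] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.eps_real, dtype=float)
        if arr.ndim != 1 or arr.size != self.grid.n_points:
            raise ValueError(
                f"eps_real must be 1-D with {self.grid.n_points} values, "
                f"got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("eps_real contains non-finite values")
        if not np.all(arr > 0):
            raise ValueError("eps_real must be strictly positive everywhere")
        self.eps_real = arr

    @property
    def frequencies(self) -> np.ndarray:
        return self.grid.values

    def assert_same_grid(self, other: "PermittivitySpectrum") -> None:
        if not self.grid.isclose(other.grid):
            raise ValueError(
                f"grids differ: {self.grid} vs {other.grid}"
            )


@dataclasses.dataclass(frozen=True)
class DebyeParams:
    """Single-pole Cole-Cole relaxation parameters.

    ``eps*(w) = eps_inf + delta_eps / (1 + (j w tau_s)^(1 - alpha))``,
    with ``alpha = 0`` reducing to the Debye form. The static value is
    ``eps_s = eps_inf + delta_eps``. ``sigma_s`` (S/m) affects only the
    imaginary part and is carried for completeness of the saline set.
    """

    eps_inf: float
    delta_eps: float
    tau_s: float
    alpha: float = 0.0
    sigma_s: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_inf < 1:
            raise ValueError(f"eps_inf must be >= 1, got {self.eps_inf}")
        if self.delta_eps < 0:
            raise ValueError(f"delta_eps must be >= 0, got {self.delta_eps}")
        if not (self.tau_s > 0):
            raise ValueError(f"tau_s must be positive, got {self.tau_s}")
        if not (0 <= self.alpha < 1):
            raise ValueError(f"alpha must lie in [0, 1), got {self.alpha}")
        if self.sigma_s < 0:
            raise ValueError(f"sigma_s must be >= 0, got {self.sigma_s}")

    @property
    def eps_static(self) -> float:
        return self.eps_inf + self.delta_eps


@dataclasses.dataclass(frozen=True)
class CouplingMedium:
    """A glycerin-water coupling liquid, labelled ``G[X]`` with X the
    glycerin volume percentage."""

    label: str
    glycerin_fraction: float
    params: DebyeParams

    def __post_init__(self) -> None:
        if not (0 <= self.glycerin_fraction <= 1):
            raise ValueError(
                f"glycerin_fraction must lie in [0, 1], got {self.glycerin_fraction}"
            )
        expected = f"G[{round(100 * self.glycerin_fraction)}]"
        if self.label != expected:
            raise ValueError(
                f"label {self.label!r} inconsistent with fraction "
                f"{self.glycerin_fraction} (expected {expected!r})"
            )


def eval_cole_cole(
    params: DebyeParams, grid: FrequencyGrid, label: str = ""
) -> PermittivitySpectrum:
    """Evaluate the real part of a Cole-Cole relaxation on a grid.

    For ``alpha = 0`` this is the Debye real part
    ``eps_inf + delta_eps / (1 + (w tau)^2)``. The result is strictly
    decreasing in frequency for ``delta_eps > 0``.
    """
    w = 2.0 * np.pi * grid.values
    denom = 1.0 + (1j * w * params.tau_s) ** (1.0 - params.alpha)
    eps = params.eps_inf + params.delta_eps / denom
    return PermittivitySpectrum(grid=grid, eps_real=eps.real, label=label)


def air_spectrum(grid: FrequencyGrid) -> PermittivitySpectrum:
    """The air reference: ``eps' = 1`` at every frequency."""
    return PermittivitySpectrum(grid=grid, eps_real=np.ones(grid.n_points), label="air")
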