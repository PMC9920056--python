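"""Material parameter sets and the glycerin-water coupling-medium family.

The workflow needs deterministic reference curves for four kinds of
material: distilled water (the calibration liquid), 0.1 M NaCl (the
calibration-validation liquid), vegetable glycerin (the other mixture
endpoint) and synthetic tooth tissue.  The water and saline sets are
Debye fits representative of the liquids near 20 C; glycerin is given a
broadened (Cole-Cole) relaxation whose main dispersion sits well below
the band, so that pure glycerin is low-permittivity (eps' ~ 4-10 across
0.5-18 GHz) while water-rich mixtures reach eps' ~ 55-70 at the low end
of the band.  Mixtures interpolate the endpoint parameters (linear in
``eps_inf``, ``delta_eps`` and ``alpha``; log-linear in ``tau_s``),
which yields a family that is strictly ordered in glycerin fraction at
every band frequency — the only property the intersection method relies
on.

Synthetic tooth targets are gentle linear trends matching the plateaus
reported for healthy dental tissue: crown-like ~10-11 and root-like
~9.5-8 over the band.

All sets can be overridden from a YAML/JSON file via
:func:`load_materials`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import yaml

from .dielectric import (
    CouplingMedium,
    DebyeParams,
    FrequencyGrid,
    PermittivitySpectrum,
    eval_cole_cole,
)

__all__ = [
    "WATER_20C",
    "GLYCERIN",
    "SALINE_0P1M_20C",
    "TOOTH_CROWN_RANGE",
    "TOOTH_ROOT_RANGE",
    "MATERIALS",
    "glycerin_water_medium",
    "media_catalogue",
    "catalogue_fractions",
    "saline_reference",
    "tooth_truth",
    "crown_truth",
    "root_truth",
    "load_materials",
]

#: Distilled water near 20 C (Debye: eps_s ~ 80.1, relaxation ~ 17 GHz).
WATER_20C = DebyeParams(eps_inf=5.2, delta_eps=74.9, tau_s=9.3e-12, alpha=0.0)

#: Vegetable glycerin: broadened relaxation centred far below the band.
GLYCERIN = DebyeParams(eps_inf=4.0, delta_eps=38.5, tau_s=1.0e-9, alpha=0.10)

#: 0.1 M NaCl near 20 C. The salt depresses the static permittivity a
#: little relative to pure water and adds ionic conductivity; only the
#: real part is consumed by the validation check.
SALINE_0P1M_20C = DebyeParams(
    eps_inf=5.2, delta_eps=72.9, tau_s=9.2e-12, alpha=0.0, sigma_s=1.07
)

#: Synthetic tooth targets: (eps' at f_min, eps' at f_max), linear in f.
TOOTH_CROWN_RANGE = (10.0, 11.0)
TOOTH_ROOT_RANGE = (9.5, 8.0)

MATERIALS: Dict[str, DebyeParams] = {
    "water": WATER_20C,
    "glycerin": GLYCERIN,
    "saline_0p1M": SALINE_0P1M_20C,
}


def glycerin_water_medium(
    glycerin_fraction: float,
    water: DebyeParams = WATER_20C,
    glycerin: DebyeParams = GLYCERIN,
) -> CouplingMedium:
    """Coupling medium at a given glycerin volume fraction.

    The mixing rule interpolates the endpoint parameter sets: linearly in
    ``eps_inf``, ``delta_eps``, ``alpha`` and ``sigma_s``, and
    log-linearly in ``tau_s`` (relaxation times vary over two orders of
    magnitude between water and glycerin).  Endpoints are returned
    exactly at fractions 0 and 1.
    """
    g = float(glycerin_fraction)
    if not (0.0 <= g <= 1.0):
        raise ValueError(f"glycerin_fraction must lie in [0, 1], got {g}")
    w = 1.0 - g
    if g == 1.0 or g == 0.0:  # endpoints returned exactly
        params = glycerin if g == 1.0 else water
        return CouplingMedium(
            label=f"G[{round(100 * g)}]", glycerin_fraction=g, params=params
        )
    params = DebyeParams(
        eps_inf=g * glycerin.eps_inf + w * water.eps_inf,
        delta_eps=g * glycerin.delta_eps + w * water.delta_eps,
        tau_s=math.exp(g * math.log(glycerin.tau_s) + w * math.log(water.tau_s)),
        alpha=g * glycerin.alpha + w * water.alpha,
        sigma_s=g * glycerin.sigma_s + w * water.sigma_s,
    )
    return CouplingMedium(
        label=f"G[{round(100 * g)}]", glycerin_fraction=g, params=params
    )


def catalogue_fractions() -> List[float]:
    """Glycerin volume fractions of the standard twelve-medium catalogue,
    1.00 down to 0.45 in steps of 0.05."""
    return [round((100 - 5 * i) / 100, 2) for i in range(12)]


def media_catalogue() -> List[CouplingMedium]:
    """The twelve standard coupling media, G[100] ... G[45]."""
    return [glycerin_water_medium(g) for g in catalogue_fractions()]


def saline_reference(
    grid: FrequencyGrid, params: DebyeParams = SALINE_0P1M_20C
) -> PermittivitySpectrum:
    """Modelled 0.1 M NaCl eps'(f): the calibration-validation reference."""
    return eval_cole_cole(params, grid, label="saline_0p1M_model")


def tooth_truth(
    grid: FrequencyGrid,
    eps_at_f_min: float,
    eps_at_f_max: float,
    label: str = "tooth",
) -> PermittivitySpectrum:
    """A synthetic tooth-tissue target: linear trend in frequency between
    the stated band-edge permittivities (set both equal for a flat target)."""
    t = (grid.values - grid.f_min) / (grid.f_max - grid.f_min)
    eps = eps_at_f_min + (eps_at_f_max - eps_at_f_min) * t
    return PermittivitySpectrum(grid=grid, eps_real=eps, label=label)


def crown_truth(grid: FrequencyGrid) -> PermittivitySpectrum:
    """Crown-like target: eps' rising gently from 10 to 11 across the band."""
    return tooth_truth(grid, *TOOTH_CROWN_RANGE, label="crown")


def root_truth(grid: FrequencyGrid) -> PermittivitySpectrum:
    """Root-like target: eps' falling from 9.5 to 8 across the band."""
    return tooth_truth(grid, *TOOTH_ROOT_RANGE, label="root")


_PARAM_FIELDS = {f.name for f in dataclasses.fields(DebyeParams)}


def load_materials(path: Union[str, Path]) -> Dict[str, DebyeParams]:
    """Load named parameter sets from a YAML or JSON file.

    The file maps set names to DebyeParams fields, e.g.::

        water:
          eps_inf: 5.2
          delta_eps: 74.9
          tau_s: 9.3e-12
          alpha: 0.0

    Unknown keys (such as ``temperature_c`` metadata) are ignored.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of parameter sets")
    out: Dict[str, DebyeParams] = {}
    for name, fields in raw.items():
        if not isinstance(fields, dict):
            raise ValueError(f"{path}: entry {name!r} is not a mapping")
        kwargs = {k: float(v) for k, v in fields.items() if k in _PARAM_FIELDS}
        missing = {"eps_inf", "delta_eps", "tau_s"} - set(kwargs)
        if missing:
            raise ValueError(f"{path}: entry {name!r} missing {sorted(missing)}")
        out[name] = DebyeParams(**kwargs)
    return out
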