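"""Spectrum CSV files, session manifests and the end-to-end pipeline.

On disk a spectrum is a two-column CSV (``frequency_hz``, ``eps_real``;
comma-separated, dot decimal, header mandatory, frequencies written as
integers where exact).  A measurement session is a directory of spectrum
CSVs plus a YAML manifest declaring the frequency grid and, per
combination, the role of every file.  The pipeline reads a manifest,
gates each combination on its calibration-validation acquisitions,
averages the medium-only acquisitions, runs the intersection estimator
and emits an estimates CSV plus a per-combination report.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .dielectric import FrequencyGrid, PermittivitySpectrum, make_frequency_grid
from .estimate import EstimatePoint, estimate_point
from .materials import glycerin_water_medium, saline_reference
from .simulate import (
    ROLE_MEDIUM_ONLY,
    ROLE_TOOTH_BARE,
    ROLE_TOOTH_WITH_MEDIUM,
    ROLE_VALIDATION,
    AcquisitionSet,
)
from .variability import DEFAULT_GATE_PERCENT, validate_calibration

__all__ = [
    "PipelineConfig",
    "CombinationReport",
    "read_spectrum",
    "write_spectrum",
    "write_session",
    "read_session",
    "estimates_to_frame",
    "frame_to_estimates",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_GRID_RTOL = 1e-6

_ROLE_ATTR = {
    ROLE_TOOTH_WITH_MEDIUM: "spectra_with_medium",
    ROLE_TOOTH_BARE: "spectra_bare",
    ROLE_MEDIUM_ONLY: "spectra_medium_only",
    ROLE_VALIDATION: "spectra_validation",
}

ESTIMATE_COLUMNS = [
    "frequency_hz",
    "eps_estimate",
    "medium_label",
    "n_intersections",
    "variability_abs",
    "excluded",
]


def read_spectrum(path: Union[str, Path]) -> PermittivitySpectrum:
    """Read and validate a spectrum CSV.

    Frequencies must be ascending and linearly spaced (relative
    tolerance 1e-6); permittivities must be strictly positive.  An
    ``eps_imag`` column, if present, is ignored with a logged warning.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = {"frequency_hz", "eps_real"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "eps_imag" in frame.columns:
        logger.warning("%s: ignoring eps_imag column (only eps' is consumed)", path)

    f = frame["frequency_hz"].to_numpy(dtype=float)
    eps = frame["eps_real"].to_numpy(dtype=float)
    if f.size < 2:
        raise ValueError(f"{path}: need >= 2 frequency points, got {f.size}")
    if np.any(np.diff(f) <= 0):
        raise ValueError(f"{path}: frequencies must be strictly ascending")
    expected = np.linspace(f[0], f[-1], f.size)
    if not np.allclose(f, expected, rtol=0, atol=_GRID_RTOL * (f[-1] - f[0])):
        raise ValueError(f"{path}: frequencies are not linearly spaced")
    if np.any(eps <= 0):
        raise ValueError(f"{path}: eps_real must be strictly positive")
    grid = make_frequency_grid(f[0], f[-1], f.size)
    return PermittivitySpectrum(grid=grid, eps_real=eps, label=path.stem)


def write_spectrum(spectrum: PermittivitySpectrum, path: Union[str, Path]) -> None:
    """Write a spectrum CSV (frequencies serialised as integers where exact)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    freqs = spectrum.grid.values
    freq_col: List[Union[int, float]] = [
        int(f) if float(f).is_integer() else float(f) for f in freqs
    ]
    rows = [
        f"{f},{float(e)!r}" for f, e in zip(freq_col, spectrum.eps_real)
    ]  # repr round-trips doubles exactly
    path.write_text("frequency_hz,eps_real\n" + "\n".join(rows) + "\n")


def _safe_name(text: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in text)


def write_session(
    sets: Sequence[AcquisitionSet],
    out_dir: Union[str, Path],
    seed: Optional[int] = None,
    temperature_c: Optional[float] = None,
) -> Path:
    """Write a session directory: one CSV per spectrum plus ``manifest.yaml``.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    combos = []
    for acq_set in sets:
        grid = acq_set.grid
        cdir = _safe_name(acq_set.combination_id)
        entries = []
        for role, attr in _ROLE_ATTR.items():
            for k, spec in enumerate(getattr(acq_set, attr)):
                rel = f"{cdir}/{role}_{k:02d}.csv"
                write_spectrum(spec, out_dir / rel)
                entries.append({"role": role, "path": rel})
        combos.append(
            {
                "combination_id": acq_set.combination_id,
                "tooth_label": acq_set.tooth_label,
                "medium_label": acq_set.medium.label,
                "glycerin_fraction": acq_set.medium.glycerin_fraction,
                "temperature_c": temperature_c,
                "seed": seed,
                "spectra": entries,
            }
        )
    if sets:
        grid = sets[0].grid
        grid_decl = {
            "f_min": grid.f_min,
            "f_max": grid.f_max,
            "n_points": grid.n_points,
            "unit": "Hz",
        }
    else:
        grid_decl = None
    manifest = {"grid": grid_decl, "combinations": combos}
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def read_session(manifest_path: Union[str, Path]) -> List[AcquisitionSet]:
    """Read a session manifest back into acquisition sets.

    Every referenced file must exist, parse, and match the declared
    grid; role counts per combination must be 9/9/3/2.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = yaml.safe_load(manifest_path.read_text())
    combos = manifest.get("combinations") or []
    declared: Optional[FrequencyGrid] = None
    if manifest.get("grid"):
        g = manifest["grid"]
        declared = make_frequency_grid(g["f_min"], g["f_max"], g["n_points"])

    sets: List[AcquisitionSet] = []
    for combo in combos:
        by_role: Dict[str, List[PermittivitySpectrum]] = {
            role: [] for role in _ROLE_ATTR
        }
        for entry in combo["spectra"]:
            role = entry["role"]
            if role not in by_role:
                raise ValueError(
                    f"{manifest_path}: unknown role {role!r} in combination "
                    f"{combo.get('combination_id')!r}"
                )
            spec = read_spectrum(base / entry["path"])
            if declared is not None and not spec.grid.isclose(declared, _GRID_RTOL):
                raise ValueError(
                    f"{entry['path']}: grid does not match the declared grid"
                )
            spec.temperature_c = combo.get("temperature_c")
            by_role[role].append(spec)
        medium = glycerin_water_medium(float(combo["glycerin_fraction"]))
        sets.append(
            AcquisitionSet(
                combination_id=combo["combination_id"],
                medium=medium,
                tooth_label=combo.get("tooth_label", ""),
                spectra_with_medium=by_role[ROLE_TOOTH_WITH_MEDIUM],
                spectra_bare=by_role[ROLE_TOOTH_BARE],
                spectra_medium_only=by_role[ROLE_MEDIUM_ONLY],
                spectra_validation=by_role[ROLE_VALIDATION],
            )
        )
    return sets


def estimates_to_frame(points: Sequence[EstimatePoint]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [
            {
                "frequency_hz": p.frequency,
                "eps_estimate": p.eps_estimate,
                "medium_label": p.medium_label,
                "n_intersections": p.n_intersections,
                "variability_abs": p.variability_abs,
                "excluded": p.excluded,
            }
            for p in points
        ],
        columns=ESTIMATE_COLUMNS,
    )
    return frame


def frame_to_estimates(frame: pd.DataFrame) -> List[EstimatePoint]:
    return [
        EstimatePoint(
            frequency=float(row.frequency_hz),
            eps_estimate=float(row.eps_estimate),
            medium_label=str(row.medium_label),
            n_intersections=int(row.n_intersections),
            variability_abs=float(row.variability_abs),
            excluded=bool(row.excluded),
        )
        for row in frame.itertuples()
    ]


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Pipeline behaviour knobs.

    ``on_validation_failure`` selects what happens to a combination whose
    calibration-validation acquisitions exceed the gate: ``warn`` keeps
    it (flagged), ``skip`` drops its estimate, ``abort`` raises.
    """

    gate_percent: float = DEFAULT_GATE_PERCENT
    on_validation_failure: str = "warn"

    def __post_init__(self) -> None:
        if self.on_validation_failure not in ("warn", "skip", "abort"):
            raise ValueError(
                f"on_validation_failure must be warn/skip/abort, "
                f"got {self.on_validation_failure!r}"
            )


@dataclasses.dataclass(frozen=True)
class CombinationReport:
    combination_id: str
    medium_label: str
    validation_avg_percent: float
    validation_passed: bool
    n_intersections: int
    excluded: Optional[bool]
    estimated: bool


def run_pipeline(
    manifest_path: Union[str, Path],
    config: PipelineConfig = PipelineConfig(),
) -> Tuple[pd.DataFrame, List[CombinationReport]]:
    """Run validation gating, medium averaging and estimation on a session.

    Returns the estimates table (one row per medium that produced an
    intersection, excluded points flagged) and per-combination reports.
    Deterministic: identical manifest and config yield identical output.
    """
    sets = read_session(manifest_path)
    points: List[EstimatePoint] = []
    reports: List[CombinationReport] = []
    for acq_set in sets:
        reference = saline_reference(acq_set.grid)
        val_avgs = []
        passed = True
        for spec in acq_set.spectra_validation:
            report, ok = validate_calibration(spec, reference, config.gate_percent)
            val_avgs.append(report.average)
            passed = passed and ok
        val_avg = float(np.mean(val_avgs))
        if not passed:
            msg = (
                f"{acq_set.combination_id}: validation error {val_avg:.2f}% "
                f"exceeds the {config.gate_percent:.1f}% gate"
            )
            if config.on_validation_failure == "abort":
                raise ValueError(msg)
            logger.warning(msg)

        point = None
        if passed or config.on_validation_failure == "warn":
            point = estimate_point(acq_set)
            if point is not None:
                points.append(point)
        reports.append(
            CombinationReport(
                combination_id=acq_set.combination_id,
                medium_label=acq_set.medium.label,
                validation_avg_percent=val_avg,
                validation_passed=passed,
                n_intersections=0 if point is None else point.n_intersections,
                excluded=None if point is None else point.excluded,
                estimated=point is not None,
            )
        )
        logger.info(
            "%s: validation %.2f%% (%s), %s",
            acq_set.combination_id,
            val_avg,
            "pass" if passed else "FAIL",
            "no intersection"
            if point is None
            else f"{point.n_intersections} intersections"
            + (" [excluded]" if point.excluded else ""),
        )
    points.sort(key=lambda p: p.frequency)
    return estimates_to_frame(points), reports
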