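"""Phantom study scenarios and the strip measurement pipeline.

The published phantom studies drive a 20 mm thick gel layer at 150 Hz
and read the shear wavelength off the lateral displacement profile.
``strip_wavelength`` reproduces that pipeline on a 2D plane-strain
strip: run the engine for a few excitation cycles, sample the top
surface at four equally spaced phases of the final cycle, pool the
peak-to-peak intervals (excluding the near-field first peak), and —
when the run used a scaled density — multiply the result back by
sqrt(S).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import default_time_step, run
from .errors import DomainError
from .grid import BoundarySpec, strip_grid, top_center_excitation, voxelize_cylinder
from .materials import ElasticMaterial, wave_speeds
from .measurement import (
    LineWaveform,
    WavelengthEstimate,
    extract_line_profile,
    peak_intervals,
)
from .rescaling import rescale_wavelength, scale_material

__all__ = [
    "ScenarioPreset",
    "phantom_presets",
    "strip_wavelength",
    "simulate_strip",
    "run_preset",
    "reflection_free_range",
]


@dataclass(frozen=True)
class ScenarioPreset:
    """One published phantom configuration."""

    name: str
    material: ElasticMaterial
    geometry: str  # "cylinder" or "strip"
    diameter: float  # m; strip length for strip geometry
    thickness: float
    frequency: float = 150.0
    bottom_fixed: tuple = ("y",)
    scaling_s: float = 1.0
    expected_wavelength: float | None = None
    note: str = ""


def phantom_presets() -> list:
    """The published study matrix.

    Bulk sweep: E in {30, 60, 120} kPa x rho in {0.5, 1, 2}e3 kg/m^3
    (expected wavelengths are the analytic bulk values V_T/f); the
    E = 90 kPa phantom whose published simulated wavelength is 37 mm;
    and the boundary-condition study variants on 20/40 mm layers.
    """
    presets = []
    for e_kpa in (30, 60, 120):
        for rho in (500.0, 1000.0, 2000.0):
            mat = ElasticMaterial(e_kpa * 1e3, 0.495, rho)
            lam_bulk = wave_speeds(mat).transverse / 150.0
            presets.append(
                ScenarioPreset(
                    name=f"bulk_E{e_kpa}k_rho{int(rho)}",
                    material=mat,
                    geometry="cylinder",
                    diameter=0.2,
                    thickness=0.02,
                    expected_wavelength=lam_bulk,
                    note="expected value is the analytic bulk shear wavelength",
                )
            )
    presets.append(
        ScenarioPreset(
            name="phantom_E90k",
            material=ElasticMaterial(90e3, 0.495, 1000.0),
            geometry="cylinder",
            diameter=0.2,
            thickness=0.02,
            expected_wavelength=37e-3,
            note="published simulated wavelength of the 150 Hz phantom study",
        )
    )
    mat90 = ElasticMaterial(90e3, 0.495, 1000.0)
    for name, thickness, fixed in (
        ("bc_20mm_yfixed", 0.02, ("y",)),
        ("bc_20mm_xfixed", 0.02, ("x",)),
        ("bc_20mm_free", 0.02, ()),
        ("bc_40mm_yfixed", 0.04, ("y",)),
        ("bc_40mm_free", 0.04, ()),
    ):
        presets.append(
            ScenarioPreset(
                name=name,
                material=mat90,
                geometry="strip",
                diameter=0.2,
                thickness=thickness,
                bottom_fixed=fixed,
                note="boundary-condition study variant",
            )
        )
    return presets


def reflection_free_range(length: float, v_t: float, t_end: float) -> float:
    """Largest source distance unreached by end reflections at t_end.

    A shear front launched at the centre of a strip of the given length
    reflects at the end (length/2 away) and walks back; positions below
    ``length - v_t * t_end`` have not yet been revisited.
    """
    return length - v_t * t_end


def simulate_strip(
    material: ElasticMaterial,
    length: float = 0.2,
    thickness: float = 0.02,
    spacing: float = 1e-3,
    frequency: float = 150.0,
    n_cycles: float = 3.0,
    amplitude: float = 1e-6,
    bottom_fixed: tuple = ("y",),
    dt: float | None = None,
    n_phases: int = 4,
):
    """Run the plane-strain strip scenario; snapshots at final-cycle phases.

    Returns ``(grid, records, meta)`` where the records hold one full
    snapshot per requested phase of the last completed excitation
    cycle and ``meta`` carries dt and the snapshot step indices.
    """
    if n_phases < 1:
        raise DomainError("n_phases must be >= 1")
    grid = strip_grid(length, thickness, spacing)
    if dt is None:
        dt = default_time_step(material, grid.spacings)
    n_steps = int(round(n_cycles / frequency / dt))
    excitation = top_center_excitation(
        grid, frequency=frequency, amplitude=amplitude, component="y"
    )
    bcs = [BoundarySpec("bottom", bottom_fixed)] if bottom_fixed else []
    steps_per_cycle = 1.0 / (frequency * dt)
    snaps = sorted(
        {
            int(round(n_steps - q * steps_per_cycle / n_phases))
            for q in range(n_phases)
        }
    )
    _, records = run(
        grid, material, excitation, bcs, dt, n_steps, snapshot_steps=snaps
    )
    meta = {"dt": dt, "n_steps": n_steps, "snapshot_steps": snaps}
    return grid, records, meta


def strip_wavelength(
    material: ElasticMaterial,
    length: float = 0.2,
    thickness: float = 0.02,
    spacing: float = 1e-3,
    frequency: float = 150.0,
    n_cycles: float = 3.0,
    amplitude: float = 1e-6,
    bottom_fixed: tuple = ("y",),
    scaling_s: float = 1.0,
    n_phases: int = 4,
    max_range: float | None = None,
) -> WavelengthEstimate:
    """Peak-to-peak shear wavelength of the strip scenario, m.

    Runs the engine (with the density scaled by ``scaling_s`` when
    requested), samples the vertical displacement along the top surface
    from the driver outward at ``n_phases`` phases of the final cycle,
    pools the peak intervals of every phase (near-field first peak
    excluded), and inverse-rescales the pooled mean by sqrt(S).  The
    measurement ray is truncated where end reflections have already
    returned (estimated with the shear speed).
    """
    sim_material = scale_material(material, scaling_s)
    grid, records, meta = simulate_strip(
        sim_material,
        length=length,
        thickness=thickness,
        spacing=spacing,
        frequency=frequency,
        n_cycles=n_cycles,
        amplitude=amplitude,
        bottom_fixed=bottom_fixed,
        n_phases=n_phases,
    )
    v_t = wave_speeds(sim_material).transverse
    t_end = meta["n_steps"] * meta["dt"]
    if max_range is None:
        max_range = reflection_free_range(length, v_t, t_end)
    max_range = min(max_range, length / 2.0 - 2.0 * spacing)
    n_samples = max(int(max_range / spacing) + 1, 8)
    centre = grid.top_center_node()
    pooled = []
    for s in meta["snapshot_steps"]:
        profile = extract_line_profile(
            records.snapshots[s],
            grid,
            centre,
            axis=0,
            component="y",
            n_samples=n_samples,
            time_stamp=records.times[s],
        )
        try:
            pooled.append(peak_intervals(profile, exclude_near_field=True))
        except Exception:
            continue  # a phase may catch the field near a zero crossing
    if not pooled:
        raise DomainError("no phase snapshot produced two or more peaks")
    intervals = np.concatenate(pooled)
    mean = rescale_wavelength(float(np.mean(intervals)), scaling_s)
    std = float(np.std(intervals)) * math.sqrt(scaling_s)
    return WavelengthEstimate(
        mean=mean, std=std, n_intervals=int(intervals.size), method="peaks"
    )


def run_preset(preset: ScenarioPreset, spacing: float | None = None, n_cycles: float = 0.5):
    """Smoke-run a preset end-to-end at reduced scale.

    Cylinder presets are voxelised in 3D at a coarse spacing (a
    fraction of the diameter), strip presets run in 2D; both use the
    default time step and a short run.  Returns the probe records.
    """
    mat = scale_material(preset.material, preset.scaling_s)
    f = preset.frequency
    if preset.geometry == "cylinder":
        dx = spacing or preset.diameter / 20.0
        grid = voxelize_cylinder(preset.diameter, preset.thickness, dx)
        excitation = top_center_excitation(grid, frequency=f, patch=1)
    else:
        dx = spacing or preset.thickness / 10.0
        grid = strip_grid(preset.diameter, preset.thickness, dx)
        excitation = top_center_excitation(grid, frequency=f)
    dt = default_time_step(mat, grid.spacings)
    n_steps = max(int(round(n_cycles / f / dt)), 10)
    bcs = [BoundarySpec("bottom", preset.bottom_fixed)] if preset.bottom_fixed else []
    _, records = run(
        grid, mat, excitation, bcs, dt, n_steps, snapshot_steps=[n_steps]
    )
    return grid, records
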