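"""Profile CSV dialects, VTK/raw snapshot writers and config loading.

CSV numbers are written in full-precision scientific notation with a
locale-independent decimal point, so a save/load round trip is
lossless.  Volumetric snapshots go out as legacy ASCII VTK
structured-points files (one scalar field per displacement component)
or as a flat float64 binary with a plain-text sidecar header.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, LisaWaveError
from .measurement import LineWaveform

__all__ = [
    "save_profile_csv",
    "load_profile_csv",
    "write_vtk_snapshot",
    "write_raw_snapshot",
    "load_config",
]

_PROFILE_HEADER = "position_m,displacement_m"


def save_profile_csv(profile: LineWaveform, path) -> None:
    """Write a line profile as ``position_m,displacement_m`` rows."""
    lines = [_PROFILE_HEADER]
    for x, u in zip(profile.positions, profile.displacements):
        lines.append(f"{x:.17e},{u:.17e}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_profile_csv(path) -> LineWaveform:
    """Read a ``position_m,displacement_m`` CSV; errors name the line."""
    text = Path(path).read_text().strip().splitlines()
    if not text or text[0].strip() != _PROFILE_HEADER:
        raise LisaWaveError(
            f"{path}: line 1: expected header {_PROFILE_HEADER!r}"
        )
    xs, us = [], []
    for lineno, row in enumerate(text[1:], start=2):
        row = row.strip()
        if not row:
            continue
        parts = row.split(",")
        if len(parts) != 2:
            raise LisaWaveError(f"{path}: line {lineno}: expected 2 fields")
        try:
            xs.append(float(parts[0]))
            us.append(float(parts[1]))
        except ValueError as exc:
            raise LisaWaveError(f"{path}: line {lineno}: {exc}") from None
    return LineWaveform(positions=np.array(xs), displacements=np.array(us))


def write_vtk_snapshot(path, snapshot: np.ndarray, spacings, names=None) -> None:
    """Legacy ASCII VTK structured-points file of a displacement field.

    ``snapshot`` has shape (ncomp, nx, ny[, nz]); 2D fields are written
    as a one-cell-deep volume.  Each component becomes one scalar
    point-data field.
    """
    snapshot = np.asarray(snapshot, float)
    ncomp = snapshot.shape[0]
    dims = snapshot.shape[1:]
    if len(dims) == 2:
        dims = (*dims, 1)
        snapshot = snapshot[..., None]
        spacings = (*spacings, spacings[-1])
    if names is None:
        names = ["u", "v", "w"][:ncomp]
    npoints = int(np.prod(dims))
    out = [
        "# vtk DataFile Version 3.0",
        "lisawave displacement snapshot",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}",
        "ORIGIN 0 0 0",
        f"SPACING {spacings[0]:.9e} {spacings[1]:.9e} {spacings[2]:.9e}",
        f"POINT_DATA {npoints}",
    ]
    for comp, name in zip(range(ncomp), names):
        out.append(f"SCALARS {name} double 1")
        out.append("LOOKUP_TABLE default")
        # VTK expects x fastest: transpose to (z, y, x) then ravel
        flat = snapshot[comp].transpose(2, 1, 0).ravel()
        out.extend(f"{v:.9e}" for v in flat)
    Path(path).write_text("\n".join(out) + "\n")


def write_raw_snapshot(path_prefix, snapshot: np.ndarray, spacings, dt: float, step: int) -> None:
    """Flat float64 binary + plain-text sidecar header (.bin / .hdr)."""
    snapshot = np.asarray(snapshot, float)
    prefix = Path(path_prefix)
    snapshot.astype("<f8").tofile(prefix.with_suffix(".bin"))
    header = [
        f"shape {' '.join(str(s) for s in snapshot.shape)}",
        f"spacing {' '.join(f'{s:.17e}' for s in spacings)}",
        f"dt {dt:.17e}",
        f"step {step}",
        "dtype float64 little-endian",
        "order C (component, x, y[, z])",
    ]
    prefix.with_suffix(".hdr").write_text("\n".join(header) + "\n")


# ---------------------------------------------------------------------------
# configuration

_SCHEMA = {
    "material": {"E", "nu", "rho"},
    "grid": {"kind", "length", "thickness", "diameter", "spacing"},
    "excitation": {"frequency", "amplitude", "component", "patch"},
    "bc": None,  # list of {region, fix}
    "run": {"n_cycles", "n_steps", "dt", "n_phases"},
    "scaling": {"S"},
}
_BC_KEYS = {"region", "fix"}
_REQUIRED = {"material": ("E", "nu", "rho"), "grid": ("kind", "spacing")}


def load_config(path) -> dict:
    """Load and validate a simulation config (YAML mapping).

    Unknown keys are rejected with the offending key named; required
    keys (material.E/nu/rho, grid.kind/spacing) must be present.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    for section, content in raw.items():
        if section not in _SCHEMA:
            raise ConfigError(f"{path}: unknown section {section!r}")
        allowed = _SCHEMA[section]
        if allowed is None:
            if not isinstance(content, list):
                raise ConfigError(f"{path}: section 'bc' must be a list")
            for i, entry in enumerate(content):
                for key in entry:
                    if key not in _BC_KEYS:
                        raise ConfigError(
                            f"{path}: unknown key 'bc[{i}].{key}'"
                        )
        else:
            if not isinstance(content, dict):
                raise ConfigError(f"{path}: section {section!r} must be a mapping")
            for key in content:
                if key not in allowed:
                    raise ConfigError(
                        f"{path}: unknown key '{section}.{key}'"
                    )
    for section, keys in _REQUIRED.items():
        if section not in raw:
            raise ConfigError(f"{path}: missing section {section!r}")
        for key in keys:
            if key not in raw[section]:
                raise ConfigError(f"{path}: missing key '{section}.{key}'")
    kind = raw["grid"]["kind"]
    if kind not in ("strip", "cylinder"):
        raise ConfigError(f"{path}: grid.kind must be 'strip' or 'cylinder'")
    if kind == "strip" and "length" not in raw["grid"]:
        raise ConfigError(f"{path}: missing key 'grid.length'")
    if kind == "cylinder" and "diameter" not in raw["grid"]:
        raise ConfigError(f"{path}: missing key 'grid.diameter'")
    if "thickness" not in raw["grid"]:
        raise ConfigError(f"{path}: missing key 'grid.thickness'")
    return raw
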