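"""Plain-text readers/writers for every in-scope data type.

Dialects:

* umbrella window tables — two whitespace columns (time ps, coordinate nm)
  with ``#`` header lines recording ``center``, ``spring`` and
  ``temperature``; a window-set directory holds one table per window plus a
  ``windows.tsv`` metadata file (filename, center, spring) so externally
  produced pull-coordinate tables can be ingested by listing them there;
* XYZ configurations with the box edges on the comment line
  (``box <lx> <ly> <lz>``);
* release curves as CSV (``time_h,fraction[,stderr]``);
* PMF profiles and bonded-parameter tables as TSV; free-energy results and
  pipeline reports as JSON.

Every reader produces line-numbered diagnostics on malformed input, and
``read(write(x))`` round trips exactly for every type.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .alchemical_mbar import FreeEnergyResult, ReducedPotentialMatrix
from .release_kinetics import ReleaseCurve
from .toy_sim import ParticleConfiguration
from .umbrella_wham import PMFProfile, UmbrellaWindow, WindowSet

__all__ = [
    "FormatError",
    "write_window_table",
    "read_window_table",
    "write_window_set",
    "read_window_set",
    "write_xyz",
    "read_xyz",
    "write_release_curve",
    "read_release_curve",
    "write_pmf",
    "write_umatrix",
    "read_umatrix",
    "write_free_energy",
    "read_free_energy",
]


class FormatError(ValueError):
    """Malformed input file; message carries file and line number."""


def _fail(path, lineno, msg):
    raise FormatError(f"{path}:{lineno}: {msg}")


# --------------------------------------------------------------------------- #
# Umbrella windows
# --------------------------------------------------------------------------- #


def write_window_table(path, window: UmbrellaWindow, temperature: float, dt: float = 1.0):
    """One window as a two-column (time ps, coordinate nm) table."""
    with open(path, "w") as fh:
        fh.write(f"# center = {float(window.center)!r}\n")
        fh.write(f"# spring = {float(window.spring_constant)!r}\n")
        fh.write(f"# temperature = {float(temperature)!r}\n")
        for i, z in enumerate(window.samples):
            fh.write(f"{i * dt:.6g}\t{float(z)!r}\n")


def read_window_table(path) -> Tuple[UmbrellaWindow, float]:
    """Read one window table; returns (window, temperature)."""
    meta = {}
    samples = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("=")
                if len(parts) == 2:
                    meta[parts[0].strip()] = parts[1].strip()
                continue
            cols = line.split()
            if len(cols) != 2:
                _fail(path, lineno, f"expected 2 columns, got {len(cols)}")
            try:
                samples.append(float(cols[1]))
            except ValueError:
                _fail(path, lineno, f"non-numeric coordinate {cols[1]!r}")
    for key in ("center", "spring", "temperature"):
        if key not in meta:
            _fail(path, 0, f"missing '# {key} = ...' header")
    if not samples:
        _fail(path, 0, "no samples")
    return (
        UmbrellaWindow(
            center=float(meta["center"]),
            spring_constant=float(meta["spring"]),
            samples=np.array(samples),
        ),
        float(meta["temperature"]),
    )


def write_window_set(directory, windows: WindowSet, dt: float = 1.0):
    """Window set as a directory of tables plus a windows.tsv metadata file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = [f"# temperature = {windows.temperature!r}", "filename\tcenter\tspring"]
    for i, w in enumerate(windows.windows):
        name = f"window_{i:03d}.dat"
        write_window_table(directory / name, w, windows.temperature, dt=dt)
        lines.append(f"{name}\t{float(w.center)!r}\t{float(w.spring_constant)!r}")
    (directory / "windows.tsv").write_text("\n".join(lines) + "\n")


def read_window_set(directory) -> WindowSet:
    """Read a window-set directory via its windows.tsv metadata file."""
    directory = Path(directory)
    meta_path = directory / "windows.tsv"
    if not meta_path.exists():
        raise FormatError(f"{meta_path}: metadata file not found")
    temperature = None
    windows: List[UmbrellaWindow] = []
    with open(meta_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("=")
                if len(parts) == 2 and parts[0].strip() == "temperature":
                    temperature = float(parts[1])
                continue
            if line.startswith("filename"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                _fail(meta_path, lineno, f"expected 3 tab-separated columns, got {len(cols)}")
            w, t_file = read_window_table(directory / cols[0])
            if temperature is None:
                temperature = t_file
            windows.append(
                UmbrellaWindow(
                    center=float(cols[1]), spring_constant=float(cols[2]), samples=w.samples
                )
            )
    if temperature is None or not windows:
        raise FormatError(f"{meta_path}: no windows listed")
    return WindowSet(windows=windows, temperature=temperature)


# --------------------------------------------------------------------------- #
# XYZ configurations
# --------------------------------------------------------------------------- #


def write_xyz(path, frames, names: Optional[Sequence[str]] = None, mode: str = "w"):
    """One or more configurations as XYZ with box edges in the comment line."""
    if isinstance(frames, ParticleConfiguration):
        frames = [frames]
    with open(path, mode) as fh:
        for cfg in frames:
            n = cfg.positions.shape[0]
            fh.write(f"{n}\n")
            box = " ".join(repr(float(b)) for b in cfg.box)
            fh.write(f"box {box} periodic {int(cfg.periodic)}\n")
            for i in range(n):
                name = names[i] if names is not None else "X"
                x, y, z = cfg.positions[i]
                fh.write(f"{name} {float(x)!r} {float(y)!r} {float(z)!r}\n")


def read_xyz(path) -> List[ParticleConfiguration]:
    """Read all frames of an XYZ file written by :func:`write_xyz`."""
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            _fail(path, i + 1, f"expected atom count, got {lines[i].strip()!r}")
        comment = lines[i + 1].split() if i + 1 < len(lines) else []
        if len(comment) < 4 or comment[0] != "box":
            _fail(path, i + 2, "comment line must start with 'box lx ly lz'")
        box = np.array([float(v) for v in comment[1:4]])
        periodic = True
        if "periodic" in comment:
            periodic = bool(int(comment[comment.index("periodic") + 1]))
        pos = np.empty((n, 3))
        for j in range(n):
            cols = lines[i + 2 + j].split()
            if len(cols) < 4:
                _fail(path, i + 3 + j, f"expected 'name x y z', got {lines[i + 2 + j]!r}")
            pos[j] = [float(c) for c in cols[1:4]]
        frames.append(ParticleConfiguration(positions=pos, box=box, periodic=periodic))
        i += 2 + n
    if not frames:
        raise FormatError(f"{path}: no frames")
    return frames


# --------------------------------------------------------------------------- #
# Release curves
# --------------------------------------------------------------------------- #


def write_release_curve(path, curve: ReleaseCurve):
    with open(path, "w") as fh:
        if curve.stderr is not None:
            fh.write("time_h,fraction,stderr\n")
            for t, f, s in zip(curve.times, curve.fraction_released, curve.stderr):
                fh.write(f"{float(t)!r},{float(f)!r},{float(s)!r}\n")
        else:
            fh.write("time_h,fraction\n")
            for t, f in zip(curve.times, curve.fraction_released):
                fh.write(f"{float(t)!r},{float(f)!r}\n")


def read_release_curve(path) -> ReleaseCurve:
    times, fracs, errs = [], [], []
    has_err = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if lineno == 1:
                cols = line.split(",")
                if cols[0] != "time_h" or cols[1] != "fraction":
                    _fail(path, lineno, "header must be time_h,fraction[,stderr]")
                has_err = len(cols) > 2 and cols[2] == "stderr"
                continue
            cols = line.split(",")
            try:
                t, f = float(cols[0]), float(cols[1])
            except (ValueError, IndexError):
                _fail(path, lineno, f"malformed row {line!r}")
            if not 0.0 <= f <= 1.0:
                _fail(path, lineno, f"fraction {f} outside [0, 1]")
            times.append(t)
            fracs.append(f)
            if has_err:
                errs.append(float(cols[2]))
    return ReleaseCurve(
        times=np.array(times),
        fraction_released=np.array(fracs),
        stderr=np.array(errs) if has_err else None,
    )


# --------------------------------------------------------------------------- #
# PMF, u-matrix, free-energy results
# --------------------------------------------------------------------------- #


def write_pmf(path, pmf: PMFProfile):
    with open(path, "w") as fh:
        fh.write(f"# temperature = {float(pmf.temperature)!r}\n")
        fh.write(
            f"# reference_region = {float(pmf.reference_region[0])!r}"
            f" {float(pmf.reference_region[1])!r}\n"
        )
        fh.write("z_nm\tG_kJ_per_mol\tstderr\n")
        se = pmf.stderr if pmf.stderr is not None else np.full(pmf.z_grid.size, np.nan)
        for z, g, s in zip(pmf.z_grid, pmf.free_energy, se):
            fh.write(f"{float(z)!r}\t{float(g)!r}\t{float(s)!r}\n")


def write_umatrix(path, u: ReducedPotentialMatrix):
    """K x N reduced-potential matrix with a header naming K, N_k, temperature."""
    with open(path, "w") as fh:
        fh.write(f"# K = {u.u.shape[0]}\n")
        fh.write(f"# N_k = {' '.join(str(int(c)) for c in u.counts)}\n")
        fh.write(f"# temperature = {u.temperature!r}\n")
        for row in u.u:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_umatrix(path) -> ReducedPotentialMatrix:
    meta = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
                continue
            try:
                rows.append([float(v) for v in line.split()])
            except ValueError:
                _fail(path, lineno, "non-numeric entry in u-matrix row")
    for key in ("K", "N_k", "temperature"):
        if key not in meta:
            _fail(path, 0, f"missing '# {key} = ...' header")
    u = np.array(rows)
    counts = np.array([int(v) for v in meta["N_k"].split()])
    if u.shape[0] != int(meta["K"]):
        raise FormatError(
            f"{path}: header says K = {meta['K']} but found {u.shape[0]} rows"
        )
    return ReducedPotentialMatrix(u=u, counts=counts, temperature=float(meta["temperature"]))


def write_free_energy(path, result: FreeEnergyResult):
    payload = {
        "delta_g_kJ_per_mol": result.delta_g,
        "stderr_kJ_per_mol": result.stderr,
        "endpoints": list(result.endpoints),
        "temperature_K": result.temperature,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_free_energy(path) -> FreeEnergyResult:
    payload = json.loads(Path(path).read_text())
    return FreeEnergyResult(
        delta_g=payload["delta_g_kJ_per_mol"],
        stderr=payload["stderr_kJ_per_mol"],
        endpoints=tuple(payload["endpoints"]),
        temperature=payload["temperature_K"],
    )
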