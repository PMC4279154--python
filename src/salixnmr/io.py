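"""File formats and run configuration.

Spectra travel as two-column ASCII (ppm, intensity) or JCAMP-DX with an
``XYDATA=(X++(Y..Y))`` block in plain AFFN form; sample factors live in a
sidecar metadata CSV keyed by sample id rather than in filenames.  Axes are
normalised to ascending ppm on read; non-uniform axes are resampled onto a
uniform grid with a warning.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .preprocess import DEFAULT_EXCLUSIONS
from .simulate import Spectrum

__all__ = [
    "RunConfig",
    "read_spectrum",
    "write_spectrum_tsv",
    "write_spectrum_jcamp",
    "read_metadata_csv",
    "write_run_log",
]


class RunConfig(BaseModel):
    """Processing parameters; defaults are the platform's standard values."""

    library_path: str | None = None
    spectra_dir: str | None = None
    metadata_path: str | None = None
    output_dir: str = "."
    bin_width_ppm: float = 0.015
    bin_range: tuple[float, float] = (-0.05, 10.0)
    exclusions: tuple[tuple[float, float], ...] = DEFAULT_EXCLUSIONS
    drop_catechin_bins: bool = False
    shift_tol_ppm: float = 0.01
    fwhm_bounds_hz: tuple[float, float] = (0.5, 6.0)
    field_mhz: float = 600.0
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))


def _normalise_axis(ppm: np.ndarray, intensity: np.ndarray, meta: dict) -> Spectrum:
    order = np.argsort(ppm)
    if not np.array_equal(order, np.arange(len(ppm))):
        ppm, intensity = ppm[order], intensity[order]
    steps = np.diff(ppm)
    # stored-precision jitter well below a point spacing is still "uniform"
    if len(steps) and not np.allclose(steps, steps[0], rtol=1e-3):
        warnings.warn("non-uniform ppm axis: resampling onto a uniform grid")
        uniform = np.linspace(ppm[0], ppm[-1], len(ppm))
        intensity = np.interp(uniform, ppm, intensity)
        ppm = uniform
    return Spectrum(ppm, intensity, meta=meta)


def read_spectrum(path: str | Path, format: str | None = None,
                  meta: dict | None = None) -> Spectrum:
    """Read a spectrum from two-column TSV or JCAMP-DX."""
    path = Path(path)
    if format is None:
        format = "jcamp" if path.suffix.lower() in (".dx", ".jdx", ".jcamp") else "tsv"
    meta = dict(meta or {})
    meta.setdefault("sample_id", path.stem)
    if format == "tsv":
        data = np.loadtxt(path)
        if data.ndim != 2 or data.shape[1] != 2:
            raise ValueError(f"{path}: expected two columns (ppm, intensity)")
        return _normalise_axis(data[:, 0], data[:, 1], meta)
    if format == "jcamp":
        return _read_jcamp(path, meta)
    raise ValueError(f"unknown format {format!r}")


def write_spectrum_tsv(spectrum: Spectrum, path: str | Path) -> None:
    np.savetxt(
        path,
        np.column_stack([spectrum.ppm, spectrum.intensity]),
        fmt="%.8f\t%.8e",
        header="ppm\tintensity",
    )


def write_spectrum_jcamp(spectrum: Spectrum, path: str | Path,
                         title: str | None = None) -> None:
    """Write a minimal JCAMP-DX 5.00 file with an (X++(Y..Y)) data table."""
    ppm, y = spectrum.ppm, spectrum.intensity
    lines = [
        f"##TITLE={title or spectrum.meta.get('sample_id', 'spectrum')}",
        "##JCAMP-DX=5.00",
        "##DATA TYPE=NMR SPECTRUM",
        f"##.OBSERVE FREQUENCY={spectrum.field_mhz}",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        f"##FIRSTX={ppm[0]:.10g}",
        f"##LASTX={ppm[-1]:.10g}",
        f"##NPOINTS={len(ppm)}",
        f"##FIRSTY={y[0]:.10g}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for i in range(0, len(y), per_line):
        chunk = y[i : i + per_line]
        lines.append(
            f"{ppm[i]:.10g} " + " ".join(f"{v:.10g}" for v in chunk)
        )
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_jcamp(path: Path, meta: dict) -> Spectrum:
    fields: dict[str, str] = {}
    ys: list[float] = []
    in_data = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper()
            if key == "XYDATA":
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            fields[key] = value.strip()
            continue
        if in_data:
            parts = line.split()
            ys.extend(float(v) for v in parts[1:])  # first token is X
    if "NPOINTS" not in fields or "FIRSTX" not in fields or "LASTX" not in fields:
        raise ValueError(f"{path}: missing FIRSTX/LASTX/NPOINTS headers")
    n = int(fields["NPOINTS"])
    if len(ys) != n:
        raise ValueError(f"{path}: expected {n} Y values, found {len(ys)}")
    xfac = float(fields.get("XFACTOR", 1.0))
    yfac = float(fields.get("YFACTOR", 1.0))
    ppm = np.linspace(float(fields["FIRSTX"]) * xfac, float(fields["LASTX"]) * xfac, n)
    y = np.asarray(ys) * yfac
    if "TITLE" in fields:
        meta.setdefault("sample_id", fields["TITLE"])
        meta["title"] = fields["TITLE"]
    if ".OBSERVE FREQUENCY" in fields:
        meta["field_mhz"] = float(fields[".OBSERVE FREQUENCY"])
    spec = _normalise_axis(ppm, y, meta)
    if "field_mhz" in meta:
        spec.field_mhz = meta["field_mhz"]
    return spec


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path).set_index("sample_id")


def write_run_log(path: str | Path, command: str, config: dict,
                  inputs: dict | None = None) -> None:
    """Machine-readable record of a run, sufficient to replay it."""
    from importlib.metadata import version, PackageNotFoundError

    try:
        pkg_version = version("salixnmr")
    except PackageNotFoundError:  # pragma: no cover
        pkg_version = "unknown"
    log = {
        "command": command,
        "package_version": pkg_version,
        "numpy_version": np.__version__,
        "config": config,
        "inputs": inputs or {},
    }
    with open(path, "w") as fh:
        json.dump(log, fh, indent=1, default=str)
        fh.write("\n")
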