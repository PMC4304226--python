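"""File formats: wide tabular spectrum series (CSV), band tables, JCAMP-DX.

Series files are comma-separated with a ``wavenumber_cm-1`` column followed
by one column per temperature, headed ``T=<K>``.  Metadata (seed, config
hash) is embedded in leading ``#`` comment lines so re-runs with the same
configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import re

import numpy as np
import pandas as pd
import yaml

from .spectra import (
    DifferenceSpectrum,
    Spectrum,
    SpectrumSeries,
    StructuralError,
    WavenumberGrid,
)

__all__ = [
    "read_series",
    "write_series",
    "write_difference",
    "read_difference",
    "write_band_table",
    "read_jcamp",
    "config_hash",
    "load_config",
]

WAVENUMBER_COL = "wavenumber_cm-1"
_TEMP_RE = re.compile(r"^T=(-?\d+(?:\.\d+)?)$")


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise StructuralError(f"{path}: config must be a mapping")
    return cfg


def _write_frame(path, df, metadata):
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def write_series(path, series: SpectrumSeries, metadata: dict | None = None):
    cols = {WAVENUMBER_COL: series.grid.values}
    for i, T in enumerate(series.temperatures):
        cols[f"T={T:g}"] = series.values[i]
    meta = dict(metadata or {})
    meta.setdefault("mode", series.mode)
    for key in ("seed", "config_hash"):
        if key in series.metadata:
            meta.setdefault(key, series.metadata[key])
    _write_frame(path, pd.DataFrame(cols), meta)


def _read_frame(path):
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        if ":" in line:
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    body = lines[i:]
    header = [h.strip() for h in body[0].rstrip("\n").split(",")]
    ncol = len(header)
    rows = []
    for lineno, line in enumerate(body[1:], start=i + 2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split(",")
        if len(parts) != ncol:
            raise StructuralError(
                f"{path}:{lineno}: expected {ncol} columns, found {len(parts)}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise StructuralError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
    if not rows:
        raise StructuralError(f"{path}: no data rows")
    return header, np.array(rows), meta


def read_series(path) -> SpectrumSeries:
    """Read a wide tabular spectrum series; temperatures parsed from headers."""
    header, data, meta = _read_frame(path)
    if header[0] != WAVENUMBER_COL:
        raise StructuralError(
            f"{path}: first column must be {WAVENUMBER_COL!r}, found {header[0]!r}"
        )
    temps = []
    for name in header[1:]:
        m = _TEMP_RE.match(name)
        if not m:
            raise StructuralError(f"{path}: bad temperature header {name!r}")
        temps.append(float(m.group(1)))
    if len(set(temps)) != len(temps):
        raise StructuralError(f"{path}: duplicate temperature columns")
    try:
        grid = WavenumberGrid(data[:, 0])
    except StructuralError as exc:
        raise StructuralError(f"{path}: {exc}") from exc
    order = np.argsort(temps)
    values = data[:, 1:].T[order]
    return SpectrumSeries(
        grid, np.asarray(temps)[order], values, meta.get("mode", "absorbance"), meta
    )


def write_difference(path, diff: DifferenceSpectrum, metadata: dict | None = None):
    df = pd.DataFrame(
        {WAVENUMBER_COL: diff.grid.values, "delta_absorbance": diff.delta_absorbance}
    )
    meta = dict(metadata or {})
    meta.setdefault("temperature_K", f"{diff.temperature:g}")
    _write_frame(path, df, meta)


def read_difference(path) -> DifferenceSpectrum:
    header, data, meta = _read_frame(path)
    if header[:2] != [WAVENUMBER_COL, "delta_absorbance"]:
        raise StructuralError(f"{path}: not a difference-spectrum file")
    return DifferenceSpectrum(
        WavenumberGrid(data[:, 0]), data[:, 1], float(meta.get("temperature_K", 4.0))
    )


def write_band_table(path, fit_results: dict, metadata: dict | None = None):
    """Tidy band table: sample, class, center_cm-1, fraction_pct, fwhm_cm-1."""
    rows = []
    for (sample, class_tag), result in fit_results.items():
        bs = result.band_set.sorted_by_center()
        fracs = bs.fractional_areas
        for band, frac in zip(bs.bands, fracs):
            rows.append(
                {
                    "sample": sample,
                    "class": class_tag,
                    "center_cm-1": round(band.center, 2),
                    "fraction_pct": round(frac, 1),
                    "fwhm_cm-1": round(band.fwhm, 2),
                }
            )
    _write_frame(path, pd.DataFrame(rows), metadata)


def read_jcamp(path) -> Spectrum:
    """Minimal JCAMP-DX import: single spectrum, AFFN ``(X++(Y..Y))`` tables.

    Supports FIRSTX/LASTX/NPOINTS/XFACTOR/YFACTOR headers; YUNITS of
    ABSORBANCE or TRANSMITTANCE select the spectrum mode.
    """
    fields = {}
    data_lines = []
    in_data = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                if key == "XYDATA":
                    in_data = True
                    continue
                if key == "END":
                    in_data = False
                fields[key] = val.strip()
            elif in_data and line:
                data_lines.append(line)
    if not data_lines:
        raise StructuralError(f"{path}: no XYDATA block found")
    xfac = float(fields.get("XFACTOR", 1.0))
    yfac = float(fields.get("YFACTOR", 1.0))
    ys = []
    for line in data_lines:
        vals = [float(v) for v in re.split(r"[,\s]+", line) if v]
        ys.extend(vals[1:])  # first value per line is the running X
    npoints = int(float(fields.get("NPOINTS", len(ys))))
    if len(ys) != npoints:
        raise StructuralError(f"{path}: NPOINTS={npoints} but {len(ys)} Y values read")
    firstx = float(fields["FIRSTX"]) * xfac
    lastx = float(fields["LASTX"]) * xfac
    x = np.linspace(firstx, lastx, npoints)
    y = np.array(ys) * yfac
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    yunits = fields.get("YUNITS", "ABSORBANCE").upper()
    mode = "absorbance" if "ABSORB" in yunits else "transmission"
    return Spectrum(WavenumberGrid(x), y, mode)
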