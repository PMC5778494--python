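"""Delimited-text readers/writers and configuration loading.

Three file formats, all plain text, comma- or tab-delimited, with optional
``#``-prefixed ``key=value`` metadata lines before the header:

* spectrum:  ``y_keV_um,d_y`` — one lineal-energy grid point per row;
* series:    ``depth_mm,y_keV_um,d_y`` — long format, one spectrum per depth;
* profile:   ``depth_mm,physical_dose_Gy`` plus the derived columns
  ``z_star_Gy,alpha_Gy-1,rbe,rbe_weighted_dose_Gy`` when they have been
  computed.

Numbers are serialized with :func:`repr` (shortest round-trip form), so a
write→read cycle reproduces every value bit-for-bit.  Parse failures raise
:class:`FileFormatError`, which carries the file, line number and a stable
error code rather than free text, so callers and tests can dispatch on it.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np

from .mkm import (REFERENCE_PRESETS, DepthProfile, Endpoint,
                  ReferenceRadiation)
from .spectra import PRESETS, LinealSpectrum, MKMParams, SpectrumSeries

__all__ = [
    "FileFormatError",
    "read_spectrum", "write_spectrum",
    "read_series", "write_series",
    "read_profile", "write_profile",
    "load_config", "resolve_mkm_params", "resolve_reference",
    "resolve_endpoint",
]

_DERIVED_COLUMNS = (("z_star_Gy", "z_star"), ("alpha_Gy-1", "alpha"),
                    ("rbe", "rbe"), ("rbe_weighted_dose_Gy",
                                     "rbe_weighted_dose"))


class FileFormatError(ValueError):
    """Structured parse error: file, 1-based line number, stable code."""

    def __init__(self, path, line_no: int | None, code: str, message: str):
        self.path = str(path)
        self.line_no = line_no
        self.code = code
        where = f"{self.path}:{line_no}" if line_no is not None else self.path
        super().__init__(f"[{code}] {where}: {message}")

    def as_dict(self) -> dict:
        return {"error": {"code": self.code, "file": self.path,
                          "line": self.line_no, "message": str(self)}}


def _fmt(x: float) -> str:
    return repr(float(x))


def _parse_meta_value(raw: str):
    try:
        return json.loads(raw)
    except json.JSONDecodeError:
        return raw


def _read_table(path) -> tuple[dict, list[str], list[tuple[int, list[str]]]]:
    """Split a delimited file into metadata, header and data rows."""
    meta: dict = {}
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    delim = None
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = _parse_meta_value(val.strip())
                continue
            if header is None:
                delim = "\t" if "\t" in line else ","
                header = [c.strip() for c in line.split(delim)]
                continue
            rows.append((line_no, [c.strip() for c in line.split(delim)]))
    if header is None:
        raise FileFormatError(path, None, "empty-file",
                              "no header line found")
    return meta, header, rows


def _columns(path, header: list[str], rows, required: tuple[str, ...]
             ) -> dict[str, np.ndarray]:
    for col in required:
        if col not in header:
            raise FileFormatError(path, None, "missing-column",
                                  f"required column {col!r} not in header "
                                  f"{header}")
    idx = {col: header.index(col) for col in header}
    out: dict[str, list[float]] = {col: [] for col in header}
    for line_no, cells in rows:
        if len(cells) != len(header):
            raise FileFormatError(path, line_no, "ragged-row",
                                  f"expected {len(header)} fields, got "
                                  f"{len(cells)}")
        for col in header:
            raw = cells[idx[col]]
            try:
                out[col].append(float(raw))
            except ValueError:
                raise FileFormatError(path, line_no, "bad-number",
                                      f"column {col!r}: cannot parse "
                                      f"{raw!r}") from None
    return {col: np.asarray(vals, dtype=float) for col, vals in out.items()}


def _check_grid(path, rows, y: np.ndarray) -> None:
    bad = np.flatnonzero(np.diff(y) <= 0)
    if bad.size:
        line_no = rows[bad[0] + 1][0]
        raise FileFormatError(path, line_no, "unsorted-grid",
                              f"y grid not strictly increasing at y="
                              f"{y[bad[0] + 1]!r}")


def read_spectrum(path) -> LinealSpectrum:
    meta, header, rows = _read_table(path)
    cols = _columns(path, header, rows, ("y_keV_um", "d_y"))
    y, d = cols["y_keV_um"], cols["d_y"]
    _check_grid(path, rows, y)
    if np.any(d < 0):
        line_no = rows[int(np.flatnonzero(d < 0)[0])][0]
        raise FileFormatError(path, line_no, "negative-density",
                              "d(y) must be non-negative")
    return LinealSpectrum(y, d, metadata=meta)


def write_spectrum(path, spec: LinealSpectrum) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in spec.metadata.items():
            fh.write(f"# {key}={json.dumps(val) if not isinstance(val, str) else val}\n")
        fh.write("y_keV_um,d_y\n")
        for y, d in zip(spec.y_grid, spec.d_density):
            fh.write(f"{_fmt(y)},{_fmt(d)}\n")


def read_series(path) -> SpectrumSeries:
    meta, header, rows = _read_table(path)
    cols = _columns(path, header, rows, ("depth_mm", "y_keV_um", "d_y"))
    depth_col = cols["depth_mm"]
    depths = np.unique(depth_col)
    spectra = []
    for depth in depths:
        sel = depth_col == depth
        y, d = cols["y_keV_um"][sel], cols["d_y"][sel]
        order = np.argsort(y)
        sub_meta = dict(meta)
        sub_meta["depth_mm"] = float(depth)
        try:
            spectra.append(LinealSpectrum(y[order], d[order],
                                          metadata=sub_meta))
        except ValueError as exc:
            raise FileFormatError(path, None, "invalid-spectrum",
                                  f"depth {depth:g} mm: {exc}") from exc
    weights = meta.pop("dose_weights_Gy", None)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
    return SpectrumSeries(depths=depths, spectra=spectra,
                          dose_weights=weights)


def write_series(path, series: SpectrumSeries) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if series.dose_weights is not None:
            kept = [float(w) for w, spec in zip(series.dose_weights,
                                                series.spectra)
                    if spec is not None]
            fh.write("# dose_weights_Gy=" + json.dumps(kept) + "\n")
        fh.write("depth_mm,y_keV_um,d_y\n")
        for depth, spec in zip(series.depths, series.spectra):
            if spec is None:
                continue
            for y, d in zip(spec.y_grid, spec.d_density):
                fh.write(f"{_fmt(depth)},{_fmt(y)},{_fmt(d)}\n")


def read_profile(path) -> DepthProfile:
    meta, header, rows = _read_table(path)
    cols = _columns(path, header, rows, ("depth_mm", "physical_dose_Gy"))
    depths = cols["depth_mm"]
    bad = np.flatnonzero(np.diff(depths) <= 0)
    if bad.size:
        raise FileFormatError(path, rows[bad[0] + 1][0], "unsorted-grid",
                              "depths not strictly increasing")
    derived = {attr: cols[col] for col, attr in _DERIVED_COLUMNS
               if col in cols}
    return DepthProfile(depths=depths,
                        physical_dose=cols["physical_dose_Gy"],
                        metadata=meta, **derived)


def write_profile(path, profile: DepthProfile) -> None:
    present = [(col, getattr(profile, attr))
               for col, attr in _DERIVED_COLUMNS
               if getattr(profile, attr) is not None]
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in profile.metadata.items():
            fh.write(f"# {key}={json.dumps(val) if not isinstance(val, str) else val}\n")
        if profile.excluded_depths:
            fh.write("# excluded_depths_mm="
                     + json.dumps(profile.excluded_depths) + "\n")
        fh.write("depth_mm,physical_dose_Gy"
                 + "".join("," + col for col, _ in present) + "\n")
        for i in range(profile.depths.size):
            cells = [_fmt(profile.depths[i]), _fmt(profile.physical_dose[i])]
            cells += [_fmt(arr[i]) for _, arr in present]
            fh.write(",".join(cells) + "\n")


# -- configuration ---------------------------------------------------------

_KNOWN_BLOCKS = {"schema_version", "mkm_params", "reference", "endpoint",
                 "normalization", "beam"}


def load_config(path) -> dict:
    """Load a JSON or TOML run configuration; unknown keys are rejected."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
    else:
        with open(path, encoding="utf-8") as fh:
            cfg = json.load(fh)
    unknown = set(cfg) - _KNOWN_BLOCKS
    if unknown:
        raise FileFormatError(path, None, "unknown-key",
                              f"unknown config keys: {sorted(unknown)}")
    return cfg


def resolve_mkm_params(spec) -> MKMParams:
    """Preset name or explicit field mapping → MKMParams."""
    if isinstance(spec, str):
        try:
            return PRESETS[spec]
        except KeyError:
            raise ValueError(f"unknown MKM preset {spec!r}; have "
                             f"{sorted(PRESETS)}") from None
    if isinstance(spec, MKMParams):
        return spec
    spec = dict(spec)
    preset = spec.pop("preset", None)
    if preset is not None:
        base = resolve_mkm_params(preset)
        merged = {"alpha0": base.alpha0, "beta": base.beta, "rd": base.rd,
                  "y0": base.y0, "rho": base.rho}
        merged.update(spec)
        return MKMParams(**merged, label=f"{preset}*")
    return MKMParams(**spec)


def resolve_reference(spec) -> ReferenceRadiation:
    if isinstance(spec, str):
        try:
            return REFERENCE_PRESETS[spec]
        except KeyError:
            raise ValueError(f"unknown reference preset {spec!r}; have "
                             f"{sorted(REFERENCE_PRESETS)}") from None
    if isinstance(spec, ReferenceRadiation):
        return spec
    return ReferenceRadiation(**spec)


def resolve_endpoint(spec) -> Endpoint:
    if isinstance(spec, Endpoint):
        return spec
    if isinstance(spec, (int, float)):
        return Endpoint(survival=float(spec))
    return Endpoint(**spec)
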