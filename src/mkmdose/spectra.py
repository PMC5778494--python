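"""Lineal-energy spectra and microdosimetric moments.

The central object is the dose-probability density ``d(y)`` of lineal energy
``y`` (keV/μm) in a sub-micrometre sensitive site.  From it the module
computes the classical microdosimetric moments (frequency-mean ``ȳ_F`` and
dose-mean ``ȳ_D`` lineal energy), the saturation-corrected mean ``y*`` that
damps the overkill regime above a saturation parameter ``y₀``, and the
saturation-corrected dose-mean specific energy per event

    z*₁D = 0.1602 · y* / (ρ · π · r_d²)   [Gy],

the radiation-quality variable of the microdosimetric kinetic model (MKM).
All integrals use the trapezoid rule on the spectrum's native grid; spectra
are smooth and the grid is caller-controlled, so deterministic fixed-grid
quadrature is preferred over adaptive schemes.

Units are fixed throughout: y in keV/μm, domain radius r_d in μm, density ρ
in g/cm³, specific energy in Gy.  The conversion constant 0.1602 follows
from 1 keV = 1.602e-16 J and a 1 μm³ site at 1 g/cm³ weighing 1e-15 kg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LinealSpectrum",
    "MKMParams",
    "SpectrumSeries",
    "SET_A",
    "SET_B",
    "KEV_PER_UM_TO_GY",
    "normalize",
    "dose_mean_y",
    "frequency_mean_y",
    "y_star",
    "z_star_1d",
    "depth_window_average",
    "rebin_log",
]

#: 1 keV/μm deposited over a mass path of 1 μm²·(g/cm³) expressed in Gy.
KEV_PER_UM_TO_GY = 0.1602

_NORM_TOL = 1e-6


@dataclass
class LinealSpectrum:
    """Dose-probability density d(y) on a strictly increasing y-grid.

    Parameters
    ----------
    y_grid : array-like
        Lineal energy values, keV/μm, strictly increasing, all > 0.
    d_density : array-like
        Dose probability density d(y), (keV/μm)⁻¹, same length as
        ``y_grid``, all ≥ 0 with at least one positive value.
    metadata : dict
        Free-form provenance tags (depth, site diameter, window, ...).
    """

    y_grid: np.ndarray
    d_density: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y_grid = np.asarray(self.y_grid, dtype=float)
        self.d_density = np.asarray(self.d_density, dtype=float)
        if self.y_grid.ndim != 1 or self.y_grid.size < 2:
            raise ValueError("y_grid must be 1-D with at least 2 points")
        if self.d_density.shape != self.y_grid.shape:
            raise ValueError("d_density and y_grid must have the same length")
        if np.any(self.y_grid <= 0):
            raise ValueError("y_grid values must be strictly positive")
        if np.any(np.diff(self.y_grid) <= 0):
            raise ValueError("y_grid must be strictly increasing")
        if np.any(self.d_density < 0):
            raise ValueError("d_density must be non-negative")
        if not np.any(self.d_density > 0):
            raise ValueError("empty spectrum: all d_density values are zero")

    @property
    def integral(self) -> float:
        """Trapezoid integral of d(y) over the grid."""
        return float(np.trapezoid(self.d_density, self.y_grid))

    @property
    def is_normalized(self) -> bool:
        return abs(self.integral - 1.0) <= _NORM_TOL

    def frequency_density(self) -> np.ndarray:
        """Normalized frequency density f(y) ∝ d(y)/y on the same grid."""
        f = self.d_density / self.y_grid
        return f / np.trapezoid(f, self.y_grid)


@dataclass(frozen=True)
class MKMParams:
    """MKM parameter set: LQ intercept/slope inputs and domain geometry.

    alpha0 : Gy⁻¹, α in the zero-LET limit.
    beta : Gy⁻², radiation-quality-independent quadratic LQ coefficient.
    rd : μm, radius of the sub-nuclear domain.
    y0 : keV/μm, saturation (overkill) parameter.
    rho : g/cm³, domain density.
    """

    alpha0: float
    beta: float
    rd: float
    y0: float
    rho: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("alpha0", "beta", "rd", "y0", "rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"MKMParams.{name} must be > 0")


#: HSG-cell parameter set used for yd(y) scoring (site diameter 2·r_d = 0.564 μm).
SET_A = MKMParams(alpha0=0.155, beta=0.0615, rd=0.282, y0=93.4, label="SET_A")
#: HSG-cell parameter set used for RBE-weighted dose estimation (carbon-ion heritage).
SET_B = MKMParams(alpha0=0.13, beta=0.05, rd=0.42, y0=150.0, label="SET_B")

PRESETS = {"SET_A": SET_A, "SET_B": SET_B}


@dataclass
class SpectrumSeries:
    """Per-depth lineal-energy spectra along a beam axis.

    ``spectra`` entries may be None to flag depths where no spectrum is
    available; downstream profile operations exclude (never interpolate)
    those depths.  ``dose_weights`` (Gy per depth) enable dose-weighted
    depth-window averaging; when absent the average is uniform.
    """

    depths: np.ndarray
    spectra: list
    dose_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.ndim != 1:
            raise ValueError("depths must be 1-D")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if len(self.spectra) != self.depths.size:
            raise ValueError("depths and spectra must have the same length")
        if self.dose_weights is not None:
            self.dose_weights = np.asarray(self.dose_weights, dtype=float)
            if self.dose_weights.shape != self.depths.shape:
                raise ValueError("dose_weights must align with depths")
            if np.any(self.dose_weights < 0):
                raise ValueError("dose_weights must be non-negative")

    def __len__(self) -> int:
        return int(self.depths.size)


def normalize(spec: LinealSpectrum) -> LinealSpectrum:
    """Return a copy of *spec* whose trapezoid integral is exactly 1."""
    total = spec.integral
    if total <= 0:
        raise ValueError("cannot normalize a spectrum with zero total mass")
    return replace(spec, d_density=spec.d_density / total,
                   metadata=dict(spec.metadata))


def _ensure_normalized(spec: LinealSpectrum) -> LinealSpectrum:
    if spec.is_normalized:
        return spec
    warnings.warn(
        "spectrum not normalized (integral = %.6g); normalizing internally"
        % spec.integral, stacklevel=3)
    return normalize(spec)


def dose_mean_y(spec: LinealSpectrum) -> float:
    """Dose-mean lineal energy ȳ_D = ∫ y d(y) dy, keV/μm."""
    spec = _ensure_normalized(spec)
    return float(np.trapezoid(spec.y_grid * spec.d_density, spec.y_grid))


def frequency_mean_y(spec: LinealSpectrum) -> float:
    """Frequency-mean lineal energy ȳ_F = 1 / ∫ d(y)/y dy, keV/μm."""
    spec = _ensure_normalized(spec)
    return float(1.0 / np.trapezoid(spec.d_density / spec.y_grid, spec.y_grid))


def y_star(spec: LinealSpectrum, y0: float) -> float:
    """Saturation-corrected mean lineal energy, keV/μm.

    y* = y₀² ∫ [1 − exp(−y²/y₀²)] · d(y)/y dy.  Since 1 − e⁻ˣ ≤ x, the
    result never exceeds ȳ_D, and approaches it when the spectrum lies
    far below y₀ (no overkill).
    """
    if y0 <= 0:
        raise ValueError("saturation parameter y0 must be > 0")
    spec = _ensure_normalized(spec)
    y = spec.y_grid
    integrand = -np.expm1(-(y / y0) ** 2) * spec.d_density / y
    return float(y0 ** 2 * np.trapezoid(integrand, y))


def z_star_1d(spec: LinealSpectrum, params: MKMParams) -> float:
    """Saturation-corrected dose-mean specific energy per event, Gy.

    z*₁D = (l̄/m)·y* with l̄/m = 1/(ρ π r_d²) for a spherical domain of
    radius r_d (mean chord length l̄ = 4r_d/3, mass m = ρ·4πr_d³/3).
    """
    ys = y_star(spec, params.y0)
    return KEV_PER_UM_TO_GY * ys / (params.rho * np.pi * params.rd ** 2)


def _interp_density(spec: LinealSpectrum, grid: np.ndarray) -> np.ndarray:
    # linear in (y, d(y)); zero outside the member's support
    return np.interp(grid, spec.y_grid, spec.d_density, left=0.0, right=0.0)


def depth_window_average(series: SpectrumSeries, center: float,
                         halfwidth: float = 1.5) -> LinealSpectrum:
    """Average the member spectra within ``center ± halfwidth`` (mm).

    Emulates a detector whose active length exceeds the scoring resolution:
    member d(y) arrays are interpolated onto the union y-grid, combined with
    dose weights (uniform when the series carries none), and renormalized.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    lo, hi = center - halfwidth, center + halfwidth
    eps = 1e-9 * max(1.0, abs(center))
    mask = (series.depths >= lo - eps) & (series.depths <= hi + eps)
    idx = [i for i in np.flatnonzero(mask) if series.spectra[i] is not None]
    if not idx:
        raise ValueError(
            f"no spectra available in depth window [{lo:g}, {hi:g}] mm")

    if series.dose_weights is not None:
        w = series.dose_weights[idx].astype(float)
        if w.sum() <= 0:
            w = np.ones(len(idx))
    else:
        w = np.ones(len(idx))
    w = w / w.sum()

    union = np.unique(np.concatenate([series.spectra[i].y_grid for i in idx]))
    mixed = np.zeros_like(union)
    for wi, i in zip(w, idx):
        mixed += wi * _interp_density(series.spectra[i], union)
    out = LinealSpectrum(union, mixed, metadata={
        "window_center_mm": center, "window_halfwidth_mm": halfwidth,
        "n_members": len(idx)})
    return normalize(out)


def rebin_log(spec: LinealSpectrum, n_bins: int, y_min: float,
              y_max: float) -> LinealSpectrum:
    """Rebin d(y) onto ``n_bins`` points equally spaced in log₁₀(y).

    The density is linearly interpolated onto the new grid and rescaled so
    that the trapezoid mass over the overlap range matches the input's mass
    there.  Mass falling outside ``[y_min, y_max]`` is reported in the
    output metadata as ``clipped_fraction``.
    """
    if y_min <= 0 or y_max <= 0 or y_min >= y_max:
        raise ValueError("require 0 < y_min < y_max")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    new_y = np.logspace(np.log10(y_min), np.log10(y_max), n_bins)
    new_d = _interp_density(spec, new_y)

    # input mass restricted to the overlap of [y_min, y_max] with the support
    lo = max(y_min, spec.y_grid[0])
    hi = min(y_max, spec.y_grid[-1])
    if lo >= hi or not np.any(new_d > 0):
        raise ValueError("rebin range does not overlap the spectrum support")
    sub = np.unique(np.concatenate(
        [[lo, hi], spec.y_grid[(spec.y_grid > lo) & (spec.y_grid < hi)]]))
    mass_in = float(np.trapezoid(_interp_density(spec, sub), sub))
    total = spec.integral
    clipped = max(0.0, 1.0 - mass_in / total)

    mass_out = float(np.trapezoid(new_d, new_y))
    if mass_out <= 0:
        raise ValueError("rebinned spectrum has zero mass")
    new_d = new_d * (mass_in / mass_out)

    meta = dict(spec.metadata)
    meta["clipped_fraction"] = clipped
    return LinealSpectrum(new_y, new_d, metadata=meta)
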