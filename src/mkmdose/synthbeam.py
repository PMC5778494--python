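"""Analytic synthetic proton beam: depth doses and lineal-energy spectra.

This module generates the inputs the MKM chain consumes — pristine and
spread-out Bragg-peak (SOBP) depth-dose curves and depth-dependent yd(y)
spectra — from closed-form models, so the whole pipeline is testable with
no external transport code or measured data.  It is an analytic stand-in
for a Monte Carlo transport step and makes no claim of fidelity to any
particular transport engine; the target is the qualitative depth structure
of a clinical passive-scattering proton field:

* range and stopping power from the Bragg–Kleeman power law R = a·Eᵖ in
  water (defaults a = 0.0022 cm/MeVᵖ, p = 1.77);
* pristine Bragg curves as cell-averaged stopping power, attenuated 1%/cm
  for nuclear fluence loss and convolved with a Gaussian range-straggling
  kernel of width σ_R = 0.012·R;
* SOBPs as non-negative superpositions of range-shifted pristine peaks,
  with weights from a Chebyshev (minimax) flatness fit over the modulation
  region, solved as a linear program;
* yd(y) spectra as dose-weighted log-normal mixtures whose component
  medians track the local stopping power of each contributing pristine
  component, with a small high-y tail emulating secondary particles.  The
  dose-mean lineal energy therefore hardens with depth, the feature the
  MKM converts into a rising RBE toward the distal edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import linprog

from .mkm import DepthProfile
from .spectra import LinealSpectrum, SpectrumSeries, normalize

__all__ = [
    "BeamConfig",
    "RangeEnergyModel",
    "residual_energy",
    "stopping_power",
    "pristine_bragg",
    "sobp_weights",
    "lineal_spectrum_at_depth",
    "generate_beam",
]

#: MeV/cm → keV/μm
MEV_CM_TO_KEV_UM = 0.1

#: fractional range-straggling width σ_R / R
STRAGGLING_FRACTION = 0.012

#: linear nuclear-fluence dose attenuation before the peak, per cm
NUCLEAR_LOSS_PER_CM = 0.01


@dataclass(frozen=True)
class RangeEnergyModel:
    """Bragg–Kleeman range–energy power law R(E) = a·Eᵖ (R in cm, E in MeV)."""

    bragg_kleeman_alpha: float = 0.0022  # cm / MeV^p
    bragg_kleeman_p: float = 1.77

    def __post_init__(self) -> None:
        if self.bragg_kleeman_alpha <= 0 or self.bragg_kleeman_p <= 0:
            raise ValueError("Bragg–Kleeman constants must be > 0")

    def range_mm(self, energy: float) -> float:
        """CSDA range in water, mm."""
        return 10.0 * self.bragg_kleeman_alpha * energy ** self.bragg_kleeman_p

    def energy_for_range_mm(self, range_mm: float) -> float:
        """Beam energy (MeV) whose range equals ``range_mm``."""
        return (range_mm / 10.0 / self.bragg_kleeman_alpha) ** (
            1.0 / self.bragg_kleeman_p)


@dataclass(frozen=True)
class BeamConfig:
    """Synthetic-beam configuration.

    entrance_energy : MeV at the phantom surface (default puts the pristine
        peak near 132 mm depth in water).
    modulation_width : mm of flat SOBP (0 = pristine beam).
    n_pristine_peaks : pristine components superposed for an SOBP.
    depth_grid : mm, uniform and increasing; default 0–180 mm at 0.5 mm
        steps (fine enough to resolve the straggled peak of every pristine
        component of a 60 mm SOBP).
    site_diameter : μm, recorded in spectrum metadata.
    energy_spread : fractional beam momentum/energy spread σ_E/E; widens
        each pristine peak by σ_R = p·(σ_E/E)·R on top of range straggling.
    spectrum_width_param : log-scale width σ of the log-normal d(y)
        components.
    tail_fraction : dose fraction in a high-y secondary-particle tail.
    rng_seed : used only when ``noise`` is enabled.
    noise : opt-in multiplicative counting noise on d(y), for robustness
        tests only.
    """

    entrance_energy: float = 136.3
    modulation_width: float = 0.0
    n_pristine_peaks: int = 13
    energy_spread: float = 0.015
    depth_grid: np.ndarray = None
    site_diameter: float = 0.564
    spectrum_width_param: float = 0.35
    tail_fraction: float = 0.05
    rng_seed: int = 0
    noise: bool = False

    def __post_init__(self) -> None:
        if self.entrance_energy <= 0:
            raise ValueError("entrance_energy must be > 0")
        if self.modulation_width < 0:
            raise ValueError("modulation_width must be >= 0")
        if not 0 <= self.tail_fraction < 0.5:
            raise ValueError("tail_fraction must lie in [0, 0.5)")
        if self.spectrum_width_param < 0:
            raise ValueError("spectrum_width_param must be >= 0")
        if not 0 <= self.energy_spread < 0.2:
            raise ValueError("energy_spread must lie in [0, 0.2)")
        grid = self.depth_grid
        if grid is None:
            grid = np.arange(0.0, 180.5, 0.5)
        grid = np.asarray(grid, dtype=float)
        if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("depth_grid must be 1-D and increasing")
        object.__setattr__(self, "depth_grid", grid)


def residual_energy(model: RangeEnergyModel, e0: float, depth) -> np.ndarray:
    """Proton energy (MeV) remaining after ``depth`` mm of water.

    E(z) = ((R(E0) − z)/a)^{1/p} for z < R(E0), else 0.
    """
    depth = np.asarray(depth, dtype=float)
    if np.any(depth < 0):
        raise ValueError("depth must be non-negative")
    rest_mm = np.maximum(model.range_mm(e0) - depth, 0.0)
    e = (rest_mm / 10.0 / model.bragg_kleeman_alpha) ** (
        1.0 / model.bragg_kleeman_p)
    return float(e) if e.ndim == 0 else e


def stopping_power(model: RangeEnergyModel, energy) -> np.ndarray:
    """Linear stopping power dE/dz (keV/μm) at proton energy E (MeV).

    S(E) = E^{1−p} / (a·p), the derivative of the Bragg–Kleeman range rule.
    """
    energy = np.asarray(energy, dtype=float)
    if np.any(energy <= 0):
        raise ValueError("stopping power diverges at E <= 0; callers must "
                         "guard against stopped protons")
    s_mev_cm = energy ** (1.0 - model.bragg_kleeman_p) / (
        model.bragg_kleeman_alpha * model.bragg_kleeman_p)
    s = s_mev_cm * MEV_CM_TO_KEV_UM
    return float(s) if s.ndim == 0 else s


def _raw_bragg_dose(model: RangeEnergyModel, e0: float,
                    grid: np.ndarray) -> np.ndarray:
    """Cell-averaged stopping power with nuclear-loss attenuation (a.u.).

    Averaging ΔE over each grid cell tames the integrable (R−z)^{−(p−1)/p}
    singularity at the end of range, keeping the discrete peak height
    independent of how the grid happens to straddle R.
    """
    dz = np.diff(grid)
    e_nodes = residual_energy(model, e0, grid)
    dose = np.zeros_like(grid)
    dose[:-1] = (e_nodes[:-1] - e_nodes[1:]) / dz  # MeV/mm, cell average
    atten = np.maximum(1.0 - NUCLEAR_LOSS_PER_CM * grid / 10.0, 0.0)
    return dose * atten


def pristine_bragg(config: BeamConfig, model: RangeEnergyModel,
                   e0: float | None = None) -> DepthProfile:
    """Depth-dose curve of a mono-energetic beam (physical dose only, a.u.).

    Cell-averaged stopping power convolved with a Gaussian range-spread
    kernel combining intrinsic range straggling (σ_R = 0.012·R) with the
    range spread induced by the beam's fractional energy spread,
    σ_R = p·(σ_E/E)·R, added in quadrature.
    """
    e0 = config.entrance_energy if e0 is None else e0
    grid = config.depth_grid
    r_mm = model.range_mm(e0)
    if grid[-1] < 1.1 * r_mm:
        raise ValueError(
            f"depth_grid must extend to 1.1×range = {1.1 * r_mm:.1f} mm")
    dz = np.diff(grid)
    if np.ptp(dz) > 1e-9 * dz[0]:
        raise ValueError("pristine_bragg requires a uniform depth grid")
    sigma_mm = _range_sigma_mm(config, model, r_mm)
    n_near = np.count_nonzero(np.abs(grid - r_mm) <= 2.0 * sigma_mm)
    if n_near < 5:
        raise ValueError(
            f"depth grid too coarse: only {n_near} points within ±2σ_R "
            f"of the range ({r_mm:.1f} ± {2 * sigma_mm:.1f} mm)")

    dose = gaussian_filter1d(_raw_bragg_dose(model, e0, grid),
                             sigma=sigma_mm / dz[0], mode="nearest")
    return DepthProfile(depths=grid, physical_dose=dose,
                        metadata={"beam": "pristine", "E0_MeV": e0,
                                  "range_mm": r_mm,
                                  "range_sigma_mm": sigma_mm})


def _flatness_lp(a: np.ndarray, mono_rows: np.ndarray | None) -> np.ndarray | None:
    """Chebyshev flatness fit: min t s.t. |a·w − 1| ≤ t, mean(a·w) = 1, w ≥ 0.

    ``mono_rows`` optionally adds non-decreasing constraints along a
    sub-range of the region.  Returns the weights, or None on LP failure.
    """
    n_pk, n_pt = a.shape[1], a.shape[0]
    cost = np.r_[np.zeros(n_pk), 1.0]
    blocks = [np.c_[a, -np.ones(n_pt)], np.c_[-a, -np.ones(n_pt)]]
    rhs = [np.ones(n_pt), -np.ones(n_pt)]
    if mono_rows is not None and len(mono_rows) > 0:
        blocks.append(np.c_[mono_rows, np.zeros(len(mono_rows))])
        rhs.append(np.zeros(len(mono_rows)))
    a_eq = np.c_[a.mean(axis=0)[None, :], [[0.0]]]
    res = linprog(cost, A_ub=np.vstack(blocks), b_ub=np.concatenate(rhs),
                  A_eq=a_eq, b_eq=[1.0], bounds=[(0, None)] * (n_pk + 1))
    return res.x[:n_pk] if res.success else None


def sobp_weights(pristine_set: list[DepthProfile],
                 flat_region: tuple[float, float],
                 flat_tol: float = 0.02,
                 distal_monotone: bool = True) -> np.ndarray:
    """Non-negative weights flattening the summed dose over ``flat_region``.

    Minimizes the maximum deviation of the summed dose from its region
    mean (a Chebyshev fit, solved as a linear program with the region mean
    pinned to 1), over non-negative weights; each pristine peak is
    pre-scaled to unit maximum.  With ``distal_monotone`` (the default) a
    second solve additionally pins the ripple phase so the plateau never
    declines locally over its distal three quarters; that solution is kept
    whenever it still meets the flatness budget, since a ridge filter is
    effectively continuous and a monotone distal plateau is the physical
    expectation.  Raises if the achieved plateau ripples by more than
    ``flat_tol`` of its mean.
    """
    if len(pristine_set) < 1:
        raise ValueError("need at least one pristine peak")
    lo, hi = flat_region
    if hi < lo:
        raise ValueError("flat_region must be (low, high)")
    grid = pristine_set[0].depths
    mask = (grid >= lo) & (grid <= hi)
    if not np.any(mask):
        raise ValueError("flat_region contains no grid depths")

    a_full = np.column_stack([p.physical_dose / p.physical_dose.max()
                              for p in pristine_set])
    a = a_full[mask]
    if a.shape[1] == 1:
        w = np.ones(1)
    else:
        w = _flatness_lp(a, None)
        if w is None:
            raise ValueError("flatness optimization failed")
        if distal_monotone:
            # ripple-phase constraint over the distal 3/4 of the plateau,
            # stopping 5% short of the end: the last few mm belong to the
            # distal transition, where flatness and monotonicity conflict
            span = hi - lo
            am = a_full[(grid >= lo + 0.25 * span) & (grid <= hi - 0.05 * span)]
            w_mono = _flatness_lp(a, am[:-1] - am[1:])
            if w_mono is not None:
                comb = a @ w_mono
                if (np.max(np.abs(comb - comb.mean())) / comb.mean()
                        <= flat_tol):
                    w = w_mono
    if w.max() <= 0:
        raise ValueError("flatness optimization returned all-zero weights")
    # symmetry tie-break: duplicate peaks share their group's mean weight
    # (equal columns ⇒ the combined dose is unchanged)
    remaining = list(range(a.shape[1]))
    while remaining:
        i = remaining[0]
        group = [j for j in remaining if np.array_equal(a[:, i], a[:, j])]
        w[group] = w[group].mean()
        remaining = [j for j in remaining if j not in group]
    w = w / w.max()

    combined = a @ w
    dev = float(np.max(np.abs(combined - combined.mean())) / combined.mean())
    if dev > flat_tol:
        raise ValueError(
            f"flatness infeasible over [{lo:g}, {hi:g}] mm: achieved "
            f"deviation {100 * dev:.2f}% exceeds ±{100 * flat_tol:.0f}%")
    return w


def _components(config: BeamConfig, model: RangeEnergyModel):
    """Pristine components (energy, weight, profile) for the configured beam."""
    if config.modulation_width == 0:
        prof = pristine_bragg(config, model)
        pos = float(prof.depths[np.argmax(prof.physical_dose)])
        return [(config.entrance_energy, 1.0, prof)], (pos, pos)
    peak_depth = model.range_mm(config.entrance_energy)
    n = config.n_pristine_peaks
    if n < 2:
        raise ValueError("an SOBP needs at least 2 pristine peaks")
    ranges = np.linspace(peak_depth - config.modulation_width, peak_depth, n)
    energies = [model.energy_for_range_mm(r) for r in ranges]
    profiles = []
    for e in energies:
        prof = pristine_bragg(config, model, e)
        # unit peak maximum: the same scaling sobp_weights optimizes against
        prof.physical_dose = prof.physical_dose / prof.physical_dose.max()
        profiles.append(prof)
    # the plateau ends at the peak maxima, slightly proximal of the CSDA
    # ranges once straggling/energy spread pull each peak forward
    peak_pos = [float(p.depths[np.argmax(p.physical_dose)]) for p in profiles]
    plateau = (min(peak_pos), max(peak_pos))
    weights = sobp_weights(profiles, plateau)
    comps = [(e, float(wi), p)
             for e, wi, p in zip(energies, weights, profiles) if wi > 0]
    if not comps:
        raise ValueError("no pristine component received positive weight")
    return comps, plateau


def _default_y_grid() -> np.ndarray:
    return np.logspace(np.log10(0.03), np.log10(3000.0), 400)


def _lognormal_density(y: np.ndarray, median: float,
                       sigma: float) -> np.ndarray:
    if sigma <= 0:
        # delta-like: narrow log-normal two grid-steps wide
        sigma = 0.5 * np.mean(np.diff(np.log(y)))
    return (np.exp(-0.5 * ((np.log(y) - np.log(median)) / sigma) ** 2) /
            (y * sigma * np.sqrt(2.0 * np.pi)))


def _range_sigma_mm(config: BeamConfig, model: RangeEnergyModel,
                    range_mm: float) -> float:
    """Total Gaussian range spread: straggling ⊕ beam energy spread."""
    return range_mm * float(np.hypot(
        STRAGGLING_FRACTION, model.bragg_kleeman_p * config.energy_spread))


def lineal_spectrum_at_depth(config: BeamConfig, model: RangeEnergyModel,
                             components, depth: float,
                             y_grid: np.ndarray | None = None,
                             rng: np.random.Generator | None = None
                             ) -> LinealSpectrum:
    """Synthetic yd(y) at one depth: dose-weighted log-normal mixture.

    Protons of each pristine component carry a Gaussian residual-range
    distribution at ``depth`` (the same spread that shapes its depth-dose
    curve).  Every residual range u maps to a stopping power S(u) which
    contributes a log-normal d(y) with median S(u) and log-width
    ``spectrum_width_param``, dose-weighted by the range density times
    S(u); a ``tail_fraction`` share sits in a second log-normal centered
    at 10× the median, emulating secondary particles.  Deeper ⇒ slower
    protons ⇒ higher medians: the spectrum hardens smoothly with depth.
    """
    if isinstance(components, (int, float)):
        components = [(float(components), 1.0, None)]
    y = _default_y_grid() if y_grid is None else np.asarray(y_grid, float)
    sigma = config.spectrum_width_param
    tail = config.tail_fraction

    ranges = [model.range_mm(e0) for e0, _, _ in components]
    sigmas = [_range_sigma_mm(config, model, r) for r in ranges]
    if depth > max(r + 4.0 * s for r, s in zip(ranges, sigmas)):
        raise ValueError(f"no dose at depth {depth:g} mm: beyond all "
                         "component ranges")

    # residual-range quadrature nodes, log-spaced to resolve track ends
    u_max = max(ranges) + 5.0 * max(sigmas)
    u = np.logspace(np.log10(0.05), np.log10(u_max), 128)
    du = np.gradient(u)
    s_u = stopping_power(model, model.energy_for_range_mm(u))

    # dose weight per node: Σ_k w_k · N(depth+u; R_k, σ_k) · S(u) · du
    node_w = np.zeros_like(u)
    for (e0, w, _), r_k, s_k in zip(components, ranges, sigmas):
        node_w += (w / s_k) * np.exp(
            -0.5 * ((depth + u - r_k) / s_k) ** 2) * s_u * du
    total_w = float(node_w.sum())
    if total_w <= 1e-12:
        raise ValueError(f"no dose at depth {depth:g} mm: beyond all "
                         "component ranges")

    basis = (1.0 - tail) * _lognormal_density(y, s_u[:, None], sigma)
    if tail > 0:
        basis = basis + tail * _lognormal_density(y, 10.0 * s_u[:, None],
                                                  sigma)
    density = basis.T @ node_w
    if config.noise:
        if rng is None:
            rng = np.random.default_rng(config.rng_seed)
        density = density * rng.gamma(shape=400.0, scale=1.0 / 400.0,
                                      size=density.shape)
    spec = LinealSpectrum(y, density, metadata={
        "depth_mm": float(depth), "site_diameter_um": config.site_diameter})
    return normalize(spec)


def generate_beam(config: BeamConfig,
                  model: RangeEnergyModel = RangeEnergyModel()
                  ) -> tuple[DepthProfile, SpectrumSeries]:
    """Full synthetic beam: aligned depth-dose profile and spectrum series.

    Deterministic for a given config unless noise injection is enabled.
    Depths receiving less than 0.1% of the maximum dose (or lying beyond
    every component's range) carry no spectrum; the series flags them with
    None and downstream profile operations exclude them.
    """
    comps, plateau = _components(config, model)
    grid = config.depth_grid
    dose = np.zeros_like(grid)
    for _, w, prof in comps:
        dose += w * prof.physical_dose
    scale = dose.max()
    dose = dose / scale  # unit maximum; absolute level set by normalization

    rng = np.random.default_rng(config.rng_seed) if config.noise else None
    y = _default_y_grid()
    cutoff = 1e-3
    spectra: list[LinealSpectrum | None] = []
    for depth, d in zip(grid, dose):
        if d < cutoff:
            spectra.append(None)
            continue
        try:
            spectra.append(lineal_spectrum_at_depth(
                config, model, comps, depth, y_grid=y, rng=rng))
        except ValueError:
            spectra.append(None)

    meta = {"beam": ("sobp" if config.modulation_width > 0 else "pristine"),
            "entrance_energy_MeV": config.entrance_energy,
            "modulation_width_mm": config.modulation_width,
            "n_components": len(comps),
            # plateau spans the pristine-peak maxima; its distal boundary
            # is resolved only to within the range-spread width
            "plateau_mm": [plateau[0], plateau[1]],
            "distal_transition_mm": _range_sigma_mm(
                config, model, model.range_mm(config.entrance_energy))}
    profile = DepthProfile(depths=grid, physical_dose=dose, metadata=meta)
    series = SpectrumSeries(depths=grid, spectra=spectra, dose_weights=dose)
    return profile, series
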