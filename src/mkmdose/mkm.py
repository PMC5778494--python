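"""Linear-quadratic / microdosimetric-kinetic-model engine.

Maps radiation quality to cell survival and relative biological
effectiveness (RBE):

* the MKM linear coefficient α = α₀ + β·z*₁D, with β independent of
  radiation quality;
* the LQ survival model S(D) = exp(−αD − βD²) and its dose inversion
  D(S) = [−α + √(α² − 4β ln S)] / (2β);
* RBE at a survival endpoint, RBE(S) = D_ref(S) / D_test(S), against a
  reference radiation (default 200 kVp X-rays, α 0.19 Gy⁻¹, β 0.05 Gy⁻²);
* depth profiles: per-depth window-averaged spectra → z*₁D → α → RBE →
  RBE-weighted dose, plus dose-normalization and survival-vs-depth
  operations matching clinical conventions (2 Gy at the Bragg peak or
  spread-out-Bragg-peak center).

The dose inversion is evaluated in the rationalized form
D = −2 ln S / (α + √(α² − 4β ln S)), which avoids cancellation for small β
and reduces exactly to −ln S / α at β = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .spectra import (LinealSpectrum, MKMParams, SpectrumSeries,
                      depth_window_average, z_star_1d)

__all__ = [
    "ReferenceRadiation",
    "LQCoefficients",
    "Endpoint",
    "DepthProfile",
    "SurvivalProfile",
    "X200KVP",
    "alpha_from_zstar",
    "dose_for_survival",
    "survival_for_dose",
    "rbe_at_endpoint",
    "rbe_depth_profile",
    "normalize_profile",
    "survival_depth_profile",
    "sobp_center_depth",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceRadiation:
    """LQ coefficients of the reference beam used in the RBE ratio."""

    alpha_x: float
    beta_x: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.alpha_x <= 0:
            raise ValueError("alpha_x must be > 0")
        if self.beta_x < 0:
            raise ValueError("beta_x must be >= 0")


#: Default reference radiation: 200 kVp X-rays.
X200KVP = ReferenceRadiation(alpha_x=0.19, beta_x=0.05, label="200 kVp X-rays")

REFERENCE_PRESETS = {"X200KVP": X200KVP}


@dataclass(frozen=True)
class LQCoefficients:
    alpha: float  # Gy^-1
    beta: float   # Gy^-2

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass(frozen=True)
class Endpoint:
    """Survival endpoint at which RBE is evaluated (default 10% survival)."""

    survival: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.survival < 1:
            raise ValueError("endpoint survival must lie in (0, 1)")


@dataclass
class DepthProfile:
    """Aligned per-depth arrays: physical dose plus MKM-derived quantities.

    Derived arrays hold NaN at depths that were excluded (no spectrum in
    the averaging window); ``excluded_depths`` lists them explicitly.
    """

    depths: np.ndarray
    physical_dose: np.ndarray
    spectra: list | None = None
    z_star: np.ndarray | None = None
    alpha: np.ndarray | None = None
    rbe: np.ndarray | None = None
    rbe_weighted_dose: np.ndarray | None = None
    excluded_depths: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.physical_dose = np.asarray(self.physical_dose, dtype=float)
        if self.depths.ndim != 1 or self.depths.size == 0:
            raise ValueError("depths must be a non-empty 1-D array")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if self.physical_dose.shape != self.depths.shape:
            raise ValueError("physical_dose must align with depths")
        if np.any(self.physical_dose < 0):
            raise ValueError("physical_dose must be non-negative")
        for name in ("z_star", "alpha", "rbe", "rbe_weighted_dose"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.depths.shape:
                    raise ValueError(f"{name} must align with depths")
                setattr(self, name, arr)


def alpha_from_zstar(params: MKMParams, zstar) -> float | np.ndarray:
    """MKM linear LQ coefficient α = α₀ + β·z*₁D (Gy⁻¹)."""
    zstar = np.asarray(zstar, dtype=float)
    if np.any(zstar < 0):
        raise ValueError("z*_1D must be non-negative")
    out = params.alpha0 + params.beta * zstar
    return float(out) if out.ndim == 0 else out


def dose_for_survival(lq: LQCoefficients, survival: float) -> float:
    """Dose (Gy) at which the LQ model yields the given surviving fraction.

    Positive root of βD² + αD + ln S = 0, evaluated in the rationalized
    form −2 ln S / (α + √(α² − 4β ln S)); exact at β = 0.
    """
    if not 0 < survival < 1:
        raise ValueError("survival must lie in (0, 1)")
    log_s = np.log(survival)
    return float(-2.0 * log_s /
                 (lq.alpha + np.sqrt(lq.alpha ** 2 - 4.0 * lq.beta * log_s)))


def survival_for_dose(lq: LQCoefficients, dose: float) -> float:
    """Surviving fraction S = exp(−αD − βD²) at dose D (Gy)."""
    if dose < 0:
        raise ValueError("dose must be non-negative")
    return float(np.exp(-lq.alpha * dose - lq.beta * dose ** 2))


def rbe_at_endpoint(lq_c: LQCoefficients, ref: ReferenceRadiation,
                    ep: Endpoint = Endpoint()) -> float:
    """RBE(S) = D_ref(S) / D_test(S) at the endpoint's surviving fraction."""
    ref_lq = LQCoefficients(ref.alpha_x, ref.beta_x)
    return (dose_for_survival(ref_lq, ep.survival) /
            dose_for_survival(lq_c, ep.survival))


def rbe_depth_profile(series: SpectrumSeries, physical_dose,
                      params: MKMParams, ref: ReferenceRadiation = X200KVP,
                      ep: Endpoint = Endpoint(),
                      window_halfwidth: float = 1.5) -> DepthProfile:
    """Run the full MKM chain at every depth of a spectrum series.

    For each depth: average the spectra over ±``window_halfwidth`` mm
    (dose-weighted when the series carries dose weights), compute z*₁D,
    α = α₀ + β·z*₁D, RBE at the endpoint, and RBE-weighted dose
    = RBE × physical dose.  Depths whose window holds no spectrum are
    excluded (NaN in the derived arrays) and logged, never interpolated.
    """
    physical_dose = np.asarray(physical_dose, dtype=float)
    if physical_dose.shape != series.depths.shape:
        raise ValueError("physical_dose must align with series depths")

    n = len(series)
    z = np.full(n, np.nan)
    excluded: list[float] = []
    for i, depth in enumerate(series.depths):
        try:
            avg = depth_window_average(series, depth, window_halfwidth)
        except ValueError:
            excluded.append(float(depth))
            continue
        z[i] = z_star_1d(avg, params)
    if excluded:
        logger.warning("excluded %d depths with no spectra in the +-%g mm "
                       "window: %s", len(excluded), window_halfwidth, excluded)

    valid = ~np.isnan(z)
    alpha = np.full(n, np.nan)
    alpha[valid] = alpha_from_zstar(params, z[valid])
    rbe = np.full(n, np.nan)
    ref_dose = dose_for_survival(LQCoefficients(ref.alpha_x, ref.beta_x),
                                 ep.survival)
    for i in np.flatnonzero(valid):
        rbe[i] = ref_dose / dose_for_survival(
            LQCoefficients(alpha[i], params.beta), ep.survival)
    rbe_dose = rbe * physical_dose

    return DepthProfile(
        depths=series.depths, physical_dose=physical_dose,
        spectra=list(series.spectra), z_star=z, alpha=alpha, rbe=rbe,
        rbe_weighted_dose=rbe_dose, excluded_depths=excluded,
        metadata={
            "mkm_params": params.label or "custom",
            "beta_Gy-2": params.beta,
            "reference": ref.label or "custom",
            "endpoint_survival": ep.survival,
            "window_halfwidth_mm": window_halfwidth,
        })


def sobp_center_depth(depths: np.ndarray, dose: np.ndarray,
                      threshold: float = 0.95) -> float:
    """Midpoint of the depths where dose first/last reaches 95% of max."""
    level = threshold * np.nanmax(dose)
    above = np.flatnonzero(dose >= level)
    if above.size == 0:
        raise ValueError("no depth reaches the SOBP plateau threshold")
    return float(0.5 * (depths[above[0]] + depths[above[-1]]))


def _anchor_index(profile: DepthProfile, mode: str, on_array: np.ndarray,
                  custom_depth: float | None) -> int:
    if mode == "bragg_peak":
        return int(np.nanargmax(profile.physical_dose))
    if mode == "sobp_center":
        center = sobp_center_depth(profile.depths, profile.physical_dose)
        return int(np.argmin(np.abs(profile.depths - center)))
    if mode == "custom_depth":
        if custom_depth is None:
            raise ValueError("custom_depth mode requires a depth")
        return int(np.argmin(np.abs(profile.depths - custom_depth)))
    raise ValueError(f"unknown normalization mode: {mode!r}")


def normalize_profile(profile: DepthProfile, mode: str = "bragg_peak",
                      target_dose: float = 2.0, on: str = "physical",
                      custom_depth: float | None = None) -> DepthProfile:
    """Rescale the dose arrays so the anchor depth carries ``target_dose``.

    ``mode`` picks the anchor (Bragg-peak maximum, SOBP plateau midpoint by
    the 95%-of-max convention, or an explicit depth); ``on`` selects whether
    the physical or the RBE-weighted dose is pinned there.  Both dose arrays
    are scaled by the same factor, so RBE(depth) is unchanged.
    """
    if on not in ("physical", "rbe_weighted"):
        raise ValueError("on must be 'physical' or 'rbe_weighted'")
    selected = (profile.physical_dose if on == "physical"
                else profile.rbe_weighted_dose)
    if selected is None:
        raise ValueError("profile carries no RBE-weighted dose yet")
    i = _anchor_index(profile, mode, selected, custom_depth)
    anchor_value = selected[i]
    if not np.isfinite(anchor_value) or anchor_value <= 0:
        raise ValueError("anchor dose is zero or undefined; cannot normalize")
    factor = target_dose / anchor_value

    meta = dict(profile.metadata)
    meta.update({"normalization_mode": mode, "normalized_on": on,
                 "target_dose_Gy": target_dose,
                 "anchor_depth_mm": float(profile.depths[i]),
                 "sobp_plateau_threshold": 0.95})
    return DepthProfile(
        depths=profile.depths, physical_dose=profile.physical_dose * factor,
        spectra=profile.spectra, z_star=profile.z_star, alpha=profile.alpha,
        rbe=profile.rbe,
        rbe_weighted_dose=(None if profile.rbe_weighted_dose is None
                           else profile.rbe_weighted_dose * factor),
        excluded_depths=list(profile.excluded_depths), metadata=meta)


@dataclass
class SurvivalProfile:
    """Survival fraction and the (rescaled) physical dose per depth."""

    depths: np.ndarray
    dose: np.ndarray
    survival: np.ndarray
    metadata: dict = field(default_factory=dict)


def survival_depth_profile(profile: DepthProfile, beta: float,
                           dose_at_center: float | None = None,
                           survival_at_center: float | None = None
                           ) -> SurvivalProfile:
    """Survival-vs-depth under a prescription at the SOBP center.

    Scales the physical-dose profile so that either the physical dose or
    the surviving fraction takes the prescribed value at the SOBP center,
    then evaluates S(depth) = exp(−α(depth)·D(depth) − β·D(depth)²) with
    the per-depth α carried by the profile.
    """
    if (dose_at_center is None) == (survival_at_center is None):
        raise ValueError(
            "give exactly one of dose_at_center / survival_at_center")
    if profile.alpha is None:
        raise ValueError("profile carries no per-depth alpha; "
                         "run rbe_depth_profile first")

    center = sobp_center_depth(profile.depths, profile.physical_dose)
    i = int(np.argmin(np.abs(profile.depths - center)))
    d_center = profile.physical_dose[i]
    if d_center <= 0:
        raise ValueError("zero physical dose at the SOBP center; "
                         "prescription unattainable")
    if not np.isfinite(profile.alpha[i]):
        raise ValueError("alpha undefined at the SOBP center")

    if dose_at_center is not None:
        target = float(dose_at_center)
    else:
        lq_c = LQCoefficients(float(profile.alpha[i]), beta)
        target = dose_for_survival(lq_c, float(survival_at_center))
    factor = target / d_center

    dose = profile.physical_dose * factor
    survival = np.exp(-profile.alpha * dose - beta * dose ** 2)
    meta = dict(profile.metadata)
    meta.update({"prescription": ("dose" if dose_at_center is not None
                                  else "survival"),
                 "center_depth_mm": float(profile.depths[i]),
                 "center_dose_Gy": float(dose[i])})
    return SurvivalProfile(depths=profile.depths, dose=dose,
                           survival=survival, metadata=meta)
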