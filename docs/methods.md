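# Methods

## Scope and model

`mkmdose` computes RBE-weighted dose for proton beams with the
microdosimetric kinetic model (MKM).  The chain is

1. lineal-energy dose spectrum d(y) per depth (input, or synthesized);
2. depth-window averaging of the spectra (±1.5 mm by default, emulating a
   detector whose active length exceeds the scoring resolution);
3. saturation-corrected dose-mean lineal energy
   y* = y₀² ∫ [1 − e^(−y²/y₀²)] d(y)/y dy and specific energy per event
   z*₁D = 0.1602·y*/(ρπr_d²);
4. LQ linear coefficient α = α₀ + β·z*₁D, with β quality-independent;
5. RBE(S) = D_ref(S)/D(S) at a survival endpoint (default S = 0.1) against
   a 200 kVp X-ray reference (α 0.19 Gy⁻¹, β 0.05 Gy⁻²);
6. RBE-weighted dose = RBE × physical dose per depth; optional dose
   normalization and survival-vs-depth profiles.

Assumptions inherited from the model: a single (α₀, β, r_d, y₀) cell
parameterization; no dose-rate, fractionation, oxygen or repair kinetics;
RBE evaluated at one endpoint irrespective of dose level.  The two preset
parameter sets were fitted to human salivary gland cell survival under
heavy ions; no proton-specific recalibration is attempted.

### Saturation integrand

The saturation correction is implemented in the Kase form — integrand
[1 − exp(−y²/y₀²)]·d(y)/y with prefactor y₀².  Written without the 1/y it
would not reduce to the dose-mean lineal energy ȳ_D in the low-y limit,
which is the defining property of the correction (no overkill for sparse
tracks); the 1/y reading is therefore the only self-consistent one, and
y* ≤ ȳ_D holds exactly since 1 − e⁻ˣ ≤ x.

### Numerical choices

* All spectral integrals use the trapezoid rule on the native y-grid:
  deterministic, oracle-checkable, and accurate to ≪0.5% for the smooth
  spectra this package handles (verified against an exact Monte-Carlo
  sampler of the piecewise-linear density).
* d(y) is the canonical stored form; f(y) ∝ d(y)/y is derived on demand.
  Grids with y ≤ 0 are rejected outright because of the 1/y terms.
* Units are fixed: y in keV/μm, r_d in μm, ρ in g/cm³, z in Gy.  The
  constant 0.1602 converts keV/μm per μm²·(g/cm³) mass path to Gy
  (1 keV = 1.602×10⁻¹⁶ J; 1 μm³ of unit-density tissue = 10⁻¹⁵ kg).
* The LQ dose inversion uses the rationalized root
  D = −2 ln S / (α + √(α² − 4β ln S)), which avoids catastrophic
  cancellation at small β and is exact at β = 0 — no separate branch is
  needed.
* Window averaging interpolates member spectra linearly onto the union
  y-grid (zero outside each member's support) and renormalizes; weights
  are dose-proportional when per-depth dose is available, uniform
  otherwise.
* Depths whose window contains no spectrum are excluded and reported
  (NaN in derived arrays plus an explicit list); they are never
  interpolated.
* Anchors for dose normalization: the Bragg peak is the argmax of
  physical dose; the SOBP center is the midpoint between the first and
  last depths reaching 95% of the maximum.  The 95% convention is
  recorded in output metadata.
* Log rebinning interpolates the density onto the log-spaced grid and
  rescales to conserve the mass over the overlap range exactly; mass
  outside the requested range is reported as a clipped fraction.

## Synthetic beam generator

The generator stands in for a Monte-Carlo transport calculation.  It
reproduces the qualitative depth structure of a clinical
passive-scattering proton field, not any specific engine's output, and
none of its constants claim transport-grade accuracy.

* **Range–energy**: Bragg–Kleeman power law R = aEᵖ with a = 0.0022
  cm/MeVᵖ, p = 1.77 (literature power-law constants for protons in
  water; the 155 MeV range lands within 2% of the tabulated 16.8 cm).
  Stopping power is its exact derivative S(E) = E^(1−p)/(ap).
* **Pristine Bragg curves**: stopping power averaged over each depth cell
  (taming the integrable (R−z)^−0.435 end-of-range singularity), reduced
  by a linear 1%/cm nuclear-fluence loss, then convolved with a Gaussian
  range-spread kernel.  The kernel width combines intrinsic straggling
  (σ_R = 0.012·R) with the spread from the beam's fractional energy
  spread σ_E/E (default 0.015, range contribution p·(σ_E/E)·R) in
  quadrature — a mono-energetic beam without momentum spread would give
  unrealistically narrow peaks that no practical modulator could flatten.
* **Default beam**: entrance energy 136.3 MeV puts the pristine peak near
  132 mm, a typical clinical depth for a nominal 155 MeV beamline after
  upstream material losses; depth grid 0–180 mm at 0.5 mm.
* **SOBP construction**: n range-shifted pristine peaks (default 13)
  whose nominal ranges span the modulation width below the deepest peak.
  Weights minimize the maximum deviation of the summed dose from its
  plateau mean — a Chebyshev fit solved as a linear program with the
  plateau mean pinned, which directly optimizes the ±2% flatness
  criterion the construction must meet (an ordinary least-squares fit
  leaves slow undulations that a minimax fit removes).  A second solve
  additionally constrains the plateau to be non-decreasing over its
  distal three quarters and is kept when it still meets the flatness
  budget: a physical ridge filter is effectively continuous, and pinning
  the ripple phase this way keeps the quality-weighted dose monotone
  where the radiation-quality gradient is small.  Identical peaks share
  their group's mean weight (symmetry tie-break).  The plateau is
  bookkept as the span of the pristine-peak maxima; its distal boundary
  is physically resolved only to within the range-spread σ, which the
  beam metadata reports as the distal transition width.
* **Spectra**: at each depth, the protons of every pristine component
  carry a Gaussian residual-range distribution (the same spread that
  shapes the dose curve).  Each residual range maps to a stopping power
  S(u), contributing a log-normal d(y) with median S(u) and log-width
  0.35, dose-weighted by range density × S(u); a 5% dose fraction sits in
  a second log-normal at 10× the median, emulating secondary particles.
  Integrating over the range distribution (128 log-spaced quadrature
  nodes) rather than assigning each component a single energy makes the
  spectra — and hence z*₁D, α and RBE — vary smoothly and monotonically
  with depth, as they must when track ends are continuously distributed.
  The defaults put the entrance ȳ_D near 1 keV/μm, the regime where the
  proton RBE against 200 kVp X-rays drops below 1.
* **Determinism and noise**: the generator is fully deterministic;
  multiplicative gamma counting noise on d(y) is available behind an
  explicit flag with a seed, for robustness testing only.

### What the generator does and does not emulate

It reproduces: the Bragg peak and its straggled falloff, realistic
peak-to-entrance dose ratios, a ±2%-flat SOBP, spectral hardening with
depth, entrance RBE < 1 and the monotone distal rise of RBE and
RBE-weighted dose.  It does not model: nuclear fragmentation spectra,
beamline hardware, lateral profiles, detector response, or the detailed
high-y tails of measured microdosimetric spectra.  Tests passing on
synthetic beams therefore validate the MKM chain's correctness and its
qualitative response to radiation-quality gradients — not quantitative
agreement with any measured beam.

## Parameters that matter

| parameter | unit | default | role |
|---|---|---|---|
| α₀, β | Gy⁻¹, Gy⁻² | 0.13, 0.05 (`SET_B`) | LQ intercept/slope of the MKM |
| r_d | μm | 0.42 (`SET_B`) | domain radius in z*₁D |
| y₀ | keV/μm | 150 (`SET_B`) | saturation (overkill) scale |
| reference α, β | Gy⁻¹, Gy⁻² | 0.19, 0.05 | 200 kVp X-ray LQ coefficients |
| endpoint S | – | 0.1 | survival level for RBE |
| window half-width | mm | 1.5 | spectral depth averaging |
| entrance energy | MeV | 136.3 | pristine peak near 132 mm |
| modulation width | mm | 0 (pristine) | SOBP plateau length |
| σ_E/E | – | 0.015 | beam energy spread |
| spectrum log-width | – | 0.35 | d(y) component width |
| tail fraction | – | 0.05 | high-y secondary share |

The sensitive-site diameter (default 0.564 μm) is provenance metadata on
generated spectra: it equals 2·r_d of `SET_A` but not of `SET_B`, and
since the synthetic spectra are not scored in an explicit site, no
consistency between site diameter and domain radius is enforced.

## Known limitations

* The power-law range-energy model degrades below ~1 MeV; spectra near
  track ends are resolved down to a 0.05 mm residual range and the last
  micrometres of track are absorbed into the nearest quadrature node.
* The 95% SOBP-center convention is one of several reasonable choices;
  profiles normalized under a different convention will disagree at the
  few-mm level in anchor position.
* Survival-vs-depth supports both a physical-dose and a survival
  prescription at the SOBP center, since either convention appears in
  practice; they differ by a scale factor.
* Problem sizes in the test-suite and the acceptance script (0.5 mm depth
  grids, 400-point y-grids, 10⁶ Monte-Carlo samples, 10³ random spectra)
  were chosen so every check runs in seconds while keeping quadrature
  error an order of magnitude below the tolerances being asserted.
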