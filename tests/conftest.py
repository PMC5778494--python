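"""Shared fixtures: canonical spectra and synthetic-beam chains.

The beam chains are session-scoped because generating a beam and running
the RBE chain over every depth is the expensive part of the suite; all
tests treat them as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

from mkmdose import (BeamConfig, LinealSpectrum, SET_B, generate_beam,
                     normalize, rbe_depth_profile)


def make_delta_spectrum(y_center: float, rel_width: float = 1e-4,
                        n: int = 65) -> LinealSpectrum:
    """Narrow Gaussian spectrum approximating a point mass.

    Support extends to ±8σ so the edge density underflows to ~0 and the
    spectrum mixes cleanly onto union grids.
    """
    y = np.linspace(y_center * (1 - 8 * rel_width),
                    y_center * (1 + 8 * rel_width), n)
    d = np.exp(-0.5 * ((y - y_center) / (rel_width * y_center)) ** 2)
    return normalize(LinealSpectrum(y, d))


def make_uniform_spectrum(y_lo: float, y_hi: float,
                          n: int = 201) -> LinealSpectrum:
    y = np.linspace(y_lo, y_hi, n)
    return normalize(LinealSpectrum(y, np.ones(n)))


def make_lognormal_spectrum(median: float, sigma: float,
                            n: int = 400) -> LinealSpectrum:
    y = np.logspace(np.log10(median) - 4 * sigma / np.log(10),
                    np.log10(median) + 4 * sigma / np.log(10), n)
    d = np.exp(-0.5 * ((np.log(y) - np.log(median)) / sigma) ** 2) / y
    return normalize(LinealSpectrum(y, d))


def make_random_spectrum(rng: np.random.Generator,
                         n_max: int = 60) -> LinealSpectrum:
    """Arbitrary positive density on a random log-spaced grid."""
    n = int(rng.integers(5, n_max))
    lo = 10 ** rng.uniform(-1.5, 1.0)
    hi = lo * 10 ** rng.uniform(0.3, 3.0)
    y = np.logspace(np.log10(lo), np.log10(hi), n)
    d = rng.gamma(shape=1.5, scale=1.0, size=n)
    d[int(rng.integers(0, n))] += 1.0  # guarantee some mass
    return normalize(LinealSpectrum(y, d))


def sample_from_spectrum(spec, n: int, rng: np.random.Generator
                         ) -> np.ndarray:
    """Draw y-values exactly from the piecewise-linear density d(y).

    Independent Monte-Carlo oracle for quadrature checks: bin selection by
    trapezoid mass, within-bin position by inverting the linear-density
    CDF (a quadratic in the bin coordinate).
    """
    y, d = spec.y_grid, spec.d_density
    h = np.diff(y)
    mass = 0.5 * (d[1:] + d[:-1]) * h
    cum = np.cumsum(mass)
    total = cum[-1]
    u = rng.random(n) * total
    idx = np.minimum(np.searchsorted(cum, u), mass.size - 1)
    v = (u - (cum[idx] - mass[idx])) / mass[idx]  # uniform within bin
    d0, d1 = d[idx], d[idx + 1]
    t = np.where(
        np.abs(d1 - d0) > 1e-300 * np.maximum(d0, 1.0),
        (-d0 + np.sqrt(d0 ** 2 + v * (d1 ** 2 - d0 ** 2)))
        / np.where(d1 != d0, d1 - d0, 1.0),
        v)
    return y[idx] + t * h[idx]


@pytest.fixture(scope="session")
def pristine_chain():
    """Default mono-energetic beam run through the full MKM chain."""
    profile, series = generate_beam(BeamConfig())
    augmented = rbe_depth_profile(series, profile.physical_dose, SET_B)
    return profile, series, augmented


@pytest.fixture(scope="session")
def sobp_chain():
    """Default 60 mm SOBP run through the full MKM chain."""
    profile, series = generate_beam(BeamConfig(modulation_width=60.0))
    augmented = rbe_depth_profile(series, profile.physical_dose, SET_B)
    return profile, series, augmented
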