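"""Predicted IR spectra from harmonic stick spectra.

Band frequencies are scaled by an empirical factor (0.98 for B3LYP);
each band (ν, I) becomes a Gaussian with mean ν, integrated area I, and
instrument-matched width σ = 0.01·ν.  Conformer composites are
abundance-weighted sums.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import CoverageError, UndefinedSimilarityError, ValidationError
from .structures import Spectrum, StickSpectrum

#: Default frequency grid: 0.5 cm⁻¹ spacing over 300–1900 cm⁻¹.
DEFAULT_GRID = np.arange(300.0, 1900.0 + 0.25, 0.5)

SCALE_FACTOR_B3LYP = 0.98
WIDTH_FRACTION_FELIX = 0.01


def scale_frequencies(s: StickSpectrum,
                      factor: float = SCALE_FACTOR_B3LYP) -> StickSpectrum:
    """Multiply band frequencies by ``factor``; intensities unchanged."""
    if factor <= 0:
        raise ValidationError("scaling factor must be positive")
    return StickSpectrum(s.frequencies * factor, s.intensities.copy())


def broaden(
    s: StickSpectrum,
    width_fraction: float = WIDTH_FRACTION_FELIX,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Convert sticks to a sum of Gaussians with σ(ν) = width_fraction·ν.

    Each Gaussian integrates (trapezoid on the grid) to its band intensity;
    the grid must cover every band ± 5σ.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, float)
    values = np.zeros_like(grid)
    for nu, inten in zip(s.frequencies, s.intensities):
        if inten == 0.0:
            continue
        sigma = width_fraction * nu
        if nu - 5 * sigma < grid[0] or nu + 5 * sigma > grid[-1]:
            raise CoverageError(
                f"grid [{grid[0]}, {grid[-1]}] does not cover band at "
                f"{nu:.1f} ± 5σ ({5 * sigma:.1f}) cm⁻¹"
            )
        values += inten / (sigma * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((grid - nu) / sigma) ** 2
        )
    return Spectrum(grid, values, provenance="harmonic-broadened")


def composite(spectra: Sequence[Spectrum],
              weights: Sequence[float]) -> Spectrum:
    """Abundance-weighted pointwise sum of spectra on a common grid."""
    if len(spectra) != len(weights) or not spectra:
        raise ValidationError("need equally many spectra and weights")
    w = np.asarray(weights, float)
    if not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValidationError("weights must sum to 1")
    grid = spectra[0].grid
    for sp in spectra[1:]:
        if sp.grid.shape != grid.shape or not np.allclose(sp.grid, grid):
            raise ValidationError("spectra are not on a common grid")
    values = sum(wk * sp.values for wk, sp in zip(w, spectra))
    return Spectrum(grid, values, provenance="composite")


def similarity(a: Spectrum, b: Spectrum) -> float:
    """Cosine similarity of mean-subtracted spectra on a common grid."""
    if a.grid.shape != b.grid.shape or not np.allclose(a.grid, b.grid):
        raise ValidationError("spectra are not on a common grid")
    u = a.values - a.values.mean()
    v = b.values - b.values.mean()
    nu_, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu_ == 0.0 or nv == 0.0:
        raise UndefinedSimilarityError("zero-variance spectrum")
    return float(np.clip(np.dot(u, v) / (nu_ * nv), -1.0, 1.0))
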