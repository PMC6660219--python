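"""Nyquist sampling limits and cone spacing under hexagonal packing.

The cone array imposes the first sampling limit on spatial vision: a
hexagonal mosaic with row-to-row spacing ``s_row`` passes gratings up to
``N = 1/(2 s_row)`` cycles before aliasing.  For a hexagonal lattice with
angular density D (cones/deg^2) the center-to-center spacing is
``s = sqrt(2 / (sqrt(3) D))`` deg and the rows are ``s * sqrt(3)/2`` apart,
giving

    N = 0.5 * sqrt(2 D / sqrt(3))     [cyc/deg]
    s = 60 / (sqrt(3) * N)            [arcmin]

and the exact mutual consistency ``s * N * sqrt(3) = 60``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SamplingEstimate", "nyquist_limit", "cone_spacing", "snellen_equivalent", "sampling_estimate"]

SQRT3 = np.sqrt(3.0)


@dataclass(frozen=True)
class SamplingEstimate:
    """Sampling limit, spacing and approximate acuity for one density."""

    angular_density: float      # cones/deg^2
    nyquist_cpd: float          # cyc/deg
    spacing_arcmin: float       # center-to-center
    snellen_denominator: float  # 20/xx, approximate


def nyquist_limit(angular_density):
    """Hexagonal-packing Nyquist limit (cyc/deg) from density (cones/deg^2)."""
    d = np.asarray(angular_density, dtype=float)
    if np.any(d < 0):
        raise ValueError("density must be non-negative")
    out = 0.5 * np.sqrt(2.0 * d / SQRT3)
    return float(out) if np.isscalar(angular_density) else out


def cone_spacing(nyquist_cpd):
    """Center-to-center cone spacing (arcmin) from the Nyquist limit (cyc/deg)."""
    n = np.asarray(nyquist_cpd, dtype=float)
    if np.any(n <= 0):
        raise ValueError("Nyquist limit must be positive")
    out = 60.0 / (SQRT3 * n)
    return float(out) if np.isscalar(nyquist_cpd) else out


def snellen_equivalent(nyquist_cpd):
    """Approximate Snellen denominator 20/xx from the primary spatial
    frequency of a letter E (30 cyc/deg at 20/20)."""
    n = np.asarray(nyquist_cpd, dtype=float)
    if np.any(n <= 0):
        raise ValueError("Nyquist limit must be positive")
    out = 20.0 * 30.0 / n
    return float(out) if np.isscalar(nyquist_cpd) else out


def sampling_estimate(angular_density: float) -> SamplingEstimate:
    """Bundle Nyquist limit, spacing and Snellen estimate for one density."""
    n = nyquist_limit(angular_density)
    if n == 0:
        return SamplingEstimate(float(angular_density), 0.0, float("inf"), float("inf"))
    return SamplingEstimate(
        angular_density=float(angular_density),
        nyquist_cpd=n,
        spacing_arcmin=cone_spacing(n),
        snellen_denominator=snellen_equivalent(n),
    )
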