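"""Preferred retinal locus (PRL) and fixation-stability analysis.

During steady fixation the retinal location of a blinking target scatters
around the habitual fixation locus.  The PRL is estimated as the centroid of
that scatter; fixation stability is quantified by the bivariate contour
ellipse area (BCEA) — the area of the best-fitting ellipse containing a
stated fraction (by default 68%) of the fixation positions.  For a bivariate
Gaussian the ellipse is the sample-covariance ellipse scaled by the
chi-square quantile k = chi2.ppf(coverage, df=2), giving

    BCEA = pi * k * sqrt(det(cov))

An empirical-containment variant dilates the covariance ellipse until it
contains exactly ceil(coverage * n) points, for scatters far from Gaussian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .mosaic_density import ConeMosaic, window_density

__all__ = ["FixationTrace", "PRLEstimate", "fit_fixation_ellipse", "prl_metrics", "bcea_coverage_constant"]


@dataclass(frozen=True)
class FixationTrace:
    """Per-frame stimulus positions on the retina, arcmin, mosaic frame."""

    xy_arcmin: np.ndarray
    eye_id: str = ""

    def __post_init__(self) -> None:
        xy = np.atleast_2d(np.asarray(self.xy_arcmin, dtype=float))
        if xy.shape[1] != 2:
            raise ValueError("trace must be (n, 2)")
        if not np.isfinite(xy).all():
            raise ValueError("non-finite fixation coordinates")
        if len(xy) < 3:
            raise ValueError("need at least 3 fixation samples")
        object.__setattr__(self, "xy_arcmin", xy)

    def __len__(self) -> int:
        return len(self.xy_arcmin)


@dataclass(frozen=True)
class PRLEstimate:
    """Fixation centroid, scatter ellipse and BCEA."""

    centroid_arcmin: tuple[float, float]
    covariance_arcmin2: np.ndarray        # 2x2 sample covariance
    semi_axes_arcmin: tuple[float, float] # major, minor of the coverage ellipse
    orientation_deg: float                # major axis vs +x, CCW
    bcea_arcmin2: float
    coverage: float
    n: int

    def bcea_um2(self, rmf_um_per_deg: float) -> float:
        """BCEA in square microns: scale by the squared microns-per-arcmin."""
        um_per_arcmin = rmf_um_per_deg / 60.0
        return self.bcea_arcmin2 * um_per_arcmin**2


def bcea_coverage_constant(coverage: float = 0.68) -> float:
    """Chi-square (2 df) quantile scaling the covariance ellipse (~2.2789 at 0.68)."""
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    return float(chi2.ppf(coverage, df=2))


def fit_fixation_ellipse(
    trace: FixationTrace, coverage: float = 0.68, mode: str = "parametric"
) -> PRLEstimate:
    """Fit the coverage ellipse to a fixation scatter.

    ``mode="parametric"`` (default) scales the sample-covariance ellipse by
    the chi-square quantile; ``mode="empirical"`` rescales it so that exactly
    ``ceil(coverage * n)`` points fall inside, which makes no Gaussian
    assumption.  A zero-variance trace yields BCEA 0 with a warning.
    """
    if mode not in ("parametric", "empirical"):
        raise ValueError("mode must be 'parametric' or 'empirical'")
    xy = trace.xy_arcmin
    centroid = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False)
    k = bcea_coverage_constant(coverage)

    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    det = float(evals[0] * evals[1])
    if det <= 0:
        warnings.warn("degenerate (collinear or constant) fixation trace; BCEA = 0")
        scale = k
    elif mode == "empirical":
        # Mahalanobis radius^2 of each point; dilate to the containment quantile
        d2 = _mahalanobis_sq(xy - centroid, cov)
        m = int(np.ceil(coverage * len(xy)))
        scale = float(np.sort(d2)[m - 1])
    else:
        scale = k

    bcea = float(np.pi * scale * np.sqrt(det))
    major = float(np.sqrt(scale * evals[1]))
    minor = float(np.sqrt(scale * evals[0]))
    orientation = float(np.degrees(np.arctan2(evecs[1, 1], evecs[0, 1])))
    return PRLEstimate(
        centroid_arcmin=(float(centroid[0]), float(centroid[1])),
        covariance_arcmin2=cov,
        semi_axes_arcmin=(major, minor),
        orientation_deg=orientation,
        bcea_arcmin2=bcea,
        coverage=coverage,
        n=len(trace),
    )


def _mahalanobis_sq(centered: np.ndarray, cov: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(cov)
    return np.einsum("ni,ij,nj->n", centered, inv, centered)


def ellipse_contains(prl: PRLEstimate, xy_arcmin: np.ndarray) -> np.ndarray:
    """Boolean mask of points inside the fitted coverage ellipse."""
    xy = np.atleast_2d(xy_arcmin)
    centered = xy - np.asarray(prl.centroid_arcmin)
    # recover the scale from area: pi * scale * sqrt(det) = bcea
    det = float(np.linalg.det(prl.covariance_arcmin2))
    if det <= 0:
        return np.zeros(len(xy), dtype=bool)
    scale = prl.bcea_arcmin2 / (np.pi * np.sqrt(det))
    # tolerance keeps boundary points inside despite the area round-trip
    return _mahalanobis_sq(centered, prl.covariance_arcmin2) <= scale * (1 + 1e-9)


def prl_metrics(
    prl: PRLEstimate,
    peak_xy_arcmin: tuple[float, float],
    rmf_um_per_deg: float,
    mosaic: ConeMosaic | None = None,
    window_diameter_arcmin: float = 10.0,
) -> dict:
    """Displacement of the PRL from the density peak, plus density at the PRL.

    Both locations must be in the same (arcmin, mosaic-aligned) frame.
    Returns displacement in arcmin and microns, and — when a mosaic is
    provided — the window density at the PRL centroid in both unit systems.
    """
    dx = prl.centroid_arcmin[0] - peak_xy_arcmin[0]
    dy = prl.centroid_arcmin[1] - peak_xy_arcmin[1]
    disp_arcmin = float(np.hypot(dx, dy))
    disp_um = disp_arcmin * rmf_um_per_deg / 60.0
    out = {
        "displacement_arcmin": disp_arcmin,
        "displacement_um": disp_um,
        "bcea_arcmin2": prl.bcea_arcmin2,
        "bcea_um2": prl.bcea_um2(rmf_um_per_deg),
    }
    if mosaic is not None:
        center_px = (
            prl.centroid_arcmin[0] * mosaic.pixels_per_arcmin,
            prl.centroid_arcmin[1] * mosaic.pixels_per_arcmin,
        )
        d_ang, d_lin, valid = window_density(mosaic, center_px, window_diameter_arcmin)
        out.update(prl_angular_density=d_ang, prl_linear_density=d_lin, prl_window_valid=valid)
    return out
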