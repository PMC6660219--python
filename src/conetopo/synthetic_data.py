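"""Synthetic mosaics, fixation traces and cohorts with known ground truth.

Every pipeline stage is exercised against data whose generating parameters
are known: quasi-hexagonal cone mosaics with a radially decreasing density
profile, bivariate-Gaussian fixation scatter, and whole cohorts whose
density-versus-axial-length behaviour follows one of three eye-growth
models:

* ``global_expansion`` — the retina stretches in proportion to eye length;
  angular density is constant, linear density falls with axial length.
* ``equatorial_stretching`` — the fovea is rigid and simply recedes from the
  nodal point; linear density is constant, angular density rises.
* ``over_development`` — foveal packing continues to increase as the eye
  grows; linear density rises and angular density rises faster.

A continuous ``blend`` between the first two (exponent ``alpha`` on the
squared magnification ratio) generates cohorts with intermediate slopes.
All randomness flows from a single seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fixation_prl import FixationTrace
from .mosaic_density import ConeMosaic
from .schematic_eye import Biometry, SchematicConstants, rmf_from_biometry

__all__ = [
    "DensityProfile",
    "GrowthModel",
    "SyntheticMosaic",
    "generate_mosaic",
    "generate_fixation_trace",
    "generate_cohort",
]

# Dart throwing at 30 candidates per target point does not fully reach the
# hexagonal packing density; the minimum-distance is shrunk by this factor
# (measured once on constant-density mosaics) so achieved density matches
# the requested profile.
SPACING_CALIBRATION = 0.86
DART_ATTEMPTS_PER_POINT = 30

BASELINE_AXIAL_LENGTH_MM = 23.5


@dataclass(frozen=True)
class DensityProfile:
    """Radial cone-density falloff D(r) = peak / (1 + (r/r0)^gamma).

    ``peak_angular_density`` is in cones/deg^2; ``r0_arcmin`` is the radius
    at which density halves; ``anisotropy`` > 1 makes the vertical falloff
    steeper (r is computed with y scaled by it), emulating the steeper
    superior/inferior density drop of real foveas.  These are test-fixture
    conventions, not biological claims.
    """

    peak_angular_density: float = 15000.0
    r0_arcmin: float = 30.0
    gamma: float = 1.2
    anisotropy: float = 1.15

    def __post_init__(self) -> None:
        if self.peak_angular_density <= 0 or self.r0_arcmin <= 0:
            raise ValueError("peak density and r0 must be positive")
        if self.gamma <= 0 or self.anisotropy <= 0:
            raise ValueError("gamma and anisotropy must be positive")

    def density(self, x_arcmin, y_arcmin):
        """Angular density (cones/deg^2) at offsets from the profile center."""
        r = np.hypot(x_arcmin, self.anisotropy * np.asarray(y_arcmin))
        return self.peak_angular_density / (1.0 + (r / self.r0_arcmin) ** self.gamma)


@dataclass(frozen=True)
class SyntheticMosaic:
    """A generated mosaic plus its ground truth."""

    mosaic: ConeMosaic
    center_px: tuple[float, float]
    profile: DensityProfile
    seed: int


def _hex_spacing_arcmin(density_deg2):
    """Center-to-center spacing (arcmin) of a hexagonal lattice at density D."""
    return 60.0 * np.sqrt(2.0 / (np.sqrt(3.0) * np.asarray(density_deg2)))


def generate_mosaic(
    profile: DensityProfile,
    extent_arcmin: float = 90.0,
    seed: int = 0,
    pixels_per_arcmin: float = 9.48,
) -> SyntheticMosaic:
    """Generate a quasi-hexagonal cone mosaic over a square field.

    Variable-radius dart throwing: uniform candidates are sorted by
    (anisotropy-scaled) radius so the dense center fills first, then each is
    accepted if no accepted point lies within the calibrated local minimum
    distance ``SPACING_CALIBRATION * s(r)`` where ``s(r)`` is the hexagonal
    spacing at the local target density.  The point process is isotropic in
    angle, blue-noise in spacing, and reproducible for a given seed.
    """
    if extent_arcmin <= 0:
        raise ValueError("extent must be positive")
    min_spacing = _hex_spacing_arcmin(profile.peak_angular_density)
    if min_spacing < 0.05:
        raise ValueError("requested density implies spacing below 0.05 arcmin")
    rng = np.random.default_rng(seed)
    half = extent_arcmin / 2.0
    area_deg2 = (extent_arcmin / 60.0) ** 2

    # expected count from the mean profile density over the field
    gx = np.linspace(-half, half, 64)
    mean_d = float(profile.density(*np.meshgrid(gx, gx)).mean())
    n_target = int(mean_d * area_deg2)
    n_cand = DART_ATTEMPTS_PER_POINT * max(n_target, 1)

    # importance-sample candidates proportional to the target density so the
    # number of attempts per accepted point is uniform across the falloff
    chunks: list[np.ndarray] = []
    n_have = 0
    while n_have < n_cand:
        draw = rng.uniform(-half, half, size=(n_cand, 2))
        keep = rng.random(n_cand) < profile.density(draw[:, 0], draw[:, 1]) / profile.peak_angular_density
        chunks.append(draw[keep])
        n_have += int(keep.sum())
    cand = np.concatenate(chunks)[:n_cand]
    r_eff = np.hypot(cand[:, 0], profile.anisotropy * cand[:, 1])
    cand = cand[np.argsort(r_eff, kind="stable")]
    local_d = profile.density(cand[:, 0], cand[:, 1])
    local_min_dist = SPACING_CALIBRATION * _hex_spacing_arcmin(local_d)

    # spatial hash with cell size >= the largest exclusion radius
    cell = float(local_min_dist.max())
    inv_cell = 1.0 / cell
    grid: dict[tuple[int, int], list[int]] = {}
    accepted: list[int] = []
    xs, ys = cand[:, 0], cand[:, 1]
    for i in range(len(cand)):
        cx, cy = int(np.floor(xs[i] * inv_cell)), int(np.floor(ys[i] * inv_cell))
        d2_min = local_min_dist[i] ** 2
        ok = True
        for ux in (cx - 1, cx, cx + 1):
            for uy in (cy - 1, cy, cy + 1):
                for j in grid.get((ux, uy), ()):
                    dx = xs[i] - xs[j]
                    dy = ys[i] - ys[j]
                    if dx * dx + dy * dy < d2_min:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            accepted.append(i)
            grid.setdefault((cx, cy), []).append(i)

    pts_arcmin = cand[accepted]
    # image frame: pixels, origin at the field corner, center at half*ppa
    pts_px = (pts_arcmin + half) * pixels_per_arcmin
    mosaic = ConeMosaic(
        cone_xy=pts_px,
        pixels_per_arcmin=pixels_per_arcmin,
        eye_id=f"synthetic-{seed}",
        bounds_px=(0.0, 0.0, extent_arcmin * pixels_per_arcmin, extent_arcmin * pixels_per_arcmin),
    )
    center = (half * pixels_per_arcmin, half * pixels_per_arcmin)
    return SyntheticMosaic(mosaic=mosaic, center_px=center, profile=profile, seed=seed)


def generate_fixation_trace(
    centroid_arcmin: tuple[float, float],
    covariance_arcmin2: np.ndarray,
    n: int = 300,
    seed: int = 0,
) -> FixationTrace:
    """Bivariate-Gaussian fixation scatter around a PRL centroid."""
    cov = np.asarray(covariance_arcmin2, dtype=float)
    if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
        raise ValueError("covariance must be symmetric 2x2")
    if np.any(np.linalg.eigvalsh(cov) < -1e-12):
        raise ValueError("covariance must be positive semi-definite")
    rng = np.random.default_rng(seed)
    xy = rng.multivariate_normal(np.asarray(centroid_arcmin, float), cov, size=n,
                                 method="eigh")
    return FixationTrace(xy_arcmin=xy, eye_id=f"synthetic-{seed}")


@dataclass(frozen=True)
class GrowthModel:
    """Eye-growth model mapping axial length to foveal cone density.

    ``kind`` is one of ``global_expansion``, ``equatorial_stretching``,
    ``over_development`` or ``blend``.  The baseline eye (angular density
    ``baseline_profile.peak_angular_density`` at axial length 23.5 mm with
    the given anterior segment) anchors the curves:

    * global_expansion:      D_ang(AL) = D_ang0
    * equatorial_stretching: D_lin(AL) = D_lin0, so D_ang = D_ang0 (m/m0)^2
    * blend(alpha):          D_ang = D_ang0 (m/m0)^(2 alpha), alpha in [0, 1]
    * over_development:      D_lin = D_lin0 exp(gain (AL - 23.5)), gain > 0

    where ``m`` is the RMF (mm/deg) of the eye and ``m0`` the baseline RMF.
    """

    kind: str = "blend"
    baseline_profile: DensityProfile = DensityProfile()
    baseline_corneal_radius_mm: float = 7.8
    baseline_acd_mm: float = 3.6
    alpha: float = 0.5
    overdev_gain_per_mm: float = 0.02

    def __post_init__(self) -> None:
        kinds = ("global_expansion", "equatorial_stretching", "over_development", "blend")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.kind == "over_development" and self.overdev_gain_per_mm <= 0:
            raise ValueError("over-development requires a positive gain")

    def densities(self, axial_length_mm, rmf_um_per_deg, rmf0_um_per_deg):
        """(D_ang cones/deg^2, D_lin cones/mm^2) at the given axial length."""
        d_ang0 = self.baseline_profile.peak_angular_density
        mm_per_deg = np.asarray(rmf_um_per_deg) / 1000.0
        ratio = np.asarray(rmf_um_per_deg) / rmf0_um_per_deg
        if self.kind == "global_expansion":
            d_ang = d_ang0 * np.ones_like(ratio)
        elif self.kind == "equatorial_stretching":
            d_ang = d_ang0 * ratio**2
        elif self.kind == "blend":
            d_ang = d_ang0 * ratio ** (2.0 * self.alpha)
        else:  # over_development
            d_lin0 = d_ang0 / (rmf0_um_per_deg / 1000.0) ** 2
            d_lin = d_lin0 * np.exp(
                self.overdev_gain_per_mm * (np.asarray(axial_length_mm) - BASELINE_AXIAL_LENGTH_MM)
            )
            return d_lin * mm_per_deg**2, d_lin
        return d_ang, d_ang / mm_per_deg**2


def generate_cohort(
    n_eyes: int,
    al_range_mm: tuple[float, float],
    model: GrowthModel,
    noise_sd: float = 0.08,
    seed: int = 0,
    prl_displacement_mean_arcmin: float = 6.1,
    prl_density_ratio: float = 0.95,
) -> pd.DataFrame:
    """Generate a per-eye cohort table in the reference-table schema.

    Axial lengths are uniform over ``al_range_mm``; the anterior segment is
    held fixed at the model baseline so the RMF varies only through axial
    length; densities follow the growth model with multiplicative log-normal
    noise of fractional SD ``noise_sd``.  Subjects contribute two eyes each
    (the last may contribute one when ``n_eyes`` is odd).  PRL displacement
    is Rayleigh-distributed with the stated mean and PRL density is the peak
    scaled by ``prl_density_ratio`` (with the same noise model).
    """
    if n_eyes < 6:
        raise ValueError("need at least 6 eyes for a meaningful cohort")
    lo, hi = al_range_mm
    if not (20.0 < lo < hi < 30.0):
        raise ValueError("axial-length range must be within (20, 30) mm")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    al = rng.uniform(lo, hi, size=n_eyes)

    def rmf_of(al_mm: float) -> float:
        biom = Biometry(
            axial_length_mm=al_mm,
            corneal_front_radius_mm=model.baseline_corneal_radius_mm,
            acd_mm=model.baseline_acd_mm,
        )
        return rmf_from_biometry(biom, SchematicConstants()).rmf_um_per_deg

    rmf0 = rmf_of(BASELINE_AXIAL_LENGTH_MM)
    rmf = np.array([rmf_of(a) for a in al])
    d_ang, d_lin = model.densities(al, rmf, rmf0)

    noise = np.exp(rng.normal(0.0, noise_sd, size=n_eyes)) if noise_sd > 0 else 1.0
    d_ang = d_ang * noise
    d_lin = d_lin * noise  # same draw: the two unit systems describe one mosaic

    prl_ratio = prl_density_ratio * (
        np.exp(rng.normal(0.0, noise_sd / 2.0, size=n_eyes)) if noise_sd > 0 else 1.0
    )
    prl_ang = d_ang * prl_ratio
    prl_lin = d_lin * prl_ratio
    rayleigh_sigma = prl_displacement_mean_arcmin / np.sqrt(np.pi / 2.0)
    disp_arcmin = rng.rayleigh(rayleigh_sigma, size=n_eyes)
    disp_um = disp_arcmin * rmf / 60.0

    subjects = [f"S{1 + i // 2:03d}" for i in range(n_eyes)]
    eyes = ["L" if i % 2 == 0 else "R" for i in range(n_eyes)]
    return pd.DataFrame(
        {
            "subject": subjects,
            "eye": eyes,
            "axial_length_mm": al,
            "corneal_radius_mm": model.baseline_corneal_radius_mm,
            "acd_mm": model.baseline_acd_mm,
            "rmf_um_per_deg": rmf,
            "peak_angular_density": d_ang,
            "peak_linear_density": d_lin,
            "prl_distance_arcmin": disp_arcmin,
            "prl_distance_um": disp_um,
            "prl_angular_density": prl_ang,
            "prl_linear_density": prl_lin,
        }
    )
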