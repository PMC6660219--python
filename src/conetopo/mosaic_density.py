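"""Sliding-window cone density maps and eccentricity profiles.

The measured object is a set of labeled cone centers in image pixels with a
known angular scale (pixels per arcminute).  Density at a point is the count
of cone centers falling on or within a circular sampling window (default 10
arcmin diameter) divided by the window area, expressed both per square degree
of visual angle and, through the retinal magnification factor, per square
millimeter of retina.  Maps evaluate the window on a pixel grid; windows that
extend beyond the labeled region are flagged invalid rather than
area-corrected, so analyses stay interior to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ConeMosaic",
    "DensityMap",
    "EccentricityProfile",
    "window_density",
    "window_density_um",
    "density_map",
    "find_peak",
    "annular_profile",
    "directional_profile",
    "convert_density",
]

DEFAULT_PIXELS_PER_ARCMIN = 9.48
DEFAULT_WINDOW_DIAMETER_ARCMIN = 10.0
MIN_CONE_SEPARATION_ARCMIN = 0.05


@dataclass
class ConeMosaic:
    """Labeled cone centers for one eye.

    Parameters
    ----------
    cone_xy : (n, 2) array
        Cone centers in image pixels, 0-based, x right / y down.
    pixels_per_arcmin : float
        Angular sampling scale of the imaging raster.
    rmf_um_per_deg : float
        Retinal magnification factor used for angular -> linear conversion.
    eye_id : str
        Identifier, e.g. ``"10003L"``.
    bounds_px : (xmin, ymin, xmax, ymax) or None
        Declared image bounds; defaults to the bounding box of the points.
    """

    cone_xy: np.ndarray
    pixels_per_arcmin: float = DEFAULT_PIXELS_PER_ARCMIN
    rmf_um_per_deg: float = float("nan")
    eye_id: str = ""
    bounds_px: tuple[float, float, float, float] | None = None
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.cone_xy = np.atleast_2d(np.asarray(self.cone_xy, dtype=float))
        if self.cone_xy.size == 0:
            self.cone_xy = np.empty((0, 2))
        if self.cone_xy.shape[1] != 2:
            raise ValueError("cone_xy must be (n, 2)")
        if self.pixels_per_arcmin <= 0:
            raise ValueError("pixels_per_arcmin must be positive")
        if len(self.cone_xy) > 1:
            # duplicate labels: two centers closer than any physical cone
            min_sep_px = MIN_CONE_SEPARATION_ARCMIN * self.pixels_per_arcmin
            if cKDTree(self.cone_xy).query_pairs(min_sep_px, output_type="ndarray").size:
                raise ValueError(
                    f"duplicate cone labels closer than {MIN_CONE_SEPARATION_ARCMIN} arcmin"
                )
        if self.bounds_px is None and len(self.cone_xy):
            xmin, ymin = self.cone_xy.min(axis=0)
            xmax, ymax = self.cone_xy.max(axis=0)
            self.bounds_px = (float(xmin), float(ymin), float(xmax), float(ymax))

    def __len__(self) -> int:
        return len(self.cone_xy)

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.cone_xy if len(self) else np.zeros((0, 2)))
        return self._tree

    def arcmin_radius_px(self, arcmin: float) -> float:
        return arcmin * self.pixels_per_arcmin


@dataclass
class DensityMap:
    """Gridded window densities with an interior-validity mask.

    ``angular`` holds cones/deg^2, ``linear`` cones/mm^2 (NaN when no RMF is
    available); ``x_px`` / ``y_px`` are the grid coordinates and
    ``valid_mask`` marks cells whose window lies fully inside the data
    bounds.
    """

    angular: np.ndarray
    linear: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid_mask: np.ndarray
    window_diameter_arcmin: float
    pixels_per_arcmin: float
    rmf_um_per_deg: float


@dataclass
class EccentricityProfile:
    """Mean density in concentric annuli around a center point."""

    inner_radii: np.ndarray       # in `unit`
    outer_radii: np.ndarray
    angular_density: np.ndarray   # cones/deg^2
    linear_density: np.ndarray    # cones/mm^2
    valid: np.ndarray             # annulus fully inside data bounds
    unit: str                     # "arcmin" or "um"
    center_px: tuple[float, float]


def _window_valid(mosaic: ConeMosaic, center: np.ndarray, radius_px: float) -> np.ndarray:
    if mosaic.bounds_px is None:
        return np.zeros(len(center), dtype=bool)
    xmin, ymin, xmax, ymax = mosaic.bounds_px
    cx, cy = center[:, 0], center[:, 1]
    return (
        (cx - radius_px >= xmin)
        & (cx + radius_px <= xmax)
        & (cy - radius_px >= ymin)
        & (cy + radius_px <= ymax)
    )


def _count_in_windows(mosaic: ConeMosaic, centers: np.ndarray, radius_px: float) -> np.ndarray:
    # boundary-inclusive: cones exactly on the window edge are counted
    if len(mosaic) == 0:
        return np.zeros(len(centers), dtype=int)
    counts = mosaic.tree.query_ball_point(centers, r=radius_px, return_length=True)
    return np.asarray(counts, dtype=int)


def window_density(
    mosaic: ConeMosaic,
    center_px: tuple[float, float],
    diameter_arcmin: float = DEFAULT_WINDOW_DIAMETER_ARCMIN,
) -> tuple[float, float, bool]:
    """Cone density in a circular window centered at ``center_px``.

    Returns ``(angular_density, linear_density, valid)`` where densities are
    cones/deg^2 and cones/mm^2 and ``valid`` is False when the window crosses
    the data bounds.  Cone centers on the boundary are counted.
    """
    if diameter_arcmin <= 0:
        raise ValueError("window diameter must be positive")
    centers = np.atleast_2d(np.asarray(center_px, dtype=float))
    radius_px = mosaic.arcmin_radius_px(diameter_arcmin / 2.0)
    count = _count_in_windows(mosaic, centers, radius_px)[0]
    area_deg2 = np.pi * (diameter_arcmin / 2.0 / 60.0) ** 2
    d_ang = count / area_deg2
    d_lin = convert_density(d_ang, mosaic.rmf_um_per_deg, "ang_to_lin")
    valid = bool(_window_valid(mosaic, centers, radius_px)[0]) if len(mosaic) else False
    return float(d_ang), float(d_lin), valid


def window_density_um(
    mosaic: ConeMosaic,
    center_px: tuple[float, float],
    diameter_um: float = 50.0,
) -> tuple[float, float, bool]:
    """Density in a window whose diameter is fixed on the retina (microns).

    Counterpart of :func:`window_density` for analyses that define the
    sampling window in linear rather than angular units; the linear density
    is computed directly from the micron window area and the angular density
    follows by unit conversion.
    """
    if diameter_um <= 0:
        raise ValueError("window diameter must be positive")
    if not np.isfinite(mosaic.rmf_um_per_deg) or mosaic.rmf_um_per_deg <= 0:
        raise ValueError("micron-window density requires a valid RMF")
    centers = np.atleast_2d(np.asarray(center_px, dtype=float))
    um_per_px = (mosaic.rmf_um_per_deg / 60.0) / mosaic.pixels_per_arcmin
    radius_px = (diameter_um / 2.0) / um_per_px
    count = _count_in_windows(mosaic, centers, radius_px)[0]
    area_mm2 = np.pi * (diameter_um / 2000.0) ** 2
    d_lin = count / area_mm2
    d_ang = convert_density(d_lin, mosaic.rmf_um_per_deg, "lin_to_ang")
    valid = bool(_window_valid(mosaic, centers, radius_px)[0]) if len(mosaic) else False
    return float(d_ang), float(d_lin), valid


def density_map(
    mosaic: ConeMosaic,
    step_px: int = 1,
    diameter_arcmin: float = DEFAULT_WINDOW_DIAMETER_ARCMIN,
) -> DensityMap:
    """Evaluate the sampling window on a regular pixel grid over the mosaic."""
    if step_px <= 0:
        raise ValueError("grid step must be a positive number of pixels")
    if diameter_arcmin <= 0:
        raise ValueError("window diameter must be positive")
    if mosaic.bounds_px is None:
        raise ValueError("empty mosaic has no data bounds to grid")
    xmin, ymin, xmax, ymax = mosaic.bounds_px
    xs = np.arange(xmin, xmax + 0.5 * step_px, step_px)
    ys = np.arange(ymin, ymax + 0.5 * step_px, step_px)
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    radius_px = mosaic.arcmin_radius_px(diameter_arcmin / 2.0)
    counts = _count_in_windows(mosaic, centers, radius_px).reshape(gy.shape)
    area_deg2 = np.pi * (diameter_arcmin / 2.0 / 60.0) ** 2
    angular = counts / area_deg2
    linear = convert_density(angular, mosaic.rmf_um_per_deg, "ang_to_lin")
    valid = _window_valid(mosaic, centers, radius_px).reshape(gy.shape)
    return DensityMap(
        angular=angular,
        linear=linear,
        x_px=xs,
        y_px=ys,
        valid_mask=valid,
        window_diameter_arcmin=diameter_arcmin,
        pixels_per_arcmin=mosaic.pixels_per_arcmin,
        rmf_um_per_deg=mosaic.rmf_um_per_deg,
    )


def find_peak(dmap: DensityMap) -> tuple[tuple[float, float], float, float]:
    """Location and value of the density maximum over valid cells.

    Ties (e.g. a flat map) resolve to the centroid of the maximal set.
    Returns ``((x_px, y_px), angular_density, linear_density)``.
    """
    if not dmap.valid_mask.any():
        raise ValueError("density map has no valid (fully interior) cells")
    vals = np.where(dmap.valid_mask, dmap.angular, -np.inf)
    peak = vals.max()
    iy, ix = np.nonzero(vals == peak)
    x = float(dmap.x_px[ix].mean())
    y = float(dmap.y_px[iy].mean())
    d_lin = convert_density(peak, dmap.rmf_um_per_deg, "ang_to_lin")
    return (x, y), float(peak), float(d_lin)


def annular_profile(
    mosaic: ConeMosaic,
    center_px: tuple[float, float],
    width: float = 5.0,
    unit: str = "arcmin",
    max_eccentricity: float | None = None,
) -> EccentricityProfile:
    """Mean density in concentric annuli of equal ``width`` around a center.

    ``unit`` selects angular annuli ("arcmin", e.g. 5-arcmin widths) or
    linear annuli on the retina ("um", e.g. 25-micron widths, converted to
    pixels through the RMF).  Boundary rule: each annulus is inner-exclusive
    and outer-inclusive; the innermost disk includes its center.  Annuli that
    extend beyond the data bounds are flagged invalid.
    """
    if width <= 0:
        raise ValueError("annulus width must be positive")
    if unit not in ("arcmin", "um"):
        raise ValueError("unit must be 'arcmin' or 'um'")
    center = np.asarray(center_px, dtype=float)
    if unit == "arcmin":
        width_px = width * mosaic.pixels_per_arcmin
        per_unit_deg = 1.0 / 60.0                    # deg per arcmin
    else:
        um_per_px = (mosaic.rmf_um_per_deg / 60.0) / mosaic.pixels_per_arcmin
        width_px = width / um_per_px
        per_unit_deg = np.nan

    if max_eccentricity is None:
        if mosaic.bounds_px is None:
            n_annuli = 1
        else:
            xmin, ymin, xmax, ymax = mosaic.bounds_px
            half_span = min(xmax - xmin, ymax - ymin) / 2.0
            n_annuli = max(1, int(np.floor(half_span / width_px)))
    else:
        n_annuli = max(1, int(np.ceil(max_eccentricity / width)))

    edges = np.arange(n_annuli + 1) * width          # in `unit`
    edges_px = edges * width_px / width
    if len(mosaic):
        r_px = np.hypot(*(mosaic.cone_xy - center).T)
    else:
        r_px = np.empty(0)

    d_ang = np.zeros(n_annuli)
    d_lin = np.zeros(n_annuli)
    valid = np.zeros(n_annuli, dtype=bool)
    rmf = mosaic.rmf_um_per_deg
    for i in range(n_annuli):
        lo, hi = edges_px[i], edges_px[i + 1]
        if i == 0:
            count = int(np.count_nonzero(r_px <= hi))
        else:
            count = int(np.count_nonzero((r_px > lo) & (r_px <= hi)))
        if unit == "arcmin":
            area_deg2 = np.pi * ((edges[i + 1] * per_unit_deg) ** 2 - (edges[i] * per_unit_deg) ** 2)
            d_ang[i] = count / area_deg2
            d_lin[i] = convert_density(d_ang[i], rmf, "ang_to_lin")
        else:
            area_mm2 = np.pi * ((edges[i + 1] / 1000.0) ** 2 - (edges[i] / 1000.0) ** 2)
            d_lin[i] = count / area_mm2
            d_ang[i] = convert_density(d_lin[i], rmf, "lin_to_ang")
        if mosaic.bounds_px is not None:
            valid[i] = bool(_window_valid(mosaic, center[None, :], hi)[0])
    return EccentricityProfile(
        inner_radii=edges[:-1],
        outer_radii=edges[1:],
        angular_density=d_ang,
        linear_density=d_lin,
        valid=valid,
        unit=unit,
        center_px=(float(center[0]), float(center[1])),
    )


def directional_profile(
    mosaic: ConeMosaic,
    center_px: tuple[float, float],
    axis: str = "horizontal",
    diameter_arcmin: float = DEFAULT_WINDOW_DIAMETER_ARCMIN,
    step_arcmin: float = 1.0,
    max_eccentricity_arcmin: float = 30.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Window density along a horizontal or vertical meridian.

    Returns ``(offsets_arcmin, angular, linear, valid)`` with signed offsets
    from the center (negative = left/up).  ``step_arcmin == 0`` degenerates
    to the single window at the center.
    """
    if axis not in ("horizontal", "vertical"):
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    if step_arcmin < 0:
        raise ValueError("step must be >= 0")
    if step_arcmin == 0:
        offsets = np.zeros(1)
    else:
        offsets = np.arange(-max_eccentricity_arcmin, max_eccentricity_arcmin + step_arcmin / 2, step_arcmin)
    cx, cy = center_px
    off_px = offsets * mosaic.pixels_per_arcmin
    if axis == "horizontal":
        centers = np.column_stack([cx + off_px, np.full_like(off_px, cy)])
    else:
        centers = np.column_stack([np.full_like(off_px, cx), cy + off_px])
    radius_px = mosaic.arcmin_radius_px(diameter_arcmin / 2.0)
    counts = _count_in_windows(mosaic, centers, radius_px)
    area_deg2 = np.pi * (diameter_arcmin / 2.0 / 60.0) ** 2
    angular = counts / area_deg2
    linear = convert_density(angular, mosaic.rmf_um_per_deg, "ang_to_lin")
    valid = _window_valid(mosaic, centers, radius_px) if len(mosaic) else np.zeros(len(centers), bool)
    return offsets, angular, linear, valid


def convert_density(d, rmf_um_per_deg: float, direction: str):
    """Convert between angular (cones/deg^2) and linear (cones/mm^2) density.

    One degree of visual angle covers ``rmf/1000`` mm of retina, so
    ``D_mm2 = D_deg2 / (rmf/1000)^2`` and conversely.
    """
    if direction not in ("ang_to_lin", "lin_to_ang"):
        raise ValueError("direction must be 'ang_to_lin' or 'lin_to_ang'")
    mm_per_deg_sq = (rmf_um_per_deg / 1000.0) ** 2
    if direction == "ang_to_lin":
        return d / mm_per_deg_sq
    return d * mm_per_deg_sq
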