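"""Four-surface paraxial schematic eye and retinal magnification.

Converting angular measurements (degrees of visual angle) to linear retinal
distances (microns) requires, for each eye, the axial length ``x`` and the
position of the secondary nodal point ``AN'``: a small visual angle ``theta``
subtends a retinal distance

    I = tan(1 deg) * (x - AN') * theta        [mm, theta in degrees]

so the retinal magnification factor (RMF) is ``1000 * tan(1 deg) * (x - AN')``
microns per degree. ``AN'`` is found by paraxial reduction of a four-surface
schematic eye: the two corneal surfaces are individualized from the measured
front radius (the back radius set to 88.31% of the front, per the Gullstrand
model), the anterior chamber depth positions the lens, and the remaining
constants (refractive indices, lens radii and thicknesses) are Gullstrand
schematic values with the lens equivalent index calibrated once against a
28-eye biometry/RMF reference table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Biometry",
    "SchematicConstants",
    "EyeModel",
    "ParaxialResult",
    "build_four_surface_eye",
    "locate_secondary_nodal_point",
    "locate_first_nodal_point",
    "retinal_magnification_factor",
    "rmf_from_biometry",
    "bennett_rmf",
    "trace_ray",
]

# Bennett's reduced-eye approximation: RMF [mm/deg] = q * (x - offset).
# The constant q corresponds to a reduced eye with its nodal point 1.82 mm
# behind the apex of a surface whose focal point falls on an emmetropic retina.
BENNETT_Q_MM_PER_DEG = 0.01306
BENNETT_OFFSET_MM = 1.82


class InvalidBiometryError(ValueError):
    """Biometry outside the physically sensible range for a human eye."""


class NoNodalPointError(ArithmeticError):
    """The composed optical system has zero equivalent power."""


@dataclass(frozen=True)
class Biometry:
    """Per-eye ocular biometry as measured by partial-coherence biometers.

    Parameters
    ----------
    axial_length_mm : float
        Corneal apex to retina distance, mm (symbol ``x``).
    corneal_front_radius_mm : float
        Radius of curvature of the anterior corneal surface, mm.
    acd_mm : float
        Anterior chamber depth, corneal front apex to lens front surface, mm
        (IOLMaster convention, i.e. it includes the corneal thickness).
    spherical_equivalent_d : float or None
        Spherical equivalent refraction in diopters; metadata only.
    """

    axial_length_mm: float
    corneal_front_radius_mm: float
    acd_mm: float
    spherical_equivalent_d: float | None = None

    def __post_init__(self) -> None:
        if not 15.0 < self.axial_length_mm < 40.0:
            raise InvalidBiometryError(
                f"axial length {self.axial_length_mm} mm outside (15, 40)"
            )
        if self.corneal_front_radius_mm <= 0:
            raise InvalidBiometryError("corneal front radius must be positive")
        if not 0.0 < self.acd_mm < self.axial_length_mm:
            raise InvalidBiometryError(
                "anterior chamber depth must be in (0, axial length)"
            )


@dataclass(frozen=True)
class SchematicConstants:
    """Fixed schematic-eye constants (Gullstrand values unless noted).

    The lens equivalent index default (1.40) was calibrated once so that
    ray-traced RMFs reproduce the reference biometry table; the remaining
    values are the classic Gullstrand constants.  Radii are signed with light
    travelling +z: positive when the center of curvature lies to the right of
    the vertex.
    """

    corneal_back_fraction: float = 0.8831
    n_air: float = 1.0
    n_cornea: float = 1.376
    n_aqueous: float = 1.336
    n_lens: float = 1.40
    n_vitreous: float = 1.336
    corneal_thickness_mm: float = 0.5
    lens_thickness_mm: float = 3.6
    lens_front_radius_mm: float = 10.0
    lens_back_radius_mm: float = -6.0

    def __post_init__(self) -> None:
        if not 0.0 < self.corneal_back_fraction <= 1.0:
            raise ValueError("corneal_back_fraction must be in (0, 1]")
        for name in ("n_cornea", "n_aqueous", "n_lens", "n_vitreous"):
            if getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must exceed 1 (air)")


@dataclass(frozen=True)
class EyeModel:
    """Ordered refracting surfaces of a schematic eye.

    ``surfaces`` is a tuple of ``(radius_mm, index_after, gap_to_next_mm)``;
    the last gap is the vitreous depth from the lens back surface to the
    retina, so the gaps sum to ``total_axial_length_mm``.
    """

    surfaces: tuple[tuple[float, float, float], ...]
    total_axial_length_mm: float

    def __post_init__(self) -> None:
        if len(self.surfaces) != 4:
            raise ValueError("EyeModel requires exactly 4 surfaces")
        gaps = sum(g for _, _, g in self.surfaces)
        if not math.isclose(gaps, self.total_axial_length_mm, rel_tol=0, abs_tol=1e-9):
            raise ValueError("surface gaps must sum to the axial length")
        if any(g < 0 for _, _, g in self.surfaces):
            raise ValueError("negative inter-surface gap")


@dataclass(frozen=True)
class ParaxialResult:
    """Secondary nodal point and retinal magnification for one eye."""

    nodal_point_2_mm: float          # AN', from the corneal apex
    rmf_um_per_deg: float            # microns of retina per degree
    retinal_image_size_mm_per_deg: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "retinal_image_size_mm_per_deg", self.rmf_um_per_deg / 1000.0
        )


def build_four_surface_eye(
    biometry: Biometry, constants: SchematicConstants = SchematicConstants()
) -> EyeModel:
    """Assemble the four-surface eye for one subject's biometry.

    Surfaces, in order along +z from the corneal apex: corneal front
    (measured radius), corneal back (88.31% of the front radius), lens front
    and lens back (schematic radii).  The aqueous gap is ``ACD - corneal
    thickness`` and the vitreous gap places the retina at the measured axial
    length.
    """
    c = constants
    b = biometry
    aqueous_gap = b.acd_mm - c.corneal_thickness_mm
    vitreous_gap = b.axial_length_mm - b.acd_mm - c.lens_thickness_mm
    if aqueous_gap < 0 or vitreous_gap < 0:
        raise InvalidBiometryError(
            "anterior chamber depth incompatible with schematic thicknesses"
        )
    surfaces = (
        (b.corneal_front_radius_mm, c.n_cornea, c.corneal_thickness_mm),
        (c.corneal_back_fraction * b.corneal_front_radius_mm, c.n_aqueous, aqueous_gap),
        (c.lens_front_radius_mm, c.n_lens, c.lens_thickness_mm),
        (c.lens_back_radius_mm, c.n_vitreous, vitreous_gap),
    )
    return EyeModel(surfaces=surfaces, total_axial_length_mm=b.axial_length_mm)


def _system_matrix(model: EyeModel) -> tuple[np.ndarray, float, float]:
    """Reduce the eye to a 2x2 system matrix acting on (height, n*angle).

    Returns the matrix from the first vertex to the last vertex, the image
    space index, and the z position of the last vertex.
    """
    n_before = 1.0
    S = np.eye(2)
    z_last = 0.0
    for i, (radius, n_after, gap) in enumerate(model.surfaces):
        if radius == 0:
            raise InvalidBiometryError("zero surface radius")
        power = (n_after - n_before) / radius  # mm^-1
        S = np.array([[1.0, 0.0], [-power, 1.0]]) @ S
        if i < len(model.surfaces) - 1:
            S = np.array([[1.0, gap / n_after], [0.0, 1.0]]) @ S
            z_last += gap
        n_before = n_after
    return S, n_before, z_last


def locate_secondary_nodal_point(model: EyeModel) -> float:
    """Distance (mm) from the corneal apex to the secondary nodal point AN'.

    With the system matrix ``[[A, B], [C, D]]`` in reduced-angle convention,
    the equivalent power is ``-C``; the back focal point lies ``-n' A / C``
    behind the last vertex and the secondary nodal point sits one *front*
    focal length (``n/P``, here ``1/P``) in front of it.  A ray aimed at the
    first nodal point therefore leaves toward the retina at its entering
    angle, which is the property that anchors the angle-to-distance
    conversion.
    """
    S, n_image, z_last = _system_matrix(model)
    A, C = S[0, 0], S[1, 0]
    power = -C
    if abs(power) < 1e-12:
        raise NoNodalPointError("system has zero equivalent power")
    back_focal_distance = -n_image * A / C
    nodal_from_last_vertex = back_focal_distance - 1.0 / power
    return z_last + nodal_from_last_vertex


def locate_first_nodal_point(model: EyeModel) -> float:
    """Distance (mm) from the corneal apex to the first nodal point AN.

    A ray aimed at AN from object space leaves the system at the same angle,
    appearing to come from AN'.
    """
    S, n_image, _ = _system_matrix(model)
    C, D = S[1, 0], S[1, 1]
    if abs(C) < 1e-12:
        raise NoNodalPointError("system has zero equivalent power")
    return (D - n_image) / C


def trace_ray(model: EyeModel, y0: float, u0: float) -> tuple[float, float]:
    """Trace a paraxial ray (height ``y0`` mm, slope ``u0`` rad at the corneal
    apex) surface by surface; return (height, slope) at the last surface.

    This explicit trace is deliberately independent of the system-matrix
    reduction so the two can be cross-checked.
    """
    y, nu = y0, 1.0 * u0
    n_before = 1.0
    for i, (radius, n_after, gap) in enumerate(model.surfaces):
        power = (n_after - n_before) / radius
        nu = nu - power * y
        if i < len(model.surfaces) - 1:
            y = y + gap * (nu / n_after)
        n_before = n_after
    return y, nu / n_before


def retinal_magnification_factor(axial_length_mm: float, nodal_point_2_mm: float) -> float:
    """RMF in microns per degree: ``1000 * tan(1 deg) * (x - AN')``."""
    if nodal_point_2_mm > axial_length_mm:
        raise ValueError("secondary nodal point beyond the retina")
    return 1000.0 * math.tan(math.radians(1.0)) * (axial_length_mm - nodal_point_2_mm)


def rmf_from_biometry(
    biometry: Biometry, constants: SchematicConstants = SchematicConstants()
) -> ParaxialResult:
    """Full pipeline: biometry -> eye model -> AN' -> RMF."""
    model = build_four_surface_eye(biometry, constants)
    an_prime = locate_secondary_nodal_point(model)
    rmf = retinal_magnification_factor(biometry.axial_length_mm, an_prime)
    return ParaxialResult(nodal_point_2_mm=an_prime, rmf_um_per_deg=rmf)


def bennett_rmf(axial_length_mm: float) -> float:
    """Bennett's reduced-eye RMF approximation, microns per degree.

    Assumes the focal point of the eye's optics coincides with the retina, so
    it overestimates RMF for hyperopic (short) eyes and underestimates it for
    myopic (long) eyes relative to the four-surface trace.
    """
    if axial_length_mm <= BENNETT_OFFSET_MM:
        raise ValueError("axial length must exceed the Bennett offset 1.82 mm")
    return 1000.0 * BENNETT_Q_MM_PER_DEG * (axial_length_mm - BENNETT_OFFSET_MM)
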