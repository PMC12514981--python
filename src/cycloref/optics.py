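"""Paraxial optics for deriving crystalline-lens features from routine biometry.

The crystalline lens cannot be measured directly in a routine (non-cycloplegic)
optometry visit, but its dioptric contribution can be inferred from quantities
that are measured: keratometry, axial length, anterior chamber depth, lens
thickness, and the autorefractor reading.  This module implements the SRK/T
intraocular-lens power formula and its two refinements (a retained-refraction
variant and a contact-lens-corrected variant) as proxies for lens power, then
inverts the Gullstrand thick-lens equation to recover the anterior lens surface
power ``Fa`` and its radius of curvature ``ra``.  It also provides the standard
power-vector conversion of sphero-cylindrical refractions.

All functions accept scalars or NumPy arrays.  On scalar input a violated
precondition raises :class:`ValueError`; on array input invalid entries become
NaN so that per-row failures can be carried as missing values downstream.

Units follow clinical convention: lengths in millimetres, powers in diopters,
angles in degrees at the interface.  Diopters are reciprocal metres, so axial
lengths are rescaled by 1000 inside the formulas where required.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "KERATOMETRIC_CONSTANT",
    "OpticalConstants",
    "OcularBiometry",
    "RefractionRecord",
    "LensDerivedFeatures",
    "corneal_radius",
    "corrected_axial_length",
    "iol_emmetropia",
    "iol_myopia",
    "contact_lens_power",
    "corrected_corneal_radius_cl",
    "iol_contact_lens",
    "anterior_surface_power",
    "anterior_radius",
    "power_vectors",
    "spherical_equivalent",
    "derive_lens_features",
]

#: Keratometric index constant: corneal radius r (mm) = 337.5 / K (D).
KERATOMETRIC_CONSTANT = 337.5


@dataclass(frozen=True)
class OpticalConstants:
    """Schematic-eye constants used throughout the lens-feature derivation.

    Parameters
    ----------
    n_aqueous
        Refractive index of aqueous and vitreous humour (1.336).
    delta_n
        Refractive-index difference used by the SRK/T formula (0.333).
    n_lens
        Refractive index of the crystalline lens (1.40).
    f_posterior
        Power of the posterior lens surface in the unaccommodated schematic
        eye of Bennett and Rabbetts, in diopters (9.26 D).
    vertex_distance
        Spectacle vertex distance in metres (0.012 m), used both by the
        contact-lens conversion and by the retained-refraction IOL variant.
    """

    n_aqueous: float = 1.336
    delta_n: float = 0.333
    n_lens: float = 1.40
    f_posterior: float = 9.26
    vertex_distance: float = 0.012

    def __post_init__(self) -> None:
        for name in ("n_aqueous", "delta_n", "n_lens", "f_posterior", "vertex_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"OpticalConstants.{name} must be strictly positive")
        if self.n_lens <= self.n_aqueous:
            raise ValueError("n_lens must exceed n_aqueous (ra must share the sign of Fa)")


DEFAULT_CONSTANTS = OpticalConstants()


@dataclass(frozen=True)
class OcularBiometry:
    """One eye's non-cycloplegic biometric measurements.

    Lengths in mm (CCT included), keratometry in diopters, IOP in mmHg.
    """

    axial_length: float
    central_corneal_thickness: float
    anterior_chamber_depth: float
    lens_thickness: float
    K1: float
    K2: float
    Km: float
    iop: float

    def __post_init__(self) -> None:
        al, cct = self.axial_length, self.central_corneal_thickness
        acd, lt = self.anterior_chamber_depth, self.lens_thickness
        if not 15 < al < 35:
            raise ValueError(f"axial length {al} mm outside (15, 35)")
        if not 0.3 < cct < 0.8:
            raise ValueError(f"central corneal thickness {cct} mm outside (0.3, 0.8)")
        if not 1.5 < acd < 5.5:
            raise ValueError(f"anterior chamber depth {acd} mm outside (1.5, 5.5)")
        if not 2.5 < lt < 6:
            raise ValueError(f"lens thickness {lt} mm outside (2.5, 6)")
        if not 35 < self.Km < 52:
            raise ValueError(f"mean keratometry {self.Km} D outside (35, 52)")
        if acd + lt + cct >= al:
            raise ValueError("anterior segment (CCT + ACD + LT) must be shorter than AL")


@dataclass(frozen=True)
class RefractionRecord:
    """Sphero-cylindrical refraction with derived SE and power vectors.

    Cylinder follows the minus convention (C <= 0); ``state`` flags whether the
    measurement was taken under cycloplegia.
    """

    sphere: float
    cylinder: float
    axis: float
    spherical_equivalent: float
    J0: float
    J45: float
    state: str = "non-cycloplegic"

    @classmethod
    def from_measurement(
        cls, sphere: float, cylinder: float, axis: float, state: str = "non-cycloplegic"
    ) -> "RefractionRecord":
        if state not in ("cycloplegic", "non-cycloplegic"):
            raise ValueError(f"unknown refraction state {state!r}")
        j0, j45 = power_vectors(cylinder, axis)
        return cls(
            sphere=float(sphere),
            cylinder=float(cylinder),
            axis=float(axis) % 180.0,
            spherical_equivalent=spherical_equivalent(sphere, cylinder),
            J0=float(j0),
            J45=float(j45),
            state=state,
        )


@dataclass(frozen=True)
class LensDerivedFeatures:
    """Lens-related quantities derived for one eye under one IOL variant."""

    variant: str  # "e" (emmetropia), "m" (retained refraction), "cl" (contact lens)
    lopt: float
    r: float
    iol: float
    fa: float
    ra: float
    fc: Optional[float] = None  # contact-lens variant only
    r_cl: Optional[float] = None  # contact-lens variant only


def _resolve(valid, value, message: str):
    """Return ``value`` masked by ``valid``; raise on invalid scalar input."""
    valid = np.asarray(valid)
    value = np.asarray(value, dtype=float)
    scalar = valid.ndim == 0 and value.ndim == 0
    if scalar:
        if not bool(valid):
            raise ValueError(message)
        return float(value)
    out = np.where(valid, value, np.nan)
    return out


def corneal_radius(km, constants: OpticalConstants = DEFAULT_CONSTANTS):
    """Mean corneal radius of curvature (mm) from mean keratometry (D)."""
    km = np.asarray(km, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = KERATOMETRIC_CONSTANT / km
    return _resolve(km > 0, r, "keratometry must be strictly positive")


def corrected_axial_length(al):
    """SRK/T retinal-thickness-corrected axial length LOPT (mm)."""
    al = np.asarray(al, dtype=float)
    return _resolve(al > 0, al + 0.65696 - 0.02029 * al, "axial length must be positive")


def iol_emmetropia(al, acd, r, constants: OpticalConstants = DEFAULT_CONSTANTS):
    """SRK/T IOL power (D) for an emmetropic target refraction.

    Uses the measured anterior chamber depth directly as the lens position in
    the denominator, which is what makes the result usable as a crystalline
    lens power proxy rather than a pseudophakic prediction.
    """
    al = np.asarray(al, dtype=float)
    acd = np.asarray(acd, dtype=float)
    r = np.asarray(r, dtype=float)
    na, dn = constants.n_aqueous, constants.delta_n
    lopt = al + 0.65696 - 0.02029 * al
    num = 1000.0 * na * (na * r - dn * lopt)
    den = (lopt - acd) * (na * r - dn * acd)
    with np.errstate(divide="ignore", invalid="ignore"):
        iol = num / den
    valid = (al > 0) & (lopt > acd) & (den != 0)
    return _resolve(valid, iol, "degenerate geometry: LOPT <= ACD or singular denominator")


def iol_myopia(al, acd, r, se, constants: OpticalConstants = DEFAULT_CONSTANTS):
    """SRK/T IOL power (D) retaining the eye's refractive error ``se``.

    ``se`` is the NON-cycloplegic spherical equivalent (S + C/2).  At se = 0
    this reduces algebraically to :func:`iol_emmetropia`.
    """
    al = np.asarray(al, dtype=float)
    acd = np.asarray(acd, dtype=float)
    r = np.asarray(r, dtype=float)
    se = np.asarray(se, dtype=float)
    na, dn = constants.n_aqueous, constants.delta_n
    vd_mm = 1000.0 * constants.vertex_distance
    lopt = al + 0.65696 - 0.02029 * al
    a = na * r - dn * lopt
    num = 1000.0 * na * (a - 0.001 * se * (vd_mm * a + lopt * r))
    den = (lopt - acd) * (na * r - dn * acd - 0.001 * se * (vd_mm * a + acd * r))
    with np.errstate(divide="ignore", invalid="ignore"):
        iol = num / den
    valid = (al > 0) & (lopt > acd) & (den != 0) & np.isfinite(se)
    return _resolve(valid, iol, "degenerate geometry: LOPT <= ACD or singular denominator")


def contact_lens_power(se, constants: OpticalConstants = DEFAULT_CONSTANTS):
    """Vertex-corrected contact-lens power (D) equivalent to spectacle ``se``."""
    se = np.asarray(se, dtype=float)
    den = 1.0 - constants.vertex_distance * se
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = se / den
    return _resolve(den != 0, fc, "spherical equivalent at the vertex singularity")


def corrected_corneal_radius_cl(km, fc, constants: OpticalConstants = DEFAULT_CONSTANTS):
    """Corneal radius (mm) after superimposing the contact-lens power on the cornea."""
    km = np.asarray(km, dtype=float)
    fc = np.asarray(fc, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_cl = KERATOMETRIC_CONSTANT / (km + fc)
    return _resolve(km + fc > 0, r_cl, "Km + Fc must be strictly positive")


def iol_contact_lens(al, acd, km, se, constants: OpticalConstants = DEFAULT_CONSTANTS):
    """SRK/T IOL power (D) with the refractive error folded into the cornea.

    Composes the contact-lens conversion, the corneal-radius correction and
    the emmetropic SRK/T formula; at se = 0 it equals :func:`iol_emmetropia`.
    """
    fc = contact_lens_power(se, constants)
    r_cl = corrected_corneal_radius_cl(km, fc, constants)
    return iol_emmetropia(al, acd, r_cl, constants)


def anterior_surface_power(f_total, lt, constants: OpticalConstants = DEFAULT_CONSTANTS):
    """Anterior lens surface power Fa (D) from total lens power and thickness.

    Inverts the Gullstrand thick-lens equation
    ``F_total = Fa + Fp - (LT/1000/n_lens) * Fa * Fp``
    for Fa, with the posterior surface power Fp fixed at its schematic-eye
    value.  LT enters in metres (diopters are reciprocal metres).
    """
    f_total = np.asarray(f_total, dtype=float)
    lt = np.asarray(lt, dtype=float)
    fp = constants.f_posterior
    den = 1.0 - (lt / 1000.0 / constants.n_lens) * fp
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = (f_total - fp) / den
    return _resolve((lt > 0) & (den != 0), fa, "degenerate lens: nonpositive LT or singular denominator")


def thick_lens_total_power(fa, fp, lt, constants: OpticalConstants = DEFAULT_CONSTANTS):
    """Gullstrand thick-lens total power (D) from the two surface powers."""
    fa = np.asarray(fa, dtype=float)
    fp = np.asarray(fp, dtype=float)
    lt = np.asarray(lt, dtype=float)
    total = fa + fp - (lt / 1000.0 / constants.n_lens) * fa * fp
    return _resolve(lt >= 0, total, "lens thickness must be nonnegative")


def anterior_radius(fa, constants: OpticalConstants = DEFAULT_CONSTANTS):
    """Anterior lens surface radius ra (mm) from its power Fa (D).

    ra = 1000 * (n_lens - n_aqueous) / Fa; with default constants ra = 64/Fa.
    The sign of ra follows the sign of Fa.
    """
    fa = np.asarray(fa, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ra = 1000.0 * (constants.n_lens - constants.n_aqueous) / fa
    return _resolve(fa != 0, ra, "anterior surface power must be nonzero")


def power_vectors(c, axis):
    """Power-vector components (J0, J45) of a cylinder C (D, <= 0) at ``axis`` degrees.

    J0 = -(C/2) cos 2a, J45 = -(C/2) sin 2a, so J0^2 + J45^2 = (C/2)^2.
    Axis values of 0 and 180 are identified (axis is reduced modulo 180).
    """
    c = np.asarray(c, dtype=float)
    if np.any(c > 1e-9):
        raise ValueError("cylinder must follow the minus convention (C <= 0)")
    axis = np.asarray(axis, dtype=float) % 180.0
    two_alpha = np.deg2rad(2.0 * axis)
    j0 = -c / 2.0 * np.cos(two_alpha)
    j45 = -c / 2.0 * np.sin(two_alpha)
    if j0.ndim == 0:
        return float(j0), float(j45)
    return j0, j45


def spherical_equivalent(s, c):
    """Spherical equivalent SE = S + C/2 (D)."""
    s = np.asarray(s, dtype=float)
    c = np.asarray(c, dtype=float)
    se = s + c / 2.0
    if se.ndim == 0:
        return float(se)
    return se


def derive_lens_features(
    bio: OcularBiometry,
    se: float,
    variant: str,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
) -> LensDerivedFeatures:
    """Compute the full lens-feature bundle for one eye under one IOL variant.

    ``variant`` is "e" (emmetropic), "m" (retained refraction) or "cl"
    (contact-lens corrected); ``se`` is the non-cycloplegic spherical
    equivalent and is ignored by the emmetropic variant.
    """
    r = corneal_radius(bio.Km, constants)
    lopt = corrected_axial_length(bio.axial_length)
    fc = r_cl = None
    if variant == "e":
        iol = iol_emmetropia(bio.axial_length, bio.anterior_chamber_depth, r, constants)
    elif variant == "m":
        iol = iol_myopia(bio.axial_length, bio.anterior_chamber_depth, r, se, constants)
    elif variant == "cl":
        fc = contact_lens_power(se, constants)
        r_cl = corrected_corneal_radius_cl(bio.Km, fc, constants)
        iol = iol_emmetropia(bio.axial_length, bio.anterior_chamber_depth, r_cl, constants)
    else:
        raise ValueError(f"unknown IOL variant {variant!r}; expected 'e', 'm' or 'cl'")
    fa = anterior_surface_power(iol, bio.lens_thickness, constants)
    ra = anterior_radius(fa, constants)
    return LensDerivedFeatures(
        variant=variant, lopt=lopt, r=r, iol=iol, fa=fa, ra=ra, fc=fc, r_cl=r_cl
    )


def constants_to_dict(constants: OpticalConstants) -> dict:
    """Serialize optical constants for pipeline configuration round-trips."""
    return dataclasses.asdict(constants)


def constants_from_dict(d: dict) -> OpticalConstants:
    return OpticalConstants(**d)
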