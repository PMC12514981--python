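"""Accommodation optics: curvature-response fits and the image principal plane.

Two physical analyses support the use of anterior-lens-surface features in
cycloplegic-refraction prediction:

1. Quadratic fits of accommodation stimulus against the change in anterior
   (ACR) and posterior (PCR) lens surface curvature radius.  The linear
   coefficient at zero curvature change gives the small-accommodation slope
   in D/mm; its reciprocal is the radius change per diopter.  The anterior
   surface moves almost an order of magnitude more per diopter than the
   posterior surface, which is why a cycloplegic shift is dominated by ACR.

2. The position of the lens's image principal plane.  For a thick lens with
   surface powers Fa (anterior) and Fp (posterior), thickness LT and index
   n_lens immersed in media of index n', the distance from the back vertex to
   the image principal point is p' = -(n'/F) * Fa * (LT/n_lens) (mm, negative
   = toward the cornea), with F the Gullstrand total power.  Re-referencing
   to the lens centre through the posterior sagitta gives
   OP' = [rp - sqrt(rp^2 - (LT/2)^2)] + p'.  OP' falls as Fa rises and rises
   as Fp rises: steepening the anterior surface is the displacement-efficient
   (least-effort) accommodation mechanism.

Curvature changes use the magnitude-decrease convention throughout: positive
delta = the surface steepened relative to the unaccommodated baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .optics import DEFAULT_CONSTANTS, OpticalConstants

__all__ = [
    "QuadraticFit",
    "PrincipalPlaneInputs",
    "delta_radii",
    "fit_quadratic",
    "slope_at_zero",
    "mm_per_diopter_small_acc",
    "mm_per_diopter_full_range",
    "lens_power_from_asoct",
    "principal_plane_offset",
    "op_prime_surface",
]


@dataclass(frozen=True)
class QuadraticFit:
    """Least-squares quadratic AccD = a*delta^2 + b*delta + c for one surface.

    ``r2`` is NaN when the response has no variance (degenerate fit, flagged
    by ``degenerate``).
    """

    a: float
    b: float
    c: float
    r2: float
    surface: Optional[str] = None
    degenerate: bool = False


@dataclass(frozen=True)
class PrincipalPlaneInputs:
    """Inputs of the image-principal-plane offset for a biconvex crystalline lens."""

    fa: float  # anterior surface power, D
    fp: float  # posterior surface power, D
    lt: float  # lens thickness, mm
    rp: float  # posterior surface radius magnitude, mm
    constants: OpticalConstants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        if self.rp < self.lt / 2.0:
            raise ValueError("posterior radius must be at least LT/2 (real sagitta)")


def delta_radii(series: pd.DataFrame) -> pd.DataFrame:
    """Per-eye curvature-radius decreases relative to the zero-stimulus baseline.

    ``series`` needs columns eye_id, stimulus_D, ACR, PCR; every eye must
    contain a zero-stimulus row, which is the only admissible reference.
    Returns eye_id, stimulus_D, delta_ACR, delta_PCR with positive values
    meaning the surface steepened (radius magnitude decreased).
    """
    required = {"eye_id", "stimulus_D", "ACR", "PCR"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"series is missing columns: {sorted(missing)}")
    frames = []
    for eye, grp in series.groupby("eye_id", sort=False):
        base = grp[grp["stimulus_D"] == 0]
        if base.empty:
            raise ValueError(f"eye {eye!r} has no zero-stimulus baseline row")
        acr0 = float(base["ACR"].iloc[0])
        pcr0 = float(base["PCR"].iloc[0])
        frames.append(
            pd.DataFrame(
                {
                    "eye_id": eye,
                    "stimulus_D": grp["stimulus_D"].to_numpy(dtype=float),
                    "delta_ACR": acr0 - grp["ACR"].to_numpy(dtype=float),
                    "delta_PCR": pcr0 - grp["PCR"].to_numpy(dtype=float),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def fit_quadratic(deltas, stimuli, surface: Optional[str] = None) -> QuadraticFit:
    """Least-squares quadratic of accommodation stimulus on curvature change.

    Requires at least three distinct delta values; the all-zero design (no
    accommodation at all) returns the zero polynomial flagged degenerate.
    """
    deltas = np.asarray(deltas, dtype=float)
    stimuli = np.asarray(stimuli, dtype=float)
    if deltas.shape != stimuli.shape:
        raise ValueError("deltas and stimuli must have the same length")
    distinct = np.unique(deltas)
    if distinct.size < 3:
        if np.all(deltas == 0) and np.all(stimuli == 0):
            return QuadraticFit(0.0, 0.0, 0.0, float("nan"), surface, degenerate=True)
        raise ValueError("need at least three distinct curvature-change values")
    a, b, c = np.polyfit(deltas, stimuli, 2)
    pred = np.polyval([a, b, c], deltas)
    ss_res = float(np.sum((stimuli - pred) ** 2))
    ss_tot = float(np.sum((stimuli - stimuli.mean()) ** 2))
    if ss_tot == 0:
        return QuadraticFit(float(a), float(b), float(c), float("nan"), surface, degenerate=True)
    return QuadraticFit(float(a), float(b), float(c), 1.0 - ss_res / ss_tot, surface)


def slope_at_zero(fit: QuadraticFit) -> float:
    """|dAccD/d(delta)| at zero curvature change, i.e. |b| (D/mm)."""
    return abs(fit.b)


def mm_per_diopter_small_acc(fit: QuadraticFit) -> float:
    """Radius change per diopter at small accommodation: 1/|b| (mm/D)."""
    if fit.b == 0:
        raise ValueError("zero slope at the origin: mm-per-diopter undefined")
    return 1.0 / abs(fit.b)


def mm_per_diopter_full_range(fit: QuadraticFit, max_stimulus: float) -> float:
    """Mean radius change per diopter over [0, max_stimulus] (mm/D).

    Inverts the fitted quadratic along the branch through the origin-side
    root and averages delta/AccD over the range; differs from the
    small-accommodation reciprocal when curvature matters.
    """
    if max_stimulus <= 0:
        raise ValueError("max_stimulus must be positive")
    a, b, c = fit.a, fit.b, fit.c
    stimuli = np.linspace(0.25, max_stimulus, 48)
    if a == 0:
        deltas = (stimuli - c) / b
    else:
        disc = b * b - 4.0 * a * (c - stimuli)
        if np.any(disc < 0):
            raise ValueError("stimulus range exceeds the fitted quadratic")
        sq = np.sqrt(disc)
        r1 = (-b + sq) / (2.0 * a)
        r2 = (-b - sq) / (2.0 * a)
        deltas = np.where(np.abs(r1) <= np.abs(r2), r1, r2)
    return float(np.mean(np.abs(deltas) / stimuli))


def lens_power_from_asoct(
    acr, pcr, lt, constants: OpticalConstants = DEFAULT_CONSTANTS
):
    """Total crystalline-lens power (D) from AS-OCT geometry.

    Surface powers Fa = 1000(n_lens - n_aqueous)/ACR and
    Fp = 1000(n_lens - n_aqueous)/PCR (biconvex lens, radii as positive
    magnitudes) combined through the Gullstrand thick-lens equation.
    """
    acr = np.asarray(acr, dtype=float)
    pcr = np.asarray(pcr, dtype=float)
    lt = np.asarray(lt, dtype=float)
    if np.any(acr <= 0) or np.any(pcr <= 0) or np.any(lt <= 0):
        raise ValueError("radii and lens thickness must be positive magnitudes")
    dn = 1000.0 * (constants.n_lens - constants.n_aqueous)
    fa = dn / acr
    fp = dn / pcr
    total = fa + fp - (lt / 1000.0 / constants.n_lens) * fa * fp
    if total.ndim == 0:
        return float(total)
    return total


def principal_plane_offset(
    fa, fp, lt, rp, constants: OpticalConstants = DEFAULT_CONSTANTS
):
    """Signed offset OP' (mm) of the image principal plane from the lens centre.

    Negative values lie toward the cornea.  Accepts scalars or broadcastable
    arrays; raises on an imaginary posterior sagitta (rp < LT/2) or zero total
    power.
    """
    fa = np.asarray(fa, dtype=float)
    fp = np.asarray(fp, dtype=float)
    lt = np.asarray(lt, dtype=float)
    rp = np.asarray(rp, dtype=float)
    if np.any(rp < lt / 2.0):
        raise ValueError("posterior radius must be at least LT/2 (real sagitta)")
    total = fa + fp - (lt / 1000.0 / constants.n_lens) * fa * fp
    if np.any(total == 0):
        raise ValueError("zero total lens power: principal plane undefined")
    p_prime = -(constants.n_aqueous / total) * fa * lt / constants.n_lens
    sagitta = rp - np.sqrt(rp**2 - (lt / 2.0) ** 2)
    out = sagitta + p_prime
    if out.ndim == 0:
        return float(out)
    return out


def offset_from_inputs(inp: PrincipalPlaneInputs) -> float:
    """Principal-plane offset for a :class:`PrincipalPlaneInputs` record."""
    return principal_plane_offset(inp.fa, inp.fp, inp.lt, inp.rp, inp.constants)


def op_prime_surface(
    fa_grid, fp_grid, lt, rp, constants: OpticalConstants = DEFAULT_CONSTANTS
) -> np.ndarray:
    """OP' on the Cartesian grid fp_grid x fa_grid (rows: Fp, columns: Fa).

    Suitable for heat-map rendering of the principal-plane landscape; rows
    are monotone decreasing in Fa, columns monotone increasing in Fp.
    """
    fa_grid = np.atleast_1d(np.asarray(fa_grid, dtype=float))
    fp_grid = np.atleast_1d(np.asarray(fp_grid, dtype=float))
    if fa_grid.size == 0 or fp_grid.size == 0:
        raise ValueError("power grids must be nonempty")
    fa, fp = np.meshgrid(fa_grid, fp_grid)
    return principal_plane_offset(fa, fp, lt, rp, constants)
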