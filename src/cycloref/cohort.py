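"""Seeded synthetic cohorts of paediatric eyes for pipeline development and testing.

The generator emulates the statistical structure a cycloplegic-refraction
prediction study rests on: 153 children (306 eyes) aged 4-15 years, a
non-cycloplegic sphere distribution of about -1.53 +/- 2.17 D truncated to
(-7.50, +10.50) D, and a cycloplegic sphere shift of about +0.34 +/- 0.53 D
that is nonnegative (cycloplegia relaxes accommodative tonus, never adds
minus power) and decreases with age.

The tonus model is deliberately lens-mediated: part of the shift is driven by
a standardized lens-geometry factor (thicker lens, shallower chamber -> more
tonus), and the tonus in turn perturbs the measured (non-cycloplegic) ACD and
LT by the usual per-diopter accommodation coefficients.  Both mechanisms make
the shift partially recoverable from lens-related features but not from the
control feature set, which is the qualitative property the prediction
experiment tests.  Intercepts of all truncated distributions are solved
numerically so configured means are population means, not pre-truncation
parameters.

An AS-OCT-style accommodation-series generator produces per-eye anterior and
posterior lens surface radii on a stimulus grid, with curvature responses
lying exactly on configurable generating quadratics (zero noise) plus
Gaussian measurement noise.  Radii are stored as positive magnitudes and
curvature changes follow the magnitude-decrease convention (positive =
steepening).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, truncnorm

from . import optics

__all__ = [
    "BiometryParams",
    "CohortConfig",
    "AccommodationSeriesConfig",
    "generate_cohort",
    "inject_missingness",
    "generate_accommodation_series",
    "MISSABLE_COLUMNS",
]

#: Biometry columns eligible for missingness injection; identifiers,
#: demographics, refractions and the target are never blanked.
MISSABLE_COLUMNS = ["IOP", "AL", "CCT", "ACD", "LT", "K1", "K2", "Km"]


@dataclass(frozen=True)
class BiometryParams:
    """Means, SDs, age trends and couplings of the biometric variables.

    Lengths in mm, keratometry in D, IOP in mmHg; ``*_per_diopter`` terms are
    the accommodative response coefficients (mm of change per diopter of
    tonus).  ``al_per_diopter`` couples axial length to the cycloplegic
    refraction (about -0.35 mm per diopter of myopia, the usual axial
    ametropia conversion).
    """

    al_intercept: float = 22.0
    al_age_slope: float = 0.10
    al_per_diopter: float = -0.35
    al_sd: float = 0.45
    al_range: Tuple[float, float] = (19.0, 30.0)
    km_mean: float = 43.0
    km_sd: float = 1.4
    km_al_corr: float = -0.4
    km_range: Tuple[float, float] = (38.0, 48.0)
    cct_mean: float = 0.55
    cct_sd: float = 0.03
    cct_range: Tuple[float, float] = (0.42, 0.68)
    acd_intercept: float = 3.0
    acd_age_slope: float = 0.04
    acd_sd: float = 0.22
    acd_range: Tuple[float, float] = (2.0, 4.6)
    lt_intercept: float = 3.75
    lt_age_slope: float = -0.015
    lt_sd: float = 0.15
    lt_range: Tuple[float, float] = (2.9, 4.6)
    iop_mean: float = 16.0
    iop_sd: float = 2.5
    iop_range: Tuple[float, float] = (8.0, 28.0)
    acd_per_diopter: float = 0.047
    lt_per_diopter: float = 0.063
    astig_corneal_scale: float = 0.85
    astig_noise_sd: float = 0.2


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults encode the emulated cohort: 306 eyes (two per subject), ages
    4-15, non-cyclo sphere -1.53 +/- 2.17 D on (-7.5, +10.5), cycloplegic
    shift +0.34 +/- 0.53 D decreasing with age, cylinder -0.87 +/- 0.75 D.
    ``lens_share`` is the fraction of the non-age tonus variance carried by
    the lens-geometry factor; ``eye_corr`` the within-subject correlation of
    eye-level latent draws.
    """

    n_eyes: int = 306
    age_range: Tuple[float, float] = (4.0, 15.0)
    s_mean: float = -1.53
    s_sd: float = 2.17
    s_range: Tuple[float, float] = (-7.5, 10.5)
    ds_mean: float = 0.34
    ds_sd: float = 0.53
    ds_age_slope: float = -0.04
    lens_share: float = 0.5
    c_mean: float = -0.87
    c_sd: float = 0.75
    dc_mean: float = -0.03
    dc_sd: float = 0.30
    eye_corr: float = 0.8
    missing_rate: float = 0.0
    seed: int = 0
    biometry: BiometryParams = field(default_factory=BiometryParams)

    def __post_init__(self) -> None:
        if self.n_eyes <= 0 or self.n_eyes % 2:
            raise ValueError("n_eyes must be a positive even count (two eyes per subject)")
        for name in ("s_sd", "c_sd", "dc_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.ds_sd < 0:
            raise ValueError("ds_sd must be nonnegative")
        if self.ds_sd == 0 and self.ds_mean != 0:
            raise ValueError("a zero-spread tonus requires ds_mean == 0 (null cohort)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0 <= self.eye_corr <= 1:
            raise ValueError("eye_corr must lie in [0, 1]")
        if not 0 <= self.lens_share <= 1:
            raise ValueError("lens_share must lie in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        bio = d.pop("biometry", None)
        if bio is not None:
            bio = {k: tuple(v) if isinstance(v, list) else v for k, v in bio.items()}
            d["biometry"] = BiometryParams(**bio)
        for key in ("age_range", "s_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _paired_normal(rng: np.random.Generator, n_subjects: int, rho: float) -> np.ndarray:
    """Standard-normal draws of shape (n_subjects, 2) with within-pair correlation rho."""
    g = rng.standard_normal((n_subjects, 1))
    e = rng.standard_normal((n_subjects, 2))
    return np.sqrt(rho) * g + np.sqrt(1.0 - rho) * e


def _paired_truncated(
    rng: np.random.Generator,
    n_subjects: int,
    rho: float,
    loc: float,
    sd: float,
    low: float,
    high: float,
    max_iter: int = 200,
) -> np.ndarray:
    """Pairwise-correlated normals rejection-truncated to [low, high].

    Out-of-range cells redraw only their eye-level component, preserving the
    subject factor; after ``max_iter`` sweeps any stragglers (probability
    ~1e-6 per cohort) are clipped.
    """
    g = rng.standard_normal((n_subjects, 1))
    sqr, sqe = np.sqrt(rho), np.sqrt(1.0 - rho)

    def draw() -> np.ndarray:
        return loc + sd * (sqr * g + sqe * rng.standard_normal((n_subjects, 2)))

    x = draw()
    for _ in range(max_iter):
        bad = (x < low) | (x > high)
        if not bad.any():
            return x
        x = np.where(bad, draw(), x)
    return np.clip(x, low, high)


def _truncnorm_mean(loc: float, sd: float, low: float, high: float) -> float:
    """Mean of N(loc, sd) truncated to [low, high]."""
    a = (low - loc) / sd
    b = (high - loc) / sd
    return float(truncnorm.mean(a, b, loc=loc, scale=sd))


def _solve_truncnorm_loc(target_mean: float, sd: float, low: float, high: float) -> float:
    """Location parameter whose [low, high]-truncated mean equals ``target_mean``.

    The truncated mean is increasing in the location and brackets the target
    within [low, high] for any target strictly inside the support.
    """
    if not low < target_mean < high:
        raise ValueError("target mean must lie strictly inside the truncation range")
    return brentq(
        lambda loc: _truncnorm_mean(loc, sd, low, high) - target_mean,
        low,
        high,
        xtol=1e-10,
    )


def _solve_tonus_intercept(cfg: CohortConfig) -> Tuple[float, float, float]:
    """Intercept, lens loading and noise SD of the latent tonus model.

    The tonus is delta = max(0, mu0 + slope*(age - mid) + lam*L + sig*eps)
    with L, eps standard normal; mu0 is solved so that the population mean of
    delta over the uniform age distribution equals ``ds_mean`` exactly.
    """
    lo, hi = cfg.age_range
    mid = 0.5 * (lo + hi)
    var_age = cfg.ds_age_slope**2 * (hi - lo) ** 2 / 12.0
    resid_var = max(cfg.ds_sd**2 - var_age, 0.0)
    lam = float(np.sqrt(cfg.lens_share * resid_var))
    sig = float(np.sqrt((1.0 - cfg.lens_share) * resid_var))
    s_w = float(np.sqrt(resid_var))
    ages = np.linspace(lo, hi, 201)

    def mean_tonus(mu0: float) -> float:
        m = mu0 + cfg.ds_age_slope * (ages - mid)
        if s_w == 0:
            return float(np.maximum(m, 0.0).mean())
        z = m / s_w
        return float((m * norm.cdf(z) + s_w * norm.pdf(z)).mean())

    mu0 = brentq(lambda m: mean_tonus(m) - cfg.ds_mean, -10.0, 10.0, xtol=1e-10)
    return mu0, lam, sig


def generate_cohort(config: CohortConfig = CohortConfig(), seed: Optional[int] = None) -> pd.DataFrame:
    """Generate a per-eye cohort table; a pure function of (config, seed).

    Returns one row per eye with demographic, refraction (non-cycloplegic S,
    C, axis and cycloplegic S_cyclo, C_cyclo) and biometric columns, plus a
    ``lens_power_latent`` diagnostic (the retained-refraction IOL power at the
    cycloplegic refraction, i.e. the lens power that makes the refraction
    optically consistent with AL and Km).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    bp = config.biometry
    n_subj = config.n_eyes // 2
    rho = config.eye_corr

    lo_age, hi_age = config.age_range
    mid_age = 0.5 * (lo_age + hi_age)
    age = np.repeat(rng.uniform(lo_age, hi_age, n_subj)[:, None], 2, axis=1)
    gender = np.repeat(rng.integers(0, 2, n_subj)[:, None], 2, axis=1).astype(float)

    # non-cycloplegic sphere, truncated to the study range with mean-preserving location
    s_loc = _solve_truncnorm_loc(config.s_mean, config.s_sd, *config.s_range)
    s = _paired_truncated(rng, n_subj, rho, s_loc, config.s_sd, *config.s_range)

    # baseline (cycloplegic-state) anterior segment, age-trended
    acd0_mean = bp.acd_intercept + bp.acd_age_slope * age
    acd0 = np.clip(acd0_mean + bp.acd_sd * _paired_normal(rng, n_subj, rho), *bp.acd_range)
    lt0_mean = bp.lt_intercept + bp.lt_age_slope * age
    lt0 = np.clip(lt0_mean + bp.lt_sd * _paired_normal(rng, n_subj, rho), *bp.lt_range)
    z_acd = (acd0 - acd0_mean) / bp.acd_sd
    z_lt = (lt0 - lt0_mean) / bp.lt_sd

    # accommodative tonus: age trend + lens-geometry factor + noise, floored at 0
    if config.ds_sd == 0 and config.ds_mean == 0:
        delta = np.zeros_like(s)
    else:
        mu0, lam, sig = _solve_tonus_intercept(config)
        lens_factor = (z_lt - z_acd) / np.sqrt(2.0)
        eps = _paired_normal(rng, n_subj, rho)
        latent = mu0 + config.ds_age_slope * (age - mid_age) + lam * lens_factor + sig * eps
        delta = np.maximum(latent, 0.0)
    s_cyclo = s + delta

    # axial length follows age and the cycloplegic (true) refraction
    al_mean = bp.al_intercept + bp.al_age_slope * age + bp.al_per_diopter * s_cyclo
    al = np.clip(al_mean + bp.al_sd * _paired_normal(rng, n_subj, rho), *bp.al_range)
    z_al = (al - al_mean) / bp.al_sd

    km_noise = _paired_normal(rng, n_subj, rho)
    km = np.clip(
        bp.km_mean
        + bp.km_sd * (bp.km_al_corr * z_al + np.sqrt(1 - bp.km_al_corr**2) * km_noise),
        *bp.km_range,
    )
    cct = np.clip(bp.cct_mean + bp.cct_sd * _paired_normal(rng, n_subj, rho), *bp.cct_range)
    iop = np.clip(bp.iop_mean + bp.iop_sd * _paired_normal(rng, n_subj, rho), *bp.iop_range)

    # measured (non-cycloplegic) anterior segment carries the tonus response
    acd = acd0 - bp.acd_per_diopter * delta
    lt = lt0 + bp.lt_per_diopter * delta

    # cylinder (minus convention) and its small cycloplegic shift
    c_loc = _solve_truncnorm_loc(config.c_mean, config.c_sd, -6.0, 0.0)
    c = _paired_truncated(rng, n_subj, rho, c_loc, config.c_sd, -6.0, 0.0)
    axis = rng.uniform(0.0, 180.0, (n_subj, 2))
    c_cyclo = np.minimum(c + config.dc_mean + config.dc_sd * _paired_normal(rng, n_subj, rho), 0.0)

    # corneal astigmatism consistent with the refractive cylinder
    astig = np.clip(
        -(bp.astig_corneal_scale * c) + bp.astig_noise_sd * _paired_normal(rng, n_subj, rho),
        0.05,
        6.0,
    )
    k1 = km - astig / 2.0
    k2 = km + astig / 2.0

    se_cyclo = s_cyclo + c_cyclo / 2.0
    r = optics.corneal_radius(km.ravel())
    lens_power = optics.iol_myopia(al.ravel(), acd0.ravel(), r, se_cyclo.ravel())

    subject_id = np.repeat([f"S{i:04d}" for i in range(n_subj)], 2)
    eye = np.tile(["OD", "OS"], n_subj)
    df = pd.DataFrame(
        {
            "subject_id": subject_id,
            "eye_id": [f"{s_}_{e}" for s_, e in zip(subject_id, eye)],
            "eye": eye,
            "gender": gender.ravel(),
            "age": age.ravel(),
            "S": s.ravel(),
            "C": c.ravel(),
            "axis": axis.ravel(),
            "S_cyclo": s_cyclo.ravel(),
            "C_cyclo": c_cyclo.ravel(),
            "IOP": iop.ravel(),
            "AL": al.ravel(),
            "CCT": cct.ravel(),
            "ACD": acd.ravel(),
            "LT": lt.ravel(),
            "K1": k1.ravel(),
            "K2": k2.ravel(),
            "Km": km.ravel(),
            "lens_power_latent": np.asarray(lens_power),
        }
    )
    if config.missing_rate > 0:
        df = inject_missingness(df, config.missing_rate, int(rng.integers(2**31 - 1)))
    return df


def inject_missingness(records: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Blank each missable biometry cell independently with probability ``rate``.

    Identifiers, demographics, refraction columns and the target are never
    blanked.  Returns a copy; rate 0 returns an identical table.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    out = records.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    cols = [c for c in MISSABLE_COLUMNS if c in out.columns]
    mask = rng.random((len(out), len(cols))) < rate
    for j, col in enumerate(cols):
        vals = out[col].to_numpy(dtype=float)
        vals[mask[:, j]] = np.nan
        out[col] = vals
    return out


@dataclass(frozen=True)
class AccommodationSeriesConfig:
    """Configuration of the AS-OCT-style accommodation series generator.

    ``quad_acr``/``quad_pcr`` are generating quadratic coefficients (a, b, c)
    mapping the curvature-radius decrease (mm, positive = steepening) to the
    accommodation stimulus (D).  Defaults are the reference anterior/posterior
    response curves in the magnitude-decrease convention.
    """

    n_eyes: int = 16
    stimulus_levels: Sequence[float] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    acr_noise_sd: float = 0.15
    pcr_noise_sd: float = 0.05
    quad_acr: Tuple[float, float, float] = (0.01, 1.21, -0.02)
    quad_pcr: Tuple[float, float, float] = (-2.40, 9.30, -0.60)
    acr0_range: Tuple[float, float] = (10.0, 12.0)
    pcr0_range: Tuple[float, float] = (5.5, 7.0)
    lt0_mean: float = 3.6
    lt0_sd: float = 0.15
    lt_per_diopter: float = 0.063
    lt_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        levels = np.asarray(self.stimulus_levels, dtype=float)
        if levels.size == 0 or np.any(levels < 0) or np.any(np.diff(levels) <= 0):
            raise ValueError("stimulus_levels must be nonnegative and strictly increasing")
        if self.acr_noise_sd < 0 or self.pcr_noise_sd < 0 or self.lt_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.n_eyes <= 0:
            raise ValueError("n_eyes must be positive")


def _quad_root_track(coeffs: Tuple[float, float, float], stimuli: np.ndarray) -> np.ndarray:
    """Radius-decrease values solving a*d^2 + b*d + c = stimulus along the branch
    continuous with d = 0 at zero stimulus.  Raises if a stimulus exceeds the
    range of the generating quadratic (no real root)."""
    a, b, c = coeffs
    deltas = np.empty_like(stimuli, dtype=float)
    prev = 0.0
    for i, y in enumerate(stimuli):
        if y == 0:
            deltas[i] = 0.0  # baseline anchored by construction
            continue
        if a == 0:
            d = (y - c) / b
        else:
            disc = b * b - 4.0 * a * (c - y)
            if disc < 0:
                raise ValueError(
                    f"stimulus {y} D is outside the range of the generating quadratic"
                )
            sq = np.sqrt(disc)
            r1 = (-b + sq) / (2.0 * a)
            r2 = (-b - sq) / (2.0 * a)
            d = r1 if abs(r1 - prev) <= abs(r2 - prev) else r2
        deltas[i] = d
        prev = d
    return deltas


def generate_accommodation_series(
    config: AccommodationSeriesConfig = AccommodationSeriesConfig(),
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Generate per-eye accommodation series (stimulus, ACR, PCR, LT).

    At zero stimulus the radii equal their unaccommodated baselines exactly
    (zero curvature change by construction); at positive stimuli the radius
    decreases lie on the generating quadratics plus Gaussian noise.  Radii are
    positive magnitudes that shrink (surfaces steepen) as stimulus increases.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    stimuli = np.asarray(config.stimulus_levels, dtype=float)
    d_acr = _quad_root_track(config.quad_acr, stimuli)
    d_pcr = _quad_root_track(config.quad_pcr, stimuli)

    rows = []
    for i in range(config.n_eyes):
        subject = f"A{i // 2:03d}"
        eye_id = f"{subject}_{'OD' if i % 2 == 0 else 'OS'}"
        acr0 = rng.uniform(*config.acr0_range)
        pcr0 = rng.uniform(*config.pcr0_range)
        lt0 = rng.normal(config.lt0_mean, config.lt0_sd)
        nonzero = (stimuli > 0).astype(float)  # baseline stays exactly at the unaccommodated radii
        acr_noise = rng.normal(0.0, config.acr_noise_sd, stimuli.size) * nonzero
        pcr_noise = rng.normal(0.0, config.pcr_noise_sd, stimuli.size) * nonzero
        lt_noise = rng.normal(0.0, config.lt_noise_sd, stimuli.size) * nonzero
        for j, d in enumerate(stimuli):
            rows.append(
                {
                    "subject_id": subject,
                    "eye_id": eye_id,
                    "stimulus_D": d,
                    "ACR": acr0 - d_acr[j] - acr_noise[j],
                    "PCR": pcr0 - d_pcr[j] - pcr_noise[j],
                    "LT": lt0 + config.lt_per_diopter * d + lt_noise[j],
                }
            )
    return pd.DataFrame(rows)
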