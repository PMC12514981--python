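"""Assembly of per-eye feature tables for the four prediction models.

One control table (routine demographic, refractive and biometric features)
and three experimental tables that extend it with lens-related features
computed from the emmetropic, retained-refraction and contact-lens-corrected
IOL variants.  Column names use ASCII aliases (``AL_over_CR`` rather than
``AL/CR``); lens-derived columns carry the variant suffix (``IOL_cl``,
``Fa_cl``, ``ra_cl``, ...).

Rows whose derived values cannot be computed (missing raw cells, degenerate
geometry) carry NaN rather than being dropped, so that downstream imputation
sees the full cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from . import optics
from .optics import DEFAULT_CONSTANTS, OpticalConstants

__all__ = [
    "GROUPS",
    "CONTROL_COLUMNS",
    "TARGET_COLUMN",
    "ID_COLUMNS",
    "FeatureTable",
    "feature_columns",
    "lens_columns",
    "derive_vcd",
    "build_features",
]

GROUPS = ("control", "IOLe", "IOLm", "IOLcl")
_VARIANT = {"IOLe": "e", "IOLm": "m", "IOLcl": "cl"}

CONTROL_COLUMNS = [
    "gender",
    "age",
    "S",
    "IOP",
    "AL",
    "CCT",
    "IOP_over_CCT",
    "AL_over_CCT",
    "K1",
    "K2",
    "Km",
    "r",
    "AL_over_CR",
    "VCD",
]

TARGET_COLUMN = "S_cyclo"
ID_COLUMNS = ["eye_id", "subject_id"]

#: Raw input columns every group needs (VCD requires ACD and LT even for control).
RAW_COLUMNS = [
    "gender",
    "age",
    "S",
    "C",
    "IOP",
    "AL",
    "CCT",
    "ACD",
    "LT",
    "K1",
    "K2",
    "Km",
]


def lens_columns(group: str) -> List[str]:
    """Lens-related columns added by an experimental group (empty for control)."""
    if group == "control":
        return []
    if group not in _VARIANT:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    v = _VARIANT[group]
    return [
        "ACD",
        "LT",
        f"IOL_{v}",
        f"Fa_{v}",
        "AL_over_ACD",
        "AL_over_LT",
        "AL_over_VCD",
        f"ra_{v}",
        f"LT_over_ra_{v}",
        f"ACD_over_ra_{v}",
    ]


def feature_columns(group: str) -> List[str]:
    """Exact feature column list for a model group."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    return CONTROL_COLUMNS + lens_columns(group)


@dataclass
class FeatureTable:
    """A per-eye feature matrix for one model group.

    ``data`` holds identifier columns, the feature columns, the age column
    (always a feature) and, when available, the cycloplegic-sphere target.
    """

    group: str
    data: pd.DataFrame
    feature_names: List[str] = field(default_factory=list)
    target: Optional[str] = None

    def features(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    def target_values(self) -> np.ndarray:
        if self.target is None:
            raise ValueError("feature table has no target column")
        return self.data[self.target].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def derive_vcd(al, cct, acd, lt):
    """Vitreous chamber depth (mm) as the residual axial segment AL - CCT - ACD - LT."""
    al = np.asarray(al, dtype=float)
    vcd = al - np.asarray(cct, float) - np.asarray(acd, float) - np.asarray(lt, float)
    valid = vcd > 0
    if vcd.ndim == 0:
        if not bool(valid) and np.isfinite(vcd):
            raise ValueError("inconsistent biometry: AL must exceed CCT + ACD + LT")
        return float(vcd)
    return np.where(valid | ~np.isfinite(vcd), vcd, np.nan)


def _safe_ratio(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    return np.where(den != 0, out, np.nan)


def build_features(
    records: pd.DataFrame,
    group: str,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
    cct_unit: str = "mm",
) -> FeatureTable:
    """Build the feature table for one model group from raw per-eye records.

    Parameters
    ----------
    records
        One row per eye with at least the columns in :data:`RAW_COLUMNS`;
        identifier columns and a ``S_cyclo`` target are carried through when
        present.  ``gender`` must be encoded 0 (male) / 1 (female).
    group
        "control", "IOLe", "IOLm" or "IOLcl".
    cct_unit
        "mm" (default) or "um" when central corneal thickness was recorded in
        micrometres.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    missing = [c for c in RAW_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records are missing required columns: {missing}")
    if cct_unit not in ("mm", "um"):
        raise ValueError("cct_unit must be 'mm' or 'um'")

    gender = records["gender"].to_numpy(dtype=float)
    observed = gender[np.isfinite(gender)]
    if not np.all(np.isin(observed, (0.0, 1.0))):
        raise ValueError("gender must be encoded 0 (male) / 1 (female)")

    cct = records["CCT"].to_numpy(dtype=float)
    if cct_unit == "um":
        cct = cct / 1000.0
    al = records["AL"].to_numpy(dtype=float)
    acd = records["ACD"].to_numpy(dtype=float)
    lt = records["LT"].to_numpy(dtype=float)
    km = records["Km"].to_numpy(dtype=float)
    s = records["S"].to_numpy(dtype=float)
    c = records["C"].to_numpy(dtype=float)

    out = pd.DataFrame(index=records.index)
    for col in ID_COLUMNS:
        if col in records.columns:
            out[col] = records[col]

    r = optics.corneal_radius(km, constants)
    vcd = derive_vcd(al, cct, acd, lt)

    out["gender"] = gender
    out["age"] = records["age"].to_numpy(dtype=float)
    out["S"] = s
    out["IOP"] = records["IOP"].to_numpy(dtype=float)
    out["AL"] = al
    out["CCT"] = cct
    out["IOP_over_CCT"] = _safe_ratio(out["IOP"].to_numpy(), cct)
    out["AL_over_CCT"] = _safe_ratio(al, cct)
    out["K1"] = records["K1"].to_numpy(dtype=float)
    out["K2"] = records["K2"].to_numpy(dtype=float)
    out["Km"] = km
    out["r"] = r
    out["AL_over_CR"] = _safe_ratio(al, r)
    out["VCD"] = vcd

    if group != "control":
        v = _VARIANT[group]
        se = optics.spherical_equivalent(s, c)
        if v == "e":
            iol = optics.iol_emmetropia(al, acd, r, constants)
        elif v == "m":
            iol = optics.iol_myopia(al, acd, r, se, constants)
        else:
            iol = optics.iol_contact_lens(al, acd, km, se, constants)
        fa = optics.anterior_surface_power(iol, lt, constants)
        ra = optics.anterior_radius(fa, constants)
        out["ACD"] = acd
        out["LT"] = lt
        out[f"IOL_{v}"] = iol
        out[f"Fa_{v}"] = fa
        out["AL_over_ACD"] = _safe_ratio(al, acd)
        out["AL_over_LT"] = _safe_ratio(al, lt)
        out["AL_over_VCD"] = _safe_ratio(al, vcd)
        out[f"ra_{v}"] = ra
        out[f"LT_over_ra_{v}"] = _safe_ratio(lt, ra)
        out[f"ACD_over_ra_{v}"] = _safe_ratio(acd, ra)

    target = None
    if TARGET_COLUMN in records.columns:
        out[TARGET_COLUMN] = records[TARGET_COLUMN].to_numpy(dtype=float)
        target = TARGET_COLUMN

    names = feature_columns(group)
    # non-finite derived values become explicit missing markers, rows are kept
    for colname in names:
        vals = out[colname].to_numpy(dtype=float)
        out[colname] = np.where(np.isfinite(vals), vals, np.nan)
    return FeatureTable(group=group, data=out, feature_names=names, target=target)
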