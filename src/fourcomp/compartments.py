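"""Deterministic four-compartment (4C) body-composition arithmetic.

The molecular 4C model partitions body weight (BW, kg) into fat mass (FM),
total body water (TBW), mineral and protein.  Fat mass is obtained from body
volume (BV, L, by densitometry), TBW (by dilution), bone mineral (Mo, kg,
from DXA bone mineral content) and BW by solving the two-equation system

    BW = FM + TBW + Mo + Ms + P
    BV = FM/d_fat + TBW/d_water + Mo/d_mo + Ms/d_ms + P/d_protein

for FM, after substituting the soft-tissue mineral model ``Ms = 0.0129*TBW``.
The linear coefficients are therefore *derived* from the component densities
rather than hard-coded, and cross-checked against the conventionally printed
rounded form (2.748*BV - 0.699*TBW + 1.129*Mo - 2.051*BW) in the test suite.

Masses are carried in kg, volumes in L and densities in g/cc; kg/L and g/cc
are numerically identical so no conversion factors appear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MS_PER_TBW",
    "MO_PER_BMC",
    "ComponentDensities",
    "Fm4cCoefficients",
    "MeasurementRecord",
    "Composition4C",
    "NonPhysiologicalResultWarning",
    "fm_coefficients",
    "soft_tissue_mineral",
    "bone_mineral_from_bmc",
    "total_mineral",
    "fm_4c",
    "percent_fm",
    "decompose_ffm",
    "ffm_density",
    "body_volume_from_components",
    "read_records",
    "write_records",
    "records_to_frame",
    "PHASES",
    "RECORD_COLUMNS",
    "REGIONAL_COLUMNS",
]

#: Soft-tissue mineral as a fraction of total body water.
MS_PER_TBW = 0.0129

#: Ashed bone mineral content -> total bone mineral conversion factor.
MO_PER_BMC = 1.0436

PHASES = ("stability", "precompetition")

RECORD_COLUMNS = [
    "subject_id",
    "phase",
    "bw_kg",
    "bv_l",
    "tbw_kg",
    "bmc_kg",
    "dxa_fm_kg",
    "dxa_ffm_kg",
]

REGIONAL_COLUMNS = [
    "trunk_fm_kg",
    "trunk_lst_kg",
    "arms_fm_kg",
    "arms_lst_kg",
    "legs_fm_kg",
    "legs_lst_kg",
]


class NonPhysiologicalResultWarning(UserWarning):
    """Raised (as a warning) when a computed quantity leaves the physiological range."""


@dataclass(frozen=True)
class ComponentDensities:
    """Densities of the molecular components, g/cc.

    Water, bone mineral, soft-tissue mineral and protein default to the
    reference values 0.9937, 2.982, 3.317 and 1.34 g/cc; fat defaults to the
    standard 0.9007 g/cc.
    """

    water: float = 0.9937
    mo: float = 2.982
    ms: float = 3.317
    protein: float = 1.34
    fat: float = 0.9007

    def __post_init__(self) -> None:
        for name in ("water", "mo", "ms", "protein", "fat"):
            if getattr(self, name) <= 0:
                raise ValueError(f"density {name!r} must be positive")


@dataclass(frozen=True)
class Fm4cCoefficients:
    """Linear coefficients of the 4C fat-mass model FM = a*BV + b*TBW + c*Mo + d*BW."""

    bv: float
    tbw: float
    mo: float
    bw: float

    def as_array(self) -> np.ndarray:
        return np.array([self.bv, self.tbw, self.mo, self.bw])


def fm_coefficients(
    densities: ComponentDensities | None = None,
    ms_per_tbw: float = MS_PER_TBW,
) -> Fm4cCoefficients:
    """Derive the 4C fat-mass coefficients from the component densities.

    Solving the mass/volume system for FM and folding in Ms = ms_per_tbw*TBW
    gives a linear form in (BV, TBW, Mo, BW).  With the default densities the
    coefficients round to (2.747, -0.699, 1.129, -2.050).
    """
    d = densities or ComponentDensities()
    k = 1.0 / (1.0 / d.fat - 1.0 / d.protein)
    return Fm4cCoefficients(
        bv=k,
        tbw=-k * ((1.0 / d.water - 1.0 / d.protein)
                  + ms_per_tbw * (1.0 / d.ms - 1.0 / d.protein)),
        mo=-k * (1.0 / d.mo - 1.0 / d.protein),
        bw=-k / d.protein,
    )


def soft_tissue_mineral(tbw):
    """Soft-tissue mineral Ms (kg) from total body water (kg): Ms = 0.0129*TBW."""
    tbw = np.asarray(tbw, dtype=float)
    if np.any(tbw < 0):
        raise ValueError("tbw must be non-negative")
    out = MS_PER_TBW * tbw
    return out.item() if out.ndim == 0 else out


def bone_mineral_from_bmc(bmc):
    """Total bone mineral Mo (kg) from ashed bone mineral content (kg): Mo = 1.0436*BMC."""
    bmc = np.asarray(bmc, dtype=float)
    if np.any(bmc < 0):
        raise ValueError("bmc must be non-negative")
    out = MO_PER_BMC * bmc
    return out.item() if out.ndim == 0 else out


def total_mineral(mo, ms):
    """Total body mineral M = Mo + Ms (kg)."""
    mo = np.asarray(mo, dtype=float)
    ms = np.asarray(ms, dtype=float)
    if np.any(mo < 0) or np.any(ms < 0):
        raise ValueError("mineral masses must be non-negative")
    out = mo + ms
    return out.item() if out.ndim == 0 else out


def fm_4c(bv, tbw, mo, bw, densities: ComponentDensities | None = None):
    """Fat mass (kg) from the 4C model.

    Parameters are body volume (L), total body water (kg), bone mineral (kg)
    and body weight (kg); scalars or arrays.  Results outside [-BW, BW] are
    flagged with :class:`NonPhysiologicalResultWarning`, never clipped.
    """
    c = fm_coefficients(densities)
    bv = np.asarray(bv, dtype=float)
    tbw = np.asarray(tbw, dtype=float)
    mo = np.asarray(mo, dtype=float)
    bw = np.asarray(bw, dtype=float)
    fm = c.bv * bv + c.tbw * tbw + c.mo * mo + c.bw * bw
    bad = (fm < -bw) | (fm > bw)
    if np.any(bad):
        warnings.warn(
            f"{int(np.count_nonzero(bad))} non-physiological fat-mass value(s) "
            "(|FM| > BW); inputs are likely inconsistent",
            NonPhysiologicalResultWarning,
            stacklevel=2,
        )
    return fm.item() if fm.ndim == 0 else fm


def percent_fm(fm, bw):
    """Fat mass as a percentage of body weight."""
    fm = np.asarray(fm, dtype=float)
    bw = np.asarray(bw, dtype=float)
    if np.any(bw <= 0):
        raise ValueError("bw must be positive")
    out = 100.0 * fm / bw
    return out.item() if out.ndim == 0 else out


def body_volume_from_components(
    fm, tbw, mo, ms, protein, densities: ComponentDensities | None = None
):
    """Body volume (L) implied by the component masses and densities.

    Inverse of the density identity underlying :func:`fm_4c`; the round trip
    ``fm_4c(body_volume_from_components(...), ...)`` recovers FM exactly.
    """
    d = densities or ComponentDensities()
    parts = [np.asarray(a, dtype=float) for a in (fm, tbw, mo, ms, protein)]
    if any(np.any(p < 0) for p in parts):
        raise ValueError("component masses must be non-negative")
    fm, tbw, mo, ms, protein = parts
    out = fm / d.fat + tbw / d.water + mo / d.mo + ms / d.ms + protein / d.protein
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class Composition4C:
    """Derived 4C decomposition of one subject-phase.

    ``fractions`` are (TBW/FFM, M/FFM, protein/FFM) and sum to 1 by
    construction; ``ffm_d`` is the fat-free mass density in g/cc.
    """

    fm: float
    ffm: float
    pfm: float
    mo: float
    ms: float
    m: float
    protein: float
    ffm_d: float
    fractions: tuple[float, float, float]


def decompose_ffm(
    bw: float,
    fm: float,
    tbw: float,
    mo: float,
    ms: float,
    densities: ComponentDensities | None = None,
    subject_id: str | None = None,
) -> Composition4C:
    """Split fat-free mass into water, mineral and protein (protein as residual).

    Raises ``ValueError`` (naming ``subject_id`` when given) if the residual
    protein mass is negative, which signals inconsistent inputs.
    """
    if bw <= fm:
        raise ValueError(f"bw must exceed fm (subject {subject_id!r})")
    ffm = bw - fm
    protein = ffm - tbw - mo - ms
    if protein < 0:
        who = f" for subject {subject_id!r}" if subject_id is not None else ""
        raise ValueError(
            f"negative residual protein ({protein:.4f} kg){who}: "
            "TBW + mineral exceeds fat-free mass"
        )
    m = mo + ms
    fractions = (tbw / ffm, m / ffm, protein / ffm)
    ffmd = ffm_density(
        tbw / ffm, mo / ffm, ms / ffm, protein / ffm, densities=densities
    )
    return Composition4C(
        fm=fm,
        ffm=ffm,
        pfm=percent_fm(fm, bw),
        mo=mo,
        ms=ms,
        m=m,
        protein=protein,
        ffm_d=ffmd,
        fractions=fractions,
    )


def ffm_density(
    tbw_frac,
    mo_frac,
    ms_frac,
    protein_frac,
    densities: ComponentDensities | None = None,
    tol: float = 1e-6,
):
    """Fat-free mass density (g/cc) from component mass fractions.

    FFM_D = 1 / sum(fraction_i / density_i).  Fractions must be non-negative
    and sum to 1 within ``tol``.
    """
    d = densities or ComponentDensities()
    fr = [np.asarray(a, dtype=float) for a in (tbw_frac, mo_frac, ms_frac, protein_frac)]
    if any(np.any(f < 0) for f in fr):
        raise ValueError("fractions must be non-negative")
    total = fr[0] + fr[1] + fr[2] + fr[3]
    if np.any(np.abs(total - 1.0) > tol):
        raise ValueError("fractions must sum to 1")
    out = 1.0 / (fr[0] / d.water + fr[1] / d.mo + fr[2] / d.ms + fr[3] / d.protein)
    return out.item() if out.ndim == 0 else out


@dataclass
class MeasurementRecord:
    """One subject-phase row of raw instrument inputs plus DXA outputs."""

    subject_id: str
    phase: str
    bw: float
    bv: float
    tbw: float
    bmc: float
    dxa_fm: float | None = None
    dxa_ffm: float | None = None
    regional: Mapping[str, tuple[float, float]] | None = field(default=None)

    def validate(self, dxa_sum_tol: float = 2.0) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r} for {self.subject_id!r}")
        if self.bw <= 0 or self.bv <= 0:
            raise ValueError(f"bw and bv must be positive ({self.subject_id!r})")
        if not 0 < self.tbw < self.bw:
            raise ValueError(f"tbw must lie in (0, bw) ({self.subject_id!r})")
        if not 0 < self.bmc < self.bw:
            raise ValueError(f"bmc must lie in (0, bw) ({self.subject_id!r})")
        if self.dxa_fm is not None and self.dxa_ffm is not None:
            if abs(self.dxa_fm + self.dxa_ffm - self.bw) > dxa_sum_tol:
                raise ValueError(
                    f"dxa_fm + dxa_ffm differs from bw by more than {dxa_sum_tol} kg "
                    f"({self.subject_id!r}, {self.phase})"
                )


def records_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "phase": r.phase,
            "bw_kg": r.bw,
            "bv_l": r.bv,
            "tbw_kg": r.tbw,
            "bmc_kg": r.bmc,
            "dxa_fm_kg": r.dxa_fm,
            "dxa_ffm_kg": r.dxa_ffm,
        }
        if r.regional:
            for region in ("trunk", "arms", "legs"):
                if region in r.regional:
                    fm, lst = r.regional[region]
                    row[f"{region}_fm_kg"] = fm
                    row[f"{region}_lst_kg"] = lst
        rows.append(row)
    return pd.DataFrame(rows)


def _frame_to_records(df: pd.DataFrame) -> list[MeasurementRecord]:
    records = []
    has_regional = all(c in df.columns for c in REGIONAL_COLUMNS)
    for _, row in df.iterrows():
        regional = None
        if has_regional and not pd.isna(row["trunk_fm_kg"]):
            regional = {
                region: (float(row[f"{region}_fm_kg"]), float(row[f"{region}_lst_kg"]))
                for region in ("trunk", "arms", "legs")
            }
        records.append(
            MeasurementRecord(
                subject_id=str(row["subject_id"]),
                phase=str(row["phase"]),
                bw=float(row["bw_kg"]),
                bv=float(row["bv_l"]),
                tbw=float(row["tbw_kg"]),
                bmc=float(row["bmc_kg"]),
                dxa_fm=None if pd.isna(row.get("dxa_fm_kg")) else float(row["dxa_fm_kg"]),
                dxa_ffm=None if pd.isna(row.get("dxa_ffm_kg")) else float(row["dxa_ffm_kg"]),
                regional=regional,
            )
        )
    return records


def read_records(
    path: str | Path, validate: bool = True, dxa_sum_tol: float = 2.0
) -> pd.DataFrame:
    """Read a measurement-record CSV, validating every row.

    The table must carry at least :data:`RECORD_COLUMNS`; extra columns (e.g.
    latent-truth columns emitted by the simulator) are preserved.
    """
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if validate:
        for rec in _frame_to_records(df):
            rec.validate(dxa_sum_tol=dxa_sum_tol)
    return df


def write_records(df: pd.DataFrame, path: str | Path) -> None:
    """Write a measurement-record table as CSV (missing optionals as empty cells)."""
    df.to_csv(path, index=False)
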