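"""Test-retest reliability (TEM, CV) and propagation into the 4C fat-mass estimate.

TEM is the Dahlberg technical error of measurement, sqrt(sum(d_i^2) / 2n) over
paired trials.  Because the 4C fat-mass model is linear in its inputs and the
instrument errors are independent, squared TEMs propagate additively through
the model coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .compartments import MO_PER_BMC, Fm4cCoefficients, fm_coefficients

__all__ = [
    "TemProfile",
    "DEFAULT_TEM_PROFILE",
    "tem_from_replicates",
    "cv_from_replicates",
    "propagate_tem",
    "read_replicates",
    "replicate_report",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TemProfile:
    """Per-instrument technical errors of measurement.

    ``bv_tem`` in L, ``tbw_tem`` and ``bmc_tem`` in kg. ``bw_tem`` defaults to
    0 (scale precision is negligible next to the other instruments).  CVs are
    optional and only used for reporting.
    """

    bv_tem: float
    tbw_tem: float
    bmc_tem: float
    bw_tem: float = 0.0
    bv_cv: float | None = None
    tbw_cv: float | None = None
    bmc_cv: float | None = None

    def __post_init__(self) -> None:
        for name in ("bv_tem", "tbw_tem", "bmc_tem", "bw_tem"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


#: Laboratory profile: BV 0.2 L (CV 0.5%), TBW 0.3 kg (CV 1.3%), BMC 0.02 kg (CV 1.6%).
DEFAULT_TEM_PROFILE = TemProfile(
    bv_tem=0.2, tbw_tem=0.3, bmc_tem=0.02, bv_cv=0.5, tbw_cv=1.3, bmc_cv=1.6
)


def _pairs_to_array(pairs: Sequence[tuple[float, float]]) -> np.ndarray:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (trial1, trial2) tuples")
    if arr.shape[0] < 2:
        raise ValueError("at least 2 replicate pairs are required")
    return arr


def tem_from_replicates(pairs: Sequence[tuple[float, float]]) -> float:
    """Dahlberg TEM, sqrt(sum d^2 / 2n), in the units of the measurements."""
    arr = _pairs_to_array(pairs)
    d = arr[:, 0] - arr[:, 1]
    return float(np.sqrt(np.sum(d**2) / (2 * len(d))))


def cv_from_replicates(pairs: Sequence[tuple[float, float]]) -> float:
    """Coefficient of variation, %: 100 * TEM / grand mean of all trials."""
    arr = _pairs_to_array(pairs)
    mean = float(arr.mean())
    if mean <= 0:
        raise ValueError("grand mean must be positive to define a CV")
    return 100.0 * tem_from_replicates(pairs) / mean


def propagate_tem(
    profile: TemProfile,
    coeffs: Fm4cCoefficients | None = None,
    mean_bw: float = 72.8,
) -> tuple[float, float]:
    """Propagate instrument TEMs into the 4C fat-mass estimate.

    Returns ``(fm_tem, pfm_tem)``: the TEM of FM in kg, and expressed in %FM
    units at ``mean_bw``.  The BMC TEM is first converted to bone-mineral
    units via the 1.0436 factor.  Independence makes the squared errors add
    in quadrature through the linear model coefficients.
    """
    if mean_bw <= 0:
        raise ValueError("mean_bw must be positive")
    c = coeffs or fm_coefficients()
    terms = np.array(
        [
            c.bv * profile.bv_tem,
            c.tbw * profile.tbw_tem,
            c.mo * profile.bmc_tem * MO_PER_BMC,
            c.bw * profile.bw_tem,
        ]
    )
    fm_tem = float(np.sqrt(np.sum(terms**2)))
    pfm_tem = 100.0 * fm_tem / mean_bw
    return fm_tem, pfm_tem


def read_replicates(path: str | Path) -> pd.DataFrame:
    """Read a replicate table CSV with columns subject_id, instrument, trial, value."""
    df = pd.read_csv(path)
    required = {"subject_id", "instrument", "trial", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"replicate table missing columns: {sorted(missing)}")
    return df


def replicate_report(df: pd.DataFrame) -> pd.DataFrame:
    """Per-instrument TEM/CV report from a long-format replicate table.

    Trials are paired per subject (trial 1 vs trial 2); one row per
    instrument with n, TEM and CV.  Emits a log line per instrument.
    """
    rows = []
    for instrument, grp in df.groupby("instrument"):
        wide = grp.pivot_table(index="subject_id", columns="trial", values="value")
        if wide.shape[1] < 2:
            raise ValueError(f"instrument {instrument!r} needs two trials per subject")
        pairs = wide.iloc[:, :2].dropna().to_numpy()
        tem = tem_from_replicates(pairs)
        cv = cv_from_replicates(pairs)
        log.info("instrument %s: n=%d TEM=%.4f CV=%.2f%%", instrument, len(pairs), tem, cv)
        rows.append({"instrument": instrument, "n": len(pairs), "tem": tem, "cv_pct": cv})
    return pd.DataFrame(rows)
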