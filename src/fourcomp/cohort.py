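"""Synthetic two-phase athlete cohort generator.

Each subject gets a latent baseline (body weight, %FM, FFM water and mineral
fractions) and latent change scores drawn from configurable normal moments.
Raw measurements (BV, TBW, BMC) are then *derived exactly* from the latent
component masses through the density identity, so the 4C arithmetic is
exercised end-to-end: ``fm_4c`` applied to a generated row reproduces the
latent fat mass to machine precision.

DXA values are built by a bivariate-normal conditional construction on the
latent 4C values: the %FM change score is the calibrated primitive (target
mean/SD/correlation hit exactly in the large-n limit), and DXA fat and
fat-free masses follow from the DXA %FM and the scale body weight.  Because
the DXA change-score SD is smaller than the criterion SD, the generated
cohorts reproduce the characteristic proportional bias (differences trending
negatively with the pairwise means) without an explicit trend term; an extra
shrinkage coefficient is available on top.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .compartments import MO_PER_BMC, MS_PER_TBW, ComponentDensities
from .error_propagation import TemProfile

__all__ = ["CohortConfig", "generate_cohort", "inject_measurement_noise",
           "config_from_yaml", "config_to_yaml", "write_cohort"]

LATENT_COLUMNS = [
    "latent_fm_kg",
    "latent_ffm_kg",
    "latent_pfm",
    "latent_tbw_kg",
    "latent_mo_kg",
    "latent_ms_kg",
    "latent_protein_kg",
    "latent_bv_l",
]


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters: phase moments, change moments and the DXA error model.

    Defaults reproduce a 27-athlete, two-phase (weight stability ->
    pre-competition) cohort: baseline BW 72.8 +/- 7.1 kg, %FM 9.2 +/- 4.1,
    FFM hydration 0.72 +/- 0.02, mineral fraction 0.057 +/- 0.003; change
    scores %FM -1.22 +/- 2.70 and FFM 0.07 +/- 2.04; DXA cross-sectional
    bias +2.9 %FM and change-score targets (mean -0.41, SD 1.05, r 0.53).

    ``corr_dpfm_dffm`` (-0.62) and ``corr_pfm_dpfm`` (-0.44) are calibrated so
    the derived body-weight change SD lands near 1.93 kg and the second-phase
    %FM SD near 3.8.
    """

    n_subjects: int = 27
    seed: int | None = None
    # baseline moments
    bw_mean: float = 72.8
    bw_sd: float = 7.1
    stature_mean: float = 1.76
    stature_sd: float = 0.05
    pfm_mean: float = 9.2
    pfm_sd: float = 4.1
    water_frac_mean: float = 0.72
    water_frac_sd: float = 0.02
    mineral_frac_mean: float = 0.057
    mineral_frac_sd: float = 0.003
    # change moments (criterion level)
    delta_pfm_mean: float = -1.22
    delta_pfm_sd: float = 2.70
    delta_ffm_mean: float = 0.07
    delta_ffm_sd: float = 2.04
    corr_dpfm_dffm: float = -0.62
    corr_pfm_dpfm: float = -0.44
    hydration_delta_mean: float = 0.006
    hydration_delta_sd: float = 0.016
    # DXA error model
    dxa_cs_bias: float = 2.9
    dxa_cs_sd: float = 3.1
    dxa_cs_corr: float = 0.78
    dxa_delta_pfm_mean: float = -0.41
    dxa_delta_pfm_sd: float = 1.05
    dxa_delta_pfm_corr: float = 0.53
    trend_coefficient: float = 0.0
    # physiological truncation
    pfm_floor: float | None = 2.5
    include_regional: bool = False

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        for name in (
            "bw_sd", "pfm_sd", "water_frac_sd", "mineral_frac_sd",
            "delta_pfm_sd", "delta_ffm_sd", "hydration_delta_sd",
            "dxa_cs_sd", "dxa_delta_pfm_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("corr_dpfm_dffm", "corr_pfm_dpfm", "dxa_cs_corr",
                     "dxa_delta_pfm_corr"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1]")
        # joint latent draw must be a valid correlation structure
        try:
            np.linalg.cholesky(self._latent_corr())
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "infeasible correlation combination: the (baseline %FM, d%FM, "
                f"dFFM) correlation matrix is not positive definite "
                f"(corr_pfm_dpfm={self.corr_pfm_dpfm}, "
                f"corr_dpfm_dffm={self.corr_dpfm_dffm})"
            ) from exc

    def _latent_corr(self) -> np.ndarray:
        return np.array(
            [
                [1.0, self.corr_pfm_dpfm, 0.0],
                [self.corr_pfm_dpfm, 1.0, self.corr_dpfm_dffm],
                [0.0, self.corr_dpfm_dffm, 1.0],
            ]
        )

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def config_from_yaml(path: str | Path) -> CohortConfig:
    """Load a :class:`CohortConfig` from a YAML mapping of field overrides."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - {f.name for f in dataclasses.fields(CohortConfig)}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return CohortConfig(**data)


def config_to_yaml(config: CohortConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def _component_volume(fm, tbw, mo, ms, protein, d: ComponentDensities):
    """Density-identity volume without the non-negativity guard.

    With ``pfm_floor=None`` (calibration mode) latent fat mass may dip below
    zero in the tails; the identity is linear so the 4C round trip still holds
    exactly, and the emitted records remain schema-valid.
    """
    return fm / d.fat + tbw / d.water + mo / d.mo + ms / d.ms + protein / d.protein


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    """Rejection-sampled truncated normal; falls back to clipping if sd == 0."""
    if sd == 0:
        return np.full(n, np.clip(mean, lo, hi))
    out = rng.normal(mean, sd, n)
    bad = (out < lo) | (out > hi)
    tries = 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
        tries += 1
        if tries > 1000:
            raise RuntimeError("truncated normal rejection sampling failed to converge")
    return out


def generate_cohort(
    config: CohortConfig,
    densities: ComponentDensities | None = None,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Generate a two-phase cohort as a measurement-record table plus metadata.

    Returns ``(df, meta)``: ``df`` has one row per subject-phase with the
    standard record columns, latent-truth columns, and regional columns when
    ``config.include_regional``; ``meta`` records the seed, config, truncation
    counts and realized sample moments.  Deterministic given the seed.
    """
    config.validate()
    d = densities or ComponentDensities()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    bw1 = _truncated_normal(rng, config.bw_mean, config.bw_sd, 45.0, 115.0, n)

    # joint latent draw: baseline %FM, %FM change, FFM change
    chol = np.linalg.cholesky(config._latent_corr())
    means = np.array([config.pfm_mean, config.delta_pfm_mean, config.delta_ffm_mean])
    sds = np.array([config.pfm_sd, config.delta_pfm_sd, config.delta_ffm_sd])
    floor = config.pfm_floor
    n_rejected = 0
    z = rng.standard_normal((n, 3)) @ chol.T
    latent = means + sds * z
    if floor is not None:
        bad = latent[:, 0] < floor
        while np.any(bad):
            n_rejected += int(bad.sum())
            z = rng.standard_normal((int(bad.sum()), 3)) @ chol.T
            latent[bad] = means + sds * z
            bad = latent[:, 0] < floor
    pfm1, dpfm, dffm = latent.T

    pfm2 = pfm1 + dpfm
    n_clipped_pfm2 = 0
    if floor is not None:
        clip = pfm2 < floor
        n_clipped_pfm2 = int(clip.sum())
        pfm2 = np.maximum(pfm2, floor)

    frac_w1 = _truncated_normal(
        rng, config.water_frac_mean, config.water_frac_sd, 0.62, 0.82, n
    )
    frac_m1 = _truncated_normal(
        rng, config.mineral_frac_mean, config.mineral_frac_sd, 0.045, 0.075, n
    )

    # phase 1 latent masses
    ffm1 = bw1 * (1.0 - pfm1 / 100.0)
    fm1 = bw1 - ffm1
    tbw1 = frac_w1 * ffm1
    m1 = frac_m1 * ffm1
    ms1 = MS_PER_TBW * tbw1
    mo1 = m1 - ms1
    protein1 = ffm1 - tbw1 - m1
    if np.any(protein1 <= 0) or np.any(mo1 <= 0):
        raise ValueError("generated baseline composition is non-physiological")
    bv1 = _component_volume(fm1, tbw1, mo1, ms1, protein1, d)
    bmc1 = mo1 / MO_PER_BMC

    # phase 2 latent masses: FFM and %FM are the drawn primitives, bone mineral
    # held constant across phases, hydration allowed a small drift
    ffm2 = ffm1 + dffm
    if np.any(ffm2 <= 0):
        raise ValueError("generated FFM change drives fat-free mass negative")
    bw2 = ffm2 / (1.0 - pfm2 / 100.0)
    fm2 = bw2 - ffm2
    dfw = rng.normal(config.hydration_delta_mean, config.hydration_delta_sd, n)
    frac_w2 = np.clip(frac_w1 + dfw, 0.62, 0.83)
    tbw2 = frac_w2 * ffm2
    mo2 = mo1
    ms2 = MS_PER_TBW * tbw2
    protein2 = ffm2 - tbw2 - mo2 - ms2
    if np.any(protein2 <= 0):
        raise ValueError("generated pre-competition composition is non-physiological")
    bv2 = _component_volume(fm2, tbw2, mo2, ms2, protein2, d)
    bmc2 = mo2 / MO_PER_BMC

    # DXA: %FM is the calibrated primitive (conditional bivariate construction)
    cs = config.dxa_cs_corr
    pfm_dxa1 = (
        config.pfm_mean + config.dxa_cs_bias
        + cs * (config.dxa_cs_sd / max(config.pfm_sd, 1e-12)) * (pfm1 - config.pfm_mean)
        + np.sqrt(max(1 - cs**2, 0.0)) * config.dxa_cs_sd * rng.standard_normal(n)
    )
    rho = config.dxa_delta_pfm_corr
    dpfm_dxa = (
        config.dxa_delta_pfm_mean
        + rho * (config.dxa_delta_pfm_sd / max(config.delta_pfm_sd, 1e-12))
        * ((pfm2 - pfm1) - config.delta_pfm_mean)
        + np.sqrt(max(1 - rho**2, 0.0)) * config.dxa_delta_pfm_sd
        * rng.standard_normal(n)
    )
    if config.trend_coefficient:
        dpfm_dxa = (
            dpfm_dxa.mean()
            + (1.0 - config.trend_coefficient) * (dpfm_dxa - dpfm_dxa.mean())
        )
    pfm_dxa2 = pfm_dxa1 + dpfm_dxa
    n_clipped_dxa = int((pfm_dxa1 < 0.5).sum() + (pfm_dxa2 < 0.5).sum())
    pfm_dxa1 = np.maximum(pfm_dxa1, 0.5)
    pfm_dxa2 = np.maximum(pfm_dxa2, 0.5)
    fm_dxa1 = pfm_dxa1 / 100.0 * bw1
    ffm_dxa1 = bw1 - fm_dxa1
    fm_dxa2 = pfm_dxa2 / 100.0 * bw2
    ffm_dxa2 = bw2 - fm_dxa2

    subject_ids = [f"S{i + 1:03d}" for i in range(n)]
    frames = []
    for phase, bw, bv, tbw, bmc, fm_dxa, ffm_dxa, fm, ffm, pfm, tbw_l, mo, ms, prot in (
        ("stability", bw1, bv1, tbw1, bmc1, fm_dxa1, ffm_dxa1,
         fm1, ffm1, pfm1, tbw1, mo1, ms1, protein1),
        ("precompetition", bw2, bv2, tbw2, bmc2, fm_dxa2, ffm_dxa2,
         fm2, ffm2, pfm2, tbw2, mo2, ms2, protein2),
    ):
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject_ids,
                    "phase": phase,
                    "bw_kg": bw,
                    "bv_l": bv,
                    "tbw_kg": tbw,
                    "bmc_kg": bmc,
                    "dxa_fm_kg": fm_dxa,
                    "dxa_ffm_kg": ffm_dxa,
                    "latent_fm_kg": fm,
                    "latent_ffm_kg": ffm,
                    "latent_pfm": pfm,
                    "latent_tbw_kg": tbw_l,
                    "latent_mo_kg": mo,
                    "latent_ms_kg": ms,
                    "latent_protein_kg": prot,
                    "latent_bv_l": bv,
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["subject_id", "phase"], ascending=[True, False])
        .reset_index(drop=True)
    )

    if config.include_regional:
        df = _add_regional(df, rng)

    meta = {
        "seed": config.seed,
        "n_subjects": n,
        "config": config.to_dict(),
        "truncation": {
            "baseline_pfm_redraws": n_rejected,
            "precompetition_pfm_clipped": n_clipped_pfm2,
            "dxa_pfm_clipped": n_clipped_dxa,
        },
        "realized_moments": {
            "delta_pfm_4c": [float(np.mean(pfm2 - pfm1)), float(np.std(pfm2 - pfm1, ddof=1))],
            "delta_pfm_dxa": [float(np.mean(dpfm_dxa)), float(np.std(dpfm_dxa, ddof=1))],
            "delta_bw": [float(np.mean(bw2 - bw1)), float(np.std(bw2 - bw1, ddof=1))],
        },
        "notes": (
            "Change-score structure for %FM is exactly calibrated; FM and FFM "
            "DXA changes are derived from DXA %FM and body weight, so their "
            "cross-method structure is approximate."
        ),
    }
    return df, meta


def _add_regional(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Split DXA fat and lean soft tissue into trunk/arms/legs proportional shares."""
    n = len(df)
    fm_props = np.clip(
        np.array([0.50, 0.12, 0.38]) + rng.normal(0, 0.03, (n, 3)), 0.02, None
    )
    fm_props /= fm_props.sum(axis=1, keepdims=True)
    lst_props = np.clip(
        np.array([0.46, 0.18, 0.36]) + rng.normal(0, 0.02, (n, 3)), 0.02, None
    )
    lst_props /= lst_props.sum(axis=1, keepdims=True)
    lst_total = (df["dxa_ffm_kg"] - df["bmc_kg"]).to_numpy()
    fm_total = df["dxa_fm_kg"].to_numpy()
    out = df.copy()
    for j, region in enumerate(("trunk", "arms", "legs")):
        out[f"{region}_fm_kg"] = fm_total * fm_props[:, j]
        out[f"{region}_lst_kg"] = lst_total * lst_props[:, j]
    return out


def inject_measurement_noise(
    df: pd.DataFrame, profile: TemProfile, seed: int | None = None
) -> pd.DataFrame:
    """Add independent zero-mean Gaussian instrument noise to bv, tbw and bmc.

    SDs are the profile TEMs (plus ``bw_tem`` for body weight when non-zero);
    latent-truth columns are left untouched.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    out = df.copy()
    n = len(out)
    for col, tem in (
        ("bv_l", profile.bv_tem),
        ("tbw_kg", profile.tbw_tem),
        ("bmc_kg", profile.bmc_tem),
        ("bw_kg", profile.bw_tem),
    ):
        if tem > 0:
            out[col] = out[col] + rng.normal(0.0, tem, n)
    return out


def write_cohort(
    df: pd.DataFrame, meta: dict[str, Any], path: str | Path
) -> Path:
    """Write the cohort CSV plus an adjacent ``<path>.meta.json`` metadata file."""
    path = Path(path)
    df.to_csv(path, index=False)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)
    return meta_path
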