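"""Study orchestration: cohort in, decomposition, change scores, agreement reports out.

``run_study`` reproduces the full validation layout: a per-phase/per-change
summary table, cross-sectional DXA-vs-criterion performance at each phase,
change-tracking agreement per variable, and a covariate scan of the method
differences.  All tables are returned in-memory and optionally written as
CSV plus a plain-text rendering and a machine-readable JSON summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    agreement_report,
    correlate_differences,
    one_sample_vs_reference,
    paired_comparison,
    r_squared_percent,
)
from .compartments import (
    MO_PER_BMC,
    ComponentDensities,
    NonPhysiologicalResultWarning,
    REGIONAL_COLUMNS,
    ffm_density,
    fm_4c,
    read_records,
    soft_tissue_mineral,
)
from .cohort import CohortConfig, generate_cohort, write_cohort

__all__ = [
    "AnalysisConfig",
    "StudyResult",
    "compute_composition",
    "build_changes",
    "apply_precision_filter",
    "run_study",
]

log = logging.getLogger(__name__)

CHANGE_VARIABLES = ("pfm", "fm", "ffm")


@dataclass
class AnalysisConfig:
    """Configuration of one study run.

    Provide either ``input_path`` (a measurement-record CSV) or ``cohort``
    (a :class:`CohortConfig` to simulate).  ``precision_exclusion_threshold``
    enables the |d%FM by DXA| >= threshold filter on change records (the
    strict interior band is excluded, boundary values retained).
    ``reference_fractions`` maps summary variables (``tbw_frac``, ``m_frac``,
    ``protein_frac``, ``ffm_d``) to reference-population constants for
    one-sample t-tests; no defaults are asserted.
    """

    input_path: str | Path | None = None
    cohort: CohortConfig | None = None
    precision_exclusion_threshold: float | None = None
    alpha: float = 0.05
    loa_multiplier: float = 1.96
    normality_alpha: float = 0.05
    reference_fractions: dict[str, float] | None = None
    densities: ComponentDensities = field(default_factory=ComponentDensities)
    dxa_sum_tol: float = 2.0
    out_dir: str | Path | None = None

    def validate(self) -> None:
        if (self.input_path is None) == (self.cohort is None):
            raise ValueError("provide exactly one of input_path or cohort")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.precision_exclusion_threshold is not None and (
            self.precision_exclusion_threshold < 0
        ):
            raise ValueError("precision_exclusion_threshold must be >= 0")
        if self.loa_multiplier <= 0:
            raise ValueError("loa_multiplier must be positive")


@dataclass
class StudyResult:
    """In-memory bundle of every table produced by :func:`run_study`."""

    cohort: pd.DataFrame
    composition: pd.DataFrame
    changes: pd.DataFrame
    summary: pd.DataFrame
    cross_sectional: pd.DataFrame
    change_agreement: pd.DataFrame
    covariate_scan: pd.DataFrame
    run_log: dict[str, Any]

    def to_json_summary(self) -> dict[str, Any]:
        def records(df: pd.DataFrame) -> list[dict]:
            return json.loads(df.to_json(orient="records"))

        return {
            "summary": records(self.summary),
            "cross_sectional": records(self.cross_sectional),
            "change_agreement": records(self.change_agreement),
            "covariate_scan": records(self.covariate_scan),
            "run_log": self.run_log,
        }


def compute_composition(
    records: pd.DataFrame, densities: ComponentDensities | None = None
) -> pd.DataFrame:
    """Per-row 4C decomposition of a measurement-record table.

    Adds the criterion outputs (fm_4c, ffm_4c, pfm_4c, mo, ms, m, protein,
    ffm_d and the FFM fractions) and the DXA-derived pfm/fm/ffm columns.
    Raises if any row yields a negative residual protein, naming the subject.
    """
    d = densities or ComponentDensities()
    out = records.copy()
    mo = MO_PER_BMC * out["bmc_kg"].to_numpy()
    tbw = out["tbw_kg"].to_numpy()
    bw = out["bw_kg"].to_numpy()
    ms = soft_tissue_mineral(tbw)
    fm = fm_4c(out["bv_l"].to_numpy(), tbw, mo, bw, densities=d)
    ffm = bw - fm
    protein = ffm - tbw - mo - ms
    bad = protein < 0
    if np.any(bad):
        who = out.loc[bad, ["subject_id", "phase"]].iloc[0]
        raise ValueError(
            f"negative residual protein for subject {who['subject_id']!r} "
            f"({who['phase']}): inconsistent inputs"
        )
    out["mo_kg"] = mo
    out["ms_kg"] = ms
    out["m_kg"] = mo + ms
    out["fm_4c_kg"] = fm
    out["ffm_4c_kg"] = ffm
    out["pfm_4c"] = 100.0 * fm / bw
    out["protein_kg"] = protein
    out["tbw_frac"] = tbw / ffm
    out["m_frac"] = (mo + ms) / ffm
    out["protein_frac"] = protein / ffm
    out["ffm_d"] = ffm_density(
        out["tbw_frac"].to_numpy(),
        mo / ffm,
        ms / ffm,
        out["protein_frac"].to_numpy(),
        densities=d,
    )
    if out["dxa_fm_kg"].notna().all() and out["dxa_ffm_kg"].notna().all():
        dxa_total = out["dxa_fm_kg"] + out["dxa_ffm_kg"]
        out["pfm_dxa"] = 100.0 * out["dxa_fm_kg"] / dxa_total
        out["fm_dxa_kg"] = out["dxa_fm_kg"]
        out["ffm_dxa_kg"] = out["dxa_ffm_kg"]
    return out


def build_changes(composition: pd.DataFrame) -> pd.DataFrame:
    """Per-subject change scores (precompetition minus stability), both methods.

    Subjects lacking either phase are dropped with a logged warning.  Regional
    DXA deltas are included when the regional columns are present.
    """
    wide = {}
    for phase, grp in composition.groupby("phase"):
        wide[phase] = grp.set_index("subject_id")
    for phase in ("stability", "precompetition"):
        if phase not in wide:
            raise ValueError(f"no records for phase {phase!r}")
    common = wide["stability"].index.intersection(wide["precompetition"].index)
    dropped = set(composition["subject_id"]) - set(common)
    if dropped:
        log.warning("dropping %d subject(s) missing a phase: %s",
                    len(dropped), sorted(dropped))
    if len(common) == 0:
        raise ValueError("no subject is present in both phases")
    pre = wide["precompetition"].loc[common]
    base = wide["stability"].loc[common]

    chg = pd.DataFrame(index=common)
    pairs = {
        "delta_pfm_4c": "pfm_4c",
        "delta_fm_4c": "fm_4c_kg",
        "delta_ffm_4c": "ffm_4c_kg",
        "delta_bw": "bw_kg",
        "delta_ffm_d": "ffm_d",
        "delta_tbw_frac": "tbw_frac",
        "delta_m_frac": "m_frac",
        "delta_protein_frac": "protein_frac",
    }
    if "pfm_dxa" in composition.columns:
        pairs.update(
            {
                "delta_pfm_dxa": "pfm_dxa",
                "delta_fm_dxa": "fm_dxa_kg",
                "delta_ffm_dxa": "ffm_dxa_kg",
            }
        )
    for out_col, col in pairs.items():
        chg[out_col] = pre[col] - base[col]
    for col in REGIONAL_COLUMNS:
        if col in composition.columns and pre[col].notna().all():
            chg[f"delta_{col}"] = pre[col] - base[col]
    return chg.reset_index().rename(columns={"index": "subject_id"})


def apply_precision_filter(
    changes: pd.DataFrame, threshold: float
) -> tuple[pd.DataFrame, int]:
    """Drop subjects whose DXA %FM change lies strictly inside (-threshold, threshold).

    Boundary values are retained.  Returns the filtered table and the count
    removed.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if threshold == 0:
        return changes, 0
    keep = changes["delta_pfm_dxa"].abs() >= threshold
    removed = int((~keep).sum())
    log.info("precision filter |d%%FM_DXA| >= %.2f: removed %d of %d subjects",
             threshold, removed, len(changes))
    return changes.loc[keep].reset_index(drop=True), removed


def _summarise(composition: pd.DataFrame, changes: pd.DataFrame,
               config: AnalysisConfig) -> pd.DataFrame:
    """Means +/- SD per phase and for the changes, plus reference-population tests."""
    variables = [
        ("pfm_4c", "pfm_4c", "delta_pfm_4c"),
        ("fm_4c_kg", "fm_4c_kg", "delta_fm_4c"),
        ("ffm_4c_kg", "ffm_4c_kg", "delta_ffm_4c"),
        ("pfm_dxa", "pfm_dxa", "delta_pfm_dxa"),
        ("fm_dxa_kg", "fm_dxa_kg", "delta_fm_dxa"),
        ("ffm_dxa_kg", "ffm_dxa_kg", "delta_ffm_dxa"),
        ("bw_kg", "bw_kg", "delta_bw"),
        ("ffm_d", "ffm_d", "delta_ffm_d"),
        ("tbw_frac", "tbw_frac", "delta_tbw_frac"),
        ("m_frac", "m_frac", "delta_m_frac"),
        ("protein_frac", "protein_frac", "delta_protein_frac"),
    ]
    refs = config.reference_fractions or {}
    ref_map = {"tbw_frac": "tbw_frac", "m_frac": "m_frac",
               "protein_frac": "protein_frac", "ffm_d": "ffm_d"}
    rows = []
    by_phase = {p: g for p, g in composition.groupby("phase")}
    for name, col, dcol in variables:
        if col not in composition.columns:
            continue
        row: dict[str, Any] = {"variable": name}
        for phase in ("stability", "precompetition"):
            vals = by_phase[phase][col].dropna()
            row[f"{phase}_mean"] = vals.mean()
            row[f"{phase}_sd"] = vals.std(ddof=1)
            ref_key = ref_map.get(name)
            if ref_key in refs:
                _, p = one_sample_vs_reference(vals, refs[ref_key])
                row[f"{phase}_ref_p"] = p
        if dcol in changes.columns:
            d = changes[dcol].dropna()
            row["change_mean"] = d.mean()
            row["change_sd"] = d.std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)


def _cross_sectional(composition: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Per-phase DXA performance against the criterion for %FM, FM and FFM."""
    pairs = {"pfm": ("pfm_dxa", "pfm_4c"), "fm": ("fm_dxa_kg", "fm_4c_kg"),
             "ffm": ("ffm_dxa_kg", "ffm_4c_kg")}
    rows = []
    for phase, grp in composition.groupby("phase"):
        for var, (a_col, b_col) in pairs.items():
            if a_col not in grp.columns:
                continue
            rep = agreement_report(
                grp[a_col], grp[b_col],
                loa_multiplier=config.loa_multiplier,
                normality_alpha=config.normality_alpha,
            )
            rows.append({"phase": phase, "variable": var, **rep.to_dict()})
    return pd.DataFrame(rows)


def _change_agreement(changes: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    rows = []
    for var in CHANGE_VARIABLES:
        a_col, b_col = f"delta_{var}_dxa", f"delta_{var}_4c"
        if a_col not in changes.columns:
            continue
        rep = agreement_report(
            changes[a_col], changes[b_col],
            loa_multiplier=config.loa_multiplier,
            normality_alpha=config.normality_alpha,
        )
        row = {"variable": var, **rep.to_dict()}
        row["r_squared_pct"] = (
            r_squared_percent(rep.r) if np.isfinite(rep.r) else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _covariate_scan(changes: pd.DataFrame) -> pd.DataFrame:
    """Correlate per-variable method differences with candidate covariates."""
    covariates = ["delta_bw", "delta_ffm_d", "delta_tbw_frac", "delta_m_frac",
                  "delta_protein_frac"]
    covariates += [c for c in changes.columns
                   if c.startswith("delta_") and c.endswith("_kg")
                   and ("trunk" in c or "arms" in c or "legs" in c)]
    rows = []
    for var in CHANGE_VARIABLES:
        a_col, b_col = f"delta_{var}_dxa", f"delta_{var}_4c"
        if a_col not in changes.columns:
            continue
        diff = changes[a_col] - changes[b_col]
        for cov in covariates:
            if cov not in changes.columns:
                continue
            r, p = correlate_differences(diff, changes[cov])
            rows.append({"variable": var, "covariate": cov, "r": r, "p": p})
    return pd.DataFrame(rows)


def _frame_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=False).to_numpy().tobytes()
    ).hexdigest()


def run_study(config: AnalysisConfig) -> StudyResult:
    """Run the complete study replica and (optionally) write the report bundle."""
    config.validate()
    run_log: dict[str, Any] = {"package_version": __version__}
    if config.cohort is not None:
        cohort_df, meta = generate_cohort(config.cohort, densities=config.densities)
        run_log["simulated"] = True
        run_log["seed"] = config.cohort.seed
        run_log["cohort_meta"] = meta
    else:
        cohort_df = read_records(config.input_path, dxa_sum_tol=config.dxa_sum_tol)
        run_log["simulated"] = False
        run_log["input_path"] = str(config.input_path)

    with warnings.catch_warnings():
        warnings.simplefilter("always", NonPhysiologicalResultWarning)
        composition = compute_composition(cohort_df, densities=config.densities)
    changes = build_changes(composition)
    if len(changes) < 3:
        raise ValueError("need at least 3 subjects with both phases")

    removed = 0
    filtered = changes
    if config.precision_exclusion_threshold:
        filtered, removed = apply_precision_filter(
            changes, config.precision_exclusion_threshold
        )
        if len(filtered) == 0:
            raise ValueError(
                "precision filter removed every subject; nothing left to analyse"
            )
        if len(filtered) < 3:
            raise ValueError(
                "fewer than 3 subjects remain after the precision filter"
            )
    run_log["precision_filter"] = {
        "threshold": config.precision_exclusion_threshold,
        "applies_to": "delta_pfm_dxa",
        "boundary": "retained",
        "removed": removed,
        "n_before": len(changes),
        "n_after": len(filtered),
    }

    summary = _summarise(composition, filtered, config)
    cross = _cross_sectional(composition, config)
    change_rep = _change_agreement(filtered, config)
    covariates = _covariate_scan(filtered)

    run_log["alpha"] = config.alpha
    run_log["loa_multiplier"] = config.loa_multiplier
    run_log["difference_direction"] = "DXA minus 4C"
    run_log["regression_orientation"] = "criterion (4C) on predictor (DXA)"
    run_log["normality_gate"] = f"shapiro-wilk at alpha={config.normality_alpha}"
    run_log["composition_table_sha256"] = _frame_hash(
        composition.drop(columns=["subject_id", "phase"]).round(12)
    )
    if not change_rep.empty:
        run_log["tests_used"] = dict(zip(change_rep["variable"], change_rep["test_used"]))

    result = StudyResult(
        cohort=cohort_df,
        composition=composition,
        changes=filtered,
        summary=summary,
        cross_sectional=cross,
        change_agreement=change_rep,
        covariate_scan=covariates,
        run_log=run_log,
    )
    if config.out_dir is not None:
        _write_bundle(result, config)
    return result


def _render_text(result: StudyResult) -> str:
    """Human-readable rendering, rounded to customary table precision."""
    lines = ["Study report", "============", ""]
    lines.append("Summary (mean +/- SD; kg, %FM, g/cc as appropriate)")
    s = result.summary.copy()
    for col in s.columns:
        if col != "variable":
            s[col] = s[col].map(lambda v: f"{v:.3f}" if pd.notna(v) else "")
    lines.append(s.to_string(index=False))
    lines.append("")
    lines.append("Cross-sectional DXA performance (diff = DXA - 4C; "
                 "regression: 4C on DXA)")
    c = result.cross_sectional.copy()
    for col in c.columns:
        if c[col].dtype.kind == "f":
            c[col] = c[col].round(2)
    lines.append(c.to_string(index=False))
    lines.append("")
    lines.append("Change-tracking agreement (precompetition - stability)")
    g = result.change_agreement.copy()
    for col in g.columns:
        if g[col].dtype.kind == "f":
            g[col] = g[col].round(2)
    lines.append(g.to_string(index=False))
    lines.append("")
    lines.append("Trend column: Pearson r of (DXA - 4C) differences vs method means.")
    lines.append("Covariate scan")
    v = result.covariate_scan.copy()
    for col in ("r", "p"):
        if col in v.columns:
            v[col] = v[col].round(3)
    lines.append(v.to_string(index=False))
    return "\n".join(lines) + "\n"


def _write_bundle(result: StudyResult, config: AnalysisConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.cohort is not None:
        write_cohort(result.cohort, result.run_log.get("cohort_meta", {}),
                     out / "cohort.csv")
    result.summary.to_csv(out / "summary.csv", index=False)
    result.cross_sectional.to_csv(out / "cross_sectional.csv", index=False)
    result.change_agreement.to_csv(out / "change_agreement.csv", index=False)
    result.covariate_scan.to_csv(out / "covariate_scan.csv", index=False)
    result.changes.to_csv(out / "changes.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(result.to_json_summary(), fh, indent=2, default=float)
    with open(out / "run_log.json", "w") as fh:
        json.dump(result.run_log, fh, indent=2, default=float)
    (out / "report.txt").write_text(_render_text(result))
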