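"""Metabolite panel quality control.

Pipeline (fixed order, idempotent): pooled-QC coefficient of variation on
raw abundances, prechamber outlier removal (> 5 SD within a diet), exclusion
of any metabolite with any missingness, then log2 transformation and
fold-change construction. Missing values are represented explicitly as NaN
and never imputed; the missingness filter drops whole metabolites instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "QCReport",
    "pooled_qc_cv",
    "remove_outliers",
    "missingness_filter",
    "log2_fold_change",
    "run_qc",
]

OUTLIER_Z = 5.0
MIN_GROUP_FOR_TRIMMING = 3

PANEL_KEY = ["participant_id", "chamber_id", "timepoint", "metabolite"]


@dataclass
class QCReport:
    """Bookkeeping for one QC run; retained + excluded = input metabolites."""

    cv_table: pd.DataFrame
    cv_median: float
    cv_q25: float
    cv_q75: float
    outlier_log: pd.DataFrame
    excluded_metabolites: list[str]
    retained_metabolites: list[str]

    @property
    def n_input_metabolites(self) -> int:
        return len(self.excluded_metabolites) + len(self.retained_metabolites)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {
                "cv_median_pct": self.cv_median,
                "cv_q25_pct": self.cv_q25,
                "cv_q75_pct": self.cv_q75,
                "n_outliers_removed": int(len(self.outlier_log)),
                "n_metabolites_input": self.n_input_metabolites,
                "n_metabolites_retained": len(self.retained_metabolites),
                "excluded_metabolites": self.excluded_metabolites,
            }, indent=1))

    def summary_text(self) -> str:
        return (
            f"pooled-QC CV: median {self.cv_median:.1f}% "
            f"(IQR {self.cv_q25:.1f}-{self.cv_q75:.1f}%)\n"
            f"outlier measurements removed (> {OUTLIER_Z:g} SD within diet): "
            f"{len(self.outlier_log)}\n"
            f"metabolites retained: {len(self.retained_metabolites)} of "
            f"{self.n_input_metabolites} "
            f"({len(self.excluded_metabolites)} excluded for missingness)\n"
        )


def _validate_panel(panel: pd.DataFrame) -> None:
    if panel.duplicated(PANEL_KEY).any():
        raise ValueError("panel must have one row per (participant, chamber, timepoint, metabolite)")
    ok = panel["abundance"].isna() | (panel["abundance"] > 0)
    if not ok.all():
        raise ValueError("raw abundances must be positive or missing")


def pooled_qc_cv(qc_replicates: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-metabolite percent CV of pooled-QC replicate injections (raw scale).

    Metabolites with fewer than two replicates get CV = NaN and a flag.
    Returns the per-metabolite table and summary quantiles (median, IQR)
    across metabolites.
    """
    g = qc_replicates.groupby("metabolite")["abundance"]
    table = pd.DataFrame({
        "n_replicates": g.size(),
        "cv_pct": 100.0 * g.std(ddof=1) / g.mean(),
    }).reset_index()
    table["flag"] = np.where(table["n_replicates"] < 2, "insufficient_replicates", "")
    cvs = table["cv_pct"].dropna()
    summary = {
        "median": float(cvs.median()) if len(cvs) else float("nan"),
        "q25": float(cvs.quantile(0.25)) if len(cvs) else float("nan"),
        "q75": float(cvs.quantile(0.75)) if len(cvs) else float("nan"),
    }
    return table, summary


def remove_outliers(panel: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Set prechamber measurements > 5 SD within their (diet, metabolite)
    group to missing.

    The SD is computed on log2 prechamber values with the candidate included;
    groups smaller than three observations are never trimmed (the SD is too
    unstable to call anything an outlier). Returns the trimmed panel and a
    log with one row per removal.
    """
    _validate_panel(panel)
    panel = panel.copy()
    pre = panel["timepoint"] == "pre"
    sub = panel.loc[pre & panel["abundance"].notna()]
    logs = []
    vals = np.log2(sub["abundance"].astype(float))
    grp = sub.groupby(["diet", "metabolite"])
    mean = grp["abundance"].transform(lambda x: np.log2(x).mean())
    sd = grp["abundance"].transform(lambda x: np.log2(x).std(ddof=1))
    size = grp["abundance"].transform("size")
    z = (vals - mean) / sd
    hit = (size >= MIN_GROUP_FOR_TRIMMING) & (z.abs() > OUTLIER_Z)
    for idx in sub.index[hit]:
        row = panel.loc[idx]
        logs.append({
            "participant_id": row["participant_id"],
            "chamber_id": row["chamber_id"],
            "diet": row["diet"],
            "metabolite": row["metabolite"],
            "abundance": row["abundance"],
            "z": float(z.loc[idx]),
        })
    panel.loc[sub.index[hit], "abundance"] = np.nan
    log = pd.DataFrame(logs, columns=[
        "participant_id", "chamber_id", "diet", "metabolite", "abundance", "z"])
    return panel, log


def missingness_filter(panel: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Partition metabolites into (retained, excluded).

    A metabolite is retained iff it has zero missing values across all rows
    (any degree of missingness, including values blanked by outlier removal,
    excludes it).
    """
    has_missing = panel.groupby("metabolite")["abundance"].apply(lambda x: x.isna().any())
    retained = sorted(has_missing.index[~has_missing])
    excluded = sorted(has_missing.index[has_missing])
    return retained, excluded


def log2_fold_change(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-(participant, chamber, metabolite) log2 fold change and prechamber
    log2 level.

    log2FC = log2(post) - log2(pre). Rows lacking either timepoint are
    dropped. Carries diet, chamber_order and class columns when present.
    """
    carry = [c for c in ("diet", "chamber_order", "met_class", "subclass")
             if c in panel.columns]
    panel = panel.copy()
    for c in ("diet", "met_class", "subclass"):
        # empty labels (e.g. no subclass) must survive the pivot index
        if c in carry:
            panel[c] = panel[c].fillna("").astype(str)
    idx = ["participant_id", "chamber_id", "metabolite"]
    wide = panel.pivot_table(index=idx + carry, columns="timepoint",
                             values="abundance", aggfunc="first", observed=True)
    wide = wide.dropna(subset=["pre", "post"]).reset_index()
    wide["log2_pre"] = np.log2(wide["pre"].astype(float))
    wide["log2_post"] = np.log2(wide["post"].astype(float))
    wide["log2_fc"] = wide["log2_post"] - wide["log2_pre"]
    return wide.drop(columns=["pre", "post"])


def run_qc(panel: pd.DataFrame,
           qc_replicates: pd.DataFrame | None = None) -> tuple[pd.DataFrame, QCReport]:
    """Full QC pipeline: outlier removal -> missingness filter -> report.

    Returns the filtered panel (retained metabolites only, no missing values)
    and the :class:`QCReport`. Running the pipeline on its own output changes
    nothing.
    """
    trimmed, outlier_log = remove_outliers(panel)
    retained, excluded = missingness_filter(trimmed)
    filtered = trimmed[trimmed["metabolite"].isin(retained)].reset_index(drop=True)
    if qc_replicates is not None and len(qc_replicates):
        cv_table, cv_summary = pooled_qc_cv(qc_replicates)
    else:
        cv_table = pd.DataFrame(columns=["metabolite", "n_replicates", "cv_pct", "flag"])
        cv_summary = {"median": float("nan"), "q25": float("nan"), "q75": float("nan")}
    report = QCReport(
        cv_table=cv_table,
        cv_median=cv_summary["median"],
        cv_q25=cv_summary["q25"],
        cv_q75=cv_summary["q75"],
        outlier_log=outlier_log,
        excluded_metabolites=excluded,
        retained_metabolites=retained,
    )
    return filtered, report
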