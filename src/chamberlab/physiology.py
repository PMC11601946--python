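"""Metabolite-physiology association models.

Links each metabolite's chamber excursion (log2 fold change) to the
session-level physiologic phenotypes from the calorimetry engine — 24-hour
EE, 24-hour RQ, substrate oxidation rates — and to NEFA:

* pooled mixed models across all chambers,
  outcome ~ log2FC + log2 pre-level + diet + age + sex + race + BMI
  + (1 | participant);
* per-diet stratified ordinary linear models (no diet term, one session per
  participant);
* NEFA models, postchamber NEFA ~ log2FC + log2 pre-level + prechamber NEFA
  + demographics + (1 | participant);
* concordance of baseline-level vs fold-change coefficient vectors
  (Spearman), asking whether where a metabolite starts and how it moves
  carry the same physiologic information.

Coefficients are left in log2 units: a beta reads as outcome change per
doubling of the metabolite.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .diet_effects import bh_adjust

__all__ = [
    "PHYSIO_OUTCOMES",
    "pooled_physiology_model",
    "stratified_diet_model",
    "nefa_model",
    "baseline_change_concordance",
]

PHYSIO_OUTCOMES = ("EE24", "RQ24", "LIPOX", "CARBOX", "PROTOX", "NEFA_post")

_COVARIATES = "age + C(sex) + C(race) + bmi"


def _join_covariates(df: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    need = {"participant_id", "age", "sex", "race", "bmi"}
    missing = need - set(covariates.columns)
    if missing:
        raise ValueError(f"covariate table lacks columns: {sorted(missing)}")
    out = df.merge(covariates[sorted(need)], on="participant_id", how="left")
    if out[["age", "sex", "race", "bmi"]].isna().any().any():
        raise ValueError("covariates incomplete for some sessions")
    return out


def _fit_mixed(formula: str, data: pd.DataFrame, groups: pd.Series,
               reml: bool = True):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        return smf.mixedlm(formula, data, groups=groups).fit(reml=reml)


def _extract(fit, rows: dict, *, fc_term: str = "log2_fc",
             pre_term: str = "log2_pre") -> dict:
    rows.update({
        "beta_foldchange": float(fit.params[fc_term]),
        "beta_prelevel": float(fit.params[pre_term]),
        "se": float(fit.bse[fc_term]),
        "p": float(fit.pvalues[fc_term]),
        "ci_low": float(fit.conf_int().loc[fc_term, 0]),
        "ci_high": float(fit.conf_int().loc[fc_term, 1]),
        "flag": "",
    })
    return rows


_FAILED = {
    "beta_foldchange": np.nan, "beta_prelevel": np.nan, "se": np.nan,
    "p": np.nan, "ci_low": np.nan, "ci_high": np.nan,
}


def pooled_physiology_model(
    outcome: str,
    fold_changes: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
    *,
    adjust_fdr: bool = True,
) -> pd.DataFrame:
    """Per-metabolite mixed model of one physiologic outcome on the
    metabolite's fold change, pooled across all chambers.

        outcome ~ log2_fc + log2_pre + diet + age + sex + race + BMI
                  + (1 | participant)

    ``outcomes`` has one row per session with columns chamber_id and the
    outcome name. Metabolites with zero fold-change variance are skipped
    with a flag. q-values (BH across metabolites within this outcome family)
    are attached when ``adjust_fdr``; raw p-values are always reported.
    """
    if outcome not in outcomes.columns:
        raise ValueError(f"outcome column {outcome!r} not in outcomes table")
    base = fold_changes.merge(
        outcomes[["chamber_id", outcome]], on="chamber_id", how="inner")
    base = _join_covariates(base, covariates)
    formula = f"Q('{outcome}') ~ log2_fc + log2_pre + C(diet) + {_COVARIATES}"
    rows = []
    for m, grp in base.groupby("metabolite", observed=True):
        grp = grp.dropna(subset=["log2_fc", "log2_pre", outcome])
        rec = {"metabolite": m, "outcome": outcome, "stratum": "pooled",
               "model": "mixed", "n": int(len(grp))}
        if grp["log2_fc"].std(ddof=0) == 0:
            rows.append({**rec, **_FAILED, "flag": "zero_variance_foldchange"})
            continue
        try:
            fit = _fit_mixed(formula, grp, grp["participant_id"])
            rows.append(_extract(fit, rec))
        except (np.linalg.LinAlgError, ValueError) as err:
            rows.append({**rec, **_FAILED, "flag": f"fit_failed:{type(err).__name__}"})
    out = pd.DataFrame(rows)
    if adjust_fdr and len(out):
        out["q"] = bh_adjust(out["p"])
    return out


def stratified_diet_model(
    outcome: str,
    fold_changes: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
    diet: str,
    *,
    adjust_fdr: bool = True,
) -> pd.DataFrame:
    """Ordinary linear model per metabolite within a single dietary chamber.

        outcome ~ log2_fc + log2_pre + age + sex + race + BMI

    Each participant must contribute exactly one session to the stratum;
    duplicates raise. A stratum smaller than the parameter count raises
    rather than fitting silently.
    """
    fc = fold_changes[fold_changes["diet"] == diet]
    if fc.empty:
        raise ValueError(f"no sessions for diet {diet!r}")
    base = fc.merge(outcomes[["chamber_id", outcome]], on="chamber_id", how="inner")
    base = _join_covariates(base, covariates)
    dup = base.groupby(["metabolite", "participant_id"], observed=True).size()
    if (dup > 1).any():
        raise ValueError(f"duplicate sessions per participant in diet {diet!r}")
    formula = f"Q('{outcome}') ~ log2_fc + log2_pre + {_COVARIATES}"
    rows = []
    for m, grp in base.groupby("metabolite", observed=True):
        grp = grp.dropna(subset=["log2_fc", "log2_pre", outcome])
        n_params = 5 + grp["race"].nunique() - 1 + grp["sex"].nunique() - 1
        if len(grp) <= n_params:
            raise ValueError(
                f"diet {diet!r}: {len(grp)} sessions cannot support "
                f"{n_params} model parameters")
        rec = {"metabolite": m, "outcome": outcome, "stratum": diet,
               "model": "ols", "n": int(len(grp))}
        if grp["log2_fc"].std(ddof=0) == 0:
            rows.append({**rec, **_FAILED, "flag": "zero_variance_foldchange"})
            continue
        fit = smf.ols(formula, grp).fit()
        rows.append(_extract(fit, rec))
    out = pd.DataFrame(rows)
    if adjust_fdr and len(out):
        out["q"] = bh_adjust(out["p"])
    return out


def nefa_model(
    fold_changes: pd.DataFrame,
    nefa: pd.DataFrame,
    covariates: pd.DataFrame,
    *,
    adjust_fdr: bool = True,
) -> pd.DataFrame:
    """Per-metabolite mixed model of postchamber NEFA.

        nefa_post ~ log2_fc + log2_pre + nefa_pre + age + sex + race + BMI
                    + (1 | participant)

    Sessions missing prechamber NEFA are dropped with a log entry in the
    returned table's attrs (``dropped_sessions``).
    """
    usable = nefa.dropna(subset=["nefa_pre", "nefa_post"])
    dropped = sorted(set(nefa["chamber_id"]) - set(usable["chamber_id"]))
    base = fold_changes.merge(
        usable[["chamber_id", "nefa_pre", "nefa_post"]], on="chamber_id", how="inner")
    base = _join_covariates(base, covariates)
    formula = f"nefa_post ~ log2_fc + log2_pre + nefa_pre + {_COVARIATES}"
    rows = []
    for m, grp in base.groupby("metabolite", observed=True):
        grp = grp.dropna(subset=["log2_fc", "log2_pre"])
        rec = {"metabolite": m, "outcome": "NEFA_post", "stratum": "pooled",
               "model": "mixed", "n": int(len(grp))}
        if grp["log2_fc"].std(ddof=0) == 0:
            rows.append({**rec, **_FAILED, "flag": "zero_variance_foldchange"})
            continue
        try:
            fit = _fit_mixed(formula, grp, grp["participant_id"])
            rows.append(_extract(fit, rec))
        except (np.linalg.LinAlgError, ValueError) as err:
            rows.append({**rec, **_FAILED, "flag": f"fit_failed:{type(err).__name__}"})
    out = pd.DataFrame(rows)
    out.attrs["dropped_sessions"] = dropped
    if adjust_fdr and len(out):
        out["q"] = bh_adjust(out["p"])
    return out


def baseline_change_concordance(assoc: pd.DataFrame) -> float:
    """Spearman correlation between prechamber-level and fold-change betas.

    Takes one association table (one outcome) and correlates the
    ``beta_prelevel`` vector with the ``beta_foldchange`` vector across
    metabolites, dropping failed fits.
    """
    ok = assoc.dropna(subset=["beta_prelevel", "beta_foldchange"])
    if len(ok) < 3:
        raise ValueError("need at least 3 metabolites with both coefficients")
    return float(stats.spearmanr(ok["beta_prelevel"], ok["beta_foldchange"]).statistic)
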