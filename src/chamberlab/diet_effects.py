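"""Diet-effect statistics for the crossover metabolome.

Two complementary views of each dietary chamber's effect on the metabolome:

1. paired pre/post t tests on log2 metabolite levels with Benjamini-Hochberg
   FDR control within each chamber's metabolite family, and
2. per-metabolite linear mixed models across all chambers,
   post ~ pre + diet (EB referent) + chamber order + (1 | participant),
   which borrow the crossover structure and adjust for carry-over via the
   order term.

Plus the pattern summaries: significant counts by metabolite class and
pairwise Spearman correlation of mean fold-change vectors between diets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "bh_adjust",
    "paired_tests",
    "crossover_mixed_model",
    "class_summary",
    "pattern_matrix",
    "diet_pattern_correlation",
]

MIN_PAIRS = 3
FDR_LEVEL = 0.05


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-safe)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def paired_tests(fold_changes: pd.DataFrame, diet: str | None = None) -> pd.DataFrame:
    """Paired two-tailed t tests of post vs pre log2 levels, per metabolite.

    ``fold_changes`` is the output of :func:`chamberlab.qc.log2_fold_change`;
    the test on the paired differences (the log2 fold changes) against zero
    is identical to the paired t test on log2 levels. q-values are BH-adjusted
    strictly within each diet's metabolite family. Metabolites with fewer
    than three pairs are skipped with a flag; zero-variance differences are
    flagged degenerate rather than given a p-value.
    """
    fc = fold_changes if diet is None else fold_changes[fold_changes["diet"] == diet]
    rows = []
    for (d, m), grp in fc.groupby(["diet", "metabolite"], observed=True):
        x = grp["log2_fc"].to_numpy(dtype=float)
        n = x.size
        est = float(np.mean(x)) if n else np.nan
        if n < MIN_PAIRS:
            rows.append({"metabolite": m, "diet": d, "estimate": est, "se": np.nan,
                         "p": np.nan, "n_pairs": n, "model": "paired_t",
                         "flag": "too_few_pairs"})
            continue
        sd = float(np.std(x, ddof=1))
        if sd == 0:
            rows.append({"metabolite": m, "diet": d, "estimate": est, "se": 0.0,
                         "p": np.nan, "n_pairs": n, "model": "paired_t",
                         "flag": "zero_variance"})
            continue
        t = stats.ttest_1samp(x, 0.0)
        rows.append({"metabolite": m, "diet": d, "estimate": est,
                     "se": sd / np.sqrt(n), "p": float(t.pvalue),
                     "n_pairs": n, "model": "paired_t", "flag": ""})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for d in out["diet"].unique():
        sel = out["diet"] == d
        out.loc[sel, "q"] = bh_adjust(out.loc[sel, "p"])
    return out


def crossover_mixed_model(
    fold_changes: pd.DataFrame,
    *,
    order_coding: str = "numeric",
    reml: bool = True,
) -> pd.DataFrame:
    """Per-metabolite crossover mixed model with EB referent.

    Fits, for each metabolite,

        log2_post ~ log2_pre + C(diet, Treatment('EB')) + chamber_order
                    + (1 | participant)

    ``chamber_order`` enters numerically by default (EB is order 1 for every
    participant) or categorically with ``order_coding='categorical'``. In the
    categorical variant order 1 is merged into the reference level: because
    EB is always the first chamber, a full set of order indicators would be
    exactly collinear with the diet dummies, so order effects are identified
    only among the intervention positions.
    Returns one row per metabolite x non-EB diet contrast; metabolites whose
    fit fails to converge are reported with a flag, never silently dropped.
    q-values are BH-adjusted within each diet's family of contrasts.
    """
    if order_coding not in ("numeric", "categorical"):
        raise ValueError("order_coding must be 'numeric' or 'categorical'")
    order_term = ("chamber_order" if order_coding == "numeric"
                  else "C(order_cat)")
    formula = (f"log2_post ~ log2_pre + C(diet, Treatment('EB')) + {order_term}")
    rows = []
    for m, grp in fold_changes.groupby("metabolite", observed=True):
        grp = grp.dropna(subset=["log2_post", "log2_pre"])
        if order_coding == "categorical":
            grp = grp.assign(order_cat=grp["chamber_order"].clip(lower=2))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = smf.mixedlm(formula, grp, groups=grp["participant_id"]).fit(reml=reml)
            for d in sorted(grp["diet"].unique()):
                if d == "EB":
                    continue
                term = f"C(diet, Treatment('EB'))[T.{d}]"
                if term not in fit.params.index:
                    continue
                rows.append({
                    "metabolite": m, "diet": d,
                    "estimate": float(fit.params[term]),
                    "se": float(fit.bse[term]),
                    "p": float(fit.pvalues[term]),
                    "ci_low": float(fit.conf_int().loc[term, 0]),
                    "ci_high": float(fit.conf_int().loc[term, 1]),
                    "n_pairs": int(grp["participant_id"].nunique()),
                    "model": "mixed", "flag": "",
                })
        except (np.linalg.LinAlgError, ValueError) as err:
            for d in sorted(set(grp["diet"].unique()) - {"EB"}):
                rows.append({"metabolite": m, "diet": d, "estimate": np.nan,
                             "se": np.nan, "p": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan,
                             "n_pairs": int(grp["participant_id"].nunique()),
                             "model": "mixed", "flag": f"fit_failed:{type(err).__name__}"})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = np.nan
        for d in out["diet"].unique():
            sel = out["diet"] == d
            out.loc[sel, "q"] = bh_adjust(out.loc[sel, "p"])
    return out


def class_summary(effects: pd.DataFrame, class_map: pd.DataFrame | dict,
                  *, q_threshold: float = FDR_LEVEL) -> pd.DataFrame:
    """Counts of significant metabolites by class x diet x direction.

    ``class_map`` maps metabolite -> class (dict or DataFrame with columns
    metabolite, met_class). Significance is q < threshold; direction is the
    sign of the estimate.
    """
    if isinstance(class_map, pd.DataFrame):
        class_map = dict(zip(class_map["metabolite"], class_map["met_class"]))
    df = effects.copy()
    df["met_class"] = df["metabolite"].map(class_map)
    sig = df[(df["q"] < q_threshold) & df["estimate"].notna()].copy()
    sig["direction"] = np.where(sig["estimate"] > 0, "up", "down")
    counts = (sig.groupby(["met_class", "diet", "direction"], observed=True)
              .size().rename("n_significant").reset_index())
    return counts


def pattern_matrix(fold_changes: pd.DataFrame) -> pd.DataFrame:
    """Diets x metabolites matrix of mean log2 fold change."""
    return fold_changes.pivot_table(index="diet", columns="metabolite",
                                    values="log2_fc", aggfunc="mean",
                                    observed=True)


def diet_pattern_correlation(pattern: pd.DataFrame,
                             *, min_shared: int = 10) -> pd.DataFrame:
    """Pairwise Spearman correlation of mean fold-change vectors between diets.

    Requires at least ``min_shared`` metabolites observed in both diets of a
    pair. The result is symmetric with unit diagonal.
    """
    diets = pattern.index.to_list()
    rho = pd.DataFrame(np.eye(len(diets)), index=diets, columns=diets)
    for i, a in enumerate(diets):
        for b in diets[i + 1:]:
            both = pattern.loc[[a, b]].dropna(axis=1).T
            if len(both) < min_shared:
                raise ValueError(
                    f"only {len(both)} shared metabolites between {a} and {b} "
                    f"(need >= {min_shared})")
            r = stats.spearmanr(both[a], both[b]).statistic
            rho.loc[a, b] = rho.loc[b, a] = float(r)
    return rho
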