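"""Cell-type composition and per-cell-type differential expression.

Composition shifts between conditions are tested with a label-permutation
scheme in the style of the scProportionTest framework: the observed
statistic per cell type is the log2 fold difference (log2FD) of its
proportion between treatment and control; the null distribution comes from
permuting condition labels across nuclei, p-values use the add-one
convention and are BH-adjusted across cell types; bootstrap percentile
intervals quantify the magnitude. For small datasets an exact mode
enumerates every distinct condition-label assignment.

Differential expression runs separately within each annotated cell type:
two-sided Wilcoxon rank-sum per gene on normalized expression, BH within
the cell type, log2FC oriented treatment/control.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse, stats

from .metabolomics import bh_adjust

__all__ = [
    "proportion_log2fd",
    "proportion_permutation_test",
    "proportion_bootstrap_ci",
    "per_celltype_de",
    "select_de_genes",
]


def _counts_by_type(
    types: np.ndarray, is_treat: np.ndarray, cats: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    t = np.bincount(types[is_treat], minlength=len(cats)).astype(float)
    c = np.bincount(types[~is_treat], minlength=len(cats)).astype(float)
    return t, c


def proportion_log2fd(
    counts_treat: np.ndarray, counts_ctrl: np.ndarray
) -> np.ndarray:
    """log2 of the proportion ratio treatment/control per cell type.

    When any cell-type count is zero a Laplace-style pseudo-count is used:
    proportions become (count + 0.5) / (total + 0.5·K) with K the number of
    types, which keeps the statistic finite.
    """
    counts_treat = np.asarray(counts_treat, float)
    counts_ctrl = np.asarray(counts_ctrl, float)
    k = len(counts_treat)
    if (counts_treat == 0).any() or (counts_ctrl == 0).any():
        pt = (counts_treat + 0.5) / (counts_treat.sum() + 0.5 * k)
        pc = (counts_ctrl + 0.5) / (counts_ctrl.sum() + 0.5 * k)
    else:
        pt = counts_treat / counts_treat.sum()
        pc = counts_ctrl / counts_ctrl.sum()
    return np.log2(pt / pc)


def proportion_permutation_test(
    annotations: pd.DataFrame,
    treatment: str,
    control: str,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    method: str = "permutation",
) -> pd.DataFrame:
    """Permutation test of cell-type composition differences.

    ``annotations`` needs ``cell_type`` and ``condition`` columns (one row
    per nucleus). The two-sided statistic is |log2FD|. ``method`` is
    ``"permutation"`` (sampled, add-one p) or ``"exact"`` (complete
    enumeration of condition-label assignments; only sensible for small
    datasets — the count of assignments is C(n, n_treatment)).

    Returns a per-cell-type table with observed proportions, obs_log2fd,
    p and BH q (adjusted across cell types).
    """
    sub = annotations[annotations["condition"].isin([treatment, control])]
    cats = np.array(sorted(sub["cell_type"].astype(str).unique()))
    if len(cats) < 2:
        raise ValueError("need at least 2 cell types")
    types = pd.Categorical(sub["cell_type"].astype(str), categories=cats).codes
    is_treat = (sub["condition"] == treatment).to_numpy()
    n_treat = int(is_treat.sum())
    if n_treat == 0 or n_treat == len(sub):
        raise ValueError("both conditions must be present")
    obs_t, obs_c = _counts_by_type(types, is_treat, cats)
    obs = proportion_log2fd(obs_t, obs_c)
    abs_obs = np.abs(obs)
    if method == "exact":
        n_total = len(sub)
        n_assign = comb(n_total, n_treat)
        if n_assign > 200_000:
            raise ValueError(f"exact enumeration infeasible: {n_assign} assignments")
        ge = np.zeros(len(cats))
        idx = np.arange(n_total)
        for chosen in combinations(idx, n_treat):
            mask = np.zeros(n_total, bool)
            mask[list(chosen)] = True
            t, c = _counts_by_type(types, mask, cats)
            ge += np.abs(proportion_log2fd(t, c)) >= abs_obs - 1e-12
        p = ge / n_assign
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        ge = np.zeros(len(cats))
        mask = is_treat.copy()
        for _ in range(n_perm):
            perm = rng.permutation(mask)
            t, c = _counts_by_type(types, perm, cats)
            ge += np.abs(proportion_log2fd(t, c)) >= abs_obs - 1e-12
        p = (1.0 + ge) / (1.0 + n_perm)
    else:
        raise ValueError("method must be 'permutation' or 'exact'")
    return pd.DataFrame(
        {
            "cell_type": cats,
            "n_treatment": obs_t.astype(int),
            "n_control": obs_c.astype(int),
            "prop_treatment": obs_t / obs_t.sum(),
            "prop_control": obs_c / obs_c.sum(),
            "obs_log2fd": obs,
            "p": p,
            "q": bh_adjust(p),
        }
    ).set_index("cell_type")


def proportion_bootstrap_ci(
    annotations: pd.DataFrame,
    treatment: str,
    control: str,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Percentile bootstrap CIs for the per-cell-type log2FD.

    Nuclei are resampled with replacement within each condition; the CI is
    the percentile interval of the resampled log2FD at ``level``.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; CIs will be unstable", stacklevel=2)
    sub = annotations[annotations["condition"].isin([treatment, control])]
    cats = np.array(sorted(sub["cell_type"].astype(str).unique()))
    types = pd.Categorical(sub["cell_type"].astype(str), categories=cats).codes
    is_treat = (sub["condition"] == treatment).to_numpy()
    t_types = types[is_treat]
    c_types = types[~is_treat]
    if t_types.size == 0 or c_types.size == 0:
        raise ValueError("both conditions must be present")
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(cats)))
    for b in range(n_boot):
        rt = rng.choice(t_types, size=t_types.size, replace=True)
        rc = rng.choice(c_types, size=c_types.size, replace=True)
        boots[b] = proportion_log2fd(
            np.bincount(rt, minlength=len(cats)),
            np.bincount(rc, minlength=len(cats)),
        )
    alpha = (1.0 - level) / 2.0
    obs = proportion_log2fd(
        np.bincount(t_types, minlength=len(cats)),
        np.bincount(c_types, minlength=len(cats)),
    )
    return pd.DataFrame(
        {
            "cell_type": cats,
            "obs_log2fd": obs,
            "ci_low": np.quantile(boots, alpha, axis=0),
            "ci_high": np.quantile(boots, 1.0 - alpha, axis=0),
        }
    ).set_index("cell_type")


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sparse.issparse(x) else np.asarray(x)


def per_celltype_de(
    adata: AnnData,
    cell_type: str,
    treatment: str,
    control: str,
    *,
    pseudocount: float = 1.0,
    expm1_means: bool = True,
) -> pd.DataFrame:
    """Wilcoxon rank-sum DE within one cell type, treatment vs control.

    Expects log-normalized expression in ``adata.X``. log2FC follows the
    single-cell DE convention: log2((mean(expm1(x_t)) + pc) / (mean(expm1(x_c)) + pc))
    — set ``expm1_means=False`` for plain means of the log values.
    ``pct_treatment``/``pct_control`` are the fractions of nuclei with
    nonzero expression. BH adjustment is applied within the cell type.
    """
    mask = (adata.obs["cell_type"].astype(str) == cell_type).to_numpy()
    cond = adata.obs["condition"].astype(str).to_numpy()
    t_mask = mask & (cond == treatment)
    c_mask = mask & (cond == control)
    if t_mask.sum() < 3 or c_mask.sum() < 3:
        raise ValueError(
            f"cell type '{cell_type}' needs >= 3 nuclei per condition "
            f"(got {int(t_mask.sum())} vs {int(c_mask.sum())})"
        )
    xt = _dense(adata.X[t_mask])
    xc = _dense(adata.X[c_mask])
    res = stats.mannwhitneyu(xt, xc, alternative="two-sided", axis=0)
    p = np.asarray(res.pvalue, float)
    # all-tied genes (e.g. all-zero in both groups) yield NaN under the
    # normal approximation; they carry no evidence
    p = np.where(np.isfinite(p), p, 1.0)
    if expm1_means:
        mt = np.expm1(xt).mean(axis=0)
        mc = np.expm1(xc).mean(axis=0)
    else:
        mt = xt.mean(axis=0)
        mc = xc.mean(axis=0)
    log2fc = np.log2((mt + pseudocount) / (mc + pseudocount))
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "q": bh_adjust(p),
            "pct_treatment": (xt > 0).mean(axis=0),
            "pct_control": (xc > 0).mean(axis=0),
        },
        index=adata.var_names,
    )
    out["significant"] = out["q"] < 0.05
    return out


def select_de_genes(
    de: pd.DataFrame,
    q_max: float = 0.05,
    lfc_min: float = 1.5,
    min_pct: float = 0.1,
) -> list[str]:
    """Gene selection for downstream enrichment.

    Keeps genes with q < ``q_max``, |log2FC| > ``lfc_min`` and an
    expression fraction above ``min_pct`` in at least one condition (the
    max-over-groups reading of a min.pct filter).
    """
    if de.empty:
        return []
    pct = de[["pct_treatment", "pct_control"]].max(axis=1)
    keep = (de["q"] < q_max) & (de["log2fc"].abs() > lfc_min) & (pct > min_pct)
    return list(de.index[keep])
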