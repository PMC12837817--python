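"""Per-nucleus quality control and normalization for snRNA-seq counts.

Nucleus count matrices live in :class:`anndata.AnnData` objects with
nuclei as observations (``obs`` columns ``cell_type`` and ``condition``)
and genes as variables (boolean ``var`` column ``mito`` flagging
mitochondrial genes). QC follows the library-complexity convention:
``log10GenesPerUMI = log10(nFeature) / log10(nCount)`` with retention
requiring complexity > 0.85, 200 < nFeature < 5000 (strict bounds, as
printed) and percent.mt < 5. Doublet detection is out of scope here, so
survivor counts are not comparable to pipelines that remove doublets; the
filter report says so explicitly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scanpy as sc
from anndata import AnnData
from scipy import sparse

__all__ = ["compute_qc_metrics", "filter_nuclei", "normalize_for_de"]


def _counts_csr(adata: AnnData) -> sparse.csr_matrix:
    x = adata.X
    x = sparse.csr_matrix(x) if not sparse.issparse(x) else x.tocsr()
    if x.nnz and (x.data < 0).any():
        raise ValueError("counts must be non-negative")
    if x.nnz and np.any(x.data != np.round(x.data)):
        raise ValueError("counts must be integral")
    return x


def compute_qc_metrics(adata: AnnData) -> pd.DataFrame:
    """Per-nucleus QC metrics.

    Returns a DataFrame indexed by barcode with columns ``n_count`` (total
    UMIs), ``n_feature`` (genes detected), ``log10_genes_per_umi``,
    ``percent_mt`` and a ``degenerate`` flag for nuclei with n_count <= 1,
    whose complexity metric is undefined (log10(1) = 0 denominator) and
    reported as 0.
    """
    if adata.n_obs == 0:
        raise ValueError("empty count matrix")
    x = _counts_csr(adata)
    n_count = np.asarray(x.sum(axis=1)).ravel()
    n_feature = x.getnnz(axis=1).astype(float)
    degenerate = n_count <= 1
    complexity = np.zeros(adata.n_obs)
    ok = ~degenerate
    with np.errstate(divide="ignore", invalid="ignore"):
        complexity[ok] = np.log10(np.maximum(n_feature[ok], 1)) / np.log10(n_count[ok])
    if "mito" in adata.var.columns:
        mito_mask = adata.var["mito"].to_numpy(bool)
    else:
        mito_mask = np.zeros(adata.n_vars, bool)
    mito_counts = np.asarray(x[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        percent_mt = np.where(n_count > 0, 100.0 * mito_counts / n_count, 0.0)
    return pd.DataFrame(
        {
            "n_count": n_count,
            "n_feature": n_feature.astype(int),
            "log10_genes_per_umi": complexity,
            "percent_mt": percent_mt,
            "degenerate": degenerate,
        },
        index=adata.obs_names,
    )


def filter_nuclei(
    metrics: pd.DataFrame,
    *,
    min_complexity: float = 0.85,
    min_features: int = 200,
    max_features: int = 5000,
    max_percent_mt: float = 5.0,
) -> tuple[pd.Index, dict]:
    """Threshold filtering of nuclei on QC metrics.

    A nucleus is kept iff log10GenesPerUMI > ``min_complexity`` AND
    ``min_features`` < nFeature < ``max_features`` (bounds excluded) AND
    percent.mt < ``max_percent_mt``. Returns the kept barcodes and a report
    counting failures per criterion (a nucleus can fail several).
    """
    fail_complexity = metrics["log10_genes_per_umi"] <= min_complexity
    fail_low = metrics["n_feature"] <= min_features
    fail_high = metrics["n_feature"] >= max_features
    fail_mt = metrics["percent_mt"] >= max_percent_mt
    kept = metrics.index[~(fail_complexity | fail_low | fail_high | fail_mt)]
    report = {
        "n_input": int(len(metrics)),
        "n_kept": int(len(kept)),
        "failed_complexity": int(fail_complexity.sum()),
        "failed_min_features": int(fail_low.sum()),
        "failed_max_features": int(fail_high.sum()),
        "failed_percent_mt": int(fail_mt.sum()),
        "thresholds": {
            "min_complexity": min_complexity,
            "min_features": min_features,
            "max_features": max_features,
            "max_percent_mt": max_percent_mt,
        },
        "note": "doublet detection not performed; survivor counts exclude only threshold failures",
    }
    return kept, report


def normalize_for_de(adata: AnnData, scale: float = 1e4, *, log10: bool = False) -> AnnData:
    """Depth-normalize and log-transform counts for scoring and DE.

    Each nucleus's counts are divided by its total, multiplied by ``scale``
    (10,000 by default) and log(1+x)-transformed — natural log by default,
    the convention of the standard single-cell toolkits; set ``log10`` for
    a base-10 variant. Sparsity is preserved. Zero-total nuclei (which QC
    filtering should already have removed) raise an error.
    """
    x = _counts_csr(adata)
    totals = np.asarray(x.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = list(np.asarray(adata.obs_names)[totals == 0][:5])
        raise ValueError(f"zero-total nuclei present (e.g. {bad}); filter first")
    out = AnnData(X=x.copy(), obs=adata.obs.copy(), var=adata.var.copy())
    sc.pp.normalize_total(out, target_sum=scale)
    sc.pp.log1p(out)
    if log10:
        out.X = out.X / np.log(10.0)
    return out
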