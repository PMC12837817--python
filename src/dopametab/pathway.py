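"""Detectability-based gene-set curation and JASMINE signature scoring.

Gene sets (glycolysis, gluconeogenesis, pentose phosphate pathway,
insulin/IGF signalling, TCA cycle, ...) are first restricted to genes that
are robustly detected somewhere in the data: for each gene the maximum,
over annotated cell types, of the percent of nuclei expressing it
(``max_pct``) and of its average normalized expression (``max_avg``) are
summarized; within each set, genes must exceed both the 70th percentile of
max_pct (floored at 5%) and the 70th percentile of max_avg. If fewer than
five genes pass, the top five by a composite of min-max-scaled max_pct and
max_avg (equal weights, lexicographic tie-break) are retained instead.

JASMINE then scores each nucleus for each curated set by combining
(a) the mean rank of the expressed signature genes among all genes the
nucleus expresses (average ranks for ties, ascending expression), divided
by the number of expressed genes, and (b) an odds-ratio enrichment of
signature membership among expressed genes (Haldane +0.5 correction on the
2×2 table). Both components are min-max scaled across nuclei and averaged
into a composite in [0, 1]. Because both components depend only on ranks
and on the expressed/not-expressed dichotomy, scores are invariant to
per-nucleus rescaling of the nonzero values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse, stats
from sklearn.base import BaseEstimator

__all__ = [
    "compute_detectability",
    "filter_gene_set",
    "jasmine_score",
    "JasmineScorer",
    "compare_scores_by_lineage",
]


def _expr_csr(adata: AnnData) -> sparse.csr_matrix:
    x = adata.X
    return x.tocsr() if sparse.issparse(x) else sparse.csr_matrix(np.asarray(x))


def compute_detectability(
    adata: AnnData, genes=None, *, cell_type_key: str = "cell_type"
) -> pd.DataFrame:
    """Per-gene detectability maxima across cell types.

    For each gene and each cell type, the percent of nuclei (of that type)
    with expression > 0 and the mean normalized expression over all nuclei
    of the type (zeros included) are computed; the maxima across cell types
    are returned as columns ``max_pct`` (0–100) and ``max_avg``.
    """
    if cell_type_key not in adata.obs.columns:
        raise ValueError(f"missing obs column '{cell_type_key}'")
    if genes is None:
        genes = list(adata.var_names)
    idx = adata.var_names.get_indexer(genes)
    if (idx < 0).any():
        missing = [g for g, i in zip(genes, idx) if i < 0]
        raise KeyError(f"genes absent from the matrix: {missing[:5]}")
    x = _expr_csr(adata)[:, idx]
    labels = adata.obs[cell_type_key].astype(str)
    max_pct = np.zeros(len(genes))
    max_avg = np.zeros(len(genes))
    for ct in labels.unique():
        mask = (labels == ct).to_numpy()
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"cell type '{ct}' has no nuclei; skipped", stacklevel=2)
            continue
        sub = x[mask]
        pct = 100.0 * sub.getnnz(axis=0) / n
        avg = np.asarray(sub.sum(axis=0)).ravel() / n
        max_pct = np.maximum(max_pct, pct)
        max_avg = np.maximum(max_avg, avg)
    return pd.DataFrame({"max_pct": max_pct, "max_avg": max_avg}, index=pd.Index(genes))


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi - lo < 1e-300:
        return np.zeros_like(v, dtype=float)
    return (v - lo) / (hi - lo)


def filter_gene_set(
    detectability: pd.DataFrame,
    *,
    pct_quantile: float = 0.70,
    pct_floor: float = 5.0,
    avg_quantile: float = 0.70,
    min_genes: int = 5,
) -> list[str]:
    """Retain robustly detected genes within one set.

    Thresholds are computed within the set: max(Q70(max_pct), 5%) and
    Q70(max_avg) (linear-interpolation quantiles); genes strictly exceeding
    both are retained. Fewer than ``min_genes`` survivors triggers the
    composite fallback: rank all genes by the mean of min-max-scaled
    max_pct and max_avg (ties broken lexicographically by gene id) and keep
    the top ``min_genes``. Sets smaller than ``min_genes`` are retained
    whole, with a warning.
    """
    if detectability.empty:
        raise ValueError("empty gene set")
    genes = detectability.index
    if len(genes) < min_genes:
        warnings.warn(
            f"set has {len(genes)} < {min_genes} genes; retained whole", stacklevel=2
        )
        return list(genes)
    pct = detectability["max_pct"].to_numpy(float)
    avg = detectability["max_avg"].to_numpy(float)
    thr_pct = max(float(np.quantile(pct, pct_quantile)), pct_floor)
    thr_avg = float(np.quantile(avg, avg_quantile))
    passing = (pct > thr_pct) & (avg > thr_avg)
    if int(passing.sum()) >= min_genes:
        return list(genes[passing])
    composite = (_minmax(pct) + _minmax(avg)) / 2.0
    order = sorted(range(len(genes)), key=lambda i: (-composite[i], genes[i]))
    return [genes[i] for i in order[:min_genes]]


def _jasmine_components(
    x: sparse.csr_matrix, sig_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Raw per-nucleus mean-rank and odds-ratio components for one set."""
    n_obs, n_genes = x.shape
    n_sig_total = int(sig_mask.sum())
    mean_rank = np.zeros(n_obs)
    odds = np.zeros(n_obs)
    indptr, indices, data = x.indptr, x.indices, x.data
    for i in range(n_obs):
        lo, hi = indptr[i], indptr[i + 1]
        cols = indices[lo:hi]
        n_expr = cols.size
        if n_expr == 0:
            continue
        in_sig = sig_mask[cols]
        a = int(in_sig.sum())  # signature genes expressed
        if a:
            ranks = stats.rankdata(data[lo:hi])  # ascending, average ties
            mean_rank[i] = ranks[in_sig].mean() / n_expr
        b = n_sig_total - a  # signature, not expressed
        c = n_expr - a  # non-signature, expressed
        d = (n_genes - n_sig_total) - c  # non-signature, not expressed
        if a:
            odds[i] = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return mean_rank, odds


def jasmine_score(adata: AnnData, retained_genes) -> pd.DataFrame:
    """JASMINE composite scores for one gene set.

    Returns per-nucleus columns ``mean_rank`` and ``enrichment`` (each
    min-max scaled across nuclei to [0, 1]), their mean ``composite``, and
    ``no_expressed_genes`` flagging nuclei that express nothing.
    """
    retained_genes = list(retained_genes)
    if not retained_genes:
        raise ValueError("retained gene set is empty")
    idx = adata.var_names.get_indexer(retained_genes)
    if (idx < 0).any():
        missing = [g for g, i in zip(retained_genes, idx) if i < 0]
        raise KeyError(f"signature genes absent from the matrix: {missing[:5]}")
    x = _expr_csr(adata)
    sig_mask = np.zeros(adata.n_vars, bool)
    sig_mask[idx] = True
    raw_rank, raw_or = _jasmine_components(x, sig_mask)
    scaled_rank = _minmax(raw_rank)
    scaled_or = _minmax(raw_or)
    return pd.DataFrame(
        {
            "mean_rank": scaled_rank,
            "enrichment": scaled_or,
            "composite": (scaled_rank + scaled_or) / 2.0,
            "no_expressed_genes": x.getnnz(axis=1) == 0,
        },
        index=adata.obs_names,
    )


class JasmineScorer(BaseEstimator):
    """Detectability-curated JASMINE scoring over a collection of gene sets.

    ``fit`` computes per-gene detectability and curates each set;
    ``transform`` produces the per-nucleus score table. Fitting and
    transforming on the same normalized data reproduces the single-pass
    pipeline; fitted curation can also be applied to held-out nuclei.

    Parameters
    ----------
    gene_sets : mapping set name -> list of gene ids.
    pct_quantile, pct_floor, avg_quantile, min_genes : curation thresholds.

    Attributes
    ----------
    detectability_ : dict set name -> per-gene (max_pct, max_avg) DataFrame.
    retained_sets_ : dict set name -> retained gene list.
    """

    def __init__(
        self,
        gene_sets: dict | None = None,
        pct_quantile: float = 0.70,
        pct_floor: float = 5.0,
        avg_quantile: float = 0.70,
        min_genes: int = 5,
        cell_type_key: str = "cell_type",
    ):
        self.gene_sets = gene_sets
        self.pct_quantile = pct_quantile
        self.pct_floor = pct_floor
        self.avg_quantile = avg_quantile
        self.min_genes = min_genes
        self.cell_type_key = cell_type_key

    def fit(self, adata: AnnData, y=None):
        if not self.gene_sets:
            raise ValueError("gene_sets must be a non-empty mapping")
        self.detectability_ = {}
        self.retained_sets_ = {}
        for name, genes in self.gene_sets.items():
            present = [g for g in genes if g in adata.var_names]
            if len(present) < len(genes):
                warnings.warn(
                    f"set '{name}': {len(genes) - len(present)} gene(s) not in matrix",
                    stacklevel=2,
                )
            det = compute_detectability(
                adata, present, cell_type_key=self.cell_type_key
            )
            self.detectability_[name] = det
            self.retained_sets_[name] = filter_gene_set(
                det,
                pct_quantile=self.pct_quantile,
                pct_floor=self.pct_floor,
                avg_quantile=self.avg_quantile,
                min_genes=self.min_genes,
            )
        return self

    def transform(self, adata: AnnData) -> pd.DataFrame:
        """Long-format score table: one row per nucleus × gene set."""
        if not hasattr(self, "retained_sets_"):
            raise ValueError("JasmineScorer is not fitted")
        frames = []
        for name, genes in self.retained_sets_.items():
            df = jasmine_score(adata, genes)
            df.insert(0, "gene_set", name)
            frames.append(df.reset_index(names="barcode"))
        out = pd.concat(frames, ignore_index=True)
        for key in ("cell_type", "condition"):
            if key in adata.obs.columns:
                out[key] = adata.obs[key].astype(str).reindex(out["barcode"]).to_numpy()
        return out

    def fit_transform(self, adata: AnnData, y=None) -> pd.DataFrame:
        return self.fit(adata).transform(adata)


def compare_scores_by_lineage(
    scores: pd.DataFrame, lineage_map: dict[str, list[str]]
) -> pd.DataFrame:
    """Glial-vs-neuronal (or any two-lineage) rank-sum test per gene set.

    ``lineage_map`` has exactly two keys, each mapping to cell-type names;
    composite scores are pooled within each lineage and compared with a
    two-sided Wilcoxon rank-sum (Mann–Whitney) test per gene set.
    """
    if len(lineage_map) != 2:
        raise ValueError("lineage_map must define exactly two lineages")
    (name_a, types_a), (name_b, types_b) = lineage_map.items()
    rows = []
    for gs, sub in scores.groupby("gene_set", sort=True):
        a = sub.loc[sub["cell_type"].isin(types_a), "composite"].to_numpy()
        b = sub.loc[sub["cell_type"].isin(types_b), "composite"].to_numpy()
        if a.size == 0 or b.size == 0:
            raise ValueError(f"empty lineage for gene set '{gs}'")
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "gene_set": gs,
                f"median_{name_a}": float(np.median(a)),
                f"median_{name_b}": float(np.median(b)),
                "statistic": float(stat),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("gene_set")
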