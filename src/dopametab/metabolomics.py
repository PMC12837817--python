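"""Metabolomics statistics: normalization, QC filtering, PCA overview,
univariate testing, differential-metabolite calling, and qPCR relative
expression.

The substrate is a :class:`MetaboliteMatrix`: a feature × sample intensity
table plus a per-sample role label (biological group, pooled ``QC``
injection, or ``blank``). Blanks are carried through I/O but ignored by all
statistics. The differential rule combines a multivariate importance score
(VIP, from the OPLS-DA companion module) with univariate evidence:
``VIP > 1`` and ``BH q < 0.05`` and ``|log2FC| >= 0.8``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

QC_ROLE = "QC"
BLANK_ROLE = "blank"

__all__ = [
    "MetaboliteMatrix",
    "normalize_total_ion",
    "qc_cv_filter",
    "pca_overview",
    "welch_test",
    "bh_adjust",
    "univariate_table",
    "call_differential",
    "delta_delta_ct",
]


@dataclass
class MetaboliteMatrix:
    """Feature × sample intensity table with per-sample roles.

    Parameters
    ----------
    intensities
        Non-negative intensities, rows = features, columns = samples.
    roles
        Per-sample label: a biological group name, ``"QC"`` for pooled-QC
        injections, or ``"blank"``.
    """

    intensities: pd.DataFrame
    roles: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.roles = pd.Series(self.roles)
        if not self.intensities.columns.equals(pd.Index(self.roles.index)):
            self.roles = self.roles.reindex(self.intensities.columns)
        if self.roles.isna().any():
            missing = list(self.roles.index[self.roles.isna()])
            raise ValueError(f"samples without a role label: {missing}")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("negative intensities are not allowed")
        if self.intensities.index.has_duplicates:
            raise ValueError("feature ids must be unique")

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.index

    def samples_with_role(self, role: str) -> list[str]:
        return list(self.roles.index[self.roles == role])

    @property
    def group_names(self) -> list[str]:
        """Biological group labels, in order of first appearance."""
        out: list[str] = []
        for r in self.roles:
            if r not in (QC_ROLE, BLANK_ROLE) and r not in out:
                out.append(r)
        return out

    @property
    def biological_samples(self) -> list[str]:
        return list(self.roles.index[~self.roles.isin([QC_ROLE, BLANK_ROLE])])

    def subset_features(self, feature_ids) -> "MetaboliteMatrix":
        return MetaboliteMatrix(self.intensities.loc[feature_ids], self.roles)


def normalize_total_ion(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Total-ion-signal normalization.

    Each non-blank sample is divided by its total intensity and rescaled by
    the mean total over those samples, so post-normalization all sample
    totals equal the original mean total and magnitudes remain
    interpretable. Blank samples are passed through untouched.
    """
    cols = [s for s in m.intensities.columns if m.roles[s] != BLANK_ROLE]
    totals = m.intensities[cols].sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero)}")
    out = m.intensities.copy().astype(float)
    out[cols] = m.intensities[cols] * (totals.mean() / totals)
    return MetaboliteMatrix(out, m.roles)


def qc_cv_filter(
    m: MetaboliteMatrix, threshold: float = 0.30
) -> tuple[MetaboliteMatrix, list[str]]:
    """Remove features whose pooled-QC coefficient of variation exceeds
    ``threshold`` (default 30%).

    CV is the sample (ddof=1) standard deviation over QC injections divided
    by their mean. Features with a zero QC mean are removed with a warning.
    Returns the filtered matrix and the list of removed feature ids.
    """
    qc = m.samples_with_role(QC_ROLE)
    if len(qc) < 2:
        raise ValueError("QC CV filtering requires at least 2 QC samples")
    vals = m.intensities[qc]
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    zero_mean = mean == 0
    if zero_mean.any():
        warnings.warn(
            f"{int(zero_mean.sum())} feature(s) with zero QC mean removed",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    removed = m.feature_ids[(cv > threshold) | zero_mean]
    kept = m.feature_ids.difference(removed, sort=False)
    return m.subset_features(kept), list(removed)


def pca_overview(
    m: MetaboliteMatrix,
    n_components: int = 2,
    *,
    include_qc: bool = True,
    log_transform: bool = True,
    scale: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the sample cloud for a separation overview.

    Features are log2-transformed (with +1 offset) and unit-variance scaled
    by default, matching the scaling convention used for the companion
    OPLS-DA. Returns (scores DataFrame indexed by sample, explained-variance
    fractions).
    """
    cols = m.biological_samples + (m.samples_with_role(QC_ROLE) if include_qc else [])
    x = m.intensities[cols].to_numpy(float).T  # samples × features
    if n_components > min(x.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples, features)={min(x.shape)}"
        )
    if log_transform:
        x = np.log2(x + 1.0)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    p = PCA(n_components=n_components, svd_solver="full").fit(x)
    scores = pd.DataFrame(
        p.transform(x),
        index=cols,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    scores["role"] = m.roles.reindex(cols).to_numpy()
    return scores, p.explained_variance_ratio_


def welch_test(a, b) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test.

    Degenerate case: both groups with zero variance and equal means returns
    (0.0, 1.0) instead of NaN.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_test needs at least 2 values per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment (monotone q-values)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def univariate_table(
    m: MetaboliteMatrix,
    treatment: str,
    control: str,
    *,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-feature Welch tests and log2 fold changes, treatment/control.

    Tests are run on log2(x+1) values by default; the log2FC is computed on
    the (normalized) group means of raw intensities, oriented
    treatment/control. Returns columns feature_id, log2fc, t, p, q.
    """
    ta = m.intensities[m.samples_with_role(treatment)].to_numpy(float)
    co = m.intensities[m.samples_with_role(control)].to_numpy(float)
    if ta.shape[1] < 2 or co.shape[1] < 2:
        raise ValueError("need >= 2 samples per biological group")
    with np.errstate(divide="ignore"):
        log2fc = np.log2(ta.mean(axis=1) / co.mean(axis=1))
    xa, xc = (np.log2(ta + 1.0), np.log2(co + 1.0)) if log_transform else (ta, co)
    rows = [welch_test(xa[i], xc[i]) for i in range(xa.shape[0])]
    t, p = (np.array(v) for v in zip(*rows))
    return pd.DataFrame(
        {
            "feature_id": m.feature_ids,
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "q": bh_adjust(p),
        }
    ).set_index("feature_id")


def call_differential(
    results: pd.DataFrame,
    vip_threshold: float = 1.0,
    q_threshold: float = 0.05,
    lfc_threshold: float = 0.8,
) -> pd.Series:
    """Differential-metabolite calls.

    ``up`` if VIP > 1 and q < 0.05 and log2FC >= 0.8; ``down`` with
    log2FC <= -0.8; otherwise ``ns``. Requires a ``vip`` column.
    """
    for col in ("vip", "q", "log2fc"):
        if col not in results.columns:
            raise ValueError(f"call_differential requires a '{col}' column")
    if results["vip"].isna().any():
        raise ValueError("missing VIP for some features")
    passing = (results["vip"] > vip_threshold) & (results["q"] < q_threshold)
    call = pd.Series("ns", index=results.index, name="call")
    call[passing & (results["log2fc"] >= lfc_threshold)] = "up"
    call[passing & (results["log2fc"] <= -lfc_threshold)] = "down"
    return call


def delta_delta_ct(
    records: pd.DataFrame, control_group: str
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Relative expression by the 2^-ΔΔCt method.

    ``records`` needs columns ``group``, ``ct_target``, ``ct_reference``
    (one row per sample). ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts
    the control-group mean ΔCt; fold change = 2^−ΔΔCt. The group comparison
    is a Welch test on ΔCt values (better behaved than on the exponentiated
    folds); fold changes are what gets reported.

    Returns (per-sample table with dct/ddct/fold, {group: p-value}).
    """
    for col in ("group", "ct_target", "ct_reference"):
        if col not in records.columns:
            raise ValueError(f"records must have a '{col}' column")
    ct = records[["ct_target", "ct_reference"]].to_numpy(float)
    if not np.isfinite(ct).all() or (ct <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    out = records.copy()
    out["dct"] = out["ct_target"] - out["ct_reference"]
    ctrl = out.loc[out["group"] == control_group, "dct"]
    if ctrl.empty:
        raise ValueError(f"control group '{control_group}' is empty")
    out["ddct"] = out["dct"] - ctrl.mean()
    out["fold"] = 2.0 ** (-out["ddct"])
    pvals = {}
    for g in out["group"].unique():
        if g == control_group:
            continue
        _, pvals[g] = welch_test(out.loc[out["group"] == g, "dct"], ctrl)
    return out, pvals
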