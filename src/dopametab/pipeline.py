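"""End-to-end orchestration of the two analysis arms.

Metabolomics arm: total-ion normalization → pooled-QC CV filter → PCA
overview → Welch tests + BH → OPLS-DA (VIP, Q²Y, permutation p) →
differential-metabolite calls.

Single-nucleus arm: QC metrics → threshold filter → depth/log
normalization → detectability-curated gene sets → JASMINE scores →
lineage comparison → proportion permutation + bootstrap → per-cell-type
DE → selection.

Each stage logs its seed, input shape and survivor counts; outputs are
deterministic given the global seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import celltype, metabolomics, opls, pathway, sn_qc
from .io import (
    RunConfig,
    read_gmt,
    read_metabolite_matrix,
    read_mtx_triplet,
    stage_seed,
)

log = logging.getLogger("dopametab")

__all__ = ["run_metabolomics_arm", "run_snrna_arm", "run_pipeline"]


def run_metabolomics_arm(matrix, config: RunConfig, out_dir) -> dict:
    """Run the full metabolomics chain on a MetaboliteMatrix."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("metabolomics: %d features × %d samples", *matrix.intensities.shape)
    normalized = metabolomics.normalize_total_ion(matrix)
    filtered, removed = metabolomics.qc_cv_filter(normalized, config.cv_threshold)
    log.info(
        "QC CV filter (threshold %.2f): removed %d, kept %d",
        config.cv_threshold, len(removed), len(filtered.feature_ids),
    )
    scores, evr = metabolomics.pca_overview(filtered)
    scores.to_csv(out / "pca_scores.tsv", sep="\t")
    uni = metabolomics.univariate_table(filtered, config.treatment, config.control)

    bio = filtered.biological_samples
    x = np.log2(filtered.intensities[bio].to_numpy(float).T + 1.0)
    y = filtered.roles.reindex(bio).to_numpy()
    model = opls.fit_oplsda(
        x, y, n_ortho=config.n_ortho, positive_class=config.treatment
    )
    seed = stage_seed(config.seed, "oplsda")
    q2 = opls.cross_validated_q2(
        x, y, n_folds=config.n_folds, n_ortho=config.n_ortho,
        random_state=seed, positive_class=config.treatment,
    )
    perm = opls.permutation_test(
        x, y, n_perm=config.n_perm_opls, n_ortho=config.n_ortho,
        n_folds=config.n_folds, random_state=seed,
        positive_class=config.treatment,
    )
    log.info("OPLS-DA: R2Y=%.3f Q2Y=%.3f perm p=%.4g", model.r2y_, q2, perm["p_value"])

    uni["vip"] = model.vip_
    uni["corr_coeff"] = model.predictive_correlations()
    uni["call"] = metabolomics.call_differential(
        uni,
        vip_threshold=config.vip_threshold,
        q_threshold=config.metabo_q_threshold,
        lfc_threshold=config.metabo_lfc_threshold,
    )
    uni.to_csv(out / "differential_metabolites.tsv", sep="\t")
    summary = {
        "n_features_input": int(matrix.intensities.shape[0]),
        "n_features_removed_cv": len(removed),
        "removed_by_cv": removed,
        "pca_explained_variance": [float(v) for v in evr],
        "r2y": float(model.r2y_),
        "q2y": float(q2),
        "permutation_p": float(perm["p_value"]),
        "n_perm": config.n_perm_opls,
        "n_up": int((uni["call"] == "up").sum()),
        "n_down": int((uni["call"] == "down").sum()),
        "thresholds": {
            "cv": config.cv_threshold,
            "vip": config.vip_threshold,
            "q": config.metabo_q_threshold,
            "log2fc": config.metabo_lfc_threshold,
        },
        "seed": seed,
    }
    with open(out / "oplsda_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1)
    return summary


def run_snrna_arm(adata, gene_sets: dict, config: RunConfig, out_dir) -> dict:
    """Run the full single-nucleus chain on an annotated AnnData."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("snRNA: %d nuclei × %d genes", adata.n_obs, adata.n_vars)
    metrics = sn_qc.compute_qc_metrics(adata)
    kept, report = sn_qc.filter_nuclei(
        metrics,
        min_complexity=config.min_complexity,
        min_features=config.min_features,
        max_features=config.max_features,
        max_percent_mt=config.max_percent_mt,
    )
    log.info("nucleus QC: kept %d / %d", report["n_kept"], report["n_input"])
    metrics.to_csv(out / "qc_metrics.tsv", sep="\t")
    pd.Series(kept).to_csv(out / "kept_barcodes.tsv", sep="\t", index=False, header=False)
    with open(out / "qc_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)
    clean = adata[kept].copy()
    norm = sn_qc.normalize_for_de(clean)

    scorer = pathway.JasmineScorer(
        gene_sets=gene_sets,
        pct_quantile=config.pct_quantile,
        pct_floor=config.pct_floor,
        avg_quantile=config.avg_quantile,
        min_genes=config.min_set_genes,
    )
    scores = scorer.fit_transform(norm)
    scores.to_csv(out / "jasmine_scores.tsv", sep="\t", index=False)
    lineage = pathway.compare_scores_by_lineage(scores, config.lineage_map)
    lineage.to_csv(out / "lineage_comparison.tsv", sep="\t")

    props = celltype.proportion_permutation_test(
        clean.obs, config.treatment, config.control,
        n_perm=config.n_perm_proportions,
        seed=stage_seed(config.seed, "proportions"),
    )
    cis = celltype.proportion_bootstrap_ci(
        clean.obs, config.treatment, config.control,
        n_boot=config.n_boot, seed=stage_seed(config.seed, "bootstrap"),
    )
    props = props.join(cis[["ci_low", "ci_high"]])
    props.to_csv(out / "proportions.tsv", sep="\t")

    de_summary = {}
    for ct in sorted(clean.obs["cell_type"].astype(str).unique()):
        n_t = int(((clean.obs["cell_type"] == ct) & (clean.obs["condition"] == config.treatment)).sum())
        n_c = int(((clean.obs["cell_type"] == ct) & (clean.obs["condition"] == config.control)).sum())
        if min(n_t, n_c) < 3:
            log.warning("skipping DE for '%s': %d vs %d nuclei", ct, n_t, n_c)
            continue
        de = celltype.per_celltype_de(norm, ct, config.treatment, config.control)
        de.to_csv(out / f"de_{ct}.tsv", sep="\t")
        selected = celltype.select_de_genes(
            de, q_max=config.de_q_threshold,
            lfc_min=config.de_lfc_threshold, min_pct=config.de_min_pct,
        )
        de_summary[ct] = {
            "n_significant": int(de["significant"].sum()),
            "n_selected": len(selected),
        }
    summary = {
        "qc": report,
        "retained_sets": scorer.retained_sets_,
        "lineage_p": {k: float(v) for k, v in lineage["p"].items()},
        "n_proportion_significant": int((props["q"] < 0.05).sum()),
        "de": de_summary,
    }
    with open(out / "sn_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1)
    return summary


def run_pipeline(
    config: RunConfig,
    out_dir,
    *,
    metabolite_matrix=None,
    metabolite_roles=None,
    mtx_dir=None,
    annotations=None,
    gmt=None,
) -> dict:
    """Execute the configured arms; any stage error aborts with its name."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    if metabolite_matrix is not None:
        try:
            m = read_metabolite_matrix(metabolite_matrix, metabolite_roles)
            results["metabolomics"] = run_metabolomics_arm(
                m, config, out / "metabolomics"
            )
        except Exception as exc:
            raise RuntimeError(f"metabolomics arm failed: {exc}") from exc
    if mtx_dir is not None:
        try:
            adata = read_mtx_triplet(mtx_dir, annotations)
            gene_sets = read_gmt(gmt)
            results["snrna"] = run_snrna_arm(adata, gene_sets, config, out / "snrna")
        except Exception as exc:
            raise RuntimeError(f"snRNA arm failed: {exc}") from exc
    with open(out / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=1)
    return results
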