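"""Synthetic dual-omics data with planted ground truth.

Two generators emulate the statistical structure the analysis assumes,
with known effects for parameter-recovery testing:

* :func:`simulate_metabolomics` — lognormal metabolite intensities
  (multiplicative noise, the standard LC-MS assumption) for two treatment
  groups of six biological replicates each, a planted log2 fold change in a
  subset of features, pooled-QC injections simulated as the all-sample mean
  with technical noise, and a subset of "unstable" features whose QC
  variation exceeds the 30% CV filter.

* :func:`simulate_snrna` — labeled multi-cell-type negative-binomial
  counts for two conditions, with planted pathway-activity shifts in
  target cell types, an optional cell-type composition shift, a flagged
  mitochondrial gene block, and a spike of low-quality nuclei (low gene
  count, high mitochondrial fraction) for QC testing.

Both are deterministic given their seed. Neither models raw spectra,
chromatography, read-level data, ambient RNA or batch effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .metabolomics import MetaboliteMatrix

__all__ = [
    "MetaboSimConfig",
    "SnSimConfig",
    "GroundTruth",
    "simulate_metabolomics",
    "simulate_snrna",
    "DEFAULT_CELL_TYPES",
    "DEFAULT_LINEAGES",
    "default_pathway_specs",
]

TREATMENT = "BRC"
CONTROL = "ddH2O"

# glial and neuronal populations of the honeybee brain, per the study design
DEFAULT_LINEAGES: dict[str, list[str]] = {
    "glial": ["SG", "AST", "CG", "EG"],
    "neuronal": ["KCs", "OLCs", "OPNs"],
}
DEFAULT_CELL_TYPES: list[tuple[str, int]] = [
    ("KCs", 450),
    ("OLCs", 180),
    ("OPNs", 120),
    ("AST", 120),
    ("SG", 100),
    ("CG", 80),
    ("EG", 100),
]


def default_pathway_specs() -> list[tuple[str, int, list[str], float]]:
    """(name, set size, target cell types, activity log2FC) for the five
    scored metabolic gene sets; glycolysis and the pentose phosphate
    pathway are planted up in the glial populations under treatment."""
    glial = DEFAULT_LINEAGES["glial"]
    return [
        ("glycolysis", 30, glial, 1.0),
        ("PPP", 25, glial, 1.0),
        ("gluconeogenesis", 25, [], 0.0),
        ("IIS", 30, [], 0.0),
        ("TCA", 30, [], 0.0),
    ]


@dataclass
class GroundTruth:
    """Planted effects of a simulated dataset (JSON-serializable)."""

    differential_feature_ids: list[str] = field(default_factory=list)
    unstable_feature_ids: list[str] = field(default_factory=list)
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    pathway_effects: dict[str, dict] = field(default_factory=dict)
    true_proportions: dict[str, dict[str, float]] = field(default_factory=dict)
    low_quality_barcodes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "differential_feature_ids": self.differential_feature_ids,
            "unstable_feature_ids": self.unstable_feature_ids,
            "gene_sets": self.gene_sets,
            "pathway_effects": self.pathway_effects,
            "true_proportions": self.true_proportions,
            "low_quality_barcodes": self.low_quality_barcodes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


@dataclass
class MetaboSimConfig:
    """Study conditions for the metabolomics generator.

    Defaults mirror the untargeted design: six biological replicates per
    treatment condition, pooled-QC injections, and the recovery conditions
    used throughout the test suite (200 features, 20 planted at
    log2FC = 1.5, 15% multiplicative noise).
    """

    n_per_group: int = 6
    n_features: int = 200
    n_diff: int = 20
    planted_log2fc: float = 1.5
    cv_noise: float = 0.15
    n_qc: int = 5
    n_unstable: int = 10
    qc_cv_stable: float = 0.10
    qc_cv_unstable: float = 0.60
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not (0 <= self.n_diff <= self.n_features):
            raise ValueError("n_diff must lie in [0, n_features]")
        if not (0 <= self.n_unstable <= self.n_features):
            raise ValueError("n_unstable must lie in [0, n_features]")
        if self.n_diff + self.n_unstable > self.n_features:
            raise ValueError("planted and unstable features must be disjoint")
        if self.cv_noise <= 0:
            raise ValueError("cv_noise must be positive")
        if self.n_diff > 0 and self.planted_log2fc == 0:
            raise ValueError("planted_log2fc must be nonzero when n_diff > 0")
        if self.n_qc < 2:
            raise ValueError("n_qc must be >= 2 (the CV filter needs replicates)")


def _lognormal_sigma(cv: float) -> float:
    """Sigma of a lognormal with the requested coefficient of variation."""
    return float(np.sqrt(np.log1p(cv**2)))


def simulate_metabolomics(
    config: MetaboSimConfig,
) -> tuple[MetaboliteMatrix, GroundTruth]:
    """Generate a feature × sample intensity table with planted effects.

    Intensities are lognormal around per-feature baselines; planted
    features are shifted by ``planted_log2fc`` in the treatment group; QC
    samples are noisy replicates of the pooled all-sample mean, with
    "unstable" features (disjoint from the planted set) given technical
    noise whose expected CV exceeds the 30% filter threshold.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_feat, n = config.n_features, config.n_per_group
    feature_ids = [f"M{i + 1:04d}" for i in range(n_feat)]
    baselines = 10.0 ** rng.uniform(4.0, 6.0, n_feat)
    special = rng.choice(n_feat, config.n_diff + config.n_unstable, replace=False)
    planted = np.sort(special[: config.n_diff])
    unstable = np.sort(special[config.n_diff:])
    sigma = _lognormal_sigma(config.cv_noise)
    shift = np.ones(n_feat)
    shift[planted] = 2.0**config.planted_log2fc
    ctrl = baselines[:, None] * np.exp(rng.normal(0.0, sigma, (n_feat, n)))
    treat = (baselines * shift)[:, None] * np.exp(rng.normal(0.0, sigma, (n_feat, n)))
    pooled = np.concatenate([ctrl, treat], axis=1).mean(axis=1)
    qc_sigma = np.full(n_feat, _lognormal_sigma(config.qc_cv_stable))
    qc_sigma[unstable] = _lognormal_sigma(config.qc_cv_unstable)
    qc = pooled[:, None] * np.exp(
        rng.normal(0.0, 1.0, (n_feat, config.n_qc)) * qc_sigma[:, None]
    )
    samples = (
        [f"{CONTROL}_{i + 1}" for i in range(n)]
        + [f"{TREATMENT}_{i + 1}" for i in range(n)]
        + [f"QC_{i + 1}" for i in range(config.n_qc)]
    )
    intensities = pd.DataFrame(
        np.concatenate([ctrl, treat, qc], axis=1),
        index=pd.Index(feature_ids, name="feature_id"),
        columns=samples,
    )
    roles = pd.Series(
        [CONTROL] * n + [TREATMENT] * n + ["QC"] * config.n_qc, index=samples
    )
    truth = GroundTruth(
        differential_feature_ids=[feature_ids[i] for i in planted],
        unstable_feature_ids=[feature_ids[i] for i in unstable],
    )
    return MetaboliteMatrix(intensities, roles), truth


@dataclass
class SnSimConfig:
    """Study conditions for the single-nucleus generator.

    Cell types default to the seven major honeybee-brain populations
    (four glial, three neuronal); pathway specs plant a +1 log2 activity
    shift for glycolysis and PPP genes in the glial types under treatment.
    """

    cell_types: list[tuple[str, int]] = field(
        default_factory=lambda: list(DEFAULT_CELL_TYPES)
    )
    n_genes: int = 2000
    mito_fraction_genes: float = 0.01
    nb_dispersion: float = 0.5
    base_mean: float = 0.5
    pathway_specs: list[tuple[str, int, list[str], float]] = field(
        default_factory=default_pathway_specs
    )
    composition_shift: dict[str, float] = field(default_factory=dict)
    low_quality_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not self.cell_types:
            raise ValueError("cell_types must be non-empty")
        names = [n for n, _ in self.cell_types]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cell-type names")
        if any(c <= 0 for _, c in self.cell_types):
            raise ValueError("cell-type counts must be positive")
        if self.nb_dispersion <= 0 or self.base_mean <= 0:
            raise ValueError("nb_dispersion and base_mean must be positive")
        if not (0 <= self.mito_fraction_genes < 1):
            raise ValueError("mito_fraction_genes must lie in [0, 1)")
        if not (0 <= self.low_quality_fraction < 1):
            raise ValueError("low_quality_fraction must lie in [0, 1)")
        for name, size, targets, _ in self.pathway_specs:
            if size < 5:
                raise ValueError(f"gene set '{name}' smaller than 5")
            unknown = set(targets) - set(names)
            if unknown:
                raise ValueError(f"set '{name}' targets unknown cell types {unknown}")
        if abs(sum(self.composition_shift.values())) > 1e-9:
            raise ValueError("composition_shift deltas must sum to 0")
        unknown = set(self.composition_shift) - set(names)
        if unknown:
            raise ValueError(f"composition_shift names unknown cell types {unknown}")

    def proportions(self) -> tuple[dict[str, float], dict[str, float]]:
        """Base (control) and shifted (treatment) cell-type proportions."""
        total = sum(c for _, c in self.cell_types)
        base = {n: c / total for n, c in self.cell_types}
        shifted = {
            n: p + self.composition_shift.get(n, 0.0) for n, p in base.items()
        }
        if any(p <= 0 for p in shifted.values()):
            raise ValueError("composition_shift drives a proportion below 0")
        return base, shifted


def _nb_draw(rng, mu: np.ndarray, dispersion: float, size) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + dispersion·mu²."""
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p, size=size)


def simulate_snrna(config: SnSimConfig) -> tuple[AnnData, GroundTruth]:
    """Generate labeled negative-binomial counts with planted effects.

    Returns an AnnData (nuclei × genes, sparse integer counts) with obs
    columns ``cell_type``, ``condition`` and ``low_quality``, a boolean
    ``mito`` var column, and the ground truth (gene-set memberships,
    planted activity shifts, true proportions, spiked low-quality
    barcodes).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    n_mito = int(round(config.mito_fraction_genes * n_genes))
    mito = np.zeros(n_genes, bool)
    mito[:n_mito] = True

    # per-gene baselines (lognormal) with mild per-cell-type modulation
    type_names = [n for n, _ in config.cell_types]
    gene_mu = config.base_mean * np.exp(rng.normal(0.0, 1.0, n_genes))
    type_factors = {
        ct: np.exp(rng.normal(0.0, 0.3, n_genes)) for ct in type_names
    }

    # assign disjoint gene sets from the non-mitochondrial pool
    pool = rng.permutation(np.flatnonzero(~mito))
    gene_sets: dict[str, list[str]] = {}
    pathway_effects: dict[str, dict] = {}
    offset = 0
    for name, size, targets, lfc in config.pathway_specs:
        members = np.sort(pool[offset : offset + size])
        offset += size
        gene_sets[name] = [gene_ids[i] for i in members]
        pathway_effects[name] = {
            "target_cell_types": list(targets),
            "activity_log2fc": float(lfc),
            "member_indices": members,
        }

    base_props, shifted_props = config.proportions()
    total = sum(c for _, c in config.cell_types)
    cond_counts = {
        CONTROL: rng.multinomial(total, [base_props[n] for n in type_names]),
        TREATMENT: rng.multinomial(total, [shifted_props[n] for n in type_names]),
    }

    blocks, obs_rows = [], []
    for condition in (CONTROL, TREATMENT):
        for ct, n_cells in zip(type_names, cond_counts[condition]):
            if n_cells == 0:
                continue
            mu = gene_mu * type_factors[ct]
            if condition == TREATMENT:
                boost = np.ones(n_genes)
                for eff in pathway_effects.values():
                    if ct in eff["target_cell_types"]:
                        boost[eff["member_indices"]] *= 2.0 ** eff["activity_log2fc"]
                mu = mu * boost
            counts = _nb_draw(rng, mu, config.nb_dispersion, (n_cells, n_genes))
            blocks.append(sparse.csr_matrix(counts))
            obs_rows += [(ct, condition, False)] * int(n_cells)

    # spike low-quality nuclei: shrunken libraries with inflated mito share
    n_lq = int(round(config.low_quality_fraction * 2 * total))
    if n_lq:
        for _ in range(n_lq):
            ct = type_names[rng.integers(len(type_names))]
            mu = gene_mu * type_factors[ct] * 0.03
            mu[mito] *= 30.0
            counts = _nb_draw(rng, mu, config.nb_dispersion, (1, n_genes))
            blocks.append(sparse.csr_matrix(counts))
            obs_rows.append((ct, CONTROL if rng.random() < 0.5 else TREATMENT, True))

    x = sparse.vstack(blocks, format="csr")
    barcodes = [f"N{i + 1:06d}" for i in range(x.shape[0])]
    obs = pd.DataFrame(
        obs_rows, columns=["cell_type", "condition", "low_quality"],
        index=pd.Index(barcodes, name="barcode"),
    )
    var = pd.DataFrame({"mito": mito}, index=pd.Index(gene_ids, name="gene_id"))
    adata = AnnData(X=x, obs=obs, var=var)
    truth = GroundTruth(
        gene_sets=gene_sets,
        pathway_effects={
            name: {
                "target_cell_types": eff["target_cell_types"],
                "activity_log2fc": eff["activity_log2fc"],
            }
            for name, eff in pathway_effects.items()
        },
        true_proportions={CONTROL: base_props, TREATMENT: shifted_props},
        low_quality_barcodes=list(obs.index[obs["low_quality"]]),
    )
    return adata, truth
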