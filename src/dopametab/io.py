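"""Readers and writers for every on-disk format the pipeline touches.

Tables are TSV (UTF-8, Unix newlines); nucleus counts are Matrix Market
triplets in the 10x layout (``matrix.mtx`` genes × nuclei, ``features.tsv``
with a mitochondrial flag column, ``barcodes.tsv``) plus an annotation TSV
(barcode, cell_type, condition); gene sets are GMT; ground truth and run
reports are JSON; run configuration is YAML with a version field and
strict (unknown keys rejected) parsing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from anndata import AnnData
from scipy import io as spio
from scipy import sparse

from .metabolomics import MetaboliteMatrix
from .synthetic import DEFAULT_LINEAGES, GroundTruth

__all__ = [
    "write_metabolite_matrix",
    "read_metabolite_matrix",
    "write_mtx_triplet",
    "read_mtx_triplet",
    "read_gmt",
    "write_gmt",
    "write_ground_truth",
    "read_ground_truth",
    "RunConfig",
    "load_config",
    "save_config",
    "stage_seed",
]


# ---------------------------------------------------------------- metabolomics

def write_metabolite_matrix(m: MetaboliteMatrix, out_dir, prefix: str = "metabolites") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m.intensities.to_csv(out / f"{prefix}.tsv", sep="\t")
    m.roles.rename("role").rename_axis("sample").to_csv(
        out / f"{prefix}_roles.tsv", sep="\t"
    )


def read_metabolite_matrix(matrix_path, roles_path) -> MetaboliteMatrix:
    intensities = pd.read_csv(matrix_path, sep="\t", index_col=0)
    roles = pd.read_csv(roles_path, sep="\t", index_col=0)["role"]
    return MetaboliteMatrix(intensities, roles)


# --------------------------------------------------------------------- snRNA

def write_mtx_triplet(adata: AnnData, out_dir) -> None:
    """Write counts as matrix.mtx (genes × nuclei) + features/barcodes/annotations."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    x = adata.X
    x = sparse.coo_matrix(x.T if sparse.issparse(x) else np.asarray(x).T)
    spio.mmwrite(str(out / "matrix.mtx"), x, field="integer")
    mito = (
        adata.var["mito"].astype(int)
        if "mito" in adata.var.columns
        else pd.Series(0, index=adata.var_names)
    )
    pd.DataFrame({"gene_id": adata.var_names, "mito": mito.to_numpy()}).to_csv(
        out / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        out / "barcodes.tsv", sep="\t", index=False, header=False
    )
    ann = adata.obs.reset_index()
    ann = ann.rename(columns={ann.columns[0]: "barcode"})
    cols = ["barcode"] + [c for c in ("cell_type", "condition") if c in ann.columns]
    ann[cols].to_csv(out / "annotations.tsv", sep="\t", index=False)


def read_mtx_triplet(mtx_dir, annotations=None) -> AnnData:
    """Read a 10x-style triplet directory into an AnnData (nuclei × genes)."""
    d = Path(mtx_dir)
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (d / name).exists():
            raise FileNotFoundError(f"missing {name} in {d}")
    try:
        x = spio.mmread(str(d / "matrix.mtx"))
    except Exception as exc:  # noqa: BLE001 - surface parse failures uniformly
        raise ValueError(f"malformed matrix.mtx: {exc}") from exc
    features = pd.read_csv(d / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    if x.shape[0] != len(features):
        raise ValueError(
            f"matrix has {x.shape[0]} rows but features.tsv lists {len(features)}"
        )
    if x.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix has {x.shape[1]} columns but barcodes.tsv lists {len(barcodes)}"
        )
    dup = barcodes[barcodes.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate barcode(s): {list(dup.unique())[:5]}")
    var = pd.DataFrame(index=pd.Index(features[0].astype(str), name="gene_id"))
    if features.shape[1] > 1:
        var["mito"] = features[1].astype(int).astype(bool).to_numpy()
    adata = AnnData(
        X=sparse.csr_matrix(x.T),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=var,
    )
    ann_path = Path(annotations) if annotations else d / "annotations.tsv"
    if ann_path.exists():
        ann = pd.read_csv(ann_path, sep="\t", dtype=str).set_index("barcode")
        unknown = ann.index.difference(adata.obs_names)
        if len(unknown):
            raise ValueError(f"annotated barcodes absent from matrix: {list(unknown)[:5]}")
        for col in ann.columns:
            adata.obs[col] = ann[col].reindex(adata.obs_names)
    return adata


# ----------------------------------------------------------------------- GMT

def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: gene ids} (duplicates dropped)."""
    import warnings

    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need >= 3 tab-separated fields"
                )
            name, genes = parts[0], [g for g in parts[2:] if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name '{name}'")
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                warnings.warn(
                    f"set '{name}': {len(genes) - len(unique)} duplicate gene id(s) dropped",
                    stacklevel=2,
                )
            sets[name] = unique
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# --------------------------------------------------------------- ground truth

def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def read_ground_truth(path) -> GroundTruth:
    with open(path, encoding="utf-8") as fh:
        return GroundTruth.from_dict(json.load(fh))


# --------------------------------------------------------------------- config

@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the published thresholds."""

    version: int = 1
    seed: int = 0
    treatment: str = "BRC"
    control: str = "ddH2O"
    # metabolomics
    cv_threshold: float = 0.30
    vip_threshold: float = 1.0
    metabo_q_threshold: float = 0.05
    metabo_lfc_threshold: float = 0.8
    n_perm_opls: int = 200
    n_folds: int = 7
    n_ortho: int = 1
    # nucleus QC
    min_complexity: float = 0.85
    min_features: int = 200
    max_features: int = 5000
    max_percent_mt: float = 5.0
    # gene-set curation
    pct_quantile: float = 0.70
    pct_floor: float = 5.0
    avg_quantile: float = 0.70
    min_set_genes: int = 5
    # proportions + DE
    n_perm_proportions: int = 1000
    n_boot: int = 1000
    de_q_threshold: float = 0.05
    de_lfc_threshold: float = 1.5
    de_min_pct: float = 0.1
    lineage_map: dict = field(default_factory=lambda: {
        k: list(v) for k, v in DEFAULT_LINEAGES.items()
    })

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load YAML config; unknown keys are rejected to catch typos."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence over (base, crc32(stage)).

    Keeps stages individually reproducible from the single global seed.
    """
    import zlib

    ss = np.random.SeedSequence([int(base_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))
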