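"""Gene-set detectability curation and JASMINE scoring, checked against
hand-computed toys and a dense brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from dopametab import pathway
from tests.conftest import make_adata


class TestComputeDetectability:
    def test_hand_counts(self):
        # gene 0 expressed in 2/4 nuclei of type A and 1/4 of type B
        counts = np.zeros((8, 2))
        counts[[0, 1], 0] = 1  # type A nuclei 0-3
        counts[4, 0] = 1       # type B nuclei 4-7
        counts[:, 1] = 1
        adata = make_adata(counts, cell_types=list("AAAABBBB"))
        det = pathway.compute_detectability(adata, ["g0", "g1"])
        assert det.loc["g0", "max_pct"] == pytest.approx(50.0)
        assert det.loc["g1", "max_pct"] == pytest.approx(100.0)

    def test_all_zero_gene(self):
        adata = make_adata(np.zeros((4, 2)), cell_types=list("AABB"))
        det = pathway.compute_detectability(adata, ["g0"])
        assert det.loc["g0", "max_pct"] == 0.0
        assert det.loc["g0", "max_avg"] == 0.0

    def test_max_avg_includes_zeros(self):
        counts = np.array([[4.0], [0.0], [2.0], [0.0]])
        adata = make_adata(counts, cell_types=list("AABB"))
        det = pathway.compute_detectability(adata, ["g0"])
        # type A mean = (4+0)/2 = 2, type B mean = 1 → max 2
        assert det.loc["g0", "max_avg"] == pytest.approx(2.0)

    def test_missing_gene_rejected(self):
        adata = make_adata(np.ones((2, 2)), cell_types=list("AB"))
        with pytest.raises(KeyError):
            pathway.compute_detectability(adata, ["nope"])


def filter_oracle(det, pct_q=0.70, floor=5.0, avg_q=0.70, min_genes=5):
    """Rule applied literally, gene by gene."""
    pct = det["max_pct"].to_numpy(float)
    avg = det["max_avg"].to_numpy(float)
    thr_p = max(np.quantile(pct, pct_q), floor)
    thr_a = np.quantile(avg, avg_q)
    passing = [g for g, p_, a_ in zip(det.index, pct, avg) if p_ > thr_p and a_ > thr_a]
    if len(passing) >= min_genes:
        return sorted(passing)
    def mm(v):
        return (v - v.min()) / (v.max() - v.min()) if v.max() > v.min() else v * 0
    comp = (mm(pct) + mm(avg)) / 2
    ranked = sorted(zip(-comp, det.index))
    return sorted(g for _, g in ranked[:min_genes])


class TestFilterGeneSet:
    def test_matches_bruteforce_oracle_on_random_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(5, 25))
            det = pd.DataFrame(
                {
                    "max_pct": rng.uniform(0, 100, n).round(1),
                    "max_avg": rng.uniform(0, 3, n).round(2),
                },
                index=[f"g{i:02d}" for i in range(n)],
            )
            got = sorted(pathway.filter_gene_set(det))
            assert got == filter_oracle(det)

    def test_identical_detectability_falls_back_to_five(self):
        det = pd.DataFrame(
            {"max_pct": [50.0] * 8, "max_avg": [1.0] * 8},
            index=[f"g{i}" for i in range(8)],
        )
        # nothing strictly exceeds the quantile; composite ties broken
        # lexicographically by gene id
        assert pathway.filter_gene_set(det) == ["g0", "g1", "g2", "g3", "g4"]

    def test_pct_floor_applies(self):
        # 70th percentile of max_pct is ~3% but the floor is 5%: genes at
        # 4% must not pass even though they exceed the quantile
        det = pd.DataFrame(
            {
                "max_pct": [1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 4.0, 4.0, 4.0, 4.0],
                "max_avg": [0.1] * 5 + [5.0] * 5,
            },
            index=[f"g{i}" for i in range(10)],
        )
        thr = max(np.quantile(det["max_pct"], 0.7), 5.0)
        assert thr == 5.0
        retained = pathway.filter_gene_set(det)
        assert len(retained) == 5  # fallback engaged: nobody passes the floor

    def test_small_set_retained_whole(self):
        det = pd.DataFrame(
            {"max_pct": [1.0, 2.0], "max_avg": [0.1, 0.2]}, index=["a", "b"]
        )
        with pytest.warns(UserWarning, match="retained whole"):
            assert pathway.filter_gene_set(det) == ["a", "b"]


def jasmine_oracle(dense, sig_idx):
    """Dense brute-force JASMINE: explicit sorting, full 2×2 tables."""
    dense = np.asarray(dense, float)
    n_obs, n_genes = dense.shape
    sig = set(sig_idx)
    raw_rank, raw_or = np.zeros(n_obs), np.zeros(n_obs)
    for i in range(n_obs):
        expr = [j for j in range(n_genes) if dense[i, j] > 0]
        if not expr:
            continue
        vals = [dense[i, j] for j in expr]
        # average ranks by explicit sorting
        order = sorted(range(len(vals)), key=lambda k: vals[k])
        ranks = [0.0] * len(vals)
        k = 0
        while k < len(order):
            j = k
            while j + 1 < len(order) and vals[order[j + 1]] == vals[order[k]]:
                j += 1
            avg = (k + j + 2) / 2.0
            for t in range(k, j + 1):
                ranks[order[t]] = avg
            k = j + 1
        sig_ranks = [r for g, r in zip(expr, ranks) if g in sig]
        a = len(sig_ranks)
        if a:
            raw_rank[i] = (sum(sig_ranks) / a) / len(expr)
            b = len(sig) - a
            c = len(expr) - a
            d = (n_genes - len(sig)) - c
            raw_or[i] = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    def mm(v):
        return (v - v.min()) / (v.max() - v.min()) if v.max() > v.min() else v * 0
    sr, so = mm(raw_rank), mm(raw_or)
    return sr, so, (sr + so) / 2


class TestJasmineScore:
    def test_hand_toy_top_ranked_signature(self):
        # nucleus 0 expresses only the two signature genes → top of both
        # components; nucleus 2 expresses no signature gene → composite 0
        counts = np.array(
            [
                [0, 0, 0, 0, 2, 3],
                [3, 2, 1, 0, 0, 1],
                [1, 2, 0, 3, 0, 0],
            ]
        )
        adata = make_adata(counts)
        s = pathway.jasmine_score(adata, ["g4", "g5"])
        assert s["composite"].iloc[0] == pytest.approx(1.0)
        assert s["composite"].iloc[2] == pytest.approx(0.0)
        # hand numbers for nucleus 1: mean rank (1.5/4)=0.375 scales to 0.5;
        # OR = (1.5·1.5)/(1.5·3.5) = 3/7, scaled by the max OR 45
        or0 = (2.5 * 4.5) / (0.5 * 0.5)
        or1 = (1.5 * 1.5) / (1.5 * 3.5)
        assert s["composite"].iloc[1] == pytest.approx((0.5 + or1 / or0) / 2)

    def test_no_expressed_genes_flagged(self):
        counts = np.array([[0, 0, 0], [1, 2, 0]])
        adata = make_adata(counts)
        s = pathway.jasmine_score(adata, ["g0"])
        assert bool(s["no_expressed_genes"].iloc[0])
        assert s["composite"].iloc[0] == 0.0

    def test_scale_invariance_of_one_nucleus(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 5, size=(10, 20))
        a = make_adata(counts)
        scaled = counts.astype(float).copy()
        scaled[3] *= 10.0
        b = make_adata(scaled)
        sa = pathway.jasmine_score(a, [f"g{j}" for j in range(5)])
        sb = pathway.jasmine_score(b, [f"g{j}" for j in range(5)])
        assert np.allclose(sa[["mean_rank", "enrichment", "composite"]],
                           sb[["mean_rank", "enrichment", "composite"]])

    def test_matches_dense_bruteforce(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n_obs = int(rng.integers(3, 50))
            n_genes = int(rng.integers(10, 100))
            dense = rng.integers(0, 4, size=(n_obs, n_genes)) * (
                rng.random((n_obs, n_genes)) < 0.5
            )
            n_sig = int(rng.integers(2, max(3, n_genes // 4)))
            sig_idx = rng.choice(n_genes, n_sig, replace=False)
            adata = make_adata(dense)
            got = pathway.jasmine_score(adata, [f"g{j}" for j in sig_idx])
            sr, so, comp = jasmine_oracle(dense, sig_idx)
            assert np.allclose(got["mean_rank"], sr, atol=1e-12)
            assert np.allclose(got["enrichment"], so, atol=1e-12)
            assert np.allclose(got["composite"], comp, atol=1e-12)

    def test_scores_within_unit_interval(self, sn_default):
        adata, truth = sn_default
        from dopametab import sn_qc

        norm = sn_qc.normalize_for_de(adata[~adata.obs["low_quality"]].copy())
        s = pathway.jasmine_score(norm, truth.gene_sets["glycolysis"])
        vals = s[["mean_rank", "enrichment", "composite"]].to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0


class TestScoreRecovery:
    def test_planted_activity_raises_target_type_scores(self):
        """A +1 log2 activity shift in a target cell type raises that
        type's median composite score under treatment in >= 95% of seeds."""
        import dopametab as dm
        from dopametab import sn_qc

        hits = 0
        for seed in range(20):
            cfg = dm.SnSimConfig(
                cell_types=[("glia", 100), ("neuron", 100)],
                pathway_specs=[("s", 15, ["glia"], 1.0)],
                n_genes=400, low_quality_fraction=0.0, seed=seed,
            )
            adata, truth = dm.simulate_snrna(cfg)
            norm = sn_qc.normalize_for_de(adata)
            s = pathway.jasmine_score(norm, truth.gene_sets["s"])
            s["cell_type"] = adata.obs["cell_type"].to_numpy()
            s["condition"] = adata.obs["condition"].to_numpy()
            glia = s[s["cell_type"] == "glia"]
            med = glia.groupby("condition")["composite"].median()
            hits += med["BRC"] > med["ddH2O"]
        assert hits >= 19


class TestLineageComparison:
    def scores_frame(self, a_vals, b_vals):
        n_a, n_b = len(a_vals), len(b_vals)
        return pd.DataFrame(
            {
                "gene_set": ["s"] * (n_a + n_b),
                "composite": list(a_vals) + list(b_vals),
                "cell_type": ["glia"] * n_a + ["neuron"] * n_b,
            }
        )

    def test_null_p_not_systematically_small(self):
        rng = np.random.default_rng(0)
        small = 0
        for _ in range(20):
            s = self.scores_frame(rng.random(60), rng.random(60))
            out = pathway.compare_scores_by_lineage(
                s, {"glial": ["glia"], "neuronal": ["neuron"]}
            )
            small += out["p"].iloc[0] < 0.05
        assert small <= 3

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        s = self.scores_frame(rng.random(40) + 0.2, rng.random(40))
        p1 = pathway.compare_scores_by_lineage(
            s, {"glial": ["glia"], "neuronal": ["neuron"]}
        )["p"].iloc[0]
        p2 = pathway.compare_scores_by_lineage(
            s, {"neuronal": ["neuron"], "glial": ["glia"]}
        )["p"].iloc[0]
        assert p1 == pytest.approx(p2)

    def test_empty_lineage_rejected(self):
        s = self.scores_frame([0.5], [0.6])
        with pytest.raises(ValueError):
            pathway.compare_scores_by_lineage(
                s, {"glial": ["glia"], "neuronal": ["missing_type"]}
            )


class TestScorerEstimator:
    def test_fit_transform_pipeline(self, sn_default):
        from dopametab import sn_qc

        adata, truth = sn_default
        clean = adata[~adata.obs["low_quality"]].copy()
        norm = sn_qc.normalize_for_de(clean)
        scorer = pathway.JasmineScorer(gene_sets=truth.gene_sets)
        scores = scorer.fit_transform(norm)
        assert set(scorer.retained_sets_) == set(truth.gene_sets)
        for name, genes in scorer.retained_sets_.items():
            assert len(genes) >= 5
            assert set(genes) <= set(truth.gene_sets[name])
        assert len(scores) == norm.n_obs * len(truth.gene_sets)
        assert scores["composite"].between(0, 1).all()

    def test_unfitted_transform_rejected(self, sn_default):
        adata, _ = sn_default
        with pytest.raises(ValueError):
            pathway.JasmineScorer(gene_sets={"s": ["G00001"]}).transform(adata)
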