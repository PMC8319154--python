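import numpy as np
import pandas as pd
import pytest

import coexpand as cx
from coexpand.corr import CorrelationMatrix


def _corr_from_r(genes, r):
    r = np.asarray(r, dtype=float)
    p = np.full_like(r, 0.5)
    np.fill_diagonal(p, 0.0)
    return CorrelationMatrix(list(genes), r, p, n_samples=16)


def _block_diag_corr():
    genes = ["a", "b", "c", "x", "y", "z"]
    r = np.eye(6)
    for i in range(3):
        for j in range(3):
            r[i, j] = 1.0 if i == j else 0.9
            r[i + 3, j + 3] = 1.0 if i == j else 0.9
    return _corr_from_r(genes, r)


class TestSeriate:
    def test_blocks_contiguous(self):
        corr = _block_diag_corr()
        order = cx.seriate(corr)
        pos = {g: i for i, g in enumerate(order)}
        for block in (["a", "b", "c"], ["x", "y", "z"]):
            idx = sorted(pos[g] for g in block)
            assert idx[-1] - idx[0] == 2

    def test_deterministic_under_ties(self):
        genes = ["d", "b", "a", "c"]
        corr1 = _corr_from_r(genes, np.eye(4))
        corr2 = _corr_from_r(sorted(genes), np.eye(4))
        assert cx.seriate(corr1) == cx.seriate(corr2)

    def test_planted_block_contiguous_in_simulation(self):
        hits = 0
        runs = 40
        for s in range(runs):
            cfg = cx.SyntheticConfig(
                n_genes=500, cluster_loading=0.9, pool_genes=0,
                pathway_genes=0, seed=3000 + s,
            )
            m, meta, truth = cx.simulate_expression(cfg)
            rng = np.random.default_rng(s)
            extras = sorted(
                str(g) for g in rng.choice(truth.background, 16, replace=False)
            )
            gl = cx.GeneList("l", sorted(truth.cluster) + extras)
            corr = cx.pairwise_correlation(m, gl, meta)
            order = cx.seriate(corr)
            pos = sorted(order.index(g) for g in truth.cluster)
            hits += pos[-1] - pos[0] == len(truth.cluster) - 1
        assert hits / runs >= 0.9


class TestIdentifyCluster:
    def test_recovers_planted_block(self):
        corr = _block_diag_corr()
        cluster = cx.identify_cluster(corr, min_size=3, min_mean_r=0.5)
        assert cluster is not None
        assert sorted(cluster.genes) in (["a", "b", "c"], ["x", "y", "z"])
        assert cluster.mean_pairwise_r == pytest.approx(0.9)

    def test_no_cluster_on_independent_genes(self):
        corr = _corr_from_r(list("abcdef"), np.eye(6))
        assert cx.identify_cluster(corr) is None

    def test_override_returns_exactly_that_list(self, planted, gwas_list):
        _, matrix, metadata, truth = planted
        corr = cx.pairwise_correlation(matrix, gwas_list, metadata)
        chosen = sorted(truth.cluster)
        cluster = cx.identify_cluster(corr, override=chosen)
        assert cluster.genes == chosen

    def test_override_with_unknown_gene_fails(self, planted, gwas_list):
        _, matrix, metadata, _ = planted
        corr = cx.pairwise_correlation(matrix, gwas_list, metadata)
        with pytest.raises(KeyError):
            cx.identify_cluster(corr, override=["NOPE1", "NOPE2", "NOPE3"])

    def test_invariant_to_input_gene_order(self, planted, gwas_list):
        _, matrix, metadata, _ = planted
        corr1 = cx.pairwise_correlation(matrix, gwas_list, metadata)
        rev = cx.GeneList("rev", gwas_list.genes[::-1])
        corr2 = cx.pairwise_correlation(matrix, rev, metadata)
        c1 = cx.identify_cluster(corr1)
        c2 = cx.identify_cluster(corr2)
        assert c1 is not None and c2 is not None
        assert sorted(c1.genes) == sorted(c2.genes)


class TestAverageProfile:
    def _meta(self, samples):
        return cx.SampleMetadata(
            pd.DataFrame(
                {
                    "sample_id": samples,
                    "diagnosis": ["case"] * len(samples),
                    "region": ["r1"] * len(samples),
                    "dataset": ["d1"] * len(samples),
                }
            )
        )

    def test_identical_rows_give_shared_zscore(self):
        base = np.array([1.0, 3.0, 2.0, 4.0])
        data = pd.DataFrame(
            [base, base, base], index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(4)],
        )
        m = cx.ExpressionMatrix(data)
        cluster = cx.GeneCluster(["a", "b", "c"], 1.0, ["a", "b", "c"])
        profile = cx.average_profile(m, cluster, self._meta(m.sample_ids))
        z = (base - base.mean()) / base.std(ddof=1)
        np.testing.assert_allclose(profile.to_numpy(), z)

    def test_negated_pair_cancels(self):
        base = np.array([1.0, 3.0, 2.0, 4.0, 0.0])
        data = pd.DataFrame(
            [base, -base, base, -base], index=list("abcd"),
            columns=[f"s{i}" for i in range(5)],
        )
        m = cx.ExpressionMatrix(data)
        cluster = cx.GeneCluster(list("abcd"), 0.0, list("abcd"))
        profile = cx.average_profile(m, cluster, self._meta(m.sample_ids))
        np.testing.assert_allclose(profile.to_numpy(), 0.0, atol=1e-12)

    def test_profile_recovers_latent_factor(self):
        cfg = cx.SyntheticConfig(
            n_genes=50, n_case=2000, n_ctrl=4, cluster_loading=0.9,
            pool_genes=0, pathway_genes=0, seed=6,
        )
        m, meta, truth = cx.simulate_expression(cfg)
        cluster = cx.GeneCluster(sorted(truth.cluster), 0.81,
                                 sorted(truth.cluster))
        profile = cx.average_profile(m, cluster, meta, diagnosis="case")
        f = truth.latent[profile.index]
        r = np.corrcoef(profile.to_numpy(), f.to_numpy())[0, 1]
        assert r >= 0.98


class TestExpand:
    def test_degenerate_expansion_returns_seed(self, planted):
        _, matrix, metadata, truth = planted
        cluster = cx.GeneCluster(sorted(truth.cluster), 0.6,
                                 sorted(truth.cluster))
        profile = cx.average_profile(matrix, cluster, metadata)
        expanded = cx.expand(matrix, profile, cluster, len(cluster.genes))
        assert sorted(expanded.members) == sorted(cluster.genes)

    def test_seed_of_7_to_800_adds_793(self, planted):
        _, matrix, metadata, truth = planted
        cluster = cx.GeneCluster(sorted(truth.cluster), 0.6,
                                 sorted(truth.cluster))
        profile = cx.average_profile(matrix, cluster, metadata)
        expanded = cx.expand(matrix, profile, cluster, 800)
        assert expanded.M == 800
        assert len(set(expanded.members) - set(cluster.genes)) == 793

    def test_members_nested_and_min_r_non_increasing(self, planted):
        _, matrix, metadata, truth = planted
        cluster = cx.GeneCluster(sorted(truth.cluster), 0.6,
                                 sorted(truth.cluster))
        profile = cx.average_profile(matrix, cluster, metadata)
        e600 = cx.expand(matrix, profile, cluster, 600)
        e800 = cx.expand(matrix, profile, cluster, 800)
        assert set(e600.members) <= set(e800.members)
        assert e800.min_r_attained <= e600.min_r_attained

    def test_members_sorted_by_descending_r(self, planted):
        _, matrix, metadata, truth = planted
        cluster = cx.GeneCluster(sorted(truth.cluster), 0.6,
                                 sorted(truth.cluster))
        profile = cx.average_profile(matrix, cluster, metadata)
        expanded = cx.expand(matrix, profile, cluster, 100)
        r = expanded.r_to_profile.to_numpy()
        assert np.all(np.diff(r) <= 1e-12)
        assert expanded.min_r_attained == pytest.approx(r[-1])

    def test_m_too_large_rejected(self, planted):
        _, matrix, metadata, truth = planted
        cluster = cx.GeneCluster(sorted(truth.cluster), 0.6,
                                 sorted(truth.cluster))
        profile = cx.average_profile(matrix, cluster, metadata)
        with pytest.raises(ValueError):
            cx.expand(matrix, profile, cluster, matrix.n_genes + 1)
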