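import numpy as np
import pandas as pd
import pytest
from scipy import stats

import coexpand as cx
from coexpand.corr import critical_r


def _matrix_from_rows(rows: dict) -> cx.ExpressionMatrix:
    n = len(next(iter(rows.values())))
    data = pd.DataFrame(
        {f"s{i}": [v[i] for v in rows.values()] for i in range(n)},
        index=list(rows),
    )
    return cx.ExpressionMatrix(data)


def _meta(samples, diagnosis="case"):
    return cx.SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": samples,
                "diagnosis": [diagnosis] * len(samples),
                "region": ["r1"] * len(samples),
                "dataset": ["d1"] * len(samples),
            }
        )
    )


class TestPairwiseCorrelation:
    def test_identical_and_negated_rows(self):
        base = [1.0, 2.0, 4.0, 3.0, 5.0]
        m = _matrix_from_rows({"a": base, "b": base, "c": [-v for v in base]})
        meta = _meta(m.sample_ids)
        corr = cx.pairwise_correlation(m, cx.GeneList("l", ["a", "b", "c"]), meta)
        frame = corr.to_frame()
        assert frame.loc["a", "b"] == pytest.approx(1.0)
        assert frame.loc["a", "c"] == pytest.approx(-1.0)
        assert corr.p[0, 1] == pytest.approx(0.0)

    def test_absent_genes_dropped(self, planted, gwas_list):
        _, matrix, metadata, _ = planted
        listed = cx.GeneList("l", gwas_list.genes + ["NOT_A_GENE"])
        corr = cx.pairwise_correlation(matrix, listed, metadata)
        assert corr.n_genes == 23
        assert "NOT_A_GENE" not in corr.genes

    def test_zero_variance_gene_flagged_not_fatal(self):
        m = _matrix_from_rows(
            {"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0, 5.0, 5.0, 5.0]}
        )
        meta = _meta(m.sample_ids)
        corr = cx.pairwise_correlation(m, cx.GeneList("l", ["a", "b"]), meta)
        assert corr.zero_variance == ["b"]
        assert corr.r[0, 1] == 0.0

    def test_p_matches_t_transform(self, planted, gwas_list):
        _, matrix, metadata, _ = planted
        corr = cx.pairwise_correlation(matrix, gwas_list, metadata)
        n = corr.n_samples
        r = corr.r[0, 1]
        t = r * np.sqrt((n - 2) / (1 - r**2))
        expected = 2 * stats.t.sf(abs(t), n - 2)
        assert corr.p[0, 1] == pytest.approx(expected, rel=1e-10)


class TestCountSignificantPairs:
    def test_identical_genes_complete_count(self):
        base = [1.0, 2.0, 4.0, 3.0, 5.0, 6.0]
        rows = {f"g{i}": base for i in range(5)}
        m = _matrix_from_rows(rows)
        meta = _meta(m.sample_ids)
        corr = cx.pairwise_correlation(m, cx.GeneList("l", list(rows)), meta)
        assert cx.count_significant_pairs(corr, "alpha", 0.05) == 10
        assert cx.count_significant_pairs(corr, "abs_r", 0.9) == 10

    def test_alpha_threshold_matches_critical_r_at_n16(self):
        # at n=16 (df=14) the two-sided 5% critical |r| is about 0.497
        assert critical_r(0.05, 16) == pytest.approx(0.4973, abs=5e-4)
        rng = np.random.default_rng(0)
        rows = {f"g{i}": list(rng.normal(size=16)) for i in range(10)}
        m = _matrix_from_rows(rows)
        meta = _meta(m.sample_ids)
        corr = cx.pairwise_correlation(m, cx.GeneList("l", list(rows)), meta)
        iu = np.triu_indices(corr.n_genes, 1)
        by_r = int(np.sum(np.abs(corr.r[iu]) > critical_r(0.05, 16)))
        assert cx.count_significant_pairs(corr, "alpha", 0.05) == by_r

    def test_null_count_near_alpha_fraction(self):
        # 23 independent genes: expected significant pairs ~ 0.05 * 253
        counts = []
        for s in range(60):
            rng = np.random.default_rng(s)
            rows = {f"g{i:02d}": list(rng.normal(size=16)) for i in range(23)}
            m = _matrix_from_rows(rows)
            meta = _meta(m.sample_ids)
            corr = cx.pairwise_correlation(m, cx.GeneList("l", list(rows)), meta)
            counts.append(cx.count_significant_pairs(corr, "alpha", 0.05))
        assert np.mean(counts) == pytest.approx(0.05 * 253, rel=0.25)

    def test_invalid_threshold_rejected(self, planted, gwas_list):
        _, matrix, metadata, _ = planted
        corr = cx.pairwise_correlation(matrix, gwas_list, metadata)
        with pytest.raises(ValueError):
            cx.count_significant_pairs(corr, "alpha", 1.5)
        with pytest.raises(ValueError):
            cx.count_significant_pairs(corr, "nope", 0.05)


class TestPermutationPatternTest:
    def test_empirical_p_is_tail_fraction(self):
        null = cx.PermutationNull(
            observed_count=12,
            null_counts=np.array([12] * 3 + [13, 14, 20] + [5] * 994),
            threshold_mode="alpha",
            threshold_value=0.05,
            n_genes=23,
            n_samples=16,
        )
        assert null.empirical_p == pytest.approx(0.006)
        assert null.empirical_p_conservative == pytest.approx(7 / 1001)

    def test_planted_cluster_is_significant(self, planted, gwas_list):
        _, matrix, metadata, _ = planted
        null = cx.permutation_pattern_test(
            matrix, gwas_list, metadata, B=500, seed=10
        )
        assert null.empirical_p <= 0.05
        assert null.B == 500

    def test_invariant_to_sample_and_gene_order(self, planted, gwas_list):
        _, matrix, metadata, _ = planted
        a = cx.permutation_pattern_test(matrix, gwas_list, metadata, B=200, seed=4)
        shuffled_samples = matrix.sample_ids[::-1]
        m2 = matrix.subset_samples(shuffled_samples)
        genes2 = cx.GeneList("rev", gwas_list.genes[::-1])
        b = cx.permutation_pattern_test(m2, genes2, metadata, B=200, seed=4)
        assert a.observed_count == b.observed_count
        assert a.empirical_p == b.empirical_p

    def test_small_universe_rejected(self, toy_matrix, toy_metadata):
        genes = cx.GeneList("l", toy_matrix.gene_ids[:3])
        with pytest.raises(ValueError, match="universe"):
            cx.permutation_pattern_test(
                toy_matrix, genes, toy_metadata, B=100, seed=0
            )

    def test_abs_r_near_one_yields_zero_counts(self, planted, gwas_list):
        _, matrix, metadata, _ = planted
        null = cx.permutation_pattern_test(
            matrix, gwas_list, metadata, mode="abs_r", value=0.999,
            B=100, seed=1,
        )
        assert null.null_counts.max() == 0

    def test_power_grows_with_loading(self):
        # weakly monotone: a stronger planted loading cannot look less
        # significant on average
        ps = {}
        for lam in (0.3, 0.9):
            vals = []
            for s in range(10):
                cfg = cx.SyntheticConfig(
                    n_genes=1000, cluster_loading=lam, pool_genes=0,
                    pathway_genes=0, seed=1000 + s,
                )
                m, meta, truth = cx.simulate_expression(cfg)
                rng = np.random.default_rng(s)
                extras = sorted(
                    str(g) for g in rng.choice(truth.background, 16, replace=False)
                )
                gl = cx.GeneList("l", sorted(truth.cluster) + extras)
                vals.append(
                    cx.permutation_pattern_test(
                        m, gl, meta, B=200, seed=s
                    ).empirical_p
                )
            ps[lam] = np.mean(vals)
        assert ps[0.9] <= ps[0.3]

    def test_json_round_trip(self, planted, gwas_list, tmp_path):
        import json

        _, matrix, metadata, _ = planted
        null = cx.permutation_pattern_test(matrix, gwas_list, metadata,
                                           B=100, seed=2)
        null.write_json(tmp_path / "null.json")
        payload = json.loads((tmp_path / "null.json").read_text())
        assert payload["observed_count"] == null.observed_count
        assert payload["empirical_p"] == null.empirical_p
        assert sum(payload["null_histogram"].values()) == 100
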