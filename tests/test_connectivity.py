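"""Enrichment and connectivity: running-sum ES, tag-KS scores, consensus."""

import numpy as np
import pandas as pd
import pytest

from thanatoset.connectivity import (
    QuerySignature,
    build_query_signature,
    connectivity_pvalue,
    consensus_screen,
    correlation_connectivity,
    ks_connectivity,
    preranked_enrichment,
    scale_scores,
    screen_library,
)


def oracle_es(stat_sorted, hit_mask, weight):
    """Independent oracle: step-by-step running-sum enumeration."""
    n = len(stat_sorted)
    m = int(sum(hit_mask))
    wsum = sum(abs(s) ** weight for s, h in zip(stat_sorted, hit_mask) if h)
    p_hit = p_miss = 0.0
    best = 0.0
    for s, h in zip(stat_sorted, hit_mask):
        if h:
            p_hit += abs(s) ** weight / wsum
        else:
            p_miss += 1.0 / (n - m)
        if abs(p_hit - p_miss) > abs(best):
            best = p_hit - p_miss
    return best


def oracle_ks_tag(v_sorted, n):
    """Independent oracle: exhaustive a/b loop over all j."""
    t = len(v_sorted)
    a = max((j + 1) / t - v_sorted[j] / n for j in range(t))
    b = max(v_sorted[j] / n - j / t for j in range(t))
    return a if a > b else -b


def oracle_connectivity(sig_up_ranks, sig_down_ranks, n):
    ks_up = oracle_ks_tag(sorted(sig_up_ranks), n)
    ks_down = oracle_ks_tag(sorted(sig_down_ranks), n)
    if np.sign(ks_up) == np.sign(ks_down):
        return 0.0
    return (ks_up - ks_down) / 2.0


class TestPrerankedEnrichment:
    def test_ten_gene_toy_matches_enumeration(self):
        profile = pd.Series(np.arange(10, 0, -1, dtype=float), index=[f"G{i}" for i in range(10)])
        panel = ["G0", "G1"]  # the two top statistics
        res = preranked_enrichment(profile, panel, weight=1.0, n_perm=200, seed=1)
        want = oracle_es(profile.to_numpy(), [True, True] + [False] * 8, 1.0)
        assert res.es == pytest.approx(want, abs=1e-12)
        assert res.leading_edge == ["G0", "G1"]

    def test_top_block_weight_zero_is_maximal(self):
        profile = pd.Series(np.arange(20, 0, -1, dtype=float), index=[f"G{i}" for i in range(20)])
        res = preranked_enrichment(profile, [f"G{i}" for i in range(5)], weight=0.0,
                                   n_perm=100, seed=1)
        assert res.es == pytest.approx(1.0)
        # no same-sign permutation magnitude can exceed the maximal ES
        assert res.nes > 0 and res.p < 0.05

    def test_interleaved_panel_is_null(self):
        n = 200
        profile = pd.Series(np.arange(n, 0, -1, dtype=float), index=[f"G{i}" for i in range(n)])
        panel = [f"G{i}" for i in range(0, n, 20)]  # evenly spread
        res = preranked_enrichment(profile, panel, weight=0.0, n_perm=1000, seed=1)
        assert abs(res.es) < 0.3
        assert res.p > 0.1

    def test_random_instances_bounded_and_sign_consistent(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 60))
            prof = pd.Series(rng.normal(size=n), index=[f"G{i}" for i in range(n)])
            m = int(rng.integers(1, n))
            panel = [f"G{i}" for i in rng.choice(n, m, replace=False)]
            res = preranked_enrichment(prof, panel, n_perm=50, seed=2)
            assert -1.0 <= res.es <= 1.0
            assert 0.0 < res.p <= 1.0
            if res.es != 0:
                assert np.sign(res.nes) == np.sign(res.es)

    def test_weight_zero_negation_antisymmetry(self, rng):
        prof = pd.Series(rng.normal(size=40), index=[f"G{i}" for i in range(40)])
        panel = [f"G{i}" for i in rng.choice(40, 6, replace=False)]
        es_fwd = preranked_enrichment(prof, panel, weight=0.0, n_perm=10, seed=3).es
        es_rev = preranked_enrichment(-prof, panel, weight=0.0, n_perm=10, seed=3).es
        assert es_fwd == pytest.approx(-es_rev, abs=1e-12)

    def test_degenerate_overlap_rejected(self):
        prof = pd.Series([3.0, 2.0, 1.0], index=["A", "B", "C"])
        with pytest.raises(ValueError):
            preranked_enrichment(prof, ["X"], n_perm=10, seed=0)
        with pytest.raises(ValueError):
            preranked_enrichment(prof, ["A", "B", "C"], n_perm=10, seed=0)


class TestQuerySignature:
    @staticmethod
    def _deg(genes, logfc):
        return pd.DataFrame({"logFC": logfc}, index=genes)

    def test_sign_split_excludes_zero(self):
        sig = build_query_signature(self._deg(["G1", "G2", "G3"], [2.0, -1.0, 0.0]),
                                    ["G1", "G2", "G3"])
        assert sig.up == frozenset({"G1"})
        assert sig.down == frozenset({"G2"})

    def test_one_sided_signature_rejected(self):
        with pytest.raises(ValueError, match="correlation"):
            build_query_signature(self._deg(["G1", "G2"], [2.0, 1.0]), ["G1", "G2"])

    def test_overlapping_arms_rejected(self):
        with pytest.raises(ValueError):
            QuerySignature(up=frozenset("A"), down=frozenset("A"), logfc=pd.Series(dtype=float))


class TestKsConnectivity:
    def test_extremal_placements(self):
        n, t = 100, 5
        genes = [f"G{i}" for i in range(n)]
        sig = QuerySignature(
            up=frozenset(genes[:t]), down=frozenset(genes[-t:]),
            logfc=pd.Series(dtype=float),
        )
        s = ks_connectivity(sig, genes)
        want = oracle_connectivity(range(1, t + 1), range(n - t + 1, n + 1), n)
        assert s == pytest.approx(want, abs=1e-12)
        assert s > 0.9  # tends to +1 as n grows
        assert ks_connectivity(sig, genes[::-1]) == pytest.approx(-want, abs=1e-12)

    def test_same_sign_arms_score_zero(self):
        n = 50
        genes = [f"G{i}" for i in range(n)]
        sig = QuerySignature(up=frozenset(genes[:3]), down=frozenset(genes[3:6]),
                             logfc=pd.Series(dtype=float))
        assert ks_connectivity(sig, genes) == 0.0

    def test_equals_exhaustive_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(25, 101))
            t_up = int(rng.integers(1, 11))
            t_down = int(rng.integers(1, 11))
            genes = [f"G{i}" for i in range(n)]
            tags = rng.choice(n, t_up + t_down, replace=False)
            sig = QuerySignature(
                up=frozenset(genes[i] for i in tags[:t_up]),
                down=frozenset(genes[i] for i in tags[t_up:]),
                logfc=pd.Series(dtype=float),
            )
            got = ks_connectivity(sig, genes)
            want = oracle_connectivity(
                [i + 1 for i in sorted(tags[:t_up])], [i + 1 for i in sorted(tags[t_up:])], n
            )
            assert got == pytest.approx(want, abs=1e-14)

    def test_swapping_arms_negates_score(self, rng):
        for _ in range(50):
            n = int(rng.integers(12, 80))
            genes = [f"G{i}" for i in range(n)]
            tags = rng.choice(n, 8, replace=False)
            sig = QuerySignature(up=frozenset(genes[i] for i in tags[:4]),
                                 down=frozenset(genes[i] for i in tags[4:]),
                                 logfc=pd.Series(dtype=float))
            swapped = QuerySignature(up=sig.down, down=sig.up, logfc=sig.logfc)
            assert ks_connectivity(sig, genes) == pytest.approx(
                -ks_connectivity(swapped, genes), abs=1e-14
            )

    def test_missing_arm_rejected(self):
        genes = ["G1", "G2", "G3"]
        sig = QuerySignature(up=frozenset({"G1"}), down=frozenset({"Gx"}),
                             logfc=pd.Series(dtype=float))
        with pytest.raises(ValueError):
            ks_connectivity(sig, genes)


class TestScaleScores:
    def test_per_sign_normalization(self):
        raw = pd.Series({"a": 0.5, "b": -0.25, "c": 0.0})
        assert scale_scores(raw).tolist() == [100.0, -100.0, 0.0]

    def test_positive_only(self):
        assert scale_scores(pd.Series({"a": 0.5, "b": 0.25})).tolist() == [100.0, 50.0]

    def test_single_negative_compound(self):
        assert scale_scores(pd.Series({"a": -0.3})).tolist() == [-100.0]

    def test_all_zero_stays_zero(self):
        assert scale_scores(pd.Series({"a": 0.0, "b": 0.0})).tolist() == [0.0, 0.0]


class TestConnectivityPvalue:
    def test_zero_score_has_p_one(self, rng):
        genes = [f"G{i}" for i in range(50)]
        sig = QuerySignature(up=frozenset(genes[:3]), down=frozenset(genes[10:13]),
                             logfc=pd.Series(dtype=float))
        p = connectivity_pvalue(sig, genes, s_obs=0.0, n_perm=200, seed=1)
        assert p == 1.0

    def test_extremal_score_attains_minimum_p(self):
        n, t = 200, 5
        genes = [f"G{i}" for i in range(n)]
        sig = QuerySignature(up=frozenset(genes[:t]), down=frozenset(genes[-t:]),
                             logfc=pd.Series(dtype=float))
        s = ks_connectivity(sig, genes)
        p = connectivity_pvalue(sig, genes, s_obs=s, n_perm=500, seed=1)
        assert p == pytest.approx(1 / 501)


class TestCorrelationConnectivity:
    QUERY = pd.Series(np.linspace(-2, 2, 68), index=[f"G{i}" for i in range(68)])

    def test_perfect_anticorrelation(self):
        rho, p = correlation_connectivity(self.QUERY, -self.QUERY, n_perm=200, seed=1)
        assert rho == pytest.approx(-1.0)
        assert p == pytest.approx(1 / 201)

    def test_perfect_correlation(self):
        rho, _ = correlation_connectivity(self.QUERY, self.QUERY, n_perm=100, seed=1)
        assert rho == pytest.approx(1.0)

    def test_independent_profile_is_null(self):
        rng = np.random.default_rng(1)
        profile = pd.Series(rng.normal(size=68), index=self.QUERY.index)
        rho, p = correlation_connectivity(self.QUERY, profile, n_perm=500, seed=1)
        assert abs(rho) < 0.35
        assert p > 0.05

    def test_too_few_shared_genes_rejected(self):
        q = pd.Series([1.0, 2.0], index=["A", "B"])
        with pytest.raises(ValueError):
            correlation_connectivity(q, q * 2, n_perm=100, seed=0)


class TestConsensusScreen:
    @staticmethod
    def _tables(rows):
        # rows: compound -> [(scaled, p) per dataset]
        names = ["d1", "d2", "d3"]
        tables = {}
        for i, name in enumerate(names):
            tables[name] = pd.DataFrame(
                {
                    "scaled": {c: v[i][0] for c, v in rows.items()},
                    "p": {c: v[i][1] for c, v in rows.items()},
                }
            ).rename_axis("compound")
        return tables

    def test_all_negative_significant_retained(self):
        tables = self._tables({"cpd": [(-80, 0.01), (-50, 0.03), (-60, 0.02)]})
        out = consensus_screen(tables)
        assert out.loc["cpd", "retained"]
        assert out.loc["cpd", "n_datasets_negative_significant"] == 3

    def test_one_positive_dataset_drops_compound(self):
        tables = self._tables({"cpd": [(-80, 0.01), (20, 0.40), (-60, 0.02)]})
        assert not consensus_screen(tables)["retained"].iloc[0]

    def test_single_dataset_rejected(self):
        with pytest.raises(ValueError):
            consensus_screen({"d1": pd.DataFrame({"scaled": [], "p": []})})

    def test_missing_compound_flagged_and_not_retained(self):
        t1 = pd.DataFrame({"scaled": [-50.0], "p": [0.01]}, index=pd.Index(["a"], name="compound"))
        t2 = pd.DataFrame(
            {"scaled": [-50.0, -60.0], "p": [0.01, 0.01]},
            index=pd.Index(["a", "b"], name="compound"),
        )
        out = consensus_screen({"d1": t1, "d2": t2})
        assert out.loc["b", "missing_d1"]
        assert not out.loc["b", "retained"]
        assert out.loc["a", "retained"]
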