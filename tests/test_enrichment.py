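"""Fisher exact, probe->gene mapping, bias-adjusted gene-set tests, BH."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

import methyltraj as mt
from methyltraj.enrichment import (
    ContingencyTable,
    EnrichmentError,
    GeneSetResult,
    read_gmt,
    write_gmt,
    _probability_weight,
)


def fisher_oracle(a, b, c, d):
    """Independent full-enumeration oracle using exact integer binomials."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = math.comb(n, c1)
    probs = []
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        probs.append((x, math.comb(r1, x) * math.comb(n - r1, c1 - x)))
    p_obs = next(p for x, p in probs if x == a)
    total = sum(p for _, p in probs if p <= p_obs)
    return total / denom


class TestFisher:
    def test_tea_tasting_style_value(self):
        p = mt.fisher_exact_two_sided(ContingencyTable(1, 9, 11, 3))
        assert p == pytest.approx(0.0027594, abs=1e-6)

    def test_strong_diagonal_table(self):
        tab = ContingencyTable(8, 2, 2, 8)
        assert tab.odds_ratio() == pytest.approx(16.0)
        assert mt.fisher_exact_two_sided(tab) == pytest.approx(0.023, abs=5e-4)

    def test_symmetric_table_p_one(self):
        assert mt.fisher_exact_two_sided(ContingencyTable(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_transpose_invariance(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(0, 12, size=4)
            if (a + b) * (c + d) * (a + c) * (b + d) == 0:
                continue
            p1 = mt.fisher_exact_two_sided(ContingencyTable(a, b, c, d))
            p2 = mt.fisher_exact_two_sided(ContingencyTable(a, c, b, d))
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            if (a + b) * (c + d) * (a + c) * (b + d) == 0:
                continue
            got = mt.fisher_exact_two_sided(ContingencyTable(a, b, c, d))
            assert got == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-9)

    def test_matches_scipy(self, rng):
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(1, 20, size=4))
            got = mt.fisher_exact_two_sided(ContingencyTable(a, b, c, d))
            assert got == pytest.approx(stats.fisher_exact([[a, b], [c, d]])[1], rel=1e-7)

    def test_degenerate_margin_warns(self):
        with pytest.warns(UserWarning):
            assert mt.fisher_exact_two_sided(ContingencyTable(0, 0, 3, 4)) == 1.0

    def test_zero_cell_odds_ratio(self):
        assert ContingencyTable(0, 5, 3, 4).odds_ratio() == 0.0
        assert ContingencyTable(3, 0, 4, 5).odds_ratio() == np.inf


class TestFeatureEnrichment:
    def _setup(self, rng, n=500, sig_n=100, tilt=False):
        probes = [f"cg{i:08d}" for i in range(n)]
        cats = rng.choice(["Body", "TSS200", "intergenic"], size=n, p=[0.5, 0.2, 0.3])
        ann = pd.DataFrame({"region_group": cats}, index=probes)
        if tilt:
            body = [p for p, c in zip(probes, cats) if c == "Body"]
            other = [p for p, c in zip(probes, cats) if c != "Body"]
            sig = body[: sig_n // 2] + other[: sig_n // 2]
        else:
            sig = list(rng.choice(probes, size=sig_n, replace=False))
        return sig, probes, ann

    def test_margins_consistent(self, rng):
        sig, universe, ann = self._setup(rng)
        for res in mt.feature_enrichment(sig, universe, ann, "region_group"):
            tab = res.counts
            assert tab.a + tab.b == len(sig)
            assert tab.a + tab.b + tab.c + tab.d == len(universe)

    def test_null_odds_near_one(self, rng):
        ors = []
        for _ in range(30):
            sig, universe, ann = self._setup(rng, n=2000, sig_n=400)
            res = mt.feature_enrichment(sig, universe, ann, "region_group")
            ors.append([r.odds_ratio for r in res if r.category == "Body"][0])
        assert abs(np.log(np.mean(ors))) < 0.1

    def test_signature_not_in_universe_rejected(self, rng):
        sig, universe, ann = self._setup(rng)
        with pytest.raises(EnrichmentError):
            mt.feature_enrichment(sig + ["cgXXXX"], universe, ann, "region_group")

    def test_empty_signature_rejected(self, rng):
        _, universe, ann = self._setup(rng)
        with pytest.raises(EnrichmentError):
            mt.feature_enrichment([], universe, ann, "region_group")

    def test_planted_tilt_recovers_log_odds(self):
        # planted odds 2 for Body among associated loci; the estimated
        # cross-product OR should center on 2 across replicates
        logs = []
        for seed in range(15):
            cfg = mt.SimulationConfig(n_probes=5000, frac_associated=0.2, seed=seed)
            _, _, truth = mt.simulate_beta_dataset(cfg)
            ann = mt.simulate_annotation(cfg, truth, region_tilt={"Body": 2.0})
            res = mt.feature_enrichment(truth.associated_loci, list(ann.index),
                                        ann, "region_group")
            body = [r for r in res if r.category == "Body"][0]
            logs.append(np.log(body.odds_ratio))
        se = np.std(logs) / np.sqrt(len(logs))
        assert abs(np.mean(logs) - np.log(2.0)) < 2.5 * se + 0.05


class TestProbeGeneMap:
    def _ann(self, genes):
        return pd.DataFrame({"gene_symbols": genes},
                            index=[f"cg{i:08d}" for i in range(len(genes))])

    def test_distinct_genes(self):
        ann = self._ann(["GA", "GB", "GC"])
        counts = mt.map_probes_to_genes(ann.index, ann)
        assert counts == {"GA": 1, "GB": 1, "GC": 1}

    def test_shared_gene_counted_per_probe(self):
        ann = self._ann(["GA", "GA", ""])
        counts = mt.map_probes_to_genes(ann.index, ann)
        assert counts == {"GA": 2}

    def test_multi_gene_probes_split(self):
        ann = self._ann(["GA;GB", "GB"])
        counts = mt.map_probes_to_genes(ann.index, ann)
        assert counts == {"GA": 1, "GB": 2}

    def test_matches_brute_tally_on_synthetic(self, study):
        counts = mt.map_probes_to_genes(study.beta.index, study.annotation)
        tally = {}
        for val in study.annotation["gene_symbols"]:
            if isinstance(val, str) and val:
                for g in val.split(";"):
                    tally[g] = tally.get(g, 0) + 1
        assert counts == tally


class TestGeneSetEnrichment:
    def test_no_bias_reduces_to_hypergeometric(self):
        counts = {f"g{i}": 4 for i in range(20)}
        sig = [f"g{i}" for i in range(6)]
        sets = {"hit": [f"g{i}" for i in range(8)],
                "miss": [f"g{i}" for i in range(12, 20)]}
        res = {r.set_id: r for r in mt.go_enrichment_bias_adjusted(sig, counts, sets)}
        for sid, r in res.items():
            expect = stats.hypergeom(20, r.n_genes_in_set, 6).sf(r.n_significant_genes - 1)
            assert r.pvalue == pytest.approx(expect, abs=1e-10)

    def test_wallenius_equals_central_at_odds_one(self):
        for M, n, N in [(20, 5, 7), (40, 12, 9), (60, 20, 15)]:
            for x in range(min(n, N) + 1):
                w = stats.nchypergeom_wallenius(M, n, N, 1.0).sf(x - 1)
                h = stats.hypergeom(M, n, N).sf(x - 1)
                assert abs(w - h) < 1e-8

    def test_planted_enrichment_ranks_first(self, rng):
        genes = [f"g{i}" for i in range(200)]
        counts = {g: int(c) for g, c in zip(genes, rng.integers(1, 20, 200))}
        sig = genes[:40]
        sets = {"enriched": genes[:30],
                "random": list(rng.choice(genes, size=30, replace=False))}
        res = {r.set_id: r for r in mt.go_enrichment_bias_adjusted(sig, counts, sets)}
        assert res["enriched"].pvalue < res["random"].pvalue

    def test_empty_significant_gives_p_one(self):
        counts = {f"g{i}": 2 for i in range(10)}
        res = mt.go_enrichment_bias_adjusted([], counts, {"s": ["g0", "g1"]})
        assert all(r.pvalue == 1.0 for r in res)

    def test_pwf_is_function_of_probe_count(self, rng):
        counts = np.array([1, 1, 1, 5, 5, 5, 9, 9, 9], dtype=float)
        sig = rng.random(9) < 0.5
        pwf = _probability_weight(counts, sig, window=3)
        for c in (1.0, 5.0, 9.0):
            assert len(set(np.round(pwf[counts == c], 12))) == 1

    def test_sets_without_overlap_skipped(self):
        counts = {"g0": 1, "g1": 1}
        res = mt.go_enrichment_bias_adjusted(["g0"], counts, {"x": ["zz"]})
        assert res == []


class TestBH:
    def test_single_p(self):
        assert mt.bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_arithmetic(self):
        q = mt.bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal(self):
        q = mt.bh_fdr([0.2] * 5)
        np.testing.assert_allclose(q, 0.2)

    def test_matches_statsmodels(self, rng):
        p = rng.random(200)
        np.testing.assert_allclose(mt.bh_fdr(p),
                                   multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_q_at_least_p(self, rng):
        p = rng.random(50)
        assert (mt.bh_fdr(p) >= p - 1e-12).all()


def test_gmt_round_trip(tmp_path):
    sets = {"pathway_a": ["GA", "GB"], "pathway_b": ["GC"]}
    path = tmp_path / "sets.gmt"
    write_gmt(sets, path)
    assert read_gmt(path) == sets
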