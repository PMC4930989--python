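"""Gst, Mantel and cytonuclear-disequilibrium statistics against oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom, kstest

import coastcline as cc
from coastcline.popgen import exact_test_3x2, multilocus_gst


class TestHeterozygosity:
    def test_hand_example(self):
        h = cc.expected_heterozygosity([[0.8], [0.2]])
        assert h["Hs"][0] == pytest.approx(0.32)
        assert h["Ht"][0] == pytest.approx(0.5)
        gst = (h["Ht"][0] - h["Hs"][0]) / h["Ht"][0]
        assert gst == pytest.approx(0.36)

    def test_identical_populations_give_zero(self):
        h = cc.expected_heterozygosity([[0.5], [0.5]])
        assert (h["Ht"][0] - h["Hs"][0]) / h["Ht"][0] == pytest.approx(0.0)

    def test_fixed_alternative_alleles_give_one(self):
        h = cc.expected_heterozygosity([[1.0], [0.0]])
        assert (h["Ht"][0] - h["Hs"][0]) / h["Ht"][0] == pytest.approx(1.0)


class TestPairwiseGst:
    def test_single_locus_table_matches_per_locus_oracle(self, two_pop_table):
        # frequencies are 0.8 / 0.2 by construction -> raw Nei Gst = 0.36
        pg = cc.pairwise_gst(two_pop_table, n_permutations=0, estimator="nei")
        assert pg.gst.loc["A", "B"] == pytest.approx(0.36, abs=1e-12)

    def test_spreadsheet_style_two_locus_oracle(self):
        # 2 pops x 2 loci, frequencies chosen by hand; multilocus Gst is
        # (sum Ht - sum Hs) / sum Ht computed with plain arithmetic
        G = np.array([[2, 1], [2, 1], [1, 2], [1, 2]])  # pop A: p = .75, .75
        H = np.array([[0, 1], [0, 0], [1, 1], [1, 1]])  # pop B: p = .25, .375
        t = cc.GenotypeTable(
            individual_ids=tuple("abcdwxyz"), sites=("A",) * 4 + ("B",) * 4,
            mitotypes=np.array(["N"] * 8, dtype=object), loci=("L1", "L2"),
            G=np.vstack([G, H]),
            site_coords={"A": (-30, -71), "B": (-40, -73)})
        hs_l, ht_l = [], []
        for pa, pb in ((0.75, 0.25), (0.75, 0.375)):
            hs_l.append((2 * pa * (1 - pa) + 2 * pb * (1 - pb)) / 2)
            pm = (pa + pb) / 2
            ht_l.append(2 * pm * (1 - pm))
        expected = (sum(ht_l) - sum(hs_l)) / sum(ht_l)
        got = multilocus_gst([t.G[:4], t.G[4:]], estimator="nei")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_duplicated_individuals_give_zero(self, two_pop_table):
        G = two_pop_table.G[:5]
        t = cc.GenotypeTable(
            individual_ids=tuple(f"x{i}" for i in range(10)),
            sites=("A",) * 5 + ("B",) * 5,
            mitotypes=np.array(["N"] * 10, dtype=object),
            loci=("L1",), G=np.vstack([G, G]),
            site_coords=dict(two_pop_table.site_coords))
        pg = cc.pairwise_gst(t, n_permutations=0, estimator="nei")
        assert pg.gst.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_pair_is_undefined(self):
        t = cc.GenotypeTable(
            individual_ids=("a", "b"), sites=("A", "B"),
            mitotypes=np.array(["N", "N"], dtype=object), loci=("L1",),
            G=np.array([[2], [2]]), site_coords={"A": (-30, -71), "B": (-40, -73)})
        pg = cc.pairwise_gst(t, n_permutations=0)
        assert math.isnan(pg.gst.loc["A", "B"])

    def test_panmictic_null_gst_near_zero_and_p_uniform(self):
        grid2 = cc.CoastGrid.regular(2, spacing_km=50.0, lat_south=-40.0)
        gsts, pvals = [], []
        for rep in range(20):
            t = cc.simulate_genotypes(grid2, {"N": 15}, 30, 0.0, seed=rep)
            pg = cc.pairwise_gst(t, n_permutations=199, seed=rep)
            gsts.append(pg.results[0].gst)
            pvals.append(pg.results[0].p_value)
        assert abs(np.mean(gsts)) < 0.02
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_permutation_p_is_reproducible(self, two_pop_table):
        a = cc.pairwise_gst(two_pop_table, n_permutations=99, seed=5)
        b = cc.pairwise_gst(two_pop_table, n_permutations=99, seed=5)
        assert a.results[0].p_value == b.results[0].p_value
        assert a.results[0].p_value >= 1 / 100


class TestRegionMeans:
    def _gst_frame(self, sites, values):
        df = pd.DataFrame(np.nan, index=sites, columns=sites)
        for (a, b), v in values.items():
            df.loc[a, b] = df.loc[b, a] = v
        return df

    def test_constant_matrix(self):
        sites = ["p1", "p2", "t1"]
        df = self._gst_frame(sites, {("p1", "p2"): 0.1, ("p1", "t1"): 0.1,
                                     ("p2", "t1"): 0.1})
        out = cc.region_mean_gst(df, {"p1": -25, "p2": -28, "t1": -35})
        assert out["peruvian"] == pytest.approx(0.1)
        assert math.isnan(out["transitional"])  # single site: undefined
        assert math.isnan(out["magellanic"])

    def test_three_site_region_mean(self):
        sites = ["m1", "m2", "m3"]
        df = self._gst_frame(sites, {("m1", "m2"): 0.1, ("m1", "m3"): 0.2,
                                     ("m2", "m3"): 0.3})
        out = cc.region_mean_gst(df, {"m1": -44, "m2": -50, "m3": -53})
        assert out["magellanic"] == pytest.approx(0.2)


class TestMantel:
    def test_affine_relation_gives_r_one(self):
        rng = np.random.default_rng(0)
        n = 8
        x = rng.random((n, n))
        D1 = (x + x.T) / 2
        np.fill_diagonal(D1, 0)
        D2 = 3.0 * D1 + 1.0
        np.fill_diagonal(D2, 0)
        res = cc.mantel(D1, D2, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_four_sites_enumerates_all_24_permutations(self):
        rng = np.random.default_rng(1)
        a = rng.random((4, 4))
        D1 = (a + a.T) / 2
        b = rng.random((4, 4))
        D2 = (b + b.T) / 2
        np.fill_diagonal(D1, 0)
        np.fill_diagonal(D2, 0)
        res = cc.mantel(D1, D2, n_permutations=999, seed=0)
        assert res.exhaustive and res.n_permutations == 24
        # independent brute-force oracle
        iu = np.triu_indices(4, 1)
        r_obs = np.corrcoef(D1[iu], D2[iu])[0, 1]
        hits = 0
        for perm in itertools.permutations(range(4)):
            P = D2[np.ix_(perm, perm)]
            hits += np.corrcoef(D1[iu], P[iu])[0, 1] >= r_obs - 1e-12
        assert res.p == pytest.approx(hits / 24)

    def test_independent_matrices_rarely_significant(self):
        n = 7  # large enough that sampling, not enumeration, is used
        ok = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            a = rng.random((n, n))
            b = rng.random((n, n))
            D1 = (a + a.T) / 2
            D2 = (b + b.T) / 2
            np.fill_diagonal(D1, 0)
            np.fill_diagonal(D2, 0)
            res = cc.mantel(D1, D2, n_permutations=199, seed=seed)
            ok += res.p > 0.05
        assert ok >= 45  # >= 90% of replicates

    def test_ibd_power_within_lineage_partition(self):
        # stepping-stone allele frequencies inside each lineage must yield a
        # positive Mantel r with p < 0.05 in most seeds
        grid12 = cc.CoastGrid.regular(12, spacing_km=100.0, lat_south=-45.0)
        hits = 0
        for seed in range(5):
            t = cc.simulate_genotypes(grid12, {"N": 20, "S": 20}, 50, 0.4,
                                      site_freq_walk_sd=0.3, seed=seed)
            res = cc.mantel_ibd(t, partition="N", n_permutations=10000, seed=seed)
            hits += (res.r > 0) and (res.p < 0.05)
        assert hits >= 4  # >= 80% of seeds

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            cc.mantel(np.array([[0, 1.0], [2.0, 0]]), np.zeros((2, 2)))


def _cnd_table(genos, mitos):
    genos = np.asarray(genos)
    return cc.GenotypeTable(
        individual_ids=tuple(f"i{k}" for k in range(len(genos))),
        sites=("X",) * len(genos),
        mitotypes=np.array(mitos, dtype=object),
        loci=("L1",), G=genos.reshape(-1, 1),
        site_coords={"X": (-41.0, -73.0)})


class TestCytonuclear:
    def test_maximal_disequilibrium_hand_example(self):
        # 5 AA individuals with northern mitotype, 5 aa with southern
        t = _cnd_table([2] * 5 + [0] * 5, ["N"] * 5 + ["S"] * 5)
        (r,) = cc.cytonuclear(t)
        assert r.D == pytest.approx(0.25)
        assert r.D1 == pytest.approx(0.25)
        assert r.D2 == pytest.approx(0.0)
        assert r.D3 == pytest.approx(-0.25)

    def test_independence_limit(self):
        rng = np.random.default_rng(0)
        n = 10_000
        genos = rng.integers(0, 3, size=n)
        mitos = np.where(rng.random(n) < 0.5, "N", "S")
        t = _cnd_table(genos, mitos)
        (r,) = cc.cytonuclear(t, n_mc=2000)
        assert abs(r.D) < 0.01

    def test_allelic_p_matches_hypergeometric_enumeration(self):
        # 8 individuals; brute-force two-sided Fisher by enumerating all 2x2
        # tables with the observed margins
        t = _cnd_table([2, 2, 2, 1, 1, 0, 0, 0],
                       ["N", "N", "S", "N", "S", "S", "S", "N"])
        (r,) = cc.cytonuclear(t)
        gg = np.array([2, 2, 2, 1, 1, 0, 0, 0])
        mm = np.array([m == "N" for m in "NNSNSSSN"])
        aM = int((gg * mm).sum())
        row1 = int(gg.sum())              # A alleles
        col1 = int(2 * mm.sum())          # alleles carried by N-mitotype inds
        N = 16
        rv = hypergeom(N, row1, col1)
        p_obs = rv.pmf(aM)
        p_bf = sum(rv.pmf(k) for k in range(max(0, row1 + col1 - N), min(row1, col1) + 1)
                   if rv.pmf(k) <= p_obs * (1 + 1e-9))
        assert r.p_allelic == pytest.approx(p_bf, abs=1e-9)

    def test_genotypic_enumeration_matches_monte_carlo(self):
        table = np.array([[6, 2], [3, 5], [1, 7]])
        p_enum = exact_test_3x2(table, max_enumeration_total=200)
        p_mc = exact_test_3x2(table, max_enumeration_total=0, n_mc=100_000, seed=0)
        assert p_mc == pytest.approx(p_enum, abs=0.01)

    def test_monomorphic_locus_flagged_untestable(self):
        t = _cnd_table([2, 2, 2, 2], ["N", "N", "S", "S"])
        (r,) = cc.cytonuclear(t)
        assert r.testable is False

    def test_bonferroni_uses_number_of_testable_loci(self):
        rng = np.random.default_rng(3)
        G = rng.integers(0, 3, size=(30, 4))
        G[:, 0] = 2  # untestable locus
        t = cc.GenotypeTable(
            individual_ids=tuple(f"i{k}" for k in range(30)), sites=("X",) * 30,
            mitotypes=np.array(["N"] * 15 + ["S"] * 15, dtype=object),
            loci=("A", "B", "C", "D"), G=G, site_coords={"X": (-41.0, -73.0)})
        results = cc.cytonuclear(t)
        testable = [r for r in results if r.testable]
        assert len(testable) == 3
        for r in testable:
            assert r.p_allelic_adj == pytest.approx(min(1.0, r.p_allelic * 3))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 2), st.booleans()),
                    min_size=4, max_size=40))
    def test_identities_hold_on_random_fixtures(self, pairs):
        genos = [g for g, _ in pairs]
        mitos = ["N" if b else "S" for _, b in pairs]
        t = _cnd_table(genos, mitos)
        (r,) = cc.cytonuclear(t, n_mc=200)
        if not r.testable:
            return
        assert r.D1 + r.D2 + r.D3 == pytest.approx(0.0, abs=1e-12)
        assert r.D == pytest.approx(r.D1 + r.D2 / 2, abs=1e-12)
        assert abs(r.D) <= 0.25 + 1e-12


class TestOverlapReport:
    def _results(self, sig_loci, all_loci):
        out = []
        for loc in all_loci:
            r = cc.CNDResult(locus=loc, n=10)
            r.significant_allelic = loc in sig_loci
            out.append(r)
        return out

    def test_disjoint_sets_give_empty_intersection(self):
        res = self._results({"a"}, ["a", "b", "c"])
        overlap, df = cc.overlap_report(res, {"a": False, "b": True, "c": False})
        assert overlap == []

    def test_flags_subset_of_significant(self):
        res = self._results({"a", "b", "c"}, ["a", "b", "c"])
        overlap, _ = cc.overlap_report(res, {"a": True, "b": True, "c": False})
        assert overlap == ["a", "b"]

    def test_five_locus_fixture_with_two_shared(self):
        res = self._results({"a", "b", "c"}, ["a", "b", "c", "d", "e"])
        flags = {"a": True, "b": True, "c": False, "d": True, "e": False}
        overlap, df = cc.overlap_report(res, flags)
        assert overlap == ["a", "b"]
        assert df["both"].sum() == 2

    def test_label_mismatch_rejected(self):
        res = self._results(set(), ["a"])
        with pytest.raises(ValueError):
            cc.overlap_report(res, {"zzz": True})
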