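"""Estimator correctness against independent brute-force oracles."""
import numpy as np
import pytest
from itertools import permutations

from helipop.core import MISSING, PopulationMap
from helipop.stats import (AmovaResult, amova, bootstrap_pi_ci,
                           clinal_regression, great_circle_distance,
                           mantel_test, per_site_pi, site_pi, weir_cockerham,
                           _amova_components, _allele_matrix,
                           _sq_distance_matrix, EARTH_RADIUS_M)

from conftest import make_table


# ---------------------------------------------------------------------------
# per-site pi
# ---------------------------------------------------------------------------
class TestSitePi:
    @pytest.mark.parametrize("a, n, expected", [
        (2, 4, 4 / 6), (0, 4, 0.0), (1, 4, 3 / 6), (4, 4, 0.0),
    ])
    def test_hand_values(self, a, n, expected):
        assert site_pi(a, n) == pytest.approx(expected)

    def test_too_few_haplotypes_rejected(self):
        with pytest.raises(ValueError):
            site_pi(1, 1)

    def test_mean_invariant_to_site_duplication(self, rng):
        g = rng.integers(0, 2, size=(15, 5, 2)).astype(np.int8)
        t1 = make_table(g)
        t2 = make_table(np.concatenate([g, g]))
        assert per_site_pi(t1).mean() == pytest.approx(per_site_pi(t2).mean())


class TestBootstrapPi:
    def test_degenerate_ci_collapses(self):
        est = bootstrap_pi_ci(np.full(20, 0.25), n_boot=100, seed=0)
        assert est.ci_low == est.ci_high == pytest.approx(0.25)

    def test_seed_determinism(self, rng):
        vals = rng.random(50)
        a = bootstrap_pi_ci(vals, n_boot=200, seed=7)
        b = bootstrap_pi_ci(vals, n_boot=200, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_ci_brackets_mean(self, rng):
        vals = rng.random(100)
        est = bootstrap_pi_ci(vals, n_boot=500, seed=3)
        assert est.ci_low <= est.mean_pi <= est.ci_high

    def test_coverage_of_generating_mean(self):
        """95% percentile CI covers the true mean at roughly nominal rate."""
        rng = np.random.default_rng(99)
        true_mean = 0.2
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            vals = rng.exponential(true_mean, size=120)
            est = bootstrap_pi_ci(vals, n_boot=300, seed=rep)
            hits += est.ci_low <= true_mean <= est.ci_high
        assert 0.89 <= hits / n_rep <= 0.99


# ---------------------------------------------------------------------------
# Weir & Cockerham
# ---------------------------------------------------------------------------
def wc_oracle(geno_by_pop):
    """Literal per-site transcription of the 1984 variance components.

    Independent of the vectorized implementation: explicit scalar loops over
    populations per site, alternate-allele statistics.
    """
    n_sites = geno_by_pop[0].shape[0]
    A, B, C = [], [], []
    for s in range(n_sites):
        ns, ps, hs = [], [], []
        for g in geno_by_pop:
            gt = g[s]
            called = [pair for pair in gt if pair[0] >= 0 and pair[1] >= 0]
            if not called:
                continue
            n_i = len(called)
            p_i = sum(int(a == 1) + int(b == 1) for a, b in called) / (2 * n_i)
            h_i = sum(int((a == 1) != (b == 1)) for a, b in called) / n_i
            ns.append(n_i), ps.append(p_i), hs.append(h_i)
        r = len(ns)
        if r < 2 or sum(ns) <= r:
            A.append(np.nan), B.append(np.nan), C.append(np.nan)
            continue
        nbar = sum(ns) / r
        nc = (sum(ns) - sum(n ** 2 for n in ns) / sum(ns)) / (r - 1)
        pbar = sum(n * p for n, p in zip(ns, ps)) / sum(ns)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / sum(ns)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        A.append(a), B.append(b), C.append(c)
    A, B, C = map(np.array, (A, B, C))
    ok = np.isfinite(A)
    fst = A[ok].sum() / (A[ok] + B[ok] + C[ok]).sum()
    fis = B[ok].sum() / (B[ok] + C[ok]).sum()
    return fst, fis


class TestWeirCockerham:
    def test_fixed_difference_gives_fst_one(self):
        g1 = np.tile([1, 1], (1, 10, 1)).astype(np.int8)
        g0 = np.tile([0, 0], (1, 10, 1)).astype(np.int8)
        t = make_table(np.concatenate([g1, g0], axis=1))
        pm = PopulationMap({f"s{i}": ("p1" if i < 10 else "p2")
                            for i in range(20)})
        fs = weir_cockerham(t, pm)
        assert fs.fst_global == pytest.approx(1.0)
        assert fs.fst_pairwise[0, 1] == pytest.approx(1.0)

    def test_identical_populations_near_zero(self, rng):
        block = rng.integers(0, 2, size=(50, 6, 2)).astype(np.int8)
        t = make_table(np.concatenate([block, block], axis=1))
        pm = PopulationMap({f"s{i}": ("p1" if i < 6 else "p2")
                            for i in range(12)})
        fs = weir_cockerham(t, pm)
        # duplicated blocks have zero among-population variance, so the
        # unbiased estimator goes slightly negative; no positive signal
        assert fs.fst_global <= 0.02

    def test_matches_bruteforce_oracle(self, rng):
        for trial in range(5):
            geno = [rng.integers(0, 2, size=(5, n, 2)).astype(np.int8)
                    for n in (4, 6, 3)]
            # sprinkle missing genotypes
            g0 = geno[0].copy()
            g0[1, 0] = MISSING
            geno[0] = g0
            t = make_table(np.concatenate(geno, axis=1))
            names = ([f"a{i}" for i in range(4)] + [f"b{i}" for i in range(6)]
                     + [f"c{i}" for i in range(3)])
            t.samples = names
            pm = PopulationMap({n: n[0] for n in names})
            fs = weir_cockerham(t, pm)
            fst_o, fis_o = wc_oracle(geno)
            assert fs.fst_global == pytest.approx(fst_o, abs=1e-12)
            assert fs.fis_global == pytest.approx(fis_o, abs=1e-12)

    def test_pairwise_uses_focal_pops_only(self, rng):
        geno = [rng.integers(0, 2, size=(30, 5, 2)).astype(np.int8)
                for _ in range(3)]
        t = make_table(np.concatenate(geno, axis=1))
        names = [f"{p}{i}" for p in "abc" for i in range(5)]
        t.samples = names
        pm = PopulationMap({n: n[0] for n in names})
        fs = weir_cockerham(t, pm)
        fst_o, _ = wc_oracle(geno[:2])
        assert fs.fst_pairwise[0, 1] == pytest.approx(fst_o, abs=1e-12)
        assert np.allclose(fs.fst_pairwise, fs.fst_pairwise.T,
                           equal_nan=True)


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------
class TestMantel:
    def test_affine_invariance_r_is_one(self):
        d1 = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.]])
        d2 = 2 * d1 + 3
        np.fill_diagonal(d2, 0)
        res = mantel_test(d1, d2, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_exhaustive_enumeration_3x3(self):
        d1 = np.array([[0, 1, 4], [1, 0, 2], [4, 2, 0.]])
        d2 = np.array([[0, 2, 5], [2, 0, 1], [5, 1, 0.]])
        v1 = d1[np.triu_indices(3, 1)]
        r_obs = np.corrcoef(v1, d2[np.triu_indices(3, 1)])[0, 1]
        count = 0
        for perm in permutations(range(3)):
            dp = d2[np.ix_(perm, perm)]
            rp = np.corrcoef(v1, dp[np.triu_indices(3, 1)])[0, 1]
            count += rp >= r_obs
        exact_p = count / 6
        res = mantel_test(d1, d2, n_perm=60_000, seed=5)
        assert res.p == pytest.approx(exact_p, abs=0.01)

    def test_constant_matrix_rejected(self):
        d = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError):
            mantel_test(d, d * 0, n_perm=10, seed=0)

    def test_seed_determinism(self, rng):
        d1 = rng.random((6, 6)); d1 = (d1 + d1.T) / 2; np.fill_diagonal(d1, 0)
        d2 = rng.random((6, 6)); d2 = (d2 + d2.T) / 2; np.fill_diagonal(d2, 0)
        a = mantel_test(d1, d2, n_perm=500, seed=9)
        b = mantel_test(d1, d2, n_perm=500, seed=9)
        assert a.p == b.p and a.r == b.r

    def test_r_matches_scikit_bio(self, rng):
        from skbio.stats.distance import mantel as skbio_mantel
        d1 = rng.random((8, 8)); d1 = (d1 + d1.T) / 2; np.fill_diagonal(d1, 0)
        d2 = d1 * 0.5 + rng.random((8, 8)); d2 = (d2 + d2.T) / 2
        np.fill_diagonal(d2, 0)
        ours = mantel_test(d1, d2, n_perm=99, seed=0)
        theirs = skbio_mantel(d1, d2, method="pearson", permutations=0,
                              alternative="greater")
        assert ours.r == pytest.approx(float(theirs[0]), abs=1e-12)


# ---------------------------------------------------------------------------
# geography and regression
# ---------------------------------------------------------------------------
class TestGeography:
    def test_identical_points_zero(self):
        assert great_circle_distance((40, -100), (40, -100)) == 0.0

    def test_one_degree_of_longitude_at_equator(self):
        d = great_circle_distance((0, 0), (0, 1))
        assert d == pytest.approx(2 * np.pi * EARTH_RADIUS_M / 360, rel=1e-9)

    def test_antipodal_points(self):
        d = great_circle_distance((0, 0), (0, 180))
        assert d == pytest.approx(np.pi * EARTH_RADIUS_M, rel=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            great_circle_distance((91, 0), (0, 0))


class TestClinalRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = clinal_regression(2 * x + 1, x)
        assert res.slope == pytest.approx(2.0)
        assert res.r == pytest.approx(1.0)

    def test_f_equals_t_squared(self, rng):
        x = rng.random(16)
        y = 0.5 * x + rng.normal(0, 0.1, 16)
        res = clinal_regression(y, x)
        from scipy import stats as sps
        lr = sps.linregress(x, y)
        assert res.F == pytest.approx((lr.slope / lr.stderr) ** 2, rel=1e-9)
        assert np.sign(res.slope) == np.sign(res.r)
        assert res.df == (1, 14)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            clinal_regression([1, 2, 3], [5, 5, 5])


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------
def amova_oracle_components(alleles, cluster_of, pop_of, ind_of):
    """Direct scalar-loop sums-of-squares partition (per-site ANOVA sums).

    Works on complete data where the distance-based and per-site group-mean
    computations agree exactly; solves the same expectation equations with
    independently computed coefficients.
    """
    n, n_sites = alleles.shape

    def ss_within(groups):
        total = 0.0
        for g in set(groups):
            idx = [i for i in range(n) if groups[i] == g]
            for s in range(n_sites):
                vals = alleles[idx, s]
                total += ((vals - vals.mean()) ** 2).sum()
        return total

    everything = np.zeros(n, dtype=int)
    ss_tot = ss_within(everything)
    ss_wc = ss_within(cluster_of)
    ss_wp = ss_within(pop_of)
    ss_wi = ss_within(ind_of)
    ss = [ss_tot - ss_wc, ss_wc - ss_wp, ss_wp - ss_wi, ss_wi]

    def a_coef(parent, child):
        tot = 0.0
        for g in set(parent):
            members = [i for i in range(n) if parent[i] == g]
            counts = {}
            for i in members:
                counts[child[i]] = counts.get(child[i], 0) + 1
            tot += sum(c ** 2 for c in counts.values()) / len(members)
        return tot

    k_cl, k_pop, k_ind = (len(set(cluster_of)), len(set(pop_of)),
                          len(set(ind_of)))
    sigma4 = ss[3] / (n - k_ind)
    sigma3 = (ss[2] - sigma4 * (k_ind - k_pop)) / (n - a_coef(pop_of, ind_of))
    sigma2 = (ss[1] - sigma4 * (k_pop - k_cl)
              - sigma3 * (a_coef(pop_of, ind_of) - a_coef(cluster_of, ind_of))
              ) / (n - a_coef(cluster_of, pop_of))
    ones = np.zeros(n, dtype=int)
    sigma1 = (ss[0] - sigma4 * (k_cl - 1)
              - sigma3 * (a_coef(cluster_of, ind_of) - a_coef(ones, ind_of))
              - sigma2 * (a_coef(cluster_of, pop_of) - a_coef(ones, pop_of))
              ) / (n - a_coef(ones, cluster_of))
    return sigma1, sigma2, sigma3, sigma4


def three_pop_setup(rng, n_sites=12):
    g = rng.integers(0, 2, size=(n_sites, 9, 2)).astype(np.int8)
    t = make_table(g)
    names = [f"{p}{i}" for p in "abc" for i in range(3)]
    t.samples = names
    pm = PopulationMap({n: n[0] for n in names})
    clusters = {"a": "west", "b": "west", "c": "east"}
    return t, pm, clusters


class TestAmova:
    def test_identical_individuals_zero_components(self):
        g = np.ones((5, 6, 2), dtype=np.int8)
        t = make_table(g)
        pm = PopulationMap({f"s{i}": ("p1" if i < 3 else "p2")
                            for i in range(6)})
        res = amova(t, pm, {"p1": "c1", "p2": "c2"}, n_perm=20, seed=0)
        for lvl, v in res.components.items():
            if np.isfinite(v):
                assert v == pytest.approx(0.0, abs=1e-12)

    def test_fixed_cluster_difference_dominates(self):
        g1 = np.zeros((8, 4, 2), dtype=np.int8)
        g2 = np.ones((8, 4, 2), dtype=np.int8)
        t = make_table(np.concatenate([g1, g2], axis=1))
        pm = PopulationMap({f"s{i}": f"p{i // 2}" for i in range(8)})
        clusters = {"p0": "c1", "p1": "c1", "p2": "c2", "p3": "c2"}
        res = amova(t, pm, clusters, n_perm=50, seed=1)
        assert res.percentages["between_clusters"] == pytest.approx(100, abs=1)

    def test_matches_bruteforce_oracle(self, rng):
        t, pm, clusters = three_pop_setup(rng)
        res = amova(t, pm, clusters, n_perm=10, seed=0)
        idx = np.arange(9)
        alleles = _allele_matrix(t, idx)
        ind_of = np.repeat(np.arange(9), 2)
        pop_of = np.repeat([0, 0, 0, 1, 1, 1, 2, 2, 2], 2)
        cl_of = np.repeat([0, 0, 0, 0, 0, 0, 1, 1, 1], 2)
        s1, s2, s3, s4 = amova_oracle_components(alleles, cl_of, pop_of,
                                                 ind_of)
        assert res.components["between_clusters"] == pytest.approx(s1,
                                                                   abs=1e-9)
        assert res.components["among_pops_within_clusters"] == \
            pytest.approx(s2, abs=1e-9)
        assert res.components["among_individuals_within_pops"] == \
            pytest.approx(s3, abs=1e-9)
        assert res.components["within_individuals"] == pytest.approx(s4,
                                                                     abs=1e-9)

    def test_percentages_sum_to_100(self, rng):
        t, pm, clusters = three_pop_setup(rng)
        res = amova(t, pm, clusters, n_perm=10, seed=0)
        assert sum(res.percentages.values()) == pytest.approx(100, abs=1e-6)

    def test_single_cluster_level_not_estimable(self, rng):
        t, pm, _ = three_pop_setup(rng)
        res = amova(t, pm, {"a": "x", "b": "x", "c": "x"}, n_perm=10, seed=0)
        assert np.isnan(res.components["between_clusters"])
        assert np.isfinite(res.components["among_pops_within_clusters"])

    def test_shuffled_labels_destroy_significance(self, rng):
        # structured data: two pop-blocks fixed for alternate alleles plus
        # noise; shuffling individuals among pops should make the
        # among-population permutation p non-significant in most shuffles
        g1 = np.zeros((10, 4, 2), dtype=np.int8)
        g2 = np.ones((10, 4, 2), dtype=np.int8)
        noise = rng.integers(0, 2, size=(10, 8, 2)).astype(np.int8)
        g = np.concatenate([g1, g2], axis=1) ^ (noise & 0)
        g[:3] = rng.integers(0, 2, size=(3, 8, 2))
        from conftest import make_table as mk
        t = mk(g)
        names = [f"p{i//4}_{i}" for i in range(8)]
        t.samples = names
        clusters = {"0": "c", "1": "c"}
        ns = 0
        n_shuffles = 10
        for k in range(n_shuffles):
            perm = rng.permutation(8)
            pm = PopulationMap({names[perm[i]]: str(i // 4)
                                for i in range(8)})
            res = amova(t, pm, clusters, n_perm=99, seed=k)
            if res.p_values["among_pops_within_clusters"] > 0.05:
                ns += 1
        assert ns >= 8
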