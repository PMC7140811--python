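"""Diversity, differentiation, isolation-by-distance and AMOVA statistics.

Implements the classical estimators used to describe geographic structure in
a wild panel: per-site nucleotide diversity pi with bootstrap confidence
intervals, Weir & Cockerham (1984) ratio-of-sums F_ST and F_IS, a seeded
permutation Mantel test, haversine great-circle distances, OLS clinal
regression, and a four-level hierarchical AMOVA (clusters > populations >
individuals > alleles) on squared allele-difference distances.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core import PopulationMap, VariantTable

EARTH_RADIUS_M = 6_378_137.0


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------
@dataclass
class DiversityEstimate:
    mean_pi: float
    ci_low: float
    ci_high: float
    n_sites: int
    n_boot: int


def site_pi(allele_count: int, n_called: int) -> float:
    """Per-site nucleotide diversity a*b / C(n, 2) for a biallelic site.

    ``allele_count`` is the count of either allele among ``n_called``
    haplotypes; monomorphic sites give 0.
    """
    if n_called < 2:
        raise ValueError("site pi requires at least 2 called haplotypes")
    a = allele_count
    b = n_called - a
    return 2.0 * a * b / (n_called * (n_called - 1))


def per_site_pi(table: VariantTable, sample_idx=None) -> np.ndarray:
    """Vector of per-site pi over called haplotypes; sites with <2 calls are
    dropped (count reported via the returned array's length)."""
    alt, n = table.allele_counts(allele=1, sample_idx=sample_idx)
    ok = n >= 2
    a = alt[ok].astype(float)
    nn = n[ok].astype(float)
    return 2.0 * a * (nn - a) / (nn * (nn - 1))


def bootstrap_pi_ci(pi_values, n_boot: int = 1000, seed: int = 0,
                    alpha: float = 0.05) -> DiversityEstimate:
    """Percentile bootstrap CI for mean per-site pi (resampling sites)."""
    pi_values = np.asarray(pi_values, dtype=float)
    if pi_values.size == 0:
        raise ValueError("no per-site pi values supplied")
    rng = np.random.default_rng(seed)
    n = pi_values.size
    means = np.empty(n_boot)
    for b in range(n_boot):
        means[b] = pi_values[rng.integers(0, n, n)].mean()
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return DiversityEstimate(mean_pi=float(pi_values.mean()), ci_low=float(lo),
                             ci_high=float(hi), n_sites=n, n_boot=n_boot)


# ---------------------------------------------------------------------------
# Weir & Cockerham F-statistics
# ---------------------------------------------------------------------------
@dataclass
class FStatistics:
    fst_global: float
    fis_global: float
    fst_pairwise: np.ndarray
    populations: list = field(default_factory=list)


def _wc_components(geno_by_pop):
    """Per-site Weir & Cockerham (1984) variance components a, b, c.

    ``geno_by_pop``: list of (n_sites, n_i, 2) genotype arrays, one per
    population.  Returns per-site arrays (a, b, c) for the alternate allele
    (components for the two alleles of a biallelic site are identical).
    Sites where fewer than two populations have >= 1 called individual get
    NaN and are excluded from the sums by the caller.
    """
    n_sites = geno_by_pop[0].shape[0]
    r_max = len(geno_by_pop)
    n_mat = np.zeros((n_sites, r_max))      # called diploids per pop
    p_mat = np.zeros((n_sites, r_max))      # alt-allele frequency per pop
    h_mat = np.zeros((n_sites, r_max))      # observed het frequency per pop
    for k, g in enumerate(geno_by_pop):
        called = np.all(g >= 0, axis=2)
        n_mat[:, k] = called.sum(axis=1)
        alt = ((g == 1) & (g >= 0)).sum(axis=2) * called
        with np.errstate(invalid="ignore", divide="ignore"):
            p_mat[:, k] = alt.sum(axis=1) / (2 * n_mat[:, k])
            h_mat[:, k] = ((alt == 1) & called).sum(axis=1) / n_mat[:, k]

    valid = n_mat >= 1
    r = valid.sum(axis=1).astype(float)
    n_tot = np.where(valid, n_mat, 0.0).sum(axis=1)
    ok = (r >= 2) & (n_tot > r)  # need >1 pop and nbar > 1 overall
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_tot / r
        nc = (n_tot - (np.where(valid, n_mat, 0.0) ** 2).sum(axis=1) / n_tot) \
            / (r - 1)
        pbar = np.where(valid, n_mat * p_mat, 0.0).sum(axis=1) / n_tot
        s2 = np.where(valid, n_mat * (p_mat - pbar[:, None]) ** 2, 0.0) \
            .sum(axis=1) / ((r - 1) * nbar)
        hbar = np.where(valid, n_mat * h_mat, 0.0).sum(axis=1) / n_tot

        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
    a = np.where(ok, a, np.nan)
    b = np.where(ok, b, np.nan)
    c = np.where(ok, c, np.nan)
    return a, b, c


def _ratio_of_sums(a, b, c):
    ok = np.isfinite(a)
    sa, sb, sc = a[ok].sum(), b[ok].sum(), c[ok].sum()
    denom = sa + sb + sc
    fst = sa / denom if denom != 0 else np.nan
    fis = sb / (sb + sc) if (sb + sc) != 0 else np.nan
    return fst, fis


def weir_cockerham(table: VariantTable, popmap: PopulationMap) -> FStatistics:
    """Global and pairwise Weir-Cockerham estimates (ratio of sums over sites).

    Global F_ST = sum(a) / sum(a+b+c) and F_IS = sum(b) / sum(b+c) over all
    sites and populations; pairwise F_ST re-estimates components from the two
    focal populations only.  Small negative estimates are legitimate sampling
    outcomes of the estimator and are reported as-is.
    """
    pops = popmap.populations
    geno = [table.genotypes[:, popmap.sample_indices(table, p), :]
            for p in pops]
    for p, g in zip(pops, geno):
        if g.shape[1] < 2:
            raise ValueError(f"population {p!r} has fewer than 2 samples")
    a, b, c = _wc_components(geno)
    fst, fis = _ratio_of_sums(a, b, c)

    n = len(pops)
    pw = np.full((n, n), np.nan)
    np.fill_diagonal(pw, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            ai, bi, ci = _wc_components([geno[i], geno[j]])
            if not np.isfinite(ai).any():
                continue  # undefined pair (e.g. all-missing)
            f, _ = _ratio_of_sums(ai, bi, ci)
            pw[i, j] = pw[j, i] = f
    return FStatistics(fst_global=float(fst), fis_global=float(fis),
                       fst_pairwise=pw, populations=list(pops))


# ---------------------------------------------------------------------------
# Mantel test and geography
# ---------------------------------------------------------------------------
@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    alternative: str = "greater"


def _offdiag_upper(mat):
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel_test(d1, d2, n_perm: int = 10_000, seed: int = 0,
                alternative: str = "greater") -> MantelResult:
    """Mantel matrix correlation with simultaneous row/column permutation.

    r is the Pearson correlation of the upper off-diagonal triangles; the
    permutation p-value is (1 + #{r* at least as extreme}) / (1 + n_perm).
    ``alternative``: 'greater' (isolation by distance: positive association),
    'less', or 'two-sided'.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape or d1.ndim != 2 or d1.shape[0] != d1.shape[1]:
        raise ValueError("need two square matrices of equal order")
    if not (np.allclose(d1, d1.T) and np.allclose(d2, d2.T)):
        raise ValueError("distance matrices must be symmetric")
    v1 = _offdiag_upper(d1)
    if v1.std() == 0 or _offdiag_upper(d2).std() == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    n = d1.shape[0]
    r_obs = float(np.corrcoef(v1, _offdiag_upper(d2))[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = np.corrcoef(v1, _offdiag_upper(d2[np.ix_(perm, perm)]))[0, 1]
        if alternative == "greater":
            count += r_perm >= r_obs
        elif alternative == "less":
            count += r_perm <= r_obs
        else:
            count += abs(r_perm) >= abs(r_obs)
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm,
                        alternative=alternative)


def great_circle_distance(coord1, coord2) -> float:
    """Haversine distance in meters between (lat, lon) points in degrees."""
    lat1, lon1 = coord1
    lat2, lon2 = coord2
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise ValueError(f"coordinates out of range: ({lat}, {lon})")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2 - lon1)
    h = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(h)))


def geographic_distance_matrix(popmap: PopulationMap, pops=None) -> np.ndarray:
    pops = list(pops) if pops is not None else popmap.populations
    n = len(pops)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = great_circle_distance(
                popmap.coords[pops[i]], popmap.coords[pops[j]])
    return d


# ---------------------------------------------------------------------------
# clinal regression
# ---------------------------------------------------------------------------
@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    F: float
    p: float
    df: tuple


def clinal_regression(values, axis_values) -> RegressionResult:
    """OLS of a per-population statistic on one coordinate axis.

    F = t^2 of the slope with (1, n-2) degrees of freedom.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(axis_values, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 matched populations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the predictor")
    res = sps.linregress(x, y)
    t = res.slope / res.stderr if res.stderr > 0 else np.inf
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r=float(res.rvalue), F=float(t ** 2),
                            p=float(res.pvalue), df=(1, len(x) - 2))


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------
@dataclass
class AmovaResult:
    components: dict
    percentages: dict
    p_values: dict
    df: dict

    LEVELS = ("between_clusters", "among_pops_within_clusters",
              "among_individuals_within_pops", "within_individuals")


def _allele_matrix(table: VariantTable, sample_idx):
    """(2*n_ind, n_sites) pseudo-haplotype allele matrix, NaN for missing.

    Phase is irrelevant: squared allele-difference distances are additive
    per site.
    """
    g = table.genotypes[:, sample_idx, :].astype(float)  # (sites, ind, 2)
    g[g < 0] = np.nan
    n_sites, n_ind, _ = g.shape
    return g.transpose(1, 2, 0).reshape(2 * n_ind, n_sites)


def _sq_distance_matrix(alleles):
    """Pairwise squared distance = count of differing alleles over shared
    called sites (pairwise-complete)."""
    n = alleles.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = (alleles[i] != alleles) & ~np.isnan(alleles[i]) \
            & ~np.isnan(alleles)
        d[i] = diff.sum(axis=1)
    return d


def _ssd_within(d2, groups):
    """Sum over groups of (1/n_g) * sum_{i<j in g} d2_ij."""
    total = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        sub = d2[np.ix_(idx, idx)]
        total += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return total


def _amova_components(d2, cluster_of, pop_of, ind_of):
    """Variance components of the 4-level nested partition.

    Levels (top to bottom): clusters, populations, individuals, alleles.
    Unbalanced-design coefficients follow the standard nested ANOVA
    expectation E[SS_l] = sigma_l^2 (N - A_{l-1}^l) +
    sum_{m>l} sigma_m^2 (A_l^m - A_{l-1}^m) with
    A_l^m = sum_{groups g at level l} sum_{subgroups h in g at level m}
    n_h^2 / n_g; solved top-down from the deepest level.
    """
    n = d2.shape[0]
    everything = np.zeros(n, dtype=int)

    def ssd(groups):
        return _ssd_within(d2, groups)

    ss_tot = ssd(everything)
    ss_wc = ssd(cluster_of)
    ss_wp = ssd(pop_of)
    ss_wi = ssd(ind_of)
    ss = {  # among-level sums of squares
        "between_clusters": ss_tot - ss_wc,
        "among_pops_within_clusters": ss_wc - ss_wp,
        "among_individuals_within_pops": ss_wp - ss_wi,
        "within_individuals": ss_wi,
    }

    def a_coef(parent, child):
        """A_parent^child = sum_g sum_{h in g} n_h^2 / n_g."""
        total = 0.0
        for g in np.unique(parent):
            in_g = parent == g
            n_g = in_g.sum()
            _, counts = np.unique(child[in_g], return_counts=True)
            total += (counts.astype(float) ** 2).sum() / n_g
        return total

    k_cl = len(np.unique(cluster_of))
    k_pop = len(np.unique(pop_of))
    k_ind = len(np.unique(ind_of))
    df = {
        "between_clusters": k_cl - 1,
        "among_pops_within_clusters": k_pop - k_cl,
        "among_individuals_within_pops": k_ind - k_pop,
        "within_individuals": n - k_ind,
    }

    a01 = a_coef(everything, cluster_of)
    a02 = a_coef(everything, pop_of)
    a03 = a_coef(everything, ind_of)
    a12 = a_coef(cluster_of, pop_of)
    a13 = a_coef(cluster_of, ind_of)
    a23 = a_coef(pop_of, ind_of)

    comp = {}
    # deepest level first
    comp["within_individuals"] = (
        ss["within_individuals"] / df["within_individuals"]
        if df["within_individuals"] > 0 else np.nan)

    lvl = "among_individuals_within_pops"
    if df[lvl] > 0:
        comp[lvl] = ((ss[lvl] - comp["within_individuals"] * df[lvl])
                     / (n - a23))
    else:
        comp[lvl] = np.nan

    lvl = "among_pops_within_clusters"
    if df[lvl] > 0:
        comp[lvl] = ((ss[lvl]
                      - comp["within_individuals"] * df[lvl]
                      - comp["among_individuals_within_pops"] * (a23 - a13))
                     / (n - a12))
    else:
        comp[lvl] = np.nan

    lvl = "between_clusters"
    if df[lvl] > 0:
        comp[lvl] = ((ss[lvl]
                      - comp["within_individuals"] * df[lvl]
                      - comp["among_individuals_within_pops"] * (a13 - a03)
                      - comp["among_pops_within_clusters"] * (a12 - a02))
                     / (n - a01))
    else:
        comp[lvl] = np.nan
    return comp, df


def amova(table: VariantTable, popmap: PopulationMap, clusters: dict,
          n_perm: int = 1000, seed: int = 0) -> AmovaResult:
    """Four-level AMOVA on squared allele-difference distances.

    ``clusters`` maps population -> cluster label (e.g. from an external
    population-clustering analysis).  Components are reported untruncated
    (negative estimates preserved); percentages are component / total * 100.
    Permutation p-values shuffle labels at the tested level: whole
    populations among clusters (between_clusters), individuals among
    populations within clusters (among_pops...), and individuals among
    populations globally (among_individuals...).
    """
    samples, pops_of_samples = [], []
    for s, p in popmap.assignments.items():
        if s in table.samples:
            samples.append(s)
            pops_of_samples.append(p)
    for p in set(pops_of_samples):
        if p not in clusters:
            raise ValueError(f"population {p!r} missing a cluster label")
    idx = np.array([table.samples.index(s) for s in samples])
    alleles = _allele_matrix(table, idx)
    d2 = _sq_distance_matrix(alleles)

    n_ind = len(samples)
    ind_of = np.repeat(np.arange(n_ind), 2)
    pop_names = sorted(set(pops_of_samples))
    pop_code = {p: i for i, p in enumerate(pop_names)}
    pop_of_ind = np.array([pop_code[p] for p in pops_of_samples])
    pop_of = np.repeat(pop_of_ind, 2)
    cl_names = sorted({clusters[p] for p in pop_names})
    cl_code = {c: i for i, c in enumerate(cl_names)}
    cl_of_pop = np.array([cl_code[clusters[p]] for p in pop_names])
    cluster_of = cl_of_pop[pop_of]

    comp, df = _amova_components(d2, cluster_of, pop_of, ind_of)
    total = sum(v for v in comp.values() if np.isfinite(v))
    pct = {k: (100.0 * v / total if np.isfinite(v) else np.nan)
           for k, v in comp.items()}

    rng = np.random.default_rng(seed)
    exceed = {k: 0 for k in AmovaResult.LEVELS[:3]}
    for _ in range(n_perm):
        # whole pops among clusters
        cl_perm_pop = cl_of_pop[rng.permutation(len(pop_names))]
        c1, _ = _amova_components(d2, cl_perm_pop[pop_of], pop_of, ind_of)
        if np.isfinite(c1["between_clusters"]) and \
                c1["between_clusters"] >= comp["between_clusters"]:
            exceed["between_clusters"] += 1
        # individuals among pops (within clusters) for the pop level
        perm_pop_ind = pop_of_ind.copy()
        for c in np.unique(cl_of_pop):
            sel = np.flatnonzero(cl_of_pop[pop_of_ind] == c)
            perm_pop_ind[sel] = pop_of_ind[sel][rng.permutation(len(sel))]
        pp = np.repeat(perm_pop_ind, 2)
        c2, _ = _amova_components(d2, cl_of_pop[pp], pp, ind_of)
        if np.isfinite(c2["among_pops_within_clusters"]) and \
                c2["among_pops_within_clusters"] >= \
                comp["among_pops_within_clusters"]:
            exceed["among_pops_within_clusters"] += 1
        # individuals among pops globally for the individual level
        perm_ind = rng.permutation(n_ind)
        pp = np.repeat(pop_of_ind[perm_ind], 2)
        # note alleles stay with their individual
        c3, _ = _amova_components(d2, cl_of_pop[pp], pp, ind_of)
        if np.isfinite(c3["among_individuals_within_pops"]) and \
                c3["among_individuals_within_pops"] >= \
                comp["among_individuals_within_pops"]:
            exceed["among_individuals_within_pops"] += 1
    pvals = {k: (1 + v) / (1 + n_perm) for k, v in exceed.items()}
    pvals["within_individuals"] = np.nan
    return AmovaResult(components=comp, percentages=pct, p_values=pvals, df=df)
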