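"""Differentiation and cytonuclear-disequilibrium statistics.

Implements, from first principles over biallelic genotype tables:

* Nei's gene-differentiation coefficient Gst = (Ht - Hs) / Ht, both the
  raw frequency-based decomposition and the Nei–Chesser small-sample
  corrected estimator, with data-by-location permutation p-values;
* region means of pairwise Gst over latitude bands;
* Mantel correlation between distance and differentiation matrices, with
  permutation (or exhaustive) p-values, optionally within a mitotype
  partition (isolation by distance inside each lineage);
* Asmussen–Basten cytonuclear disequilibria: allelic D and genotypic
  D1/D2/D3 with exact association tests (Fisher 2x2 for alleles;
  Freeman–Halton 3x2 for genotype-by-mitotype, exhaustively enumerated
  for small tables, seeded Monte Carlo above a size cutoff) and plain
  Bonferroni correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import fisher_exact

from .core import MISSING, GenotypeTable, haversine_km

# ---------------------------------------------------------------------------
# heterozygosity and Gst


def expected_heterozygosity(freqs, sample_sizes=None, het_obs=None):
    """Per-locus Hs and Ht from population allele frequencies.

    ``freqs`` is (n_pops, n_loci) reference-allele frequencies (NaN where a
    population has no data at a locus).  Returns a dict with the raw Nei
    decomposition (``Hs``, ``Ht``) and, when per-population genotyped
    sample sizes and observed-heterozygote frequencies are supplied, the
    Nei–Chesser corrected estimators (``Hs_corrected``, ``Ht_corrected``).
    """
    p = np.atleast_2d(np.asarray(freqs, dtype=float))
    q = 1.0 - p
    hs = np.nanmean(2.0 * p * q, axis=0)
    pbar = np.nanmean(p, axis=0)
    ht = 2.0 * pbar * (1.0 - pbar)
    out = {"Hs": hs, "Ht": ht}
    if sample_sizes is not None and het_obs is not None:
        n = np.atleast_2d(np.asarray(sample_sizes, dtype=float))
        ho = np.atleast_2d(np.asarray(het_obs, dtype=float))
        s = p.shape[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            n_harm = s / np.nansum(1.0 / n, axis=0)
            ho_bar = np.nanmean(ho, axis=0)
            sum_p2 = np.nanmean(p ** 2 + q ** 2, axis=0)
            hs_c = n_harm / (n_harm - 1.0) * (1.0 - sum_p2 - ho_bar / (2.0 * n_harm))
            ht_c = 1.0 - (pbar ** 2 + (1.0 - pbar) ** 2) + hs_c / (n_harm * s) - ho_bar / (2.0 * n_harm * s)
        out["Hs_corrected"] = hs_c
        out["Ht_corrected"] = ht_c
    return out


def _pop_locus_stats(G: np.ndarray):
    """Allele freq, genotyped n and observed-het freq per locus for one population."""
    ok = G != MISSING
    n = ok.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p = np.where(ok, G, 0).sum(axis=0) / (2.0 * n)
        ho = ((G == 1) & ok).sum(axis=0) / n
    p[n == 0] = np.nan
    ho[n == 0] = np.nan
    return p, n, ho


def multilocus_gst(G_by_pop, estimator: str = "nei_chesser") -> float:
    """Multilocus Gst = (sum Ht - sum Hs) / sum Ht over usable loci.

    Loci where any population has zero genotyped individuals are skipped;
    NaN is returned when no locus retains any total diversity.
    """
    stats = [_pop_locus_stats(G) for G in G_by_pop]
    p = np.vstack([s[0] for s in stats])
    n = np.vstack([s[1] for s in stats])
    ho = np.vstack([s[2] for s in stats])
    usable = (n > 0).all(axis=0)
    if not usable.any():
        return float("nan")
    h = expected_heterozygosity(p[:, usable], n[:, usable], ho[:, usable])
    if estimator == "nei":
        hs, ht = h["Hs"], h["Ht"]
    elif estimator == "nei_chesser":
        hs, ht = h["Hs_corrected"], h["Ht_corrected"]
    else:
        raise ValueError("estimator must be 'nei' or 'nei_chesser'")
    denom = np.nansum(ht)
    if not denom > 0:
        return float("nan")
    return float(np.nansum(ht - hs) / denom)


@dataclass
class GstResult:
    """Pairwise differentiation between two sites."""

    site_a: str
    site_b: str
    gst: float
    p_value: float | None = None
    n_permutations: int = 0


@dataclass
class PairwiseGst:
    """All pairwise Gst values with permutation p-values."""

    gst: pd.DataFrame
    p_value: pd.DataFrame
    results: list = field(default_factory=list)
    estimator: str = "nei_chesser"


def pairwise_gst(table: GenotypeTable, n_permutations: int = 1000, seed: int = 0,
                 estimator: str = "nei_chesser") -> PairwiseGst:
    """Pairwise multilocus Gst over all site pairs.

    Significance comes from data-by-location permutations: individuals of
    the two sites are pooled and reassigned at the observed sample sizes;
    p = (1 + #{permuted Gst >= observed}) / (n_permutations + 1).
    """
    sites = table.site_labels()
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    site_arr = np.asarray(table.sites, dtype=object)
    rng = np.random.default_rng(seed)
    gst_m = pd.DataFrame(np.nan, index=list(sites), columns=list(sites))
    p_m = pd.DataFrame(np.nan, index=list(sites), columns=list(sites))
    results = []
    for a, b in itertools.combinations(sites, 2):
        ra = np.nonzero(site_arr == a)[0]
        rb = np.nonzero(site_arr == b)[0]
        obs = multilocus_gst([table.G[ra], table.G[rb]], estimator)
        pval = None
        if n_permutations > 0 and np.isfinite(obs):
            pool = table.G[np.concatenate([ra, rb])]
            na = ra.size
            hits = 0
            for _ in range(n_permutations):
                perm = rng.permutation(pool.shape[0])
                g = multilocus_gst([pool[perm[:na]], pool[perm[na:]]], estimator)
                hits += np.isfinite(g) and g >= obs - 1e-12
            pval = (1 + hits) / (n_permutations + 1)
        gst_m.loc[a, b] = gst_m.loc[b, a] = obs
        if pval is not None:
            p_m.loc[a, b] = p_m.loc[b, a] = pval
        results.append(GstResult(a, b, obs, pval, n_permutations))
    return PairwiseGst(gst_m, p_m, results, estimator)


def region_mean_gst(gst: pd.DataFrame, site_latitudes,
                    boundaries: tuple = (-30.0, -42.0)) -> dict:
    """Mean pairwise Gst within latitude regions.

    Default regions follow the Chilean biogeographic provinces: Peruvian
    north of 30°S, transitional between 30 and 42°S, Magellanic south of
    42°S.  Regions with fewer than 2 sites (or no defined pair) get NaN.
    """
    north, south = max(boundaries), min(boundaries)
    lats = dict(site_latitudes)
    regions = {"peruvian": [], "transitional": [], "magellanic": []}
    for s in gst.index:
        lat = lats[s]
        if lat > north:
            regions["peruvian"].append(s)
        elif lat >= south:
            regions["transitional"].append(s)
        else:
            regions["magellanic"].append(s)
    out = {}
    for name, members in regions.items():
        vals = [gst.loc[a, b] for a, b in itertools.combinations(members, 2)
                if np.isfinite(gst.loc[a, b])]
        out[name] = float(np.mean(vals)) if vals else float("nan")
    return out


# ---------------------------------------------------------------------------
# Mantel


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    seed: int | None = None
    exhaustive: bool = False


def _offdiag_r(D1: np.ndarray, D2: np.ndarray) -> float:
    iu = np.triu_indices_from(D1, k=1)
    x, y = D1[iu], D2[iu]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def mantel(D1, D2, n_permutations: int = 999, seed: int = 0) -> MantelResult:
    """Mantel correlation between two symmetric matrices.

    r is the Pearson correlation over off-diagonal upper-triangle pairs;
    p is one-tailed (permuted r >= observed), obtained by jointly permuting
    the rows and columns of the second matrix.  When the number of sites is
    small enough that all n! relabellings fit within ``n_permutations``,
    the permutation distribution is enumerated exhaustively instead of
    sampled.
    """
    A = np.asarray(D1, dtype=float)
    B = np.asarray(D2, dtype=float)
    if isinstance(D1, pd.DataFrame) and isinstance(D2, pd.DataFrame):
        B = D2.loc[D1.index, D1.columns].to_numpy(dtype=float)
        A = D1.to_numpy(dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square with matching shape")
    if not (np.allclose(A, A.T, equal_nan=True) and np.allclose(B, B.T, equal_nan=True)):
        raise ValueError("matrices must be symmetric")
    n = A.shape[0]
    r_obs = _offdiag_r(A, B)
    if not np.isfinite(r_obs):
        return MantelResult(r_obs, float("nan"), 0, seed)
    if math.factorial(n) <= max(n_permutations, 24):
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            r = _offdiag_r(A, B[np.ix_(perm, perm)])
            if np.isfinite(r):
                total += 1
                hits += r >= r_obs - 1e-12
        return MantelResult(r_obs, hits / total, total, seed, exhaustive=True)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r = _offdiag_r(A, B[np.ix_(perm, perm)])
        hits += np.isfinite(r) and r >= r_obs - 1e-12
    return MantelResult(r_obs, (1 + hits) / (n_permutations + 1), n_permutations, seed)


def distance_matrix(site_coords, sites) -> pd.DataFrame:
    """Great-circle (haversine) distances in km between the named sites."""
    lats = np.array([site_coords[s][0] for s in sites])
    lons = np.array([site_coords[s][1] for s in sites])
    D = haversine_km(lats[:, None], lons[:, None], lats[None, :], lons[None, :])
    return pd.DataFrame(D, index=list(sites), columns=list(sites))


def mantel_ibd(table: GenotypeTable, partition: str | None = None,
               n_permutations: int = 999, seed: int = 0,
               estimator: str = "nei_chesser") -> MantelResult:
    """Isolation by distance: Mantel of pairwise Gst against distance (km).

    With ``partition`` ("N" or "S") only individuals of that mitotype are
    used and Gst is recomputed within the lineage, mirroring a
    mitotype-partitioned analysis; sites left without individuals drop out.
    """
    t = table
    if partition is not None:
        rows = np.nonzero(t.mitotypes == partition)[0]
        if rows.size == 0:
            raise ValueError(f"no individuals with mitotype {partition!r}")
        t = t.subset(individuals=rows)
    pg = pairwise_gst(t, n_permutations=0, estimator=estimator)
    sites = list(pg.gst.index)
    if len(sites) < 3:
        raise ValueError("need at least 3 sites for a Mantel test")
    D = distance_matrix(t.site_coords, sites)
    return mantel(D, pg.gst, n_permutations=n_permutations, seed=seed)


# ---------------------------------------------------------------------------
# cytonuclear disequilibrium


@dataclass
class CNDResult:
    """Asmussen–Basten cytonuclear disequilibria at one locus.

    D is the allelic disequilibrium P(A,M) - p_A p_M computed over 2n
    allele-by-mitotype entries (each diploid contributes two); D1, D2, D3
    are the genotypic disequilibria for AA, Aa and aa with the northern
    mitotype.  Identities D1 + D2 + D3 = 0 and D = D1 + D2/2 hold exactly.
    """

    locus: str
    n: int
    D: float = float("nan")
    D1: float = float("nan")
    D2: float = float("nan")
    D3: float = float("nan")
    p_allelic: float = float("nan")
    p_genotypic: float = float("nan")
    p_allelic_adj: float = float("nan")
    p_genotypic_adj: float = float("nan")
    significant_allelic: bool = False
    significant_genotypic: bool = False
    testable: bool = True


def _log_table_prob(x: np.ndarray, logfact_margins: float, logN: float) -> float:
    return logfact_margins - logN - gammaln(x + 1.0).sum()


def exact_test_3x2(table: np.ndarray, max_enumeration_total: int = 200,
                   n_mc: int = 100000, seed: int = 0) -> float:
    """Freeman–Halton exact test for a 3x2 contingency table.

    The p-value is the total conditional probability (fixed margins,
    multivariate hypergeometric) of tables no more probable than the one
    observed.  Full enumeration when the grand total is at most
    ``max_enumeration_total``; otherwise seeded Monte Carlo over ``n_mc``
    resampled tables with the add-one convention.
    """
    x = np.asarray(table, dtype=np.int64)
    if x.shape != (3, 2) or (x < 0).any():
        raise ValueError("need a nonnegative 3x2 table")
    r = x.sum(axis=1)
    c = x.sum(axis=0)
    N = int(x.sum())
    if N == 0:
        return float("nan")
    logfact_margins = gammaln(r + 1.0).sum() + gammaln(c + 1.0).sum()
    logN = gammaln(N + 1.0)
    lp_obs = _log_table_prob(x, logfact_margins, logN)
    tol = 1e-9
    if N <= max_enumeration_total:
        p = 0.0
        for x11 in range(min(r[0], c[0]) + 1):
            lo = max(0, c[0] - x11 - r[2])
            hi = min(r[1], c[0] - x11)
            for x21 in range(lo, hi + 1):
                x31 = c[0] - x11 - x21
                t = np.array([[x11, r[0] - x11], [x21, r[1] - x21], [x31, r[2] - x31]])
                lp = _log_table_prob(t, logfact_margins, logN)
                if lp <= lp_obs + tol:
                    p += math.exp(lp)
        return min(1.0, p)
    # Monte Carlo: permute column labels over individuals, i.e. draw tables
    # from the multivariate hypergeometric with the observed margins
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(3), r)
    hits = 0
    for _ in range(n_mc):
        pick = rng.permutation(N)[:c[0]]
        x1 = np.bincount(rows[pick], minlength=3)
        t = np.stack([x1, r - x1], axis=1)
        if _log_table_prob(t, logfact_margins, logN) <= lp_obs + tol:
            hits += 1
    return (1 + hits) / (n_mc + 1)


def cytonuclear(table: GenotypeTable, loci=None, alpha: float = 0.05,
                max_enumeration_total: int = 200, n_mc: int = 100000,
                seed: int = 0) -> list[CNDResult]:
    """Cytonuclear disequilibrium between each SNP and the mitotype.

    Per locus, only individuals with a known mitotype (N/S) and a
    non-missing genotype enter.  Loci monomorphic for either the nuclear
    allele or the mitotype are flagged untestable.  The allelic p-value is
    a two-sided Fisher exact test on the 2x2 allele-by-mitotype counts;
    the genotypic p-value is the Freeman–Halton exact test on the 3x2
    genotype-by-mitotype table.  Bonferroni adjustment multiplies by the
    number of testable loci.
    """
    loci_idx = (range(table.n_loci) if loci is None
                else [table.loci.index(l) if isinstance(l, str) else int(l) for l in loci])
    known = np.isin(table.mitotypes, ("N", "S"))
    results = []
    for j in loci_idx:
        g = table.G[:, j]
        rows = known & (g != MISSING)
        gg = g[rows]
        mm = table.mitotypes[rows] == "N"
        n = int(rows.sum())
        res = CNDResult(locus=table.loci[j], n=n)
        geno = np.zeros((3, 2), dtype=np.int64)  # rows AA, Aa, aa; cols M (north), m
        for dose, row in ((2, 0), (1, 1), (0, 2)):
            geno[row, 0] = int(((gg == dose) & mm).sum())
            geno[row, 1] = int(((gg == dose) & ~mm).sum())
        if n == 0 or (gg == 0).all() or (gg == 2).all() or 0 in geno.sum(axis=0):
            # nuclear locus or mitotype monomorphic in the subset
            res.testable = False
            results.append(res)
            continue
        pm = mm.mean()
        p_geno = geno.sum(axis=1) / n
        j_geno = geno[:, 0] / n  # joint P(genotype, M)
        res.D1, res.D2, res.D3 = (j_geno - p_geno * pm).tolist()
        pa = gg.mean() / 2.0
        pam = (gg * mm).sum() / (2.0 * n)  # P(A, M) over 2n gametes
        res.D = float(pam - pa * pm)
        allelic = np.array([
            [int((gg * mm).sum()), int((gg * ~mm).sum())],
            [int(((2 - gg) * mm).sum()), int(((2 - gg) * ~mm).sum())],
        ])
        res.p_allelic = float(fisher_exact(allelic, alternative="two-sided")[1])
        res.p_genotypic = float(exact_test_3x2(geno, max_enumeration_total, n_mc, seed))
        results.append(res)
    n_tested = sum(r.testable for r in results)
    for r in results:
        if r.testable:
            r.p_allelic_adj = min(1.0, r.p_allelic * n_tested)
            r.p_genotypic_adj = min(1.0, r.p_genotypic * n_tested)
            r.significant_allelic = r.p_allelic_adj < alpha
            r.significant_genotypic = r.p_genotypic_adj < alpha
    return results


def cnd_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame([{
        "locus": r.locus, "n": r.n, "D": r.D, "D1": r.D1, "D2": r.D2, "D3": r.D3,
        "p_allelic": r.p_allelic, "p_genotypic": r.p_genotypic,
        "p_allelic_adj": r.p_allelic_adj, "p_genotypic_adj": r.p_genotypic_adj,
        "significant_allelic": r.significant_allelic,
        "significant_genotypic": r.significant_genotypic, "testable": r.testable,
    } for r in results])


def overlap_report(cnd_results, outlier_flags: dict) -> tuple[list, pd.DataFrame]:
    """Loci that are both Bonferroni-significant for CND and flagged outliers.

    ``outlier_flags`` is a per-locus boolean mapping supplied externally
    (e.g. from an outlier scan run elsewhere); its labels must cover
    exactly the loci of the CND results.
    """
    cnd_loci = [r.locus for r in cnd_results]
    if set(outlier_flags) != set(cnd_loci):
        raise ValueError("outlier flag labels do not match CND locus labels")
    rows = []
    overlap = []
    for r in cnd_results:
        sig = bool(r.significant_allelic or r.significant_genotypic)
        out = bool(outlier_flags[r.locus])
        both = sig and out
        rows.append({"locus": r.locus, "cnd_significant": sig,
                     "outlier": out, "both": both})
        if both:
            overlap.append(r.locus)
    return overlap, pd.DataFrame(rows)
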