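"""Classical population-genetic statistics and isolation-by-distance tests.

Diversity summaries (He, Ho, A, Ar, FIS), Weir–Cockerham theta with
permutation significance, Hardy–Weinberg and linkage-equilibrium probability
tests, Holm's sequential Bonferroni, and Mantel test / correlogram.

All permutation p-values use the +1 correction, p = (#{extreme} + 1) /
(n_perm + 1), so p is never 0 and respects the resolution of the number of
permutations run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeTable

__all__ = [
    "DiversitySummary",
    "FstMatrix",
    "MantelResult",
    "CorrelogramResult",
    "allele_frequencies",
    "weir_cockerham_fst",
    "diversity_stats",
    "hwe_exact_test",
    "ld_permutation_test",
    "holm_bonferroni",
    "mantel_test",
    "mantel_correlogram",
]


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


def allele_frequencies(table: GenotypeTable, groups=None) -> pd.DataFrame:
    """Per-group, per-locus allele frequency table.

    Missing genotypes are excluded from denominators.  Returns a tidy frame
    with columns (group, locus, allele, count, freq); loci with no data in a
    group are absent from that group's rows.
    """
    groups = _resolve_groups(table, groups)
    rows = []
    for g in pd.unique(groups):
        sel = groups == g
        if sel.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        sub = table.alleles[sel]
        for j, locus in enumerate(table.locus_names):
            genes = sub[:, j, :].ravel()
            genes = genes[genes != MISSING]
            if genes.size == 0:
                continue
            vals, counts = np.unique(genes, return_counts=True)
            for a, c in zip(vals, counts):
                rows.append((g, locus, int(a), int(c), c / genes.size))
    return pd.DataFrame(rows, columns=["group", "locus", "allele", "count", "freq"])


def _resolve_groups(table: GenotypeTable, groups) -> np.ndarray:
    if groups is None:
        if table.group is None:
            raise ValueError("no group labels supplied and table.group is None")
        groups = table.group
    groups = np.asarray(groups, dtype=object)
    if groups.shape[0] != table.n:
        raise ValueError("groups length must equal table.n")
    return groups


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------


@dataclass
class FstMatrix:
    labels: list
    theta: np.ndarray          # symmetric, zero diagonal
    p_values: np.ndarray       # NaN on diagonal


def _wc_components(alleles: np.ndarray, grp: np.ndarray):
    """Summed Weir–Cockerham (1984) variance components over loci and alleles.

    ``alleles`` is (n, L, 2); ``grp`` integer group codes 0..r-1.  Returns
    (sum_a, sum_abc).  Per locus, individuals missing that locus are dropped.
    """
    r = grp.max() + 1
    sum_a = 0.0
    sum_abc = 0.0
    for j in range(alleles.shape[1]):
        gen = alleles[:, j, :]
        ok = ~(gen == MISSING).all(axis=1)
        gen = gen[ok]
        gj = grp[ok]
        sizes = np.bincount(gj, minlength=r).astype(float)
        if (sizes < 1).any():
            continue
        nbar = sizes.mean()
        if nbar <= 1:
            continue
        n_c = (r * nbar - (sizes**2).sum() / (r * nbar)) / (r - 1)
        allele_vals = np.unique(gen[gen != MISSING])
        if allele_vals.size < 2:
            continue
        for a in allele_vals:
            dose = (gen == a).sum(axis=1) / 2.0          # per-individual freq
            het = ((gen == a).sum(axis=1) == 1).astype(float)
            p_i = np.bincount(gj, weights=dose, minlength=r) / sizes
            h_i = np.bincount(gj, weights=het, minlength=r) / sizes
            pbar = (sizes * p_i).sum() / (r * nbar)
            hbar = (sizes * h_i).sum() / (r * nbar)
            s2 = (sizes * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            term = pbar * (1 - pbar) - (r - 1) / r * s2
            va = nbar / n_c * (s2 - (term - hbar / 4) / (nbar - 1))
            vb = nbar / (nbar - 1) * (term - (2 * nbar - 1) / (4 * nbar) * hbar)
            vc = hbar / 2
            sum_a += va
            sum_abc += va + vb + vc
    return sum_a, sum_abc


def _theta(alleles, grp):
    a, abc = _wc_components(alleles, grp)
    return a / abc if abc != 0 else 0.0


def weir_cockerham_fst(
    table: GenotypeTable,
    groups=None,
    n_perm: int = 999,
    random_state=None,
) -> FstMatrix:
    """Pairwise multilocus Weir–Cockerham theta with permutation p-values.

    Variance components a, b, c are summed over alleles and loci before the
    ratio.  For each group pair, p is obtained by permuting individuals
    between the two groups: p = (#{theta_perm >= theta_obs} + 1)/(n_perm + 1).
    """
    groups = _resolve_groups(table, groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for g in labels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 individuals")
    rng = np.random.default_rng(random_state)
    k = len(labels)
    theta = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            sel = (groups == labels[i]) | (groups == labels[j])
            sub = table.alleles[sel]
            grp = (groups[sel] == labels[j]).astype(int)
            obs = _theta(sub, grp)
            theta[i, j] = theta[j, i] = obs
            if n_perm > 0:
                hits = 0
                g = grp.copy()
                for _ in range(n_perm):
                    rng.shuffle(g)
                    if _theta(sub, g) >= obs:
                        hits += 1
                p = (hits + 1) / (n_perm + 1)
                pvals[i, j] = pvals[j, i] = p
    return FstMatrix(labels=labels, theta=theta, p_values=pvals)


# ---------------------------------------------------------------------------
# Diversity statistics
# ---------------------------------------------------------------------------


@dataclass
class DiversitySummary:
    per_locus: pd.DataFrame    # group, locus, n, He, Ho, A, Ar
    per_group: pd.DataFrame    # group, He, Ho, A_mean, Ar_mean, Fis, p_Fis


def _rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Expected allele count in a sample of ``g`` genes (hypergeometric)."""
    n = counts.sum()
    if g > n:
        raise ValueError("rarefaction size exceeds sample")
    # 1 - C(n - Na, g)/C(n, g) per allele, via log-gammas for stability
    def log_c(a, b):
        if b < 0 or b > a:
            return -np.inf
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    tot = 0.0
    for c in counts:
        tot += 1.0 - np.exp(log_c(n - c, g) - log_c(n, g))
    return tot


def diversity_stats(
    table: GenotypeTable,
    groups=None,
    n_perm: int = 999,
    random_state=None,
) -> DiversitySummary:
    """He, Ho, A, Ar and FIS per group, with a permutation test of FIS.

    He uses the unbiased small-sample correction 2n/(2n-1); Ar rarefies to
    the smallest per-locus complete-genotype sample across groups (in genes);
    multilocus FIS = 1 - sum(Ho)/sum(He) with sums over loci.  The FIS
    p-value permutes alleles among individuals within the group (two-sided
    on |FIS|).
    """
    groups = _resolve_groups(table, groups)
    labels = list(pd.unique(groups))
    rng = np.random.default_rng(random_state)

    # rarefaction target per locus: 2 x smallest per-group complete count
    L = table.n_loci
    complete = ~table.missing_mask()
    g_per_locus = np.zeros(L, dtype=int)
    for j in range(L):
        counts = [int(complete[groups == g, j].sum()) for g in labels]
        g_per_locus[j] = 2 * min(counts)

    per_locus_rows = []
    per_group_rows = []
    for g in labels:
        sel = groups == g
        sub = table.alleles[sel]
        he_sum = ho_sum = 0.0
        a_vals, ar_vals = [], []
        for j, locus in enumerate(table.locus_names):
            gen = sub[:, j, :]
            ok = ~(gen == MISSING).all(axis=1)
            gen = gen[ok]
            n = gen.shape[0]
            if n == 0 or g_per_locus[j] < 2:
                if g_per_locus[j] < 2:
                    warnings.warn(
                        f"locus {locus}: rarefaction size < 2 genes, dropped",
                        stacklevel=2,
                    )
                continue
            genes = gen.ravel()
            vals, counts = np.unique(genes, return_counts=True)
            p = counts / counts.sum()
            he = (2 * n) / (2 * n - 1) * (1 - (p**2).sum()) if n > 0 else np.nan
            ho = float((gen[:, 0] != gen[:, 1]).mean())
            A = len(vals)
            Ar = _rarefied_richness(counts, g_per_locus[j])
            per_locus_rows.append((g, locus, n, he, ho, A, Ar))
            he_sum += he
            ho_sum += ho
            a_vals.append(A)
            ar_vals.append(Ar)
        fis = 1 - ho_sum / he_sum if he_sum > 0 else np.nan
        p_fis = np.nan
        if n_perm > 0 and he_sum > 0:
            hits = 0
            for _ in range(n_perm):
                ho_p = 0.0
                he_p = 0.0
                for j in range(L):
                    gen = sub[:, j, :]
                    ok = ~(gen == MISSING).all(axis=1)
                    genes = gen[ok].ravel().copy()
                    if genes.size == 0 or g_per_locus[j] < 2:
                        continue
                    rng.shuffle(genes)
                    pairs = genes.reshape(-1, 2)
                    n = pairs.shape[0]
                    _, counts = np.unique(genes, return_counts=True)
                    pr = counts / counts.sum()
                    he_p += (2 * n) / (2 * n - 1) * (1 - (pr**2).sum())
                    ho_p += float((pairs[:, 0] != pairs[:, 1]).mean())
                fis_p = 1 - ho_p / he_p if he_p > 0 else 0.0
                if abs(fis_p) >= abs(fis):
                    hits += 1
            p_fis = (hits + 1) / (n_perm + 1)
        n_used = max(len(a_vals), 1)
        per_group_rows.append(
            (g, he_sum / n_used, ho_sum / n_used,
             float(np.mean(a_vals)) if a_vals else np.nan,
             float(np.mean(ar_vals)) if ar_vals else np.nan, fis, p_fis)
        )
    return DiversitySummary(
        per_locus=pd.DataFrame(
            per_locus_rows, columns=["group", "locus", "n", "He", "Ho", "A", "Ar"]
        ),
        per_group=pd.DataFrame(
            per_group_rows,
            columns=["group", "He", "Ho", "A_mean", "Ar_mean", "Fis", "p_Fis"],
        ),
    )


# ---------------------------------------------------------------------------
# HWE and LE probability tests
# ---------------------------------------------------------------------------


def _log_table_prob(gen: np.ndarray) -> float:
    """Log conditional probability of a genotype table given allele counts."""
    n = gen.shape[0]
    genes = gen.ravel()
    _, allele_counts = np.unique(genes, return_counts=True)
    pairs = np.sort(gen, axis=1)
    _, gcounts = np.unique(pairs, axis=0, return_counts=True)
    n_het = int((gen[:, 0] != gen[:, 1]).sum())
    return (
        gammaln(n + 1)
        + n_het * np.log(2.0)
        + gammaln(allele_counts + 1).sum()
        - gammaln(2 * n + 1)
        - gammaln(gcounts + 1).sum()
    )


def hwe_exact_test(
    table: GenotypeTable,
    group=None,
    locus: str | int = 0,
    n_mc: int = 10000,
    random_state=None,
) -> float:
    """Monte-Carlo exact probability test of Hardy–Weinberg equilibrium.

    p is the probability mass, conditional on the allele counts, of genotype
    tables whose conditional probability is <= that of the observed table,
    estimated from ``n_mc`` tables sampled by shuffling the 2n allele list.
    A locus with fewer than two observed alleles gives p = 1 by convention.
    """
    if n_mc < 100:
        raise ValueError("n_mc < 100 gives an unstable estimate")
    sel = np.ones(table.n, bool) if group is None else _resolve_groups(table, None) == group
    j = locus if isinstance(locus, int) else table.locus_names.index(locus)
    gen = table.alleles[sel, j, :]
    gen = gen[~(gen == MISSING).all(axis=1)]
    if np.unique(gen.ravel()).size < 2:
        return 1.0
    rng = np.random.default_rng(random_state)
    obs = _log_table_prob(gen)
    genes = gen.ravel().copy()
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(genes)
        if _log_table_prob(genes.reshape(-1, 2)) <= obs + 1e-10:
            hits += 1
    return (hits + 1) / (n_mc + 1)


def ld_permutation_test(
    table: GenotypeTable,
    group=None,
    locus_pair=(0, 1),
    n_perm: int = 999,
    random_state=None,
) -> float:
    """Permutation probability test of linkage equilibrium for a locus pair.

    Statistic: G = 2 * sum O * ln(O/E) over the two-locus genotype-class
    contingency table; the null is built by permuting one locus's genotypes
    among individuals.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives an unstable estimate")
    sel = np.ones(table.n, bool) if group is None else _resolve_groups(table, None) == group
    idx = [
        lp if isinstance(lp, int) else table.locus_names.index(lp) for lp in locus_pair
    ]
    g1 = np.sort(table.alleles[sel, idx[0], :], axis=1)
    g2 = np.sort(table.alleles[sel, idx[1], :], axis=1)
    ok = ~(g1 == MISSING).all(axis=1) & ~(g2 == MISSING).all(axis=1)
    g1, g2 = g1[ok], g2[ok]
    for g in (g1, g2):
        if np.unique(g.ravel()).size < 2:
            raise ValueError("both loci must have >= 2 alleles in the group")

    def codes(g):
        _, c = np.unique(g, axis=0, return_inverse=True)
        return c.ravel()

    c1, c2 = codes(g1), codes(g2)
    k1, k2 = c1.max() + 1, c2.max() + 1
    obs = _g_statistic(c1, c2, k1, k2)
    rng = np.random.default_rng(random_state)
    perm = c2.copy()
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(perm)
        if _g_statistic(c1, perm, k1, k2) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def _g_statistic(c1: np.ndarray, c2: np.ndarray, k1: int, k2: int) -> float:
    """G = 2 sum O ln(O/E) of the contingency table of two code vectors."""
    tab = np.bincount(c1 * k2 + c2, minlength=k1 * k2).reshape(k1, k2).astype(float)
    E = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
    mask = tab > 0
    return float(2.0 * (tab[mask] * np.log(tab[mask] / E[mask])).sum())


# ---------------------------------------------------------------------------
# Holm sequential Bonferroni
# ---------------------------------------------------------------------------


def holm_bonferroni(pvals, alpha: float = 0.05) -> np.ndarray:
    """Holm's step-down sequential Bonferroni; returns boolean reject flags."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, i in enumerate(order):
        if p[i] <= alpha / (m - rank):
            reject[i] = True
        else:
            break
    return reject


# ---------------------------------------------------------------------------
# Mantel test and correlogram
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    r: float
    p: float
    n: int
    n_perm: int


def _check_distance(D, name):
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(D), 0, atol=1e-10):
        raise ValueError(f"{name} must have zero diagonal")
    return D


def mantel_test(
    D1,
    D2,
    n_perm: int = 999,
    random_state=None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the n(n-1)/2 upper-triangle entries; the
    null distribution permutes rows and columns of D2 simultaneously.
    """
    D1 = _check_distance(D1, "D1")
    D2 = _check_distance(D2, "D2")
    if D1.shape != D2.shape:
        raise ValueError("D1 and D2 must have the same shape")
    n = D1.shape[0]
    iu = np.triu_indices(n, 1)
    x = D1[iu]
    if np.ptp(x) == 0 or np.ptp(D2[iu]) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    xc = x - x.mean()
    xn = xc / np.linalg.norm(xc)

    def corr(D):
        y = D[iu]
        yc = y - y.mean()
        return float(xn @ yc / np.linalg.norm(yc))

    r_obs = corr(D2)
    rng = np.random.default_rng(random_state)
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r_p = corr(D2[np.ix_(p, p)])
        if alternative == "greater":
            extreme = r_p >= r_obs - 1e-12
        elif alternative == "two-sided":
            extreme = abs(r_p) >= abs(r_obs) - 1e-12
        else:
            raise ValueError("alternative must be 'greater' or 'two-sided'")
        hits += extreme
    p_val = (hits + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p_val, n=n, n_perm=n_perm)


@dataclass
class CorrelogramResult:
    class_upper: np.ndarray      # upper bound of each distance class (m)
    n_pairs: np.ndarray
    r: np.ndarray
    p: np.ndarray                # raw permutation p (two-sided)
    p_corrected: np.ndarray      # progressive Bonferroni, increasing distance


def mantel_correlogram(
    Dgeo,
    Dgen,
    n_classes: int = 10,
    n_perm: int = 999,
    random_state=None,
    min_pairs: int = 20,
) -> CorrelogramResult:
    """Mantel correlogram: autocorrelation of genetic distance by distance class.

    Classes are equal-frequency breaks of the pairwise geographic distances.
    Per class, r is the Mantel correlation of genetic distance with the
    complement of the within-class indicator, so positive autocorrelation at
    short distance appears as positive r.  p-values are two-sided permutation
    tests, sequentially corrected (progressive Bonferroni) in
    increasing-distance order.  Classes with fewer than ``min_pairs`` pairs
    are merged into their lower neighbor.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    Dgeo = _check_distance(Dgeo, "Dgeo")
    Dgen = _check_distance(Dgen, "Dgen")
    n = Dgeo.shape[0]
    iu = np.triu_indices(n, 1)
    d = Dgeo[iu]
    qs = np.quantile(d, np.linspace(0, 1, n_classes + 1))
    qs[-1] = qs[-1] + 1e-9
    cls = np.clip(np.searchsorted(qs, d, side="right") - 1, 0, n_classes - 1)
    # merge undersized classes into the lower neighbor
    uppers, members = [], []
    for k in range(n_classes):
        mask = cls == k
        if mask.sum() == 0:
            continue
        if members and mask.sum() < min_pairs:
            warnings.warn(f"distance class {k}: <{min_pairs} pairs, merged", stacklevel=2)
            members[-1] |= mask
            uppers[-1] = max(uppers[-1], d[mask].max())
        else:
            members.append(mask)
            uppers.append(d[mask].max())
    if len(members) < 2:
        raise ValueError(
            "min_pairs merging left fewer than 2 distance classes; "
            "reduce n_classes or min_pairs"
        )
    rng = np.random.default_rng(random_state)
    rs, ps, npairs = [], [], []
    for mask in members:
        A = np.ones((n, n))
        A[iu[0][mask], iu[1][mask]] = 0.0
        A = np.minimum(A, A.T)
        np.fill_diagonal(A, 0.0)
        # complement coding: r > 0 <=> genetic similarity within the class
        res = mantel_test(
            A, Dgen, n_perm=n_perm, random_state=rng, alternative="two-sided"
        )
        rs.append(res.r)
        ps.append(res.p)
        npairs.append(int(mask.sum()))
    ps = np.asarray(ps)
    p_corr = np.minimum(ps * (np.arange(len(ps)) + 1), 1.0)
    return CorrelogramResult(
        class_upper=np.asarray(uppers),
        n_pairs=np.asarray(npairs),
        r=np.asarray(rs),
        p=ps,
        p_corrected=p_corr,
    )
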