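"""Diversity statistics, F-statistics, equilibrium tests, Mantel machinery."""

import itertools

import numpy as np
import pytest

from conftest import make_table, random_table
from landgen.popgen import (
    allele_frequencies,
    diversity_stats,
    holm_bonferroni,
    hwe_exact_test,
    ld_permutation_test,
    mantel_correlogram,
    mantel_test,
    weir_cockerham_fst,
)
from landgen.popgen import _rarefied_richness


class TestAlleleFrequencies:
    def test_simple_counts(self):
        t = make_table([[(1, 1)], [(1, 2)]], group=["g", "g"])
        df = allele_frequencies(t)
        f = dict(zip(df["allele"], df["freq"]))
        assert f == {1: 0.75, 2: 0.25}

    def test_all_missing_locus_absent(self):
        t = make_table([[(1, 1), (0, 0)], [(1, 2), (0, 0)]], group=["g", "g"])
        df = allele_frequencies(t)
        assert set(df["locus"]) == {"L1"}

    def test_matches_exhaustive_enumeration(self, rng):
        t = random_table(rng, n=20, L=5, missing_rate=0.15)
        groups = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        df = allele_frequencies(t, groups)
        for g in ("A", "B"):
            sel = groups == g
            for j, locus in enumerate(t.locus_names):
                genes = [
                    a
                    for row in t.alleles[sel, j, :]
                    for a in row
                    if a != 0
                ]
                sub = df[(df["group"] == g) & (df["locus"] == locus)]
                for _, r in sub.iterrows():
                    assert r["count"] == genes.count(r["allele"])
                if genes:
                    assert sub["freq"].sum() == pytest.approx(1.0)


def wc_theta_oracle(alleles, grp):
    """Independent loop-wise transcription of the 1984 variance components."""
    r = int(max(grp)) + 1
    A = B = C = 0.0
    for j in range(alleles.shape[1]):
        rows = [
            (alleles[i, j, 0], alleles[i, j, 1], grp[i])
            for i in range(alleles.shape[0])
            if alleles[i, j, 0] != 0
        ]
        sizes = [sum(1 for *_, g in rows if g == k) for k in range(r)]
        if min(sizes) < 1:
            continue
        nbar = sum(sizes) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - sum(s * s for s in sizes) / (r * nbar)) / (r - 1)
        obs_alleles = sorted({a for a1, a2, _ in rows for a in (a1, a2)})
        if len(obs_alleles) < 2:
            continue
        for al in obs_alleles:
            p = []
            h = []
            for k in range(r):
                doses = [
                    int(a1 == al) + int(a2 == al)
                    for a1, a2, g in rows
                    if g == k
                ]
                hets = [
                    bool(a1 == al) != bool(a2 == al)
                    for a1, a2, g in rows
                    if g == k
                ]
                p.append(sum(doses) / (2 * sizes[k]))
                h.append(sum(hets) / sizes[k])
            pbar = sum(sizes[k] * p[k] for k in range(r)) / (r * nbar)
            hbar = sum(sizes[k] * h[k] for k in range(r)) / (r * nbar)
            s2 = sum(sizes[k] * (p[k] - pbar) ** 2 for k in range(r)) / (
                (r - 1) * nbar
            )
            inner = pbar * (1 - pbar) - (r - 1) / r * s2
            a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
            b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            A += a
            B += b
            C += c
    tot = A + B + C
    return A / tot if tot else 0.0


class TestWeirCockerham:
    def test_identical_groups_no_differentiation(self, rng):
        # copies of one group: the among-group variance component s2 is 0,
        # so the (unbiased) estimator sits at or slightly below 0 — never
        # positive
        t = random_table(rng, n=10, L=9)
        al = np.concatenate([t.alleles, t.alleles])
        t2 = make_table(al.tolist())
        groups = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        res = weir_cockerham_fst(t2, groups, n_perm=0)
        assert res.theta[0, 1] <= 1e-12
        assert res.theta[0, 1] > -0.1
        # and it agrees exactly with the independent oracle
        grp = (groups == "B").astype(int)
        assert res.theta[0, 1] == pytest.approx(
            wc_theta_oracle(t2.alleles, grp), abs=1e-10
        )

    def test_matches_independent_oracle(self, rng):
        # two groups simulated from divergent allele frequencies
        freqs_a = np.array([0.7, 0.2, 0.1])
        freqs_b = np.array([0.1, 0.3, 0.6])
        al = np.zeros((20, 4, 2), dtype=np.int32)
        for j in range(4):
            al[:10, j, :] = rng.choice([1, 2, 3], p=freqs_a, size=(10, 2))
            al[10:, j, :] = rng.choice([1, 2, 3], p=freqs_b, size=(10, 2))
        t = make_table(al.tolist())
        groups = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        res = weir_cockerham_fst(t, groups, n_perm=0)
        grp = (groups == "B").astype(int)
        assert res.theta[0, 1] == pytest.approx(
            wc_theta_oracle(t.alleles, grp), abs=1e-8
        )
        assert res.theta[0, 1] > 0.05

    def test_allele_relabeling_invariance(self, rng):
        t = random_table(rng, n=16, L=4, n_alleles=4)
        groups = np.array(["A"] * 8 + ["B"] * 8, dtype=object)
        res1 = weir_cockerham_fst(t, groups, n_perm=0)
        relabel = {1: 7, 2: 5, 3: 9, 4: 2}
        al2 = np.vectorize(lambda a: relabel.get(a, 0))(t.alleles)
        t2 = make_table(al2.tolist())
        res2 = weir_cockerham_fst(t2, groups, n_perm=0)
        assert res1.theta[0, 1] == pytest.approx(res2.theta[0, 1], abs=1e-12)

    def test_small_group_rejected(self, rng):
        t = random_table(rng, n=3, L=4)
        with pytest.raises(ValueError, match="fewer than 2"):
            weir_cockerham_fst(t, np.array(["A", "A", "B"], dtype=object), n_perm=0)

    def test_permutation_p_significant_for_divergent_groups(self, rng):
        al = np.zeros((30, 5, 2), dtype=np.int32)
        al[:15] = 1
        al[15:] = 2
        t = make_table(al.tolist())
        groups = np.array(["A"] * 15 + ["B"] * 15, dtype=object)
        res = weir_cockerham_fst(t, groups, n_perm=199, random_state=0)
        assert res.p_values[0, 1] == pytest.approx(1 / 200)


class TestDiversity:
    def test_monomorphic_locus(self):
        t = make_table([[(1, 1)]] * 6, group=["g"] * 6)
        d = diversity_stats(t, n_perm=0)
        row = d.per_locus.iloc[0]
        assert row["He"] == 0 and row["Ho"] == 0 and row["A"] == 1

    def test_all_heterozygous_unbiased_he(self):
        t = make_table([[(1, 2)]] * 5, group=["g"] * 5)
        d = diversity_stats(t, n_perm=99, random_state=0)
        row = d.per_locus.iloc[0]
        assert row["Ho"] == 1.0
        assert row["He"] == pytest.approx(0.5 * 10 / 9)
        assert d.per_group.iloc[0]["Fis"] < 0

    def test_rarefaction_matches_exhaustive_subsampling(self):
        # 6 individuals, one locus; compare against enumeration of all
        # g-gene subsets of the 12 genes
        genes = [1, 1, 1, 2, 2, 3, 3, 3, 3, 4, 4, 4]
        counts = np.array([genes.count(a) for a in sorted(set(genes))])
        for g in (2, 4, 6):
            exhaustive = np.mean(
                [len(set(c)) for c in itertools.combinations(genes, g)]
            )
            assert _rarefied_richness(counts, g) == pytest.approx(
                exhaustive, abs=1e-10
            )

    def test_ar_rarefied_to_smallest_group(self, rng):
        t = random_table(rng, n=12, L=3, n_alleles=5)
        groups = np.array(["A"] * 4 + ["B"] * 8, dtype=object)
        d = diversity_stats(t, groups, n_perm=0)
        merged = d.per_locus
        for locus in t.locus_names:
            sub = merged[merged["locus"] == locus]
            assert (sub["Ar"] <= sub["A"] + 1e-12).all()


class TestHWE:
    def test_monomorphic_p_one(self):
        t = make_table([[(1, 1)]] * 10, group=["g"] * 10)
        assert hwe_exact_test(t, locus=0, n_mc=200) == 1.0

    def test_all_heterozygotes_extreme(self):
        t = make_table([[(1, 2)]] * 50)
        p = hwe_exact_test(t, locus=0, n_mc=2000, random_state=0)
        # complete enumeration oracle: 2 alleles, counts 50/50, tables
        # indexed by heterozygote count (same parity as 50)
        from scipy.special import gammaln

        def logprob(nab):
            naa = (50 - nab) // 2
            nbb = 50 - nab - naa
            return (
                gammaln(51) - gammaln(naa + 1) - gammaln(nab + 1)
                - gammaln(nbb + 1) + nab * np.log(2)
                + 2 * gammaln(51) - gammaln(101)
            )

        lps = {nab: logprob(nab) for nab in range(0, 51, 2)}
        obs = lps[50]
        exact = sum(
            np.exp(lp) for lp in lps.values() if lp <= obs + 1e-10
        ) / sum(np.exp(lp) for lp in lps.values())
        assert p <= 0.001
        assert exact < 1e-6  # the MC p is bounded below by 1/(n_mc+1)

    def test_uniform_under_null(self, rng):
        # genotypes simulated at HWE: rejection rate at alpha=0.05 within
        # a generous binomial band
        n_reps, hits = 150, 0
        for i in range(n_reps):
            g = rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2], size=(60, 1, 2))
            t = make_table(g.tolist())
            p = hwe_exact_test(t, locus=0, n_mc=400, random_state=rng)
            hits += p <= 0.05
        assert hits / n_reps < 0.12

    def test_low_mc_count_rejected(self):
        t = make_table([[(1, 2)]] * 10)
        with pytest.raises(ValueError):
            hwe_exact_test(t, locus=0, n_mc=50)


class TestLD:
    def test_duplicated_locus_maximal_association(self, rng):
        g = rng.choice([1, 2, 3], size=(40, 1, 2))
        al = np.concatenate([g, g], axis=1)
        t = make_table(al.tolist())
        p = ld_permutation_test(t, locus_pair=(0, 1), n_perm=199, random_state=0)
        assert p == pytest.approx(1 / 200)

    def test_g_statistic_hand_computed(self):
        from landgen.popgen import _g_statistic

        # 2x2 genotype-class contingency table with counts 20/10/10/20
        c1 = np.array([0] * 30 + [1] * 30)
        c2 = np.array([0] * 20 + [1] * 10 + [0] * 10 + [1] * 20)
        obs = np.array([[20, 10], [10, 20]], dtype=float)
        E = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        g_hand = 2 * (obs * np.log(obs / E)).sum()
        assert _g_statistic(c1, c2, 2, 2) == pytest.approx(g_hand, abs=1e-10)

    def test_independent_loci_type_one(self, rng):
        hits, reps = 0, 100
        for i in range(reps):
            al = rng.choice([1, 2], size=(50, 2, 2))
            t = make_table(al.tolist())
            try:
                p = ld_permutation_test(
                    t, locus_pair=(0, 1), n_perm=199, random_state=rng
                )
            except ValueError:
                continue
            hits += p <= 0.05
        assert hits / reps < 0.12


class TestHolm:
    def test_step_down_example(self):
        rej = holm_bonferroni([0.01, 0.2, 0.02], alpha=0.05)
        assert rej.tolist() == [True, False, True]

    def test_all_ones_no_rejections(self):
        assert not holm_bonferroni([1.0, 1.0, 1.0]).any()

    def test_single_test_plain_alpha(self):
        assert holm_bonferroni([0.04], alpha=0.05).tolist() == [True]
        assert holm_bonferroni([0.06], alpha=0.05).tolist() == [False]

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(10):
            p = rng.random(12)
            mine = holm_bonferroni(p, alpha=0.05)
            ref = multipletests(p, alpha=0.05, method="holm")[0]
            np.testing.assert_array_equal(mine, ref)


def _rand_dist(rng, n):
    pts = rng.random((n, 2))
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(pts))


class TestMantel:
    def test_identical_matrices_r_one(self, rng):
        D = _rand_dist(rng, 12)
        res = mantel_test(D, D, n_perm=99, random_state=0)
        assert res.r == pytest.approx(1.0)

    def test_matches_scikit_bio(self, rng):
        from skbio.stats.distance import DistanceMatrix, mantel

        D1, D2 = _rand_dist(rng, 15), _rand_dist(rng, 15)
        res = mantel_test(D1, D2, n_perm=199, random_state=0)
        r_ref, _, _ = mantel(
            DistanceMatrix(D1), DistanceMatrix(D2), permutations=0,
            alternative="greater",
        )
        assert res.r == pytest.approx(r_ref, abs=1e-10)

    def test_monotone_linear_invariance(self, rng):
        D1, D2 = _rand_dist(rng, 12), _rand_dist(rng, 12)
        r1 = mantel_test(D1, D2, n_perm=49, random_state=0).r
        D2t = 0.3 + 2.5 * D2
        np.fill_diagonal(D2t, 0.0)
        r2 = mantel_test(D1, D2t, n_perm=49, random_state=0).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_constant_matrix_rejected(self):
        D = np.zeros((5, 5))
        with pytest.raises(ValueError, match="constant"):
            mantel_test(D, D, n_perm=9)

    def test_subset_equals_restricted(self, rng):
        # sex-stratified IBD: testing a subset equals testing the full
        # matrices restricted to that subset
        D1, D2 = _rand_dist(rng, 20), _rand_dist(rng, 20)
        idx = np.arange(0, 20, 2)
        a = mantel_test(D1[np.ix_(idx, idx)], D2[np.ix_(idx, idx)],
                        n_perm=99, random_state=3)
        b = mantel_test(D1[idx][:, idx], D2[idx][:, idx],
                        n_perm=99, random_state=3)
        assert a.r == b.r and a.p == b.p

    def test_p_lower_bound(self, rng):
        D = _rand_dist(rng, 12)
        res = mantel_test(D, D, n_perm=99, random_state=0)
        assert res.p >= 1 / 100


class TestCorrelogram:
    def test_monotone_structure(self, rng):
        pts = rng.random((60, 2)) * 1000
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(pts))
        Dgen = np.sqrt(D / D.max())  # monotone transform of distance
        res = mantel_correlogram(D, Dgen, n_classes=5, n_perm=99, random_state=0)
        assert res.r[0] > 0
        assert res.r[-1] < 0
        assert (np.diff(res.class_upper) > 0).all()

    def test_undersized_classes_merge_or_error(self, rng):
        pts = rng.random((25, 2))
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(pts))
        Dgen = _rand_dist(rng, 25)
        # equal-frequency classes of ~37 pairs: min_pairs above that makes
        # every class merge downward, collapsing the correlogram
        with pytest.warns(UserWarning, match="merged"):
            with pytest.raises(ValueError, match="fewer than 2"):
                mantel_correlogram(
                    D, Dgen, n_classes=8, n_perm=49, random_state=0,
                    min_pairs=50,
                )
        # with the default floor all 8 classes survive intact
        res = mantel_correlogram(
            D, Dgen, n_classes=8, n_perm=49, random_state=0, min_pairs=20
        )
        assert len(res.r) == 8
        assert res.n_pairs.sum() == 300

    def test_corrected_p_progressive(self, rng):
        pts = rng.random((40, 2))
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(pts))
        res = mantel_correlogram(
            D, _rand_dist(rng, 40), n_classes=4, n_perm=99, random_state=0
        )
        expected = np.minimum(res.p * (np.arange(len(res.p)) + 1), 1)
        np.testing.assert_allclose(res.p_corrected, expected)
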