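"""Classic sweep statistics: iHS, nSL, DIND, SAFE/iSAFE, HAF, H12(80%)."""

import math

import numpy as np
import pytest

from sweepnet.classicstats import (
    dind,
    h12_80,
    haf_scores,
    haf_top,
    ihs,
    isafe_scores,
    nsl,
    safe_or_isafe,
    safe_scores,
)
from sweepnet.hapdata import HaplotypeMatrix
from sweepnet.sweepstats import context_at, focal_contexts

from .oracles import (
    dind_brute,
    h12_brute,
    haf_top_brute,
    ihs_brute,
    nsl_brute,
    random_matrix,
    safe_brute,
)


def _matrix(cols, positions=None, locus=10_000):
    A = np.array(cols).T
    pos = positions or list(range(100, 100 * (A.shape[1] + 1), 100))
    return HaplotypeMatrix(A, pos, locus)


class TestIhs:
    def test_mirror_symmetric_configuration_is_zero(self):
        focal = [1] * 4 + [0] * 4
        c1 = [0, 1, 0, 1] * 2  # same pattern on both backgrounds
        c2 = [0, 0, 1, 1] * 2  # together with c1 breaks every pair
        m = _matrix([focal, c1, c2])
        assert ihs(m, context_at(m, 0)) == pytest.approx(0.0)

    def test_identical_derived_background_is_positive(self):
        focal = [1] * 4 + [0] * 4
        c1 = [0, 0, 0, 0] + [0, 1, 0, 1]
        c2 = [0, 0, 0, 0] + [0, 0, 1, 1]
        m = _matrix([focal, c1, c2])
        assert ihs(m, context_at(m, 0)) > 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            m = random_matrix(rng, max_hap=10, max_sites=14)
            for ctx in focal_contexts(m):
                got = ihs(m, ctx, None, 4000)
                want = ihs_brute(m.alleles, m.positions, ctx.focal_index, 4000)
                assert (np.isnan(got) and np.isnan(want)) or got == pytest.approx(want)

    def test_genetic_map_changes_integration_axis(self):
        from sweepnet.hapdata import GeneticMap

        rng = np.random.default_rng(3)
        m = random_matrix(rng, max_hap=10, max_sites=14)
        # nonlinear map: compresses the left half, stretches the right half
        gm = GeneticMap([0.0, 5_000.0, 10_000.0], [0.0, 0.1, 10.0])
        ctx = focal_contexts(m)[0]
        flat = ihs(m, ctx, None, None)
        warped = ihs(m, ctx, gm, None)
        if np.isfinite(flat) and np.isfinite(warped):
            assert warped != pytest.approx(flat)


class TestNsl:
    def test_identical_decay_is_zero(self):
        focal = [1] * 4 + [0] * 4
        c1 = [0, 1, 0, 1] * 2
        c2 = [0, 0, 1, 1] * 2
        m = _matrix([focal, c1, c2])
        assert nsl(m, context_at(m, 0)) == pytest.approx(0.0)

    def test_identical_derived_pair_is_positive(self):
        focal = [1, 1] + [0] * 4
        c1 = [0, 0] + [0, 1, 0, 1]
        c2 = [0, 0] + [0, 0, 1, 1]
        m = _matrix([focal, c1, c2])
        assert nsl(m, context_at(m, 0)) > 0

    def test_tiny_background_not_computable(self):
        focal = [1] + [0] * 3  # single derived carrier
        c1 = [0, 1, 0, 1]
        m = _matrix([focal, c1])
        assert np.isnan(nsl(m, context_at(m, 0)))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(22)
        for _ in range(25):
            m = random_matrix(rng, max_hap=10, max_sites=14)
            for ctx in focal_contexts(m):
                got = nsl(m, ctx, 4000)
                want = nsl_brute(m.alleles, m.positions, ctx.focal_index, 4000)
                assert (np.isnan(got) and np.isnan(want)) or got == pytest.approx(want)


class TestDind:
    def test_symmetric_diversity_is_one(self):
        focal = [1] * 4 + [0] * 4
        both = [1, 0, 0, 0, 1, 0, 0, 0]
        m = _matrix([focal, both])
        assert dind(m, context_at(m, 0)) == pytest.approx(1.0)

    def test_ratio_arithmetic(self):
        focal = [1] * 4 + [0] * 4
        der_single = [1, 0, 0, 0] + [0] * 4  # pi_d = 0.5
        anc_single = [0] * 4 + [1, 0, 0, 0]  # each contributes 0.5 to pi_a
        m = _matrix([focal, der_single, anc_single, anc_single])
        assert dind(m, context_at(m, 0)) == pytest.approx(2.0)

    def test_zero_derived_diversity_not_computable(self):
        focal = [1] * 4 + [0] * 4
        anc_only = [0, 0, 0, 0, 1, 0, 0, 0]
        m = _matrix([focal, anc_only])
        assert np.isnan(dind(m, context_at(m, 0)))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            m = random_matrix(rng, max_hap=10, max_sites=14)
            for ctx in focal_contexts(m):
                got = dind(m, ctx, 4000)
                want = dind_brute(m.alleles, m.positions, ctx.focal_index, 4000)
                assert (np.isnan(got) and np.isnan(want)) or got == pytest.approx(want)


class TestSafeIsafe:
    def _big_matrix(self, n_sites, seed=0):
        rng = np.random.default_rng(seed)
        A = (rng.random((20, n_sites)) < 0.3).astype(np.int8)
        A[:, 0] = [1] * 10 + [0] * 10  # keep at least one mid-frequency site
        pos = np.sort(rng.choice(np.arange(1, 10 * n_sites), n_sites, replace=False))
        return HaplotypeMatrix(A, pos, 10 * n_sites + 1)

    def test_safe_branch_below_300_snps(self):
        _, branch = safe_or_isafe(self._big_matrix(299))
        assert branch == "safe"

    def test_isafe_branch_at_300_snps(self):
        _, branch = safe_or_isafe(self._big_matrix(300))
        assert branch == "isafe"

    def test_safe_scores_match_formula_oracle(self):
        rng = np.random.default_rng(24)
        for _ in range(20):
            m = random_matrix(rng, max_hap=10, max_sites=15)
            np.testing.assert_allclose(safe_scores(m), safe_brute(m.alleles), atol=1e-10)

    def test_isafe_equals_safe_when_single_window(self):
        m = self._big_matrix(120)
        np.testing.assert_allclose(isafe_scores(m, window_snps=300), safe_scores(m))

    def test_too_few_snps_rejected(self):
        m = _matrix([[1, 1, 0, 0]])
        with pytest.raises(ValueError, match="2 SNPs"):
            safe_or_isafe(m)


class TestHaf:
    def test_uniform_haplotypes(self):
        # every haplotype carries d derived alleles, each at count n
        n, d = 10, 4
        m = _matrix([[1] * n for _ in range(d)])
        assert haf_top(m) == pytest.approx(d * n)
        assert np.all(haf_scores(m) == d * n)

    def test_top_fraction_set_size_is_ceil(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng, max_hap=10, max_sites=10)
        scores = np.sort(haf_scores(m))[::-1]
        k = math.ceil(0.1 * m.n_haplotypes)
        assert haf_top(m) == pytest.approx(scores[:k].mean())

    def test_zero_sites_is_zero(self):
        m = HaplotypeMatrix(np.zeros((4, 0), dtype=np.int8), [], 100)
        assert haf_top(m) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(25)
        for _ in range(30):
            m = random_matrix(rng)
            assert haf_top(m) == pytest.approx(haf_top_brute(m.alleles))


class TestH12:
    def test_identical_haplotypes_give_one(self):
        m = _matrix([[1] * 6, [0] * 6, [1] * 6])
        assert h12_80(m) == pytest.approx(1.0)

    def test_two_equal_distant_clusters_give_one(self):
        # two clusters of identical haplotypes, mutually < 80% identical
        a = [0] * 10
        b = [1] * 10
        A = np.array([a, a, a, b, b, b])
        m = HaplotypeMatrix(A, list(range(100, 1100, 100)), 2000)
        assert h12_80(m) == pytest.approx(1.0)

    def test_singleton_haplotypes_closed_form(self):
        # n mutually <80%-identical singletons: (2/n)^2 + (n-2)/n^2
        n = 5
        A = np.zeros((n, n * 3), dtype=np.int8)
        for i in range(n):
            A[i, 3 * i : 3 * i + 3] = 1  # pairwise identity 9/15 = 0.6 < 0.8
        m = HaplotypeMatrix(A, list(range(100, 100 * (3 * n) + 100, 100)), 10_000)
        assert h12_80(m) == pytest.approx((2 / n) ** 2 + (n - 2) / n**2)

    def test_no_snps_not_computable(self):
        m = HaplotypeMatrix(np.zeros((4, 0), dtype=np.int8), [], 100)
        assert np.isnan(h12_80(m))

    def test_exact_threshold_recovers_classic_h12(self):
        rng = np.random.default_rng(26)
        for _ in range(30):
            m = random_matrix(rng)
            _, counts = np.unique(m.alleles, axis=0, return_counts=True)
            p = np.sort(counts / m.n_haplotypes)[::-1]
            p2 = p[1] if p.size > 1 else 0.0
            classic = (p[0] + p2) ** 2 + np.sum(p[2:] ** 2)
            assert h12_80(m, identity_threshold=1.0) == pytest.approx(classic)

    def test_matches_brute_force_at_80(self):
        rng = np.random.default_rng(27)
        for _ in range(30):
            m = random_matrix(rng)
            assert h12_80(m) == pytest.approx(h12_brute(m.alleles))


def test_all_statistics_invariant_to_haplotype_row_order():
    rng = np.random.default_rng(30)
    m = random_matrix(rng, max_hap=10, max_sites=14)
    perm = rng.permutation(m.n_haplotypes)
    shuffled = HaplotypeMatrix(m.alleles[perm], m.positions, m.locus_length)
    assert haf_top(m) == pytest.approx(haf_top(shuffled))
    assert h12_80(m) == pytest.approx(h12_80(shuffled))
    for ctx, ctx2 in zip(focal_contexts(m), focal_contexts(shuffled)):
        for fn in (dind, nsl):
            a, b = fn(m, ctx), fn(shuffled, ctx2)
            assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)
        a, b = ihs(m, ctx, None, 4000), ihs(shuffled, ctx2, None, 4000)
        assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)
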