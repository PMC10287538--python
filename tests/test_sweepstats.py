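"""Derived/ancestral-background statistics and DAF-binned standardization."""

import numpy as np
import pytest

from sweepnet.hapdata import HaplotypeMatrix
from sweepnet.sweepstats import (
    BinnedNorms,
    build_norms,
    context_at,
    daf_bin,
    focal_contexts,
    hapdaf,
    hapdaf_o,
    hapdaf_s,
    highfreq,
    lowfreq,
    sratio,
)

from .oracles import (
    hapdaf_brute,
    highfreq_brute,
    lowfreq_brute,
    random_matrix,
    sratio_brute,
)


def _matrix(cols: list[list[int]], positions=None, locus=10_000) -> HaplotypeMatrix:
    A = np.array(cols).T
    pos = positions or list(range(100, 100 * (A.shape[1] + 1), 100))
    return HaplotypeMatrix(A, pos, locus)


class TestHapDAF:
    def test_single_qualifying_variant_value(self):
        # focal DAF 0.5; flanking variant on 4/5 derived and 1/5 ancestral
        focal = [1] * 5 + [0] * 5
        flank = [1, 1, 1, 1, 0] + [1, 0, 0, 0, 0]
        m = _matrix([focal, flank])
        v = hapdaf_o(m, context_at(m, 0))
        assert v == pytest.approx((0.8**2 - 0.2**2) / 1)  # 0.60

    def test_standing_variation_thresholds_exclude(self):
        # same construction: f_a = 0.2 >= 0.1 fails the hapDAF-s criterion
        focal = [1] * 5 + [0] * 5
        flank = [1, 1, 1, 1, 0] + [1, 0, 0, 0, 0]
        m = _matrix([focal, flank])
        assert hapdaf_s(m, context_at(m, 0)) == 0.0

    def test_focal_daf_out_of_range_not_computable(self):
        focal = [1, 1] + [0] * 8  # DAF 0.2 < 0.25
        flank = [1, 0] * 5
        m = _matrix([focal, flank])
        assert np.isnan(hapdaf_o(m, context_at(m, 0)))

    def test_variant_outside_window_ignored(self):
        focal = [1] * 5 + [0] * 5
        flank = [1, 1, 1, 1, 0] + [1, 0, 0, 0, 0]
        m = _matrix([focal, flank], positions=[100, 9000])
        assert hapdaf_o(m, context_at(m, 0), half_span_bp=1000) == 0.0

    def test_bounded_in_unit_interval_and_matches_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            m = random_matrix(rng)
            for ctx in focal_contexts(m):
                for fa_max, sum_min in ((0.25, 0.25), (0.10, 0.10)):
                    got = hapdaf(m, ctx, 4000, fa_max, sum_min)
                    want = hapdaf_brute(
                        m.alleles, m.positions, ctx.focal_index, 4000, fa_max, sum_min
                    )
                    assert got == pytest.approx(want, abs=1e-12)
                    assert 0.0 <= got <= 1.0

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng)
        perm = rng.permutation(m.n_haplotypes)
        shuffled = HaplotypeMatrix(m.alleles[perm], m.positions, m.locus_length)
        for j in [c.focal_index for c in focal_contexts(m)]:
            assert hapdaf_o(m, context_at(m, j)) == pytest.approx(
                hapdaf_o(shuffled, context_at(shuffled, j))
            )


class TestSratio:
    def test_formula_arithmetic(self):
        # 4 sites segregating on the ancestral background, 2 on the derived
        focal = [1] * 4 + [0] * 4
        anc_only = [0, 0, 0, 0, 1, 0, 0, 0]
        both = [1, 0, 0, 0, 1, 0, 0, 0]
        m = _matrix([focal, anc_only, anc_only, both, both])
        assert sratio(m, context_at(m, 0)) == pytest.approx(4 / 2)

    def test_symmetric_backgrounds_give_one(self):
        focal = [1] * 4 + [0] * 4
        both = [1, 0, 0, 0, 1, 0, 0, 0]
        m = _matrix([focal, both, both, both])
        assert sratio(m, context_at(m, 0)) == pytest.approx(1.0)

    def test_no_derived_segregation_not_computable(self):
        focal = [1] * 4 + [0] * 4
        anc_only = [0, 0, 0, 0, 1, 0, 0, 0]
        m = _matrix([focal, anc_only])
        assert np.isnan(sratio(m, context_at(m, 0)))

    def test_matches_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            m = random_matrix(rng)
            for ctx in focal_contexts(m):
                got = sratio(m, ctx, 4000)
                want = sratio_brute(m.alleles, m.positions, ctx.focal_index, 4000)
                assert (np.isnan(got) and np.isnan(want)) or got == pytest.approx(want)
                if np.isfinite(got):
                    assert got >= 0


class TestFreqStatistics:
    def test_lowfreq_single_term(self):
        focal = [1] * 5 + [0] * 5
        flank = [1, 0, 0, 0, 0] + [0] * 5  # f_dd = 0.2
        m = _matrix([focal, flank])
        assert lowfreq(m, context_at(m, 0)) == pytest.approx(0.64)

    def test_lowfreq_boundary_exclusion(self):
        focal = [1] * 5 + [0] * 5
        flank = [1, 1, 0, 0, 0] + [0] * 5  # f_dd = 0.4 not < 0.25
        m = _matrix([focal, flank])
        assert lowfreq(m, context_at(m, 0)) == 0.0

    def test_highfreq_fixed_on_derived_background(self):
        focal = [1] * 5 + [0] * 5
        flank = [1] * 5 + [0] * 5  # f_dd = 1.0 (still segregating overall)
        m = _matrix([focal, flank])
        assert highfreq(m, context_at(m, 0)) == pytest.approx(1.0)

    def test_highfreq_single_term(self):
        focal = [1] * 5 + [0] * 5
        flank = [1, 1, 1, 1, 0] + [0] * 5  # f_dd = 0.8
        m = _matrix([focal, flank])
        assert highfreq(m, context_at(m, 0)) == pytest.approx(0.64)

    def test_ranges_when_nonzero_and_oracle_equality(self):
        rng = np.random.default_rng(13)
        for _ in range(60):
            m = random_matrix(rng)
            for ctx in focal_contexts(m):
                lo = lowfreq(m, ctx, 4000)
                hi = highfreq(m, ctx, 4000)
                assert lo == pytest.approx(
                    lowfreq_brute(m.alleles, m.positions, ctx.focal_index, 4000)
                )
                assert hi == pytest.approx(
                    highfreq_brute(m.alleles, m.positions, ctx.focal_index, 4000)
                )
                # strict 0.25 cutoffs force these ranges for nonzero values
                if lo > 0:
                    assert 0.5625 < lo < 1.0
                if hi > 0:
                    assert 0.0625 < hi <= 1.0


class TestDafBinning:
    def test_bin_edges_half_open(self):
        assert daf_bin(0.251) == 12
        assert daf_bin(0.02) == 0
        assert daf_bin(0.0200001) == 1
        assert daf_bin(1.0) == 49

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            daf_bin(0.0)
        with pytest.raises(ValueError):
            daf_bin(1.1)


class TestBinnedNorms:
    def test_constant_statistic_rejected(self):
        rng = np.random.default_rng(0)
        dafs = rng.uniform(0.01, 1.0, 5000)
        with pytest.raises(ValueError, match="zero variance"):
            build_norms({"flat": (np.full(5000, 3.0), dafs)})

    def test_per_bin_moments_recovered(self):
        rng = np.random.default_rng(5)
        n_per_bin = 10_000
        dafs = np.repeat((np.arange(50) + 0.5) / 50, n_per_bin)
        values = rng.normal(0.0, 1.0, dafs.size)
        norms = build_norms({"x": (values, dafs)})
        frame = norms.to_frame()
        assert np.all(np.abs(frame["mean"]) < 0.05)
        assert np.all((frame["sd"] > 0.95) & (frame["sd"] < 1.05))

    def test_standardize_centres_and_scales(self):
        rng = np.random.default_rng(2)
        dafs = rng.uniform(0.01, 1.0, 20_000)
        values = rng.normal(3.0, 2.0, 20_000)
        norms = build_norms({"x": (values, dafs)})
        b = daf_bin(0.5)
        mean, sd = norms._mean["x"][b], norms._sd["x"][b]
        assert norms.standardize("x", mean, 0.5) == pytest.approx(0.0)
        assert norms.standardize("x", mean + sd, 0.5) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            norms.standardize("x", 1.0, 1.5)
        with pytest.raises(KeyError):
            norms.standardize("nope", 1.0, 0.5)

    def test_sparse_bins_pooled_with_neighbours(self):
        rng = np.random.default_rng(9)
        # values only in bins 10-19; other bins must pool outward, not fail
        dafs = rng.uniform(0.20, 0.40, 2000)
        values = rng.normal(0, 1, 2000)
        norms = build_norms({"x": (values, dafs)})
        assert np.all(norms._sd["x"] > 0)

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        dafs = rng.uniform(0.01, 1.0, 5000)
        norms = build_norms(
            {"a": (rng.normal(size=5000), dafs), "haf": (rng.normal(size=100), None)},
            provenance="unit",
        )
        path = tmp_path / "norms.tsv"
        norms.save(path)
        again = BinnedNorms.load(path)
        assert again == norms
        assert again.provenance == "unit"
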