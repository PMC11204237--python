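"""The colocalization statistic: the per-pair index, nearest-neighbor
pairing, and the complete pairwise-permutation null checked against a naive
double-loop oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lincoloc.colocalization import (
    ColocalizationParams,
    DegenerateVarianceError,
    NeighborPair,
    NoPairsError,
    colocalize,
    io_index,
    pair_nearest_neighbors,
    permutation_summary,
    permuted_pair_io,
    z_to_pvalue,
    zeta_statistic,
)
from lincoloc.intervals import GenomicInterval, Track


def make_pair(L, a, b):
    """NeighborPair with prescribed geometry (intervals are bookkeeping)."""
    a_iv = GenomicInterval("chr1", 1000, 1000 + max(a, 1))
    b_iv = GenomicInterval("chr1", 5000, 5000 + max(b, 1))
    return NeighborPair(a_iv, b_iv, float(L), a, b, io_index(L, a, b))


class TestIoIndex:
    @pytest.mark.parametrize(
        "L,a,b,expected",
        [
            (0.0, 100, 50, -1.0),   # coincident centers
            (75.0, 100, 50, 0.0),   # L equals the mean combined half-length
            (225.0, 100, 50, 0.5),  # 150/300
        ],
    )
    def test_values(self, L, a, b, expected):
        assert io_index(L, a, b) == pytest.approx(expected, abs=1e-15)

    def test_degenerate_zero_over_zero(self):
        with pytest.raises(ZeroDivisionError):
            io_index(0.0, 0, 0)

    @settings(derandomize=True, max_examples=200)
    @given(
        # center distances are half-integral in practice; 0 is the only way
        # to reach -1 (a denormal L would underflow to -1 in float anyway)
        L=st.one_of(st.just(0.0), st.integers(1, 2 * 10**7).map(lambda v: v / 2.0)),
        a=st.integers(1, 10**6),
        b=st.integers(1, 10**6),
    )
    def test_bounds(self, L, a, b):
        v = io_index(L, a, b)
        assert -1.0 <= v < 1.0
        assert (v == -1.0) == (L == 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        L1=st.floats(0, 1e6),
        dL=st.floats(1e-3, 1e6),
        a=st.integers(1, 10**5),
        b=st.integers(1, 10**5),
    )
    def test_strictly_increasing_in_distance(self, L1, dL, a, b):
        assert io_index(L1 + dL, a, b) > io_index(L1, a, b)


class TestPermutedPairIo:
    def test_hand_value(self):
        p1 = make_pair(0.0, 100, 100)
        p2 = make_pair(300.0, 10, 10)
        # ½[(0−10)/(0+10) + (300−100)/(300+100)] = ½[−1 + 0.5] = −0.25
        assert permuted_pair_io(p1, p2) == pytest.approx(-0.25, abs=1e-15)

    def test_symmetric(self, rng):
        for _ in range(20):
            p = make_pair(float(rng.uniform(0, 1e5)), int(rng.integers(1, 1e4)),
                          int(rng.integers(1, 1e4)))
            q = make_pair(float(rng.uniform(0, 1e5)), int(rng.integers(1, 1e4)),
                          int(rng.integers(1, 1e4)))
            assert permuted_pair_io(p, q) == permuted_pair_io(q, p)

    def test_equal_lengths_swap_is_noop(self):
        p = make_pair(50.0, 60, 40)
        q = make_pair(700.0, 70, 30)  # same a+b
        assert permuted_pair_io(p, q) == pytest.approx((p.io + q.io) / 2, abs=1e-15)


def naive_summary(pairs):
    """Literal double-loop evaluation of the observed/permuted aggregates."""
    K = len(pairs)
    io = [p.io for p in pairs]
    io_mean = sum(io) / K
    perm = []
    for k in range(K - 1):
        for k2 in range(k + 1, K):
            perm.append(permuted_pair_io(pairs[k], pairs[k2]))
    perm_mean = sum(perm) / len(perm)
    # ΔI via the explicit double-sum form
    delta = io_mean - 2.0 / (K * (K - 1)) * sum(perm)
    var_io = sum((v - io_mean) ** 2 for v in io) / K
    var_perm = sum((v - perm_mean) ** 2 for v in perm) / len(perm)
    cov = 0.0
    i = 0
    for k in range(K - 1):
        for k2 in range(k + 1, K):
            cov += (io[k] - io_mean) * (perm[i] - perm_mean)
            cov += (io[k2] - io_mean) * (perm[i] - perm_mean)
            i += 1
    cov *= 2.0 / (K * K * (K - 1))
    return io_mean, perm_mean, delta, var_io, var_perm, cov


class TestPermutationSummary:
    def test_worked_example(self):
        pairs = [make_pair(0.0, 100, 100), make_pair(300.0, 10, 10)]
        s = permutation_summary(pairs)
        assert s.io_mean == pytest.approx((-1 + 290 / 310) / 2, abs=1e-12)
        assert s.io_perm_mean == pytest.approx(-0.25, abs=1e-12)
        assert s.delta_i == pytest.approx(s.io_mean + 0.25, abs=1e-12)

    def test_equal_combined_lengths_give_zero_delta(self):
        pairs = [make_pair(10.0, 50, 50), make_pair(400.0, 30, 70), make_pair(90.0, 99, 1)]
        s = permutation_summary(pairs)  # all a+b = 100: swaps change nothing
        assert abs(s.delta_i) < 1e-14

    @pytest.mark.parametrize("K", [2, 3, 7, 40])
    def test_matches_naive_oracle(self, K, rng):
        pairs = [
            make_pair(float(rng.uniform(0, 1e5)), int(rng.integers(1, 5e4)),
                      int(rng.integers(1, 5e4)))
            for _ in range(K)
        ]
        s = permutation_summary(pairs)
        io_mean, perm_mean, delta, var_io, var_perm, cov = naive_summary(pairs)
        assert s.io_mean == pytest.approx(io_mean, abs=1e-12)
        assert s.io_perm_mean == pytest.approx(perm_mean, abs=1e-12)
        assert s.delta_i == pytest.approx(delta, abs=1e-12)
        assert s.var_io == pytest.approx(var_io, abs=1e-12)
        assert s.var_io_perm == pytest.approx(var_perm, abs=1e-12)
        assert s.cov == pytest.approx(cov, abs=1e-12)
        # the "≡" identity between the double-sum and difference-of-means forms
        assert abs(s.delta_i - (s.io_mean - s.io_perm_mean)) < 1e-12

    def test_requires_two_pairs(self):
        with pytest.raises(ValueError):
            permutation_summary([make_pair(10.0, 5, 5)])


class TestZeta:
    def test_zeta_is_delta_over_sigma(self, rng):
        pairs = [
            make_pair(float(rng.uniform(0, 1e5)), int(rng.integers(1, 1e4)),
                      int(rng.integers(1, 1e4)))
            for _ in range(20)
        ]
        s = permutation_summary(pairs)
        sigma, zeta = zeta_statistic(s)
        assert sigma > 0
        assert zeta == pytest.approx(s.delta_i / sigma, abs=1e-15)

    def test_zero_delta_gives_zero_zeta(self):
        from lincoloc.colocalization import PermutationSummary

        s = PermutationSummary(
            K=10, io_mean=-0.2, io_perm_mean=-0.2, delta_i=0.0,
            var_io=0.1, var_io_perm=0.05, cov=0.01,
            var_delta=0.02, var_delta_approx=0.03,
        )
        sigma, zeta = zeta_statistic(s)
        assert sigma > 0
        assert zeta == 0.0

    def test_identical_pairs_degenerate(self):
        pairs = [make_pair(100.0, 50, 50) for _ in range(5)]
        with pytest.raises(DegenerateVarianceError):
            zeta_statistic(permutation_summary(pairs))

    @pytest.mark.parametrize(
        "z,expected",
        [(0.0, 1.0), (-4.1379, 0.000035), (-4.9922, 0.000001)],
    )
    def test_z_to_pvalue(self, z, expected):
        assert round(z_to_pvalue(z), 6) == expected


class TestPairing:
    def test_coincident_centers(self):
        A = Track(intervals=[GenomicInterval("chr1", 100, 200)])
        B = Track(intervals=[GenomicInterval("chr1", 120, 180)])
        pairs = pair_nearest_neighbors(A, B)
        assert len(pairs) == 1
        assert pairs[0].L == 0.0
        assert pairs[0].io == -1.0

    def test_no_shared_chromosomes(self):
        A = Track(intervals=[GenomicInterval("chr1", 0, 10)])
        B = Track(intervals=[GenomicInterval("chr2", 0, 10)])
        with pytest.raises(NoPairsError):
            pair_nearest_neighbors(A, B)

    def test_distance_tie_broken_to_smaller_start(self):
        A = Track(intervals=[GenomicInterval("chr1", 990, 1010)])  # center 1000
        B = Track(
            intervals=[
                GenomicInterval("chr1", 890, 910),   # center 900, d=100
                GenomicInterval("chr1", 1090, 1110), # center 1100, d=100
            ]
        )
        pairs = pair_nearest_neighbors(A, B)
        assert pairs[0].b_iv.start == 890

    def test_matches_brute_force_nearest(self, rng):
        for _ in range(30):
            A = Track(
                intervals=[
                    GenomicInterval("chr1", s, s + int(rng.integers(1, 50)))
                    for s in sorted(rng.integers(0, 9000, size=8))
                ]
            )
            B = Track(
                intervals=[
                    GenomicInterval("chr1", s, s + int(rng.integers(1, 50)))
                    for s in sorted(rng.integers(0, 9000, size=12))
                ]
            )
            pairs = pair_nearest_neighbors(A, B, ColocalizationParams(max_pair_size=1e9))
            assert len(pairs) == len(A)
            for a_iv, pair in zip(A, pairs):
                dists = [abs(b.center - a_iv.center) for b in B]
                assert abs(pair.b_iv.center - a_iv.center) == min(dists)

    def test_max_pair_size_drops_remote(self):
        A = Track(intervals=[GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 5000, 5010)])
        B = Track(intervals=[GenomicInterval("chr1", 4990, 5000)])
        pairs = pair_nearest_neighbors(A, B, ColocalizationParams(max_pair_size=100))
        assert len(pairs) == 1
        assert pairs[0].a_iv.start == 5000


class TestColocalize:
    def test_identical_tracks_full_overlap(self):
        t = Track(
            intervals=[GenomicInterval("chr1", s, s + 100) for s in range(0, 5000, 500)]
        )
        pairs = pair_nearest_neighbors(t, t)
        s = permutation_summary(pairs)
        assert s.io_mean == pytest.approx(-1.0, abs=1e-12)
        # every observed and swapped index is exactly -1: the null carries no
        # variance, so the full chain reports the degenerate diagnostic
        with pytest.raises(DegenerateVarianceError):
            colocalize(t, t)

    def test_planted_signal_detected(self, small_config):
        from dataclasses import replace

        from lincoloc.simulate import simulate_tracks

        genes, _, lincs = simulate_tracks(
            replace(small_config, coloc_fraction=1.0, linc_length=1)
        )
        res = colocalize(genes, lincs)
        assert res.io_mean < -0.3
        assert res.zeta < -1.96
        assert res.colocalized

    def test_diagnostics_counts(self, small_config):
        from lincoloc.simulate import simulate_tracks

        genes, _, lincs = simulate_tracks(small_config)
        res = colocalize(genes, lincs)
        assert res.n_track_a == len(genes)
        assert res.n_track_b == len(lincs)
        assert 0 < res.n_b_records_used <= res.K
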