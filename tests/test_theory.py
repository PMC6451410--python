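"""Noise-free refractory pulse-interval coding theory."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mapkinfo import theory as th


def brute_fixed_point_count(L: int, k: int) -> int:
    """Count sequences whose 1s are pairwise more than k slots apart."""
    n = 0
    for bits in itertools.product("01", repeat=L):
        ones = [i for i, b in enumerate(bits) if b == "1"]
        if all(b - a > k for a, b in zip(ones, ones[1:])):
            n += 1
    return n


def bisection_root(k: int) -> float:
    lo, hi = 1.0, 2.0
    f = lambda a: a ** (k + 1) - a**k - 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestRefractoryIndex:
    @pytest.mark.parametrize(
        "T,tau,k",
        [(30, 51.5, 1), (60, 51.5, 0), (15, 51.5, 3), (20, 51.5, 2), (51.5, 51.5, 0)],
    )
    def test_examples(self, T, tau, k):
        assert th.refractory_index(T, tau) == k

    def test_strict_inequality_at_divisor(self):
        # j*T < tau strictly: tau an exact multiple of T stays below
        assert th.refractory_index(30, 60) == 1
        assert th.refractory_index(20, 60) == 2

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            th.refractory_index(0, 51.5)
        with pytest.raises(ValueError):
            th.refractory_index(30, -1)


class TestTranscode:
    @pytest.mark.parametrize(
        "seq,k,out",
        [
            ("111", 1, "101"),
            ("111", 2, "100"),
            ("110", 1, "100"),
            ("011", 1, "010"),
            ("1111", 1, "1010"),
            ("110", 2, "100"),
            ("101", 2, "100"),
            ("000", 3, "000"),
        ],
    )
    def test_worked_examples(self, seq, k, out):
        assert th.transcode(seq, k) == out

    def test_k0_is_identity(self):
        for L in (1, 3, 5):
            for s in th.all_sequences(L):
                assert th.transcode(s, 0) == s

    def test_idempotent_exhaustive(self):
        for k in range(5):
            for L in range(1, 9):
                for s in th.all_sequences(L):
                    once = th.transcode(s, k)
                    assert th.transcode(once, k) == once

    def test_fixed_points_are_gap_constrained(self):
        for k in range(5):
            for L in range(1, 9):
                fixed = [s for s in th.all_sequences(L) if th.transcode(s, k) == s]
                assert len(fixed) == brute_fixed_point_count(L, k)

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            th.transcode("10x", 1)


class TestGroups:
    def test_L4_k1_groups_match_worked_partition(self):
        part = th.enumerate_groups(4, 1)
        expected = {
            ("0000",),
            ("0001",),
            ("0010", "0011"),
            ("0100", "0110"),
            ("0101", "0111"),
            ("1000", "1100"),
            ("1001", "1101"),
            ("1010", "1011", "1110", "1111"),
        }
        assert set(part.groups) == expected
        assert part.K == 8

    @pytest.mark.parametrize("L,k,K", [(3, 1, 5), (3, 2, 4), (2, 0, 4), (4, 2, 6), (4, 3, 5)])
    def test_group_counts(self, L, k, K):
        assert th.enumerate_groups(L, k).K == K

    def test_representatives_are_fixed_points_and_members(self):
        for L, k in [(4, 1), (5, 2), (6, 3)]:
            part = th.enumerate_groups(L, k)
            for rep, grp in zip(part.representatives, part.groups):
                assert th.transcode(rep, k) == rep
                assert rep in grp

    def test_groups_partition_all_sequences(self):
        for L, k in [(4, 1), (6, 2)]:
            part = th.enumerate_groups(L, k)
            seqs = sorted(s for g in part.groups for s in g)
            assert seqs == th.all_sequences(L)

    def test_K_equals_fixed_point_count_exhaustive(self):
        for k in range(4):
            for L in range(1, 11):
                assert th.enumerate_groups(L, k).K == th.count_fixed_points(L, k)


class TestCounts:
    @pytest.mark.parametrize("L,k,n", [(3, 1, 5), (4, 2, 6), (1, 0, 2), (1, 7, 2), (4, 1, 8)])
    def test_examples(self, L, k, n):
        assert th.count_fixed_points(L, k) == n

    @given(L=st.integers(1, 14), k=st.integers(0, 4))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, L, k):
        assert th.count_fixed_points(L, k) == brute_fixed_point_count(L, k)

    def test_recurrence_holds(self):
        for k in (1, 2, 3, 10):
            ns = [th.count_fixed_points(L, k) for L in range(1, 40)]
            for L in range(k + 1, 38):
                assert ns[L] == ns[L - 1] + ns[L - 1 - k]


class TestAsymptotics:
    @pytest.mark.parametrize("k", [1, 2, 3, 5, 10])
    def test_dominant_root_matches_bisection_oracle(self, k):
        assert th.dominant_root(k) == pytest.approx(bisection_root(k), abs=1e-9)

    def test_golden_ratio(self):
        assert th.dominant_root(1) == pytest.approx((1 + np.sqrt(5)) / 2, abs=1e-10)

    def test_roots_decrease_within_unit_band(self):
        roots = [th.dominant_root(k) for k in range(1, 30)]
        assert all(1 < a < 2 for a in roots)
        assert all(a > b for a, b in zip(roots, roots[1:]))

    def test_prefactor_matches_eigendecomposition_oracle(self):
        for k in (1, 2, 3, 10):
            coeffs = [1.0, -1.0] + [0.0] * (k - 1) + [-1.0]
            roots = np.roots(coeffs)
            A = np.array([[r**L for r in roots] for L in range(1, k + 2)])
            b = np.array([L + 1 for L in range(1, k + 2)], dtype=complex)
            c = np.linalg.solve(A, b)
            c_dom = c[np.argmax(np.abs(roots))].real
            assert th.prefactor(k) == pytest.approx(c_dom, abs=1e-4)

    def test_prefactor_self_consistency(self):
        for k in (1, 2, 3):
            a, c = th.dominant_root(k), th.prefactor(k)
            ratio = th.count_fixed_points(40, k) / (c * a**40)
            assert ratio == pytest.approx(1.0, rel=0.01)

    def test_golden_prefactor_closed_form(self):
        phi = (1 + np.sqrt(5)) / 2
        assert th.prefactor(1) == pytest.approx(phi**2 / np.sqrt(5), abs=1e-4)

    @pytest.mark.parametrize("k,C", [(1, 1.39), (2, 1.65), (3, 1.86)])
    def test_asymptotic_bitrates(self, k, C):
        assert th.asymptotic_bitrate(k) == pytest.approx(C, abs=0.005)

    def test_capacity_increases_and_approaches_log2k(self):
        Cs = [th.asymptotic_bitrate(k) for k in range(1, 101)]
        assert all(b > a for a, b in zip(Cs, Cs[1:]))
        ratios = [th.asymptotic_bitrate(k) / np.log2(k) for k in (10, 30, 100)]
        # C(k)/log2(k) -> 1 from above as k grows
        assert all(r1 > r2 for r1, r2 in zip(ratios, ratios[1:]))
        assert ratios[-1] == pytest.approx(1.0, abs=0.35)

    def test_finite_L_mi(self):
        assert th.finite_L_mi(0, 4)[0] == pytest.approx(4.0)
        assert th.finite_L_mi(1, 4)[0] == pytest.approx(3.0)
        assert th.finite_L_mi(1, 3)[0] == pytest.approx(np.log2(5), abs=1e-9)
        for k in (1, 2, 3):
            exact, asym = th.finite_L_mi(k, 12)
            assert exact == pytest.approx(asym, abs=0.02)


def brute_partition_mi(part, p):
    """Eq-3.2-style finite sum over the deterministic conditional channel."""
    seqs = th.all_sequences(part.L)
    gof = part.group_of()
    q = np.zeros(part.K)
    for i, s in enumerate(seqs):
        q[gof[s]] += p[i]
    mi = 0.0
    for i, s in enumerate(seqs):
        if p[i] > 0:
            mi += p[i] * np.log2(1.0 / q[gof[s]])  # P(y|x)=1 at the group output
    return mi


class TestPartitionMI:
    def test_equal_all_worked_values(self):
        assert th.exact_mi_partition(th.enumerate_groups(4, 1)).MI == pytest.approx(2.875)
        assert th.exact_mi_partition(th.enumerate_groups(4, 2)).MI == pytest.approx(2.375)
        assert th.exact_mi_partition(th.enumerate_groups(4, 3)).MI == pytest.approx(1.875)

    def test_maximized_equals_log2K(self):
        for L, k in [(4, 1), (4, 2), (4, 3), (3, 1)]:
            part = th.enumerate_groups(L, k)
            assert th.exact_mi_partition(part, scheme="maximized").MI == pytest.approx(
                np.log2(part.K)
            )

    def test_equal_all_below_maximized(self):
        for L in (3, 4, 5, 6):
            for k in (1, 2, 3):
                part = th.enumerate_groups(L, k)
                lo = th.exact_mi_partition(part, scheme="equal-all").MI
                hi = th.exact_mi_partition(part, scheme="maximized").MI
                assert lo <= hi + 1e-12

    @given(L=st.integers(2, 6), k=st.integers(0, 3), seed=st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_sum_for_random_p(self, L, k, seed):
        part = th.enumerate_groups(L, k)
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(2**L))
        got = th.exact_mi_partition(part, p=p)
        assert got.MI == pytest.approx(brute_partition_mi(part, p), abs=1e-10)
        assert got.MI == pytest.approx(got.H_X - got.H_X_given_Y, abs=1e-9)

    def test_any_group_mass_eighth_achieves_max(self):
        part = th.enumerate_groups(4, 1)
        seqs = th.all_sequences(4)
        rng = np.random.default_rng(0)
        p = np.zeros(16)
        for grp in part.groups:
            w = rng.dirichlet(np.ones(len(grp)))
            for s, wi in zip(grp, w):
                p[seqs.index(s)] = wi / 8.0
        assert th.exact_mi_partition(part, p=p).MI == pytest.approx(3.0, abs=1e-12)

    def test_rejects_bad_distribution(self):
        part = th.enumerate_groups(3, 1)
        with pytest.raises(ValueError):
            th.exact_mi_partition(part, p=np.full(8, 0.2))


class TestBitrate:
    @pytest.mark.parametrize(
        "mi,L,T,rate",
        [(np.log2(5), 3, 30, 1.55), (np.log2(8), 3, 60, 1.0), (2.0, 3, 20, 2.0), (0, 5, 17, 0)],
    )
    def test_examples(self, mi, L, T, rate):
        assert th.bitrate(mi, L, T) == pytest.approx(rate, abs=0.005)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            th.bitrate(-1, 3, 30)


def test_theory_report_shapes():
    per_k, per_lk = th.theory_report(ks=(1, 2), Ls=(3, 4))
    assert list(per_k["k"]) == [1, 2]
    assert len(per_lk) == 4
    assert (per_lk["MI_max"] >= per_lk["MI_equal_all"] - 1e-12).all()
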