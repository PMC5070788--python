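import math
from fractions import Fraction

import pytest

from seedopt import (
    HomologyModel,
    ObjectiveState,
    PairOverlapTable,
    Pattern,
    PatternError,
    PatternSet,
    contributions,
    overlap_complexity,
    overlap_halfpower_sum,
    shared_count,
    shift_range,
    union_count,
    update_after_swap,
    variance_decomposition,
    variance_of_matches,
    variance_surrogate,
)
from conftest import brute_force_oc, random_set


P1 = Pattern("101011")
P2 = Pattern("111001")


class TestCounts:
    def test_worked_example_shift_two(self):
        assert union_count(P1, P2, 2) == 6
        assert shared_count(P1, P2, 2) == 2

    def test_self_zero_shift(self):
        assert union_count(P1, P1, 0) == P1.weight
        assert shared_count(P1, P1, 0) == P1.weight

    def test_disjoint_shift(self):
        p = Pattern("11")
        assert union_count(p, p, 5) == 4
        assert shared_count(p, p, 5) == 0

    def test_sigma_identity_random(self, rng):
        # sigma = 2w - n wherever both patterns have weight w
        for _ in range(300):
            s = random_set(rng, m=2)
            a, b = s[0], s[1]
            shift = int(rng.integers(-a.length - b.length, a.length + b.length))
            assert shared_count(a, b, shift) == 2 * s.weight - union_count(a, b, shift)

    def test_shift_ranges(self):
        assert list(shift_range(6, 4)) == list(range(-3, 6))
        assert list(shift_range(5, 5, self_pair=True)) == list(range(0, 5))

    def test_pair_table_consistent(self):
        t = PairOverlapTable.compute(P1, P2)
        assert (t.sigma == 2 * 4 - t.n).all()
        assert (t.n >= 4).all() and (t.n <= 8).all()


class TestOverlapComplexity:
    @pytest.mark.parametrize(
        "masks, expected",
        [(["11"], 8), (["11001"], 22), (["10101"], 24), (["1101"], 20), (["1011"], 20)],
    )
    def test_single_pattern_values(self, masks, expected):
        assert overlap_complexity(PatternSet.from_strings(masks)) == expected

    def test_matches_string_oracle(self, rng):
        for _ in range(25):
            s = random_set(rng)
            masks = [p.mask for p in s]
            assert overlap_complexity(s) == brute_force_oc(masks)
            assert overlap_complexity(s, self_range="half") == brute_force_oc(
                masks, self_range="half"
            )

    def test_halfpower_identity_exact(self, rng):
        # OC == 2^(2w) * sum (1/2)^n, exactly, in rational arithmetic
        for _ in range(25):
            s = random_set(rng)
            lhs = Fraction(overlap_complexity(s))
            rhs = Fraction(2) ** (2 * s.weight) * overlap_halfpower_sum(s)
            assert lhs == rhs

    def test_reversal_and_permutation_invariance(self, rng):
        for _ in range(10):
            s = random_set(rng, m=3)
            assert overlap_complexity(s.reversed()) == overlap_complexity(s)
            perm = PatternSet(tuple(s.patterns[i] for i in (2, 0, 1)))
            assert overlap_complexity(perm) == overlap_complexity(s)


MODEL = HomologyModel(p=0.75, q=0.25, L=500)


class TestVariance:
    def test_single_position_closed_form(self):
        s = PatternSet.from_strings(["1"])
        for p, q, L in [(0.9, 0.25, 100), (0.5, 0.1, 7), (0.75, 0.25, 2)]:
            got = variance_of_matches(s, HomologyModel(p=p, q=q, L=L))
            want = L * (p - p**2) + L * (L - 1) * (q - q**2)
            assert got == pytest.approx(want, rel=1e-12)

    def test_deterministic_sequences_zero_variance(self, rng):
        s = random_set(rng, m=2)
        model = HomologyModel(p=1.0, q=1.0, L=100)
        assert variance_of_matches(s, model) == pytest.approx(0.0, abs=1e-9)

    def test_surrogate_single_position(self):
        s = PatternSet.from_strings(["1"])
        got = variance_surrogate(s, HomologyModel(p=0.5, q=0.25, L=2))
        assert got == pytest.approx(0.75, rel=1e-12)

    def test_surrogate_ranks_like_variance(self, rng):
        # same-shape sets: Eq-4 ordering equals surrogate ordering
        for _ in range(20):
            w = int(rng.integers(2, 6))
            lengths = [int(rng.integers(w + 2, 12))] * 3
            a = random_set_fixed(rng, lengths, w)
            b = random_set_fixed(rng, lengths, w)
            va, vb = variance_of_matches(a, MODEL), variance_of_matches(b, MODEL)
            sa, sb = variance_surrogate(a, MODEL), variance_surrogate(b, MODEL)
            if abs(va - vb) > 1e-9:
                assert (va < vb) == (sa < sb)

    def test_reversal_and_permutation_invariance(self, rng):
        for _ in range(10):
            s = random_set(rng, m=3)
            model = HomologyModel(p=0.8, q=0.25, L=100)
            v = variance_of_matches(s, model)
            assert variance_of_matches(s.reversed(), model) == pytest.approx(v, rel=1e-12)
            perm = PatternSet(tuple(s.patterns[i] for i in (1, 2, 0)))
            assert variance_of_matches(perm, model) == pytest.approx(v, rel=1e-12)

    def test_nonnegative_and_growth_in_L(self, rng):
        s = random_set(rng, m=2, max_len=8)
        ell = s.max_length
        for L1, L2 in [(50, 100)]:
            d1 = variance_decomposition(s, HomologyModel(p=0.8, q=0.25, L=L1))
            d2 = variance_decomposition(s, HomologyModel(p=0.8, q=0.25, L=L2))
            assert d1.total >= 0 and d2.total >= 0
            # homologous summand ~ (L - l + 1): linear growth
            assert d2.homologous / d1.homologous == pytest.approx(
                (L2 - ell + 1) / (L1 - ell + 1), rel=1e-9
            )
            # background summand ~ (L - l + 1)(L - l): quadratic growth
            assert d2.background / d1.background == pytest.approx(
                (L2 - ell + 1) * (L2 - ell) / ((L1 - ell + 1) * (L1 - ell)), rel=1e-9
            )

    def test_sequence_shorter_than_pattern_rejected(self):
        s = PatternSet.from_strings(["10101"])
        with pytest.raises(ValueError, match="shorter"):
            variance_of_matches(s, HomologyModel(p=0.75, q=0.25, L=4))


def random_set_fixed(rng, lengths, w):
    from seedopt import random_pattern_set

    return random_pattern_set(len(lengths), lengths, w, rng, anchored=False)


class TestContributions:
    def test_single_pattern_is_whole_objective(self):
        s = PatternSet.from_strings(["11001"])
        assert contributions(s, "oc") == [overlap_complexity(s)]

    def test_sum_identity(self, rng):
        # sum_r C_r = 2 * objective - sum_r alpha_{r,r}
        for objective in ("oc", "variance"):
            s = random_set(rng, m=3)
            model = HomologyModel(p=0.8, q=0.25, L=100)
            state = ObjectiveState(s, objective=objective, model=model)
            c = state.contributions()
            diag = [state.alpha[r, r] for r in range(s.m)]
            lhs = math.fsum(c)
            rhs = 2 * state.objective() - math.fsum(diag)
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_mirror_pair_symmetric(self):
        # a pattern and its reversal play symmetric roles
        s = PatternSet.from_strings(["1101", "1011"])
        c = contributions(s, "oc")
        assert c[0] == c[1]


class TestIncrementalUpdate:
    def test_swap_is_involution(self):
        s = PatternSet.from_strings(["110101", "111001"])
        state = ObjectiveState(s, objective="oc")
        before_obj = state.objective()
        before_alpha = state.alpha.copy()
        update_after_swap(s, 0, 1, 2, state=state)
        update_after_swap(state.pattern_set(), 0, 2, 1, state=state)
        assert state.objective() == before_obj
        assert (state.alpha == before_alpha).all()

    @pytest.mark.parametrize("objective", ["oc", "variance"])
    def test_incremental_equals_scratch(self, rng, objective):
        model = HomologyModel(p=0.75, q=0.25, L=300)
        s = random_set(rng, m=3, anchored=False, max_len=10)
        state = ObjectiveState(s, objective=objective, model=model)
        for _ in range(60):
            r = int(rng.integers(s.m))
            cur = Pattern.from_bits(int(state.bits[r]), int(state.lengths[r]))
            if not cur.dontcare_positions:
                continue
            i = cur.match_positions[int(rng.integers(len(cur.match_positions)))]
            j = cur.dontcare_positions[int(rng.integers(len(cur.dontcare_positions)))]
            try:
                obj, contr = update_after_swap(
                    state.pattern_set(), r, i, j, state=state
                )
            except PatternError:
                continue  # swap collides with another mask in the set
            fresh = ObjectiveState(state.pattern_set(), objective=objective, model=model)
            assert obj == fresh.objective()
            assert contr == fresh.contributions()

    def test_anchoring_violation_rejected(self):
        s = PatternSet.from_strings(["11011", "10111"])
        state = ObjectiveState(s)
        state.swap_bits(0, 1, 2)  # interior swap: allowed
        with pytest.raises(PatternError, match="anchor"):
            state.swap_bits(0, 0, 2)  # breaking an end is refused

    def test_known_swap_keeps_oc(self):
        # 1101 -> 1011 is a reversal; the OC (20) is invariant
        s = PatternSet.from_strings(["1101"])
        obj, _ = update_after_swap(s, 0, 1, 2)
        assert obj == 20


class TestHomologyModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            HomologyModel(p=1.2)
        with pytest.raises(ValueError):
            HomologyModel(p=0.5, L=0)
        with pytest.warns(UserWarning, match="regime"):
            HomologyModel(p=0.2, q=0.5)
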