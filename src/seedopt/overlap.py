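"""Pairwise shift combinatorics of spaced-seed sets and the two closed-form
objectives built on them: the *overlap complexity* (OC) and the approximate
*variance* of the number N of spaced-word matches.

For two patterns P_r, P_r' and an integer shift s (P_r' shifted s positions
to the right of P_r; negative s shifts left), n(P_r, P_r', s) is the number
of columns that are match positions of P_r *or* P_r', and sigma_{r,r'}[s]
the number of columns that are match positions of *both*.  When the two
patterns have equal weight w, sigma = 2w - n.

The overlap complexity of a set P = {P_1, ..., P_m} is

    OC(P) = sum_{r <= r'} sum_{s = 1 - l_r'}^{l_r - 1} 2^sigma_{r,r'}[s]

summed over the full symmetric shift range for every pair, the diagonal
pairs included.  In the homology model without indels -- match probability
p at homologous positions (i = j), background match probability q
elsewhere, sequences of length L -- the variance of the P-match count N is
approximated by

    Var(N) ~= (L - l + 1)       * sum_{r<=r'} sum_{s in R(r,r')} (p^n - p^2w)
            + (L - l + 1)(L - l) * sum_{r<=r'} sum_{s in R(r,r')} (q^n - q^2w)

with l = max_r l_r and the shift range R(r,r') = {1-l_r', ..., l_r - 1} for
r < r' but only {0, ..., l_r - 1} on the diagonal (shifting a pattern
against itself in both directions would double-count).  Note the OC as
defined above uses the full range on the diagonal as well; both diagonal
conventions are available through the ``self_range`` flag.

Minimizing Var(N) over sets of fixed shape (m, lengths, weight) is
equivalent to minimizing the surrogate

    sum_{r<=r'} sum_{s in R(r,r')} p^n  +  (L - l) * sum ... q^n

because the subtracted p^2w / q^2w terms only depend on the shape.

Both objectives decompose into additive per-pair terms alpha_{r,r'}, and
the contribution of one pattern, C_r = sum_{r'} alpha_{r,r'}, falls out as
a by-product; the hill climber uses C_r to decide which pattern to mutate
first.  :class:`ObjectiveState` caches the per-pair terms so that probing
a single match/don't-care swap costs only the pairs involving the touched
pattern, O(m * l^2), instead of a full recomputation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Literal

import numpy as np

from .patterns import Pattern, PatternSet, PatternError

__all__ = [
    "HomologyModel",
    "PairOverlapTable",
    "union_count",
    "shared_count",
    "shift_range",
    "overlap_complexity",
    "overlap_halfpower_sum",
    "VarianceDecomposition",
    "variance_decomposition",
    "variance_of_matches",
    "variance_surrogate",
    "contributions",
    "ObjectiveState",
    "update_after_swap",
]

# int64 bit arithmetic on shifted masks needs l_r + l_r' - 1 <= 62; longer
# pairs take the arbitrary-precision Python path.
_INT64_BITS = 62


@dataclass(frozen=True)
class HomologyModel:
    """Parameters of the indel-free homology model.

    p : match probability at homologous positions (i = j)
    q : background match probability (i != j); 0.25 for uniform nucleotides
    L : sequence length in the variance model
    H : homology-region length in the sensitivity model
    """

    p: float
    q: float = 0.25
    L: int = 10_000
    H: int = 64

    def __post_init__(self) -> None:
        for name in ("p", "q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if not self.q <= self.p:
            warnings.warn(
                f"homology model outside the intended regime: q={self.q} > p={self.p}",
                stacklevel=2,
            )
        if self.L < 1:
            raise ValueError(f"L must be positive, got {self.L}")
        if self.H < 1:
            raise ValueError(f"H must be positive, got {self.H}")


def union_count(p1: Pattern, p2: Pattern, s: int) -> int:
    """n(P_r, P_r', s): columns that are match positions of either pattern."""
    a, b = p1.bits, p2.bits
    if s >= 0:
        return ((a | (b << s))).bit_count()
    return (((a << -s) | b)).bit_count()


def shared_count(p1: Pattern, p2: Pattern, s: int) -> int:
    """sigma_{r,r'}[s]: columns that are match positions of both patterns."""
    a, b = p1.bits, p2.bits
    if s >= 0:
        return ((a & (b << s))).bit_count()
    return (((a << -s) & b)).bit_count()


def shift_range(len_r: int, len_rp: int, self_pair: bool = False) -> range:
    """R(r, r'): shifts of P_r' against P_r.

    ``{1 - l_r', ..., l_r - 1}`` for distinct patterns; ``{0, ..., l_r - 1}``
    for a pattern against itself.
    """
    if self_pair:
        return range(0, len_r)
    return range(1 - len_rp, len_r)


@dataclass(frozen=True)
class PairOverlapTable:
    """Per-shift union and shared counts for one pattern pair."""

    shifts: np.ndarray
    n: np.ndarray
    sigma: np.ndarray

    @classmethod
    def compute(cls, p1: Pattern, p2: Pattern, self_pair: bool = False) -> "PairOverlapTable":
        shifts = np.array(shift_range(p1.length, p2.length, self_pair=self_pair))
        n = np.array([union_count(p1, p2, int(s)) for s in shifts])
        sigma = np.array([shared_count(p1, p2, int(s)) for s in shifts])
        return cls(shifts=shifts, n=n, sigma=sigma)


# ---------------------------------------------------------------------------
# vectorized per-pair shift tables (internal)
# ---------------------------------------------------------------------------

def _sigma_over_shifts(a: int, la: int, b: int, lb: int, lo: int) -> np.ndarray:
    """sigma over shifts s = lo .. la-1 of pattern b against pattern a."""
    s = np.arange(lo, la)
    if la + lb - 1 <= _INT64_BITS:
        aa = np.int64(a) << np.maximum(-s, 0)
        bb = np.int64(b) << np.maximum(s, 0)
        return np.bitwise_count(aa & bb).astype(np.int64)
    vals = [((a << max(-int(t), 0)) & (b << max(int(t), 0))).bit_count() for t in s]
    return np.array(vals, dtype=np.int64)


def _n_over_shifts(a: int, la: int, b: int, lb: int, lo: int) -> np.ndarray:
    s = np.arange(lo, la)
    if la + lb - 1 <= _INT64_BITS:
        aa = np.int64(a) << np.maximum(-s, 0)
        bb = np.int64(b) << np.maximum(s, 0)
        return np.bitwise_count(aa | bb).astype(np.int64)
    vals = [((a << max(-int(t), 0)) | (b << max(int(t), 0))).bit_count() for t in s]
    return np.array(vals, dtype=np.int64)


def _pair_ranges(pset: PatternSet, self_range: Literal["full", "half"]):
    """Yield (r, r', lo) for all unordered pairs with their shift-range start."""
    lengths = pset.lengths
    for r in range(pset.m):
        for rp in range(r, pset.m):
            if r == rp and self_range == "half":
                lo = 0
            else:
                lo = 1 - lengths[rp]
            yield r, rp, lo


# ---------------------------------------------------------------------------
# overlap complexity
# ---------------------------------------------------------------------------

def overlap_complexity(
    pset: PatternSet, *, self_range: Literal["full", "half"] = "full"
) -> int:
    """Exact integer overlap complexity of a pattern set.

    ``self_range='full'`` sums diagonal pairs over the full symmetric shift
    range (the definition of the OC); ``'half'`` restricts the diagonal to
    non-negative shifts, the convention of the variance formula.
    """
    pats = pset.patterns
    total = 0
    for r, rp, lo in _pair_ranges(pset, self_range):
        a, b = pats[r], pats[rp]
        sigma = _sigma_over_shifts(a.bits, a.length, b.bits, b.length, lo)
        total += sum(1 << int(x) for x in sigma)
    return total


def overlap_halfpower_sum(
    pset: PatternSet, *, self_range: Literal["full", "half"] = "full"
) -> Fraction:
    """Exact value of sum_{r<=r'} sum_s (1/2)^n(P_r, P_r', s).

    Satisfies ``overlap_complexity(S) == 2**(2w) * overlap_halfpower_sum(S)``
    exactly: with equal weights, sigma = 2w - n for every pair and shift.
    """
    pats = pset.patterns
    total = Fraction(0)
    for r, rp, lo in _pair_ranges(pset, self_range):
        a, b = pats[r], pats[rp]
        n = _n_over_shifts(a.bits, a.length, b.bits, b.length, lo)
        total += sum(Fraction(1, 1 << int(x)) for x in n)
    return total


# ---------------------------------------------------------------------------
# variance of the number of spaced-word matches
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceDecomposition:
    """Approximate Var(N) split into its homologous and background parts."""

    homologous: float
    background: float

    @property
    def total(self) -> float:
        return self.homologous + self.background


def _check_model(pset: PatternSet, model: HomologyModel) -> None:
    if model.L < pset.max_length:
        raise ValueError(
            f"sequence length L={model.L} is shorter than the longest pattern "
            f"({pset.max_length})"
        )


def variance_decomposition(
    pset: PatternSet, model: HomologyModel, *, complete: bool = False
) -> VarianceDecomposition:
    """Approximate variance of the P-match count N, by summand.

    The homologous part grows linearly in L, the background part
    quadratically; for long sequences the background dominates.

    With ``complete=False`` (default) each unordered pair of window
    positions contributes its covariance term once -- the conventional
    one-sided pair sum, the quantity the optimizer minimizes and reports.
    With ``complete=True`` every off-diagonal covariance is counted twice,
    as the full expansion Var(sum X) = sum Var(X) + 2 sum_{pairs} Cov
    requires; this is the value to compare against an empirical variance
    from simulation.  The two differ by a shape-dependent factor close to
    2, so they rank pattern sets of fixed shape identically.
    """
    _check_model(pset, model)
    pats = pset.patterns
    ell = pset.max_length
    w2 = 2 * pset.weight
    p, q, L = model.p, model.q, model.L
    hom_terms: list[float] = []
    bg_terms: list[float] = []
    for r in range(pset.m):
        for rp in range(r, pset.m):
            a, b = pats[r], pats[rp]
            if complete:
                # ordered pairs: cross-pattern terms twice; the self pair
                # over the full symmetric shift range (s = 0 once)
                lo, mult = 1 - b.length, (1 if r == rp else 2)
            else:
                lo = 0 if r == rp else 1 - b.length
                mult = 1
            n = _n_over_shifts(a.bits, a.length, b.bits, b.length, lo)
            hom_terms.extend((mult * (np.power(p, n) - p**w2)).tolist())
            bg_terms.extend((mult * (np.power(q, n) - q**w2)).tolist())
    hom = (L - ell + 1) * math.fsum(hom_terms)
    bg = (L - ell + 1) * (L - ell) * math.fsum(bg_terms)
    return VarianceDecomposition(homologous=hom, background=bg)


def variance_of_matches(
    pset: PatternSet, model: HomologyModel, *, complete: bool = False
) -> float:
    """Approximate Var(N) in the indel-free homology model."""
    return variance_decomposition(pset, model, complete=complete).total


def variance_surrogate(pset: PatternSet, model: HomologyModel) -> float:
    """Shape-constant-free surrogate whose minimizers coincide with Var(N)'s."""
    _check_model(pset, model)
    pats = pset.patterns
    ell = pset.max_length
    p, q, L = model.p, model.q, model.L
    terms: list[float] = []
    for r, rp, lo in _pair_ranges(pset, "half"):
        a, b = pats[r], pats[rp]
        n = _n_over_shifts(a.bits, a.length, b.bits, b.length, lo)
        terms.extend(np.power(p, n).tolist())
        terms.extend(((L - ell) * np.power(q, n)).tolist())
    return math.fsum(terms)


# ---------------------------------------------------------------------------
# per-pair terms, contributions, incremental state
# ---------------------------------------------------------------------------

Objective = Literal["oc", "variance"]


def _default_self_range(objective: Objective) -> Literal["full", "half"]:
    # Each objective follows its own printed definition on the diagonal.
    return "full" if objective == "oc" else "half"


def contributions(
    pset: PatternSet,
    objective: Objective = "oc",
    model: HomologyModel | None = None,
    *,
    self_range: Literal["full", "half"] | None = None,
) -> list:
    """Per-pattern contributions C_r = sum_{r'} alpha_{r,r'}.

    Off-diagonal pair terms are counted in both C_r and C_r', the diagonal
    term once, so ``sum_r C_r == 2 * objective - sum_r alpha_{r,r}``.
    Integer values for the OC, floats for the variance objective.
    """
    state = ObjectiveState(pset, objective=objective, model=model, self_range=self_range)
    return state.contributions()


class ObjectiveState:
    """Cached per-pair objective terms supporting O(m * l^2) swap probes.

    Stores alpha_{r,r'} for all unordered pairs of the current set.  The
    canonical objective value is the sum of the upper triangle in row-major
    order (``math.fsum`` for the variance objective), and a probe evaluates
    a candidate by recomputing only the row of pairs that involve the
    touched pattern -- the result is bit-identical to a from-scratch
    rebuild of the state.
    """

    def __init__(
        self,
        pset: PatternSet,
        objective: Objective = "oc",
        model: HomologyModel | None = None,
        *,
        self_range: Literal["full", "half"] | None = None,
    ) -> None:
        if objective not in ("oc", "variance"):
            raise ValueError(f"unknown objective {objective!r}")
        if objective == "variance":
            if model is None:
                raise ValueError("the variance objective requires a HomologyModel")
            _check_model(pset, model)
        self.objective_kind: Objective = objective
        self.model = model
        self.self_range = self_range or _default_self_range(objective)
        self.m = pset.m
        self.weight = pset.weight
        self.lengths = np.array(pset.lengths, dtype=np.int64)
        self.max_length = pset.max_length
        self.anchored = pset.is_anchored
        self.bits = np.array([p.bits for p in pset.patterns], dtype=np.int64)
        if int(self.lengths.max()) * 2 - 1 > _INT64_BITS:
            raise ValueError(
                "incremental evaluation supports pattern lengths up to "
                f"{(_INT64_BITS + 1) // 2}; use the from-scratch functions instead"
            )
        if objective == "oc" and self.weight + math.ceil(
            math.log2(2 * self.max_length * self.m**2 + 1)
        ) > _INT64_BITS:
            raise ValueError("pattern weight too large for exact int64 OC accumulation")
        if objective == "variance":
            p, q, L = model.p, model.q, model.L
            npow = np.arange(2 * self.weight + 1)
            # per-shift alpha term: (L-l+1) * (p^n + (L-l) q^n), n = 2w - sigma
            self._term_by_sigma = (L - self.max_length + 1) * (
                np.power(p, npow) + (L - self.max_length) * np.power(q, npow)
            )[::-1].copy()
        self._iu = np.triu_indices(self.m)
        # cached shift-index arrays for the probe hot path
        self._kpos = np.arange(int(self.lengths.max())).reshape(-1, 1)
        self._valid_pos = self._kpos < self.lengths.reshape(1, -1)
        self._kneg = {
            int(l): np.arange(1, int(l)).reshape(-1, 1) for l in set(self.lengths.tolist())
        }
        self.probe_count = 0
        # alpha[r, rp]: per-pair additive term, symmetric storage
        dtype = np.int64 if objective == "oc" else np.float64
        self.alpha = np.zeros((self.m, self.m), dtype=dtype)
        for r in range(self.m):
            row = self._alpha_row(r, int(self.bits[r]))
            self.alpha[r, :] = row
            self.alpha[:, r] = row

    # -- per-pair term computation ------------------------------------------

    def _alpha_row(self, r: int, new_bits: int) -> np.ndarray:
        """alpha terms of pattern r (with mask ``new_bits``) against every
        pattern of the current set, itself included."""
        lr = int(self.lengths[r])
        others = self.bits.copy()
        others[r] = new_bits
        # shifts s = 1 .. lr - 1: the partner mask shifted right against r's
        kneg = self._kneg[lr]
        sig_neg = np.bitwise_count((others << kneg) & new_bits)
        # shifts s = 0 .. -(l_{r'} - 1): r's mask shifted right against partner
        shifted = np.int64(new_bits) << self._kpos
        sig_pos = np.bitwise_count(shifted & others)
        valid_pos = self._valid_pos
        if self.objective_kind == "oc":
            row = (np.int64(1) << sig_pos * valid_pos) * valid_pos
            row = row.sum(axis=0) + (np.int64(1) << sig_neg).sum(axis=0)
            if self.self_range == "half":
                # drop one side of the diagonal; sigma(A, A, s) = sigma(A, A, -s)
                row[r] -= int((np.int64(1) << sig_neg[:, r]).sum())
            return row
        term = self._term_by_sigma
        row = (term[sig_pos] * valid_pos).sum(axis=0) + term[sig_neg].sum(axis=0)
        if self.self_range == "half":
            row[r] -= term[sig_neg[:, r]].sum()
        return row

    # -- objective / contributions ------------------------------------------

    def _total(self, alpha: np.ndarray):
        vals = alpha[self._iu]
        if self.objective_kind == "oc":
            return int(vals.sum())
        return math.fsum(vals.tolist())

    def objective(self):
        """Current objective value (exact int for OC, float for variance)."""
        return self._total(self.alpha)

    def contributions(self) -> list:
        """C_r = sum_{r'} alpha_{r,r'}, diagonal counted once."""
        sums = self.alpha.sum(axis=1)
        if self.objective_kind == "oc":
            return [int(x) for x in sums]
        return [float(x) for x in sums]

    def pattern_set(self) -> PatternSet:
        return PatternSet(
            tuple(
                Pattern.from_bits(int(b), int(l))
                for b, l in zip(self.bits, self.lengths)
            )
        )

    # -- probing and committing swaps ---------------------------------------

    def swap_bits(self, r: int, i: int, j: int) -> int:
        """Mask of pattern r after swapping match position i with don't-care j."""
        bits = int(self.bits[r])
        lr = int(self.lengths[r])
        if not 0 <= i < lr or not 0 <= j < lr:
            raise PatternError(f"positions ({i}, {j}) outside pattern of length {lr}")
        if not bits >> i & 1:
            raise PatternError(f"position {i} of pattern {r} is not a match position")
        if bits >> j & 1:
            raise PatternError(f"position {j} of pattern {r} is not a don't-care position")
        if self.anchored and (i in (0, lr - 1) or j in (0, lr - 1)):
            raise PatternError(
                f"swap ({i}, {j}) would break end-anchoring of pattern {r}"
            )
        return bits ^ (1 << i) ^ (1 << j)

    def probe(self, r: int, new_bits: int):
        """Objective value if pattern r's mask became ``new_bits``.

        Returns ``(candidate_objective, alpha_row)``; the state is unchanged.
        """
        self.probe_count += 1
        row = self._alpha_row(r, new_bits)
        alpha = self.alpha.copy()
        alpha[r, :] = row
        alpha[:, r] = row
        return self._total(alpha), row

    def probe_delta(self, r: int, new_bits: int):
        """Objective change if pattern r's mask became ``new_bits``.

        Returns ``(delta, alpha_row)``; exact for the OC (integer), a
        compensated float difference for the variance objective.  The
        state is unchanged.
        """
        self.probe_count += 1
        row = self._alpha_row(r, new_bits)
        old = self.alpha[r]
        if self.objective_kind == "oc":
            return int(row.sum()) - int(old.sum()), row
        return math.fsum((row - old).tolist()), row

    def commit(self, r: int, new_bits: int, row: np.ndarray) -> None:
        self.bits[r] = new_bits
        self.alpha[r, :] = row
        self.alpha[:, r] = row


def update_after_swap(
    pset: PatternSet,
    r: int,
    i: int,
    j: int,
    objective: Objective = "oc",
    model: HomologyModel | None = None,
    *,
    state: ObjectiveState | None = None,
):
    """Objective and contributions after swapping match position ``i`` with
    don't-care position ``j`` in pattern ``r``.

    Reuses a cached :class:`ObjectiveState` when given one (recomputing only
    the pairs involving pattern ``r``); returns
    ``(new_objective, new_contributions)``.  Raises :class:`PatternError`
    if the swap is invalid or would break end-anchoring.
    """
    if state is None:
        state = ObjectiveState(pset, objective=objective, model=model)
    new_bits = state.swap_bits(r, i, j)
    for rp in range(state.m):
        if rp != r and int(state.bits[rp]) == new_bits and state.lengths[rp] == state.lengths[r]:
            raise PatternError(
                f"swap ({i}, {j}) in pattern {r} would duplicate pattern {rp}"
            )
    _, row = state.probe(r, new_bits)
    state.commit(r, new_bits, row)
    return state.objective(), state.contributions()
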