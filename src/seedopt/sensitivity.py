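"""Hit sensitivity of a spaced-seed set in the Bernoulli homology model.

A gap-free homology region of length H is modelled as an i.i.d. 0/1 string
b_0 ... b_{H-1} with P(b_t = 1) = p (1 = the two sequences match at that
position).  A pattern P_r *hits* at offset o (0 <= o, o + l_r <= H) if
b_{o+k} = 1 for every match position k of P_r; don't-care positions are
unconstrained.  The *sensitivity* of a pattern set is the probability that
at least one pattern hits somewhere in the region -- the quantity a
hit-and-extend homology search trades against its filtration cost.

The exact value is computed by dynamic programming over the suffix state
of the region: scanning the string left to right, the distribution of the
last (l - 1) bits (l = longest relevant pattern) among the strings that
contain no hit so far is tracked; transitions that complete a hit window
are absorbed.  The state space has 2^(l-1) elements, so the cost is
O(H * 2^(l-1)) -- exponential in the pattern length, as for all known
exact algorithms (the problem is NP-hard), but entirely practical for the
seed lengths used in read mapping (l <= ~22) because each scan step is a
pair of vectorized gathers.

``sensitivity_bruteforce`` enumerates all 2^H strings and serves as the
independent oracle for the DP.
"""

from __future__ import annotations

import numpy as np

from .patterns import Pattern, PatternSet

__all__ = ["sensitivity", "sensitivity_bruteforce"]

_BRUTEFORCE_MAX_H = 22


def _dp_masks(pset: PatternSet, H: int) -> list[tuple[int, int]]:
    """(length, reversed-bit mask) per pattern that can fit in the region.

    The DP keeps the most recent bit in the least significant position, so
    a window ending at the current position holds pattern position k at
    bit (l_r - 1 - k): the pattern mask is bit-reversed.
    """
    out = []
    for p in pset:
        if p.length > H:
            continue  # cannot fit; contributes no hits, but is legal input
        rev = 0
        for k in p.match_positions:
            rev |= 1 << (p.length - 1 - k)
        out.append((p.length, rev))
    return out


def sensitivity(pset: PatternSet, H: int, p: float) -> float:
    """Probability of at least one seed hit in a length-H homology region.

    Exact up to floating point; monotone in ``p`` and ``H`` and never
    decreased by adding a pattern to the set.
    """
    if H < 1:
        raise ValueError(f"homology length H must be >= 1, got {H}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"match probability must lie in [0, 1], got {p}")
    masks = _dp_masks(pset, H)
    if not masks:
        return 0.0
    ell = max(l for l, _ in masks)
    if ell == 1:
        # only the single-position seed '1': a hit iff any of the H bits is 1
        return 1.0 - (1.0 - p) ** H
    S = 1 << (ell - 1)
    u = np.arange(S)
    pred_lo = u >> 1          # predecessor with top state bit 0: full word = u
    pred_hi = pred_lo | (S >> 1)  # top state bit 1: full word = u + S
    p_bit = np.where(u & 1, p, 1.0 - p)

    # hit[f] for a full l-bit suffix word f; patterns are enabled once the
    # scan has read l_r bits, so windows never reach before the region start
    full = np.arange(1 << ell, dtype=np.int64)
    hit = np.zeros(1 << ell, dtype=bool)
    by_step: dict[int, list[int]] = {}
    for l_r, rev in masks:
        by_step.setdefault(l_r - 1, []).append(rev)

    prob = np.zeros(S)
    prob[0] = 1.0  # virtual all-zero history; harmless, as no pattern is enabled yet
    keep_lo = np.ones(S)
    keep_hi = np.ones(S)
    for t in range(H):
        if t in by_step:
            for rev in by_step[t]:
                hit |= (full & rev) == rev
            keep_lo = 1.0 - hit[u]
            keep_hi = 1.0 - hit[u + S]
        prob = p_bit * (prob[pred_lo] * keep_lo + prob[pred_hi] * keep_hi)
    return float(1.0 - prob.sum())


def sensitivity_bruteforce(pset: PatternSet, H: int, p: float) -> float:
    """Oracle: sum P(string) over all 2^H strings that contain a hit."""
    if H < 1:
        raise ValueError(f"homology length H must be >= 1, got {H}")
    if H > _BRUTEFORCE_MAX_H:
        raise ValueError(
            f"brute-force enumeration is limited to H <= {_BRUTEFORCE_MAX_H}, got {H}"
        )
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"match probability must lie in [0, 1], got {p}")
    strings = np.arange(1 << H, dtype=np.int64)  # bit t of v = region position t
    hit = np.zeros(1 << H, dtype=bool)
    for pat in pset:
        if pat.length > H:
            continue
        mask = np.int64(pat.bits)
        for o in range(H - pat.length + 1):
            m = mask << o
            hit |= (strings & m) == m
    ones = np.bitwise_count(strings[hit]).astype(np.float64)
    return float(np.sum(p**ones * (1.0 - p) ** (H - ones)))
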