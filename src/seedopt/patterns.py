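"""Binary match / don't-care patterns ("spaced seeds") and sets of them.

A pattern is a word over {'1', '0'}: '1' marks a *match position*, '0' a
*don't-care position*.  The number of match positions is the pattern's
*weight* w.  A pattern set holds m patterns that share a common weight;
sets of this kind are used as match filters in database searching, read
mapping and alignment-free sequence comparison.

By default patterns are *end-anchored*: the first and last position must
be match positions.  This is the usual convention in seed design (a
leading or trailing don't-care position never helps, it only lengthens
the seed), but it can be switched off wherever it matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Pattern",
    "PatternSet",
    "PatternError",
    "parse_pattern_file",
    "format_pattern_set",
    "load_pattern_file",
    "write_pattern_file",
    "random_pattern_set",
    "schedule_lengths",
]


class PatternError(ValueError):
    """Invalid pattern or pattern set."""


@dataclass(frozen=True)
class Pattern:
    """A single binary match/don't-care mask.

    Parameters
    ----------
    mask : str
        Nonempty string over ``{'0', '1'}``; position 0 is the leftmost
        position of the seed.
    """

    mask: str

    def __post_init__(self) -> None:
        if not self.mask:
            raise PatternError("pattern mask must be nonempty")
        bad = set(self.mask) - {"0", "1"}
        if bad:
            raise PatternError(
                f"pattern mask may contain only '0'/'1', got {sorted(bad)!r}"
            )
        if "1" not in self.mask:
            raise PatternError("pattern must have at least one match position")

    @property
    def length(self) -> int:
        return len(self.mask)

    @property
    def weight(self) -> int:
        return self.mask.count("1")

    @cached_property
    def bits(self) -> int:
        """Integer encoding: bit k set iff position k (from the left) is a match."""
        return sum(1 << k for k, c in enumerate(self.mask) if c == "1")

    @property
    def match_positions(self) -> tuple[int, ...]:
        return tuple(k for k, c in enumerate(self.mask) if c == "1")

    @property
    def dontcare_positions(self) -> tuple[int, ...]:
        return tuple(k for k, c in enumerate(self.mask) if c == "0")

    @property
    def is_anchored(self) -> bool:
        """True iff the first and last positions are match positions."""
        return self.mask[0] == "1" and self.mask[-1] == "1"

    def reversed(self) -> "Pattern":
        return Pattern(self.mask[::-1])

    def swap(self, i: int, j: int) -> "Pattern":
        """Swap match position ``i`` with don't-care position ``j``."""
        if self.mask[i] != "1":
            raise PatternError(f"position {i} is not a match position")
        if self.mask[j] != "0":
            raise PatternError(f"position {j} is not a don't-care position")
        chars = list(self.mask)
        chars[i], chars[j] = "0", "1"
        return Pattern("".join(chars))

    @classmethod
    def from_bits(cls, bits: int, length: int) -> "Pattern":
        return cls("".join("1" if bits >> k & 1 else "0" for k in range(length)))

    def __str__(self) -> str:
        return self.mask

    def __len__(self) -> int:
        return len(self.mask)


@dataclass(frozen=True)
class PatternSet:
    """An ordered set of distinct patterns sharing a common weight."""

    patterns: tuple[Pattern, ...]

    def __post_init__(self) -> None:
        if not self.patterns:
            raise PatternError("pattern set must contain at least one pattern")
        weights = sorted({p.weight for p in self.patterns})
        if len(weights) > 1:
            raise PatternError(
                f"all patterns must share one weight; found weights {weights}"
            )
        seen: set[str] = set()
        for p in self.patterns:
            if p.mask in seen:
                raise PatternError(f"duplicate pattern {p.mask!r} in set")
            seen.add(p.mask)

    @classmethod
    def from_strings(cls, masks: Iterable[str]) -> "PatternSet":
        return cls(tuple(Pattern(m) for m in masks))

    @property
    def m(self) -> int:
        return len(self.patterns)

    @property
    def weight(self) -> int:
        return self.patterns[0].weight

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(p.length for p in self.patterns)

    @property
    def max_length(self) -> int:
        return max(p.length for p in self.patterns)

    @property
    def is_anchored(self) -> bool:
        return all(p.is_anchored for p in self.patterns)

    def replace(self, r: int, pattern: Pattern) -> "PatternSet":
        """Return a copy with pattern ``r`` replaced."""
        pats = list(self.patterns)
        pats[r] = pattern
        return PatternSet(tuple(pats))

    def reversed(self) -> "PatternSet":
        return PatternSet(tuple(p.reversed() for p in self.patterns))

    def __iter__(self) -> Iterator[Pattern]:
        return iter(self.patterns)

    def __getitem__(self, r: int) -> Pattern:
        return self.patterns[r]

    def __len__(self) -> int:
        return len(self.patterns)


# ---------------------------------------------------------------------------
# pattern-file I/O: one '0'/'1' mask per line, '#' comments and blanks ignored
# ---------------------------------------------------------------------------

def parse_pattern_file(text: str, anchored: bool = False) -> PatternSet:
    """Parse pattern-file content into a :class:`PatternSet`.

    Each non-blank, non-``#`` line must be a run of ``'0'``/``'1'``
    characters.  All patterns must share one weight.  With
    ``anchored=True`` every pattern must additionally start and end with
    a match position.
    """
    patterns: list[Pattern] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        bad = set(line) - {"0", "1"}
        if bad:
            raise PatternError(
                f"line {lineno}: invalid character(s) {sorted(bad)!r} in pattern {line!r}"
            )
        patterns.append(Pattern(line))
    if not patterns:
        raise PatternError("pattern file contains no patterns")
    weights = [p.weight for p in patterns]
    if len(set(weights)) > 1:
        raise PatternError(f"patterns have mixed weights {weights}; one shared weight required")
    if anchored:
        for k, p in enumerate(patterns):
            if not p.is_anchored:
                raise PatternError(
                    f"pattern {k + 1} ({p.mask}) violates end-anchoring: "
                    "first and last position must be match positions"
                )
    return PatternSet(tuple(patterns))


def format_pattern_set(pset: PatternSet, header: Sequence[str] = ()) -> str:
    """Render a pattern set as file content, optionally with '#' header lines."""
    lines = [f"# {h}" for h in header]
    lines.extend(p.mask for p in pset)
    return "\n".join(lines) + "\n"


def load_pattern_file(path, anchored: bool = False) -> PatternSet:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_pattern_file(fh.read(), anchored=anchored)


def write_pattern_file(path, pset: PatternSet, header: Sequence[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(format_pattern_set(pset, header=header))


# ---------------------------------------------------------------------------
# random generation and length scheduling
# ---------------------------------------------------------------------------

def _n_distinct_masks(length: int, w: int, anchored: bool) -> int:
    if anchored:
        if length == 1:
            return 1 if w == 1 else 0
        return math.comb(length - 2, w - 2)
    return math.comb(length, w)


def random_pattern_set(
    m: int,
    lengths: Sequence[int],
    w: int,
    rng: np.random.Generator,
    anchored: bool = True,
) -> PatternSet:
    """Draw ``m`` distinct random patterns of the given lengths and weight.

    The ``w`` match positions of each pattern are placed uniformly at
    random among its eligible positions (the interior positions when
    end-anchoring is active).  Duplicate masks are re-drawn, so the
    result is a valid :class:`PatternSet`; the draw is deterministic for
    a given generator state.
    """
    if m < 1:
        raise PatternError("m must be at least 1")
    if len(lengths) != m:
        raise PatternError(f"expected {m} lengths, got {len(lengths)}")
    for ell in lengths:
        if w > ell:
            raise PatternError(f"weight {w} exceeds pattern length {ell}")
        if anchored and ell >= 2 and w < 2:
            raise PatternError(
                f"end-anchoring requires weight >= 2 for length {ell} (got w={w})"
            )
    # Distinct masks only exist per length class; check the pigeonhole bound.
    by_length: dict[int, int] = {}
    for ell in lengths:
        by_length[ell] = by_length.get(ell, 0) + 1
    for ell, needed in by_length.items():
        avail = _n_distinct_masks(ell, w, anchored)
        if needed > avail:
            raise PatternError(
                f"cannot draw {needed} distinct patterns of length {ell}, weight {w}"
                f"{' (anchored)' if anchored else ''}: only {avail} distinct masks exist"
            )
    patterns: list[Pattern] = []
    seen: set[str] = set()
    for ell in lengths:
        while True:
            chars = ["0"] * ell
            if anchored and ell >= 2:
                chars[0] = chars[-1] = "1"
                interior = rng.choice(ell - 2, size=w - 2, replace=False) if w > 2 else []
                for k in interior:
                    chars[int(k) + 1] = "1"
            else:
                pos = rng.choice(ell, size=w, replace=False)
                for k in pos:
                    chars[int(k)] = "1"
            mask = "".join(chars)
            if mask not in seen:
                seen.add(mask)
                patterns.append(Pattern(mask))
                break
    return PatternSet(tuple(patterns))


def schedule_lengths(m: int, min_length: int, max_length: int) -> list[int]:
    """Pattern lengths evenly distributed between two extreme values.

    Returns a monotone non-decreasing arithmetic progression from
    ``min_length`` to ``max_length`` with ``m`` terms, rounded to the
    nearest integer.  For ``m == 1`` the single pattern takes
    ``max_length`` (for fixed weight, the longer seed is never worse).
    """
    if m < 1:
        raise PatternError("m must be at least 1")
    if min_length > max_length:
        raise PatternError(
            f"min_length ({min_length}) must not exceed max_length ({max_length})"
        )
    if m == 1:
        return [max_length]
    step = (max_length - min_length) / (m - 1)
    # floor(x + 0.5): round-half-up, independent of the platform's banker's rounding
    return [int(math.floor(min_length + r * step + 0.5)) for r in range(m)]
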