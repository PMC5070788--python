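"""Monte-Carlo machinery for the indel-free sequence-pair model.

Pairs of DNA sequences S1, S2 of equal length L are generated so that
positions match with probability p at homologous sites (i = j) and with
the uniform background probability q = 1/4 everywhere else: S1 is i.i.d.
uniform over {A, C, G, T}, and S2[i] copies S1[i] with probability p or
substitutes one of the three other letters uniformly.  The number N of
P-matches (window pairs agreeing at every match position of some pattern
in the set) is the statistic whose variance the closed-form approximation
in :mod:`seedopt.overlap` predicts; the empirical moments computed here
are the independent check of that formula.

Window coordinates in the public match-checking interface are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .patterns import Pattern, PatternSet

__all__ = [
    "SequencePair",
    "simulate_pair",
    "spaced_word_match",
    "count_matches",
    "count_matches_bruteforce",
    "empirical_moments",
    "EmpiricalMoments",
    "write_fasta_pair",
    "read_fasta_pair",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _k, _c in enumerate(b"ACGT"):
    _CODE[_c] = _k
for _k, _c in enumerate(b"acgt"):
    _CODE[_c] = _k


@dataclass(frozen=True)
class SequencePair:
    """Two equal-length nucleotide sequences."""

    s1: str
    s2: str

    def __post_init__(self) -> None:
        if len(self.s1) != len(self.s2):
            raise ValueError(
                f"sequences must have equal length, got {len(self.s1)} and {len(self.s2)}"
            )

    @property
    def length(self) -> int:
        return len(self.s1)


def _encode(seq) -> np.ndarray:
    """Sequence (str or uint8 codes) -> codes in {0, 1, 2, 3}."""
    if isinstance(seq, np.ndarray):
        return seq
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.max(initial=0) > 3:
        raise ValueError("sequence contains characters outside ACGT")
    return codes


def _simulate_codes(
    L: int, p: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    s1 = rng.integers(0, 4, size=L, dtype=np.uint8)
    keep = rng.random(L) < p
    # substitution: shift by 1..3 mod 4, uniform over the three other letters
    shift = rng.integers(1, 4, size=L, dtype=np.uint8)
    s2 = np.where(keep, s1, (s1 + shift) % 4).astype(np.uint8)
    return s1, s2


def simulate_pair(L: int, p: float, rng: np.random.Generator) -> SequencePair:
    """Draw one sequence pair of length L under the homology model.

    Realizes homologous match probability exactly ``p`` and background
    match probability q = 1/4 (both marginals are uniform).  No indels.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"match probability must lie in [0, 1], got {p}")
    c1, c2 = _simulate_codes(L, p, rng)
    return SequencePair(
        s1=_ALPHABET[c1].tobytes().decode("ascii"),
        s2=_ALPHABET[c2].tobytes().decode("ascii"),
    )


def spaced_word_match(s1: str, s2: str, i: int, j: int, pattern: Pattern) -> bool:
    """True iff the windows at 1-based starts (i, j) agree at every match
    position of ``pattern``."""
    ell = pattern.length
    if i < 1 or i + ell - 1 > len(s1) or j < 1 or j + ell - 1 > len(s2):
        raise ValueError(
            f"window ({i}, {j}) of length {ell} does not fit in sequences of "
            f"length {len(s1)}, {len(s2)}"
        )
    return all(s1[i - 1 + k] == s2[j - 1 + k] for k in pattern.match_positions)


def _spaced_words(codes: np.ndarray, pattern: Pattern) -> np.ndarray:
    """Integer-packed spaced word at every window start (2 bits per match)."""
    L = len(codes)
    W = L - pattern.length + 1
    words = np.zeros(W, dtype=np.int64)
    for idx, k in enumerate(pattern.match_positions):
        words |= codes[k : k + W].astype(np.int64) << (2 * idx)
    return words


def count_matches(s1, s2, pset: PatternSet) -> int:
    """Number N of P-matches between two sequences.

    Counts, over every pattern in the set, the window pairs (i, j) that
    agree at all of the pattern's match positions.  Computed by packing
    spaced words and multiplying per-word occurrence counts; agrees
    exactly with the brute-force definition.
    """
    c1, c2 = _encode(s1), _encode(s2)
    total = 0
    for pattern in pset:
        if pattern.length > min(len(c1), len(c2)):
            raise ValueError(
                f"pattern length {pattern.length} exceeds sequence length"
            )
        v1, cnt1 = np.unique(_spaced_words(c1, pattern), return_counts=True)
        v2, cnt2 = np.unique(_spaced_words(c2, pattern), return_counts=True)
        common, i1, i2 = np.intersect1d(v1, v2, assume_unique=True, return_indices=True)
        total += int(np.dot(cnt1[i1], cnt2[i2]))
    return total


def count_matches_bruteforce(s1: str, s2: str, pset: PatternSet) -> int:
    """Reference semantics: enumerate all window pairs (tiny inputs only)."""
    total = 0
    for pattern in pset:
        ell = pattern.length
        for i in range(1, len(s1) - ell + 2):
            for j in range(1, len(s2) - ell + 2):
                total += spaced_word_match(s1, s2, i, j, pattern)
    return total


@dataclass(frozen=True)
class EmpiricalMoments:
    """Sample moments of the P-match count over simulated pairs."""

    mean: float
    variance: float
    se_mean: float
    se_variance: float
    reps: int


def empirical_moments(
    pset: PatternSet, L: int, p: float, reps: int, rng: np.random.Generator
) -> EmpiricalMoments:
    """Sample mean and variance of N over ``reps`` independent pairs.

    The standard error of the sample variance uses the moment formula
    ``sqrt((m4 - s^4 (n-3)/(n-1)) / n)``, valid without normality.
    """
    if reps < 2:
        raise ValueError(f"reps must be >= 2, got {reps}")
    counts = np.empty(reps, dtype=np.float64)
    for t in range(reps):
        c1, c2 = _simulate_codes(L, p, rng)
        counts[t] = count_matches(c1, c2, pset)
    mean = float(counts.mean())
    var = float(counts.var(ddof=1))
    dev = counts - mean
    m4 = float(np.mean(dev**4))
    se_var = float(np.sqrt(max(m4 - var**2 * (reps - 3) / (reps - 1), 0.0) / reps))
    se_mean = float(np.sqrt(var / reps))
    return EmpiricalMoments(
        mean=mean, variance=var, se_mean=se_mean, se_variance=se_var, reps=reps
    )


def write_fasta_pair(path, pair: SequencePair, ids: tuple[str, str] = ("S1", "S2")) -> None:
    records = [
        SeqRecord(Seq(pair.s1), id=ids[0], description=""),
        SeqRecord(Seq(pair.s2), id=ids[1], description=""),
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta_pair(path) -> SequencePair:
    records = list(SeqIO.parse(path, "fasta"))
    if len(records) != 2:
        raise ValueError(f"expected exactly 2 FASTA records, found {len(records)}")
    return SequencePair(s1=str(records[0].seq), s2=str(records[1].seq))
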