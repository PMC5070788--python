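import numpy as np
import pytest
from hypothesis import settings

from seedopt import random_pattern_set

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_oc(masks, self_range="full"):
    """Independent overlap-complexity oracle working directly on mask strings.

    Places the two masks on a common column axis for every shift and counts
    shared '1' columns by character comparison; no bit tricks shared with
    the implementation under test.
    """
    total = 0
    for r, a in enumerate(masks):
        for rp in range(r, len(masks)):
            b = masks[rp]
            lo = 0 if (rp == r and self_range == "half") else 1 - len(b)
            for s in range(lo, len(a)):
                shared = 0
                for col in range(min(0, s), max(len(a), s + len(b))):
                    ca = a[col] if 0 <= col < len(a) else "0"
                    cb = b[col - s] if 0 <= col - s < len(b) else "0"
                    shared += ca == "1" and cb == "1"
                total += 2**shared
    return total


def random_set(rng, m=None, w=None, anchored=None, max_len=12):
    """Small random pattern set for property tests (re-draws infeasible shapes)."""
    from seedopt import PatternError

    while True:
        mm = m if m is not None else int(rng.integers(1, 4))
        ww = w if w is not None else int(rng.integers(2, 6))
        anc = anchored if anchored is not None else bool(rng.integers(0, 2))
        lengths = [int(rng.integers(ww, max_len + 1)) for _ in range(mm)]
        try:
            return random_pattern_set(mm, lengths, ww, rng, anchored=anc)
        except PatternError:
            continue
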