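"""Hill-climbing search for spaced-seed sets.

Two climbers are provided.  The *contribution-sorted* climber is the
workhorse: it keeps the per-pattern contributions C_r to the objective,
processes patterns in descending order of C_r (mutate the worst offender
first), and in each step probes a single random swap of a match position
with a don't-care position inside the current pattern.  An improving swap
is accepted, the contributions are updated incrementally and the scan
restarts at the top of the re-sorted list; otherwise the scan advances,
wrapping around with fresh random draws.  Each probe costs one candidate
evaluation touching only the pairs that involve the mutated pattern,
O(m * l^2).  The *all-triplet* climber evaluates every (pattern, match
position, don't-care position) swap and takes the best one, iterating to
a local minimum; it is quadratically slower and serves as the reference.

The outer driver restarts the climb from fresh random sets.  For the
sensitivity objective the climb itself always minimizes the overlap
complexity (probing the sensitivity directly would be far too expensive);
the exact sensitivity is evaluated once per batch of climbs, for the
batch's lowest-OC set, and the best set over all batches is returned --
by default 100 climbs per batch and 5,000 batches, i.e. 5,000 sensitivity
evaluations per run.

Every budget counts swap *probes* (candidate evaluations), not accepted
swaps; single climbs converge to a flat plateau well within the default
budget of 25,000 probes for typical seed shapes.  An optional
``budget_mode='accepts'`` counts accepted swaps instead, combined with a
stagnation cutoff so that a climb at a local optimum terminates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .overlap import HomologyModel, ObjectiveState, overlap_complexity, variance_of_matches
from .patterns import PatternSet, random_pattern_set, schedule_lengths
from .sensitivity import sensitivity

__all__ = [
    "HillClimbConfig",
    "OptimizationResult",
    "hill_climb",
    "hill_climb_all_triplets",
    "optimize",
]

ObjectiveName = Literal["oc", "variance", "sensitivity"]


@dataclass(frozen=True)
class HillClimbConfig:
    """Search configuration: objective, seed-set shape, model and budgets."""

    objective: ObjectiveName = "oc"
    m: int = 10
    weight: int = 8
    min_length: int = 14
    max_length: int = 14
    anchored: bool = True
    model: HomologyModel | None = None
    swaps: int = 25_000           # probe budget per hill climb
    inner: int = 100              # climbs per sensitivity evaluation
    outer: int = 5_000            # outer repetitions
    seed: int | None = None
    budget_mode: Literal["probes", "accepts"] = "probes"
    stagnation_sweeps: int | None = None  # stop after this many sweeps w/o accept

    def __post_init__(self) -> None:
        if self.objective not in ("oc", "variance", "sensitivity"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if min(self.swaps, self.inner, self.outer) < 0:
            raise ValueError("budgets must be non-negative")
        if self.objective == "variance" and self.model is None:
            raise ValueError("the variance objective requires a HomologyModel (p, q, L)")
        if self.objective == "sensitivity" and self.model is None:
            raise ValueError("the sensitivity objective requires a HomologyModel (p, H)")

    def lengths(self) -> list[int]:
        return schedule_lengths(self.m, self.min_length, self.max_length)

    @property
    def climb_objective(self) -> Literal["oc", "variance"]:
        # the sensitivity objective is never probed inside a climb; the OC
        # serves as its cheap inner surrogate
        return "variance" if self.objective == "variance" else "oc"


@dataclass
class OptimizationResult:
    """Best set found, its objective values, and the search trace."""

    pattern_set: PatternSet
    objective: ObjectiveName
    value: float | int
    oc: int | None = None
    variance: float | None = None
    sensitivity: float | None = None
    trace: list[tuple[int, float]] = field(default_factory=list)
    start_value: float | int | None = None  # objective of the first start set
    probes: int = 0
    accepts: int = 0
    seed: int | None = None


class _BlockUniform:
    """Buffered uniform(0,1) draws from a numpy Generator."""

    __slots__ = ("rng", "buf", "i", "n")

    def __init__(self, rng: np.random.Generator, block: int = 8192) -> None:
        self.rng = rng
        self.n = block
        self.buf = rng.random(block)
        self.i = 0

    def pick(self, k: int) -> int:
        """Uniform index in range(k)."""
        if self.i == self.n:
            self.buf = self.rng.random(self.n)
            self.i = 0
        u = self.buf[self.i]
        self.i += 1
        return int(u * k)


def _position_pools(state: ObjectiveState) -> tuple[list[list[int]], list[list[int]]]:
    """Swappable (match, don't-care) positions per pattern; interior only
    when the set is end-anchored."""
    matches: list[list[int]] = []
    dontcares: list[list[int]] = []
    for r in range(state.m):
        bits = int(state.bits[r])
        lr = int(state.lengths[r])
        lo, hi = (1, lr - 1) if state.anchored else (0, lr)
        matches.append([k for k in range(lo, hi) if bits >> k & 1])
        dontcares.append([k for k in range(lo, hi) if not bits >> k & 1])
    return matches, dontcares


def hill_climb(
    start: PatternSet,
    cfg: HillClimbConfig,
    rng: np.random.Generator,
) -> OptimizationResult:
    """One contribution-sorted hill climb from ``start``.

    Minimizes the OC or the match-count variance (per ``cfg``); the trace
    records ``(probe index, objective value)`` at every accepted swap.
    Deterministic for a given generator state.
    """
    state = ObjectiveState(
        start, objective=cfg.climb_objective, model=cfg.model
    )
    matches, dontcares = _position_pools(state)
    swappable = [bool(matches[r]) and bool(dontcares[r]) for r in range(state.m)]
    current = state.objective()
    start_value = current
    trace: list[tuple[int, float]] = []
    probes = accepts = 0
    if any(swappable) and cfg.swaps > 0:
        draw = _BlockUniform(rng)
        contrib = state.contributions()
        order = sorted(range(state.m), key=lambda r: (-contrib[r], r))
        taken = {int(b): int(l) for b, l in zip(state.bits, state.lengths)}
        ptr = 0
        idle_sweeps = 0
        max_probes = cfg.swaps if cfg.budget_mode == "probes" else 200 * cfg.swaps
        while probes < max_probes:
            if cfg.budget_mode == "accepts" and accepts >= cfg.swaps:
                break
            if cfg.stagnation_sweeps is not None and idle_sweeps >= cfg.stagnation_sweeps:
                break
            r = order[ptr]
            if not swappable[r]:
                ptr += 1
                if ptr == state.m:
                    ptr = 0
                continue
            i = matches[r][draw.pick(len(matches[r]))]
            j = dontcares[r][draw.pick(len(dontcares[r]))]
            new_bits = int(state.bits[r]) ^ (1 << i) ^ (1 << j)
            probes += 1
            # a swap that collides with another pattern of the set is never
            # an improvement (duplicates are forbidden); count the probe
            duplicate = taken.get(new_bits) == int(state.lengths[r]) and new_bits != int(
                state.bits[r]
            )
            if not duplicate:
                delta, row = state.probe_delta(r, new_bits)
                if delta < 0:
                    old_bits = int(state.bits[r])
                    del taken[old_bits]
                    taken[new_bits] = int(state.lengths[r])
                    state.commit(r, new_bits, row)
                    matches[r][matches[r].index(i)] = j
                    dontcares[r][dontcares[r].index(j)] = i
                    current = (
                        current + delta
                        if state.objective_kind == "oc"
                        else state.objective()
                    )
                    accepts += 1
                    trace.append((probes, float(current)))
                    contrib = state.contributions()
                    order = sorted(range(state.m), key=lambda rr: (-contrib[rr], rr))
                    ptr = 0
                    idle_sweeps = 0
                    continue
            ptr += 1
            if ptr == state.m:
                ptr = 0
                idle_sweeps += 1
    best = state.pattern_set()
    return OptimizationResult(
        pattern_set=best,
        objective=cfg.objective,
        value=current,
        trace=trace,
        start_value=start_value,
        probes=probes,
        accepts=accepts,
    )


def hill_climb_all_triplets(
    start: PatternSet,
    cfg: HillClimbConfig,
    rng: np.random.Generator | None = None,
) -> OptimizationResult:
    """Reference climber: evaluate every (r, i, j) swap, take the best,
    repeat until no swap improves the objective (a local minimum)."""
    state = ObjectiveState(start, objective=cfg.climb_objective, model=cfg.model)
    current = state.objective()
    start_value = current
    trace: list[tuple[int, float]] = []
    probes = accepts = 0
    taken = {int(b): int(l) for b, l in zip(state.bits, state.lengths)}
    while True:
        matches, dontcares = _position_pools(state)
        best_move = None
        best_val = current
        for r in range(state.m):
            for i in matches[r]:
                for j in dontcares[r]:
                    new_bits = int(state.bits[r]) ^ (1 << i) ^ (1 << j)
                    if taken.get(new_bits) == int(state.lengths[r]):
                        continue
                    cand, row = state.probe(r, new_bits)
                    probes += 1
                    if cand < best_val:
                        best_val, best_move = cand, (r, new_bits, row)
        if best_move is None:
            break
        r, new_bits, row = best_move
        del taken[int(state.bits[r])]
        taken[new_bits] = int(state.lengths[r])
        state.commit(r, new_bits, row)
        current = best_val
        accepts += 1
        trace.append((probes, float(current)))
    return OptimizationResult(
        pattern_set=state.pattern_set(),
        objective=cfg.objective,
        value=current,
        trace=trace,
        start_value=start_value,
        probes=probes,
        accepts=accepts,
    )


def _restart_rng(seed: int | None, outer_idx: int, inner_idx: int) -> np.random.Generator:
    # independent, execution-order-free substream per restart
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(outer_idx, inner_idx))
    return np.random.default_rng(ss)


def optimize(cfg: HillClimbConfig) -> OptimizationResult:
    """Full restart search per ``cfg``.

    OC / variance objectives: ``outer * inner`` independent climbs from
    fresh random sets; returns the overall minimum.  Sensitivity objective:
    per outer repetition, ``inner`` OC-minimizing climbs are run and the
    exact sensitivity is computed only for the batch's lowest-OC set; the
    set with the highest sensitivity over all repetitions wins.  The trace
    holds one row ``(repetition, batch value, best value so far)`` per
    outer repetition.
    """
    lengths = cfg.lengths()
    want_sens = cfg.objective == "sensitivity"
    best_res: OptimizationResult | None = None
    best_metric: float | None = None
    first_start: float | int | None = None
    trace: list[tuple[int, float]] = []
    probes = accepts = 0
    for k in range(cfg.outer):
        batch_res: OptimizationResult | None = None
        for i in range(cfg.inner):
            rng = _restart_rng(cfg.seed, k, i)
            start = random_pattern_set(
                cfg.m, lengths, cfg.weight, rng, anchored=cfg.anchored
            )
            res = hill_climb(start, cfg, rng)
            if first_start is None:
                first_start = res.start_value
            probes += res.probes
            accepts += res.accepts
            if batch_res is None or res.value < batch_res.value:
                batch_res = res
        assert batch_res is not None
        if want_sens:
            metric = -sensitivity(batch_res.pattern_set, cfg.model.H, cfg.model.p)
        else:
            metric = batch_res.value
        if best_metric is None or metric < best_metric:
            best_metric = metric
            best_res = batch_res
        trace.append((k, float(metric), float(best_metric)))
    assert best_res is not None
    out = OptimizationResult(
        pattern_set=best_res.pattern_set,
        objective=cfg.objective,
        value=-best_metric if want_sens else best_res.value,
        trace=trace,
        start_value=first_start,
        probes=probes,
        accepts=accepts,
        seed=cfg.seed,
    )
    out.oc = overlap_complexity(out.pattern_set)
    if cfg.model is not None:
        out.variance = variance_of_matches(out.pattern_set, cfg.model)
    if want_sens:
        out.sensitivity = float(-best_metric)
    return out
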