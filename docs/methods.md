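# Methods

## Model

All computations assume the standard indel-free pairwise homology model for
nucleotide sequences: two sequences S₁, S₂ of length L match at homologous
positions (i = j) with probability p and at all other position pairs with
the background probability q, independently across positions.  For uniform
letter composition q = 1/4, and this is the default wherever q is not given
explicitly.  A gap-free homology region of length H is the corresponding
Bernoulli(p) 0/1 string; seed hits are full windows (offset o with
o + ℓ_r ≤ H), no wrap-around or partial windows.

A pattern set holds m distinct masks sharing one weight w; lengths may
differ.  *End-anchoring* — first and last position of every mask are match
positions — is on by default, as is conventional in seed design (a
boundary don't-care only lengthens the seed without constraining
anything), and can be switched off everywhere; both conventions are
first-class because published pattern collections differ on this point.

## Objectives

**Overlap complexity.**  Computed exactly in integer arithmetic
(Python/int64 with an explicit guard on w), never in floating point: the
hill climb's accept/reject decisions on OC must not depend on rounding.
The equivalent half-power form Σ (1/2)^n is exposed as an exact rational
(`fractions.Fraction`) and the identity `OC = 2^{2w} · Σ(1/2)^n` is
asserted in the tests.  Diagonal (self) pairs are summed over the full
symmetric shift range, the definition of the OC; the variance formula
instead restricts the diagonal to s ∈ {0, …, ℓ_r−1}.  Both conventions
are available through the `self_range` flag; each quantity defaults to
its own definition.

**Variance of N.**  `variance_of_matches` implements the one-sided
pair-sum form quoted in the README (each unordered pair of window
positions counted once), which is the conventional reported scale and the
scale on which the optimizer's results are comparable with published
values.  Note that the full expansion Var(ΣX) = ΣVar(X) + 2·Σ_{pairs}Cov
counts every off-diagonal covariance twice; `complete=True` applies that
accounting, and the two are related exactly by

    complete = 2·onesided − (L−ℓ+1)·m·(p^w − p^{2w})
                          − (L−ℓ+1)(L−ℓ)·m·(q^w − q^{2w}).

Monte-Carlo validation (below) targets the complete form; for ranking
pattern sets of fixed shape the two are equivalent (affine relation with
positive slope).  Terms are accumulated with compensated summation
(`math.fsum`): up to ~m²ℓ terms spanning many orders of magnitude.
The formula itself remains an approximation — it neglects covariances
between homologous and background matches and word-collision effects —
and is accurate when spaced words are specific (weight ≳ 8 for
nucleotide alphabets); the simulation tests choose shapes in that
regime, and at w = 16 the residual bias is within ~2 sampling SEs at
20,000 replicates.

**Sensitivity.**  Exact DP over the distribution of the last ℓ−1 region
bits among hit-free prefixes, with per-pattern enablement once the scan
has read ℓ_r bits so that windows never protrude past the region start.
Each step is a pair of vectorized gathers over 2^(ℓ−1) states; ordinary
doubles throughout (H ≤ ~64 and probabilities well above underflow).
Cost O(H·2^(ℓ−1)) — seconds up to ℓ ≈ 24 — exponential in ℓ as for all
known exact methods.  A 2^H enumeration oracle (guarded at H ≤ 22) pins
correctness to 1e-12.

## Optimizer

The contribution-sorted single-swap climber is described in the README.
Numerical/design choices that were genuinely open:

- **Budget semantics.**  The budget counts swap *probes* (candidate
  evaluations), not accepted swaps: observed climbs plateau after a few
  thousand probes with only dozens of accepts, so an accept-counting
  budget would never terminate at a local optimum.  `budget_mode="accepts"`
  is provided, paired with a stagnation cutoff (`stagnation_sweeps`).
- **Strict improvement only**; ties are rejected.  This prevents cycling
  without a tabu list.  Equal contributions C_r are ordered by pattern
  index (stable sort) for determinism.
- A probe whose swap would duplicate another mask of the set is counted
  against the budget and rejected (duplicates add nothing and are invalid
  in a set).
- **Reproducibility.**  One root seed; each restart (outer k, inner i)
  derives an independent `SeedSequence(entropy=seed, spawn_key=(k, i))`
  stream, so results are independent of restart execution order.
- Sensitivity is never probed inside a climb; OC is always the inner
  surrogate.  Per outer repetition, `inner` climbs are run and one exact
  DP evaluation is spent on the batch's lowest-OC set (defaults
  100 × 5,000, matching common practice for this family of tools).
- Degenerate patterns (w = ℓ_r, or anchored with no interior positions of
  one kind) are skipped; if no pattern is swappable the climb returns its
  start set.

## Simulator

`simulate_pair` draws S₁ i.i.d. uniform and copies S₂ from S₁ with
per-position probability p, substituting one of the three other letters
otherwise.  This realizes exactly the model above with q = 1/4; a general
q would require correlated letter distributions and is deliberately out
of scope (the analytic formulas still take q as a free parameter).
Match counting packs each pattern's spaced words into 2w-bit integers and
multiplies per-word occurrence counts (O(mLw) per pair); a quadratic
brute-force counter defines the reference semantics and the two are
asserted equal.  What the simulator does *not* model: indels, composition
bias, correlated substitution processes — so passing tests validate the
formulas under the stated model, not robustness to real-genome deviations
from it.

## Benchmark problem sizes

The test and acceptance benchmarks scale the published search budgets
down to desk scale, as the package's own default experiment sizes:

- OC benchmark (m=10, ℓ=20, w=8): restart climbs converge within ~3,000
  probes at this shape, so 2,000–3,000 restarts × 3,500 probes are used;
  the best set found reaches OC ≤ 11,116.
- Variance benchmark (same shape, p=0.75, q=0.25, L=10,000): 400–500
  restarts suffice to reach Var ≤ 156,061 (one-sided scale).
- Sensitivity settings: 16 seeds w=11 H=64 p=0.70 with lengths 14–24, and
  4 seeds w=10 H=50 p=0.75 with lengths 14–22.  Length ranges were chosen
  once from an OC-surrogate scan over candidate ranges: at these weights,
  longer seeds dominate shorter ones up to the point where the DP cost
  explodes.  Reduced budgets (4 × 12 and 8 × 25 climbs per batch,
  3,000 probes each) already exceed the strongest published Iedera
  baselines for these settings (92.0708% and 90.6820%) with ~0.2–0.4
  points of margin across seeds.
- Monte-Carlo validation: m=3, ℓ=20, w=16, L=1,000, 20,000 simulated
  pairs per p ∈ {0.75, 0.9}.

## Known limitations

- Exact OC and the incremental evaluator use 64-bit mask arithmetic:
  pairs with ℓ_r + ℓ_r′ − 1 > 62 fall back to arbitrary-precision Python
  integers in the from-scratch functions, and the incremental state
  refuses lengths above 31.  Long-seed search (ℓ ≈ 44) works but loses
  the vectorized fast path.
- The sensitivity DP's memory grows as 2^(ℓ−1) doubles; ℓ ≳ 28 is
  impractical.
- The variance formula's accuracy degrades at low weight (abundant
  word collisions); see above.
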