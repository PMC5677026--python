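# Methods

## Model

A single photon-emitting target sits at an unknown position x₀, uniform on
a 1D domain [0, L].  A query illuminates a half-open interval [b, c) with an
idealized top-hat profile: the target emits exactly one signal photon iff it
is inside.  The photon survives collection with probability 1 − α₀; the
detector is assumed dark-count-free.  The readout r ∈ {0, 1} therefore obeys

    P(r=1 | inside)  = 1 − α₀        (a detection is never a lie)
    P(r=0 | inside)  = α₀            (the "half-lie")
    P(r=0 | outside) = 1             (absence is reported faithfully)

This is the statistical (probabilistic, unbounded-lie) variant of a search
game with asymmetric errors.  Because losses are unbounded, worst-case query
budgets do not exist; all results concern the *expected* query count.  The
game is one-dimensional; higher dimensions factor into independent games per
axis.  Assumptions deliberately *not* modelled: non-flat (Gaussian) beam
profiles, dark counts, photobleaching/photodamage penalties, and hardware
costs of moving or resizing the illuminated region.

## Information of a single query

With the turn-on boundary fixed at the left edge, a query [0, v) has a
binary outcome whose joint with X is piecewise constant, giving a closed
form for I(X:R) (see README).  Internal unit is nats (the entropy integrals
use ln); conversions to bits divide by ln 2 only at reporting boundaries,
keeping the "33.2 bits for ε = 10⁻¹⁰" bookkeeping exact.  p·ln p terms are
evaluated through `scipy.special.xlogy`, which implements the 0·ln 0 = 0
limit explicitly; tiny negative rounding residues at the degenerate
boundaries v ∈ {0, L} are clipped to 0.

The information-maximizing boundary v₀(α₀) is evaluated in closed form.  At
α₀ = 0 the raw expression is a 0⁰ form; the code returns the analytic limit
L/2 exactly.  v₀ is strictly decreasing in α₀, bounded in (L/e, L/2]; the
game (and v₀) is undefined at α₀ = 1, which every constructor rejects.

`estimated_optimal_queries` is the budget yardstick
⌈log₂(ε⁻¹)/I_bits(α₀, v₀)⌉.  It is not attainable by any verification-based
strategy; it is the comparison line the heuristics are measured against.

## The q-sectioning-with-verification heuristic

Each level splits the current interval into q equal subdomains, indexed
from the left.  Subdomains are queried cyclically until one returns r = 1;
only then does the search recurse.  Since r = 1 is incorruptible, the final
interval is guaranteed to contain the target at every loss rate below 1.
Every game runs exactly ⌈log_q(ε⁻¹)⌉ levels — the last split is into q
subdomains even when fewer would reach ε — so the surviving width is
≤ εL.

Expected cost: reaching the target's subdomain costs 1/(1 − α₀) passes in
expectation; each failed pass wastes q − 1 additional queries on the other
subdomains, and the final successful pass costs (q+1)/2 for a uniform
target, giving the m̄ formula of the README, which collapses to
((q+1)/2)⌈log_q(ε⁻¹)⌉ at zero loss.

Two engines produce trial outcomes:

- the **naive** simulator plays every query through the measurement model,
  consuming one RNG draw per illuminated query and none otherwise, so any
  trace replays exactly from its seed;
- the **fast** sampler draws, per level, the target's subdomain index
  l ~ U{1..q} (the base-q digits of a uniform variate are independent and
  uniform) and the detection pass count k ~ Geometric(1 − α₀), contributing
  (k − 1)q + l queries.  The two laws are identical; the tests verify this
  against an exhaustive (k, l) enumeration oracle and by two-engine
  comparison.

Interval boundaries inside a trial are tracked as integer subdomain indices
per level and materialized as L·j/qᵗ only when a query is issued, so ~30+
levels accumulate no floating-point drift and adjacent subdomains tile the
parent exactly.  Half-open intervals make subdomain membership unambiguous;
a target exactly at L (a measure-zero event never produced by the uniform
sampler) is nudged to the largest representable value below L.

## Level counts and exact arithmetic

⌈log_q(ε⁻¹)⌉ is never computed with floating-point logarithms alone:
naive `ceil(log(n)/log(q))` misfires at exact powers (e.g. 5³ and 7⁵),
silently changing level counts and every downstream cost.  `ceil_log` uses
exact integer power accumulation for integer arguments and brackets the
float estimate with exact integer powers otherwise; level counts are exact
for resolutions up to at least 2⁴⁸ (well past where raw double-precision
cost evaluation degrades).

Cost comparisons in the optimality scans are exact: the per-level prefactor
q(1/(1−α₀) − 1) + (q+1)/2 is evaluated as a rational number (a float loss
rate is interpreted as its shortest decimal repr, so 0.99 means 99/100),
costs are scaled to a common integer denominator, and argmin sets are found
by integer comparison.  Consequently tie classification is exact: at zero
loss q = 3 and q = 4 genuinely tie at many resolutions ("optimal" counts
every winner; "unique" requires a singleton), whereas at α₀ = 0.99 the
prefactors 199q + 1 (×2) break every tie and all winners are unique.  If a
loss rate's rational form needs a common denominator beyond 2³⁰ the scan
falls back to floats with a 10⁻⁹ relative tie guard.

Dense scans are vectorized (levels via `searchsorted` against exact power
tables); the full ε⁻¹ ∈ {2..2²⁴} scan runs in seconds.  For maps over both
ε and α₀, `epsilon_grid_near_powers` exploits the step-function structure of
m̄ in ε⁻¹ — it changes only as ε⁻¹ crosses a power of some candidate q — to
evaluate only {qⁱ − 1, qⁱ, qⁱ + 1} grid points.

Candidate sets default to q ∈ {2..8} for zero-loss scans (larger q never
wins outside trivially small resolutions) and q ∈ {2..5} for lossy scans;
both are arguments.  Which universe of q the notion "no better q-sectioning
solution exists" quantifies over is genuinely ambiguous; beyond q = 6 the
counts are insensitive, and the choice is surfaced as the `q_candidates`
parameter rather than hidden.

A reproducibility caveat: dense-scan win counts computed here with exact
arithmetic can differ by a handful of cells (≲ 10 in 10⁶, at resolutions
adjacent to exact powers of q) from counts computed with float-logarithm
ceilings, whose errors depend on the C library used.  The package reports
the exact-arithmetic counts.

## Monte Carlo summaries

Query counts are integers; histograms are unit-width and the CDF is
reported at the observed support.  The median of an even sample is the mean
of the central pair; the mode breaks ties toward the smallest count, and —
being an argmax over a wide discrete support — is the noisiest of the three
location summaries at feasible trial counts.  Every mean is reported with
its standard error so downstream comparisons are self-documenting.

Seeding: the fast engine draws a whole batch from `SeedSequence((seed,))`;
the naive engine derives trial i's generator from `SeedSequence((seed, i))`
so any single trial can be replayed in isolation.  Identical
(config, n_trials, seed, engine) give bit-identical summaries.

Default problem sizes: headline comparisons use 10⁶ fast-sampler trials
(matching the study design this package operationalizes); the per-query
reference engine is exercised at reduced scale (10³–10⁴ trials at
ε⁻¹ ≤ 10³), where the two engines' means are required to agree within
combined standard errors.

## What the generator does and does not emulate

Synthetic targets are uniform on [0, L], matching the model prior.  The
simulator emulates exactly the idealized physics above: top-hat queries with
perfectly controllable boundaries, i.i.d. loss, no dark counts, no sample
damage, no cost for moving or resizing the illuminated region.  Passing
tests therefore validate the mathematics of the search strategies, not the
performance of any real instrument: with a Gaussian point-spread function,
position-dependent efficiency, or appreciable dark counts, both the optimal
boundary and the verification guarantee would need re-derivation.

## Known limitations

- 1D only (higher dimensions are separable but not implemented as such).
- The greedy per-query information-maximization strategy is deliberately
  out of scope: its posterior is not a simple interval, making it costly to
  update and incompatible with the sectioning recursion.
- The Rivest-style lower bound includes the E·log₂E term for E ≥ 2, taking
  it as exactly 0 for E ≤ 1; it is a bound for *bounded* numbers of
  half-lies and serves only as a reference point in the statistical game.
- Naive-engine trials at α₀ = 0.99 cost ~10³–10⁴ queries each in Python;
  use the fast engine for large batches.
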