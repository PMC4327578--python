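# Methods

## The simulation model

`ssabatch` simulates well-mixed chemical systems as Markov jump processes:
the state is a vector of integer molecule counts, and each of the model's
irreversible reaction channels fires as a Poisson-like event whose
instantaneous rate (propensity) depends on the current counts. Simulation is
exact — Gillespie's direct method — not an approximation scheme: one reaction
fires per step, the waiting time between firings is exponential in the total
propensity, and the fired channel is chosen with probability proportional to
its propensity.

Per step, with propensities `a_i` and `a_total = Σ a_i`:

1. draw `r1, r2` uniform on `(0, 1]`;
2. `τ = ln(1/r1) / a_total`;
3. the fired channel is the smallest `m` with
   `Σ_{i<m} a_i < r2·a_total ≤ Σ_{i≤m} a_i`, found by a linear cumulative
   scan;
4. apply the net-change row of reaction `m`, advance `t += τ`, `step += 1`,
   and record the state.

Propensity forms are the mass-action stochastic-kinetics ones, restricted to
orders 0–2 (higher-order channels must be rewritten as combinations of lower
order): `c` (zeroth order), `c·x` (unimolecular), `c·x1·x2` (heterodimer),
and `c·x·(x−1)/2` (homodimer — the number of distinct pairs). The rate
constant `c` is the stochastic rate constant on the molecule-count scale;
no volume or concentration conversion is ever applied. A switch
(`combinatorial=False`, off by default) selects the non-combinatorial
`c·x²` homodimer variant for comparison with tools that use it; the
combinatorial form is the default because it is the convention under which
exact SSA matches the chemical master equation, and because it guarantees
counts can never go negative (the propensity vanishes whenever the required
reactants are insufficient). Negative counts are nevertheless asserted
against at every firing.

## Stoichiometry storage

The net-change matrix (species × reactions) of a reaction network is
typically sparse. Besides the dense form, the package stores it in
compressed row storage oriented **reaction-major**: one CRS row per
reaction, holding the indices and signed net changes of only the species
that reaction actually changes. Firing a reaction then touches `O(row)`
entries instead of scanning a matrix column, and a catalyst (same species,
same coefficient on both sides, as in `G -> G + P`) occupies no storage at
all — it is kept only in the reactant list for propensity evaluation. Note
the reaction-major orientation is deliberately transposed from the
species-major convention used when *displaying* a stoichiometry matrix: the
compressed structure exists to serve the firing update.

Footprints are reported as abstract element counts: `m·r` for the dense
matrix and `r + 2α` for the CRS (row pointers plus one index and one net
change per stored entry, `α` entries total), which equals `(2·m̄ + 1)·r`
when each reaction touches `m̄` species on average. Under equal element
widths the CRS is *larger* for very small dense models (18 vs 12 elements
for the 3-species/4-reaction benchmark); both counts are always reported and
byte figures are stated for an explicitly declared integer width, because
the crossover depends on sparsity and width, not on a universal constant.

## Random numbers and reproducibility

Every realization `r` of an ensemble run with base seed `s` draws from an
independent Mersenne Twister (MT19937) substream keyed by
`SeedSequence(entropy=s, spawn_key=(r,))`. Uniforms are mapped to `(0, 1]`
as `1 − U[0, 1)` so `ln(1/r1)` is always finite. Each step consumes exactly
two uniforms, `r1` then `r2`, in that order; together with the keyed
substreams this makes every trajectory — and therefore every output byte —
a pure function of `(seed, realization index, stop criterion)`, independent
of chunking, buffering, and writer scheduling. Any generator exposing the
same stream contract can be substituted.

## Ensemble execution and streaming

Ensembles exploit only coarse-grained parallelism semantics: realizations
are independent and run to completion one after another inside a chunk, with
no lockstep synchronization. A `StreamPlan(n_ways)` splits `[0, N)` into
contiguous chunks; a background writer thread drains a bounded queue
(capacity one chunk), so simulation of chunk `k+1` overlaps the writing of
chunk `k` — the n-way overlap contract — while output remains ordered by
realization id, then step. Ensemble state snapshots use a species-major
layout (for each species, the `N` per-realization values contiguous,
realization index fastest-varying), which is the cache- and
vectorization-friendly structure-of-arrays arrangement for batched
simulation; `ensemble_layout_check` verifies both the contiguity and that
slicing realization `r` out of a batch reproduces the standalone run `r`.

Sinks: per-realization CSV files, a single streaming gzip CSV (gzip header
written with `mtime=0` and no filename so identical runs are byte-identical),
and an HDF5 container with one group per realization plus a JSON manifest.
CSV rows pass through a `RecordBuffer` that flushes in blocks (default 1024
records; any capacity produces identical bytes — the buffer batches I/O
only). Every run emits a manifest (model content hash, seed, N, stop,
cadence, n_ways, sink, version) sufficient to reproduce it bitwise.

## Recording and stop criteria

The full state is recorded at every fired step by default (`cadence=1`);
`cadence=k` records every k-th step, plus the initial state and the final
state. Stop criteria are a step budget, a time horizon, or both (whichever
triggers first). Following the classic direct-method loop, the time check
happens *after* firing, so a time-horizon run records one state at or past
the horizon; ensemble summaries sample trajectories as piecewise-constant
functions (last recorded state at time ≤ t), so the overshoot is harmless.
A state with `a_total = 0` terminates the realization early with an
`absorbed` flag rather than an error.

## SBML import/export

Models are exchanged as SBML (Levels 2 and 3 read, L3V1 written). Species
are substance amounts read as integer counts (amounts must be integral
within 1e-9); reversible reactions are rejected with instructions to split
them into two irreversible channels, since the simulator needs one
propensity per channel. Kinetic laws are matched *symbolically*: the law's
expression is divided by the mass-action polynomial implied by the reactant
list and simplified with sympy, so any algebraically equivalent arrangement
(e.g. `0.5*c*S*(S-1)`) is accepted and the rate constant recovered; local
parameters shadow global ones on id collision. In strict mode (default)
anything that does not reduce to a supported form is rejected naming the
offending element; lenient mode falls back to the law's single parameter.
SBML unit definitions are ignored — rate constants are used verbatim on the
count scale — and the import report says so loudly. Events, rules,
function definitions, and volume semantics of compartments are out of scope.

## Benchmark families

* **Decay dimerization** (3 species, 4 reactions): `S1 -> 0` (c1),
  `S1 + S1 -> S2` (c2), `S2 -> S1 + S1` (c3), `S2 -> S3` (c4); defaults
  c = (1.0, 0.002, 0.5, 0.04), initial counts (10000, 0, 0), step budget
  11,000. The weighted total `Q = S1 + 2·S2 + 2·S3` decreases by exactly 1
  on each `S1`-decay firing and is untouched by the other three channels —
  a per-step structural invariant checked over whole trajectories.
* **Gene battery** (2k species, 2k reactions): k independent
  production-reduction units `Gi -> Gi + Pi` (c5), `Pi -> 0` (c6).
  Defaults c5 = 10, c6 = 1, G = 1, P = 0 are this package's choice (the
  family is traditionally specified without rates), picked so each `Pi` is
  an immigration–death process with stationary distribution Poisson(10) —
  a convenient analytic target. Sizes k ∈ {4, 8, 16, 32, 64, 128} reproduce
  the 8–256-reaction benchmark range.

## Validation suite and what it shows

* Waiting times at the frozen benchmark initial state vs `Exp(a_total)`
  (Kolmogorov–Smirnov, n = 10^5, significance 0.01), with a negative
  control (squared `r1`) that must fail.
* Selection frequencies through the real linear-scan selector vs
  `a_i/a_total` (chi-square, n = 10^6, significance 0.01), with an
  always-channel-0 negative control.
* Ensemble mean of a pure-decay model at t = 1 vs `x0·e^{−ct}` within 3
  standard errors at N = 10^4 (the exact SE comes from the binomial
  thinning law `X(t) ~ Bin(x0, e^{−ct})`).
* Stationary mean *and* variance of battery `P` vs `c5·G/c6` within 3 SE
  (the variance SE uses the Poisson fourth central moment), after a burn-in
  of `10/c6` time units — at least ten relaxation times of the
  immigration–death process.

Statistical tests run under fixed seeds, so the suite is deterministic in
CI; at a fresh seed each 3-SE or 0.01-significance check has roughly a
0.3–1% false-alarm rate. Ensemble variance uses the unbiased (N−1)
estimator. These checks validate the sampler's distributional correctness
and the engineering contracts; simulated trajectories are exact draws of the
model, but the benchmark families are small idealized networks — passing
says nothing about how faithfully any particular biological system is
captured by a mass-action model of it.

## Problem sizes

Default test and acceptance runs use: 10^5 KS draws, 10^6 selection draws,
10^4 pure-decay realizations, 2·10^3 battery realizations, and the benchmark
ensemble workload of 1,000 realizations × 11,000 steps with every step
recorded (~10^7 firings, tens of seconds on one CPU core; the wall time is
reported in the run manifest, never asserted). These sizes make the
statistical tolerances meaningful while keeping a full run in minutes.

## Known limitations

* Only the direct method: no next-reaction, optimized/sorting direct, or
  tau-leaping variants; propensity evaluation is O(n) per step, so very
  large networks (hundreds of reactions) are slow.
* Python inner loop: throughput is roughly 0.3–0.5 million firings per
  second per core; GPU/SIMD-style throughput is out of scope.
* SBML support covers irreversible mass-action models only.
* Chunks execute sequentially with overlapped writing; no multi-process
  simulation (results would be identical by construction, so parallelism is
  an orthogonal optimization).
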