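# Methods

## Model

A lineage starts from one founder cell carrying a division factor: content
1.0 in the deterministic engine, an integer count of `n0` molecules in the
stochastic engines.  Growth proceeds in synchronous iterations.  At each
iteration every not-yet-quiescent cell is tested against the threshold and,
if eligible, divides:

- **Deterministic**: a cell with content `x >= phi` divides into daughters
  `x*(1-p)` and `x*p`.  The large daughter is stored first, so tree
  serialization is canonical.
- **Stochastic**: a cell with `m >= phi*n0` molecules divides; the p-side
  daughter receives `a ~ Binomial(m, p)` molecules, the other `m - a`.
  Molecules segregate independently (pure binomial), the regime expected
  when asymmetry arises from daughter-volume differences.  Zero-molecule
  daughters are real quiescent cells and count toward the final size.
- **Perturbed**: as stochastic, but each eligibility test draws a fresh
  `phi' ~ Normal(phi, sigma_phi*phi)` (clipped below at 0) and each executed
  division draws `p' ~ Normal(p, sigma_p*p)` (clipped to [0, 1]).

A cell that fails its threshold test is permanently quiescent and is never
re-tested.  In the unperturbed engines this is a pure optimization (its
content never changes, so a re-test could never succeed); in the perturbed
engine it is a modelling decision — threshold noise must not let stalled
cells resume, which would contradict the quiescence interpretation.  The
clipping policy for out-of-range Gaussian draws is likewise a choice made
here; re-drawing would be an alternative.

The model deliberately excludes factor synthesis and degradation, cell
death, asynchronous division and correlated (ordered/disordered)
segregation.

## Parameters

| parameter | meaning | range / default |
|---|---|---|
| `p` | fraction of factor to the small-side daughter | (0, 0.5]; p and 1-p are the same split, p > 0.5 is folded |
| `phi` | quiescence threshold, fraction of founder content | (0, 1]; phi = 0 never terminates and is rejected |
| `n0` | founder molecule count, sets the noise scale | default 10,000 |
| `reps` | replicates per grid point | 100 (confidence maps), 1,000 (robustness curves) |
| `sigma` | Gaussian perturbation width, fraction of the mean | 0–0.10 |
| mesh | grid spacing in p and phi | 0.0025 (production), coarser for demos/tests |
| caps | safety limits | 1e5 iterations, 1e6 cells |

## Boundary and numerical conventions

- **Divide iff content >= phi.**  The rule matters at exact powers: p = 0.5,
  phi = 0.25 gives N_f = 8 because the content-0.25 generation still
  divides.  All closed forms use the same rule.
- Contents are IEEE doubles; comparisons are plain `>=` with no tolerance.
  Daughters are computed as `x*(1-p)` and `x*p`, so a division conserves
  content up to one rounding each (tests assert conservation to ~1e-14
  relative); the stochastic engines conserve integer molecules exactly.
- The fast sweep path (`final_size_deterministic`) performs the identical
  float operations as the tree builder, only without nodes, so the two agree
  exactly on every grid point.
- `linear_chain_size` accumulates `(1-p)^n` by repeated multiplication —
  the same float sequence the engine produces along the large-daughter
  spine — so closed-form/engine agreement in the p < phi regime is exact,
  not approximate.
- The molecule threshold `phi*n0` is snapped to the nearest integer when
  within 1e-9 relative (0.0025 * 10000 evaluates to 25.000000000000004 in
  floats; the intended decimal threshold is 25).
- When `phi*n0 <= 1`, every cell holding at least one molecule divides and
  molecule conservation guarantees at least one such cell forever; the
  engines raise a runaway-growth error immediately rather than spinning to
  the iteration cap.  Sweeps record such grid points as missing with the
  reason, rather than aborting.
- Mode ties in a size distribution break toward the smallest N_f.  A grid
  point's topology class under noise is the majority class over its
  replicates (replicates can genuinely disagree near region borders); an
  exact tie counts as non-linear.

## Randomness

One master seed governs a run.  Substreams are derived through
`numpy.random.SeedSequence` spawn keys addressed by (grid i, grid j,
replicate), so any single replicate is reproducible in isolation.
`simulate_size_distribution` defaults to this per-replicate layout; the
sweep analyses (`confidence_map`, `census_vs_n0`, `robustness_curve`) use a
batched layout — all replicates of a grid point advance together on one
substream, with one vectorized binomial draw per iteration — which is the
same model with a different draw ordering, and is roughly two orders of
magnitude faster.  With both sigmas zero the perturbed engine makes no
Gaussian draws at all, so it consumes the stream identically to the plain
engine and matched seeds give identical trees (regression-tested).

## Exact final-size oracle

For small founder counts (n0 <= 30) the distribution of N_f is computed
exactly.  Writing D_m for the subtree-size law of a cell with m molecules:
m below threshold gives D_m = delta_1; otherwise the binomial split mixes
convolutions D_a * D_{m-a}.  The all-or-none splits a in {0, m} reproduce
D_m shifted by one leaf, giving the linear recurrence
`D_m[n] = (p^m + q^m) D_m[n-1] + C_m[n]`, solved exactly as an IIR filter.
Because all-or-none splits recur, final-size laws have geometric tails; the
support is truncated at a size cap (default 512) and the lost mass is
reported as `truncated_mass`, which Monte-Carlo comparisons treat as an
explicit tail bin.  This oracle shares no code with the simulation kernels.

## Problem sizes used by the shipped checks

The deterministic sweep runs at the full production mesh 0.0025 (80,000
points; a few seconds).  The stochastic analyses are validated at scaled
problem sizes chosen to keep the suite fast while leaving the conclusions
unchanged: the convergence check uses mesh 0.01 with 50 replicates at
n0 in {100; 1,000; 10,000}; the high-confidence ceiling is verified on the
symmetric (p = 0.5) column of the full-resolution grid at n0 = 10,000 with
100 replicates — the locus of the largest high-confidence sizes (powers of
two, phi in (2^-(k+1), 2^-k]), where the grid's discrete phi values leave
N_f = 128 without a workable threshold window while N_f = 64 sits
comfortably inside one; oracle agreement uses 20 random grid pairs per
n0 in {5, 10, 20} at 10,000 replicates.  A full-grid stochastic sweep at
mesh 0.0025 (80,000 points x 100 replicates) is an overnight job via
`hourglass sweep-stoch --mesh 0.0025`.

## What the generator does and does not emulate

The simulator is the data generator; there is no external data.  It captures
dilution, binomial segregation noise and parameter jitter.  It does not
model real-tissue features such as extrinsic niche signals, apoptosis,
factor production/degradation, cell-cycle length variability or correlated
segregation machinery — so passing tests demonstrate the internal
consistency and noise behaviour of the mechanism, not its sufficiency for
any particular tissue.

## Known limitations

- Growth-curve "topology" is the population-size trajectory; finer tree
  shape statistics (Colless/Sackin) are out of scope, so trees with the same
  curve but different branch placements are not distinguished.
- The confidence of a mode is a raw replicate fraction; no uncertainty
  interval accompanies it (at 100 replicates, "confidence > 0.9" means at
  least 91 hits).
- Region grouping by growth curve requires a freshly computed map; CSV
  round-trips keep the matrices but drop the curves.
- Heavy-tailed regimes (tiny p with a threshold just above one molecule)
  make both the exact oracle's truncated mass and Monte-Carlo runtimes
  large; the safety caps, not the model, bound that work.
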