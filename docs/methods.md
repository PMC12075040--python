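# Methods

This note documents the models, estimators, defaults and design choices
behind `grn_softmem`, and what the surrogate-based tests do and do not show
about real regulatory networks.

## Network model and recurrent core

Networks are signed digraphs: at most one edge per ordered (regulator,
target) pair, sign +1 (activation) or −1 (repression), self-edges allowed.
The *recurrent core* ("reservoir") is defined as the induced subgraph on all
nodes lying on at least one directed cycle — members of strongly connected
components of size ≥ 2, plus self-loop nodes. This is the maximal subgraph
that can sustain self-driven recurrent dynamics; the definition is
idempotent and an acyclic graph has an empty core. "Giant component" means
the largest *weakly* connected component by default (directed signals still
propagate inside it); strong connectivity is available via a flag, and size
ties break toward the component containing the lexicographically smallest
node id so the operation is deterministic.

Mean degree is reported as total degree 2m/n, the convention under which
the published E. coli figures (3236 nodes / 8366 edges → 5.17; 70 / 317 →
9.05) are reproduced. Edge-list files are TSV `source target sign`; on
duplicate (source, target) rows the last sign wins with a logged warning —
duplicates have no biological meaning here and silently keeping the first
row would hide file errors.

## Surrogate generator (the study conditions)

The published E. coli network is not redistributable, so every analysis runs
on surrogates drawn from the uniform null: exactly m distinct ordered pairs
chosen uniformly (self-loops allowed), with an *exact* repression count
round(f·m) rather than per-edge Bernoulli signs, so composition sweeps are
noiseless. Defaults match the published statistics: 70 nodes, 317 edges,
f = 0.41 for the core (3236 / 8366 / 0.24 whole-graph). The core surrogate
is resampled until fully recurrent and weakly connected (acceptance
probability ≈ 0.2 per draw at this density), since the published core is a
single reservoir. All generators are bit-reproducible given their seed.

The same uniform model is the motif null. It reproduces the published
randomized-network columns for self-loops and mutual regulation at both
network sizes (means m/n and ≈ m²/2n²; e.g. 2.6 and 3.3 whole-graph, 4.5
and 10.2 for the core). The published reservoir FFL null (73 ± 10) sits
below the uniform-model expectation (≈ 89 at 70/317); no additional
constraint on the published randomization is stated, so the uniform null is
used and the discrepancy is simply noted.

What the surrogates do *not* emulate: the real network's heavy-tailed
out-degree distribution (global regulators), its modularity, and any
correlation between sign and topology. Consequences observed in this
package's own experiments are flagged below.

## Reservoir dynamics

`x_t = tanh(W_in u_t + W x_{t−1})`, with `W[i, j]` coupling presynaptic
node j into node i (the orientation is a package convention; results are
orientation-agnostic for the uniform surrogate). Edge magnitudes are i.i.d.
U(0, 1), signed per edge, and `W` is rescaled to spectral radius ρ —
nilpotent (acyclic) matrices cannot be rescaled and raise. `W_in` entries
are ±0.05 equiprobable on every node; a mask restricts input to chosen
nodes when a strict delay-line fixture is wanted. The initial state is the
origin for all tasks.

## Readout and scoring

Ridge regression `W_out = Y_tgt Xᵀ(X Xᵀ + γ²I)⁻¹` is solved by Cholesky
factorization, never explicit inversion. Default γ = 1e−6 (the readout is
essentially unregularized at the protocol's 8100 training samples; γ is
exposed and recorded in every output). When strongly saturated dynamics
make the normal matrix numerically indefinite at tiny γ, a minimum-norm
least-squares fallback is used with a warning. With γ = 0 a singular system
raises instead.

NRMSE uses the population (divide-by-T) variance convention, matching the
time-average definition: 0 for a perfect fit, exactly 1 for the constant
mean predictor, 2 for the anti-phase binary case. MC_k is the squared
Pearson correlation between the delayed input and the test output — the
printed covariance-over-variances form is algebraically r², which keeps
MC_k in [0, 1] and makes it invariant to affine rescaling of the readout.

Protocol for every task: 10 input/output series, 9 concatenated for
training, the last held out; the first 100 steps of every series are
discarded from fitting and scoring as transient washout (the washout also
covers the largest delay scanned, so delayed targets never index before the
series start). Series are 1000 steps (600 for the delayed AND task, whose
pulse statistics are sparse).

k\* is the *largest* delay with MC_k > 0.5, read literally even across
non-monotone profiles; a first-crossing variant is available.

## Benchmark tasks

- **Memory capacity**: input u ~ U(−1, 1), target u_{t−k}, k = 1..30.
  Implementation detail: reservoir trajectories are independent of k, so
  states are computed once and only the targets change across delays.
- **NARMA-10**: `y(t+1) = 0.3y(t) + 0.05y(t)Σ_{i=0..9}y(t−i)
  + 1.5s(t−9)s(t) + 0.1`, s ~ U(0, 0.5), zero initial history. The
  recursion diverges for rare input draws; series with |y| > 10 are logged
  and resampled with the next sub-seed.
- **Delayed AND**: two pulse-train inputs (pulses of unit height, 3 steps
  long; Bernoulli onsets at rate 0.02 with a refractory gap of
  duration + 6 so lagged pairs stay resolvable), target
  I1[t−6] AND I2[t]. Half of the I1 pulses get a matching I2 pulse planted
  at lag 6 so both AND classes occur several times per 600-step series;
  these statistics are package choices (only depicted, never parameterized,
  in the source figure) and are all exposed. The readout output is
  binarized at 0.5 before NRMSE scoring; a constant test target triggers a
  resample.

## Lyapunov exponent

Two-trajectory renormalization: companion displaced by γ₀ = 1e−8, advanced
under identical input, one-step log expansions accumulated after a 100-step
washout over a 1000-step horizon, companion renormalized to γ₀ along the
difference vector each step. Separation underflow is floored at 1e−300 with
a warning.

By default the exponent is measured on the **autonomous** (zero-input)
dynamics, where the Jacobian at the quiescent state is W itself and the
estimate converges to ln ρ — the transition then sits exactly at ρ = 1, and
on the surrogate the memory peak (ρ ≈ 0.9–0.95) lies just below it,
reproducing the published geometry of a memory maximum at the onset of
chaos. A **driven** variant (same U(−1, 1) input as the memory task) is
selectable; on homogeneous surrogates the small input stabilizes the
dynamics and smears the sign change into a broad plateau of λ ≈ −0.01 over
ρ ≈ 1.0–1.3 (first non-negative mean only near ρ ≈ 1.4), which localizes
the transition poorly — this, not fidelity to the drive, is why the
autonomous measure is the default for transition localization. Because the
autonomous exponent is *exactly* zero at the grid point ρ = 1, sign
determination there uses a tie tolerance of 1e−3 (three orders of magnitude
below the ≈ 0.1 exponent increment between adjacent grid points); without it
the reported crossing would be a coin flip between 1.0 and 1.1 on
seed-to-seed noise of order 1e−4.

## Repression sweep

Per realization, one reservoir is built from the network's natural signing
and normalized to ρ; each repression fraction then re-signs those
fixed-magnitude weights with an exact negative count and **no
renormalization**. The sign balance then genuinely changes the operating
regime: the effective spectral radius of the re-signed matrix is ≈ 1.8 at
f = 0 or 1 and ≈ 1.04 in the balanced band, which is what produces the
U-shaped performance curves (NARMA NRMSE ≈ 0.8 at the extremes vs
≈ 0.35–0.40 in the middle; k* ≈ 9 vs ≈ 23). Renormalizing every re-signed
matrix back to ρ (available as `renormalize=True`) removes almost the
entire effect — the curves flatten to within 1–2 standard errors — so the
fixed-scale reading is the one consistent with the strongly non-monotone
published curves.

Known limitation: on the uniform surrogate the optimal basin is broad and
flat (f ≈ 0.1–0.7 for NARMA, 0.3–0.7 for k\*, differences inside the basin
within ~2 s.e.m. at 20 realizations/point and still flat at 100), so the
argmin/argmax point estimate wanders inside the basin across seeds
(typically landing at 10–30% repression for NARMA). The sharply localized
40–60% optimum reported for the real network is not reproduced by uniform
surrogates under this pipeline; plausibly it reflects the real network's
hub structure and/or a less expressive readout configuration (the published
best NARMA NRMSE is ≈ 0.7 where this pipeline reaches ≈ 0.35; the published
regularization coefficient is unstated, and re-running at γ = 1e−3 and 0.1
does not relocate the surrogate's optimum).

## Sub-reservoir sampling and size–performance

Starting from the full core, each run repeatedly deletes one uniform random
node, re-extracts the recurrent core, keeps the giant weak component, and
records every intermediate graph of ≥ 3 nodes until the graph falls below
that size; 100 runs yield a library of a few thousand sub-reservoirs with
sizes spanning 3 to n−1 (duplicates retained). Snapshots are recorded at
every step — the only reading under which ~100 runs produce the reported
few thousand samples. Performance clouds are filtered to values within 1.25
sample standard deviations of the library mean, and "good
size-performance" networks are flagged as Pareto-efficient on (size ↓,
k\* ↑, NARMA NRMSE ↓, delayed-AND NRMSE ↓), since no explicit selection
rule is published.

## Problem sizes and reproducibility

Default experiment scales — 10 realizations per ρ grid point (0.1 steps over
[0.1, 2.0], refined to 0.05 near the transition for the memory peak), 20
realizations per repression fraction, 1000-draw motif nulls — were chosen so
a full analysis completes in minutes on a single CPU while keeping standard
errors well below the effect sizes of interest; every realization count is
configurable upward. All randomness flows from a single master seed through
`numpy.random.SeedSequence` spawn keys, so every CSV row and JSON value is
exactly reproducible from (config, seed), and every output carries
provenance columns (seed, γ, washout, protocol sizes).

## Plotting

Deliberately out of scope: every experiment returns a tidy DataFrame / CSV,
and the numbers — not figures — are the tested surface. The CSVs plot
directly with pandas/matplotlib if wanted.
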