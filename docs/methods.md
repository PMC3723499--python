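# Methods

## Models

All models share one substrate: `N` binary synapses with states
`s_i ∈ {-1, +1}` storing a stream of random, uncorrelated memories. A
memory is a vector of plasticity events `ξ_i ∈ {-1, +1}` (potentiate /
depress), i.i.d. with probability 1/2 each. The **signal** of the memory
encoded at `t = 0` is the overlap `S(t) = Σ_i s_i(t) ξ_i(0)`; the noise
is the standard deviation of the overlap with an uncorrelated pattern,
`√L` for `L` synapses read, and `SNR = S/√L`. The **lifetime** is the
largest `t` with (optimal-readout) SNR ≥ 1. Time is counted in encoded
memories throughout; any conversion to hours is presentational only.

**Homogeneous.** Every synapse adopts its event with probability `q`.
Exact discrete mean field `S(t) = N q (1-q)^t`; continuous approximation
`SNR(t) = √N q e^{-qt}` (deviation below 2 % of the initial signal for
`q ≤ 0.1`).

**Heterogeneous.** `n` equal groups, rates on the geometric ladder
`q_k = q₁ r^{k-1}`, `r = (q_n/q₁)^{1/(n-1)}` (timescales tile
`[1/q₁, 1/q_n]` evenly in log). Every group sees every memory and groups
are independent: each group is in law a homogeneous model with its own
rate (verified by a Kolmogorov–Smirnov test against separately simulated
homogeneous runs).

**Transfer chain.** Only stage 1 encodes. Each step, synapse `j` of
stage `k+1` copies the state its stage-`k` counterpart had at the end of
the previous step, with probability `q_{k+1}` (Jacobi semantics; at
copy rate 1 the chain is exactly a delay line, which fixes the
convention). Mean field: `S₁(t+1) = (1-q₁) S₁(t)` with
`S₁(0) = (N/n) q₁`, and `S_k(t+1) = (1-q_k) S_k(t) + q_k S_{k-1}(t)`,
`S_k(0) = 0` for `k ≥ 2`; continuous limit `dS_k/dt = q_k (S_{k-1} - S_k)`.

## Numerical layer

* **Simulators** are vectorized over realizations (int8 state arrays,
  one float32 uniform per synapse per step; the same uniform decides
  update and new value — valid since `P(u < q/2 | u < q) = 1/2`).
  Randomness flows from one master seed through named, CRC32-keyed child
  streams (`memsim.rng`), so outputs are bit-reproducible and independent
  across components.
* **ODE integration**: LSODA, `rtol 1e-8`, absolute tolerance scaled to
  the initial stage-1 signal; validated to 1e-6 relative against the
  stage-2 closed forms `S₂ = S₁(0) q₂ (e^{-q₂t} - e^{-q₁t})/(q₁-q₂)` and
  the confluent limit `S₁(0) q t e^{-qt}`.
* **Pulse asymptotics**: in Laplace space the chain is a product of
  simple poles, `S_k(s) = (S₁(0)/q₁) Π_{j≤k} q_j/(s+q_j)`. The inverse
  transform is evaluated by a saddle-point (Laplace) approximation with
  the second-order correction; the saddle `s*` solves
  `Σ_j 1/(s*+q_j) = t` (scalar Brent root find). The pulse peak advances
  along `t(x) = (e^{λ(x-1)} - 1)/(λ q₁)`, `λ = ln(q₁/q_n)/(n-1)` —
  exponentially decreasing speed. Validity: many stages (n ≳ 10) and
  `1/q₁ ≲ t ≲` the last-stage arrival time; outside this region a
  warning is issued. Measured accuracy at the pulse peak: ≤ 1 % relative
  against the ODE for n = 50, `q₁ = 1`, `q_n = 1e-4` over the mid
  decades (the stated requirement is 10 %).
* **Optimal readout**: maximize `Σ_{k∈K} S_k / √(Σ_{k∈K} L_k)` over
  subsets `K`. For equal stage sizes the optimum is provably a prefix of
  the stages sorted by signal (for fixed |K| take the largest signals,
  then scan |K|); that exact path is used everywhere in the models. For
  unequal sizes the implementation falls back to exhaustive search up to
  20 stages and a density-ordered scan with local search beyond.
  Combined noise uses the uncorrelated `√(Σ L_k)` approximation.
* **Lifetimes**: bracketing on a log grid (≥ 200 points per decade) plus
  Brent refinement for callables, linear interpolation for sampled
  curves. The two-regime asymptotic mirrors the travelling pulse: if the
  pulse is still detectable on arrival at the last stage, lifetime ≈
  arrival time + `ln(SNR_arrival)/q_n`; otherwise it is the time at
  which the pulse's own optimal-readout SNR drops to 1. It is an
  order-of-magnitude estimate; measured agreement with the numeric
  lifetime is within a factor 2 (typically 1 %) across
  n ∈ {10, 20, 50}, `q_n ∈ {1e-3, 1e-4}`.
* **Crossing time** between the heterogeneous and transfer curves is the
  permanent-dominance time: the interpolated time after the last grid
  point where the transfer curve is still below the heterogeneous one,
  evaluated over the detectable range (t ≤ lifetime). Near `t = 0` both
  models read only stage 1 and the curves coincide exactly, so a
  "first-touch" definition would degenerately return 0; far beyond the
  lifetime (SNR ~ 1e-15) the slow heterogeneous group's residue
  re-overtakes, which is physically meaningless — both motivate the
  detectable-range, permanent-dominance definition.

## Neuronal implementation

Each stage is `N` all-to-all McCulloch–Pitts neurons with plastic
recurrent weights `J_ij ∈ {-1, +1}` (no self-connections) and fixed
one-to-one feedforward links to the next stage. **Encoding** (stage 1
only): a random half of the neurons is active; synapses with active
presynaptic neuron move to the Hebbian target (+1 if the postsynaptic
neuron is active, else -1) with probability `q₁`. The memory's synaptic
target is this eligible set; its signal is the overlap of the stage's
weights with the Hebbian targets over that set. Because a synapse is
only addressed when its presynaptic neuron is active (probability 1/2),
the stage-1 signal decays by `(1 - q₁/2)` per subsequent encoding — the
effective stage-1 rate in the neuronal mean field is `q₁/2`.

**Transfer**: per replay, `round(fN)` random neurons are stimulated;
neuron `i` receives `h_i = Σ_{j∈stim} J_ij` and responds if `h_i`
exceeds the threshold (strict comparison; thresholds are non-integer so
integer input sums never tie). One of two thresholds is drawn per replay
with probability 1/2 (a global signal shared by the stage pair). The
downstream stage, slaved through the feedforward links, potentiates
(stimulated → responder) pairs under the high threshold and depresses
(stimulated → non-responder) pairs under the low one, each with
probability `q`; all activity is then cleared. Stimulated neurons may
themselves respond; downstream recurrent inputs are treated as fully
down-regulated during transfer.

**Transfer statistics.** For a tracked upstream synapse `(i, j)` the
replay input decomposes as `J_ij` plus a background of the other
`m - 1` stimulated weights (`m = round(fN)`), an exactly binomial sum.
The per-replay update probability is
`p = (m/N) q [½ P(h > θ_high) + ½ P(h ≤ θ_low)]`, the transfer rate
`R = 1 - (1-p)^M` (small-p prefactor `γ = p/q`, `R ≈ γ M q`), and the
accuracy `A` is the correctly-signed share of the two tails. Tails are
computed exactly from the binomial by default; the Gaussian
approximation (mean `fN(2ρ-1)`, variance `4fNρ(1-ρ)`) is available as
`method="gaussian"` and agrees with the exact tails to a few per cent
once `fN` is large (hundreds). The corrupted mean field replaces `q_k`
by learning `R_k A_k` toward the upstream signal plus decay
`R_k (1-A_k)` from incorrect copies — for binary synapses an incorrect
copy is necessarily the opposite value, forcing
`dS_k/dt = R_k (2A_k - 1) S_{k-1} - R_k S_k`.

**Collective replay effects.** The per-synapse calculus conditions only
on the tracked synapse's own contribution to `h_i`. In the network the
*background* stimulated synapses of row `i` also carry the stored
memory's alignment, so the whole response pattern is biased toward the
memory — replay reads out the row, not one synapse. This is a
linear-in-signal population channel that grows with the stimulated-set
size; `linear_response_transfer` computes it exactly (binomial tails and
their ρ-derivatives) and the measured downstream gain indeed exceeds the
per-synapse bound `2A - 1` whenever `m ≥ 2`. A further
update-selection correlation (synapses in strongly-aligned rows are
re-updated consistently) remains beyond the linear theory; it is visible
as a few-SE bias at `m ≥ 3`. Consequently the corrupted mean field with
per-synapse rates is *exact* only in the single-neuron-stimulation
regime (`m = 1`, where the background vanishes and every update copies
the upstream synapse, `A = 1`); the quantitative network-vs-mean-field
validation is run there, and the collective regime is validated
separately against the linear-response theory at its documented few-SE
accuracy. This mirrors the model's own design logic: accurate transfer
wants few synapses per replay and many replays.

## Validation design

Monte-Carlo-vs-mean-field checks compare pointwise z-scores
`(mean - prediction)/SE` against 3. Two calibration facts shape the
test design, both measured on replicate null runs before the tests were
frozen: (i) the pointwise deviations are AR(1) in time with
decorrelation time `1/q`, so comparing on a dense grid turns the check
into a max over hundreds of correlated z-scores that exceeds 3 with high
probability even for a correct simulator — comparison grids are
therefore spaced at least one decorrelation time apart; (ii) with few
realizations (the network runs use 10) the raw per-point SE has ~9
degrees of freedom, making `|z| > 3` a 1.5 %-per-point Student-t event —
the network comparison therefore pools the variance over a 21-point
moving window (it varies smoothly in time), restoring near-normal
calibration. Residual false-alarm probability of the frozen checks is a
few per cent per suite run.

## Synthetic-data scope

All inputs are generated internally: dense i.i.d. ±1 memories at a
balanced potentiation/depression ratio, stationary i.i.d. initial
states, and exactly-half-active neuronal patterns. Real memories are
sparse, correlated, and structured; within these models sparseness is
equivalent to scaling every learning rate by the coding level `F`
(`coding_level_rescale`; SNR curves collapse under `t → Ft` with
amplitude `F`, residual < 5 % on mean-field curves), but correlations
and semantic structure are genuinely outside scope. Passing tests show
the implementation matches the stated stochastic models and their
theory, not that the theory describes any particular biological system.

## Default study sizes

Chosen to resolve each effect with ~per-cent precision on one CPU in
minutes: homogeneous validation `N = 1e4`, 1000 realizations; transfer
chain `N = 5e4` over 5 stages, 500 realizations, 500 steps; pulse and
scaling studies on analytic mean fields (`N` up to 1e30 where a scaling
law's asymptotic regime demands it — these are formula evaluations, not
simulations); replay statistics `N = 2000` neurons with 10⁴ tracked
synapses; network validation `N = 300` neurons, 3 stages, 10
realizations. Scaling regimes follow the consolidation setting the
models were built for: stage sizes large enough that the memory wave is
still detectable at the last stage (multi-year lifetimes at one memory
per hour).

## Known limitations

* The optimal readout assumes uncorrelated noise across stages;
  correlated-noise corrections for naive multi-stage readout are not
  implemented (the optimal readout is close to the uncorrelated case).
* The lifetime asymptotic is order-of-magnitude by construction.
* `linear_response_transfer` is first order in the upstream alignment;
  at large stimulated fractions and strong signals the network transfers
  faster than any linear theory predicts.
* No sparse/low-activity representations, no multi-state or metaplastic
  synapses, no spiking dynamics, no random feedforward projections.
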