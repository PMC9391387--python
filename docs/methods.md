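# Methods

This note records the scientific and numerical choices behind the package:
what each component computes, which conventions had to be frozen where the
underlying definitions leave freedom, and what the synthetic benchmark does
and does not establish.

## Effort-to-compress and its conventions

ETC counts NSRPS passes: each pass replaces the most frequent adjacent
symbol pair with a fresh symbol (the current alphabet size, which then
grows by one) and therefore strictly shortens the sequence, so a length-L
input terminates in at most L−1 passes.  Termination is a constant or
length-1 sequence.  Two conventions are not forced by that definition and
are frozen here:

* **Occurrence counting** is non-overlapping and greedy left-to-right:
  `aaa` contains one `(a,a)` pair, `aaaa` two.
* **Tie-break** among equally frequent pairs goes to the pair whose first
  occurrence comes earliest in the sequence.  This choice is deliberate:
  it depends only on *positions*, never on symbol values, which makes ETC
  exactly invariant under bijective relabeling of the alphabet.  A
  value-based rule (e.g. lexicographically smallest pair, available as
  `tiebreak="lex"`) is not relabeling-invariant — `0001001` compresses in 5
  passes while its 0↔1 relabeling takes 4 — and relabeling invariance is
  load-bearing: the joint ETC of a pair with itself is a relabeling of the
  plain sequence, and the exact identity CCC(x→x) = 0 rests on it.

The joint (two-sequence) ETC codes contemporaneous symbol pairs into a
product alphabet, fresh codes assigned in first-appearance order, and
compresses the coded sequence.  The coding is a bijection on observed
pairs, so any relabeling-invariant ETC gives the same answer regardless of
the code order.

The compression loop is jitted with numba when importable; the identical
source runs un-jitted otherwise.  Tests pin the implementation to an
independently written brute-force NSRPS on all binary sequences of length
2–10 and on random ternary/denser-alphabet sequences.

## CCC windowing

Windows are anchored at index 0 and advance by δ; trailing samples that do
not fill a full L+w window are dropped, giving
`n_windows = floor((N−L−w)/δ) + 1`.  The CC terms subtract **raw ETC step
counts** by default.  Raw differences keep the statistic in interpretable
units (substitution passes), but they carry a null bias: ETC of a length
L+w window is compared with ETC of a length-L window, and the joint terms
saturate differently from the self terms.  Measured on independent iid
4-symbol pairs (N = 2048, L = 25, w = 15, δ = 20, 100 seeds) the bias is
−2.84 ± 0.02 raw steps (or +0.009 ± 0.001 with the `normalized=True`
option, which divides each ETC by length−1).  The bias has no directional
component — x→y and y→x distributions agree under the null — and the
surrogate protocol cancels it entirely, because surrogates share it.  This
is why every coupling decision in the package is surrogate-calibrated and
no raw CCC value should be read as evidence by itself.

## Ordinal coding and PCCC

Delay vectors are labelled by ascending rank (0 = lowest), exact ties by
order of occurrence (earlier occurrence → smaller label), and the rank
pattern is mapped to `[0, m!)` by its lexicographic (Lehmer) index.  The
coding is invariant under strictly monotone transforms of the amplitudes,
which is what buys robustness to observational distortion.

PCCC embeds **only the driver** (forward embedding, so the pattern at time
t uses x(t), x(t+η), …); the target is truncated to the driver's valid
index range and equidistantly binned with m! bins, keeping both alphabets
the same size.  The reverse direction swaps the roles (and uses the
target's own embedding delay).  Window parameters for the benchmark system
are L = 25, w = 15, δ = 20 with m = 3, η = 5; the scalar-CCC comparator
uses L = 300, w = 30, δ = 30, B = 8.

## CMI family

All entropies are plug-in (empirical frequencies, natural log, 0·log 0 = 0)
and CMI is assembled as H(X,Z) + H(Y,Z) − H(X,Y,Z) − H(Z), which is
non-negative up to rounding.  Continuous inputs to CMI1/CMI3 are
discretized with Q = 8 marginal-equiprobable bins by default (quantile
edges; configurable).  Equiprobable bins keep the conditioning cells
populated under heavy-tailed amplitudes.  No bias correction is applied:
bias is handled by the surrogate calibration, which evaluates original and
surrogates with the identical estimator.  PCMI shifts the horizon to
τ′ = τ + (m−1)η so the ordinal pattern of the target's future shares no
sample with the pattern of its present.

For protocols that scan a horizon range (as real-data analyses commonly
do), the natural aggregate is the mean of the measure over τ, computed
identically for original and surrogates; this package's significance entry
point takes a single τ and callers average outside if desired.

## Surrogate protocol

AAFT surrogates Gaussianize by rank, randomize Fourier phases (conjugate
symmetry preserved; the Nyquist bin keeps a random sign), and restore the
original amplitudes by rank — the output is an exact permutation of the
observed values with approximately the original power spectrum.  The
stationary bootstrap concatenates circular blocks with geometric(p)
lengths, p = 0.1 by default (mean block 10 samples), for data whose
spectrum is not trustworthy (irregular sampling).  Surrogates are
generated in pairs (surrogate i of x with surrogate i of y): paired
surrogates destroy the cross-coupling while each marginal keeps its linear
structure.

Significance is a one-sided z-test, `z = (s − mean(s_surr))/sd(s_surr)`
with the sample standard deviation (ddof = 1), significant when
`z > 1.6449` at α = 0.05, each direction tested independently.  The tested
statistic is the **absolute value** of the measure: the sign of CCC
reflects the nature of the coupling, its magnitude the strength, and on
the benchmark system the true-direction PCCC is systematically more
negative than its surrogates — magnitude testing is what turns that into a
detection.  (The CMI measures are non-negative, so the absolute value is a
no-op there.)  A zero-variance surrogate distribution is flagged
degenerate and judged not significant.

When missing samples are emulated, surrogates are generated from the
full-length series first and the *same* deletion index sets are then
applied to the original pair and every surrogate pair (one shared set in
synchronous mode; the per-series sets in asynchronous mode).  Deleting
after surrogate generation keeps the sampling structure of the tested pair
and its reference distribution identical.

## The benchmark generator

The synthetic system is a pair of chaotic Rössler oscillators
(a = 0.15, b = 0.2, c = 10) with mismatched frequencies ω₁ = 1.015,
ω₂ = 0.985, the master driving the slave through ε(x₁−x₂) in the slave's
first coordinate only, ε = 0.09 — strong enough to detect, weak enough to
avoid synchronization.  Integration uses an adaptive 8th-order Runge-Kutta
(DOP853) at tolerance 1e-9; only sampled statistics are reproducible, not
bit-exact trajectories, because on a chaotic orbit any tolerance-level
difference grows exponentially (the ε = 0 consistency test therefore
compares trajectories over a short horizon).  Sampling interval 0.314
resolves one oscillation by 17–21 samples; 5000 transient samples are
discarded; initial conditions are drawn uniformly from x,y ∈ [−5,5],
z ∈ [0,1] per realization (transient removal makes the box immaterial).

Observational degradations: white Gaussian noise with σ_n expressed as a
percentage of the signal's σ_s, and random deletion of a fraction α of
samples (shared or independent index sets), after which the remainder is
concatenated — downstream measures never see gap markers, mimicking an
analyst who does not know samples are missing.

What the generator does *not* emulate: measurement jitter in time,
non-stationary drifts, age-model uncertainty of proxy archives, or
autocorrelated noise.  Passing the benchmark therefore shows correct
directionality detection for deterministic coupled dynamics under the
stated degradations, not performance guarantees on any particular field's
data.

## Benchmark harness and scale

TPR is the fraction of realizations with a significant master→slave call,
FPR the fraction significant in reverse, each realization tested against
its own 100 surrogate pairs.  The seed hierarchy is
master seed → (condition, realization) → surrogate stream, so any subset
of a sweep reproduces in isolation and every decision in the output is
traceable to its seeds in the run manifest.

The shipped verification runs a reduced ensemble of 25 realizations (the
full study design uses 100); at N = 2048 the surrogate-tested PCMI
separates the directions so widely (forward z ≈ +5 to +8, reverse z < 0)
that 25 realizations already pin the rates.  Null calibration uses 100
repetitions of independent iid pairs with 40 surrogates each, the smallest
geometry that accommodates every windowing preset.

## Known limitations

* Plug-in CMI needs enough samples per cell; with Q = 8 and CMI3's
  five-column table, records under ~10³ points are dominated by bias (the
  benchmark reproduces the known result that condition-embedded CMI only
  becomes reliable at lengths ≫ 10⁴ without ordinal coding).
* The raw-ETC CCC bias means CCC values from different window geometries
  or lengths are not comparable with each other — only with their own
  surrogates.
* `run_pair_analysis` requires pre-aligned series sampled on a common
  grid; it does no interpolation or age-model alignment.
* AAFT assumes a stationary, roughly invertible amplitude transform of a
  Gaussian linear process; for heavily irregular archives prefer the
  stationary bootstrap.
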