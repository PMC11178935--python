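# Methods

This note documents the models and procedures implemented in `mtwdbn`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## Dependency discovery: multi-timescale weighted DBNs

Population spike trains are discretised into fixed-width bins (1.2 ms for
the simulated networks, 15 ms for cortical-style data) and clipped to two or
three activity levels. Each row of the resulting *binned-and-sliced table*
holds the current bin (lag 0) and the preceding `n_lags` bins for every
population; rows slide one bin at a time and never straddle trial
boundaries. The lag-0 columns are *effect* variables; every edge of the
learned graph must point at one of them. Edges among lag-0 columns are
allowed during search — they can absorb dependencies faster than the bin
width — but carry no causal interpretation and are excluded from inference.

Structure search maximises a decomposable AIC,

    score(G) = sum_v [ max log L(v | parents_v) − (L − 1) · L^|parents_v| ]

with natural logs and L activity levels (equivalent to standard AIC up to a
factor of −2). Search is a greedy best-improving hill climb over single-edge
additions/deletions (plus reversals within lag-0 pairs, preserving
acyclicity of the lag-0 subgraph) with a tabu list holding the inverses of
the last 7 applied moves. Each of `B` row bootstraps (default size 8000,
emulating the data scarcity of real recordings) is searched from
`n_restarts` random starting graphs (Erdős–Rényi over the allowed mask,
expected in-degree 2, resampled to lag-0 acyclicity); only the best-scoring
local optimum per bootstrap is kept. Restart ties are broken by the first
restart reaching the best score.

Edge weights are bootstrap presence frequencies: each of 100 weighted graphs
resamples the `B` unweighted graphs with replacement and records, per edge,
the fraction containing it. Significance comes from re-running the identical
pipeline on time-shuffled surrogates (per row, permute each population's
slices across lags; then permute every column across rows — marginals are
preserved, temporal structure destroyed).

### Significance test choice

Two tests of "real weights exceed null weights" are provided.

* `mannwhitney` — one-sided Mann-Whitney U over the pooled weighted-graph
  weights, as in the original analysis pipeline. The 100 weighted graphs of
  one ensemble are resamples of the *same* `B` unweighted graphs, so this
  test treats tightly correlated replicates as independent. Direct
  simulation shows its one-sided false-positive rate for chance edges is
  0.3–0.5 at any `B` and any number of pooled sessions.
* `presence` (default) — one-sided Fisher exact test on the implied edge
  presence counts among the `B` independent bootstrap graphs per ensemble.
  This controls its nominal alpha: on fully time-shuffled laminar data the
  pipeline flags 0 of 72 possible cross-lag edges at alpha = 0.05.

New analyses default to `presence`. The validation experiments that
reproduce the original method comparison (`subsampling_experiment`,
`lag_sweep`, `decoder_experiment`) default to `mannwhitney`, because the
comparison being replicated was defined with that rule.

## The stochastic spiking simulator

Neurons are coupled two-state Markov processes: active → quiescent with
probability `alpha·dt` per step, quiescent → active (a spike) with
probability `beta·G(S)·dt`, where `S = Σ_j w_ij A_j + I` is the total
synaptic input (`A_j` = 1 while neuron j is active) and `I` a constant
drive. E cells use `alpha = 0.075 /ms`, `beta = 1 /ms`; I cells
`alpha = 0.4 /ms`, `beta = 2 /ms`. Euler–Bernoulli stepping with
`dt = 0.1 ms`; per-step probabilities ≥ 1 raise an error naming the neuron.
The inter-spike interval of an isolated cell is the sum of two independent
exponentials (rates `alpha` and `beta·G(I)`), verified by a KS test on 10⁴
intervals.

Two reference networks have known ground truth:

* **Two-neuron chain** — two E cells, one synapse n1→n2 with weight on the
  grid 0.5…9.5.
* **Laminar network** — 3 layers × (10 E + 5 I), all-to-all within a layer
  (weight 1.5 from E, −2 from I), all-to-all E→E across layers (weight 1)
  on the feedforward routing input→superficial→deep, plus per-layer E⇄I.
  Ground truth: 8 non-self population edges + 6 self-edges.

### Gain and drive calibration

The gain `G` and drive `I` are not dictated by the model family; they were
calibrated once, jointly, against three qualitative behaviours the pipeline
must exhibit on these networks, and then frozen:

1. bootstrap edge confidence of the two-neuron edge rises monotonically
   across the whole 0.5–9.5 weight grid (not saturating at the grid floor);
2. the LASSO-baseline F-curve over penalties 0.005–0.05 is unimodal with an
   interior peak;
3. isolated E cells fire ~5–15 spk/s.

A unit-scale saturating gain (`tanh(s)`) fails (1) and (2): with the stated
connection weights the laminar network's total input is O(10), pinning every
unit at its ceiling rate, while the two-neuron edge is detected with
evidence ~100× the AIC threshold at every grid weight. The default is
therefore `G(s) = tanh(s / 30)` for `s ≥ 0` (zero below) — the gain scale
matches the magnitude of total synaptic input implied by the published
connection weights — with `I = 0.345`, giving isolated E cells ≈ 9 spk/s.
Both are exposed (`NetworkSpec.gain`, the `drive` argument), and
`make_laminar_spec(per_connection_weights=False)` offers a mean-activity
coupling convention (weights divided by presynaptic population size) for
O(1) gain scales.

Under the frozen calibration, couplings are deliberately weak relative to
noise. One consequence is documented as a known limitation below.

## Validation experiments

* **F-score** — precision/recall/F over deduplicated, lag-collapsed directed
  population edges; self-edges are part of the ground truth (refractoriness
  and within-population recurrence). 0/0 ratios are 0.
* **Subsampling** — drop d% of units per population (d ∈ {0,20,40,60,80},
  multiple random subsets), rerun all methods. Baselines: LASSO regression
  (`rr_baseline`, one linear model per lag-0 column; an edge is any nonzero
  lagged coefficient), fixed-threshold weighted graphs (mean weight > 0.5),
  and the single best-AIC unweighted DAG, scored on its own bootstrap as in
  the original procedure.
* **Lag sweep** — pipeline at 3–7 lags; accuracy is statistically flat.
* **Decoder** — split the table 95/5; CPTs for each effect variable are fit
  by MLE on 12 000 held-out rows (unseen parent configurations fall back to
  the marginal mode) and score 4 000 validation rows, predicting one
  randomly chosen effect variable per row. Edge subsets of size 6 or 13 are
  drawn from the shuffle-surviving edges uniformly or proportionally to
  edge weight; paired over 100 subgraph seeds; M-score = multiclass
  Matthews correlation (accuracy also available).

## Information decomposition on the toy network

Eight binary variables: per sample all are initialised i.i.d.
Bernoulli(0.5); a shared coin (prob `p_shared`) sets all eight to 1; a
unique coin (prob `p_unique`) sets target and unique source to 1.
Initialisation is per-sample, the only reading that yields i.i.d. rows.

Atoms follow the additive identities
`I(T;S1,S2) = U1 + U2 + R + S`, `I(T;S_i) = U_i + R`. The default
redundancy is the pointwise common change in surprisal: local
co-information under the maximum-entropy joint matching the three pairwise
marginals (iterative proportional fitting), counted only where the two
local informations and the co-information share a sign. Minimum specific
information (`measure="min"`) is the fallback; it alone guarantees
nonnegative atoms in general (the pointwise measure can yield small
negative unique atoms on this generator — observed ≈ −0.01 bit), and it is
always used for redundancy over more than two sources
(`shared_info_fraction`, random three-source subsets).

The pairwise model is a univariate logistic regression (slope = log odds
ratio for binary data); the network model is an L1-penalised multivariate
logistic regression. The default per-observation penalty 0.005 is the
smallest grid value that zeroes none of the seven true coefficients in the
strong-unique/weak-shared regime (0.4, 0.1). Note that the unique-source
coefficient retains a weak positive dependence on `p_shared` at *any*
penalty, including zero: the shared coin writes into both target and unique
source, and the main-effects logistic model (misspecified for the OR-style
generative rule) absorbs part of that shared variance. The unique axis is
~3× steeper than the shared axis, which is the contrast the decomposition
relies on.

## Modulation analysis

Edge-wise condition contrasts use the index `(w_A − w_B)/(w_A + w_B)`
(condition A minus B), computed over 5000 bootstrap pairs of weighted
graphs; 0/0 pairs are dropped and counted. Total (pairwise) dependency is
the absolute univariate logistic slope |β₁|, bootstrapped with resample
size equal to the larger condition's row count; for binary variables each
refit reduces to a multinomial draw of the 2×2 table (log odds ratio), with
a 0.5-per-cell jitter on separated tables. Summaries use the mean and a
BCa bootstrap interval (resample count and size both default to 5000, the
deliberately conservative setting for very large bootstrap-generated
samples; the implementation matches `scipy.stats.bootstrap(method="BCa")`
when the resample size equals the sample size, with ~93–94% empirical
coverage for a Gaussian mean at n = 200 — the known small-sample behaviour
of BCa). Modulation sign is the sign of the mean when the interval excludes
zero, else 0; the shared-dependency sign is inferred from
total ≈ unique + shared with nonnegative components, returning
indeterminate exactly when both directions are consistent.

## Generalized phase

LFP traces are band-passed 5–40 Hz with a zero-phase FIR filter (~3 cycles
of the low edge, < 1 dB passband ripple); the generalized phase is the
angle of the analytic signal. Optional correction of negative-frequency
excursions interpolates the unwrapped phase across phase-slip samples.
Events (optionally shifted by a response latency, e.g. 75 ms) take the
phase of their nearest sample; phase histograms use equal bins over
(−π, π], and condition comparisons are per-bin rank-sum tests on per-trial
probabilities, Bonferroni-adjusted over bins.

## Problem sizes

Default experiment sizes in the test-suite and acceptance script are scaled
down from the original settings (200–400 trials instead of 1000; B = 12–50
instead of 200; 6–12 restarts instead of 120), chosen so each experiment
remains a faithful miniature of its full-scale counterpart while the entire
validation battery runs on a single CPU in minutes. All sizes are plain
function arguments.

## Known limitations

* Under the frozen simulation calibration the laminar couplings are weak:
  the full true structure improves a CPT decoder by only ~0.005 Matthews
  correlation over a marginal-mode predictor. The weight-biased-vs-uniform
  decoder contrast therefore reproduces in sign but not at the published
  significance level; a stronger-coupling calibration recovers that
  significance but breaks the two-neuron monotonicity. One calibration is
  used for everything rather than per-experiment regimes.
* The published Mann-Whitney edge-significance rule is anti-conservative by
  construction (correlated bootstrap replicates); it is kept for the
  method-comparison experiments and replaced by a calibrated presence test
  as the pipeline default.
* Synthetic spike trains have no rate nonstationarity, no oscillatory
  drive, and no refractory structure beyond the two-state dwell times;
  passing tests demonstrate correct recovery of known dependency structure
  in this model class, not performance on cortical recordings.
* Synergistic information is decomposed on the toy network but not
  estimated for spiking data.
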