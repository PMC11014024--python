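# Methods

This note documents the models and procedures implemented in `cosoft`, the
defaults and why they were chosen, the numerical conventions, and the known
limitations. It states nothing the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

Process data are held as a three-way tensor `X (I × J × K)` with a quality
series `Y (I × K)` and a boolean mask marking which (batch, time) cells were
actually assayed. Storing `Y` on the full process-time grid with a mask —
rather than as a separate shorter series — unifies the simulated case
(everything observable, then sparsified) with the plant case (assays every
m-th process sample): the assay count is simply the mask's true-count. All
indices are 0-based; flat samples are ordered batch-major, then time.
Labels are placed at a deterministic time stride (`t mod ratio == offset`),
mirroring fixed assay intervals; a seeded random mask exists for robustness
experiments. Long-format CSV I/O is bit-exact for finite values
(`float_precision="round_trip"` on read).

## Synthetic campaign generator

The generator exists so the whole pipeline is testable end to end without
proprietary plant data. It is a minimal three-state discrete-time fed-batch
model, not a mechanistic simulator of any particular organism:

- biomass `B`: logistic growth at rate `μ = μ_max · g(pH, T) · S/(K_S + S)`,
  with `g` a product of Gaussian response curves in the batch's pH and
  temperature setpoints (optima 5.0 and 298.0 K, widths 0.35 and 1.2 K);
- substrate `S`: consumed at `μB/Y_XS`, replenished by a constant feed that
  switches on at 25 % of the horizon (fed-batch onset);
- product `P` (the quality variable): Luedeking–Piret,
  `dP/dt = α·dB/dt + β·B`.

Defaults: `μ_max = 0.11 h⁻¹`, `K_S = 0.5 g/L`, `Y_XS = 0.45`, `α = 0.6`,
`β = 0.002 h⁻¹`, 400 h horizon, Euler integration at `400/K` h. These are
generic fed-batch magnitudes chosen once for plausibility (product rises
from 0 to ≈ 15–18 g/L over the run); nothing downstream depends on their
exact values.

**2D structure.** Across the campaign, pH drifts linearly 4.95 → 5.2 and
temperature 297.5 → 298.5 K (first to last batch); both feed the growth
kinetics through `g`, so quality trajectories are correlated along the batch
direction by construction, as well as autocorrelated in time through the
kinetics.

**Disturbances.** Each batch's setpoints are jittered once per batch,
uniformly within ±1 % of the setpoint — except temperature, where a
fraction of the absolute Kelvin value would be physically absurd (1 % of
298 K = 3 K against a controller that holds ±0.2 K); its jitter uses a 20 K
reference scale, i.e. ±0.2 K at the default 1 %. Measurement noise is
additive iid Gaussian per time point at per-variable instrument scales
(0.1 K temperature, 0.02 pH, 0.15 g/L substrate, …); `noise_sd` is a
multiplier on those scales, 1.0 ≈ typical probe precision, 0 disables noise.
"Noiseless" in the tests means both `noise_sd = 0` **and**
`fluctuation_fraction = 0`, so trajectories are exact deterministic
functions of the batch index.

**What the generator does not emulate:** ragged batches, phase transitions
and multi-phase recipes, control-loop dynamics, sensor drift or outliers,
missing process-variable readings, non-Gaussian noise. Tests passing on
these campaigns show the machinery behaves as specified under clean 2D
dynamics with sparse labels; they do not certify performance on any real
plant's data.

The quality variable carries no observation noise: it is a deterministic
function of the latent states, which gives the tests an exact ground truth
at every grid point.

## Multi-player co-training

`n` kNN regressors with pairwise distinct Minkowski orders (all ≥ 1, where
the distance is a metric) are initialized on copies of the labeled set.
Per iteration, players act in turn; each scans the shared pool, pseudo-labels
every candidate with its own prediction, computes the Δ-score on the
candidate's k nearest labeled neighbors, and accepts the minimizer if
negative. Accepted samples leave the pool immediately (so later players in
the same iteration cannot re-select them) and are cross-fed at iteration end
to every *other* player's labeled set — a player never receives its own
selection. The loop exits early when no labeled set changes, and always
terminates because the pool is finite.

Conventions fixed for exact reproducibility:

- neighbor ties break toward the lower sample index (stable sort); a
  tentatively inserted candidate ranks last, so on a distance tie the
  incumbent wins;
- Δ-score ties break toward the earliest pool position;
- the neighborhood `a` is taken from the player's labeled set under the
  player's own metric, and `P(x_i)` includes `x_i` itself as a neighbor
  (distance 0), matching the literal regressor-on-L definition;
- kNN prediction is the unweighted neighbor mean; a distance-weighted
  option exists for prediction but the Δ-criterion is always evaluated with
  the unweighted mean.

Candidate scanning uses an exact incremental update: adding one point to a
labeled set either displaces a neighbor's current k-th nearest sample
(strictly closer) or leaves its prediction unchanged, so
`P′(x_i) = P(x_i) + (ŷ − y_(k))/k` in the first case. Tests assert exact
agreement with the literal from-scratch `delta_score` and, for two players,
with an independently coded reference of the classic two-regressor scheme.

Default orders: (2, 5) for two players (the classic convention), (1, 2, 5)
for three — p = 1 adds a robust, outlier-tolerant metric — then 3, 4, 6, …
Default `k = 10` at desk scale (it must not exceed the initial labeled-set
size), iteration budget 100. The candidate pool is the full unlabeled set by
default, with an optional seeded `pool_size` cap for cost.

## Standardization and 2D window

Standardization is per variable over the pooled `I·K` training values with
the population σ (divide by N). Variables with σ = 0 map to 0 with a
warning. The quality variable gets its own (mean, σ) fitted on measured
labels only, retained for inverse-transforming predictions. The model is
fitted on the training split only and applied unchanged to the test split.

The `p × q` window slides time-inner, batch-outer; window (i, k) covers
batches [i, i+p−1] × times [k, k+q−1], flattened to a (p·q) × J matrix with
rows batch-major. The label is anchored at the window's last (batch, time)
corner — the latest cell — so prediction is causal in time: a soft sensor
estimates *current* quality from the recent past. Windows never straddle
the train/test boundary; test windows are built from test batches only, so
the first p−1 test batches contribute no scored anchors.

Two window-to-network conversions are provided because the tensor-to-network
interface admits two readings. The default, `stacked_sample`, feeds each of
a window's p·q rows separately (input width = J, consistent with network
widths equal to the variable count) and averages the p·q row scores at
prediction time; `flatten` concatenates the window into one (p·q·J)-wide
row. Default window 3 × 3 at desk scale (7 × 5 is the natural choice for
100-batch × 400-point campaigns).

## GSTAE

Layer widths strictly decrease after the input layer (presets
{11, 9, 7, 4} for 11 variables, {7, 6, 5, 3} for 7). Encoders use the
logistic sigmoid; decoders are linear, since inputs are z-scored and
unbounded. Pretraining is layerwise: each layer's decoder reconstructs
[x, y] jointly with the convex mix
`(1−λ)·MSE(x, x̃) + λ·MSE(y, ỹ)`, λ = 0.5 by default. Every layer applies
the joint [x, y] decoder to its own input; the per-layer decoder heads are
discarded after pretraining. Prediction is the gated sum
`ŷ = Σ_i σ(w_g,i·h_i + b_g,i) · tanh(w_o,i·h_i + b_o,i)` with scalar
per-layer contributions, so |ŷ| < number of layers — appropriate for
z-scored targets. Gates are initialized fresh (fan-in-scaled Gaussians from
the run seed) and trained only during fine-tuning, which minimizes the mean
squared prediction error over all parameters jointly. The loss is the
*mean* rather than the sum over samples so the learning rate is independent
of sample count; the gradient direction is identical.

**Optimizer.** Full-batch updates with Adam at lr 0.01 by default. Plain
full-batch gradient descent (retained as `optimizer="gd"`) needs orders of
magnitude more epochs at the same learning rate to reach a comparable fit on
the desk-scale training sets, so Adam is the practical default; all
gradients are hand-derived and checked against finite differences to 1e−4
relative in the tests. Default epochs: 200 per layer (pretraining), 500
(fine-tuning) — enough for the training loss to plateau at desk scale.

## Pipeline and evaluation

`run_pipeline` executes: co-train → impute pseudo-labels (training split
only; measured labels are never overwritten, and a provenance channel keeps
`measured`/`pseudo` apart) → fit/apply standardization → window → train
GSTAE → predict test anchors → inverse-standardize → score. With one player
or a zero iteration budget, the co-training stage is skipped and the network
trains on measured anchors only — the supervised windowed baseline.

Metrics: RMSE and R² in original units, the latter in both the standard
1 − RSS/TSS form and the regression-SS/TSS ratio form (they agree only for
least-squares-optimal predictions; outputs label which is which, and the
headline `r2` is always the standard form).

**Seed policy.** One master seed fans out via `SeedSequence.spawn` into
independent simulation, co-training, and network-initialization streams, so
every sweep cell is reproducible in isolation. Sweeps report per-seed
metrics and their arithmetic seed means; paired per-seed comparisons (not
pooled metrics) are used when claiming one configuration beats another.

**Problem sizes.** The package's study conditions are desk-scale: campaigns
of 20 batches × 7 variables × 100 time points, split 15/5, ratios 5–40,
ten seeds for paired comparisons and three for the ratio sweep. Larger
campaigns (e.g. 100 × 11 × 400, split 75/25) are a configuration away but
are not what the shipped tests run.

## Known limitations

- kNN co-training scans the full pool each iteration; cost grows with
  |U| · |L| per player per iteration. The incremental Δ update keeps this
  vectorized, but very large campaigns will want the `pool_size` cap.
- Co-training operates on raw (unstandardized) features, per the pipeline's
  stage order; with the instrument-scale noise model this is benign, but
  variables with wildly disparate variances could dominate the metric.
- No validation split or early stopping; epoch budgets are fixed.
- The Δ-criterion evaluates improvement only on the candidate's immediate
  neighborhood, a local proxy for regressor quality.
- `r2_ratio` can exceed 1 for over-dispersed predictions; it is reported
  for comparability, not as a goodness-of-fit measure.
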