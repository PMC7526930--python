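# Methods

This note records the modelling and numerical choices behind `chrysopt`,
what the synthetic validation does and does not establish, and the known
limitations of the analysis.

## Data resolution

The packaged database is a transcription of 49 published chrysanthemum
transformation experiments. Published cells are not directly numeric, so
three explicit policies turn them into training rows:

* **Ranges** ("4.3–13.4 %", "15–25 mg/L") collapse to the arithmetic
  midpoint. The midpoint is the least-biased single-value summary when the
  underlying distribution is unknown; `min` and `max` policies are
  available on `ResolutionPolicy` for sensitivity checks. A degenerate
  range (a single value) is returned exactly, so resolution never perturbs
  clean cells.
* **Multi-strain studies** expand to one row per strain with all other
  fields duplicated. Strain is one input variable of the model, and
  expansion preserves the association between the remaining factors and
  the outcome. The expansion count is conserved: 75 rows from 49 studies.
* **Absent antibiotics** ("-") are dose 0 — absence of a compound is a
  physical zero, not a missing observation. One study has a blank
  co-culture cell; a zero would be physically wrong for a duration, so it
  is imputed with the column median (the only imputation in the pipeline).

Strain is integer-coded in order of first appearance (14 codes), keeping
the model at exactly eleven inputs so the sensitivity analysis ranks
"strain" as a single variable; one-hot encoding would dilute it over 14
binary columns. The OD wavelength (540/550/600/660 nm) is retained as
metadata, not a feature: optical densities at different wavelengths are
treated as one scale. All features are min–max scaled to [0, 1] over the
full resolved table (the same extrema parameterize the optimizer's bounds);
targets stay on the raw 0–100 % scale so RMSE and MBE read in percentage
points.

Splits are uniform 70/20/10 partitions with largest-remainder rounding
(ties resolved train > test > validation), giving 53/15/7 rows.

## Member regressors

All three members are implemented from first principles in numpy and share
a contract: deterministic given their seed, JSON-serializable, reload-
identical, trained on squared error.

**MLP.** One hidden layer of 10 sigmoid units, linear output. Training is
mini-batch gradient descent (batch 16, learning rate 0.01, 500 epochs)
with classical momentum 0.9. The hidden layer is Glorot-initialized; the
output layer starts at zero weights with the bias at the target mean, so
the network begins as the constant predictor and the small learning rate
still converges within the epoch budget. Divergence (non-finite loss)
raises immediately rather than returning a broken model. An optional 10 %
internal holdout with early stopping exists but is off by default.

**RBF network.** Centers by seeded k-means (15 by default); when as many
centers as distinct training rows are requested, the rows themselves
become centers, which recovers exact interpolation as the ridge vanishes.
Kernel widths default to per-center nearest-neighbor distances scaled by
1.5; the textbook shared width σ = d_max/√(2c) is available as
`width_rule="max_pairwise"` but measures poorly here — in eleven
dimensions it leaves most of the space uncovered and the network
degenerates to its intercept. The output layer is solved in closed form by
ridge least squares (ridge 1e-3, intercept unpenalized) over the basis
responses plus a linear tail in the raw features; the tail is the standard
polynomial augmentation and lets the network represent affine trends
exactly. The closed-form solve makes the fit deterministic and gives the
output weights an explicit normal-equations oracle used in the tests.

**ANFIS.** First-order Takagi–Sugeno system with one rule per fuzzy
cluster (4 clusters by seeded k-means; a grid partition over 11 inputs
would need 2¹¹ rules and is intractable). Gaussian memberships, product
t-norm, firing strengths normalized in log space with max-subtraction so a
sample far from every cluster renormalizes gracefully instead of dividing
by zero. Hybrid training alternates per epoch: consequents by least
squares with premises fixed, then a gradient step on membership centers
and widths. The consequent solve carries a small Tikhonov ridge (1e-3,
rule biases unpenalized, min-norm solution) — without it the ~48-parameter
solve on a ~34-distinct-row bootstrap sample is ill-posed and held-out
predictions explode. The premise step is accepted only if the post-step
loss does not increase (otherwise the step is reverted and the step size
halved), so the recorded loss trace is non-increasing by construction.

## Fusion and metrics

Bagging: each member kind is refit on B = 25 bootstrap resamples of the
training rows (resamples with fewer than two distinct rows are redrawn),
the member's prediction is the mean over its refits, and the fused
prediction is the unweighted mean of the three members — a convex
combination, so fusion can never leave the member envelope. A weighted
mean is available behind `weights`. The degenerate configuration B = 1
without resampling (a test hook) reduces fusion to the plain mean of the
three single fits.

Metrics: R² = 1 − SSE/SST (not squared correlation — the two differ off
the 45° line), RMSE, and MBE = mean(ŷ − y), so over-prediction is
positive. Constant observations make R² undefined and raise.

## Optimizer

The fruit-fly algorithm is implemented in its standard multi-dimensional
extension: every decision variable keeps an independent (x, y) coordinate
pair per fly; flights add uniform offsets from [−10, 10] to the swarm
axis; Distᵢ = √(xᵢ² + yᵢ²) (floored at 1e-12) gives Sᵢ = 1/Distᵢ; each
dimension's S, clamped to [0, 1] against the unit-distance reference,
maps linearly into that variable's bounds, with the strain dimension
rounded to the nearest valid code. The axis moves only when a fly beats
the incumbent (elitism), so the best-smell history is non-decreasing and
a run costs exactly maxgen × sizepop = 1000 objective evaluations.
Defaults: maxgen 100, sizepop 10, axis initialized uniformly in [0, 1].
Ties at the argmax resolve to the lowest fly index; non-finite objective
values are treated as −∞.

Bounds default to the observed min–max of each factor in the resolved
database. The production objective is maximization of the fused ensemble's
predicted efficiency.

On benchmarks within its reach the optimizer is reliable (2-D sphere
located within 0.05 per coordinate in 20/20 seeds; a 6-level categorical
matches exhaustive enumeration in 19/20). Its character should be
understood plainly, though: with a fixed flight range of ±10 the S = 1/Dist
transform makes the search close to elitist random sampling, which cannot
place all eleven coordinates of a joint optimum precisely within a
1000-evaluation budget (see Limitations).

## Sensitivity analysis

VSE of a variable is the ensemble's RMSE with that variable "removed";
VSR = VSE / full-model RMSE, ranks descending (ties broken by canonical
variable order). Removal defaults to mean substitution — the column is
replaced by its training-split mean, no retraining — which measures how
much the fitted surface uses the variable. A retrain-without-column policy
is available for the stronger "information content" question, and an
identity policy (VSR ≡ 1) anchors the scale in tests. VSE is evaluated
over the full database.

## Synthetic generator

The generator emulates the statistical shape of the literature table: one
categorical factor with additive per-level effects (default spread 0–12
pp, making strain the dominant factor), ten continuous factors on
realistic dose/density/duration scales with interior optima, response

  efficiency = base + strain effect + Σ wⱼ exp(−(vⱼ − oⱼ)²/2τⱼ²) + N(0, σ²),

clipped to [0, 100] (clip fraction reported; < 1 % at defaults). Bump
widths default to a quarter of each factor's range; amplitudes are
heterogeneous (8 pp down to 1 pp); antibiotic columns are structurally
zero in 30–50 % of rows, as most studies use only a subset of compounds.
Defaults are n = 500 rows and noise SD 2 pp — the conditions used by the
recovery experiments. Because the surface is a separable sum, the argmax
and maximum are closed-form, giving exact oracles for optimizer recovery
and importance ranking.

What passing synthetic tests show: the pipeline can learn a smooth
11-factor response from 350 training rows (ensemble validation R² ≈ 0.86
noiseless), identify the dominant factor (VSR rank 1 in 20/20 seeds), and
fuse members without losing to the best one beyond seed-sampling noise.
What they do not show: real literature data meets none of the generator's
assumptions — its noise is not additive Gaussian, protocols are correlated
with labs, and the response need not be unimodal — so synthetic success
bounds the pipeline's behaviour under its own assumptions only.

A note on the fused ensemble's ceiling: the radial-basis member cannot
represent a 10-bump additive surface with 15 Euclidean-radial kernels
(its validation R² plateaus near 0.4 regardless of widths or center
count), which caps the unweighted three-member fusion near R² 0.86
noiseless rather than the ~0.95 the other two members would reach alone.
This is an architectural property of radial kernels in high dimension,
not a fitting failure.

## Statistical tolerances

Stochastic properties over seeds (fusion dominance) are asserted up to
2× the bootstrap standard error of the statistic across the 20 seeds,
i.e. up to the Monte-Carlo uncertainty of a 20-seed median; fixed-seed
suites make these checks deterministic in CI. Simulation sizes are chosen
for a single CPU: the synthetic experiments bag B = 5 refits per member,
the literature sweep runs the full B = 25.

## Limitations

* **The literature compilation is extremely noisy.** Identical protocols
  report efficiencies differing by an order of magnitude (e.g. 0.5 % and
  39 % under near-identical AGL0 regimes), and range midpoints are crude.
  Out-of-sample R² on 7-point validation splits is typically negative for
  every member and for the fusion; the honest multi-seed medians in
  `results/sweep_summary.csv` are therefore far more pessimistic than any
  single favourable split. Conclusions about *which* protocol maximizes
  efficiency should be read as hypotheses, not estimates.
* **Joint optimum recovery in 11 dimensions is out of reach.** Factors
  whose true effect amplitude is at or below the noise SD are statistically
  unidentifiable at n = 500 — the fitted surface's argmax along those axes
  is noise, so no optimizer can recover them — and the 1000-evaluation
  swarm is near-random search in 11 dimensions, so even well-identified
  factors land within 10 % of their range only occasionally. The recovery
  experiment records this honestly; the identifiable structure (dominant
  factor, categorical optimum, low-dimensional benchmarks) is recovered
  reliably.
* **Mean-substitution sensitivity measures the fitted surface, not the
  biology.** With heavily bagged, heavily smoothed members, substituting
  one column moves predictions little, so VSR ratios compress toward 1;
  ranking remains meaningful, magnitudes are not effect sizes.
* **Model capacity is deliberately small** (10 hidden units, 15 centers,
  4 rules) to fit 53 training rows; none of the members is suited to
  larger feature spaces without reconfiguration.
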