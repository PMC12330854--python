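# Methods

## Signal model

The pipeline assumes a linear time-invariant coupling between neuronal
events and the BOLD signal. An activity-inducing train of changes in the
transverse relaxation rate, `ΔR2*(t)` in s⁻¹, produces at echo time `TE_k`
the fractional signal change

```
ΔS_k(t)/S̄_k = −TE_k[s] · (h ∗ ΔR2*)(t),
```

so a negative ΔR2\* event is a positive BOLD deflection whose amplitude
grows linearly with echo time. `h` is the canonical double-gamma HRF
(response delay 6 s, undershoot delay 16 s, unit dispersions,
response:undershoot ratio 6, 32 s support), sampled at the repetition time
and normalised to unit sum — the convention of the standard canonical-HRF
implementation — so that a sustained unit ΔR2\* passes with unit gain
(sustained −0.1 s⁻¹ at TE = 35 ms ⇒ +0.35% steady state). The kernel scale
is therefore not a free parameter; it is absorbed into the ΔR2\* units.

Percent signal change divides the Legendre-detrended raw series by the
voxel's raw temporal mean (×100). The default detrend order is 4,
mirroring the low-order polynomial nuisance regression such data receive;
it is configurable because the order used inside the original
deconvolution tool is not documented. The deconvolution design has the
same Legendre projection applied per echo block, keeping model and data in
one subspace; without this the detrending would bias event amplitudes.
Note the projection removes rank from the stacked design, so plain least
squares on it is non-unique — sparsity, not the pseudo-inverse, resolves
the ambiguity.

## Sparse deconvolution and penalty selection

Per voxel, the three echoes' percent-change series are stacked (divided by
100, so coefficients carry s⁻¹) and the L1-penalised problem

```
min_b  (1/2n)‖y − Xb‖² + α‖b‖₁ ,   n = E·T
```

is solved along a 50-point logarithmic grid from `α_max` (smallest penalty
with an empty model) down to `10⁻³·α_max`. The exact piecewise-linear path
is traced by LARS homotopy with a precomputed Gram matrix and interpolated
onto the grid; every returned solution satisfies the KKT conditions
exactly. On this heavily collinear design the homotopy can stop above the
requested floor when smaller penalties are no longer numerically
controlled; the grid floor is then raised to the last well-controlled
knot. (Coordinate descent was tried first and needed two orders of
magnitude more time to reach comparable stationarity on this design.)

The penalty is chosen by `BIC(α) = n·ln(RSS(α)/n) + k(α)·ln(n)` with
`k` the support size. The RSS entering the criterion is that of the
**penalised (shrunk) path solution**, not a debiased refit. This choice is
load-bearing: with debiased RSS the best single-coefficient model on a
pure-noise voxel reduces the RSS by roughly the maximum of ~T correlated
χ²₁ variables (≈10), which beats the `ln n ≈ 6.4` penalty, so 40–65% of
noise voxels sprout spurious events; with path RSS the shrinkage keeps
early entries from paying for themselves, and noise voxels select the
empty model essentially always while CNR-3 events are still detected at
~100%. The coefficients *returned* at the selected penalty are debiased
(OLS on the support), so event amplitudes are unbiased. Both choices are
recorded in the result metadata; `bic_rss="debiased"` is available.

Selection is voxelwise-independent, seed-free and deterministic. Ties in
BIC go to the larger penalty (sparser model).

## Event detection

After deconvolution: (1) a 3-point sliding temporal filter replaces each
value by the largest-magnitude value in its window (sign kept, boundaries
truncated); (2) per volume, connected components of nonzero voxels smaller
than 10 are removed (6-connectivity by default; 18/26 configurable); the
surviving mask is applied to the *unfiltered* estimates; (3) the
activation timeseries (ATS) counts voxels with negative coefficients per
timepoint. The Random pads are trimmed by schedule lookup before any of
this, leaving the six 60 s experimental blocks (200 volumes at TR 1.8 s).

The null is a surrogate run: one volume-order permutation of the trimmed
raw data (shared across voxels and echoes, one seeded draw per run),
re-analysed end-to-end. The detection threshold is the median of the
surrogate ATS over all timepoints (including zeros; a nonzero-only variant
is available). The stated alternative reading — "exceeds the surrogate
ATS" pointwise — is not used; the median rule is operative. ROI peaks are
the per-segment maxima of the ROI-restricted ATS strictly above the
ROI-restricted surrogate median; plateaus resolve to their midpoint
(earlier sample for even length). An empty event set is a valid outcome.

## Consensus clustering of event maps

Event maps (ΔR2\* at selected peaks) are clustered with squared-Euclidean
k-means — operating on the raw map vectors is identical geometry to
clustering their pairwise Euclidean distances. The number of clusters is
chosen by consensus: for each k in 2..15, 100 k-means runs on 80%
subsamples accumulate a consensus matrix (proportion of co-sampled runs in
which each pair was co-assigned); the consensus value of k averages those
proportions within the clusters of a reference partition at that k. A
simpler summary — the raw fraction of co-assigned pairs per run — is
~1/k for any data and always selects k = 2; the within-cluster form is the
standard consensus-clustering summary, matches the stability reading of
"average proportion of times a pair is assigned together", and recovers
planted k reliably. Ties go to the smaller k. Inside the consensus loop a
light single-restart Lloyd's k-means (k-means++ init) runs on a
principal-axis projection of the maps (an exact isometry, at most N
nontrivial axes); it is cross-checked against scikit-learn's k-means in
the tests, and the definitive partition always comes from scikit-learn's
k-means with 50 restarts.

Cluster summary maps are the voxelwise mean of member maps (identical to
the squared-Euclidean centroid), Z-normalised in space, multiplied by −1
(negative ΔR2\* = positive BOLD) and binarised at Z ≥ 3.2.

## First-level GLM comparator

The design has 10 columns: Random/Okay/Suppress block boxcars, a
parametric regressor of the standardised urge (one rating per second,
experimental period only), a blink event regressor, and one temporal
derivative per column (first differences, zero prepended — standard
practice, not otherwise documented). Stimulus functions are sampled on the
TR grid as fractional overlaps and convolved with the canonical HRF.
Behavioural events that fall after the last acquired volume but inside the
run are ignored rather than rejected. Fitting is plain OLS (no
prewhitening; synthetic noise is white by default — a flagged limitation
for AR(1) stress tests), the contrast t statistic is mapped to Z by
matching tail probabilities, and maps are binarised at Z ≥ 3.2. Group-level
mixed-effects averaging and random-field cluster correction are out of
scope; maps are compared at the run level with conjunction, percent
overlap within the GLM mask, Jaccard and Dice. The GLM input for synthetic
runs defaults to the middle echo's percent change (the optimally-combined
weighting belongs to preprocessing, which is out of scope).

## Behavioural statistics

Urge is down-sampled 10 → 1 Hz by within-second means (preserves slow
dynamics better than decimation) and z-scored per run, Random seconds and
experimental seconds separately; zero-variance groups raise an error. Time
bins are half-open `[s, s+1)` with the origin at the first volume. Blink
occurrence is binarised per second. The blink–urge association is a
maximum-likelihood logistic regression reporting B, Exp(B), Wald, the
likelihood-ratio χ² against the intercept-only model and Cox–Snell R²;
single-class outcomes and separation are flagged, with no estimates.

Peri-blink curves average 11-second windows centred on blinks that fall at
least 5 s after their block's start and more than 5 s before its end.
Participants with no retained (escape) blinks are excluded via an explicit
signal. Curve shape statistics treat the curve as a weight distribution
over lags after subtracting the curve minimum (the shape statistics of a
partly negative z-curve need non-negative weights; the shift is logged and
configurable); peak latency is the lag of the maximum, earliest lag on
ties. Group tests are two-tailed one-sample tests of latency vs 0,
skewness vs 0 and kurtosis vs 3 — the kurtosis scale is raw (normal = 3)
with excess kurtosis reported alongside, since values near 3 compared
against normality only make sense on the raw scale. A Shapiro–Wilk gate at
α = 0.05 switches t to Wilcoxon (the normality test is otherwise
unnamed).

The linear-vs-quadratic comparison of the group curve chooses the
quadratic model when its squared term is significant at p ≤ 0.05 **and**
its overall F exceeds the linear model's; otherwise linear. The compound
rule follows the published reasoning (which weighed the F statistics and
the term's significance together) and, unlike the significance-only rule,
keeps the false-quadratic rate under the linear truth comfortably below
5% instead of exactly at it. Block summaries report per-participant mean
urge (raw % scale) and blinks/min per condition, tested with a paired
t-test (one-tailed, Suppress > Okay for urge) and a Wilcoxon signed-rank
test (one-tailed, Suppress < Okay for blinks).

## The synthetic-data generator

The generator emulates the study conditions: the 420 s template (30 s
Random pads, three alternating pairs of 60 s Okay/Suppress blocks, order
set by a counterbalancing flag); urge at 10 Hz in [0, 100]; blinks from an
inhomogeneous Bernoulli process per 0.1 s bin with a 0.3 s refractory
period (hazard corrected for the dead time). Defaults target the observed
behaviour: ~31 blinks/min free blinking vs ~5/min under suppression, mean
urge ~22% vs ~52%. Under suppression the latent urge rises toward a soft
ceiling (6.5 %/s toward 92) and escape blinks require urge above a
threshold (30, hazard scaling 24), which concentrates them at urge highs;
after each blink the urge keeps rising for 0.7 s, then relief spreads an
18-point drop over 3.5 s while growth pauses. The resulting latent
peri-blink template peaks at the blink at 1 Hz resolution (the published
group curve peaked at, or just after, blink onset), rises ~quadratically
into it and falls after it — the estimated group peak latency still reads
~0.3–0.5 s early because the lag-0 second mixes pre-peak rise with
post-blink relief, an intrinsic discretisation bias of 1 Hz binning; under free blinking relief is mild (3 points)
and the trace relaxes toward its baseline, giving a flat-to-linear
peri-blink shape. Reported urge adds white noise (sd 2) and clips to
[0, 100]; the pre-clipping latent trace is retained so template oracles
are exact. Where the study reports no value (e.g. per-condition blink-rate
variability), defaults are plausible rather than calibrated.

The imaging phantom plants impulsive ΔR2\* events (shared within each
cuboid ROI, minimum separation 12 TRs) on a 1000-unit baseline, expresses
them per echo via the linear-TE model, and adds optional Legendre drift
and white (optionally AR(1)) Gaussian noise in percent units. CNR is
defined as peak percent change at the middle echo divided by the noise sd;
the helper `evaluation.amplitude_for_cnr` inverts it. The generator does
not simulate scanner physics, motion, multiband artefacts or ME-ICA
residual structure — so passing tests demonstrate the estimator's
correctness under its own model assumptions, not robustness to real
acquisition artefacts.

## Problem sizes used by the evaluations

The property evaluations (`urgepfm.evaluation`, driven by the test suite
and `scripts/acceptance.py`) use desk-scale sizes chosen so the whole
battery runs in minutes on one CPU while keeping every statistical
property meaningful: noiseless forward/inverse on the full 20×20×10 grid
(T = 200, 3 echoes); detection on 8×8×4 phantoms with one 3×3×2 ROI and 6
CNR-3 events, 20 seeds, each seed paired with a matched event-free
phantom; null exchangeability on 6×6×4 event-free phantoms, 50 seeds;
clustering on 60-map stacks over 120 voxels with 3 planted groups, 50
seeds; GLM calibration on 10⁶ white-noise voxel draws; behavioural
recovery with 200 logistic seeds (10⁴ samples each), 200 curvilinear
seeds, and 100 generator seeds for the peri-blink latency. On null
phantoms the empty-model BIC keeps both the original and surrogate ATS at
(near-)zero counts, so their KS agreement is typically exact — the check
verifies that the pipeline does not manufacture asymmetry between original
and shuffled data anywhere along the chain.

## Known limitations

- Noise is white by default; AR(1) is available as a stress option but no
  prewhitening is implemented in the GLM.
- The deconvolution models R2\* changes only (no ΔS0/non-BOLD regressor)
  with a fixed canonical HRF; HRF mismatch is not estimated.
- The surrogate uses one seeded permutation per run, not an average over
  draws.
- The exact BIC variant of the original deconvolution tool is not
  documented; the formula implemented here is declared in the result
  metadata rather than asserted as equivalent.
- Group-level (mixed-effects, cluster-corrected) inference is out of
  scope; all maps are run-level.
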