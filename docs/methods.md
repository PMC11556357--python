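# Methods

## The model

`binocgain` implements the two-stage binocular contrast gain control
model. Contrasts shown to the left and right eyes, `C_L` and `C_R`,
expressed in linear units normalized to the monocular detection
threshold, drive a monocular stage with divisive interocular
suppression,

    Stage1_L = C_L^m / (S + C_L + ω·C_R)
    Stage1_R = C_R^m / (S + C_R + ω·C_L),

whose outputs sum (`binsum = Stage1_L + Stage1_R`) and pass through a
second, binocular gain control stage,

    Stage2 = binsum^p / (Z + binsum^q).

A 2IFC discrimination threshold is the smallest target increment `T`
for which the Stage-2 response difference between the target interval
and the null interval equals the criterion `k`. Dividing that response
difference by the internal noise `k/τ` gives d′, where
`τ = Φ⁻¹(0.75)·√2 ≈ 0.954` is d′ at a 75%-correct threshold. d′ maps
to percent correct through the standard unbiased 2AFC link
`P(correct) = λ/2 + (1−λ)·Φ(d′/√2)` with a small lapse rate λ
(default 0.01). The link is our choice — it is the unique one
consistent with τ defining 75% correct at threshold — and it lets
negative d′ produce below-chance performance (the "swan" region of
strong within-channel dichoptic masking, where a weak target
suppresses the mask more than it excites the detecting mechanism).

### Parameters

| name | meaning | units | typical value |
|------|---------|-------|---------------|
| m | stage-1 excitatory exponent; sets binocular summation at threshold (≈ 2^(1/m)) | — | 1.1–1.4 |
| S | stage-1 saturation constant | normalized contrast | 0.3–1.2 |
| ω | interocular suppression weight; ω ≈ 1 yields ocularity invariance | — | 0.9–1.05 |
| p, q | stage-2 numerator/denominator exponents; p−q sets the handle slope | — | 4–16 |
| Z | stage-2 saturation constant | — | 0–0.25 |
| k | response-difference criterion; k/τ is the internal noise SD | response units | 0.1–0.35 |
| τ | d′ at detection threshold | — | fixed, 0.954 |

τ is a derived constant, not a free parameter. Published parameter
sets for achromatic gratings, L-M and S-(L+M) isoluminant gratings and
flickering discs are bundled in `gain_model.PUBLISHED_PARAMS`.

### Cross-pathway extension

Three mechanisms (achromatic AC, red/green RG = L-M, blue/yellow BY =
S-(L+M)) run the same two stages on their own pathway's contrast, but
each monocular denominator pools other-eye contrast from *all three*
pathways through a 3×3 weight matrix `W[target][mask]`, e.g.

    AC_Stage1_L = AC_L^m / (S + AC_L + ω_AA·AC_R + ω_AR·RG_R + ω_AB·BY_R).

The diagonal holds the within-pathway ω. Same-eye (monocular)
cross-pathway suppression is deliberately absent: no data constrain
it, so cross-pathway masks act only through the opposite eye. The
readout mechanism is always the one tuned to the target's
chromaticity (the task design removes target uncertainty); no
max-over-mechanisms rule is applied. Each pathway's contrasts are
normalized by that pathway's own monocular threshold, which places the
standard high-contrast dichoptic masks at ≈ 16 normalized units.

## Numerical choices

**Threshold solver.** The criterion equation is solved by scanning 64
log-spaced points over [1e−4, 1e4] normalized units for the first
upward crossing of `(response difference − k)`, then bisecting in log
contrast to relative tolerance 1e−6. The *first* crossing matters:
dichoptic response differences are non-monotonic in the swan region
and the contract is the smallest criterion-reaching target. Absence of
a crossing raises a solver error, never a clamped value; parameter
regimes with m < 1 and strong suppression genuinely saturate below
criterion at high pedestals. Zero contrasts are handled analytically
(response exactly 0, also when Z = 0), with no epsilon padding.

**Low-contrast summation limit.** The summation ratio approaches
2^(1/m) only once thresholds fall far below S. For m = 1 and ω = 1 the
ratio is exactly 2 at any k (algebraic identity); for m > 1 the tests
scale k to ~1e−30 to reach the limit within 1%.

**dB convention.** `C_dB = 20·log10(C%)`; all model computation is in
linear normalized units, with dB used only for reporting, staircase
steps and regression. Handle slopes are ordinary least squares on dB
threshold vs dB pedestal over the four highest nonzero pedestals; the
detection point is excluded.

## Synthetic observers

The generator emulates the three study designs with a stochastic
observer whose per-trial probability correct is the generating model's
d′ through the 2AFC link:

- **Dipper experiments** (gratings, and flickering discs with their own
  parameter set — the model does not distinguish flicker from gratings;
  stimulus type is a condition label): per pathway, pedestal and
  repetition, eight interleaved 3-down-1-up staircases (4 ocular
  arrangements × 2 target eyes) moving in 3 dB steps. Pedestal grids:
  0–32% (achromatic) and 0–64% of maximum (chromatic), converted to
  normalized units via a generating monocular threshold of 1% contrast.
  Three repetitions per pedestal, three participants. Trials per
  staircase (50) and start level (10 dB above the generating threshold)
  are not dictated by the design and are configurable.
- **Dichoptic masking** by method of constant stimuli: 12 conditions
  (3 baselines + 9 target×mask pairings), 10 target levels in 3 dB
  steps straddling the model-predicted masked threshold, 200-trial
  blocks, 10 repetitions, masks at 16× monocular threshold — 72,000
  trials for three participants.

Participant heterogeneity is log-normal jitter (SD 0.1 in log units)
on (m, ω, k) around group values — exactly the structure the
hierarchical fit assumes. The generator does **not** emulate session
effects, learning/fatigue, response bias, interval order effects or
eye dominance; passing recovery tests therefore demonstrates the
correctness of the fitting machinery under the model's own
assumptions, not robustness to the full messiness of real data.

## Psychometric fitting

Cumulative Gaussian on dB contrast with guess rate 0.5, fit by
grid-based Bayesian numerical integration over (location, σ, lapse):
uniform prior on location over the tested range ± 6 dB, log-uniform σ
∈ [0.3, 30] dB, Beta(1,4)-weighted lapse ∈ [0, 0.06]. Point estimates
are posterior means; intervals are central 95% quantiles computed by
direct summation (no sampling). Threshold is reported at 75% absolute
correct on the lapse-corrected function; the Gaussian slope converts
to an equivalent Weibull slope via β = 10.3/σ. Data that are all
correct or all wrong pile posterior mass against the location prior's
edge and are flagged non-identifiable rather than raising. The
estimator is intentionally not a clone of any published fitting
package; no adaptive-procedure-aware corrections are applied, so
staircase-sampled cells carry a small extra variance relative to
constant-stimuli cells.

## Model fitting

**Simplex.** Multi-start Nelder-Mead on log-parameters minimizing the
dB RMSE between model and data thresholds; 100 log-uniform random
starting vectors by default, ties broken by lowest start index,
followed by a polish phase that restarts the simplex at the incumbent
(a fresh simplex escapes premature collapse in higher dimensions).
Solver failures inside the objective score a large penalty rather than
aborting the start.

**Hierarchical Bayesian.** Trial-level binomial likelihood at each
(arrangement, pedestal, target) cell, fit simultaneously to all
participants with emcee's affine-invariant ensemble sampler
(differential-evolution moves, walkers treated as chains for rhat/ESS
diagnostics via arviz; unconverged chains are flagged, never raised).
Priors: Gaussian on p, q, m, ω centered on the published achromatic
values (SDs 2.0, 2.0, 0.3, 0.3), uniform on S ∈ (0, 3], Z ∈ [0, 1],
k ∈ (0, 2], all sampled on log scale with the appropriate Jacobians.
Hierarchy: (p, q, S, Z) shared at group level; participant-level
(m, ω, k) log-normally pooled around group means via non-centered
offsets. The between-participant SD of each pooled parameter is
estimated (half-normal prior, scale 0.2) rather than fixed: with only
three participants, fixing it makes the group-mean intervals
overconfident, and a 20-replicate calibration study showed materially
better interval coverage when it is estimated. A fixed SD remains
available through the `pooling_sd` argument. The lapse rate is fixed
at the generator's 0.01 rather than estimated.

The cross-pathway fit frees exactly nine parameters — one Z per
mechanism (uniform [0, 1]) and the six cross-pathway weights (uniform
[0, 2.5]) — with p, q, m, S, k and the diagonal weights fixed from
single-pathway fits, and pools all participants under shared
parameters. Its recovery simulations therefore generate data with
shared parameters; with per-participant jitter on (m, k) the pooled
fit acquires weight biases, which is model mismatch rather than a
defect of the sampler.

Desk-scale MCMC defaults (≈ 40 walkers × ≈ 1,000 steps per fit, i.e.
tens of thousands of draws) are far below the > 10⁶ samples a
production analysis would use; 10% of draws are retained in posterior
summaries. Recovery and calibration tests run at reduced designs
(4 pedestals, 25-trial staircases, 1 repetition) so that a 20-replicate
study completes on a single CPU in a few minutes.

## Known limitations

- Group-level 95% intervals from three-participant designs track the
  *realized* participant sample; when the three jitter draws happen to
  land collectively ~2.4σ from the group mean (a few percent of
  replicates), the generating group value falls outside even a
  perfectly calibrated interval. Calibration studies at this scale
  should expect occasional such replicates.
- Ensemble MCMC in the 19-dimensional hierarchical posterior mixes
  slowly (split-walker rhat ≈ 1.1–1.2 at desk scale); diagnostics are
  attached to every fit and should be consulted before interpreting
  tail quantiles.
- The cross-pathway model omits monocular (same-eye) cross-pathway
  suppression and any stage-2 cross terms.
- Real-data ingestion, stimulus rendering, display calibration and
  isoluminance adjustment are out of scope; the trial-table CSV schema
  is the interface for observed data.
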