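# Methods

## Assay model

A transduction-inhibition assay reads reporter luminescence (RLU) from
cells transduced by an AAV vector in the presence of serially diluted test
serum.  The package models one well's expected signal as

    RLU = baseline · E(s_aav) · I(s_medium) · H(d) · ε

with four multiplicative factors:

- **Enhancement** `E(s) = 1 + A·s/(s + K)` — serum pre-incubated with the
  vector increases transduction.  A saturating hyperbola matches the
  observed behaviour (a sharp rise that plateaus near 5% serum); no
  mechanistic form is established for this effect, so the hyperbola is a
  deliberate phenomenological choice.  Defaults: amplitude `A = 2`
  (3-fold maximal enhancement) and half-saturation `K = 0.05` (5% serum
  volume fraction).
- **Inhibition** `I(s) = 1/(1 + c·s^k)` — serum in the cell-culture medium
  decreases transduction; Hill-type decay, defaults `c = 8`, `k = 1`
  (≈ 45% loss at 10% serum).  Within one assay format the medium serum is
  constant, so this factor cancels in normalization; it matters for the
  antibody-free serum-titration experiment (`simulate_serum_titration`).
- **Neutralization survival** `H(d) = 1/(1 + (d/ND50)^h)` at serum dilution
  fraction `d`, a Hill function with bottom 0 and top 1 in the generator
  (the fit does not assume this).  `H ≡ 1` for seronegative samples;
  `H(ND50) = 0.5` by construction.
- **Noise** `ε = exp(N(0, σ))`, multiplicative lognormal (luminescence is
  positive and heteroscedastic), default `σ = 0.05`.

Serum composition per well follows the format: **CSC** holds total serum at
`0.10` for every dilution (test serum balanced by antibody-free serum
diluent; the control well is the pure serum matrix, so `E` cancels exactly
against the control).  **VSC** adds the test serum on top of the medium's
fixed serum: `s_total(d) = 0.0125 + 0.25·d` by default (1.25% medium serum;
a 20 µL transduction mix into 100 µL total gives the 0.25 scale; both are
configurable, since exact per-well volumes differ between laboratories).
Its antibody-free control contains no test serum, so seronegative VSC
curves are inflated above 100% by the ratio `E(s_total(d))/E(0.0125)` —
increasing toward the 1/4 dilution.  This is the masking mechanism: the
documented demonstration set (`masking_demo_truth`) contains a sample with
true ND50 = 1/5 whose noise-free CSC curve crosses 50% inside the tested
range while its VSC curve never drops below 50%, plus a very weak
neutralizer (1/3) that only the pool-eligibility rule catches under CSC.

### What the generator does and does not emulate

It reproduces the statistical structure relevant to the pipeline: 2-fold
dilution series, format-specific serum composition and baseline inflation,
Hill-shaped neutralization, plate-wise antibody-free controls, replicate
structure and multiplicative noise.  It does **not** model serum
biochemistry (albumin–capsid interaction, complement, heat-inactivation),
empty-capsid decoys, plate-position effects, or non-Hill neutralization
shapes.  Passing tests therefore demonstrate correctness of the analysis
given this generative structure, not robustness to every artifact of real
plates.

## Normalization

Transduction % = `100 · RLU / mean(control RLU)` within the matched
(plate, serotype, format) group; normalization never crosses plates (a test
group without its own control is an error, not silently pooled).  Controls
aggregate by arithmetic mean; replicate means and SDs are computed on the
normalized scale.  Values above 100% are preserved.  Blank-well
subtraction exists behind a flag and is off by default, since the assay's
ratiometric design does not require it.  The relative standard error of the
control mean is carried on each curve (`control_rse`) because dividing all
points by the same noisy control induces a *shared* scale error — see the
Hill likelihood below.

## ND50 estimation

ND50 is reported on the dilution-fraction scale; a *higher* titer means a
*smaller* fraction (neutralization persists at stronger dilution).

**Four-parameter Hill fit.**  Parameters (bottom, top, slope, x50) on
`x = log2(d)` plus a noise SD.  Priors: bottom ~ Normal(0, 20) truncated at
−10, top ~ Normal(100, 20), slope ~ lognormal(0, 1), x50 ~ Uniform(tested
range ± 2 doublings), noise SD ~ half-Normal(0, 10); the asymptote priors
reflect the assay construction (top near 100% by normalization, bottom near
0 at saturating antibody).  The likelihood is Normal on the transduction-%
scale and consumes replicates exactly through per-dilution sufficient
statistics.  When `control_rse > 0` a shared scale nuisance `c` with
`log c ~ Normal(0, control_rse)` multiplies the curve, so credible
intervals include the normalization uncertainty; the ND50 is read off the
descaled curve.  Sampling uses emcee (20 walkers, differential-evolution +
snooker moves, 500 warmup steps, thinning 3, 8 000 retained draws — the
move mixture and thinning were chosen for mixing quality on this correlated
posterior).  Convergence is flagged when the split-chain rank-normalized
R-hat of any parameter (walkers grouped into 4 pseudo-chains of 2 000 draws)
exceeds 1.01; this threshold is deliberately strict, and flagged fits still
return draws — the flag marks them for inspection rather than discarding
them.

The reported ND50 is the posterior of the *absolute* 50%-of-control
crossing, `x50 + log2((top − 50)/(50 − bottom))/slope`, defined for draws
with bottom < 50 < top; if fewer than half the draws admit a crossing the
curve is treated as non-identifiable for the ND50 (flat or fully masked)
and censored.  Point estimate = posterior median, interval = 2.5–97.5
percentiles.

**Linear fit.**  Bayesian simple linear regression of transduction % on
log2 dilution under the standard noninformative reference prior
(Normal–inverse-χ² posterior); the ND50 posterior is the 50% crossing
`(50 − a)/b` over draws with negative slope.  The crossing is reported only
when the slope is credibly negative (posterior probability ≥ 0.95);
otherwise the sample is censored — this operationalizes "no crossing" for
flat or rising series.  With two points or a perfect fit the posterior
degenerates to the least-squares line and the crossing is deterministic.
The fit uses all tested dilutions by default; a `window` argument restricts
it to points flanking 50% when the series is sigmoidal enough that global
linearity is a poor approximation.  This robust route is applied to all
serum samples of both formats (model policy `auto`), keeping the CSC/VSC
comparison on one analytical footing; the Hill route serves
monoclonal-antibody calibration series.

**Censoring.**  An estimate weaker than the strongest tested serum
concentration (dilution fraction > 1/4, i.e. titer below 4) or an absent
crossing yields `censored = True` and the display placeholder titer `1/1`.
Result tables serialize titers as the authoritative decimal plus a
rounded-reciprocal display string (`0.1207` → `1/8`).

## Classification and discordance

Labels are assigned from the replicate-mean transduction at the 1/4
dilution: pool-eligibility seronegative requires strictly `> 90%`;
neutralizing requires strictly `< 50%`.  Boundary values fall conservative
(ineligible / non-neutralizing).  Paired CSC/VSC labels form a 2×2 table;
the exact McNemar p-value is the two-sided binomial on the discordant
cells, `min(1, 2·P(X ≤ min(b,c)))` with `X ~ Binomial(b+c, ½)` — exact
because discordant counts are typically small; the χ² approximation is
available behind `method="asymptotic"` for cross-checking.

## Effect size and equivalence

Cliff's delta uses the exact O(n·m) pairwise count (ties count to neither
side); the absolute value is the default statistic, the signed variant is
exposed for directional statements.  The 95% CI is a percentile bootstrap
(10⁴ resamples, within-group resampling, seeded); bootstrap replicates use
an equivalent sort-based counter for speed, tested equal to the pairwise
count.  Magnitude bands: |δ| ≥ 0.11 / 0.28 / 0.43 for small / medium /
large.

The practical-equivalence test models each group of log2 ND50 values as
Normal with scale-adaptive priors — mean ~ Normal(pooled mean, 2·pooled
SD), SD ~ half-Normal(0, 2·pooled SD) — and evaluates
`P(|μ_a − μ_b| > 0.3)` on the posterior of the mean difference; the verdict
is *different* only above 0.95.  The per-group posterior over (μ, log σ) is
computed on a 161×161 grid (wide enough to hold essentially all mass) and
sampled with within-cell jitter: deterministic to grid resolution, orders
of magnitude faster than MCMC at this dimensionality, and reproducible.
Groups may also be supplied as posterior draws of their log2 ND50
(`as_draws=True`, ≥ 100 draws), in which case the difference posterior is
formed directly; single-value groups are refused with instructions to pass
draws, since they carry no dispersion information.

## Problem sizes used in the test suite

The validation suite runs at desk scale by design: ND50 recovery
calibration uses 200 simulated seropositive CSC curves (6 dilutions × 3
replicates, noise σ = 0.05, true log2 ND50 uniform on [−6, −3], Hill slope
uniform on [1, 3]); equivalence-test calibration uses 500 null and 500
separated pairs (n = 20 per group, SD 0.2); Cliff's delta and McNemar
implementations are checked against brute-force oracles on exhaustive small
instances.  Noise-model convergence is tested at 10⁴ replicates.

## Known limitations

- The Hill fit's convergence flag is conservative: under the strict 1.01
  R-hat threshold a substantial minority of routine fits are flagged even
  though their posterior summaries are accurate and reproducible.
- The linear route ignores the shared control-scale error (its purpose is
  robustness, not calibrated intervals); its CIs can be wide or slightly
  optimistic depending on curvature.
- Cross-plate effects (edge wells, drift within a run) are out of scope;
  normalization assumes controls are exchangeable with test wells on the
  same plate.
- Dilutions are restricted to exact 2-fold series by the design container;
  irregular series would need relaxation of that validation.
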