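# Methods

## The stress index and its response curves

The waterlogging stress response index of plant parameter *P* at treatment
duration *d* (days of surface ponding) is the treatment mean normalised by
the unstressed control mean:

    WSRI_P(d) = mean(P | d) / mean(P | 0)

It is computed from treatment means, not per-replicate ratios; replicate
dispersion is exposed separately as the per-cell standard deviation for
optional inverse-variance weighting. The index at *d* = 0 is mean/mean of
the identical cell and therefore exactly 1 in floating point. Indices above
1 are allowed and meaningful: flavonoid and anthocyanin indices and NPQ
rise under waterlogging. Negative indices (possible only from negative raw
measurements) are retained with a warning. Missing cells stay missing —
nothing is imputed.

Each parameter's WSRI-vs-duration relation is summarised by one of three
families, chosen to match the published curve shapes:

| family | form | arity | used for |
|---|---|---|---|
| linear | slope·x + intercept | 2 | 15 parameters (roots, pigments, gas exchange) |
| quadratic | a·x² + b·x + c | 3 | 6 parameters (height, stem, leaves, root counts) |
| exp_decay | a·e^{b·x}, a>0, b<0 | 2 | 5 parameters (leaf area, dry weights) |

## The packaged registry and coefficient disambiguation

The registry ships the 26 published coefficient sets verbatim. The
published linear rows do not consistently follow the stated y = ax + b
orientation (e.g. photosynthesis prints (1.2, −0.051), which as
slope = 1.2 would have the index explode). The loader resolves each linear
row by scoring both orientations and keeping the one whose intercept is
nearest 1, ties going to the printed order. Outcomes are recorded as flags,
never as silent edits:

- `column_swapped` — the printed order was (intercept, slope); 11 of 15
  linear rows.
- `direction_conflict` — the resolved slope sign contradicts the narrative
  trend (chlorophyll and the nitrogen balance index print positive slopes
  although their indices are described as declining). Coefficients are kept
  as printed; `ResponseCurve.with_direction_corrected()` negates the slope
  on request.
- `intercept_anomaly` — |y(0) − 1| > 0.5 after disambiguation. Only NPQ
  trips this: its printed pair (0.051, 0.052) gives y(0) ≈ 0.05 either way,
  plausibly a typo for an intercept near 1.05, but unverifiable, so it is
  stored as printed.

Durations are real-valued to support daily simulation. The default
evaluation mode is `raw` (preserves the fits); `clamp_nonneg` floors at 0
for use as a physical mean, and `clamp01` additionally caps at 1 for use as
a stress factor.

## Fitting

`DurationResponseModel.fit()` estimates coefficients by least squares:
linear and quadratic families in closed form via the normal equations
(`numpy.linalg.lstsq` on the Vandermonde design), exponential decay by
Levenberg–Marquardt (`scipy.optimize.least_squares`) started from a
log-linear regression of log(index) on duration over points with index
> 1e−9 (fallback: amplitude from the maximum index, rate from the
first/last positive pair). Tolerances are 1e−10 on coefficients and cost;
hitting the iteration cap reports `converged=False` rather than raising.
Standard errors come from the usual asymptotic covariance
s²(JᵀJ)⁻¹. Fits are unweighted by default because the emulated experiment
reports no dispersion; inverse-variance weights are accepted.

Model selection fits all three families and keeps the highest R², except
that a family with fewer coefficients wins when its R² is within 0.01 of
the best (ties at equal arity prefer linear). The margin stops the
quadratic from always edging out the line it nests. The published R²
values depend on unpublished raw means and are carried as provenance only,
never asserted.

## Soil oxygen

Ambient soil oxygen is 20.9%. Under the default linear shape, ponded-soil
oxygen falls as `max(0, 20.9·(1 − t/t_depletion))` with t_depletion = 5 d,
matching the observation that sensors first read zero five days after
ponding; after release it returns linearly to ambient over t_recovery = 2 d
(the observed range was one to two days; the default takes the
conservative end). An exponential shape is provided for soils where the
drawdown decelerates; its rate is calibrated so oxygen passes within 1% of
ambient above the anoxia threshold at t_depletion. The published figure's
fitted oxygen curve prints no coefficients, which is why shape and time
constants are configuration, not constants.

Anoxic days are counted over left-closed day bins [t, t+1) evaluated at the
bin start, during treatment only. For the linear shape with threshold 0
this equals max(0, duration − t_depletion): the 2- and 4-day treatments
never go anoxic, the 14-day treatment accumulates 9 anoxic days, and a
quadratic fitted to the eight design counts reproduces them with R² = 0.99.

## Phenology

The packaged squaring observations are: control and 2-day treatments
square 25 days after emergence; 4 and 6 days of ponding delay squaring by
2 and 4 days; the 8–14-day treatments had not squared when observation
ended at 30 days and are censored. Censored treatments are excluded from
fitting, never imputed. The default quadratic fit to the four uncensored
points is exactly (0.125, −0.05, 24.9); it predicts 24.9 d (rounds to 25)
for the control and 36.9 d (rounds to 37) at 10 days of ponding. Published
extrapolations for the censored treatments (32/37/43/50 d) came from an
unstated function and cannot all be reproduced by any family fitted to the
four printed points (the quadratic gives 42.3 rather than 43 at 12 d);
they are documentation, not targets. Rounding of predicted days is
half-away-from-zero. A pedantic note on monotonicity: the fitted quadratic
has its vertex at x = 0.2 d, so it dips 0.005 d below the intercept before
rising; at daily resolution predictions never move earlier under more
stress.

## Synthetic experiment generator

The generator emulates the pot-experiment design: durations
{0, 2, …, 14} days, five replicates, 26 parameters. Cell means are
`control_mean × curve(d)` floored at zero; replicate values are independent
Normal(μ, cv·μ) draws floored at zero, a constant coefficient of variation
of 0.05 by default. The dispersion is a convention — the emulated
experiment reports none — chosen small enough that the zero floor is never
hit at the defaults (all means sit far above 5 sd), keeping the noise model
effectively unbiased. Only the control mainstem leaf count (9.4) is a
published value; every other control mean is a synthetic placeholder of
plausible magnitude, marked as such in the source and in generated-file
headers. Replicates are independent: no pot or block random effect is
modelled. Consequently, passing recovery tests demonstrate the correctness
of the pipeline arithmetic, not robustness to real replicate structure,
outliers or heteroscedasticity beyond the constant-CV form.

One consequence of the index definition is worth stating: a table generated
from a curve with y(0) ≠ 1 yields WSRI values renormalised by 1/y(0), so
the full generate → index → refit round trip recovers each packaged curve
up to that scale factor (exactly, except root crossings, whose quadratic
goes slightly negative at 14 d and is clamped). Direct WSRI-space
generation (`generate_wsri_points`) has no renormalisation and recovers the
packaged coefficients to 1e−6 (closed-form families) / 1e−4 (exponential).

## Growth simulator

A deliberately minimal demonstrator of the coupling route into a crop
model: daily potential biomass increments are multiplied by the
photosynthesis stress factor, the response curve evaluated with `clamp01`
at the elapsed waterlogging duration. Organ partitioning is untouched
because relative organ responses were observed to be similar, so the
carbon-supply route suffices. Post-release recovery of the plant (as
opposed to the soil) is unquantified; the default holds the
end-of-treatment factor, with an optional linear relaxation back to 1 over
a chosen number of days. An option drives stress by the accumulated
anoxic-day count from the oxygen module instead of elapsed ponding days,
which delays stress onset by the depletion lag. When several parameter
curves could apply simultaneously (photosynthesis, conductance, leaf
area), only the single-factor route is implemented — how such factors
should combine is not established.

## Numerical conventions and problem sizes

All analyses in the tests and the acceptance script run at the design
scale the package emulates: 8 durations × 5 replicates × 26 parameters
(1040 records), 200 Monte-Carlo repetitions for the noisy-recovery
coverage check (recovered slope within 3 standard errors of truth in at
least 95% of repetitions), and 500-replicate cells for the
law-of-large-numbers check. Every stochastic path takes an explicit seed
through `numpy.random.default_rng`; identical seeds give identical tables.

## Known limitations

- Absolute control means (except the leaf count) and replicate variances
  are conventions; conclusions about real-data dispersion do not follow.
- The oxygen model is a calibrated phenomenological shape, not a
  diffusion/respiration model; soil-texture effects are out of scope.
- Published raw-mean percentage declines (75% photosynthesis, 88% leaf
  area, and similar) derive from unpublished raw means and are not
  reproducible from the fitted curves; `percent_change` reports the
  curve-based figure (e.g. 55.9% for plant height at 14 d), which can
  legitimately differ.
- The simulator is a concept demonstrator: no temperature or radiation
  drivers, no organ partitioning, no yield.
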