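# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
surveys do and do not establish about real monitoring data.

## Trait assignment

Traits are binary *potentials* per taxon: N-fixation, mixotrophy,
motility, buoyancy, harmfulness. Records identified above species level
are treated as potential carriers of a trait if one or more member species
carry it (a logical OR over member species present in the table). The OR
rule can be overridden per trait by data-level entries in the table's
`override_note` column; the shipped fixture pre-populates the overrides
that matter for Baltic summer communities (*Snowella* not buoyant,
*Amphidinium* not harmful, *Anabaena* and *Aphanizomenon* harmful, the
order Prymnesiales harmful). Order-level and other records without
enumerable members in the table resolve to their stored flags, so
order-level decisions are expressed as stored values, not member scans.
Taxa absent from the table fail loudly; defaulting to all-false would
silently bias every share downward for the traits the taxon carries.

Harmfulness is split by lineage into harmful cyanobacteria, harmful
eukaryotes, and non-harmful taxa — an exhaustive, mutually exclusive
three-way partition.

## Filtering and biomass

Exclusion is driven entirely by the trait table's `excluded_category`
column (heterotrophs, akinetes, heterocytes, cysts, mainly
benthic/littoral taxa, single-celled picoplankton, *Synechococcus*); no
name-pattern heuristics are applied, which keeps filtering reproducible
from the data files alone. Biovolume converts to wet-weight biomass at
1 g cm⁻³, i.e. 10⁻⁶ µg per µm³ — the standard convention for
microscopy-derived biovolumes; the factor is a function argument for other
conventions. Samples whose post-filter total biomass is zero are dropped
with a warning, since shares are undefined there.

## Morphometrics

A counting unit is `small` when its maximum morphometric dimension is
≤ 10 µm (boundary inclusive) and `large` otherwise; the unit, not the
cell, is classified, so a colony of small cells is large. When a counting
result lacks cells-per-unit, the value is filled from an optional
per-taxon defaults table — the single fallback — and otherwise the row is
rejected by name rather than guessed. The ESD of a
cell of biovolume V µm³ is (6V/π)^(1/3); per-cell biovolume is the unit
biovolume divided by cells per unit. Sample aveESD is the
cell-density-weighted mean ESD. Records with cells but zero biovolume
contribute zero to the numerator; whether their cells count in the
denominator is a flag (`include_zero_biovolume`, default true, warning
logged), since the right answer depends on why the biovolume is missing.

## Hydrography

Surface-layer means of temperature, salinity and TP are unweighted means
over measurements at 0–10 m; stations shallower than 10 m contribute their
entire water column. Density is the one-atmosphere EOS-80 polynomial
(UNESCO 1983) — appropriate for coastal surface waters, with published
check values (999.96675 kg m⁻³ at 5 °C/0 psu, 1027.67547 at 5 °C/35 psu)
asserted to five decimals in the tests; the pressure term is omitted. The
stratification index is

    E = (σ_bottom − σ_surface) × 1000 / depth_deepest

where the bottom value is the deepest joint T/S measurement (nominally 1 m
above the bottom) and `depth_deepest` is that measurement's depth, not the
charted bottom depth. The ×1000 scaling is kept exactly as conventionally
printed and the unit is carried opaquely. E may be negative for an
unstable column.

Water bodies are typed by the dominant source (argmax of shares) of their
N and P loads; only five combinations are meaningful (N & P offshore;
N river & P point; N river & P offshore; N & P river; N river &
P sediment). Ties and unmapped combinations raise errors rather than
guessing — the typology presupposes clear dominance.

## Responses and transformation

The 27 response variables are biomass and share for carriers and
non-carriers of N-fixation, buoyancy, motility and mixotrophy (the
non-mixotrophic complement is labelled autotrophic, AU), small/large
biomass and share, aveESD, and the three-way harmfulness partition.
Complementary pairs sum to the sample total by construction.

All responses are Box–Cox transformed before modelling. λ is estimated per
response on the pooled data by profile likelihood over the grid [−2, 2] in
steps of 0.01 (one transform per response, then one model).
Zero-containing responses are shifted by half their smallest positive
value first — a standard positivity fix, recorded per response in the
transform metadata. |λ| < 10⁻⁸ uses the logarithm branch for numerical
stability. A toggle to skip transformation for individual responses is
deliberately not provided; transforming all responses keeps the model
family uniform.

## The additive mixed model

Each smooth is a cubic regression spline in the value-at-knot
parameterisation with the integrated squared second derivative penalty,
knots at covariate quantiles, basis dimension k = 6 (small k suits ~900
samples with five smooths; the penalty does the rest), and a sum-to-zero
centering constraint absorbed by a null-space reparameterisation (k − 1
free columns per smooth). Sea area and loading type are fixed factors
(treatment coding); water-body and station intercepts are ridge-penalized
coefficient blocks, which is exactly the mixed-model view of penalized
smoothing. An area-level random intercept alongside the fixed area factor
is deliberately not included (it would be confounded with the factor).

Smoothing parameters and random-intercept precisions are estimated by
restricted marginal likelihood with σ² profiled out; the criterion
includes log|V| for the residual covariance structure, so all structural
parameters are compared on the same REML scale. The residual structure —
continuous-time AR(1) within station with decay φ^|Δt| (Δt in days) and
one variance multiplier per sea area — is estimated in an outer loop:
quasi-Newton REML for the log smoothing parameters, a bounded line search
on φ against the same REML criterion, and a moment update of the area
multipliers from correlation-whitened residuals, iterated until the
relative change in all structural parameters falls below 10⁻⁶ (cap 200
iterations). Non-convergence sets a flag and is never silently ignored;
non-converged fits are excluded from effect-direction classification.
φ is restricted to [0, 0.99): a continuous-time decay φ^|Δt| with
non-integer gaps is only real-valued for non-negative φ, matching the
usual continuous-AR(1) convention. Coincident sampling times within a
station would make a correlation block singular; a small nugget is added
only in that degenerate case.

### Inference

The coefficient covariance is the Bayesian posterior σ²(XᵀV⁻¹X + S_λ)⁻¹.
Naive Wald tests on penalized smooths are anti-conservative, so
smooth-term p-values use a fractional-rank statistic: the fitted smooth at
the observed covariate values, tested with a pseudo-inverse of its
covariance whose rank is the term's alternative EDF (2·tr F − tr F², F the
influence block), the trailing eigendirection downweighted by the
fractional part, referred to an F distribution on (rank, residual df).
Calibration is verified by simulation in the acceptance suite (empirical
type-I error ≈ 0.06–0.07 at nominal 0.05 over 500 null fits). Factor
terms use a joint Wald F-test. Following the analysis convention for
large families of models, only p < 0.001 is reported as significant.

Significant smooths are classified `positive` / `negative` when the
fitted curve is monotone over the inner 95% of the observed covariate
range (terms with EDF ≤ 1.5 are effectively straight lines and always
receive a direction), and `nonlinear` when non-monotone (unimodal and
more complex shapes). The monotonicity criterion — rather than an EDF
cutoff alone — is what separates directional from unimodal effects: a
monotone but mildly curved response is still a directional effect. The
inner-95% window keeps boundary wiggle on sparse support from masking a
clear trend.

Marginal means per sea area are model predictions at reference covariates
(smooth covariates at their observed means, balanced weights over loading
type, random intercepts at zero). All pairwise contrasts are adjusted with
the studentized-range distribution on |t|·√2 with residual degrees of
freedom n − total EDF; this reproduces classical Tukey HSD exactly on
balanced one-way layouts (verified to 10⁻⁶ against a direct
studentized-range computation) and reduces to the unadjusted two-sided
t-test for two levels.

## The synthetic survey generator

The generator emulates the survey's design: 4 sea areas, 11 water bodies
per area (44 total), 2 stations per water body, 912 samples by default,
visit dates drawn uniformly in the 1 July – 15 September window over
2009–2020 with at most one visit per station-day. Per-area environmental
distributions mirror the reported gradients: AS warmest (mean 17 °C) and
most saline (6 psu), eGF freshest (2.8 psu), clearest (Secchi 3.5 m) and
most strongly stratified, wGF most variable with the highest TP
(log-normal, median ≈ 27 µg L⁻¹), BS cool and clear. Depth profiles carry
0/5/10 m surface measurements plus a bottom measurement 1 m above the
bottom, with colder, saltier bottom water so the implied stratification
index is predominantly positive; the per-sample covariates used for
effect injection are computed *through the hydrography module*, so the
generator and the pipeline cannot drift apart.

Trait flags are drawn per taxon with prevalences (N-fixation 0.10,
buoyancy 0.15, mixotrophy 0.25, motility 0.35, harmfulness 0.15) under
consistency rules: N-fixers and buoyant taxa are cyanobacteria;
cyanobacteria are neither mixotrophic nor motile here. One taxon per
exclusion category is always present so the filters are exercised, and at
least one carrier of every trait, harmfulness class and size class is
guaranteed so that no response variable is identically zero.

Communities are generated at taxon level and aggregated by the real
pipeline. Each taxon's log biomass is a linear function of the
standardized covariates through the traits it carries (defaults mirror
the qualitative pattern of the study: temperature +0.8 on N-fixers, +0.7
on buoyant taxa, −0.6 on mixotrophs and motile taxa; transparency −0.5
on everything and an extra −0.5 on harmful taxa; TP +0.6 on large units
and −0.5 on mixotrophs; salinity and stratification null), plus
water-body (SD 0.30) and station (SD 0.20) intercepts, a sample-level
CAR(1) component shared across taxa (φ = 0.4 per day, SD 0.25),
area-scaled residual noise (SD 0.40 × multipliers 1.0/1.2/1.5/0.8), and
per-taxon microscale noise (SD 0.15). Occupancy 0.85 introduces
presence/absence sparsity. All randomness flows from one seed through
named child generators, so every artefact is bitwise reproducible.

### What the generator does not emulate

Real counting data have far more taxa (~700), shape-specific biovolume
geometry, detection limits, counting error that scales with rarity,
drifting community composition across years, and environmental
confounding between covariates. Passing the recovery experiments
demonstrates that the pipeline's estimators recover the structure they
assume — it does not validate the ecological conclusions of any real-data
analysis, and the model's p-values inherit the usual caveats of
REML-based smooth tests near the significance boundary.

## Experiment sizes

The validation experiments are sized to give stable answers at desk
scale: 500 null fits (n = 120, one smooth) for type-I calibration; 200
replicates for power of a standardized slope 1 (n = 300) and for the
station-SD recovery median (40 stations × 10); 120 replicates for CAR(1)
φ recovery (40 stations × 12 regular dates, φ = 0.6); one 912-sample
default survey with ten injected |effect| ≥ 0.5 trait-covariate pairs for
sign recovery, with the same fits supplying 16 null-covariate term tests
for specificity. Medians are used for the recovery summaries because the
REML variance estimates are right-skewed at these sizes.

## Known limitations

- The spline basis clamps at the training-data knot range, so prediction
  outside the observed covariate range is flat, not linearly extrapolated.
- Variance multipliers are moment updates inside the REML loop, not full
  REML estimates; with few stations per area they are noisy, and they are
  clipped to [10⁻³, 10³].
- The AR(1) parameter is shared across the whole dataset rather than
  varying by area or station.
- Smooth-term p-values are approximate; their calibration was verified at
  the simulation sizes above, not asymptotically.
- The loading-source typology rejects ties and unmapped dominant-source
  pairs by design; surveys whose water bodies fall outside the five types
  need an extended map.
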