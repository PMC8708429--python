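# phytotraits

Trait-based analysis of summer phytoplankton monitoring data from coastal
sea areas, built as a tested, reusable pipeline.

Phytoplankton communities can be described not only by their taxonomy but
by the morpho-functional traits their members carry — the potential for
atmospheric N₂ fixation, mixotrophy, motility, buoyancy, harmfulness, and
cell size. Summed over a counted community, each trait yields a biomass
(µg L⁻¹ wet weight) and a share of total biomass; community cell size is
additionally summarized by the cell-count-weighted average Equivalent
Spherical Diameter. These 27 response variables can then be related to
environmental gradients — surface temperature, salinity, water transparency
(Secchi depth), total phosphorus, density stratification, and the dominant
nutrient-loading source of the water body — with a penalized-spline
additive mixed model that respects the survey design (stations nested in
water bodies nested in sea areas, repeated summer visits).

The package is aimed at aquatic ecologists working with HELCOM-style
community counting data who want trait aggregation, the supporting
hydrographic covariates, and the mixed-model inference in one place, with
a synthetic-survey generator for validating every stage against known
ground truth.

## The model

For each Box–Cox-transformed response y and sample i,

    y_i = β₀ + L(i) + Area(i) + Σ_c s_c(x_ci) + b_wb(i) + b_st(i) + ε_i

where the s_c are penalized cubic regression splines over the five
continuous covariates (Temp, Sal, Secchi, E, TP), L is the five-level
loading-source type, Area the sea-area factor, b_wb and b_st nested random
intercepts, and the residuals follow a continuous-time AR(1) process
within station, corr(ε_i, ε_j) = φ^|t_i − t_j|, with one variance
multiplier per sea area. Smoothing parameters and variance components are
estimated by REML. Per-term tests use fractional-rank Wald statistics on
the fitted smooths; sea-area contrasts use estimated marginal means with
studentized-range (Tukey) adjustment, and a term is reported significant
only below α = 0.001.

The stratification index is E = (σ_bottom − σ_surface) × 1000 / depth,
with one-atmosphere seawater density σ from the EOS-80 polynomial, and the
ESD of a cell of biovolume V is (6V/π)^(1/3).

## Worked example

```python
from phytotraits import gamm, pipeline
from phytotraits.synthetic_data import SimulationConfig, simulate_survey

bundle = simulate_survey(SimulationConfig(seed=42, n_samples=912))
result = pipeline.prepare_bundle(bundle)
print(result.response_matrix.shape)

fits = pipeline.fit_all(result, which=["Nfix biom", "MX biom"])
fit = fits["Nfix biom"]
for term in ("Temp", "Sal", "Secchi", "E", "TP"):
    print(term, round(gamm.term_pvalue(fit, term), 4),
          gamm.classify_effect_direction(fit, term))
```

prints

```
(912, 27)
Temp 0.0 positive
Sal 0.3858 ns
Secchi 0.0 negative
E 0.3638 ns
TP 0.0 positive
```

i.e. the response matrix holds 27 trait variables for all 912 samples, and
for the N-fixer biomass the model recovers the warming benefit injected by
the generator (significant positive temperature effect) and the negative
transparency relation, correctly reports the two null covariates
(salinity, stratification) as non-significant at α = 0.001, and picks up
the positive TP effect that N-fixing filaments inherit through their large
counting units.

Pairwise regional contrasts:

```python
emm = gamm.estimated_marginal_means(fit, "Area")
for c in gamm.tukey_pairwise(emm):
    print(c.level_a, c.level_b, round(c.p_adjusted, 3))
```

```
AS BS 0.977
AS eGF 0.811
AS wGF 0.828
BS eGF 0.546
BS wGF 0.588
eGF wGF 0.998
```

(no regional differences beyond the environmental gradients for this
response, as the generator injects none).

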