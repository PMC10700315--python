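# dungbef

Analysis pipeline for a worldwide paired grazing experiment: how does
cattle-farming intensification affect dung-beetle communities and the dung
removal they provide?

The design: in each of 38 landscapes, one pasture under low-intensity
management (< 2 animals/ha) is paired with one under high-intensity
management (> 4 animals/ha). At every pasture, ten 300-g experimental
dung pats (plus five mesh-covered controls that measure evaporation) are
exposed for 48 h, the dung-beetle community is trapped and measured, and
management covariates and 13 bioclimatic variables are recorded. The
package implements every analysis stage as a tested library, plus a
synthetic-data generator that reproduces the whole design with known
ground truth, so each estimator has a recovery test without any downloads.

## What it computes

**Dung removal rate (DRR).** With `WP = (FWwet − FWdry)/FWwet` the water
proportion, `IWdry = IWwet·(1 − WP)` the estimated initial dry mass, and
`DRR = IWdry − FWdry` the grams of dry dung removed in 48 h. `WP` comes
either from each pat's own final weights or (default) from the
beetle-proof control pats.

**Community descriptors.** Abundance, species richness, Pielou evenness,
and two functional-dispersion indices computed as mean pairwise distances
among the species present: *FDisMorphology* in a z-scored space of nine
morphological traits + log biomass (Euclidean), and *FDisBehavior* on a
fixed behavioral tree whose root splits kleptocoprids/endocoprids from
paracoprids/telecoprids, with the four guilds below and three body-size
classes (small < 10 mm, medium 10–18 mm, large > 18 mm) as the 12 tips.

**Effect sizes and meta-regression.** Per landscape, Hedges'
g = J·(x̄_low − x̄_high)/s_pooled with J = 1 − 3/(4(n₁+n₂−2)−1), pooled
with the random-effects model `g_i = Xβ + u_i + e_i`,
`u ~ N(0, T²R(ρ))`, `e_i ~ N(0, v_i)`, where `R` is one of five
between-site correlation structures (independent, exponential, Gaussian,
rational quadratic, spherical) over great-circle distances, selected by
AICc. (T², ρ) are estimated by REML, β by GLS; coefficient tests use
Knapp–Hartung-scaled variances with t(n − m − 1) references, moderators
jointly with F(m, n − m − 1). Heterogeneity is summarized by Cochran's
Q, T², and I² = T²/(T² + s̃²). Moderators are first-axis PCA scores of
the 13 climate variables and of the paired low-minus-high diversity
differences, plus the cattle-density difference.

**Piecewise SEM.** The between-site causal hypothesis is a DAG fitted as
separate linear mixed models with a biogeographical-region random
intercept. Shipley's d-separation basis set (one claim per non-adjacent
pair, conditioning on both parents' sets, correlated-error pairs
excluded) yields Fisher's C = −2Σln pᵢ ~ χ²(2k): a model-wide p > 0.05
means the data do not contradict the hypothesized paths.

## Worked example

`examples/` holds one short script per capability. The full pipeline on
a synthetic study (`python examples/05_full_pipeline.py`) prints:

```
stages completed: data -> removal -> diversity -> pca -> meta -> sem

climate PCA axis 1: 56.0% of variance; diversity-difference PCA axis 1: 45.6%
pooled Hedges' g = +0.128 (t = 0.59, p = 0.559), structure = none
T^2 = 1.48, Q = 239.9 (df 37), I^2 = 0.869
meta-regression: F(3,34) = 1.44, p = 0.249, pseudo-R^2 = 0.034
piecewise SEM: Fisher's C = 44.1 (df 22, p = 0.0034)
```

Read: the two regimes do not differ overall (pooled g ≈ 0), but ~87% of
the effect-size variance lies between landscapes (I²), which is what the
moderators and the SEM then dissect. The meta-regression example
(`examples/03_effect_sizes_and_meta.py`, 150 simulated landscapes with a
built-in diversity slope of 0.4) prints:

```
          term  estimate    se     t  df     p  vif
     intercept     0.029 0.131 0.223 148 0.824  NaN
diversity_diff     0.420 0.142 2.968 148 0.004  1.0
```

i.e. the true moderator effect is recovered (0.42 ± 0.14).

The same stages run from the shell on CSV inputs:

```bash
dungbef simulate --seed 1 --out data/          # or bring your own tables
dungbef run --input data/ --out results/
```

## Layout

- `src/dungbef/data_model.py` — CSV schemas, validation, guild aliases
- `src/dungbef/dung_removal.py` — removal rates with evaporation correction
- `src/dungbef/community_diversity.py` — richness/evenness, FDis indices, behavioral tree
- `src/dungbef/covariate_pca.py` — climate and diversity-difference PCAs
- `src/dungbef/effect_meta.py` — Hedges' g, spatial REML meta-regression, Wilcoxon
- `src/dungbef/piecewise_sem.py` — mixed-model path analysis, d-separation, Fisher's C
- `src/dungbef/synthetic_data.py` — study generator with ground truth, recovery experiments
- `src/dungbef/pipeline.py`, `cli.py` — orchestration and the thin `dungbef` command
- `docs/methods.md` — modelling assumptions, defaults, numerical choices, limitations
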