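# Methods

## Removal rates and the evaporation correction

Removal is computed on the dry-mass scale. A pat's water proportion
`WP = (FWwet − FWdry)/FWwet` converts the known initial wet weight into
an estimated initial dry mass, `IWdry = IWwet(1 − WP)`, and
`DRR = IWdry − FWdry` is the dry mass removed over the 48-h exposure.
The printed equations use only the experimental pat's own final weights,
yet the design includes mesh-covered control pats whose stated purpose is
to measure evaporation. Both readings are implemented behind
`site_removal(mode=...)`: `"unit"` applies each pat's own water
proportion; `"control"` (default) uses the mean water proportion of that
pasture's control pats. They coincide exactly when all pats share one
water proportion, and the package treats that as a tested invariant.

Negative rates (apparent mass gain, e.g. rain-soaked pats) are retained
and flagged by default; `clamp_negative=True` truncates them at zero.
Site summaries use the arithmetic mean and the n−1 sample SD because the
downstream Hedges'-g estimator is defined on those.

A consequence of the control-based correction worth knowing: the control
pats estimate the water proportion with error, and that error propagates
into every experimental pat's removal rate as extra within-site noise.
Standardized effect sizes therefore attenuate slightly relative to the
generating model under `"control"` mode, while `"unit"` mode inverts the
synthetic generator exactly. The acceptance script reports the
end-to-end slope recovery under both modes to make this visible.

## Functional diversity

Both dispersion indices are the unweighted mean pairwise distance between
the species present at a pasture (an abundance-weighted variant is
available). Species trait profiles are per-trait means over up to ten
measured individuals, skipping missing values individual-wise; body
length is head + pronotum + elytra length.

*FDisMorphology* uses nine linear traits plus dry biomass. Biomass is
log-transformed (it spans orders of magnitude against mm-scale traits)
and every column is z-scored before Euclidean distances. The
standardization pool is the joint species set of a landscape's two
pastures, so the low- and high-intensity values of one pair live in the
same trait space and their difference is meaningful. Zero-variance
columns are dropped with a warning rather than producing NaNs.

*FDisBehavior* places each species on one of 12 functional-group tips of
a fixed phenetic tree: the root separates the kleptocoprid/endocoprid
behaviors from paracoprid/telecoprid, the next level holds the four
guilds, and each guild carries its three body-size classes. Size classes
use thresholds >18 mm (large), <10 mm (small), with the boundary values
10.0 and 18.0 mm assigned to medium, since only the medium range is
printed inclusively. All edges default to unit length, making cophenetic
distances 2 (same guild), 4 (same root clade) or 6 (across the root) —
so the index is bounded by 6 and equals 0 for single-group communities.
Body length enters through the size-class tip assignment; a
continuous-body-length variant is deliberately not implemented.

Evenness is Pielou's J = H′/ln(richness), undefined (NaN) for fewer than
two species. The evenness formula is an assumption: the source analysis
names evenness without a formula.

## PCA summaries

Both moderator PCAs run on the correlation matrix (variables z-scored),
because climate variables carry heterogeneous units and loadings are
reported as variable–axis correlations. Only axis 1 is used. Eigenvector
sign is arbitrary, so each axis is anchored: the climate axis so that the
first bioclim column (mean-annual-temperature analogue) loads negatively,
the diversity axis so that the FDisBehavior difference loads positively —
positive diversity scores then mean higher diversity under low-intensity
management. Climate observations are the 38 landscapes (the pair shares
its climate), and the diversity PCA runs on the paired low-minus-high
differences of abundance, richness, and the two FDis indices.

## Effect sizes and the spatial random-effects model

Hedges' g uses the pooled (n−1-weighted) SD, the small-sample correction
J = 1 − 3/(4(n₁+n₂−2)−1), and the variance
J²[(n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂−2))]. Positive g means more removal
under low-intensity management.

The pooling model is marginal: `y = Xβ + u + e` with `u ~ N(0, T²R(ρ))`
and independent `e_i ~ N(0, v_i)` at the known sampling variances.
`R(ρ)` is exponential `exp(−d/ρ)`, Gaussian `exp(−(d/ρ)²)`, rational
quadratic `1/(1+(d/ρ)²)`, or spherical `1 − 1.5(d/ρ) + 0.5(d/ρ)³` (0
beyond ρ), over haversine distances (Earth radius 6371 km). (T², ρ) are
REML estimates — T² profiled in closed form for the independent
structure, (log T², log ρ) by Nelder–Mead with three ρ starts otherwise —
and β is GLS at the optimum. REML was chosen over moment estimators
because the spatial structures require likelihood-based fitting and AICc
comparison; AICc = −2ℓ_R + 2k + 2k(k+1)/(n−k−1) with k counting variance
/correlation parameters plus one.

Small-sample inference follows the Knapp–Hartung approach: the GLS
coefficient covariance is scaled by the residual quadratic form over its
degrees of freedom, with t(n − m − 1) references per coefficient and
F(m, n − m − 1) for the joint moderator test. Seeded simulation under
the study design (n = 38, 10 + 10 replicates) puts the moderator t-test's
type-I rate at ~5% and 95%-interval coverage at ~95%; without the
scaling, rejection rates run visibly hot. Q, I² (via the typical
within-study variance s̃²) and pseudo-R² (intercept-only T² minus
residual T², floored at zero — sampling noise can push it negative) are
computed as standard. Moderator collinearity is screened through the
condition number of the moderator correlation matrix (threshold 10⁶),
with VIFs from its inverse diagonal. Anthelmintic use is not offered as
a default moderator because it is collinear with cattle density by
design.

The paired low-vs-high comparisons of individual variables use two-tailed
Wilcoxon signed-rank tests: zero differences dropped, exact null for up
to 25 tie-free differences, normal approximation with continuity
correction otherwise.

## Piecewise SEM

Component regressions are linear mixed models with a region random
intercept, fitted by REML (statsmodels MixedLM); a fit whose random
variance collapses (or fails to converge at the boundary) falls back to
OLS, noted per response. Fixed-effect tests use residual degrees of
freedom n − p − 1. This is an approximation: with few groups and
predictors that themselves carry group-level variance it is mildly
liberal (per-claim type-I up to ~8% with 6 groups in simulation, ~5%
with 12). Satterthwaite-style df would remove this and are not
implemented; calibration results below are reported at 12 groups.

The d-separation basis set contains one claim per non-adjacent pair,
conditioning on the union of both nodes' parents, with the pair member
later in (name-tie-broken) topological order as the tested response.
Pairs declared as correlated errors (`a ~~ b` in the model block) are
excluded — the correlation is acknowledged without a causal reading, and
no joint covariance is estimated. Fisher's C = −2Σln pᵢ is compared to
χ²(2k); an empty basis set yields C = 0, df = 0, p = 1. When the global
p ≤ 0.05 the most significant violated claim is *reported* as a suggested
path; nothing is ever added automatically, since path additions are a
biological judgment.

Marginal and conditional r² follow the Nakagawa–Schielzeth variance
decomposition. Standardized coefficients are β·sd(x)/sd(y) over the
analysis sample, with the binary management regime coded 0/1.

The shipped path model is a *reconstruction*: management → {cattle
density, anthelmintic use}; management, cattle density, anthelmintic use,
climate → the four community descriptors; the descriptors and climate →
dung removal; richness → FDisBehavior; FDisBehavior ~~ FDisMorphology;
land history excluded. It can be swapped for any plain-text model block
(`cause -> effect`, `a ~~ b`). In the pipeline's SEM table, cattle
density enters as log10 and abundance as log1p to tame their skew.

## The synthetic generator

`SyntheticConfig` defaults encode the study conditions: 38 landscapes in
6 regions (stratified across a −42°…52° latitude range, pastures of a
pair ~7 km apart), 10 experimental + 5 control 300-g pats per pasture,
regional pools of 60 species with guild probabilities (0.45, 0.20, 0.25,
0.10) for paracoprids, telecoprids, endocoprids, kleptocoprids, and
log-normal body-size factors (median 12 mm) from which the nine traits
and biomass follow allometrically with species- and individual-level
jitter. Low-intensity richness is Poisson (mean 15, increased toward
warmer landscapes); the high-intensity community is a binomial thinning
(retention 0.75, abundance thinning 0.8) of its pair — which reproduces
the observed richness advantage of low-intensity pastures while keeping
species overlap realistic.

The true effect model lives on the effect-size scale:
`g_i = γ₀ + γ₁·z(ΔFDisBehavior_i) + τ·ε_i` with defaults γ₀ = 0,
γ₁ = 0.4 and τ = 1.4, so the between-site variance (≈ γ₁² + τ² ≈ 2.1)
sits at the scale the field study reports. Pat weights are back-computed
from intended dry-mass removal with a site-level water proportion in
[0.70, 0.85] and per-pat jitter (SD 0.01), so the removal equations
invert the generator exactly in unit mode. One independent random stream
per table (all spawned from the master seed) keeps tables stable when
others are added; bundles are byte-deterministic per seed.

What the generator does *not* emulate: real species pools or Worldclim
fields (climate is a two-latent-factor construction), within-site spatial
structure of pats, temporal removal kinetics, or a spatial correlation in
the site effects (τ is iid by default, so structure selection on
generated studies typically — and correctly — picks the independent
structure; spatially correlated effect sizes are available through
`simulate_effect_sizes(structure=...)`). Passing recovery tests
therefore validate the estimators under the declared statistical
structure, not the full ecology of field data.

## Problem sizes and numerical choices

The packaged test and acceptance runs use: 500 replicates for the
meta-regression type-I and slope-recovery calibrations and 100 for the
null-T² check (each replicate a fresh 38-site study at the effect level);
100 datasets of 12 regions × 12 observations for the SEM global-test
calibration; 30 full generator-to-meta-regression pipelines per
water-proportion mode for end-to-end recovery; and a REML-vs-grid-search
agreement tolerance of 1e-4 on T². The slope-recovery check uses the
95% Monte-Carlo confidence interval of the replicate mean, because
inverse-variance weighting of standardized mean differences carries a
small intrinsic bias (sampling variances depend on the effect magnitude)
that any fixed band tighter than the Monte-Carlo error would eventually
flag. T² optimization is bounded at zero and snaps to the boundary when
the profile favors it; ρ is optimized on the log scale for positivity.

## Known limitations

- Residual-df t-tests in the SEM are liberal with few groups (above).
- The control-based evaporation correction attenuates standardized
  effects (above); analyses mixing both WP modes are not comparable.
- Exact Wilcoxon p-values require tie-free absolute differences; ties
  switch to the corrected normal approximation regardless of n.
- The spatial meta-analysis estimates a single range parameter ρ jointly
  with T²; with n = 38 sites and weak spatial signal the likelihood in ρ
  is flat and AICc will usually prefer the independent structure.
- Correlated errors are excluded from the basis set, not modelled.
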