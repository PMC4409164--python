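# Methods

`estmeio` implements, end to end, the computational chain used to link
benthic microbial-eukaryote (meiofaunal) community structure in tidal
estuaries to candidate environmental drivers. Because the original
survey data of this kind (454 amplicon reads, field granulometry,
tide-gauge records) are not redistributable at desk scale, the package
pairs every analysis stage with a synthetic-data generator that has
known ground truth, so each method can be validated on data where the
right answer is known. This note records the models, the defaults and
why, and what the synthetic scenarios do and do not establish.

## Study design emulated

Two contrasting estuaries sampled along their full salinity gradients:
20 intertidal stations over ~106 km and 15 stations over ~46 km, three
replicate sediment cores per station (60 and 45 samples). Fourteen
candidate drivers per station, in fixed order: spring tidal range,
mean velocity, maximum velocity, mean bed shear stress, maximum bed
shear stress, D50, D10, % clay, % silt, % fine sand, % medium sand,
% coarse sand, % gravel and salinity range. Read depths per sample
span 1 044–30 786, the published range for this survey design.

## Synthetic scenarios (`synthio`)

**Environmental gradients.** Stations are evenly spaced along the
channel (normalised position `s`). Mean salinity follows a logistic
ecocline from fresh at the tidal head to ~34 p.p.t. at the mouth.
Salinity *range* (mean high-tide minus mean low-tide salinity) is
unimodal, `max · 4s(1−s)`, largest where the tidal excursion sweeps
the steepest part of the salt intrusion, bounded by the scenario
maximum (14.16 and 18.97 p.p.t. in the two default scenarios) and
scattered station-by-station by local bathymetric control (15%
half-normal multiplicative noise). Hydrodynamics are parametric in
the generator (the 1-D solver can replace them): tidal range amplifies
seaward, the velocity maximum sits seaward of mid-estuary (funnel
convergence), bed shear stress follows the quadratic law
τ = ρ·C_D·U², each with independent station noise so that no two
drivers are near-duplicates — a deliberate identifiability
requirement: a driver-inference benchmark is uninformative when two
candidate variables differ only by noise.

**Granulometry.** Each station's sediment is a two-component sand–mud
mixture on the log2 (phi) scale — the classic estuarine bimodal
distribution. The mud weight declines seaward and the sand mode
coarsens seaward, both with independent patchiness; D50 and D10 are
numerical quantiles of the mixture CDF and the six Wentworth-class
percentages are CDF increments, so all eight summaries are internally
consistent while none is a deterministic transform of another. (An
earlier single-lognormal design made every fraction a monotone
function of D50, which rendered a planted D50 effect unidentifiable
against its own derived proxies — the mixture model fixes this and is
also the more realistic sediment description.)

**Communities.** Occupancy of OTU *j* in sample *i* is Bernoulli with

    logit p_ij = β0_j + Σ_k β_kj · z_k(station_i) + δ_ir

where `z_k` are station-level driver z-scores, `β0_j ~ N(intercept,
0.5)` with intercept −0.8 (baseline occupancy ≈ 0.3), and `δ_ir ~
N(0, 0.35)` is a per-replicate logit offset shared across OTUs —
replicates resemble each other without being identical. Effects are
assigned per phylum as `(driver, β, sd)`: each OTU draws its slope
from `N(β, sd)`. A directional β plants a richness trend along the
driver (e.g. Mollusca declining with salinity range); a zero-mean β
with a wide sd plants *turnover* — taxon replacement along the
gradient with no net richness change, the structure an ecocline
produces and the signal that dissimilarity-based methods (BIOENV,
CCA) are built to detect. A purely directional model instead produces
nested communities whose Sørensen distances track the poorer
station's richness, which is why both kinds of effect exist. Default
taxon pools are Nematoda-dominated (260 and 233 OTUs of 493 and 425),
with Arthropoda and Platyhelminthes next, mirroring the rank order of
meiofaunal metabarcoding surveys. Reads are multinomial per sample
over the present OTUs with log-normal (sdlog 1) relative abundances;
totals are uniform over the configured range. All randomness flows
through one seeded `numpy` generator; identical seeds give
byte-identical datasets.

**What the generator does not emulate.** Sequence-level artefacts
(chimeras, denoising errors, tag switching), phylogenetic correlation
between OTUs, abundance-dependent detection, temporal variation, and
covariance between replicate noise and environment. Passing the
recovery tests therefore shows the inference chain is correct and
well calibrated on communities whose assembly follows the stated
logistic model — not that real estuarine data meet those assumptions.

## 1-D tidal model (`hydro1d`)

The solver integrates the sectional-averaged shallow-water balances

    B ∂η/∂t + ∂(AU)/∂x = 0
    ∂U/∂t + U ∂U/∂x = −g ∂η/∂x − C_D U|U| / (h + η)

on a staggered grid (η at cell centres, U at faces; default spacing
500 m) with a forward-backward step: semi-implicit quadratic friction,
first-order upwind advection, then a finite-volume continuity update.
Because the continuity update is in flux form, the interior volume
budget telescopes to the boundary flux exactly; the per-cycle mass
residual is ~1e-14 relative (machine precision), and is recomputable
from the stored series. The seaward cell carries the prescribed
harmonic elevation Σ aᵢcos(ωᵢt − φᵢ) (defaults M2, S2, N2, K1 — four
constituents led by the semidiurnal pair), ramped with a sin² factor
over a 2-day spin-up that is excluded from all outputs; the landward
face is a closed weir. Runs default to one spring–neap cycle
(14.77 days). The explicit gravity-wave CFL bound is checked up
front and violations name the largest stable Δt. Total depth is
clamped at 0.1 m by default (upper-estuary shallowness); a config
flag errors instead.

Defaults C_D = 2.5×10⁻³, ρ = 1025 kg m⁻³, g = 9.81 m s⁻² are standard
coastal values, all overridable. Station statistics: the tidal range
per cycle is high minus low water in successive windows of one M2
period, the spring range is the largest cycle range; velocity and
stress statistics are taken on |U| and |τ| (the direction-free
convention, recorded in output metadata). Validation: the frictionless
small-amplitude run reproduces the analytic co-oscillation profile
a·cos(k(L−x))/cos(kL) to ~0.02% RMS (the 2% test bound is generous);
halving Δx and Δt moves station spring ranges by well under 1%.

## Environmental features (`envfeat`)

Grain-size percentiles interpolate the cumulative curve linearly in
log2(size) (phi-scale convention); D50/D10 return exact bin edges on
exact crossings and refuse to extrapolate outside the observed
cumulative span. Class bounds are Wentworth-style 4/63/250/500/2000 μm
with 63–250 μm ("fine sand") absorbing very fine sand to keep six
classes; fractions are CDF increments and sum to 100 by construction.
Mechanically sieved and laser-diffraction curves are treated
identically (constant-particle-density assumption). Salinity-range
models are ordinary least squares with two kinds — range vs mean
salinity (spot-sampled estuaries) and range vs distance from the
tidal head (gauged estuaries) — with coefficients pluggable so an
externally published equation can be substituted; predictions clip at
0 p.p.t. with a warning. The assembler joins hydrodynamics,
granulometry and salinity range into the canonical 14-column matrix
and, when macrofauna metrics cover only a subset of stations, returns
both the full-station core view and the macrofauna-inclusive subset
view (mirroring surveys where some sites cannot be cored).

## Community statistics (`commstats`)

Counts are normalised to percent reads per sample (samples differ in
coverage); presence/absence is taken over the eleven metazoan target
phyla (Nematoda, Platyhelminthes, Arthropoda, Mollusca, Annelida,
Gastrotricha, Tardigrada, Kinorhyncha, Rotifera, Cnidaria, Bryozoa).
Sørensen dissimilarity d = 1 − 2a/(2a+b+c) is computed as the Dice
coefficient on the binary matrix; a pair of empty samples is defined
d = 0 with a warning (the formula is 0/0 and a pipeline must not
crash). Clustering is unweighted group-average (UPGMA) via scipy,
whose merge heights are the average inter-cluster dissimilarities and
whose tie-breaks follow input order deterministically; dendrograms
export to Newick with branch lengths as height differences, and
cutting at 0.75 dissimilarity reproduces the "25% similarity"
grouping convention.

**SIMPROF** follows the similarity-profile algorithm: at each
dendrogram node (top-down), the observed ordered dissimilarity
profile is compared with the mean profile of `n_profile_perms`
independent within-OTU permutations across the node's samples;
π = Σ|obs − mean|, with a null distribution from `n_test_perms`
further permutations scored against the same mean profile and
p = (b+1)/(m+1). Significant nodes are split and their children
tested; non-significant or <3-sample nodes become final groups.
Defaults 1000/999 at α = 0.05 (the analysis-level configuration uses
100/199 to keep full runs fast); the counts are flagged in the result
metadata as choices, not data. Under an i.i.d.-column null the root
test rejects at the nominal rate (measured 3–7% at α = 0.05).

**NMDS** minimises Kruskal stress-1,
√(Σ(d_ij − d̂_ij)² / Σd_ij²), alternating isotonic regression of
configuration distances on the ranked dissimilarities (scikit-learn
PAV, ties averaged) with a Guttman-transform update. Restart 0 starts
from the classical-scaling (PCoA) configuration, further restarts are
random; an iteration that would raise stress terminates its restart,
making the stress trace non-increasing by construction; the best
restart is returned, centred. A planted 2-D configuration is
recovered with stress < 0.01 and Procrustes RMS < 0.01.

Richness tables count OTUs with ≥1 read per sample (station-level
richness pools the replicate cores). Between-estuary comparisons use
an independent-samples t-test gated by Levene's test (absolute
deviations from group means): pooled variance when equality is not
rejected — giving the df = n₁+n₂−2 = 33 structure for a 20+15-station
design — Welch otherwise. Measured type-I error is 5% ± 1%.

## Driver inference (`drivers`)

**BIOENV** standardises the chosen variables to z-scores, builds
Euclidean inter-station distances for every non-empty subset up to a
size cap (exhaustive enumeration; a guard refuses >20 variables
unlimited), and ranks subsets by the Spearman correlation (plain,
average-rank ties) between the environmental and the Sørensen
distance lower triangles. The ten best subsets are reported in the
published table shape (No. of variables, Correlation, Environmental
variables). The full 14-variable search (16 383 subsets, 20 stations)
runs in a few seconds. The biotic matrix is fixed to presence/absence
Sørensen with presence pooled across the three replicate cores per
station (environment exists at station resolution; sample-level mode
is available).

**Mantel** uses the same rank statistic with a null from
simultaneously permuting rows and columns of the second matrix;
p = (b+1)/(m+1), two-sided on |ρ| by default. Null p-values are
uniform (KS-checked).

**CCA.** With P = Y/total, row sums r, column sums c, the chi-square
standardised table is Q̄ = (P − rcᵀ)/√(rcᵀ); total inertia Σ Q̄² equals
the Pearson chi-square statistic over the grand total. Explanatory
variables are r-weighted centred and scaled, √r-row-weighted, and Q̄
is regressed on them; the SVD of the fitted table gives the
constrained eigenvalues and the site/species/biplot scores of the
first two axes. Variables with pairwise |r| > 0.7 are removed first
(greedy, keeping the variable with the lower mean |r| to the others;
a configurable retention priority defaults to {mean velocity, D50,
salinity range}, the classic retained set). Stepwise selection is
forward-backward on the deviance-style AIC, n·log(residual
inertia/n) + 2k; marginal variable significance permutes the
reduced-model residuals (999 permutations by default, seeded).

**PLS-VIP.** Univariate PLS on z-scored X and y by NIPALS deflation
(w = Xᵀy/‖Xᵀy‖, t = Xw, deflate, 2 components by default — y is
standardised as well as X). The variable importance in projection is

    VIP_j = sqrt( p · Σ_a SS_a (w_aj)² / Σ_a SS_a )

with SS_a the y-variance captured by component a; since each weight
vector is unit-norm, Σ_j VIP_j² = p exactly (mean squared VIP = 1).
VIP is reported for the first latent variable and cumulatively;
pertinence is VIP > 1 on the first-component score (both are in the
output, since the convention differs between reports). The
association sign is the sign of the first-component regression
coefficient (w₁_j·q₁). Per-predictor R² and permutation p-values
(999 permutations of y) on the univariate association supply the
significance stars that annotate VIP tables; this is an
interpretation choice — the published tables print an R² next to
high-VIP entries without defining it, and the univariate reading is
the most conservative.

## Orchestration, sizes and determinism

`pipeline.run_full` drives simulate → community → drivers for both
estuaries from one validated config; a master seed derives each
stage's seed by hashing, so full re-runs are byte-identical. Stage
outputs are written as plain-text tables (TSV/CSV/JSON/Newick) under
one directory. Content-hash stage caching was considered and dropped:
the default analysis runs in well under a minute, so caching would
add surface without value. Default permutation counts in the
orchestration layer (SIMPROF 100/199, CCA 199, Mantel 499) are chosen
so a full two-estuary analysis plus the idealised tidal run completes
in tens of seconds; the library-level defaults are the conventional
1000/999. Simulation-based checks (driver recovery, type-I error) use
50–500 replicates, sizes at which the pass criteria have comfortable
margins under the fixed seeds.

## Known limitations

- The salinity-range "equation" kinds are linear; the original
  mean-salinity relation from the estuarine literature is not printed
  here, so its coefficients must be supplied to reproduce it exactly.
- The 1-D solver has no salt transport, no wetting-drying physics
  beyond a depth clamp, and first-order advection (adequate for tidal
  co-oscillation, not for bores or overtides).
- SIMPROF tests each node against the same first-stage mean profile;
  with very few profile permutations the π null is slightly noisy
  (the calibration test uses 100 and stays within 3–7%).
- CCA stepwise AIC is the ecological-package heuristic, not a
  likelihood AIC; with few stations it co-selects noise variables in
  a minority of runs.
- Station-level BIOENV assumes the three cores are exchangeable;
  ecologically distinct replicate habitats would violate this.
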