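# Methods

This note documents the models and procedures implemented in `phytoflux`,
the assumptions behind them, the tunable parameters and their defaults,
and what the synthetic-data generator does and does not emulate.

## Analysis procedures

### Trophic filter

ASVs are labelled from an editable rule list (`data/trophic_rules.tsv`,
rank + name + label). Precedence is fixed: parasite rules dominate
everything; the dinoflagellate-inclusion switch (on by default, because
dinoflagellate trophic strategies are variable and often fluid) dominates
photosynthetic/heterotrophic rules; photosynthetic rules dominate
heterotrophic ones, so e.g. Chlorarachniophyceae stay photosynthetic
although Cercozoa as a division is heterotrophic. Unmatched lineages are
`unknown` and excluded from all phytoplankton analyses. The shipped list
is a PR2 v4-compatible default covering the common open-ocean groups; it
is a data file precisely so users can extend it without touching code.

The read-saturation filter removes samples with strictly fewer than 5000
photosynthetic reads (a sample with exactly 5000 is retained). The
threshold is a parameter (`--min-reads`) because saturation depends on
sequencing depth and community evenness.

### Pigment groups and genus bins

The group map (`data/pigment_groups.tsv`) is an ordered rule list; the
first matching rule wins, so class-level rules (Bacillariophyta,
Dictyochophyceae, …) precede division-level fallbacks (Ochrophyta →
other_ochrophyta). Photosynthetic taxa outside the six pigment groups
(rappemonads, chlorarachniophytes, red algae) map to the explicit
`other_photo` fallback and therefore count in the ratio denominator
("all other phytoplankton"). Genus bins use the genus name when assigned,
otherwise `unassigned:<deepest assigned rank>`; the bin count is
data-dependent and never hard-coded.

### Partition and packaging

Presence means ≥1 read after filtering — the packaging rule is a
detection rule, and imposing a higher per-ASV floor would conflate
abundance with presence. Pools are built per basin with all deployments
and depths pooled. Platform pairing is by (deployment, platform id);
cross-deployment matches are not allowed. The four packaging labels are
mutually exclusive and exhaustive over a basin's detected ASVs:
`large_particle` (bulk ∧ same-platform particle), `small_particle_only`
(bulk, never a same-platform particle), `particle_only` (particles,
never bulk), `surface_only`. A fifth "bulk and surface only" category is
unreachable under this rule — bulk presence without a same-platform
particle is small-particle export regardless of surface detection — so it
is not part of the label set.

Export fractions per pigment group split a basin's surface ASVs into
detected-in-particles, bulk-only, and not-exported; the read-weighted
variant weights by summed surface reads. ASVs detected in individual
particles but not in bulk count as particle export (detection in a picked
particle is direct evidence of large-particle packaging). A group with no
surface ASVs reports NaN fractions — undefined, deliberately not zero.

### Compositional statistics

Counts are compositional, so comparisons run in CLR space:
`clr(x)_j = log((x_j+δ)/g(x+δ))` per sample. The default pseudocount is
δ = 1 on raw counts before closure; the choice is logged in output
metadata and configurable because no zero-replacement strategy is
canonical, and results at very low depth are sensitive to it. Euclidean
distance on CLR rows is the Aitchison distance.

PCA is computed by SVD of the column-centred CLR matrix: scores `U·S`,
loadings `V`, variance fractions `S²/ΣS²`. The sign of each component is
fixed (largest-magnitude loading positive) for reproducible outputs.

PERMANOVA uses the standard distance-based decomposition: with
`SS_T = Σ_{i<j} d²_ij / n` and `SS_W = Σ_g Σ_{i<j∈g} d²_ij / n_g`,
`F = ((SS_T−SS_W)/(a−1)) / (SS_W/(n−a))`. Group labels are permuted
uniformly (default 9999 permutations), and
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)` — the add-one rule keeps p
positive and ties count as exceedances (conservative). Fixed seeds make
every p-value bit-reproducible. Pairwise tests use Bonferroni with m =
the number of pairwise tests actually performed in the run. The pipeline
runs the basin comparison on all samples and, within each basin, the
pairwise sample-type comparisons; both conventions (pooled or stratified
subsets per comparison) are available through the library API.

Covariability of pigment groups with flux standardizes each variable
(mean 0, sd 1 with ddof = 1) before PCA and reports the squared Pearson
correlation of every variable with every component score.

Richness is compared by one-way ANOVA with Tukey–Kramer honest
significant differences (studentized-range based, valid for unequal group
sizes; `scipy.stats.tukey_hsd`). The degenerate all-constant case is
reported as F = 0, p = 1 rather than NaN.

### Flux model

The ratio statistic per bulk trap sample is
`x = Σ reads(numerator groups) / Σ reads(all other photosynthetic
groups)`, computed within the shared-ASV mask (ASVs detected in ≥1
surface sample and ≥1 sinking-particle sample — bulk or individual — of
the basin, pooled over deployments and depths, since the relationship is
a basin-scale one). x is computed from counts; because it is a
within-sample ratio this is identical to computing it from closed
relative abundances, and it is invariant to library size. The numerator
defaults to {diatoms, hacrobia} and is configurable for single-group
variants. Samples with a zero denominator get NaN, are logged, and are
excluded from fitting.

The fit is unweighted OLS of measured flux on x (an inverse-variance
weighting flag exists but is off by default, since measured flux
uncertainties are reported but the relationship is a plain linear fit);
pooled and per-basin fits share one code path differing only in the row
filter. Predictions are `ŷ = a·x + b`; negative predictions are returned
as-is with a warning rather than clipped, so the caller sees the model's
actual behaviour. Depth profiles report measured vs. modelled flux by
basin, deployment and depth, by default restricted to surface-tethered
trap (STT) platforms whose five-depth arrays give clean profiles.

## The synthetic-data generator

### What it emulates

* **Two contrasting basins.** Surface group compositions are drawn per
  sample from a Dirichlet around the basin profile (concentration =
  profile × 70); within groups, ASV weights follow log-normal
  propensities (σ = 0.5). The NP default profile is
  dinoflagellate-dominated and the NA profile diatom-dominated, giving a
  low NP and high NA diatom+Hacrobia ratio and strong basin separation in
  CLR space.
* **Sampling design.** 54 surface samples per basin (3 deployments × 6
  days × 3 light depths), 43 bulk trap samples (28 NP across STT and NBST
  platforms, 15 NA across STT platforms) matching the size of the flux
  regression, and ~11 (NP) / ~30 (NA) picked particles per platform
  (758 total).
* **Particles.** Per-particle phytoplankton richness is
  1 + Poisson(mean−1) with basin means 8 (NP) and 14 (NA); members are
  drawn from the platform's export pool with abundance-tempered weights
  (exponent 0.35, so particles are not monopolised by the few most
  abundant surface taxa) plus rare deep taxa absent from the surface.
  Particle-class preferences enrich one designated ASV per class (salp
  pellets a Hacrobia ASV ×4, aggregates and long pellets distinct diatom
  ASVs ×3), mirroring class-specific indicator taxa rather than
  wholesale group shifts.
* **Bulk samples and packaging truth.** Each surface ASV is planted as
  large-export (probability increasing with surface abundance, base
  0.45), small-export (0.20) or not exported. Bulk samples pool their
  platform's large-particle material and add counts for planted small
  ASVs; the sparse deep tags picked up by individual particles stay below
  the bulk library's detection limit, which is what produces
  particle-only ASVs. Under this construction perfect detection makes
  packaging inference exactly recoverable, and a planted-large ASV that
  the picked particles happen never to capture is demoted to planted
  small (indistinguishable from small export even in principle).
  `detection_completeness` < 1 removes each exported ASV from the basin's
  particles with one shared uniform draw per ASV, so datasets at lower
  completeness are nested within those at higher completeness and
  inferred small-particle sets grow monotonically.
* **Flux law.** `flux = 3.4·x + 0.47 + N(0, 0.7)` mmol C m⁻² day⁻¹,
  truncated at zero with a log message; x is computed on the generated
  bulk counts with the same shared-mask definition the analysis uses
  (asserted equivalent in the tests). The noise sd is set from the
  analytic relation σ² = a²·var(x)·(1−R²)/R² with the generator's
  realised var(x) ≈ 0.11, targeting R² ≈ 0.7 at n = 43. The basin
  profiles are deliberately less extreme than the most dominated field
  observations: with a homoscedastic Gaussian law, pushing the basin
  ratio contrast to its field extremes while holding R² ≈ 0.7 would
  force a noise sd larger than the low-basin fluxes themselves, making
  zero-truncation common instead of rare and biasing the OLS recovery
  the generator exists to demonstrate. With the defaults, truncation
  occurs in ≈0.1 samples per dataset.

### What it does not emulate

Sequencing error and chimeras; rarefaction-depth artefacts (library sizes
are high and nearly uniform, so the 5000-read filter removes nothing
under the defaults and per-sample surface richness is nearly constant);
taxonomic mis-annotation; within-basin temporal succession (days are
exchangeable draws); any dependence of flux on particle class beyond its
effect on x; and heteroscedastic flux noise (field residuals likely scale
with flux magnitude, so the per-basin fit qualities seen in real data —
e.g. no within-basin relationship in an oligotrophic basin — are not
reproduced; in the generator, flux tracks x within basins by
construction). Passing tests therefore demonstrate correctness of the
inference machinery under the stated statistical model, not robustness to
these field effects.

## Numerical choices

* Count tables are validated to integers ≥ 0 and sorted by identifier on
  read, so all downstream orderings are deterministic.
* CLR requires strictly positive entries; zeros with δ = 0 are a hard
  error rather than a silent drop.
* PERMANOVA permutations are generated by `numpy.random.Generator`
  streams derived from the user seed; the tie rule is ≥.
* OLS confidence intervals are two-sided t intervals from
  `scipy.stats.linregress` standard errors.
* Degenerate inputs fail loudly and name the offending record: duplicate
  ids, missing taxonomy, constant regressors, zero-variance PCA
  variables, singleton PERMANOVA/ANOVA groups.

## Problem sizes

The default test and acceptance workloads use the generator's default
design (909 samples × 314 ASVs per dataset): 500 replicate datasets for
confidence-interval coverage, 1000 surface-only null datasets (9 samples
per basin) × 999 permutations for PERMANOVA calibration, and 100
randomized ≤20 × 50 instances for the brute-force oracle comparisons.
These sizes give Monte-Carlo error comfortably inside the asserted bands
while keeping a full run to a few minutes on one CPU.

## Known limitations

* The shipped trophic and pigment rule lists are deliberately compact
  defaults; real studies should extend them to their PR2 version and
  regional taxa.
* The Venn partition and export fractions treat detection as binary;
  there is no occupancy modelling of imperfect detection in bulk
  libraries (the packaging inference criterion quantifies this instead
  via `detection_completeness`).
* Pairwise PERMANOVA Bonferroni counts only the tests in the current run;
  combining results across runs requires re-adjustment by the caller.
* The flux model is a two-parameter linear law; no attempt is made to
  model transfer functions from surface communities to particle
  packaging, nonlinear flux responses, or attenuation with depth beyond
  what x itself carries.
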