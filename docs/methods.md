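# Methods

This note documents the statistical procedures, their assumptions, the
tunable parameters, and the design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Codon statistics

Sequences are read in frame 0 as non-overlapping triplets; a trailing
partial triplet and any triplet containing a character outside {A, C, G, T}
are skipped and tallied. Stop codons are counted but excluded from every
downstream statistic (GC, RSCU, ENC, amino-acid usage), following the
convention of classic codon-usage software. Only the standard genetic code
(translation table 1) is built in; `GeneticCode.from_table_id` is the
extension hook for other tables.

**GC by position.** GCk is the fraction of G/C at codon position k over
counted sense codons; GC12 = (GC1+GC2)/2 exactly. A gene with zero sense
codons has undefined GC values and is excluded from sample means.

**RSCU.** RSCU(c) = count(c)·k / n_fam for a codon in a family of degeneracy
k with family total n_fam. A family with n_fam = 0 is *undefined*, not zero:
absence of observation is not absence of usage. Single-codon families (Met,
Trp) are 1 when observed. Within any observed family the values sum to k.

**ENC.** Wright's estimator: per-family homozygosity
F̂ = (n·Σp² − 1)/(n − 1), undefined for n < 2 and clamped to the
uniform-usage floor 1/k when the small-sample estimate is ≤ 0; then
ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ over the degeneracy-class means of
defined families, clamped to [20, 61]. When the single three-fold family
(Ile) is unobserved, 1/F̄₃ is interpolated from (F̄₂+F̄₄)/2 (Wright's rule);
if any other class is empty the gene's ENC is undefined. The original C
implementation this statistic is usually computed with is not bit-matched;
the class formula above is implemented exactly as stated and checked against
an independently coded brute-force evaluation in the tests. The expected
curve under pure GC3 drift is ENC* = 2 + GC3 + 29/(GC3²+(1−GC3)²),
symmetric about GC3 = 0.5 with maximum 60.5; note the true no-bias ceiling
of the estimator is 61, so unbiased genes sit slightly above the curve near
GC3 = 0.5.

**Strong bias.** Genes with defined ENC ≤ 35 (inclusive).

**Sample aggregation.** GC12/GC3/ENC are unweighted means over genes with
defined values. Amino-acid and codon percentage abundances and RSCU are
computed from counts *pooled* across the gene set, not as means of per-gene
fractions: pooling is the only choice that makes percentages sum to exactly
100 and weights genes by their codon content. Two gene sets are analysed
throughout: the single-copy orthologues (conserved genes) and all annotated
genes (genome-wide context). The codon-usage feature family comprises the
61 sense codons by default; a flag drops the single-codon families (59
columns). The convention of reporting "60" codons does not correspond to any
partition of the standard code and is not reproduced.

**Neutrality regression.** OLS of GC12 on GC3 with Pearson r and its
two-sided t-test (df = n−2). The default unit is per-sample means: the
published p-value at this analysis's scale is arithmetically consistent with
n = 27 samples rather than with hundreds of thousands of genes. A per-gene
mode is available (`neutrality_per_gene`).

**Correspondence analysis.** Standard CA: P = N/ grand total,
S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}, SVD of S, principal coordinates
= singular vectors scaled by singular values and D^{−1/2}; inertia per
dimension is the squared singular value, and total inertia equals χ²/N.
The input RSCU matrix drops single-codon families and any codon whose RSCU
is undefined in at least one sample (undefined ≠ zero usage); an all-zero
row or column is a validation error.

## Climate PCA and correlation screen

The 11 temperature bioclim variables are standardized (they mix °C, an
index and a ×100 scale) and the correlation matrix eigen-decomposed.
Loadings are reported as variable–PC correlations; contributions are
100·(unit eigenvector entry)², summing to 100 per PC. Since a PC's sign is
arbitrary, each PC is oriented so its largest-magnitude loading is positive;
users should interpret sign *patterns* jointly, not absolute signs.

Retention: PCs with ≥ 5% variance explained (boundary inclusive).
Important variables: contribution strictly > 10%.

The screen tests every feature against every retained PC with Pearson
correlation by default (the reported statistics are r with linear fits;
Spearman is available by flag). BH-FDR is applied within the amino-acid
family and within the codon family separately, across all retained PCs
(conservative; a per-PC mode is available). Scalar features (GC12, GC3,
ENC, user-supplied columns such as CAZyme class counts) are reported with
raw p-values, since the FDR convention is stated only for the two large
families; `pool_scalars` groups them into a third adjusted family.
Significance is p (adjusted where applicable) < α = 0.05.

## Amino-acid enrichment

Relative enrichment fold = (C_q − C_b)/C_b per residue between a query and a
background set. Significance follows the bootstrap z-test scheme of
composition-profiling tools: both sets are resampled with replacement at
their own totals from the *pooled* composition (the null of no difference),
the fold recomputed per replicate, and the observed fold standardized
against the bootstrap centre and spread; two-sided normal p, BH across the
20 residues. The z-test was chosen over an empirical-fraction p because the
fraction has a 1/n_boot resolution floor that truncates small p-values.
Residues absent from the background have undefined fold and are flagged.
Power at the default n_boot = 2000 is limited by the fold's sampling noise:
a 20% relative enrichment of a ~9% residue at 10,000 residues per set is
detected after BH roughly 80% of the time (measured in the test suite);
smaller sets or rarer residues need larger effects.

## Zone comparisons

The generic machinery is normality-gated as the study prescribes:
Shapiro–Wilk on each group at 0.05 selects one-way ANOVA with Tukey HSD
post-hoc pairs, otherwise Kruskal–Wallis with pairwise Mann–Whitney tests,
BH-adjusted; post-hoc tests run only when the omnibus p < α. The printed
"signed-rank" test on unpaired, unequal-size groups is implemented as the
rank-sum (Mann–Whitney) test; a paired signed-rank mode exists for matched
inputs. A "(p < 0.5)" significance gate in the source material is treated
as a typo for 0.05; α is configurable.

dN/dS records with ratio > 10 are discarded (idempotent). Strata are
half-open exactly as printed: positive selection [1, 10), negative
selection (0, 1). Within each gene group (CAFE-family vs other genes) every
zone pair is compared; within each zone the two gene groups are compared;
BH is applied across the whole comparison set.

## Methylation

Sites with coverage < 10 **or** modification score < 50 are removed
(boundary inclusive: a (10, 50) site survives). A "methylated site" is a
passing site whose boolean call is positive; a fractional call column is
reduced at a configurable cutoff (default 0.5). Windows tile each contig
from coordinate 0 in 1-Mb steps (bed-style 0-based half-open: position
1,000,000 opens the second window); the final partial window is kept.
Windows with no passing sites are undefined and excluded from tests rather
than scored 0% — absence of data is not absence of methylation. Within each
species sampled in ≥ 2 zones, window percentages are compared with
Kruskal–Wallis, reporting the zone with the higher median and whether it is
the colder one. All samples of a species must share one reference
coordinate system; the package assumes rather than performs that mapping.

## Synthetic data generator

The generator emulates a 27-sample, 11-species panel spanning three climate
zones, with the species/zone/elevation layout of the study panel it stands
in for. Default problem sizes are scaled down to desk scale — 120 genes ×
300 codons per sample, five 2-Mb contigs with 1000 CpG sites each, 400
dN/dS records per zone — chosen so a full end-to-end run completes in
seconds while every statistical structure remains comfortably detectable.

*CDS.* Amino acids are drawn i.i.d. from a fungal-like composition; the
synonymous codon is a family-wise multinomial combining a Boltzmann bias
toward one preferred codon per family (inverse temperature
`bias_strength`, default 0.4, giving mid-50s mean ENC) with a GC3 pressure
toward `gc3_target` (default 0.55 ± 0.04 per-sample jitter). At
`bias_strength = 0` the construction reproduces Wright's expected ENC–GC3
curve within the estimator's small-sample wobble. No dinucleotide context,
no codon autocorrelation, no length variation: sufficient for ENC/RSCU/GC
targets, and a stated simplification — passing tests say nothing about
context-dependent biases in real genomes.

*Bioclim.* Two latent axes generate the table: a means/extrema axis (tied
to zone coldness) drives BIO1/BIO5/BIO10/BIO11; an independent variability
axis drives BIO2/BIO4/BIO7 positively and BIO6 negatively; BIO3/BIO8/BIO9
are weak mixtures plus noise. The axes are orthogonalized in-sample and the
per-variable noise residualized against both axes, so each variable's axis
loadings are exact and the PCA attributes each block to a single component;
BIO5 ≥ BIO6 and BIO7 ≥ 0 are enforced. This exactness is a deliberate
idealization — real bioclim tables mix their axes, so recovery there is
approximate.

*Feature links.* Planted effects shift per-sample composition parameters
along a latent axis through a per-feature signal x = r·z + √(1−r²)·ε:
GC12 via an exponential tilt of the composition along each residue's
GC12 propensity (~1.5 percentage points per unit signal), a residue via a
multiplicative tilt (~25% relative), a codon via a within-family preference
tilt strong enough to dominate opposing family-level effects. Defaults
plant the study's sign pattern (GC12, Arg, GTG up; Val down, |r| = 0.8 on
the variability axis). Realized correlations are attenuated by sampling
noise; the generator records intended r in `truth.json`.

*Methylome.* CpG positions uniform per contig, coverage negative-binomial
(mean 20), modification score normal with a higher mean for truly
methylated sites, per-site methylation probability
base_prob·(1+zone_effect)^coldness with base 0.25 and effect 0.5 — an
idealized, spatially homogeneous methylome (no CpG islands, no
window-to-window heterogeneity beyond binomial noise).

*dN/dS.* Log-normal per gene with zone medians 0.10 (alpine) < 0.12
(mediterranean) < 0.15 (cold temperate), matching the ordering the pipeline
should detect, and a 0.8× median shift for CAFE-family genes.

One master seed fixes every output byte; stages draw from independent
child generators so adding a stage never perturbs another.

## Numerical and interface choices

* Elevation→zone helper (optional; explicit labels always win): Europe
  <900 m Mediterranean, 900–1900 m cold temperate, ≥1900 m alpine;
  California <1200 m Mediterranean, ≥1200 m cold temperate, never alpine.
  Boundaries are half-open with the lower zone owning its upper bound;
  the gap ranges in the stated conventions are assigned to the adjacent
  lower-elevation zone's neighbour as documented in `data_io`.
* Methylation input is bed-like 0-based half-open; column order is
  remappable.
* All GC quantities are fractions internally; reports render percentages.
* Thresholds (5% retention, 10% contribution, ENC ≤ 35, dN/dS ≤ 10,
  coverage ≥ 10, score ≥ 50, 1-Mb windows, α = 0.05) live in `RunConfig`,
  overridable by YAML config file and flags (flags > file > defaults).
* `run-all` writes a manifest (config hash, seed, package version, output
  list) and is byte-deterministic given its inputs and seed.

## Known limitations

* ENC is not bit-compatible with legacy C implementations whose handling of
  missing families is undocumented; the class formula and Ile interpolation
  are stated above and frozen by oracle tests.
* The correlation screen treats samples as independent; phylogenetic
  non-independence (closely related samples sharing features) is out of
  scope and would require a comparative-methods treatment.
* The enrichment bootstrap's power at 10⁴-residue sets is ~0.8 for a 20%
  relative change of a common residue; whole-proteome inputs are far more
  powerful.
* The synthetic generator's idealizations (exact axis orthogonality,
  homogeneous methylome, i.i.d. codons) mean green tests demonstrate the
  pipeline's correctness and calibration, not its behaviour under real
  data's confounders.
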