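# Methods

`gcregulome` re-implements, as one tested library, the computational
stages of an integrative glucocorticoid (GC) response analysis in acute
lymphoblastic leukemia (ALL): differential chromatin and expression over
a treatment time course, super-enhancer (SE) calling, a high-confidence
glucocorticoid-receptor site (HGR) atlas with GRE motif annotation,
enhancer–promoter loop linkage, ATAC-STARR-seq activity calling, TF
footprint dynamics, CRISPRi tiling-screen aggregation, and
patient-cohort analyses culminating in a prioritization funnel. All
stages run end to end on synthetic data with planted ground truth; the
generator is first-class, tested code.

## The count model and differential testing

Counts (region-level ATAC/H3K27ac/GR reads, gene-level RNA, sgRNA
abundances, patient accessibility) follow a negative binomial with the
mean–dispersion parameterisation Var = μ + αμ². Library size factors
use the median-of-ratios rule restricted to features with no zero
count. Dispersion is estimated per feature by method of moments on
normalised counts — pooled within contrast groups so condition effects
do not inflate it — then shrunk 50/50 toward a least-squares trend
α(μ) = a₀ + a₁/μ fitted on positive raw estimates, floored at 1e-8.
The test is a Wald z on log2((μ̂_t + 0.5)/(μ̂_r + 0.5)) with the delta-
method variance Var(log μ̂_g) = n_g⁻² Σ_j (1/(s_j μ̂_g) + α); p-values
are two-sided normal, corrected by Benjamini–Hochberg.

Deliberate simplifications relative to full GLM machinery: two-group
contrasts only (every comparison the pipeline makes is two-group), no
shrunken fold changes, no independent filtering. This keeps every
number oracle-checkable; the calibration suite verifies the type-I
error (p < 0.01 rate within [0.005, 0.02]; ≤ 2% of null features at
q < 0.01) and power (≥ 90% sensitivity for |log2FC| = 2 at 4 replicates
and depth 10⁶).

One caveat worth naming: under the median-of-ratios formula, scaling a
single column by c moves its factor by c^(1−1/m) (the geometric-mean
reference moves too); only factor *ratios* are exactly equivariant. The
tests assert the true property.

Chromatin contrasts are per treated timepoint vs 0 h (the time-course
phrasing admits either a per-timepoint or a joint model; per-timepoint
is transparent and matches the combined-DEG convention). The DEG
universe is the union of the 6 h and 24 h contrasts at FDR < 0.01 and
fold > 2.

## Super-enhancers

H3K27ac peaks are stitched at a 12,500 bp gap (the conventional
default; TSS exclusion is off by default, with a flag, because
intragenic SEs are biologically expected). Stitched regions are ranked
by total signal; with rank and signal scaled to [0, 1], the cutoff sits
where the discrete slope of the curve first exceeds 1, and everything
above is an SE. GC-responsive SEs are unions of overlapping treated-
timepoint SE calls supported at ≥ 2 treated timepoints; a call is
*de novo* when no 0 h SE overlaps and *pre-established* when one does
and the treated/0 h stitched **total** signal ratio is ≥ 2 (the
constituent-mean alternative was rejected as less stable for regions
whose constituent lists differ across timepoints). On smooth synthetic
baselines the 0 h tangent cutoff is liberal (no natural outliers), so
planted SEs usually classify as pre-established rather than de novo;
both routes are exercised by unit tests on constructed inputs.

## HGRs and the GRE matrix

An HGR is a GR peak overlapping (≥ 1 bp) both an ATAC and an H3K27ac
peak at the same timepoint; the final atlas is the union over
timepoints with overlapping GR peaks merged and supporting timepoints
retained. The HGR footprint is always the GR interval, never the
triple intersection — HGRs are sites of GR occupancy.

The GRE is a 15-column base-2 log-odds matrix against a uniform
background, built from the canonical NR3C1 consensus structure: two
AGAACA half-sites in inverted orientation with a 3 bp spacer
(AGAACAnnnTGTTCT). Informative columns put probability 0.85 on the
consensus base; spacer columns are uniform. Scanning maximises over
both strands and all offsets; ambiguous bases score as each column's
worst base; a hit requires ≥ 0.8 of the maximal achievable score (no
published cutoff exists for "discernable motif"; the fraction is a
config parameter). Allele scoring replaces the variant base and
re-scans the whole HGR window; the reported delta is alt − ref best
score in bits.

## Loops

Anchors overlapping any TSS ± 2,000 bp (configurable; no published
window) are promoter anchors. Only unambiguous distal→promoter loops
enter the Fisher linkage counts — promoter↔promoter loops are excluded
to avoid directional double counting — and each (loop, gene) pair
counts once. The linkage table crosses {enhanced, reduced} H3K27ac at
the distal anchor with {up, down} DEG at the promoter. Because the
per-loop vs per-gene denominator for "promoter loops mapped to DEGs"
is ambiguous, both fractions are reported.

## STARR-seq

RNA output libraries are first downsampled to the minimum library
total by a seeded multivariate hypergeometric draw (exact totals,
expected proportions preserved). The binomial caller tests, per
region, RNA count x against Binomial(total RNA, DNA proportion) and
requires p < 0.001 plus DNA coverage ≥ 10 (the coverage floor guards an
unstable p₀; no published value). Calling uses merged replicates;
per-replicate calling is exposed as an option. The count-model caller
contrasts RNA output replicates against pooled input replicates through
the NB machinery (FDR < 0.05, positive fold change); concordance
between the two callers is reported and must stay high under planted
truth. GC-active = union of 6 h and 24 h calls; GC-specific removes
0 h actives.

## Footprints

A footprint score is computed per motif site from insertion counts in a
±100 bp window: counts are normalised to window mean 1 (depth
invariance), and score = mean(flank) − mean(core) with 20 bp flanks.
Differential occupancy between conditions uses a per-site condition-
label flip permutation (≥ 100 permutations enforced; default 1,000)
with BH across TFs. No insertion-bias correction is applied — the
synthetic profiles carry no sequence bias — and the permutation scheme
is a stated replacement for, not a replication of, external footprint
tools' internal significance models.

## CRISPRi screen

Per-sgRNA enrichment is the NB contrast post-selection vs baseline;
size factors come from the non-targeting controls alone when ≥ 10 are
present, which removes the composition bias a large enriched fraction
otherwise leaves in every null sgRNA. Element aggregation is α-RRA:
with a site's sgRNA percentile ranks r(1) ≤ … ≤ r(k) (assigned by
ascending one-sided p, ties broken by sgRNA id), ρ = min over j ≤ j_max
of BetaCDF(r(j); j, k−j+1) where j_max counts sgRNAs with p < 0.05;
ρ = 1 when none qualify. Site significance comes from 1,000 seeded
permutations drawing k ranks (with their α flags) from the pool;
sites are ranked by mean sgRNA log2FC with ρ and its permutation p as
companion evidence. Arms are treated as unpaired (the replicate
pairing of the selection arms is not specified anywhere). Sensitivity
at the default 2× sgRNA effect is bounded by sites carrying only 1–2
sgRNAs (Poisson(6.5) with a floor of 1); the element-level recall sits
at ≈ 0.90–0.98 across seeds.

## Cohort analyses

Resistance stratification supports a median split, a fixed threshold,
or provided labels. Resistance-associated accessibility is the
resistant-vs-sensitive NB contrast run inter-subtype (all samples) and
intra-subtype (each subtype with ≥ 4 samples and both classes
represented, both thresholds configurable); the union at FDR < 0.1
carries arm provenance and direction. A CpG probe is concordant when
its resistant–sensitive beta difference opposes the accessibility
log2FC; probes at zero-difference sites leave the denominator.

Fine-mapping takes lead variants at association q < 0.05 (config
default; no published threshold), expands by LD proxies at r² > 0.8
(squared Pearson correlation of dosages), and keeps any lead *or*
proxy inside an HGR — the "any of lead/proxies" reading of an
ambiguous criterion. Associations are plain additive OLS without
covariates: the eQTL/phenotype models are pipeline-stage linkage, not
a methods claim. The funnel intersects CRISPRi candidates (mean
log2FC > 0, HGR-overlapping) with region→gene association
(basal-plus-extension: 5 kb up / 1 kb down basal, ≤ 1 Mb extension
stopping at neighbouring basal domains — that association tool's
documented defaults), GC-responsive DEGs, and a supplied resistance
gene list; per-stage survivor counts are reported and are monotone by
construction.

## The synthetic-data generator

The generator emulates the statistical structure of the study, not its
sequences: a 3 × 10 Mb toy genome with 200–1,000 bp disjoint peaks
(≥ 500 bp apart), one TSS per gene, NB counts with α = 0.05 and
log-normal library sizes (sd 0.2) around a mean depth of 10⁶,
|log2FC| = 2 planted effects on 15% of features (2:1
enhanced:reduced), STARR activity factor 4, ~6.5 sgRNAs per site with
100 non-targeting controls and a 2× post-selection effect, and a
100-patient cohort (two subtypes, half resistant). Quantities the
source study reports as outcomes are planted as conditions where the
downstream stage is meant to recover them: GREs in 50% of GR-occupied
peaks, 78% of resistance sites occluded in resistant patients,
methylation anti-correlated at 85% of probes (a parameter; the
acceptance run also exercises 100% and 50%), 35% of loops
distal→promoter with concordant enhanced→up wiring planted, and a
causal common variant (MAF 0.3) striking a high-information GRE column
inside one "showcase" HGR that also carries screen enrichment,
resistance occlusion, a loop to its target gene, and membership of the
resistance gene list — the locus the end-to-end funnel must recover.
The cohort phenotype is built so the residual around the additive
genetic effect has sd ≈ 1.0 (status term 1.2 × class + N(0, 0.8)),
matching the power conditions the recovery checks assume.

Planted SE peaks get H3K27ac boosts sized against both the per-peak
median (≥ 15×) and their own stitched region's baseline total (≥ 20×),
so a high-signal stitched neighbour cannot mask the treated/0 h fold.

What the generator does **not** emulate: raw reads, fragment-level Tn5
sequence bias, ChIP enrichment profiles within peaks, LD structure
beyond planted proxies, population stratification, or batch effects.
Passing tests therefore demonstrate the pipeline's internal
correctness and calibration under the stated noise model — not
robustness to the artefacts of real sequencing data.

Determinism: every stage draws from `default_rng([seed, crc32(stage)])`
so stages are independently reproducible and full runs are
byte-identical under a fixed seed (asserted by test).

## Numerical choices and degenerate inputs

* 0-based half-open coordinates everywhere; 1-based only in VCF output.
* Fisher's two-sided p uses the probability-mass rule; odds ratios are
  the sample a·d/(b·c) with ∞ for a zero denominator and NaN for 0/0
  (degenerate linkage tables report NA rather than a number).
* KS p-values are asymptotic only; sample sizes in use are ≥ hundreds.
* +0.5 pseudocounts bound log fold changes when a group mean is zero.
* All-equal SE signals yield zero SEs with a warning; all-zero
  footprint sites are skipped; monomorphic variants return NaN;
  zero-DNA STARR regions are excluded from RNA generation and calling.
* Ties: nearest-TSS ties break to the lexicographically smaller gene
  id; RRA rank ties break by sgRNA id.

## Problem sizes

The default study conditions (2,000 regions, 300 genes, 5 timepoints ×
4 replicates, 100 patients) complete a full pipeline run in well under
a minute on one CPU. The test suite and the acceptance script use
these defaults for recovery/enrichment checks and a 300-region
configuration for the seed-swept calibration and 20-run funnel checks,
chosen to keep the whole suite in the low minutes while leaving every
statistical conclusion unchanged at larger sizes.

## Known limitations

* The NB Wald test is anti-conservative at very low counts (< ~10
  reads/feature); the synthetic depths keep features well above this.
* The SE tangent cutoff on a smooth signal curve (no outliers) calls a
  liberal 0 h SE set; real H3K27ac landscapes have heavier tails.
* α-RRA permutation p-values are cached per sgRNA-count k, which makes
  sites with equal k share a null; exact per-site nulls would differ
  only through their α flags.
* Fine-mapping treats the best-scoring PWM window per allele; a variant
  creating a *new* motif elsewhere in the HGR can mask a disruption.
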