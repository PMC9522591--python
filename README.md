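# gcregulome

Glucocorticoids (GCs) are a backbone of acute lymphoblastic leukemia
(ALL) therapy: they act through the glucocorticoid receptor (GR,
*NR3C1*), which binds GC response elements (GREs), remodels chromatin,
rewires enhancer–promoter contacts and drives the apoptotic gene
program. Resistance to GCs is a major cause of treatment failure, and a
growing body of work locates part of that resistance in *cis*-regulatory
elements — GR-occupied enhancers whose genetic or epigenetic disruption
blunts the GC response.

`gcregulome` is a Python library that implements the computational
spine of such an integrative analysis, end to end, with every stage
tested against planted ground truth on synthetic data:

* **Differential chromatin and expression** over a GC treatment course
  (negative-binomial Wald tests with median-of-ratios normalisation and
  trend-shrunk dispersions).
* **Super-enhancers**: 12.5 kb stitching, rank-curve tangent cutoff,
  and classification of reproducible GC-responsive SEs into de novo
  vs pre-established (≥ 2-fold H3K27ac gain).
* **HGR atlas**: high-confidence GR sites (GR ∩ ATAC ∩ H3K27ac per
  timepoint), GRE motif scanning with a palindromic 15-bp log-odds
  matrix, and GRE × chromatin-response enrichment tests.
* **Loop linkage**: promoter/distal anchor annotation and Fisher tests
  of enhanced-H3K27ac → upregulated-gene wiring.
* **ATAC-STARR-seq**: library downsampling, a binomial RNA-vs-DNA
  activity caller (p < 0.001), a replicate count-model caller
  (FDR < 0.05) and their concordance, condition-specificity classes.
* **TF footprints**: flank-minus-core insertion scores and permutation
  tests for GC-induced occupancy change (AP-1 loss).
* **CRISPRi screens**: per-sgRNA enrichment with control-based
  normalisation and α-RRA element aggregation (~6.5 sgRNAs/site,
  100 non-targeting controls).
* **Patient integration**: GC-resistance-associated accessibility
  (inter- and intra-subtype, FDR < 0.1), methylation concordance,
  LD fine-mapping (r² > 0.8) of variants into HGRs with allele-specific
  GRE scoring, and the final prioritization funnel down to candidate
  HGR–gene pairs.

The synthetic-data module is part of the library: it generates every
input (BED/FASTA/VCF/TSV) on a toy 3 × 10 Mb genome with planted
effects and records the truth, so every caller can be scored for
calibration and sensitivity. See `docs/methods.md` for the models,
defaults and their rationale.

## Worked example

```bash
python examples/01_differential_response.py
```

```
ATAC 6 h vs 0 h: 78 responsive sites at FDR < 0.01
planted effects: 76; recovered: 76 (100% sensitivity)
median |log2FC| among hits: 1.97 (planted magnitude is 2)
```

The generator planted 76 accessibility changes of magnitude log2FC = 2;
the caller recovers all of them at FDR < 0.01 with two extra calls
(consistent with its calibrated false-positive rate), and the estimated
effect size is unbiased. The other examples walk the remaining
capabilities:

* `02_superenhancers_and_hgrs.py` — SE calling and the HGR/GRE atlas
  (~52% of HGRs carry a discernable GRE at the 0.8 score threshold).
* `03_starr_and_footprints.py` — STARR activity classes, two-caller
  concordance, AP-1 footprint loss at 24 h.
* `04_screen_and_prioritization.py` — screen aggregation and the
  funnel stage counts, ending with the planted showcase locus.
* `05_cohort_finemapping.py` — resistance sites, methylation
  concordance, and fine-mapping a GRE-disrupting variant
  (delta score ≈ −4.1 bits for the planted causal allele).

A thin CLI covers shell use:

```bash
gcregulome simulate --seed 1 --out sim/          # all inputs + truth JSON
gcregulome run-all  --seed 1 --out run/          # full pipeline + manifest
gcregulome default-config                        # YAML of every knob
```

Every run directory contains a `manifest.json` with the seed, all
thresholds and per-stage row counts; rerunning with the same seed is
byte-identical.

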