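"""End-to-end orchestration of a full synthetic run plus configuration.

``run_all`` executes simulate -> differential -> super-enhancers -> HGR
atlas -> loops -> STARR -> footprints -> CRISPRi screen -> cohort ->
prioritization on one seeded synthetic study, writes per-stage TSV/BED
outputs into a run directory and records a provenance manifest (seed,
thresholds, per-stage row counts). All cutoffs live in
``PipelineThresholds`` and are serialized with every run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    crispri_screen,
    diff_counts,
    footprints,
    hgr_atlas,
    intervals,
    loops as loops_mod,
    patient_integration,
    starr_activity,
    superenhancers,
    synthetic_data,
)

__version__ = "0.1.0"


@dataclass
class PipelineThresholds:
    """Every decision cutoff used across the pipeline."""

    chromatin_q: float = 0.01
    deg_q: float = 0.01
    deg_min_fold: float = 2.0
    se_fold: float = 2.0
    se_min_timepoints: int = 2
    loop_q: float = 0.01
    starr_p: float = 0.001
    starr_min_dna: int = 10
    starr_q: float = 0.05
    screen_q: float = 0.05
    resistance_q: float = 0.1
    ld_r2: float = 0.8
    motif_frac: float = 0.8
    promoter_window: int = 2000
    stitch_gap: int = 12500
    lead_variant_q: float = 0.05
    min_subtype_n: int = 4
    rra_alpha: float = 0.05
    n_perm: int = 1000

    def __post_init__(self) -> None:
        for name in ("chromatin_q", "deg_q", "starr_p", "starr_q", "screen_q", "resistance_q"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 < self.ld_r2 <= 1 or not 0 < self.motif_frac <= 1:
            raise ValueError("ld_r2 and motif_frac must lie in (0, 1]")
        if self.stitch_gap < 0 or self.promoter_window < 0:
            raise ValueError("window sizes must be >= 0")


def _peak_frames_by_timepoint(study, assay_mask_col: str) -> dict[float, pd.DataFrame]:
    """Peak interval frames per timepoint for one assay's occupancy mask."""
    peaks = study.genome.peaks
    sub = peaks[peaks[assay_mask_col]] if assay_mask_col else peaks
    return {tp: sub[["chrom", "start", "end", "name"]].copy() for tp in study.config.timepoints}


def run_all(
    cfg: synthetic_data.SimConfig,
    thresholds: PipelineThresholds | None = None,
    outdir: str | Path | None = None,
    write_outputs: bool = True,
) -> dict:
    """Full synthetic run. Returns a dict of stage results + the manifest."""
    thr = thresholds or PipelineThresholds()
    results: dict = {"config": cfg, "thresholds": thr}
    study = synthetic_data.simulate_study(cfg)
    results["study"] = study
    treated = [tp for tp in cfg.timepoints if tp != 0.0]

    # differential chromatin and expression, per treated timepoint vs 0 h
    diff: dict[str, dict[float, pd.DataFrame]] = {}
    for assay in ("atac", "k27", "rna"):
        cm = study.counts[assay]
        per_tp = {}
        for tp in treated:
            ids = list(cm.samples.index[cm.samples["timepoint"].isin([0.0, tp])])
            sub = cm.subset(ids)
            grp = sub.samples["timepoint"].map(lambda t: "treated" if t != 0.0 else "ref")
            sub.samples["group"] = grp
            per_tp[tp] = diff_counts.run_contrast(sub, "group", "treated", "ref")
        diff[assay] = per_tp
    results["diff"] = diff

    def responsive_union(assay, q, min_fold=1.0):
        frames = [
            diff_counts.classify_responsive(diff[assay][tp], q_max=q, min_fold=min_fold)
            for tp in treated
        ]
        allhits = pd.concat(frames).sort_values("q", kind="mergesort")
        return allhits[~allhits.index.duplicated(keep="first")]

    responsive_atac = responsive_union("atac", thr.chromatin_q)
    responsive_k27 = responsive_union("k27", thr.chromatin_q)
    degs = diff_counts.combined_degs(
        {tp: diff["rna"][tp] for tp in (6.0, 24.0) if tp in diff["rna"]},
        q_max=thr.deg_q,
        min_fold=thr.deg_min_fold,
    )
    results["responsive_atac"] = responsive_atac
    results["responsive_k27"] = responsive_k27
    results["degs"] = degs

    # super-enhancers from per-timepoint stitched H3K27ac signal
    peaks = study.genome.peaks
    k27_cm = study.counts["k27"]
    stitched = intervals.stitch(peaks, gap_bp=thr.stitch_gap)
    se_by_tp = {}
    for tp in cfg.timepoints:
        cols = list(k27_cm.samples.index[k27_cm.samples["timepoint"] == tp])
        sig_per_peak = k27_cm.counts[cols].mean(axis=1)
        totals = np.array(
            [sig_per_peak.loc[c].sum() for c in stitched["constituents"]]
        )
        frame = stitched.assign(signal=totals)
        se_by_tp[tp] = superenhancers.rank_and_cutoff(frame)
    gc_se = superenhancers.call_gc_responsive_se(
        se_by_tp,
        min_treated_timepoints=thr.se_min_timepoints,
        fold_threshold=thr.se_fold,
    )
    results["se_by_tp"] = se_by_tp
    results["gc_responsive_se"] = gc_se

    # HGR atlas
    gr_by_tp = _peak_frames_by_timepoint(study, "gr_occupied")
    atac_by_tp = _peak_frames_by_timepoint(study, "")
    k27_by_tp = _peak_frames_by_timepoint(study, "k27_positive")
    hgrs = hgr_atlas.call_hgrs(gr_by_tp, atac_by_tp, k27_by_tp)
    # HGRs inherit the GR-peak names; sequences are keyed by source peak
    hgr_seqs = {}
    for _, row in hgrs.iterrows():
        src = row["source_peaks"][0]
        hgr_seqs[row["name"]] = study.genome.sequences[src]
    hgrs = hgr_atlas.annotate_gre(hgrs, hgr_seqs, study.genome.pwm, thr.motif_frac)
    enh_ids = set(responsive_atac.index[responsive_atac["direction"] == "enhanced"]) | set(
        responsive_k27.index[responsive_k27["direction"] == "enhanced"]
    )
    hgrs["enhanced"] = [
        any(p in enh_ids for p in srcs) for srcs in hgrs["source_peaks"]
    ]
    results["hgrs"] = hgrs
    results["hgr_sequences"] = hgr_seqs
    try:
        results["gre_enrichment"] = hgr_atlas.gre_response_enrichment(hgrs)
    except ValueError:
        results["gre_enrichment"] = None

    # loops
    annotated = loops_mod.annotate_loops(
        study.loops, study.genome.genes, promoter_window_bp=thr.promoter_window, q_max=thr.loop_q
    )
    k27_sites = peaks.set_index("name").loc[responsive_k27.index].reset_index(names="name")
    k27_sites["direction"] = responsive_k27["direction"].to_numpy()
    results["loops_annotated"] = annotated
    results["loop_linkage"] = loops_mod.loop_deg_linkage(annotated, degs, k27_sites, hgrs)

    # STARR
    ds = starr_activity.downsample_libraries(study.starr["rna_merged"], seed=cfg.seed)
    binom = {
        cond: starr_activity.call_active_binomial(
            study.starr["dna"], ds[cond], p_max=thr.starr_p, min_dna=thr.starr_min_dna
        )
        for cond in ds.columns
    }
    classes = starr_activity.classify_condition_specificity(
        binom["0h"]["active"], binom["6h"]["active"], binom["24h"]["active"]
    )
    countmodel = starr_activity.call_active_countmodel(
        study.starr["rna_replicates"]["24h"], study.starr["input_replicates"], q_max=thr.starr_q
    )
    gre_flags = peaks.set_index("name")["has_gre_planted"]
    results["starr"] = {
        "binomial": binom,
        "classes": classes,
        "countmodel": countmodel,
        "concordance": starr_activity.concordance(
            countmodel["active"], binom["24h"]["active"]
        ),
        "tests": starr_activity.starr_enrichment_tests(
            classes,
            set(responsive_atac.index),
            gre_flags,
            degs,
            regions=peaks,
            genes=study.genome.genes,
        ),
    }

    # footprints
    fp = footprints.differential_footprint(
        study.footprints, n_perm=thr.n_perm, seed=cfg.seed
    )
    ap1_flag = peaks.set_index("name")["ap1"]
    reduced_flag = pd.Series(False, index=ap1_flag.index)
    red_ids = responsive_atac.index[responsive_atac["direction"] == "reduced"]
    reduced_flag.loc[reduced_flag.index.intersection(red_ids)] = True
    results["footprints"] = fp
    results["ap1_test"] = footprints.ap1_site_depletion_test(ap1_flag, reduced_flag)

    # CRISPRi screen
    enr = crispri_screen.sgrna_enrichment(
        study.screen["counts"], study.screen["arms"], site_map=study.screen["site_map"]
    )
    agg = crispri_screen.aggregate_sites_rra(
        enr,
        study.screen["site_map"],
        alpha=thr.rra_alpha,
        n_perm=thr.n_perm,
        seed=cfg.seed,
    )
    candidates = crispri_screen.select_candidate_sites(agg, peaks, hgrs)
    results["screen"] = {"sgrna": enr, "aggregate": agg, "candidates": candidates}

    # cohort analyses
    cohort = study.cohort
    labels = patient_integration.stratify_resistance(cohort, "provided_labels")
    res_sites = patient_integration.resistance_accessibility(
        cohort, labels, q_max=thr.resistance_q, min_subtype_n=thr.min_subtype_n
    )
    per_probe, meth_frac = patient_integration.methylation_concordance(
        res_sites, peaks, cohort, labels
    )
    hgr_enrich = patient_integration.hgr_resistance_enrichment(res_sites, peaks, hgrs)
    assoc = patient_integration.variant_phenotype_association(
        cohort.dosages, cohort.samples["phenotype"]
    )
    # fine-mapping scores alleles against source GR peak sequences
    hgr_by_src = {}
    for _, row in hgrs.iterrows():
        for src in row["source_peaks"]:
            hgr_by_src[src] = row["name"]
    src_peaks = peaks[peaks["name"].isin(hgr_by_src)][["chrom", "start", "end", "name"]]
    finemapped = patient_integration.finemap_to_hgrs(
        assoc,
        cohort.dosages,
        cohort.variants,
        src_peaks,
        study.genome.sequences,
        study.genome.pwm,
        lead_q_max=thr.lead_variant_q,
        r2_min=thr.ld_r2,
    )
    results["cohort"] = {
        "labels": labels,
        "resistance_sites": res_sites,
        "methylation_concordance": meth_frac,
        "methylation_per_probe": per_probe,
        "hgr_enrichment": hgr_enrich,
        "association": assoc,
        "finemapped": finemapped,
    }

    # prioritization funnel
    prioritized, stage_counts = patient_integration.prioritize_hgrs(
        candidates, peaks, study.genome.genes, degs, study.truth.resistance_gene_list
    )
    results["prioritized"] = prioritized
    results["funnel_counts"] = stage_counts

    manifest = {
        "seed": cfg.seed,
        "version": __version__,
        "thresholds": asdict(thr),
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "stage_rows": {
            "peaks": len(peaks),
            "genes": len(study.genome.genes),
            "responsive_atac": len(responsive_atac),
            "responsive_k27": len(responsive_k27),
            "degs": len(degs),
            "gc_responsive_se": len(gc_se),
            "hgrs": len(hgrs),
            "loops": len(annotated),
            "starr_gc_active": int(classes.isin(["GC_specific", "shared"]).sum()),
            "screen_sites": len(agg),
            "screen_candidates": len(candidates),
            "resistance_sites": len(res_sites),
            "finemapped_variants": len(finemapped),
            "prioritized_hgrs": stage_counts["top_hgrs"],
            "prioritized_genes": stage_counts["linked_genes"],
        },
        "funnel_counts": stage_counts,
    }
    results["manifest"] = manifest

    if write_outputs and outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        synthetic_data.write_study(study, out / "inputs")
        for assay in diff:
            for tp, res in diff[assay].items():
                res.to_csv(out / f"diff_{assay}_{tp:g}h.tsv", sep="\t")
        degs.to_csv(out / "degs.tsv", sep="\t")
        gc_se.to_csv(out / "gc_responsive_se.tsv", sep="\t", index=False)
        if len(gc_se):
            intervals.write_bed(gc_se[["chrom", "start", "end", "name"]], out / "gc_responsive_se.bed")
        superenhancers.hockey_stick_table(se_by_tp[treated[-1]]).to_csv(
            out / f"se_hockey_{treated[-1]:g}h.tsv", sep="\t", index=False
        )
        hgrs.drop(columns=["timepoints", "source_peaks"]).to_csv(
            out / "hgrs.tsv", sep="\t", index=False
        )
        intervals.write_bed(hgrs[["chrom", "start", "end", "name"]], out / "hgrs.bed")
        annotated.drop(columns=["genesA", "genesB"]).to_csv(
            out / "loops_annotated.tsv", sep="\t", index=False
        )
        classes.to_frame().to_csv(out / "starr_classes.tsv", sep="\t")
        fp.to_csv(out / "footprints.tsv", sep="\t")
        agg.to_csv(out / "screen_sites.tsv", sep="\t")
        res_sites.drop(columns=["arms"], errors="ignore").to_csv(
            out / "resistance_sites.tsv", sep="\t"
        )
        finemapped.to_csv(out / "finemapped_variants.tsv", sep="\t")
        prioritized.to_csv(out / "prioritized_hgrs.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return results
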