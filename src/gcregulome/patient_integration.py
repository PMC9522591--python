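"""Patient-cohort integration: resistance-associated accessibility,
methylation concordance, LD fine-mapping with allele-specific GRE
scoring, and the final HGR prioritization funnel.

The cohort carries per-patient subtype labels, a continuous ex vivo drug
sensitivity phenotype (metric-agnostic; larger = more resistant),
accessibility counts over the peak universe, CpG methylation betas,
genotype dosages and gene expression. Resistance-associated sites come
from NB contrasts of resistant vs sensitive patients run inter-subtype
(all samples) and intra-subtype (each subtype with enough samples);
fine-mapping expands phenotype-associated lead variants by LD proxies
(r^2 > 0.8) and keeps those falling inside HGRs, scoring the ref/alt
alleles against the GRE matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals
from .diff_counts import CountMatrix, classify_responsive, run_contrast
from .hgr_atlas import PWM, scan_pwm
from .stats_core import ContingencyTable2x2, bh_fdr, fisher_exact


@dataclass
class Cohort:
    """Patient-level multi-omic bundle; all frames share the sample axis."""

    samples: pd.DataFrame  # index: sample id; columns: subtype, phenotype[, resistance_class]
    accessibility: CountMatrix
    methylation: pd.DataFrame | None = None  # rows: probes (chrom,pos + per-sample betas)
    dosages: pd.DataFrame | None = None  # variants x samples in {0,1,2}
    variants: pd.DataFrame | None = None  # variant id -> chrom, pos (0-based), ref, alt
    expression: CountMatrix | None = None

    def __post_init__(self) -> None:
        if self.methylation is not None:
            betas = self.methylation[self.sample_ids].to_numpy(dtype=float)
            if ((betas < 0) | (betas > 1)).any():
                raise ValueError("methylation betas must lie in [0, 1]")
        if self.dosages is not None:
            d = self.dosages.to_numpy()
            if not np.isin(d, [0, 1, 2]).all():
                raise ValueError("dosages must be 0/1/2")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)


def stratify_resistance(cohort: Cohort, rule: str = "median_split") -> pd.Series:
    """Deterministic sensitive/resistant class labels from the phenotype.

    Rules: ``median_split`` (>= median is resistant), ``threshold:<v>``,
    or ``provided_labels`` (pass-through of the resistance_class column).
    Both classes must be non-empty.
    """
    pheno = cohort.samples["phenotype"]
    if rule == "median_split":
        labels = np.where(pheno >= pheno.median(), "resistant", "sensitive")
    elif rule.startswith("threshold:"):
        thr = float(rule.split(":", 1)[1])
        if not pheno.min() <= thr <= pheno.max():
            raise ValueError(f"threshold {thr} outside phenotype range")
        labels = np.where(pheno >= thr, "resistant", "sensitive")
    elif rule == "provided_labels":
        labels = cohort.samples["resistance_class"].to_numpy()
    else:
        raise ValueError(f"unknown stratification rule {rule!r}")
    out = pd.Series(labels, index=pheno.index, name="resistance_class")
    if out.nunique() < 2:
        raise ValueError("degenerate split: one class is empty")
    return out


def resistance_accessibility(
    cohort: Cohort,
    labels: pd.Series,
    q_max: float = 0.1,
    min_subtype_n: int = 4,
) -> pd.DataFrame:
    """Resistance-associated accessibility sites, inter- and intra-subtype.

    Runs the resistant-vs-sensitive NB contrast on all samples and within
    every subtype with >= ``min_subtype_n`` samples (and both classes
    represented); returns the union of q < q_max sites with arm
    provenance and direction (``occluded_in_resistant`` when log2fc < 0).
    """
    arms: dict[str, list[str]] = {"inter_subtype": cohort.sample_ids}
    for subtype, grp in cohort.samples.groupby("subtype"):
        if len(grp) >= min_subtype_n:
            arms[f"intra_subtype:{subtype}"] = list(grp.index)
    frames = []
    for arm, ids in arms.items():
        sub_labels = labels.loc[ids]
        if sub_labels.nunique() < 2 or sub_labels.value_counts().min() < 2:
            warnings.warn(f"arm {arm}: fewer than 2 samples per class; skipped", stacklevel=2)
            continue
        cm = CountMatrix(
            cohort.accessibility.counts[ids],
            cohort.accessibility.samples.loc[ids].assign(resistance=sub_labels),
        )
        res = run_contrast(cm, "resistance", "resistant", "sensitive")
        hits = classify_responsive(res, q_max=q_max, min_fold=1.0).copy()
        hits["arm"] = arm
        frames.append(hits)
    if not frames:
        return pd.DataFrame(columns=["log2fc", "q", "direction", "arm"])
    allhits = pd.concat(frames)
    allhits["direction"] = np.where(
        allhits["log2fc"] < 0, "occluded_in_resistant", "open_in_resistant"
    )
    allhits = allhits.sort_values("q", kind="mergesort")
    first = allhits[~allhits.index.duplicated(keep="first")].copy()
    arms_per_site = allhits.groupby(level=0)["arm"].apply(lambda s: tuple(sorted(set(s))))
    first["arms"] = arms_per_site.loc[first.index]
    return first


def methylation_concordance(
    resistance_sites: pd.DataFrame,
    site_intervals: pd.DataFrame,
    cohort: Cohort,
    labels: pd.Series,
) -> tuple[pd.DataFrame, float]:
    """Per-probe accessibility/methylation consistency at resistance sites.

    A CpG probe overlapping a resistance site is consistent when the sign
    of (mean beta in resistant - sensitive) opposes the sign of the
    site's accessibility log2fc (closed chromatin <-> gained
    methylation). Probes at sites with zero accessibility difference are
    excluded from the denominator. Returns (per-probe frame, overall
    fraction); the fraction is NaN when no probe overlaps.
    """
    if cohort.methylation is None:
        raise ValueError("cohort has no methylation data")
    meth = cohort.methylation
    probes = intervals.make_peaks(
        pd.DataFrame(
            {
                "chrom": meth["chrom"],
                "start": meth["pos"],
                "end": meth["pos"] + 1,
                "name": meth.index,
            }
        )
    )
    sites = site_intervals.set_index("name")
    keep = sites.index.intersection(resistance_sites.index)
    if len(keep) == 0:
        warnings.warn("no resistance-site intervals found", stacklevel=2)
        return pd.DataFrame(), np.nan
    site_frame = sites.loc[keep].reset_index(names="name")
    pairs = intervals.intersect(probes, intervals.make_peaks(site_frame))
    if pairs.empty:
        warnings.warn("no CpG probe overlaps a resistance site", stacklevel=2)
        return pd.DataFrame(), np.nan
    res_ids = labels.index[labels == "resistant"]
    sen_ids = labels.index[labels == "sensitive"]
    rows = []
    for _, pr in pairs.iterrows():
        probe, site = pr["name_a"], pr["name_b"]
        l2fc = resistance_sites.at[site, "log2fc"]
        if l2fc == 0:
            continue
        betas = meth.loc[probe]
        dbeta = betas[res_ids].astype(float).mean() - betas[sen_ids].astype(float).mean()
        if dbeta == 0:
            continue
        rows.append(
            {
                "probe": probe,
                "site": site,
                "delta_beta": float(dbeta),
                "site_log2fc": float(l2fc),
                "consistent": bool(np.sign(dbeta) == -np.sign(l2fc)),
            }
        )
    per_probe = pd.DataFrame(rows)
    frac = float(per_probe["consistent"].mean()) if len(per_probe) else np.nan
    return per_probe, frac


def hgr_resistance_enrichment(
    resistance_sites: pd.DataFrame,
    all_peaks: pd.DataFrame,
    hgrs: pd.DataFrame,
) -> tuple[ContingencyTable2x2, float, float]:
    """Fisher test: resistance sites vs other peaks, HGR overlap vs not."""
    peaks = intervals.make_peaks(all_peaks)
    is_res = peaks["name"].isin(resistance_sites.index).to_numpy()
    if not is_res.any() or is_res.all():
        raise ValueError("resistance and non-resistance strata must both be non-empty")
    hits = intervals.overlaps_any(peaks, hgrs)
    t = ContingencyTable2x2(
        int((is_res & hits).sum()),
        int((is_res & ~hits).sum()),
        int((~is_res & hits).sum()),
        int((~is_res & ~hits).sum()),
    )
    odds, p = fisher_exact(t)
    return t, odds, p


def ld_r2(g1, g2) -> float:
    """Squared Pearson correlation of dosage vectors (composite LD).

    Pairs with a missing value on either side are dropped; needs >= 3
    complete pairs; returns NaN when either vector is constant.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~(np.isnan(g1) | np.isnan(g2))
    if ok.sum() < 3:
        raise ValueError("need >= 3 non-missing dosage pairs")
    x, y = g1[ok], g2[ok]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def variant_phenotype_association(
    dosages: pd.DataFrame, outcome: pd.Series
) -> pd.DataFrame:
    """Per-variant additive OLS of the outcome on dosage (beta, p, BH q).

    Monomorphic variants get NaN. The outcome may be the resistance
    phenotype or (log-) expression of a gene (eQTL use).
    """
    y = outcome.loc[dosages.columns].to_numpy(dtype=float)
    if len(y) < 8:
        raise ValueError("need n >= 8 samples")
    rows = []
    for vid, g in dosages.iterrows():
        x = g.to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            rows.append({"variant": vid, "beta": np.nan, "p": np.nan})
            continue
        res = stats.linregress(x, y)
        rows.append({"variant": vid, "beta": float(res.slope), "p": float(res.pvalue)})
    out = pd.DataFrame(rows).set_index("variant")
    ok = out["p"].notna()
    q = pd.Series(np.nan, index=out.index)
    if ok.any():
        q[ok] = bh_fdr(out.loc[ok, "p"])
    out["q"] = q
    return out


def allele_delta_score(
    hgr_seq: str,
    variant_offset: int,
    ref: str,
    alt: str,
    pwm: PWM,
) -> float:
    """Best-PWM-score difference, alt minus ref, over the HGR window.

    ``variant_offset`` is the 0-based position of the variant within
    ``hgr_seq``; the reference base there must match ``ref``. Negative
    values mean the alternative allele disrupts the motif.
    """
    if hgr_seq[variant_offset].upper() != ref.upper():
        raise ValueError(
            f"reference mismatch at offset {variant_offset}: "
            f"sequence has {hgr_seq[variant_offset]!r}, expected {ref!r}"
        )
    alt_seq = hgr_seq[:variant_offset] + alt.upper() + hgr_seq[variant_offset + 1 :]
    ref_hit = scan_pwm(hgr_seq, pwm, threshold_frac=0.0)
    alt_hit = scan_pwm(alt_seq, pwm, threshold_frac=0.0)
    if ref_hit is None or alt_hit is None:
        return np.nan
    return float(alt_hit.score - ref_hit.score)


def finemap_to_hgrs(
    assoc: pd.DataFrame,
    dosages: pd.DataFrame,
    variants: pd.DataFrame,
    hgrs: pd.DataFrame,
    sequences: dict[str, str],
    pwm: PWM,
    lead_q_max: float = 0.05,
    r2_min: float = 0.8,
) -> pd.DataFrame:
    """LD-expanded fine-mapping of phenotype-associated variants to HGRs.

    Leads = variants with association q < ``lead_q_max``; each lead is
    expanded by proxies with r^2 > ``r2_min``; lead/proxy variants whose
    position lies inside an HGR are retained and scored for allele-level
    GRE disruption (alt - ref best PWM score over the HGR sequence).
    Variants without sequence coverage are skipped with a warning.
    Output order is independent of lead enumeration order.
    """
    lead_ids = list(assoc.index[(assoc["q"] < lead_q_max) & assoc["q"].notna()])
    candidates: dict[str, dict] = {}
    for lead in lead_ids:
        g_lead = dosages.loc[lead].to_numpy(dtype=float)
        for vid, g in dosages.iterrows():
            if vid == lead:
                r2 = 1.0
            else:
                r2 = ld_r2(g_lead, g.to_numpy(dtype=float))
            if vid == lead or (not np.isnan(r2) and r2 > r2_min):
                prev = candidates.get(vid)
                entry = {
                    "lead": lead,
                    "r2_to_lead": 1.0 if vid == lead else float(r2),
                    "is_lead": vid == lead,
                }
                if prev is None or entry["r2_to_lead"] > prev["r2_to_lead"] or entry["is_lead"]:
                    candidates[vid] = entry
    if not candidates:
        return pd.DataFrame(
            columns=["lead", "r2_to_lead", "is_lead", "hgr", "delta_score", "beta", "p", "q"]
        )
    hgr_sorted = intervals.make_peaks(hgrs)
    rows = []
    for vid in sorted(candidates):
        info = candidates[vid]
        var = variants.loc[vid]
        vframe = pd.DataFrame(
            [{"chrom": var["chrom"], "start": int(var["pos"]), "end": int(var["pos"]) + 1, "name": vid}]
        )
        hit = intervals.intersect(vframe, hgr_sorted)
        if hit.empty:
            continue
        hgr_name = hit.iloc[0]["name_b"]
        hrow = hgr_sorted.set_index("name").loc[hgr_name]
        seq = sequences.get(hgr_name)
        if seq is None:
            warnings.warn(f"{vid}: no sequence for HGR {hgr_name}; skipped", stacklevel=2)
            continue
        offset = int(var["pos"]) - int(hrow["start"])
        delta = allele_delta_score(seq, offset, var["ref"], var["alt"], pwm)
        arow = assoc.loc[vid] if vid in assoc.index else None
        rows.append(
            {
                "variant": vid,
                "lead": info["lead"],
                "r2_to_lead": info["r2_to_lead"],
                "is_lead": info["is_lead"],
                "hgr": hgr_name,
                "delta_score": delta,
                "beta": float(arow["beta"]) if arow is not None else np.nan,
                "p": float(arow["p"]) if arow is not None else np.nan,
                "q": float(arow["q"]) if arow is not None else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("variant") if rows else pd.DataFrame(
        columns=["lead", "r2_to_lead", "is_lead", "hgr", "delta_score", "beta", "p", "q"]
    )


def prioritize_hgrs(
    candidates: pd.DataFrame,
    site_intervals: pd.DataFrame,
    genes: pd.DataFrame,
    degs: pd.DataFrame,
    resistance_genes: list[str] | pd.Series,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """The integrative prioritization funnel.

    Stages: CRISPRi candidate sites (mean log2fc > 0, HGR-overlapping,
    from crispri_screen.select_candidate_sites) -> region-to-gene
    association (basal-plus-extension rule) -> keep pairs whose gene is a
    GC-responsive DEG -> keep pairs whose gene is in the supplied
    resistance gene list. Returns the surviving (HGR site, gene) table
    ranked by screen mean log2fc, plus per-stage survivor counts.
    """
    res_genes = set(resistance_genes)
    if not res_genes:
        raise ValueError("resistance gene list is empty")
    stage_counts = {"crispri_candidates": len(candidates)}
    si = site_intervals.set_index("name")
    keep = si.index.intersection(candidates.index)
    regions = si.loc[keep].reset_index(names="name")
    assoc = (
        intervals.associate_regions_to_genes(regions, genes)
        if len(regions)
        else pd.DataFrame(columns=["name", "gene_id"])
    )
    stage_counts["gene_associated"] = assoc["name"].nunique()
    deg_ids = set(degs.index)
    assoc_deg = assoc[assoc["gene_id"].isin(deg_ids)]
    stage_counts["deg_linked"] = assoc_deg["name"].nunique()
    final = assoc_deg[assoc_deg["gene_id"].isin(res_genes)].copy()
    stage_counts["resistance_gene_linked"] = final["name"].nunique()
    if len(final):
        final["mean_log2fc"] = candidates.loc[final["name"], "mean_log2fc"].to_numpy()
        final = final.sort_values("mean_log2fc", ascending=False).reset_index(drop=True)
    else:
        final = final.assign(mean_log2fc=pd.Series(dtype=float))
    stage_counts["top_hgrs"] = final["name"].nunique()
    stage_counts["linked_genes"] = final["gene_id"].nunique()
    return final, stage_counts
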