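"""ATAC-STARR-seq activity calling and condition classification.

Activity = RNA output over-representation relative to DNA plasmid input.
Two callers are provided and cross-checked: a per-region binomial upper
tail on the merged RNA library against the DNA input proportions
(p < 0.001, DNA coverage >= 10), and a replicate count-model caller that
contrasts RNA output replicates against pooled input replicates through
the NB differential machinery (FDR < 0.05, positive fold change).
RNA libraries are first downsampled to equal totals so treatment
conditions are comparable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diff_counts import CountMatrix, run_contrast
from .stats_core import (
    ContingencyTable2x2,
    binomial_upper_tail_vec,
    fisher_exact,
    ks_two_sample,
)
from . import intervals
from scipy import stats as _sp_stats


def downsample_libraries(
    rna_counts: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Equalise RNA library totals by sampling reads without replacement.

    Each column (condition library) is reduced to the minimum column total
    via a seeded multivariate hypergeometric draw over its read units, so
    totals are exactly equal afterwards and expected per-region
    proportions are preserved. Columns already at the minimum pass
    through unchanged; a zero-total library is an error.
    """
    if rna_counts.shape[1] < 2:
        raise ValueError("need >= 2 condition libraries")
    totals = rna_counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("zero-total RNA library cannot be downsampled")
    target = int(totals.min())
    rng = np.random.default_rng(seed)
    out = {}
    for col in rna_counts.columns:
        counts = rna_counts[col].to_numpy(dtype=np.int64)
        if counts.sum() == target:
            out[col] = counts
        else:
            out[col] = rng.multivariate_hypergeometric(counts, target, method="marginals")
    return pd.DataFrame(out, index=rna_counts.index)


def call_active_binomial(
    dna_counts: pd.Series,
    rna_counts: pd.Series,
    p_max: float = 0.001,
    min_dna: int = 10,
) -> pd.DataFrame:
    """Per-region binomial test of RNA output against DNA input proportion.

    For region r: x = RNA count, n = total RNA reads, p0 = DNA_r / DNA
    total; active iff P(X >= x) < p_max and DNA_r >= min_dna.
    """
    dna = dna_counts.to_numpy(dtype=float)
    rna = rna_counts.loc[dna_counts.index].to_numpy(dtype=float)
    n_total = rna.sum()
    dna_total = dna.sum()
    p0 = np.clip(dna / dna_total, 1e-12, 1 - 1e-12)
    p = binomial_upper_tail_vec(rna, int(n_total), p0)
    out = pd.DataFrame(
        {
            "dna_count": dna,
            "rna_count": rna,
            "p": p,
            "active": (p < p_max) & (dna >= min_dna),
        },
        index=dna_counts.index,
    )
    return out


def call_active_countmodel(
    rna_replicates: pd.DataFrame,
    input_replicates: pd.DataFrame,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Replicate count-model caller: NB contrast of RNA output vs pooled input."""
    if rna_replicates.shape[1] < 2 or input_replicates.shape[1] < 2:
        raise ValueError("need >= 2 replicates on each side")
    counts = pd.concat([rna_replicates, input_replicates], axis=1)
    samples = pd.DataFrame(
        {
            "arm": ["rna"] * rna_replicates.shape[1] + ["input"] * input_replicates.shape[1]
        },
        index=list(rna_replicates.columns) + list(input_replicates.columns),
    )
    res = run_contrast(CountMatrix(counts, samples), "arm", "rna", "input")
    res["active"] = (res["q"] < q_max) & (res["log2fc"] > 0)
    return res


def classify_condition_specificity(
    active_0h: pd.Series, active_6h: pd.Series, active_24h: pd.Series
) -> pd.Series:
    """Region classes from per-condition activity calls on a shared universe.

    GC-active = union(6 h, 24 h). Classes: ``GC_specific`` (GC-active,
    not 0 h), ``0h_specific`` (0 h only), ``shared`` (both), ``inactive``.
    The three inputs are boolean Series over the same region index, so
    overlap reduces to identity of region ids.
    """
    idx = active_0h.index
    gc = active_6h.reindex(idx, fill_value=False) | active_24h.reindex(idx, fill_value=False)
    zero = active_0h.astype(bool)
    cls = pd.Series("inactive", index=idx, name="class")
    cls[gc & ~zero] = "GC_specific"
    cls[~gc & zero] = "0h_specific"
    cls[gc & zero] = "shared"
    return cls


def starr_enrichment_tests(
    classes: pd.Series,
    responsive_ids: set,
    gre_flags: pd.Series,
    degs: pd.DataFrame,
    regions: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
) -> dict:
    """Downstream battery on classified STARR regions.

    (i) Fisher: GC-responsive chromatin x GC-active STARR activity;
    (ii) chi-square on the GRE fraction, GC-specific vs 0h-specific
    classes, with the fold ratio;
    (iii) KS on distances to upregulated-DEG TSSs, GC-specific vs
    0h-specific (requires ``regions`` and ``genes``).
    Tests whose class is empty are skipped (result None) with a warning.
    """
    import warnings

    results: dict = {}
    gc_active = classes.isin(["GC_specific", "shared"])
    responsive = classes.index.isin(list(responsive_ids))
    if gc_active.any() and (~gc_active).any():
        t = ContingencyTable2x2(
            int((responsive & gc_active).sum()),
            int((responsive & ~gc_active).sum()),
            int((~responsive & gc_active).sum()),
            int((~responsive & ~gc_active).sum()),
        )
        odds, p = fisher_exact(t)
        results["responsive_fisher"] = {"table": t, "odds_ratio": odds, "p": p}
    else:
        warnings.warn("GC-active class empty; Fisher test skipped", stacklevel=2)
        results["responsive_fisher"] = None

    gc_spec = classes == "GC_specific"
    zero_spec = classes == "0h_specific"
    if gc_spec.any() and zero_spec.any():
        g = gre_flags.reindex(classes.index).fillna(False).astype(bool)
        a, b = int((g & gc_spec).sum()), int((~g & gc_spec).sum())
        c, d = int((g & zero_spec).sum()), int((~g & zero_spec).sum())
        frac_gc = a / (a + b)
        frac_0h = c / (c + d) if (c + d) else np.nan
        chi2, p, *_ = _sp_stats.chi2_contingency([[a, b], [c, d]], correction=False)
        fold = frac_gc / frac_0h if frac_0h else np.inf
        results["gre_chi2"] = {
            "chi2": float(chi2),
            "p": float(p),
            "fold": float(fold),
            "frac_gc_specific": frac_gc,
            "frac_0h_specific": frac_0h,
        }
    else:
        warnings.warn("a specificity class is empty; chi-square skipped", stacklevel=2)
        results["gre_chi2"] = None

    results["deg_distance_ks"] = None
    if regions is not None and genes is not None:
        up_genes = genes[genes["gene_id"].isin(degs.index[degs["direction"] == "enhanced"])]
        r = regions.set_index("name")
        gc_regions = r.loc[r.index.intersection(classes.index[gc_spec])].reset_index(names="name")
        z_regions = r.loc[r.index.intersection(classes.index[zero_spec])].reset_index(names="name")
        if len(gc_regions) >= 2 and len(z_regions) >= 2 and len(up_genes) >= 1:
            d_gc = intervals.nearest_tss_distance(gc_regions, up_genes)["distance"].abs().dropna()
            d_0h = intervals.nearest_tss_distance(z_regions, up_genes)["distance"].abs().dropna()
            D, p = ks_two_sample(d_gc, d_0h)
            results["deg_distance_ks"] = {
                "D": D,
                "p": p,
                "median_gc": float(d_gc.median()),
                "median_0h": float(d_0h.median()),
            }
    return results


def concordance(countmodel_active: pd.Series, binomial_active: pd.Series) -> float:
    """Fraction of count-model actives also called by the binomial route."""
    cm = countmodel_active[countmodel_active].index
    if len(cm) == 0:
        return np.nan
    b = binomial_active.reindex(cm).fillna(False)
    return float(b.mean())
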