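"""CRISPRi tiling-screen analysis: per-sgRNA enrichment and alpha-RRA
element aggregation.

After drug selection, sgRNAs silencing resistance-relevant elements are
enriched over baseline. Per-sgRNA enrichment is the NB contrast
post-selection vs baseline; element (GR-site) aggregation follows the
modified robust-rank-aggregation scheme: with a site's sgRNA percentile
ranks r(1) <= ... <= r(k), rho = min over the first j_max order
statistics of BetaCDF(r(j); j, k-j+1), where j_max counts sgRNAs with
one-sided enrichment p below alpha (rho = 1 when none qualify). Site
significance comes from a seeded permutation of sgRNA rank assignments;
sites are ranked by mean sgRNA log2 fold change, with rho and its
permutation p as companion evidence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diff_counts import CountMatrix, estimate_dispersion, nb_wald_test, run_contrast, size_factors
from .stats_core import bh_fdr
from . import intervals

CONTROL_SITE = "control"


def sgrna_enrichment(
    counts: pd.DataFrame, arms: pd.Series, site_map: pd.Series | None = None
) -> pd.DataFrame:
    """Per-sgRNA NB contrast of post-selection vs baseline counts.

    ``counts``: sgRNA x sample matrix; ``arms``: sample -> {baseline,
    post}. When ``site_map`` identifies non-targeting controls, library
    size factors are estimated on the control sgRNAs alone, which removes
    the composition bias a large enriched fraction would otherwise leave
    in every null sgRNA. Adds a one-sided enrichment p (``p_enrich``)
    used for RRA and an ``enriched`` flag (one-sided BH q < 0.05,
    log2fc > 0).
    """
    ctrl_ids = None
    if site_map is not None:
        flagged = site_map.reindex(counts.index) == CONTROL_SITE
        if flagged.sum() >= 10:
            ctrl_ids = list(counts.index[flagged])
    if ctrl_ids is None:
        samples = pd.DataFrame({"arm": arms})
        res = run_contrast(CountMatrix(counts, samples), "arm", "post", "baseline")
    else:
        factors = size_factors(counts.loc[ctrl_ids])
        disp = estimate_dispersion(counts, factors, groups=arms)
        res = nb_wald_test(counts, factors, disp, arms, "post", "baseline")
    res["p_enrich"] = stats.norm.sf(res["wald_stat"])
    res["q_enrich"] = bh_fdr(res["p_enrich"])
    res["enriched"] = (res["q_enrich"] < 0.05) & (res["log2fc"] > 0)
    return res


def _rho(sorted_ranks: np.ndarray, j_max: int) -> float:
    k = len(sorted_ranks)
    if j_max <= 0:
        return 1.0
    j = np.arange(1, j_max + 1)
    return float(stats.beta.cdf(sorted_ranks[:j_max], j, k - j + 1).min())


def aggregate_sites_rra(
    enrichment: pd.DataFrame,
    site_map: pd.Series,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Alpha-RRA aggregation of sgRNA enrichment to the element level.

    ``enrichment``: per-sgRNA frame with ``p_enrich`` and ``log2fc``;
    ``site_map``: sgRNA -> site id (controls mapped to ``control`` are
    excluded from site aggregation but retained in the rank pool).
    Percentile ranks are assigned by ascending (p, sgRNA id) so ties are
    broken deterministically. The permutation p for a site with k sgRNAs
    draws k ranks (and their alpha flags) at random from the pool,
    n_perm times. Output is sorted by mean log2fc, descending.
    """
    sg = enrichment.copy()
    sg["site"] = site_map.reindex(sg.index)
    if sg["site"].isna().any():
        raise ValueError("every sgRNA needs a site mapping (controls -> 'control')")
    order = sg.loc[sorted(sg.index, key=lambda i: (sg.at[i, "p_enrich"], str(i)))]
    m = len(order)
    ranks = pd.Series((np.arange(m) + 1) / m, index=order.index)
    passing = pd.Series(order["p_enrich"].to_numpy() < alpha, index=order.index)

    rng = np.random.default_rng(seed)
    rank_pool = ranks.to_numpy()
    pass_pool = passing.to_numpy()
    rows = []
    targeting = sg[sg["site"] != CONTROL_SITE]
    if (targeting.groupby("site").size() == 0).any():
        raise ValueError("site with zero sgRNAs")
    perm_cache: dict[int, np.ndarray] = {}
    for site, grp in targeting.groupby("site"):
        k = len(grp)
        r = np.sort(ranks.loc[grp.index].to_numpy())
        j_max = int(passing.loc[grp.index].sum())
        rho = _rho(r, j_max)
        if k not in perm_cache:
            null = np.empty(n_perm)
            for b in range(n_perm):
                pick = rng.choice(m, size=k, replace=False)
                null[b] = _rho(np.sort(rank_pool[pick]), int(pass_pool[pick].sum()))
            perm_cache[k] = null
        null = perm_cache[k]
        p_site = (1 + np.sum(null <= rho)) / (n_perm + 1)
        rows.append(
            {
                "site": site,
                "n_sgrnas": k,
                "mean_log2fc": float(grp["log2fc"].mean()),
                "rra_rho": rho,
                "p": p_site,
            }
        )
    out = pd.DataFrame(rows).set_index("site")
    out["q"] = bh_fdr(out["p"])
    return out.sort_values("mean_log2fc", ascending=False)


def control_pseudo_sites(
    enrichment: pd.DataFrame,
    site_map: pd.Series,
    k: int = 5,
    n_groups: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Random k-sgRNA pseudo-groups of control sgRNAs, summarised like sites.

    Used to check that non-targeting controls sit near the centre of the
    element ranking rather than at its extremes.
    """
    rng = np.random.default_rng(seed)
    ctrl = enrichment.index[site_map.reindex(enrichment.index) == CONTROL_SITE]
    if len(ctrl) < k:
        raise ValueError("not enough control sgRNAs")
    rows = []
    for g in range(n_groups):
        pick = rng.choice(len(ctrl), size=k, replace=False)
        grp = enrichment.loc[ctrl[pick]]
        rows.append({"site": f"ctrl_group_{g}", "mean_log2fc": float(grp["log2fc"].mean())})
    return pd.DataFrame(rows).set_index("site")


def select_candidate_sites(
    aggregates: pd.DataFrame,
    site_intervals: pd.DataFrame,
    hgrs: pd.DataFrame,
) -> pd.DataFrame:
    """CRISPRi-enriched sites (mean log2fc > 0) whose interval overlaps an HGR."""
    pos = aggregates[aggregates["mean_log2fc"] > 0]
    si = site_intervals.set_index("name")
    keep_idx = si.index.intersection(pos.index)
    cand = si.loc[keep_idx].reset_index(names="name")
    if len(cand) == 0 or len(hgrs) == 0:
        return aggregates.iloc[0:0]
    cand_sorted = intervals.make_peaks(cand)
    mask = intervals.overlaps_any(cand_sorted, hgrs)
    names = cand_sorted.loc[mask, "name"]
    out = aggregates.loc[aggregates.index.intersection(names)]
    return out.sort_values("mean_log2fc", ascending=False)
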