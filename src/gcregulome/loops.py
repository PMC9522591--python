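"""HiChIP loop annotation and enhancer-promoter / DEG linkage statistics.

Loops arrive as significant anchor pairs (q < 0.01 filtered upstream).
An anchor is a promoter anchor when it overlaps any TSS +/- the promoter
window; loops are classed distal<->promoter, promoter<->promoter or
distal<->distal. Only unambiguous distal->promoter loops enter the
Fisher linkage counts, avoiding directional double counting.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import intervals
from .stats_core import ContingencyTable2x2, fisher_exact

LOOP_COLS = ["chromA", "startA", "endA", "chromB", "startB", "endB", "q"]


def read_loops(path) -> pd.DataFrame:
    loops = pd.read_csv(path, sep="\t")
    missing = [c for c in LOOP_COLS if c not in loops.columns]
    if missing:
        raise ValueError(f"loop table missing columns: {missing}")
    return loops


def write_loops(loops: pd.DataFrame, path) -> None:
    loops.to_csv(path, sep="\t", index=False)


def _anchor_frame(loops: pd.DataFrame, side: str) -> pd.DataFrame:
    return intervals.make_peaks(
        pd.DataFrame(
            {
                "chrom": loops[f"chrom{side}"],
                "start": loops[f"start{side}"],
                "end": loops[f"end{side}"],
                "name": [f"{side}_{i}" for i in loops.index],
            }
        )
    )


def annotate_loops(
    loops: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_window_bp: int = 2_000,
    q_max: float = 0.01,
) -> pd.DataFrame:
    """Classify each significant loop's anchors as promoter or distal.

    Adds ``classA``/``classB`` ({promoter, distal}), ``loop_class``
    ({distal_promoter, promoter_promoter, distal_distal}), and
    ``genesA``/``genesB`` — tuples of gene ids whose TSS window each
    anchor overlaps. Self-loops (identical anchors) are rejected.
    Annotation is symmetric in the two anchors.
    """
    loops = loops[loops["q"] < q_max].reset_index(drop=True).copy()
    selfloop = (
        (loops["chromA"] == loops["chromB"])
        & (loops["startA"] == loops["startB"])
        & (loops["endA"] == loops["endB"])
    )
    if selfloop.any():
        raise ValueError(f"{selfloop.sum()} self-loops (identical anchors) in input")
    prom = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": (genes["tss"] - promoter_window_bp).clip(lower=0),
            "end": genes["tss"] + promoter_window_bp,
            "name": genes["gene_id"],
        }
    )
    prom = intervals.make_peaks(prom)
    for side in ("A", "B"):
        anchors = _anchor_frame(loops, side)
        pairs = intervals.intersect(anchors, prom)
        gene_map: dict[int, list[str]] = {}
        for _, row in pairs.iterrows():
            li = int(row["name_a"].split("_", 1)[1])
            gene_map.setdefault(li, []).append(row["name_b"])
        loops[f"genes{side}"] = [
            tuple(sorted(set(gene_map.get(i, ())))) for i in loops.index
        ]
        loops[f"class{side}"] = [
            "promoter" if gene_map.get(i) else "distal" for i in loops.index
        ]
    cls = []
    for a, b in zip(loops["classA"], loops["classB"]):
        pair = {a, b}
        if pair == {"promoter"}:
            cls.append("promoter_promoter")
        elif pair == {"distal"}:
            cls.append("distal_distal")
        else:
            cls.append("distal_promoter")
    loops["loop_class"] = cls
    return loops


def loop_deg_linkage(
    annotated: pd.DataFrame,
    degs: pd.DataFrame,
    k27_sites: pd.DataFrame,
    hgrs: pd.DataFrame | None = None,
) -> dict:
    """Fisher linkage of responsive-K27 distal anchors to DEG promoters.

    Counts unambiguous distal->promoter loops whose distal anchor overlaps
    an enhanced vs reduced H3K27ac responsive site and whose promoter gene
    is an up- vs down-regulated DEG; each (loop, gene) pair counts once.
    Also reports the fraction of DEG-promoter loops whose distal anchor
    overlaps an HGR, and the fraction of DEGs with any promoter loop
    (both the per-loop and per-gene denominators).
    """
    dp = annotated[annotated["loop_class"] == "distal_promoter"].copy()
    up_ids = set(degs.index[degs["direction"] == "enhanced"])
    down_ids = set(degs.index[degs["direction"] == "reduced"])
    enh_sites = intervals.make_peaks(k27_sites[k27_sites["direction"] == "enhanced"]) if len(
        k27_sites[k27_sites["direction"] == "enhanced"]
    ) else None
    red_sites = intervals.make_peaks(k27_sites[k27_sites["direction"] == "reduced"]) if len(
        k27_sites[k27_sites["direction"] == "reduced"]
    ) else None

    counts = np.zeros((2, 2), dtype=int)  # rows: enh/red site; cols: up/down gene
    deg_loop_rows = []
    for i, row in dp.iterrows():
        dist_side = "A" if row["classA"] == "distal" else "B"
        prom_side = "B" if dist_side == "A" else "A"
        anchor = pd.DataFrame(
            [
                {
                    "chrom": row[f"chrom{dist_side}"],
                    "start": row[f"start{dist_side}"],
                    "end": row[f"end{dist_side}"],
                    "name": f"loop_{i}",
                }
            ]
        )
        is_enh = enh_sites is not None and intervals.overlaps_any(anchor, enh_sites)[0]
        is_red = red_sites is not None and intervals.overlaps_any(anchor, red_sites)[0]
        for gene in row[f"genes{prom_side}"]:
            is_up = gene in up_ids
            is_down = gene in down_ids
            if is_up or is_down:
                deg_loop_rows.append({"loop": i, "gene": gene, "anchor": anchor})
            if (is_enh ^ is_red) and (is_up ^ is_down):
                counts[0 if is_enh else 1, 0 if is_up else 1] += 1

    if counts.sum() == 0:
        warnings.warn("no direction-resolved DEG-promoter loops", stacklevel=2)
        odds, p, table = np.nan, np.nan, None
    else:
        a, b, c, d = counts[0, 0], counts[0, 1], counts[1, 0], counts[1, 1]
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
        if a * d == 0 and b * c == 0:
            odds, p = np.nan, np.nan  # degenerate table, OR undefined
        else:
            odds, p = fisher_exact(table)

    # HGR overlap of DEG-promoter distal anchors
    frac_hgr = np.nan
    if hgrs is not None and len(hgrs) and deg_loop_rows:
        hgr_sorted = intervals.make_peaks(hgrs)
        hits = [
            bool(intervals.overlaps_any(r["anchor"], hgr_sorted)[0]) for r in deg_loop_rows
        ]
        frac_hgr = float(np.mean(hits))

    all_deg_ids = up_ids | down_ids
    genes_with_loop = {r["gene"] for r in deg_loop_rows}
    n_prom_loops = len(dp)
    frac_loops_to_deg = (
        len({r["loop"] for r in deg_loop_rows}) / n_prom_loops if n_prom_loops else np.nan
    )
    frac_degs_with_loop = (
        len(genes_with_loop) / len(all_deg_ids) if all_deg_ids else np.nan
    )
    return {
        "table": table,
        "odds_ratio": odds,
        "p": p,
        "counts": counts,
        "frac_deg_anchor_hgr": frac_hgr,
        "frac_promoter_loops_to_deg": frac_loops_to_deg,
        "frac_degs_with_promoter_loop": frac_degs_with_loop,
        "n_distal_promoter_loops": n_prom_loops,
    }
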