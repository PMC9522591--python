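"""Genomic-interval algebra and BED/gene-model I/O.

All coordinates are 0-based half-open (BED convention) throughout the
package; conversion to 1-based happens only at the VCF boundary. Interval
sets are plain pandas DataFrames with at least ``chrom``, ``start``,
``end`` and ``name`` columns, sorted by (chrom, start, end); every
operation here preserves that sort order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

BED_CORE = ["chrom", "start", "end", "name"]


@dataclass(frozen=True)
class GenomicInterval:
    """A single half-open genomic interval."""

    chrom: str
    start: int
    end: int
    id: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its TSS; expression is tracked elsewhere by id."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")


def make_peaks(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise an interval frame (sort, reset index)."""
    missing = [c for c in BED_CORE[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"interval frame missing columns: {missing}")
    out = df.copy()
    if "name" not in out.columns:
        out["name"] = [f"peak_{i}" for i in range(len(out))]
    bad = out["start"] >= out["end"]
    if bad.any():
        row = out.index[bad][0]
        raise ValueError(f"empty or inverted interval at row {row}")
    out = out.sort_values(["chrom", "start", "end"], kind="mergesort")
    return out.reset_index(drop=True)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3+ into a sorted interval frame.

    Accepts 3-6 columns (chrom, start, end[, name, score, strand]).
    Unsorted input is accepted and sorted on load. Raises ValueError with
    the 1-based line number for malformed or empty intervals.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(
                    f"line {lineno}: start >= end ({parts[0]}:{start}-{end})"
                )
            rows.append(
                {
                    "chrom": parts[0],
                    "start": start,
                    "end": end,
                    "name": parts[3] if len(parts) > 3 else f"peak_{lineno}",
                    "score": float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0,
                    "strand": parts[5] if len(parts) > 5 else ".",
                }
            )
    return make_peaks(pd.DataFrame(rows, columns=BED_CORE + ["score", "strand"]))


def write_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    """Write an interval frame as BED (3-6 columns, sorted)."""
    df = make_peaks(peaks)
    cols = BED_CORE + [c for c in ("score", "strand") if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read the 5-column gene-model TSV (gene_id, chrom, tss, strand, biotype)."""
    genes = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    bad = ~genes["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"invalid gene strand at rows {list(genes.index[bad])}")
    return genes.sort_values(["chrom", "tss"]).reset_index(drop=True)


def write_gene_models(genes: pd.DataFrame, path: str | Path) -> None:
    cols = ["gene_id", "chrom", "tss", "strand", "biotype"]
    out = genes.copy()
    if "biotype" not in out.columns:
        out["biotype"] = "protein_coding"
    out[cols].to_csv(path, sep="\t", index=False)


def intersect(
    a: pd.DataFrame, b: pd.DataFrame, min_overlap_bp: int = 1
) -> pd.DataFrame:
    """All pairs of intervals from ``a`` and ``b`` overlapping by >= min_overlap_bp.

    Returns a frame with columns name_a, name_b, overlap_bp, idx_a, idx_b
    (positional indices into the sorted inputs).
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    a = make_peaks(a)
    b = make_peaks(b)
    out = {"name_a": [], "name_b": [], "overlap_bp": [], "idx_a": [], "idx_b": []}
    for chrom, ga in a.groupby("chrom", sort=False):
        gb = b[b["chrom"] == chrom]
        if gb.empty:
            continue
        bs = gb["start"].to_numpy()
        be = gb["end"].to_numpy()
        # sorted sweep: for each a-interval, candidate b-intervals are those
        # starting before a.end; prune by max running end
        order = np.argsort(bs, kind="mergesort")
        bs, be = bs[order], be[order]
        bidx = gb.index.to_numpy()[order]
        bnames = gb["name"].to_numpy()[order]
        for ia, (sa, ea, na) in enumerate(
            zip(ga["start"].to_numpy(), ga["end"].to_numpy(), ga["name"].to_numpy())
        ):
            hi = np.searchsorted(bs, ea, side="left")
            if hi == 0:
                continue
            ov = np.minimum(ea, be[:hi]) - np.maximum(sa, bs[:hi])
            keep = ov >= min_overlap_bp
            if keep.any():
                k = np.flatnonzero(keep)
                out["name_a"].extend([na] * len(k))
                out["name_b"].extend(bnames[k])
                out["overlap_bp"].extend(ov[k])
                out["idx_a"].extend([ga.index[ia]] * len(k))
                out["idx_b"].extend(bidx[k])
    return pd.DataFrame(out)


def overlaps_any(a: pd.DataFrame, b: pd.DataFrame, min_overlap_bp: int = 1) -> np.ndarray:
    """Boolean mask over sorted ``a`` rows: does each interval hit anything in ``b``?"""
    a = make_peaks(a)
    mask = np.zeros(len(a), dtype=bool)
    if len(b) == 0:
        return mask
    pairs = intersect(a, b, min_overlap_bp=min_overlap_bp)
    if not pairs.empty:
        mask[pairs["idx_a"].to_numpy()] = True
    return mask


def stitch(peaks: pd.DataFrame, gap_bp: int) -> pd.DataFrame:
    """Merge same-chromosome peaks whose gap is <= gap_bp (enhancer-cluster stitching).

    Returns stitched regions with ``constituents`` (list of peak names) and
    ``n_constituents``. Overlapping peaks always merge (negative gap).
    """
    if gap_bp < 0:
        raise ValueError("gap_bp must be >= 0")
    peaks = make_peaks(peaks)
    rows = []
    for chrom, g in peaks.groupby("chrom", sort=False):
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        names = g["name"].to_numpy()
        cur_s, cur_e, members = starts[0], ends[0], [names[0]]
        for s, e, n in zip(starts[1:], ends[1:], names[1:]):
            if s - cur_e <= gap_bp:
                cur_e = max(cur_e, e)
                members.append(n)
            else:
                rows.append((chrom, cur_s, cur_e, list(members)))
                cur_s, cur_e, members = s, e, [n]
        rows.append((chrom, cur_s, cur_e, list(members)))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "constituents"])
    out["name"] = [f"stitched_{i}" for i in range(len(out))]
    out["n_constituents"] = out["constituents"].map(len)
    return out[["chrom", "start", "end", "name", "constituents", "n_constituents"]]


def nearest_tss_distance(
    regions: pd.DataFrame, genes: pd.DataFrame
) -> pd.DataFrame:
    """Signed distance (region midpoint - TSS) to the nearest TSS per region.

    Nearest by absolute distance among same-chromosome genes; ties broken by
    lexicographically smaller gene_id. Regions on a chromosome without genes
    get NaN distance. Raises on an empty gene set.
    """
    if len(genes) == 0:
        raise ValueError("gene set is empty")
    regions = make_peaks(regions)
    mids = ((regions["start"] + regions["end"]) // 2).to_numpy()
    dist = np.full(len(regions), np.nan)
    gene_id = np.full(len(regions), None, dtype=object)
    for chrom, g in genes.groupby("chrom", sort=False):
        rmask = (regions["chrom"] == chrom).to_numpy()
        if not rmask.any():
            continue
        # sort by (tss, gene_id) so equidistant ties resolve to smaller id
        g = g.sort_values(["tss", "gene_id"])
        tss = g["tss"].to_numpy()
        gids = g["gene_id"].to_numpy()
        m = mids[rmask]
        d = m[:, None] - tss[None, :]
        absd = np.abs(d)
        # tie-break by gene_id among minimal |d|
        best = np.empty(len(m), dtype=int)
        for i in range(len(m)):
            cand = np.flatnonzero(absd[i] == absd[i].min())
            best[i] = cand[np.argmin(gids[cand])] if len(cand) > 1 else cand[0]
        dist[rmask] = d[np.arange(len(m)), best]
        gene_id[rmask] = gids[best]
    return pd.DataFrame(
        {
            "name": regions["name"],
            "distance": dist,
            "gene_id": gene_id,
        }
    )


def regulatory_domains(
    genes: pd.DataFrame,
    basal_up: int = 5_000,
    basal_down: int = 1_000,
    max_extension: int = 1_000_000,
) -> pd.DataFrame:
    """Per-gene regulatory domains under the basal-plus-extension rule.

    Basal domain: ``basal_up`` upstream and ``basal_down`` downstream of the
    TSS, strand-aware. The domain then extends in both directions up to
    ``max_extension`` from the TSS, stopping at the nearest neighbouring
    basal domain, but never shrinking below the gene's own basal domain.
    """
    genes = genes.sort_values(["chrom", "tss", "gene_id"]).reset_index(drop=True)
    plus = genes["strand"] == "+"
    basal_start = np.where(
        plus, genes["tss"] - basal_up, genes["tss"] - basal_down
    ).clip(min=0)
    basal_end = np.where(plus, genes["tss"] + basal_down, genes["tss"] + basal_up)
    dom_start = np.empty(len(genes), dtype=np.int64)
    dom_end = np.empty(len(genes), dtype=np.int64)
    for chrom, g in genes.groupby("chrom", sort=False):
        idx = g.index.to_numpy()
        bs, be, tss = basal_start[idx], basal_end[idx], g["tss"].to_numpy()
        for k, i in enumerate(idx):
            lo = tss[k] - max_extension
            hi = tss[k] + max_extension
            if k > 0:
                lo = max(lo, be[k - 1])
            if k < len(idx) - 1:
                hi = min(hi, bs[k + 1])
            dom_start[i] = min(bs[k], max(lo, 0))
            dom_end[i] = max(be[k], hi)
    out = genes[["gene_id", "chrom", "tss", "strand"]].copy()
    out["start"] = dom_start.clip(min=0)
    out["end"] = dom_end
    return out


def associate_regions_to_genes(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    basal_up: int = 5_000,
    basal_down: int = 1_000,
    max_extension: int = 1_000_000,
) -> pd.DataFrame:
    """Region-to-gene association: a region maps to every gene whose
    regulatory domain (basal-plus-extension rule) it overlaps by >= 1 bp.

    Returns a (region name, gene_id) pair frame; regions overlapping no
    domain are absent from the output.
    """
    doms = regulatory_domains(genes, basal_up, basal_down, max_extension)
    doms = doms.rename(columns={"gene_id": "name"})
    pairs = intersect(make_peaks(regions), make_peaks(doms))
    if pairs.empty:
        return pd.DataFrame(columns=["name", "gene_id"])
    out = pairs[["name_a", "name_b"]].rename(
        columns={"name_a": "name", "name_b": "gene_id"}
    )
    return out.drop_duplicates().reset_index(drop=True)
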