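"""High-confidence GR regulatory sites (HGRs) and GRE motif annotation.

An HGR is a GR occupancy site supported by open chromatin and active
enhancer marks: a GR peak that overlaps both an ATAC peak and an H3K27ac
peak at the same timepoint. The HGR footprint is the GR peak interval
itself (merged when GR peaks overlap), never the three-way intersection.

The glucocorticoid response element (GRE) is modelled as a 15-column
log-odds position-weight matrix with the canonical nuclear-receptor
palindromic structure — two AGAACA half-sites in inverted orientation
separated by a 3-bp spacer (consensus AGAACAnnnTGTTCT, NR3C1-style).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals
from .stats_core import ContingencyTable2x2, fisher_exact, ks_two_sample

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

GRE_CONSENSUS = "AGAACANNNTGTTCT"


@dataclass(frozen=True)
class PWM:
    """Log-odds matrix (base 2, uniform 0.25 background), rows A/C/G/T."""

    matrix: np.ndarray  # shape (4, L)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        if not np.isfinite(m).all():
            raise ValueError("PWM entries must be finite")
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))


def gre_pwm(strong_prob: float = 0.85) -> PWM:
    """The packaged GRE matrix: informative half-site columns carry
    ``strong_prob`` on the consensus base, spacer columns are uniform."""
    probs = np.full((4, len(GRE_CONSENSUS)), 0.25)
    minor = (1.0 - strong_prob) / 3.0
    for j, base in enumerate(GRE_CONSENSUS):
        if base == "N":
            continue
        probs[:, j] = minor
        probs[_BASE_INDEX[base], j] = strong_prob
    return PWM(np.log2(probs / 0.25))


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; any other symbol -> 4 (scored as the column's worst base)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        out[arr == ord(base)] = i
    return out


@dataclass(frozen=True)
class PWMHit:
    position: int
    strand: str
    score: float
    is_hit: bool


def _scan_strand(codes: np.ndarray, score_cols: np.ndarray) -> tuple[int, float]:
    L = score_cols.shape[1]
    n = len(codes) - L + 1
    offsets = np.arange(L)
    windows = codes[np.arange(n)[:, None] + offsets]
    scores = score_cols[windows, offsets].sum(axis=1)
    best = int(scores.argmax())
    return best, float(scores[best])


def scan_pwm(
    sequence: str, pwm: PWM, threshold_frac: float = 0.8
) -> PWMHit | None:
    """Best log-odds match of ``pwm`` over both strands of ``sequence``.

    Returns None when the sequence is shorter than the matrix. A position
    counts as a hit when its score reaches ``threshold_frac`` of the
    maximal achievable matrix score. Ambiguous bases score as the worst
    base of each column.
    """
    L = pwm.length
    if len(sequence) < L:
        return None
    # append the per-column minimum as the score of ambiguous symbols
    cols = np.vstack([pwm.matrix, pwm.matrix.min(axis=0)])
    fwd_codes = _encode(sequence)
    rev_codes = _encode(reverse_complement(sequence))
    fpos, fscore = _scan_strand(fwd_codes, cols)
    rpos, rscore = _scan_strand(rev_codes, cols)
    if fscore >= rscore:
        pos, strand, score = fpos, "+", fscore
    else:
        pos, strand, score = len(sequence) - L - rpos, "-", rscore
    return PWMHit(pos, strand, score, score >= threshold_frac * pwm.max_score)


def annotate_gre(
    hgrs: pd.DataFrame,
    sequences: dict[str, str],
    pwm: PWM,
    threshold_frac: float = 0.8,
) -> pd.DataFrame:
    """Attach has_gre / best_motif_score to an HGR frame from its sequences."""
    out = hgrs.copy()
    has, score = [], []
    for name in out["name"]:
        seq = sequences.get(name)
        hit = scan_pwm(seq, pwm, threshold_frac) if seq else None
        if hit is None:
            has.append(False)
            score.append(np.nan)
        else:
            has.append(bool(hit.is_hit))
            score.append(hit.score)
    out["has_gre"] = has
    out["best_motif_score"] = score
    return out


def call_hgrs(
    gr_peaks: dict[float, pd.DataFrame],
    atac_peaks: dict[float, pd.DataFrame],
    k27_peaks: dict[float, pd.DataFrame],
) -> pd.DataFrame:
    """Triple-intersection HGR calling.

    Per timepoint a GR peak qualifies iff it overlaps (>= 1 bp) both an
    ATAC and an H3K27ac peak; the final set is the union of qualifying GR
    peaks over timepoints, with overlapping GR peaks merged and the list
    of supporting timepoints retained. Timepoints missing either
    companion assay are skipped with a warning.
    """
    import warnings

    qualifying = []
    for tp in sorted(gr_peaks):
        if tp not in atac_peaks or tp not in k27_peaks:
            warnings.warn(f"timepoint {tp}: missing ATAC or H3K27ac peaks; skipped", stacklevel=2)
            continue
        gr = intervals.make_peaks(gr_peaks[tp])
        hit_atac = intervals.overlaps_any(gr, atac_peaks[tp])
        hit_k27 = intervals.overlaps_any(gr, k27_peaks[tp])
        q = gr.loc[hit_atac & hit_k27].copy()
        q["timepoint"] = tp
        qualifying.append(q)
    if not qualifying or all(q.empty for q in qualifying):
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "timepoints", "source_peaks"])
    allq = pd.concat(qualifying, ignore_index=True)
    merged = intervals.stitch(intervals.make_peaks(allq), gap_bp=0)
    allq_sorted = intervals.make_peaks(allq)
    rows = []
    for i, reg in merged.iterrows():
        reg_df = pd.DataFrame(
            [{"chrom": reg["chrom"], "start": reg["start"], "end": reg["end"], "name": "r"}]
        )
        hit = intervals.intersect(allq_sorted, reg_df)
        sup = allq_sorted.iloc[sorted(hit["idx_a"].unique())]
        rows.append(
            {
                "chrom": reg["chrom"],
                "start": reg["start"],
                "end": reg["end"],
                "name": f"hgr_{i}",
                "timepoints": tuple(sorted(sup["timepoint"].unique())),
                "source_peaks": tuple(sorted(sup["name"].unique())),
            }
        )
    return pd.DataFrame(rows)


def gre_response_enrichment(
    hgrs: pd.DataFrame, enhanced_col: str = "enhanced"
) -> tuple[ContingencyTable2x2, float, float]:
    """Fisher test: do GRE-bearing HGRs preferentially carry enhanced
    (accessibility / H3K27ac) responses compared to GRE-less HGRs?

    Requires boolean ``has_gre`` and ``enhanced_col`` columns. Returns
    (table, odds_ratio, p).
    """
    gre = hgrs["has_gre"].astype(bool)
    enh = hgrs[enhanced_col].astype(bool)
    if gre.all() or (~gre).all():
        raise ValueError("need both GRE and non-GRE HGRs")
    t = ContingencyTable2x2(
        int((gre & enh).sum()),
        int((gre & ~enh).sum()),
        int((~gre & enh).sum()),
        int((~gre & ~enh).sum()),
    )
    odds, p = fisher_exact(t)
    return t, odds, p


def hgr_deg_distance_test(
    hgrs: pd.DataFrame,
    hgr_direction_col: str,
    degs: pd.DataFrame,
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """KS tests of HGR-to-DEG-TSS distance distributions by direction.

    For each HGR direction class (enhanced / reduced), compares the
    distribution of |distance to nearest up-DEG TSS| against |distance to
    nearest down-DEG TSS|. ``degs`` must carry a ``direction`` column
    (enhanced = upregulated); ``genes`` supplies the TSS coordinates.
    """
    up_ids = degs.index[degs["direction"] == "enhanced"]
    down_ids = degs.index[degs["direction"] == "reduced"]
    up_genes = genes[genes["gene_id"].isin(up_ids)]
    down_genes = genes[genes["gene_id"].isin(down_ids)]
    if len(up_genes) < 2 or len(down_genes) < 2:
        raise ValueError("need >= 2 genes in each DEG direction class")
    rows = []
    for direction in ("enhanced", "reduced"):
        sub = hgrs[hgrs[hgr_direction_col] == direction]
        if len(sub) < 2:
            continue
        d_up = intervals.nearest_tss_distance(sub, up_genes)["distance"].abs().dropna()
        d_down = intervals.nearest_tss_distance(sub, down_genes)["distance"].abs().dropna()
        D, p = ks_two_sample(d_up, d_down)
        rows.append(
            {
                "hgr_direction": direction,
                "n_hgrs": len(sub),
                "median_dist_up": float(d_up.median()),
                "median_dist_down": float(d_down.median()),
                "ks_D": D,
                "ks_p": p,
            }
        )
    return pd.DataFrame(rows)
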