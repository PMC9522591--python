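"""TF footprint scoring from Tn5 insertion-count profiles.

A bound transcription factor protects its motif core from transposase
insertion, producing a local dip relative to the flanking accessible
DNA. The score is depth-normalised per site (window mean scaled to 1)
and computed as mean(flank) - mean(core), with 20-bp flanks on either
side of the motif core inside a +/-100 bp window; higher means a
stronger footprint. Differential occupancy between conditions uses a
per-site label-flip permutation null, with BH correction across TFs.

No insertion-bias correction is applied: the synthetic profiles carry no
sequence bias. A bias-correction hook would slot in before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats_core import ContingencyTable2x2, bh_fdr, fisher_exact


@dataclass
class FootprintProfile:
    """Per-site insertion counts for one TF in one condition.

    ``counts``: (n_sites, window_size) array of insertion counts over
    offsets centred on the motif; ``core_halfwidth``: half the motif core
    length in bp.
    """

    tf: str
    counts: np.ndarray
    core_halfwidth: int
    flank_bp: int = 20

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be (n_sites, window)")
        if (self.counts < 0).any():
            raise ValueError("insertion counts must be non-negative")
        window_half = self.counts.shape[1] // 2
        if window_half < self.core_halfwidth + self.flank_bp:
            raise ValueError("window must cover core plus flanks")


def footprint_score(profile: FootprintProfile) -> tuple[np.ndarray, float]:
    """Per-site and aggregate footprint scores.

    Each site's counts are normalised to window mean 1 (making the score
    invariant to sequencing depth); score = mean(flank) - mean(core).
    All-zero sites are skipped (NaN per-site, excluded from the
    aggregate mean).
    """
    c = profile.counts
    w = c.shape[1]
    centre = w // 2
    core = slice(centre - profile.core_halfwidth, centre + profile.core_halfwidth + 1)
    left = slice(core.start - profile.flank_bp, core.start)
    right = slice(core.stop, core.stop + profile.flank_bp)
    site_mean = c.mean(axis=1)
    scores = np.full(c.shape[0], np.nan)
    ok = site_mean > 0
    norm = c[ok] / site_mean[ok, None]
    flank = np.concatenate([norm[:, left], norm[:, right]], axis=1).mean(axis=1)
    corev = norm[:, core].mean(axis=1)
    scores[ok] = flank - corev
    agg = float(np.nanmean(scores)) if ok.any() else np.nan
    return scores, agg


def differential_footprint(
    profiles: dict[str, dict[str, FootprintProfile]],
    cond_a: str = "0h",
    cond_b: str = "24h",
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-TF footprint change between two conditions with permutation p.

    delta = aggregate(cond_b) - aggregate(cond_a). The null swaps the two
    condition labels independently per site (both conditions must score
    the same site set); p = (1 + #{|delta_perm| >= |delta|}) / (n_perm+1),
    q across TFs by BH.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    rows = []
    for tf, byc in sorted(profiles.items()):
        pa, pb = byc[cond_a], byc[cond_b]
        if pa.counts.shape[0] != pb.counts.shape[0]:
            raise ValueError(f"{tf}: site sets differ between conditions")
        sa, _ = footprint_score(pa)
        sb, _ = footprint_score(pb)
        ok = ~(np.isnan(sa) | np.isnan(sb))
        sa, sb = sa[ok], sb[ok]
        delta = float(np.mean(sb) - np.mean(sa))
        n = len(sa)
        flips = rng.random((n_perm, n)) < 0.5
        diffs = sb - sa
        perm_delta = np.where(flips, -diffs, diffs).mean(axis=1)
        p = (1 + np.sum(np.abs(perm_delta) >= abs(delta))) / (n_perm + 1)
        rows.append({"tf": tf, "n_sites": n, "delta": delta, "p": p})
    out = pd.DataFrame(rows).set_index("tf")
    out["q"] = bh_fdr(out["p"])
    return out


def ap1_site_depletion_test(
    ap1_flag: pd.Series, reduced_flag: pd.Series
) -> tuple[ContingencyTable2x2, float, float]:
    """Fisher test: AP-1-footprinted accessible sites vs sites with
    GC-reduced accessibility.

    Both arguments are boolean Series over the same accessible-site
    universe. Returns (table, odds_ratio, p); a table with an empty
    AP-1 or reduced margin raises.
    """
    ap1 = ap1_flag.astype(bool)
    red = reduced_flag.reindex(ap1.index).fillna(False).astype(bool)
    if ap1.all() or (~ap1).all():
        raise ValueError("AP-1 stratum is empty on one side")
    t = ContingencyTable2x2(
        int((ap1 & red).sum()),
        int((ap1 & ~red).sum()),
        int((~ap1 & red).sum()),
        int((~ap1 & ~red).sum()),
    )
    odds, p = fisher_exact(t)
    return t, odds, p
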