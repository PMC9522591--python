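"""Super-enhancer calling: signal ranking, tangent cutoff, GC-response classes.

Stitched H3K27ac regions are ranked by total input-normalised signal and
the classic hockey-stick rule is applied: with rank and signal both
scaled to [0, 1], the cutoff sits where the discrete slope of the curve
first exceeds 1; everything above is a super-enhancer. GC-responsive SEs
are SE calls reproducible at two or more treated timepoints, split into
de novo (absent at 0 h) and pre-established (present at 0 h with >= 2-fold
treated/0 h signal gain); baseline SEs are excluded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import intervals


def rank_and_cutoff(
    stitched: pd.DataFrame,
    signal_col: str = "signal",
    slope_threshold: float = 1.0,
) -> pd.DataFrame:
    """Call SEs on a stitched-region frame by the scaled-curve tangent rule.

    Requires >= 3 regions with positive signal. Returns the input with
    ``rank`` (1 = lowest signal), ``is_se`` and ``cutoff_signal`` columns.
    All-equal signals yield zero SEs with a warning.
    """
    sig = stitched[signal_col].to_numpy(dtype=float)
    if (sig < 0).any():
        raise ValueError("signal must be non-negative")
    if (sig > 0).sum() < 3:
        raise ValueError("need >= 3 regions with positive signal")
    out = stitched.copy()
    order = np.argsort(sig, kind="mergesort")
    n = len(sig)
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    out["rank"] = ranks
    smin, smax = sig.min(), sig.max()
    if smax == smin:
        warnings.warn("all signals equal; no super-enhancers called", stacklevel=2)
        out["is_se"] = False
        out["cutoff_signal"] = np.nan
        return out
    x = np.arange(n) / (n - 1)
    y = (sig[order] - smin) / (smax - smin)
    slope = np.diff(y) / np.diff(x)
    above = np.flatnonzero(slope > slope_threshold)
    if len(above) == 0:
        out["is_se"] = False
        out["cutoff_signal"] = np.nan
        return out
    cut = above[0]  # first gap whose slope exceeds the unit tangent
    cutoff_signal = sig[order][cut + 1]
    out["is_se"] = sig >= cutoff_signal
    out["cutoff_signal"] = cutoff_signal
    return out


def hockey_stick_table(ranked: pd.DataFrame, signal_col: str = "signal") -> pd.DataFrame:
    """Rank-vs-signal table for plotting the SE hockey stick."""
    return (
        ranked.sort_values("rank")[["name", "rank", signal_col, "is_se"]]
        .reset_index(drop=True)
    )


def call_gc_responsive_se(
    se_by_timepoint: dict[float, pd.DataFrame],
    baseline_timepoint: float = 0.0,
    min_treated_timepoints: int = 2,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Classify reproducible GC-responsive SEs across the treatment course.

    ``se_by_timepoint`` maps hours to ranked stitched frames (``is_se``,
    ``signal``). A candidate SE interval (the union of overlapping treated
    SE calls) is reproducible iff supported at >= ``min_treated_timepoints``
    distinct treated timepoints. Classes: ``de_novo`` when no 0 h SE
    overlaps; ``pre_established`` when a 0 h SE overlaps and the maximal
    treated/0 h stitched-signal ratio is >= ``fold_threshold``; otherwise
    ``baseline`` (dropped from the returned set).
    """
    treated_tps = sorted(tp for tp in se_by_timepoint if tp != baseline_timepoint)
    if len(treated_tps) < min_treated_timepoints:
        raise ValueError(
            f"need >= {min_treated_timepoints} treated timepoints, got {len(treated_tps)}"
        )
    if baseline_timepoint not in se_by_timepoint:
        raise ValueError("baseline timepoint SE calls are required")

    frames = []
    for tp in treated_tps:
        df = se_by_timepoint[tp]
        sub = df.loc[df["is_se"], ["chrom", "start", "end", "name", "signal"]].copy()
        sub["timepoint"] = tp
        frames.append(sub)
    if all(f.empty for f in frames):
        return pd.DataFrame(
            columns=["chrom", "start", "end", "name", "timepoints", "class", "fold_change_vs_0h"]
        )
    treated = pd.concat(frames, ignore_index=True)
    merged = intervals.stitch(intervals.make_peaks(treated), gap_bp=0)

    base_df = se_by_timepoint[baseline_timepoint]
    base_se = base_df.loc[base_df["is_se"], ["chrom", "start", "end", "name", "signal"]]
    base_all = base_df[["chrom", "start", "end", "name", "signal"]]

    treated_sorted = intervals.make_peaks(treated)
    rows = []
    for i, reg in merged.iterrows():
        # constituent names can repeat across timepoints; re-intersect by coordinates
        reg_df = pd.DataFrame(
            [{"chrom": reg["chrom"], "start": reg["start"], "end": reg["end"], "name": reg["name"]}]
        )
        hit = intervals.intersect(treated_sorted, reg_df)
        sup = treated_sorted.iloc[sorted(hit["idx_a"].unique())]
        tps = sorted(sup["timepoint"].unique())
        if len(tps) < min_treated_timepoints:
            continue
        max_signal = float(sup["signal"].max())
        base_hit = (
            intervals.intersect(intervals.make_peaks(base_se), reg_df)
            if len(base_se)
            else pd.DataFrame()
        )
        base_any = (
            intervals.intersect(intervals.make_peaks(base_all), reg_df)
            if len(base_all)
            else pd.DataFrame()
        )
        if not base_any.empty:
            b = base_all.iloc[sorted(base_any["idx_a"].unique())]["signal"].max()
        else:
            b = 0.0
        fold = max_signal / b if b > 0 else np.inf
        if base_hit.empty:
            cls = "de_novo"
        elif fold >= fold_threshold:
            cls = "pre_established"
        else:
            cls = "baseline"
        rows.append(
            {
                "chrom": reg["chrom"],
                "start": reg["start"],
                "end": reg["end"],
                "name": f"gcse_{i}",
                "timepoints": tuple(tps),
                "class": cls,
                "fold_change_vs_0h": fold,
            }
        )
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "timepoints", "class", "fold_change_vs_0h"]
    )
    return out[out["class"] != "baseline"].reset_index(drop=True)
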