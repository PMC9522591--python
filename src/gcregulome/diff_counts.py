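"""Negative-binomial differential testing of region/gene counts.

The model is the standard bulk-count one: counts k_ij ~ NB with
Var = mu + alpha * mu^2, sample-specific library-size factors by the
median-of-ratios rule, per-feature method-of-moments dispersion shrunk
toward a fitted mean-dispersion trend, and a Wald test on the log2 ratio
of group means. Contrasts are always two-group (treated vs reference),
which covers every comparison the pipeline makes: chromatin/expression
per treated timepoint vs 0 h, STARR RNA output vs pooled input,
CRISPRi post-selection vs baseline, resistant vs sensitive patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .stats_core import bh_fdr

DISPERSION_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """Integer feature x sample counts plus per-sample metadata.

    ``samples`` is indexed by sample id and must cover every count column;
    typical metadata columns: assay, timepoint, replicate, condition.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"sample metadata missing for: {sorted(missing)}")

    def subset(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.samples.loc[list(sample_ids)])

    def to_tsv(self, counts_path: str | Path, samples_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="feature")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="feature")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
        return cls(counts, samples)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors.

    s_j = median over features i of k_ij / geometric_mean_i, using only
    features with no zero count. Scale-equivariant: multiplying a column
    by c multiplies its factor by c.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    k = counts.to_numpy(dtype=float)
    allpos = (k > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no feature has all-positive counts; pseudo-reference fallback is disabled"
        )
    logk = np.log(k[allpos])
    loggeo = logk.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logk - loggeo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _trend_fit(mu: np.ndarray, alpha_raw: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha ~ a0 + a1/mu on positive raw estimates."""
    keep = (alpha_raw > 0) & (mu > 0)
    if keep.sum() < 2:
        pos = alpha_raw[alpha_raw > 0]
        return (float(pos.mean()) if pos.size else DISPERSION_FLOOR), 0.0
    x = 1.0 / mu[keep]
    y = alpha_raw[keep]
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef[0]), float(coef[1])


def estimate_dispersion(
    counts: pd.DataFrame,
    factors: pd.Series,
    groups: pd.Series | None = None,
) -> pd.Series:
    """Per-feature NB dispersion alpha (Var = mu + alpha mu^2).

    Method-of-moments on normalised counts, alpha_i = max(0, (s^2 - mu)/mu^2),
    with the sample variance pooled within ``groups`` when given (so that
    real condition effects do not inflate dispersion). Raw estimates are
    shrunk 50/50 toward the fitted trend a0 + a1/mu and floored at 1e-8.
    """
    norm = counts.to_numpy(dtype=float) / factors.loc[counts.columns].to_numpy()
    n = norm.shape[1]
    if groups is None:
        groups = pd.Series("all", index=counts.columns)
    labels = groups.loc[counts.columns].to_numpy()
    uniq = pd.unique(labels)
    if max((labels == g).sum() for g in uniq) < 2:
        raise ValueError("dispersion estimation needs >= 2 replicates in some group")
    resid_ss = np.zeros(norm.shape[0])
    dof = 0
    for g in uniq:
        cols = labels == g
        if cols.sum() < 2:
            continue
        sub = norm[:, cols]
        resid_ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += cols.sum() - 1
    s2 = resid_ss / dof
    mu = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(mu > 0, np.maximum(0.0, (s2 - mu) / mu**2), 0.0)
    a0, a1 = _trend_fit(mu, alpha_raw)
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a0 + a1 / mu, a0)
    alpha = 0.5 * alpha_raw + 0.5 * np.maximum(trend, 0.0)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    return pd.Series(alpha, index=counts.index, name="alpha")


def nb_wald_test(
    counts: pd.DataFrame,
    factors: pd.Series,
    alpha: pd.Series,
    groups: pd.Series,
    treated: str,
    reference: str,
) -> pd.DataFrame:
    """Wald test on log2 group-mean ratio under the NB variance model.

    Per feature: group means of normalised counts; log2fc =
    log2((mu_t + 0.5) / (mu_r + 0.5)); Var(log mu_g) =
    (1/n_g^2) * sum_j (1/mu_gj + alpha) with mu_gj = s_j * mu_g the
    expected raw count in sample j; Wald z = log2fc / se, two-sided
    normal p, BH q. Direction: enhanced (log2fc > 0) / reduced.
    """
    labels = groups.loc[counts.columns]
    t_cols = list(labels.index[labels == treated])
    r_cols = list(labels.index[labels == reference])
    if not t_cols or not r_cols:
        raise ValueError(f"empty contrast group: treated={len(t_cols)}, ref={len(r_cols)}")
    a = alpha.loc[counts.index].to_numpy()

    def group_stats(cols):
        k = counts[cols].to_numpy(dtype=float)
        s = factors.loc[cols].to_numpy()
        norm = k / s
        mu = norm.mean(axis=1)
        mu_safe = np.maximum(mu, 0.5)  # pseudocount guards zero groups
        nj = len(cols)
        var_log = (1.0 / nj**2) * (
            (1.0 / (mu_safe[:, None] * s[None, :])) + a[:, None]
        ).sum(axis=1)
        return mu, var_log

    mu_t, var_t = group_stats(t_cols)
    mu_r, var_r = group_stats(r_cols)
    log2fc = np.log2((mu_t + 0.5) / (mu_r + 0.5))
    se = np.sqrt(var_t + var_r) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    p = 2 * stats.norm.sf(np.abs(wald))
    res = pd.DataFrame(
        {
            "base_mean": (np.concatenate([mu_t[:, None], mu_r[:, None]], axis=1)).mean(axis=1),
            "log2fc": log2fc,
            "se": se,
            "wald_stat": wald,
            "p": p,
            "q": bh_fdr(p),
            "direction": np.where(log2fc > 0, "enhanced", "reduced"),
        },
        index=counts.index,
    )
    res.index.name = "feature"
    return res


def run_contrast(cm: CountMatrix, group_col: str, treated: str, reference: str) -> pd.DataFrame:
    """Convenience wrapper: size factors + dispersion + Wald on one contrast."""
    groups = cm.samples[group_col]
    cols = list(groups.index[groups.isin([treated, reference])])
    sub = cm.subset(cols)
    factors = size_factors(sub.counts)
    alpha = estimate_dispersion(sub.counts, factors, groups=sub.samples[group_col])
    return nb_wald_test(sub.counts, factors, alpha, sub.samples[group_col], treated, reference)


def classify_responsive(
    results: pd.DataFrame, q_max: float = 0.01, min_fold: float = 1.0
) -> pd.DataFrame:
    """Features passing q < q_max and |log2fc| >= log2(min_fold), direction attached."""
    min_abs_l2fc = np.log2(min_fold) if min_fold > 1 else 0.0
    mask = (results["q"] < q_max) & (results["log2fc"].abs() >= min_abs_l2fc)
    return results.loc[mask].copy()


def combined_degs(
    results_by_timepoint: dict[float, pd.DataFrame],
    q_max: float = 0.01,
    min_fold: float = 2.0,
) -> pd.DataFrame:
    """Union of DEG calls over the given timepoint contrasts.

    A gene significant at any contributing timepoint enters the combined
    set; its direction/log2fc come from the timepoint with smallest q.
    """
    frames = []
    for tp, res in results_by_timepoint.items():
        hit = classify_responsive(res, q_max=q_max, min_fold=min_fold).copy()
        hit["timepoint"] = tp
        frames.append(hit)
    if not frames:
        return pd.DataFrame(columns=["log2fc", "q", "direction", "timepoint"])
    allhits = pd.concat(frames)
    allhits = allhits.sort_values("q", kind="mergesort")
    return allhits[~allhits.index.duplicated(keep="first")].copy()
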