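"""Synthetic study generator with planted ground truth.

Emulates the statistical structure of a glucocorticoid time-course
functional-genomics study in ALL cell lines plus a primary-patient
cohort: negative-binomial region/gene counts with planted treatment
effects, peak geometry on a toy 3 x 10 Mb genome, GRE-bearing peak
sequences, STARR-seq DNA/RNA libraries, a CRISPRi tiling screen,
HiChIP-style loop lists, TF insertion profiles, and a patient cohort
with resistance phenotypes, methylation, genotypes and a planted causal
GRE-disrupting variant. Everything is deterministic under a fixed seed
and every planted feature id is recorded in the GroundTruth bundle so
downstream callers can be scored against truth.

One coordinated locus (the "resistance showcase" locus) is always
planted: a GRE-bearing GR/ATAC/H3K27ac peak sitting in the basal
regulatory domain of an upregulated resistance-list gene, enriched in
the CRISPRi screen, occluded in resistant patients, looped to its
target promoter, and carrying the causal motif-disrupting variant.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import intervals
from .diff_counts import CountMatrix
from .hgr_atlas import GRE_CONSENSUS, PWM, gre_pwm
from .footprints import FootprintProfile

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults are the conditions the downstream calibration and recovery
    checks assume: 4 replicates per condition, mean library depth 1e6,
    NB dispersion 0.05, planted |log2FC| = 2 for chromatin/expression,
    STARR activity factor 4, 2x sgRNA enrichment, n = 100 patients.
    """

    seed: int = 0
    n_regions: int = 2000
    n_genes: int = 300
    timepoints: tuple = (0.0, 2.0, 6.0, 12.0, 24.0)
    replicates_per_condition: int = 4
    depth_mean: float = 1e6
    nb_dispersion: float = 0.05
    frac_responsive: float = 0.15
    planted_log2fc: float = 2.0
    frac_se_planted: float = 0.01
    n_patients: int = 100
    frac_resistant: float = 0.5
    n_variants: int = 60
    sgrnas_per_site_mean: float = 6.5
    n_control_sgrnas: int = 100
    # genome geometry
    n_chroms: int = 3
    chrom_length: int = 10_000_000
    peak_min_bp: int = 200
    peak_max_bp: int = 1000
    min_gap_bp: int = 500
    # occupancy / annotation fractions
    frac_gr_occupied: float = 0.4
    frac_k27_positive: float = 0.8
    frac_gre: float = 0.5
    frac_ap1: float = 0.3
    library_size_sd: float = 0.2
    # STARR conditions
    starr_activity_factor: float = 4.0
    frac_starr_active: float = 0.12
    starr_dna_mean: float = 100.0
    starr_rna_total: float = 2e5
    # screen conditions
    screen_log2fc: float = 1.0
    screen_depth: float = 500.0
    screen_replicates: int = 4
    frac_screen_planted: float = 0.1
    # cohort conditions
    subtypes: tuple = ("ETV6_RUNX1", "hyperdiploid")
    frac_resistance_sites: float = 0.05
    frac_occluded: float = 0.78
    methylation_anticorr_frac: float = 0.85
    causal_effect_per_allele: float = 1.0
    cohort_depth: float = 5e5
    # loops
    n_loops: int = 400
    promoter_fraction: float = 0.35
    n_planted_loops: int = 40
    # footprints
    n_footprint_tfs: int = 12
    footprint_sites_per_tf: int = 150

    def __post_init__(self) -> None:
        fracs = {
            "frac_responsive": self.frac_responsive,
            "frac_se_planted": self.frac_se_planted,
            "frac_resistant": self.frac_resistant,
            "frac_gr_occupied": self.frac_gr_occupied,
            "frac_k27_positive": self.frac_k27_positive,
            "frac_gre": self.frac_gre,
            "frac_ap1": self.frac_ap1,
            "frac_starr_active": self.frac_starr_active,
            "frac_screen_planted": self.frac_screen_planted,
            "frac_resistance_sites": self.frac_resistance_sites,
            "frac_occluded": self.frac_occluded,
            "methylation_anticorr_frac": self.methylation_anticorr_frac,
            "promoter_fraction": self.promoter_fraction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.frac_resistant < 1.0:
            raise ValueError("frac_resistant must lie strictly in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.starr_activity_factor <= 0:
            raise ValueError("STARR activity factor must be > 0")
        for name in ("n_regions", "n_genes", "n_patients", "n_variants"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Planted feature ids, recoverable by the corresponding stage."""

    responsive: dict = field(default_factory=dict)  # assay -> direction -> ids
    planted_se_ids: list = field(default_factory=list)
    planted_active_starr: dict = field(default_factory=dict)  # class -> ids
    planted_resistance_site_ids: list = field(default_factory=list)
    occluded_site_ids: list = field(default_factory=list)
    causal_variant: dict = field(default_factory=dict)
    planted_footprint_tfs: dict = field(default_factory=dict)  # tf -> direction
    planted_screen_site_ids: list = field(default_factory=list)
    gre_peak_ids: list = field(default_factory=list)
    ap1_peak_ids: list = field(default_factory=list)
    hgr_peak_ids: list = field(default_factory=list)
    showcase: dict = field(default_factory=dict)  # peak/gene of the coordinated locus
    planted_loop_pairs: list = field(default_factory=list)
    resistance_gene_list: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True, default=str)


@dataclass
class SimGenome:
    chromosomes: pd.DataFrame
    genes: pd.DataFrame
    peaks: pd.DataFrame
    sequences: dict
    pwm: PWM
    gre_offsets: dict  # peak -> offset of planted GRE


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed % (2**31), zlib.crc32(stage.encode()) % (2**31)])


def _nb(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB draws with Var = mu + alpha mu^2 (gamma-Poisson mixture)."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mean * alpha)
    return rng.poisson(lam)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_genome(cfg: SimConfig, truth: GroundTruth | None = None) -> SimGenome:
    """Toy genome: disjoint peaks, gene models, peak sequences, GRE planting.

    Raises when the requested peak count cannot fit on the chromosomes.
    The showcase peak/gene pair is placed so the peak lies inside the
    gene's basal regulatory domain.
    """
    rng = _rng(cfg.seed, "genome")
    need = cfg.n_regions * (cfg.peak_max_bp + cfg.min_gap_bp)
    if need > cfg.n_chroms * cfg.chrom_length:
        raise ValueError(
            f"n_regions={cfg.n_regions} too large for "
            f"{cfg.n_chroms} x {cfg.chrom_length} bp chromosomes"
        )
    chroms = [f"chr{i+1}" for i in range(cfg.n_chroms)]
    chrom_df = pd.DataFrame({"chrom": chroms, "length": cfg.chrom_length})
    per_chrom = np.full(cfg.n_chroms, cfg.n_regions // cfg.n_chroms)
    per_chrom[: cfg.n_regions % cfg.n_chroms] += 1
    rows = []
    pk = 0
    for ci, chrom in enumerate(chroms):
        k = int(per_chrom[ci])
        if k == 0:
            continue
        widths = rng.integers(cfg.peak_min_bp, cfg.peak_max_bp + 1, size=k)
        slack = cfg.chrom_length - int(widths.sum()) - k * cfg.min_gap_bp
        cuts = np.sort(rng.integers(0, slack + 1, size=k))
        pos = 0
        starts = []
        for j in range(k):
            start = cuts[j] + int(widths[:j].sum()) + j * cfg.min_gap_bp
            starts.append(start)
        for j in range(k):
            rows.append((chrom, starts[j], starts[j] + int(widths[j]), f"peak_{pk}"))
            pk += 1
    peaks = intervals.make_peaks(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))

    # gene models: random TSS, then the showcase gene re-anchored near its peak
    gene_rows = []
    for gi in range(cfg.n_genes):
        chrom = chroms[gi % cfg.n_chroms]
        gene_rows.append(
            (
                f"gene_{gi}",
                chrom,
                int(rng.integers(10_000, cfg.chrom_length - 10_000)),
                "+" if rng.random() < 0.5 else "-",
                "protein_coding",
            )
        )
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "tss", "strand", "biotype"])
    showcase_peak = peaks[peaks["chrom"] == "chr1"].iloc[0]
    genes.loc[genes["gene_id"] == "gene_0", ["chrom", "tss", "strand"]] = [
        "chr1",
        int(showcase_peak["end"]) + 2_000,
        "+",
    ]
    genes = genes.sort_values(["chrom", "tss"]).reset_index(drop=True)

    # occupancy flags and GRE planting
    n = len(peaks)
    gr_mask = rng.random(n) < cfg.frac_gr_occupied
    k27_mask = rng.random(n) < cfg.frac_k27_positive
    ap1_mask = rng.random(n) < cfg.frac_ap1
    si = peaks.index[peaks["name"] == showcase_peak["name"]][0]
    gr_mask[si] = True
    k27_mask[si] = True
    ap1_mask[si] = False
    gre_mask = gr_mask & (rng.random(n) < cfg.frac_gre)
    gre_mask[si] = True
    peaks = peaks.assign(gr_occupied=gr_mask, k27_positive=k27_mask, ap1=ap1_mask, has_gre_planted=gre_mask)

    pwm = gre_pwm()
    sequences: dict[str, str] = {}
    gre_offsets: dict[str, int] = {}
    L = pwm.length
    motif_core = GRE_CONSENSUS
    for _, row in peaks.iterrows():
        width = int(row["end"] - row["start"])
        seq = _random_seq(rng, width)
        if row["has_gre_planted"]:
            off = int(rng.integers(10, width - L - 10))
            spacer = _random_seq(rng, 3)
            planted = motif_core.replace("NNN", spacer)
            seq = seq[:off] + planted + seq[off + L :]
            gre_offsets[row["name"]] = off
        sequences[row["name"]] = seq

    if truth is not None:
        truth.gre_peak_ids = list(peaks.loc[gre_mask, "name"])
        truth.ap1_peak_ids = list(peaks.loc[ap1_mask, "name"])
        truth.hgr_peak_ids = list(peaks.loc[gr_mask & k27_mask, "name"])
        truth.showcase = {
            "peak": showcase_peak["name"],
            "gene": "gene_0",
            "gre_offset": gre_offsets[showcase_peak["name"]],
        }
    return SimGenome(chrom_df, genes, peaks, sequences, pwm, gre_offsets)


def _pick_biased(
    rng: np.random.Generator, pool: np.ndarray, prefer: np.ndarray, k: int, bias: float = 0.7
) -> np.ndarray:
    """Pick k ids, a ``bias`` fraction from ``prefer`` and the rest from the complement."""
    prefer = np.intersect1d(pool, prefer)
    other = np.setdiff1d(pool, prefer)
    k_pref = min(int(round(bias * k)), len(prefer))
    k_other = min(k - k_pref, len(other))
    picked = np.concatenate(
        [
            rng.choice(prefer, size=k_pref, replace=False),
            rng.choice(other, size=k_other, replace=False),
        ]
    )
    return picked


def simulate_counts(
    cfg: SimConfig, genome: SimGenome, truth: GroundTruth
) -> dict[str, CountMatrix]:
    """NB count matrices for ATAC / H3K27ac / GR over peaks and RNA over genes.

    Counts ~ NB(mean = baseline x library size x fold effect, Var = mu +
    alpha mu^2). Planted responsive features carry 2^planted_log2fc
    (enhanced) or 2^-planted_log2fc (reduced) at treated timepoints;
    enhanced chromatin is planted preferentially at GRE-bearing GR peaks
    and reduced chromatin at AP-1-flagged peaks. Planted SE peaks get an
    additional large H3K27ac gain at treated timepoints. RNA effects are
    planted at the 6 h and later timepoints; the showcase gene is always
    an upregulated DEG.
    """
    rng = _rng(cfg.seed, "counts")
    peaks = genome.peaks
    names = peaks["name"].to_numpy()
    n = len(names)
    gre = peaks["has_gre_planted"].to_numpy()
    ap1 = peaks["ap1"].to_numpy()

    n_resp = int(cfg.frac_responsive * n)
    n_enh = (2 * n_resp) // 3
    n_red = n_resp - n_enh
    enh_ids = _pick_biased(rng, names, names[gre], n_enh)
    red_ids = _pick_biased(rng, np.setdiff1d(names, enh_ids), names[ap1 & ~gre], n_red)
    showcase_peak = truth.showcase.get("peak")
    if showcase_peak is not None and showcase_peak not in enh_ids:
        enh_ids = np.append(enh_ids[enh_ids != showcase_peak], showcase_peak)
        red_ids = red_ids[red_ids != showcase_peak]

    n_se = max(1, int(cfg.frac_se_planted * n))
    k27_names = names[peaks["k27_positive"].to_numpy()]
    se_ids = rng.choice(np.setdiff1d(k27_names, red_ids), size=n_se, replace=False)

    treated = [tp for tp in cfg.timepoints if tp != 0.0]
    reps = cfg.replicates_per_condition
    alpha = cfg.nb_dispersion

    out: dict[str, CountMatrix] = {}
    truth.responsive = {}
    for assay in ("atac", "k27", "gr"):
        baseline = rng.lognormal(0.0, 0.8, size=n)
        if assay == "gr":
            baseline = baseline * peaks["gr_occupied"].to_numpy() + 0.05
        if assay == "k27":
            baseline = baseline * peaks["k27_positive"].to_numpy() + 0.05
        rel = baseline / baseline.sum()
        if assay == "k27":
            # planted SE boosts are sized against the whole stitched region's
            # baseline so the treated/0 h ratio survives high-signal neighbours
            stitched = intervals.stitch(peaks[["chrom", "start", "end", "name"]], 12_500)
            region_rel = {}
            for members in stitched["constituents"]:
                tot = rel[np.isin(names, members)].sum()
                for m in members:
                    region_rel[m] = tot
            region_rel_arr = np.array([region_rel[n] for n in names])
        cols, meta = {}, []
        for tp in cfg.timepoints:
            effect = np.ones(n)
            if tp != 0.0:
                effect[np.isin(names, enh_ids)] = 2.0**cfg.planted_log2fc
                effect[np.isin(names, red_ids)] = 2.0**-cfg.planted_log2fc
                if assay == "k27":
                    # planted SE peaks reach >= ~15x the median per-peak signal
                    # and >= 20x their own stitched region's baseline total
                    se_mask = np.isin(names, se_ids)
                    rel_se = np.maximum(rel[se_mask], 1e-12)
                    floor = np.maximum(
                        15.0 * np.median(rel) / rel_se,
                        20.0 * region_rel_arr[se_mask] / rel_se,
                    )
                    effect[se_mask] = np.maximum(
                        np.maximum(effect[se_mask], 50.0), floor
                    )
            for r in range(reps):
                depth = cfg.depth_mean * rng.lognormal(0.0, cfg.library_size_sd)
                mu = rel * effect
                mu = mu / mu.sum() * depth
                sample = f"{assay}_t{tp:g}_rep{r+1}"
                cols[sample] = _nb(rng, mu, alpha)
                meta.append({"sample": sample, "assay": assay, "timepoint": tp, "replicate": r + 1})
        counts = pd.DataFrame(cols, index=names)
        counts.index.name = "feature"
        samples = pd.DataFrame(meta).set_index("sample")
        out[assay] = CountMatrix(counts, samples)
        truth.responsive[assay] = {"enhanced": list(enh_ids), "reduced": list(red_ids)}
    truth.planted_se_ids = list(se_ids)

    # RNA over genes: DEGs planted from 6 h onward
    gnames = genome.genes["gene_id"].to_numpy()
    ng = len(gnames)
    n_deg = int(cfg.frac_responsive * ng)
    n_up = (2 * n_deg) // 3
    up_ids = rng.choice(gnames, size=n_up, replace=False)
    showcase_gene = truth.showcase.get("gene")
    if showcase_gene is not None and showcase_gene not in up_ids:
        up_ids = np.append(up_ids, showcase_gene)
    down_ids = rng.choice(np.setdiff1d(gnames, up_ids), size=n_deg - n_up, replace=False)
    baseline = rng.lognormal(0.0, 0.8, size=ng)
    rel = baseline / baseline.sum()
    cols, meta = {}, []
    for tp in cfg.timepoints:
        effect = np.ones(ng)
        if tp >= 6.0:
            effect[np.isin(gnames, up_ids)] = 2.0**cfg.planted_log2fc
            effect[np.isin(gnames, down_ids)] = 2.0**-cfg.planted_log2fc
        for r in range(reps):
            depth = cfg.depth_mean * rng.lognormal(0.0, cfg.library_size_sd)
            mu = rel * effect
            mu = mu / mu.sum() * depth
            sample = f"rna_t{tp:g}_rep{r+1}"
            cols[sample] = _nb(rng, mu, alpha)
            meta.append({"sample": sample, "assay": "rna", "timepoint": tp, "replicate": r + 1})
    counts = pd.DataFrame(cols, index=gnames)
    counts.index.name = "feature"
    out["rna"] = CountMatrix(counts, pd.DataFrame(meta).set_index("sample"))
    truth.responsive["rna"] = {"enhanced": list(up_ids), "reduced": list(down_ids)}
    return out


def simulate_starr(
    cfg: SimConfig, genome: SimGenome, truth: GroundTruth
) -> dict:
    """STARR-seq DNA input and RNA output libraries per condition.

    DNA counts scale with region length; planted active regions carry an
    RNA/DNA proportion ratio of ``starr_activity_factor`` in their active
    conditions (shared: all; GC-specific: 6 h/24 h; 0h-specific: 0 h).
    Regions with zero DNA are excluded from RNA generation. Returns
    merged per-condition RNA, replicate RNA, pooled input replicates
    and the DNA counts.
    """
    rng = _rng(cfg.seed, "starr")
    peaks = genome.peaks
    names = peaks["name"].to_numpy()
    n = len(names)
    widths = (peaks["end"] - peaks["start"]).to_numpy(dtype=float)
    dna = rng.poisson(cfg.starr_dna_mean * widths / widths.mean())

    n_active = int(cfg.frac_starr_active * n)
    n_shared = int(0.4 * n_active)
    n_gc = int(0.4 * n_active)
    n_0h = n_active - n_shared - n_gc
    covered = names[dna >= 50]
    # GC-activity coincides with the planted GC-responsive chromatin, and
    # the GC-specific class preferentially carries GREs, mirroring the
    # regulatory logic the enrichment tests probe
    enh = np.asarray(truth.responsive.get("atac", {}).get("enhanced", []), dtype=object)
    gre = np.asarray(truth.gre_peak_ids, dtype=object)
    gc_ids = _pick_biased(rng, covered, np.intersect1d(enh, gre), n_gc, bias=0.7)
    rest = np.setdiff1d(covered, gc_ids)
    shared_ids = _pick_biased(rng, rest, enh, n_shared, bias=0.6)
    rest = np.setdiff1d(rest, shared_ids)
    zero_ids = _pick_biased(rng, rest, np.setdiff1d(rest, gre), n_0h, bias=0.9)
    truth.planted_active_starr = {
        "shared": list(shared_ids),
        "GC_specific": list(gc_ids),
        "0h_specific": list(zero_ids),
    }

    conditions = {"0h": 0.0, "6h": 6.0, "24h": 24.0}
    factor = cfg.starr_activity_factor
    merged = {}
    replicate_rna = {}
    for cond in conditions:
        act = np.ones(n)
        act[np.isin(names, shared_ids)] = factor
        if cond in ("6h", "24h"):
            act[np.isin(names, gc_ids)] = factor
        else:
            act[np.isin(names, zero_ids)] = factor
        w = dna * act
        w[dna == 0] = 0.0
        p = w / w.sum()
        total = int(cfg.starr_rna_total * rng.lognormal(0.0, 0.1))
        merged[cond] = rng.multinomial(total, p)
        rep_cols = {}
        for r in range(4):
            rep_total = int(cfg.starr_rna_total / 4 * rng.lognormal(0.0, 0.15))
            rep_cols[f"rna_{cond}_rep{r+1}"] = rng.multinomial(rep_total, p)
        replicate_rna[cond] = pd.DataFrame(rep_cols, index=names)

    input_cols = {}
    p_dna = dna / dna.sum() if dna.sum() else np.full(n, 1 / n)
    for r in range(3):
        total = int(cfg.starr_rna_total * rng.lognormal(0.0, 0.1))
        input_cols[f"input_rep{r+1}"] = rng.multinomial(total, p_dna)
    return {
        "dna": pd.Series(dna, index=names, name="dna"),
        "rna_merged": pd.DataFrame(merged, index=names),
        "rna_replicates": replicate_rna,
        "input_replicates": pd.DataFrame(input_cols, index=names),
    }


def simulate_screen(
    cfg: SimConfig, hgr_site_ids: list[str], truth: GroundTruth
) -> dict:
    """CRISPRi sgRNA count table over the HGR site universe.

    ~``sgrnas_per_site_mean`` sgRNAs per site (Poisson, min 1) plus
    ``n_control_sgrnas`` non-targeting controls; planted resistance
    sites have post-selection means inflated by 2^screen_log2fc on every
    sgRNA; all other sgRNAs follow the null count model.
    """
    if not hgr_site_ids:
        raise ValueError("HGR site universe is empty")
    rng = _rng(cfg.seed, "screen")
    sites = list(hgr_site_ids)
    n_planted = max(1, int(cfg.frac_screen_planted * len(sites)))
    showcase_peak = truth.showcase.get("peak")
    pool = [s for s in sites if s != showcase_peak]
    planted = list(rng.choice(pool, size=min(n_planted, len(pool)), replace=False))
    if showcase_peak in sites:
        planted.append(showcase_peak)
    truth.planted_screen_site_ids = planted
    planted_set = set(planted)

    rows = []
    sg_id = 0
    for site in sites:
        k = max(1, int(rng.poisson(cfg.sgrnas_per_site_mean)))
        for _ in range(k):
            rows.append((f"sg_{sg_id}", site))
            sg_id += 1
    for _ in range(cfg.n_control_sgrnas):
        rows.append((f"sg_{sg_id}", "control"))
        sg_id += 1
    table = pd.DataFrame(rows, columns=["sgrna", "site"]).set_index("sgrna")

    m = len(table)
    base_mean = cfg.screen_depth * rng.lognormal(0.0, 0.3, size=m)
    effect = np.where(table["site"].isin(planted_set), 2.0**cfg.screen_log2fc, 1.0)
    cols, meta = {}, []
    for r in range(cfg.screen_replicates):
        sf = rng.lognormal(0.0, cfg.library_size_sd)
        cols[f"baseline_rep{r+1}"] = _nb(rng, base_mean * sf, cfg.nb_dispersion)
        meta.append({"sample": f"baseline_rep{r+1}", "arm": "baseline"})
    for r in range(cfg.screen_replicates):
        sf = rng.lognormal(0.0, cfg.library_size_sd)
        cols[f"post_rep{r+1}"] = _nb(rng, base_mean * effect * sf, cfg.nb_dispersion)
        meta.append({"sample": f"post_rep{r+1}", "arm": "post"})
    counts = pd.DataFrame(cols, index=table.index)
    return {
        "counts": counts,
        "site_map": table["site"],
        "arms": pd.DataFrame(meta).set_index("sample")["arm"],
    }


def simulate_loops(
    cfg: SimConfig, genome: SimGenome, truth: GroundTruth
) -> pd.DataFrame:
    """Significant loop list (anchors + q) with planted regulatory wiring.

    A ``promoter_fraction`` of loops joins a distal peak anchor to a
    promoter anchor; the planted pairs connect enhanced-K27 responsive
    peaks to upregulated DEG promoters and reduced peaks to downregulated
    ones (pure concordant wiring), always including the showcase
    peak-gene pair. Self-loops are never emitted.
    """
    rng = _rng(cfg.seed, "loops")
    peaks = genome.peaks
    genes = genome.genes.set_index("gene_id")
    rows = []

    def add_loop(peak_row, gene_id):
        tss = int(genes.at[gene_id, "tss"])
        rows.append(
            {
                "chromA": peak_row["chrom"],
                "startA": int(peak_row["start"]),
                "endA": int(peak_row["end"]),
                "chromB": genes.at[gene_id, "chrom"],
                "startB": max(0, tss - 1000),
                "endB": tss + 1000,
                "q": float(rng.uniform(0, 0.009)),
                "planted": True,
            }
        )

    resp = truth.responsive.get("k27", {})
    rna = truth.responsive.get("rna", {})
    peak_by_name = peaks.set_index("name")
    pairs = []
    enh = [p for p in resp.get("enhanced", []) if p in peak_by_name.index]
    red = [p for p in resp.get("reduced", []) if p in peak_by_name.index]
    up = list(rna.get("enhanced", []))
    down = list(rna.get("reduced", []))
    n_half = cfg.n_planted_loops // 2
    for _ in range(n_half):
        pairs.append((enh[int(rng.integers(len(enh)))], up[int(rng.integers(len(up)))]))
    for _ in range(cfg.n_planted_loops - n_half):
        pairs.append((red[int(rng.integers(len(red)))], down[int(rng.integers(len(down)))]))
    if truth.showcase:
        pairs.append((truth.showcase["peak"], truth.showcase["gene"]))
    for peak, gene in pairs:
        add_loop(peak_by_name.loc[peak], gene)
    truth.planted_loop_pairs = pairs

    n_rand = cfg.n_loops - len(pairs)
    n_prom = int(cfg.promoter_fraction * cfg.n_loops) - len(pairs)
    names = peaks["name"].to_numpy()
    gene_ids = genome.genes["gene_id"].to_numpy()
    for i in range(max(0, n_rand)):
        pr = peak_by_name.loc[names[int(rng.integers(len(names)))]]
        if i < max(0, n_prom):
            add_loop(pr, gene_ids[int(rng.integers(len(gene_ids)))])
            rows[-1]["planted"] = False
        else:
            other = peak_by_name.loc[names[int(rng.integers(len(names)))]]
            while other.name == pr.name:
                other = peak_by_name.loc[names[int(rng.integers(len(names)))]]
            rows.append(
                {
                    "chromA": pr["chrom"],
                    "startA": int(pr["start"]),
                    "endA": int(pr["end"]),
                    "chromB": other["chrom"],
                    "startB": int(other["start"]),
                    "endB": int(other["end"]),
                    "q": float(rng.uniform(0, 0.009)),
                    "planted": False,
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(cfg: SimConfig, genome: SimGenome, truth: GroundTruth):
    """Patient cohort with planted resistance biology.

    Resistant patients carry reduced accessibility at planted resistance
    sites (``frac_occluded`` of which close; the rest open), planted
    preferentially at HGR peaks; CpG probes at those sites move opposite
    to accessibility for ``methylation_anticorr_frac`` of probes; one
    causal variant sits in the showcase peak's GRE (alt allele = worst
    base of a high-information column) and shifts both the phenotype and
    the showcase gene's expression additively. Returns a
    ``patient_integration.Cohort``.
    """
    from .patient_integration import Cohort

    if cfg.n_patients < 8:
        raise ValueError("need n_patients >= 8")
    if len(cfg.subtypes) < 2:
        raise ValueError("need >= 2 subtypes")
    rng = _rng(cfg.seed, "cohort")
    n = cfg.n_patients
    ids = [f"pt_{i}" for i in range(n)]
    subtype = np.array([cfg.subtypes[i % len(cfg.subtypes)] for i in range(n)])
    resistant = rng.random(n) < cfg.frac_resistant
    if resistant.all() or (~resistant).all():
        resistant[0] = ~resistant[0]

    peaks = genome.peaks
    names = peaks["name"].to_numpy()
    hgr_names = names[(peaks["gr_occupied"] & peaks["k27_positive"]).to_numpy()]
    n_sites = max(2, int(cfg.frac_resistance_sites * len(names)))
    site_ids = _pick_biased(rng, names, hgr_names, n_sites, bias=0.7)
    showcase_peak = truth.showcase.get("peak")
    if showcase_peak is not None and showcase_peak not in site_ids:
        site_ids = np.append(site_ids, showcase_peak)
    n_occ = int(round(cfg.frac_occluded * len(site_ids)))
    occluded = set(site_ids[:n_occ]) | ({showcase_peak} if showcase_peak else set())
    opened = [s for s in site_ids if s not in occluded]
    truth.planted_resistance_site_ids = list(site_ids)
    truth.occluded_site_ids = sorted(occluded)

    # genotypes: causal variant in the showcase GRE plus LD proxies and nulls
    pwm = genome.pwm
    off = truth.showcase["gre_offset"]
    # strongest consensus column within the planted motif (skip spacer)
    col = int(np.argmax(pwm.matrix.max(axis=0)))
    ref_base = GRE_CONSENSUS[col] if GRE_CONSENSUS[col] != "N" else "A"
    worst = "ACGT"[int(np.argmin(pwm.matrix[:, col]))]
    prow = peaks.set_index("name").loc[showcase_peak]
    causal_pos = int(prow["start"]) + off + col
    maf = rng.uniform(0.1, 0.5, size=cfg.n_variants)
    causal_idx = 0
    maf[causal_idx] = 0.3  # the planted causal variant is a common SNP
    dosage = rng.binomial(2, maf[:, None], size=(cfg.n_variants, n))
    var_ids = [f"var_{i}" for i in range(cfg.n_variants)]
    # two proxies in high LD with the causal variant (few genotype flips)
    for proxy_idx in (1, 2):
        d = dosage[causal_idx].copy()
        flip = rng.random(n) < 0.03
        d[flip] = rng.integers(0, 3, size=flip.sum())
        dosage[proxy_idx] = d
    var_rows = []
    for i, vid in enumerate(var_ids):
        if i == causal_idx:
            var_rows.append((vid, prow["chrom"], causal_pos, ref_base, worst))
        else:
            chrom = f"chr{(i % cfg.n_chroms) + 1}"
            var_rows.append(
                (vid, chrom, int(rng.integers(0, cfg.chrom_length)), "A", "G")
            )
    variants = pd.DataFrame(
        var_rows, columns=["variant", "chrom", "pos", "ref", "alt"]
    ).set_index("variant")
    # proxies sit inside the same showcase HGR so fine-mapping keeps them;
    # their ref allele must match the emitted sequence at that offset
    seq = genome.sequences[showcase_peak]
    for k, proxy_idx in enumerate((1, 2)):
        poff = 3 + k
        base = seq[poff]
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[base]
        variants.iloc[proxy_idx, variants.columns.get_loc("chrom")] = prow["chrom"]
        variants.iloc[proxy_idx, variants.columns.get_loc("pos")] = int(prow["start"]) + poff
        variants.iloc[proxy_idx, variants.columns.get_loc("ref")] = base
        variants.iloc[proxy_idx, variants.columns.get_loc("alt")] = alt
    dosages = pd.DataFrame(dosage, index=var_ids, columns=ids)
    truth.causal_variant = {
        "variant": var_ids[causal_idx],
        "hgr": showcase_peak,
        "gene": truth.showcase.get("gene"),
        "ref": ref_base,
        "alt": worst,
        "pos": causal_pos,
    }

    # status term sd 0.6 + noise sd 0.8 => residual sd ~1.0 around the
    # additive genetic effect
    pheno = (
        1.2 * resistant
        + cfg.causal_effect_per_allele * dosage[causal_idx]
        + rng.normal(0, 0.8, size=n)
    )
    samples = pd.DataFrame(
        {
            "subtype": subtype,
            "phenotype": pheno,
            "resistance_class": np.where(resistant, "resistant", "sensitive"),
        },
        index=ids,
    )

    # accessibility counts over the peak universe
    baseline = rng.lognormal(0.0, 0.8, size=len(names))
    rel = baseline / baseline.sum()
    occ_mask = np.isin(names, sorted(occluded))
    open_mask = np.isin(names, opened)
    cols = {}
    for j, pid in enumerate(ids):
        effect = np.ones(len(names))
        if resistant[j]:
            effect[occ_mask] = 2.0**-cfg.planted_log2fc
            effect[open_mask] = 2.0**cfg.planted_log2fc
        depth = cfg.cohort_depth * rng.lognormal(0.0, cfg.library_size_sd)
        mu = rel * effect
        mu = mu / mu.sum() * depth
        cols[pid] = _nb(rng, mu, cfg.nb_dispersion)
    acc_counts = pd.DataFrame(cols, index=names)
    acc_counts.index.name = "feature"
    acc = CountMatrix(acc_counts, samples[["subtype"]].copy())

    # methylation probes at resistance sites
    prow_all = peaks.set_index("name")
    probe_rows = []
    betas = {}
    for k, site in enumerate(sorted(site_ids)):
        s = prow_all.loc[site]
        pos = int((s["start"] + s["end"]) // 2)
        probe = f"cg_{k}"
        base_beta = rng.uniform(0.25, 0.45)
        concordant = rng.random() < cfg.methylation_anticorr_frac
        acc_down = site in occluded
        meth_up = acc_down if concordant else not acc_down
        shift = 0.25 if meth_up else -0.2
        vals = np.clip(
            base_beta + shift * resistant + rng.normal(0, 0.03, size=n), 0.0, 1.0
        )
        probe_rows.append({"probe": probe, "chrom": s["chrom"], "pos": pos})
        betas[probe] = vals
    meth = pd.DataFrame(probe_rows).set_index("probe")
    beta_frame = pd.DataFrame(
        np.vstack([betas[pr] for pr in meth.index]) if len(meth) else np.empty((0, n)),
        index=meth.index,
        columns=ids,
    )
    meth = pd.concat([meth, beta_frame], axis=1)

    # expression over genes, with the causal eQTL on the showcase gene
    gnames = genome.genes["gene_id"].to_numpy()
    gbase = rng.lognormal(0.0, 0.8, size=len(gnames))
    grel = gbase / gbase.sum()
    gidx = {g: i for i, g in enumerate(gnames)}
    cols = {}
    tgt = gidx[truth.showcase["gene"]]
    for j, pid in enumerate(ids):
        effect = np.ones(len(gnames))
        effect[tgt] = 2.0 ** (-0.5 * dosage[causal_idx, j])
        depth = cfg.cohort_depth * rng.lognormal(0.0, cfg.library_size_sd)
        mu = grel * effect
        mu = mu / mu.sum() * depth
        cols[pid] = _nb(rng, mu, cfg.nb_dispersion)
    expr_counts = pd.DataFrame(cols, index=gnames)
    expr_counts.index.name = "feature"
    expr = CountMatrix(expr_counts, samples[["subtype"]].copy())

    # resistance gene list: the showcase gene plus a random draw of DEGs
    deg_up = truth.responsive.get("rna", {}).get("enhanced", [])
    extra = [g for g in deg_up if g != truth.showcase["gene"]]
    listed = [truth.showcase["gene"]] + list(
        rng.choice(extra, size=min(10, len(extra)), replace=False)
    )
    truth.resistance_gene_list = listed

    return Cohort(
        samples=samples,
        accessibility=acc,
        methylation=meth,
        dosages=dosages,
        variants=variants,
        expression=expr,
    )


def simulate_footprints(cfg: SimConfig, truth: GroundTruth) -> dict:
    """Per-TF insertion profiles at 0 h and 24 h.

    All TFs are bound at 0 h (core insertion rate at half the flank
    rate); a quarter of TFs — AP-1 family members — lose the footprint
    at 24 h (core rate returns to the flank level). The remaining TFs
    are null (unchanged between conditions).
    """
    rng = _rng(cfg.seed, "footprints")
    window = 201
    core_hw = 5
    centre = window // 2
    tf_names = [f"AP1_TF{i}" for i in range(max(1, cfg.n_footprint_tfs // 4))]
    tf_names += [f"TF{i}" for i in range(cfg.n_footprint_tfs - len(tf_names))]
    profiles: dict[str, dict[str, FootprintProfile]] = {}
    truth.planted_footprint_tfs = {}
    for tf in tf_names:
        planted = tf.startswith("AP1_")
        lam = np.full(window, 2.0)
        lam_bound = lam.copy()
        lam_bound[centre - core_hw : centre + core_hw + 1] = 1.0
        n_sites = cfg.footprint_sites_per_tf
        c0 = rng.poisson(lam_bound, size=(n_sites, window))
        lam24 = lam if planted else lam_bound
        c24 = rng.poisson(lam24, size=(n_sites, window))
        profiles[tf] = {
            "0h": FootprintProfile(tf, c0, core_hw),
            "24h": FootprintProfile(tf, c24, core_hw),
        }
        if planted:
            truth.planted_footprint_tfs[tf] = "reduced_at_24h"
    return profiles


@dataclass
class SyntheticStudy:
    config: SimConfig
    genome: SimGenome
    counts: dict
    starr: dict
    screen: dict
    loops: pd.DataFrame
    cohort: object
    footprints: dict
    truth: GroundTruth


def simulate_study(cfg: SimConfig) -> SyntheticStudy:
    """Run every generator stage in order and return the full bundle."""
    truth = GroundTruth()
    genome = simulate_genome(cfg, truth)
    counts = simulate_counts(cfg, genome, truth)
    starr = simulate_starr(cfg, genome, truth)
    screen = simulate_screen(cfg, truth.hgr_peak_ids, truth)
    loops = simulate_loops(cfg, genome, truth)
    cohort = simulate_cohort(cfg, genome, truth)
    fps = simulate_footprints(cfg, truth)
    return SyntheticStudy(cfg, genome, counts, starr, screen, loops, cohort, fps, truth)


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_vcf(variants: pd.DataFrame, dosages: pd.DataFrame, path: str | Path) -> None:
    """Minimal VCF 4.2 with GT calls derived from dosages (0-based pos -> 1-based)."""
    samples = list(dosages.columns)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for vid, row in variants.iterrows():
            gts = "\t".join(gt_map[int(d)] for d in dosages.loc[vid])
            fh.write(
                f"{row['chrom']}\t{int(row['pos']) + 1}\t{vid}\t{row['ref']}\t{row['alt']}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Emit every generator output as plain-text standard formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    intervals.write_bed(study.genome.peaks, out / "peaks.bed")
    intervals.write_gene_models(study.genome.genes, out / "genes.tsv")
    write_fasta(study.genome.sequences, out / "peaks.fasta")
    for assay, cm in study.counts.items():
        cm.to_tsv(out / f"counts_{assay}.tsv", out / f"samples_{assay}.tsv")
    study.starr["dna"].to_csv(out / "starr_dna.tsv", sep="\t", header=True, index_label="feature")
    study.starr["rna_merged"].to_csv(out / "starr_rna_merged.tsv", sep="\t", index_label="feature")
    study.loops.to_csv(out / "loops.tsv", sep="\t", index=False)
    study.screen["counts"].assign(site=study.screen["site_map"]).to_csv(
        out / "screen_counts.tsv", sep="\t", index_label="sgrna"
    )
    study.cohort.samples.to_csv(out / "cohort_samples.tsv", sep="\t", index_label="sample")
    study.cohort.methylation.to_csv(out / "methylation.tsv", sep="\t", index_label="probe")
    write_vcf(study.cohort.variants, study.cohort.dosages, out / "variants.vcf")
    study.cohort.dosages.to_csv(out / "dosages.tsv", sep="\t", index_label="variant")
    study.truth.to_json(out / "ground_truth.json")
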