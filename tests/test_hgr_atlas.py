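"""HGR calling, PWM scanning, GRE/response enrichment."""

import numpy as np
import pandas as pd
import pytest

from gcregulome import intervals
from gcregulome.hgr_atlas import (
    GRE_CONSENSUS,
    PWM,
    call_hgrs,
    gre_pwm,
    gre_response_enrichment,
    hgr_deg_distance_test,
    reverse_complement,
    scan_pwm,
)


def peaks_df(tuples):
    return intervals.make_peaks(
        pd.DataFrame(
            [
                {"chrom": c, "start": s, "end": e, "name": n}
                for c, s, e, n in tuples
            ]
        )
    )


class TestPWM:
    def test_consensus_scores_max(self):
        pwm = gre_pwm()
        seq = "TTTT" + GRE_CONSENSUS.replace("NNN", "ACG") + "TTTT"
        hit = scan_pwm(seq, pwm)
        assert hit.is_hit
        assert hit.score == pytest.approx(pwm.max_score)
        assert hit.position == 4 and hit.strand == "+"

    def test_reverse_complement_strand_symmetry(self):
        pwm = gre_pwm()
        fwd = "AAAA" + GRE_CONSENSUS.replace("NNN", "CCT") + "GGGG"
        rev = reverse_complement(fwd)
        h1 = scan_pwm(fwd, pwm)
        h2 = scan_pwm(rev, pwm)
        assert h1.score == pytest.approx(h2.score)

    def test_short_sequence_returns_none(self):
        assert scan_pwm("ACGT", gre_pwm()) is None

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_per_offset_rescoring(self, seed):
        rng = np.random.default_rng(seed)
        pwm = gre_pwm()
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
        hit = scan_pwm(seq, pwm, threshold_frac=0.0)
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}

        def score(s, off):
            return sum(pwm.matrix[idx[s[off + j]], j] for j in range(pwm.length))

        best = -np.inf
        for strand_seq in (seq, reverse_complement(seq)):
            for off in range(len(seq) - pwm.length + 1):
                best = max(best, score(strand_seq, off))
        assert hit.score == pytest.approx(best)

    def test_ambiguous_base_scores_worst(self):
        pwm = gre_pwm()
        consensus = GRE_CONSENSUS.replace("NNN", "AAA")
        broken = "N" + consensus[1:]
        h = scan_pwm(broken, pwm, threshold_frac=0.0)
        assert h.score < pwm.max_score

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            PWM(np.ones((3, 10)))
        with pytest.raises(ValueError):
            PWM(np.full((4, 6), np.inf))


class TestCallHgrs:
    def test_triple_overlap_qualifies(self):
        gr = {0.0: peaks_df([("chr1", 100, 200, "g1")])}
        atac = {0.0: peaks_df([("chr1", 150, 250, "a1")])}
        k27 = {0.0: peaks_df([("chr1", 0, 1000, "k1")])}
        out = call_hgrs(gr, atac, k27)
        assert len(out) == 1
        assert out.iloc[0][["start", "end"]].tolist() == [100, 200]

    def test_missing_companion_excludes(self):
        gr = {0.0: peaks_df([("chr1", 100, 200, "g1")])}
        atac = {0.0: peaks_df([("chr1", 500, 600, "a1")])}
        k27 = {0.0: peaks_df([("chr1", 0, 1000, "k1")])}
        assert call_hgrs(gr, atac, k27).empty

    def test_footprint_is_gr_interval_not_intersection(self):
        gr = {0.0: peaks_df([("chr1", 100, 900, "g1")])}
        atac = {0.0: peaks_df([("chr1", 850, 950, "a1")])}
        k27 = {0.0: peaks_df([("chr1", 0, 120, "k1")])}
        out = call_hgrs(gr, atac, k27)
        assert out.iloc[0][["start", "end"]].tolist() == [100, 900]

    def test_timepoint_order_invariance_and_union(self):
        gr_a = peaks_df([("chr1", 100, 200, "g1")])
        gr_b = peaks_df([("chr1", 5000, 5100, "g2")])
        atac = peaks_df([("chr1", 100, 5100, "a1")])
        k27 = peaks_df([("chr1", 100, 5100, "k1")])
        out1 = call_hgrs({0.0: gr_a, 6.0: gr_b}, {0.0: atac, 6.0: atac}, {0.0: k27, 6.0: k27})
        out2 = call_hgrs({6.0: gr_b, 0.0: gr_a}, {6.0: atac, 0.0: atac}, {6.0: k27, 0.0: k27})
        pd.testing.assert_frame_equal(
            out1[["chrom", "start", "end"]], out2[["chrom", "start", "end"]]
        )
        assert len(out1) == 2

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_triple_overlap_oracle(self, seed):
        rng = np.random.default_rng(seed)

        def rand(n, prefix):
            s = rng.integers(0, 50_000, size=n)
            return peaks_df(
                [("chr1", int(a), int(a + rng.integers(50, 400)), f"{prefix}{i}") for i, a in enumerate(s)]
            )

        gr, atac, k27 = rand(60, "g"), rand(60, "a"), rand(60, "k")
        out = call_hgrs({0.0: gr}, {0.0: atac}, {0.0: k27})

        def hits(p, others):
            return any(
                max(p["start"], o["start"]) < min(p["end"], o["end"])
                for _, o in others.iterrows()
            )

        qualifying = [
            (r["start"], r["end"])
            for _, r in gr.iterrows()
            if hits(r, atac) and hits(r, k27)
        ]
        covered = 0
        for s, e in qualifying:
            assert ((out["start"] <= s) & (out["end"] >= e)).any()
            covered += 1
        # every output interval is a merge of qualifying GR peaks
        for _, r in out.iterrows():
            assert any(s >= r["start"] and e <= r["end"] for s, e in qualifying)
        assert covered == len(qualifying)


class TestEnrichment:
    def test_planted_gre_activation_enriched(self):
        rng = np.random.default_rng(0)
        n = 400
        gre = rng.random(n) < 0.5
        enh = np.where(gre, rng.random(n) < 0.6, rng.random(n) < 0.2)
        hgrs = pd.DataFrame({"has_gre": gre, "enhanced": enh})
        _, odds, p = gre_response_enrichment(hgrs)
        assert odds > 1 and p < 0.05

    def test_shuffled_labels_null(self):
        rng = np.random.default_rng(1)
        n = 400
        hgrs = pd.DataFrame(
            {"has_gre": rng.random(n) < 0.5, "enhanced": rng.random(n) < 0.3}
        )
        _, odds, p = gre_response_enrichment(hgrs)
        assert p > 0.001 and 0.4 < odds < 2.5

    def test_perfect_separation_infinite_odds(self):
        hgrs = pd.DataFrame(
            {"has_gre": [True] * 10 + [False] * 10, "enhanced": [True] * 10 + [False] * 10}
        )
        _, odds, _ = gre_response_enrichment(hgrs)
        assert odds == np.inf


class TestDegDistance:
    def test_planted_proximity_detected(self):
        rng = np.random.default_rng(2)
        up_genes = pd.DataFrame(
            {
                "gene_id": [f"u{i}" for i in range(20)],
                "chrom": "chr1",
                "tss": np.arange(20) * 100_000,
                "strand": "+",
            }
        )
        down_genes = up_genes.assign(
            gene_id=[f"d{i}" for i in range(20)], tss=np.arange(20) * 100_000 + 50_000
        )
        genes = pd.concat([up_genes, down_genes], ignore_index=True)
        degs = pd.DataFrame(
            {"direction": ["enhanced"] * 20 + ["reduced"] * 20},
            index=list(up_genes["gene_id"]) + list(down_genes["gene_id"]),
        )
        # enhanced HGRs placed within 2 kb of up-gene TSSs
        starts = up_genes["tss"].to_numpy()[:15] + 1_000
        hgrs = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": starts,
                "end": starts + 500,
                "name": [f"h{i}" for i in range(15)],
                "direction": "enhanced",
            }
        )
        out = hgr_deg_distance_test(hgrs, "direction", degs, genes)
        row = out[out["hgr_direction"] == "enhanced"].iloc[0]
        assert row["ks_p"] < 0.01
        assert row["median_dist_up"] < row["median_dist_down"]

    def test_too_few_genes_rejected(self):
        genes = pd.DataFrame(
            {"gene_id": ["g1"], "chrom": ["chr1"], "tss": [100], "strand": ["+"]}
        )
        degs = pd.DataFrame({"direction": ["enhanced"]}, index=["g1"])
        hgrs = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [10], "name": ["h"], "direction": ["enhanced"]}
        )
        with pytest.raises(ValueError):
            hgr_deg_distance_test(hgrs, "direction", degs, genes)
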