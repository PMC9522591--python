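"""Interval algebra against brute-force oracles and hand-enumerated layouts."""

import numpy as np
import pandas as pd
import pytest

from gcregulome import intervals


def random_peaks(rng, n, chroms=("chr1", "chr2"), span=100_000):
    starts = rng.integers(0, span, size=n)
    widths = rng.integers(1, 500, size=n)
    return intervals.make_peaks(
        pd.DataFrame(
            {
                "chrom": rng.choice(chroms, size=n),
                "start": starts,
                "end": starts + widths,
                "name": [f"p{i}" for i in range(n)],
            }
        )
    )


class TestBedIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        peaks = random_peaks(rng, 1000)
        path = tmp_path / "x.bed"
        intervals.write_bed(peaks, path)
        back = intervals.read_bed(path)
        pd.testing.assert_frame_equal(
            back[["chrom", "start", "end", "name"]], peaks[["chrom", "start", "end", "name"]]
        )

    def test_simple_line(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t0\t100\n")
        df = intervals.read_bed(p)
        assert df.iloc[0][["chrom", "start", "end"]].tolist() == ["chr1", 0, 100]

    def test_empty_interval_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t50\t60\nchr1\t100\t100\n")
        with pytest.raises(ValueError, match="line 2"):
            intervals.read_bed(p)

    def test_unsorted_input_sorted_on_load(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t500\t600\tb\nchr1\t0\t100\ta\n")
        df = intervals.read_bed(p)
        assert list(df["name"]) == ["a", "b"]


class TestIntersect:
    def test_basic_overlap(self):
        a = intervals.make_peaks(pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100], "name": ["a"]}))
        b = intervals.make_peaks(pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [150], "name": ["b"]}))
        pairs = intervals.intersect(a, b)
        assert len(pairs) == 1 and pairs.iloc[0]["overlap_bp"] == 50

    def test_half_open_adjacency(self):
        a = intervals.make_peaks(pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100], "name": ["a"]}))
        b = intervals.make_peaks(pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200], "name": ["b"]}))
        assert intervals.intersect(a, b).empty

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = random_peaks(rng, 200)
        b = random_peaks(rng, 200)
        got = {
            (r["name_a"], r["name_b"]) for _, r in intervals.intersect(a, b, 5).iterrows()
        }
        want = set()
        for _, ra in a.iterrows():
            for _, rb in b.iterrows():
                if ra["chrom"] != rb["chrom"]:
                    continue
                ov = min(ra["end"], rb["end"]) - max(ra["start"], rb["start"])
                if ov >= 5:
                    want.add((ra["name"], rb["name"]))
        assert got == want

    def test_reflexive(self):
        rng = np.random.default_rng(3)
        a = random_peaks(rng, 50)
        pairs = intervals.intersect(a, a)
        self_pairs = {(n, n) for n in a["name"]}
        assert self_pairs <= {(r["name_a"], r["name_b"]) for _, r in pairs.iterrows()}

    def test_monotone_in_min_overlap(self):
        rng = np.random.default_rng(4)
        a = random_peaks(rng, 100)
        b = random_peaks(rng, 100)
        sizes = [len(intervals.intersect(a, b, m)) for m in (1, 50, 200)]
        assert sizes == sorted(sizes, reverse=True)


class TestStitch:
    def test_merges_within_gap(self):
        p = intervals.make_peaks(
            pd.DataFrame({"chrom": ["chr1"] * 2, "start": [0, 200], "end": [100, 300], "name": ["a", "b"]})
        )
        out = intervals.stitch(p, 12500)
        assert len(out) == 1
        assert out.iloc[0]["start"] == 0 and out.iloc[0]["end"] == 300
        assert out.iloc[0]["constituents"] == ["a", "b"]

    def test_keeps_far_apart(self):
        p = intervals.make_peaks(
            pd.DataFrame({"chrom": ["chr1"] * 2, "start": [0, 20000], "end": [100, 20100], "name": ["a", "b"]})
        )
        assert len(intervals.stitch(p, 12500)) == 2

    def test_negative_gap_rejected(self):
        p = intervals.make_peaks(pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10], "name": ["a"]}))
        with pytest.raises(ValueError):
            intervals.stitch(p, -1)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_union_find(self, seed):
        rng = np.random.default_rng(seed)
        peaks = random_peaks(rng, 150)
        gap = 300
        out = intervals.stitch(peaks, gap)
        # union-find oracle: link pairs with gap <= threshold on the same chrom
        parent = {n: n for n in peaks["name"]}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        rows = list(peaks.iterrows())
        for _, ra in rows:
            for _, rb in rows:
                if ra["chrom"] != rb["chrom"] or ra["name"] == rb["name"]:
                    continue
                if max(ra["start"], rb["start"]) - min(ra["end"], rb["end"]) <= gap:
                    parent[find(ra["name"])] = find(rb["name"])
        oracle_groups = {}
        for n in peaks["name"]:
            oracle_groups.setdefault(find(n), set()).add(n)
        got_groups = {frozenset(c) for c in out["constituents"]}
        assert got_groups == {frozenset(g) for g in oracle_groups.values()}


class TestNearestTss:
    GENES = pd.DataFrame(
        {
            "gene_id": ["gA", "gB"],
            "chrom": ["chr1", "chr1"],
            "tss": [4000, 9000],
            "strand": ["+", "-"],
        }
    )

    def test_picks_closer_tss(self):
        region = pd.DataFrame({"chrom": ["chr1"], "start": [4500], "end": [5500], "name": ["r"]})
        out = intervals.nearest_tss_distance(region, self.GENES)
        assert out.iloc[0]["distance"] == 1000 and out.iloc[0]["gene_id"] == "gA"

    def test_exact_tss_distance_zero(self):
        region = pd.DataFrame({"chrom": ["chr1"], "start": [3500], "end": [4500], "name": ["r"]})
        assert intervals.nearest_tss_distance(region, self.GENES).iloc[0]["distance"] == 0

    def test_tie_broken_lexicographically(self):
        genes = self.GENES.assign(tss=[4000, 6000])
        region = pd.DataFrame({"chrom": ["chr1"], "start": [4500], "end": [5500], "name": ["r"]})
        assert intervals.nearest_tss_distance(region, genes).iloc[0]["gene_id"] == "gA"

    def test_empty_gene_set_rejected(self):
        region = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10], "name": ["r"]})
        with pytest.raises(ValueError):
            intervals.nearest_tss_distance(region, self.GENES.iloc[0:0])

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        regions = random_peaks(rng, 80, chroms=("chr1",))
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(20)],
                "chrom": "chr1",
                "tss": rng.integers(0, 100_000, size=20),
                "strand": "+",
            }
        )
        out = intervals.nearest_tss_distance(regions, genes).set_index("name")
        for _, r in regions.iterrows():
            mid = (r["start"] + r["end"]) // 2
            dmin = min(abs(mid - t) for t in genes["tss"])
            assert abs(out.at[r["name"], "distance"]) == dmin


class TestGeneAssociation:
    def test_basal_domain_hit(self):
        genes = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["chr1"], "tss": [50_000], "strand": ["+"]}
        )
        region = pd.DataFrame({"chrom": ["chr1"], "start": [46_000], "end": [46_500], "name": ["r"]})
        out = intervals.associate_regions_to_genes(region, genes)
        assert list(out["gene_id"]) == ["g"]

    def test_beyond_extension_empty(self):
        genes = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["chr1"], "tss": [50_000], "strand": ["+"]}
        )
        region = pd.DataFrame(
            {"chrom": ["chr1"], "start": [2_100_000], "end": [2_100_500], "name": ["r"]}
        )
        assert intervals.associate_regions_to_genes(region, genes).empty

    def test_three_gene_layout_hand_enumerated(self):
        # g1 (+) tss 100k, g2 (+) tss 160k, g3 (-) tss 400k, all on chr1.
        # basal: g1 [95k,101k), g2 [155k,161k), g3 [399k,405k)
        # extension: g1 left to 0 (1 Mb cap at -900k clipped), right to g2 basal 155k
        #            g2 left to g1 basal end 101k, right to g3 basal start 399k
        #            g3 left to g2 basal end 161k, right to 1.4 Mb
        genes = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3"],
                "chrom": ["chr1"] * 3,
                "tss": [100_000, 160_000, 400_000],
                "strand": ["+", "+", "-"],
            }
        )
        # hand-enumerated domains: g1 [0,155k), g2 [101k,399k), g3 [161k,1400k)
        regions = pd.DataFrame(
            {
                "chrom": ["chr1"] * 4,
                "start": [120_000, 50_000, 300_000, 1_500_000],
                "end": [121_000, 51_000, 301_000, 1_500_100],
                "name": ["between_g1_g2", "in_g1_only", "between_g2_g3", "beyond_g3"],
            }
        )
        out = intervals.associate_regions_to_genes(regions, genes)
        got = set(map(tuple, out[["name", "gene_id"]].to_numpy()))
        assert got == {
            ("between_g1_g2", "g1"),
            ("between_g1_g2", "g2"),
            ("in_g1_only", "g1"),
            ("between_g2_g3", "g2"),
            ("between_g2_g3", "g3"),
        }
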