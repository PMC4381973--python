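"""5'-end reduction, peak calling stand-in, pairing, and genomic summaries."""

import numpy as np
import pandas as pd
import pytest

from tfmap import chipexo as exo
from tfmap import synth

CHROM_SIZES = {"chr1": 200_000, "chr2": 150_000}


def _bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])


class TestFivePrimeReduction:
    def test_forward_read_maps_to_start(self):
        counts = exo.reads_to_5prime(_bed([("chr1", 100, 150, ".", 0, "+")]))
        assert counts.iloc[0]["pos"] == 100

    def test_reverse_read_maps_to_last_base(self):
        counts = exo.reads_to_5prime(_bed([("chr1", 100, 150, ".", 0, "-")]))
        assert counts.iloc[0]["pos"] == 149

    def test_toy_tally_matches_manual_count(self):
        reads = _bed([
            ("chr1", 10, 40, ".", 0, "+"), ("chr1", 10, 45, ".", 0, "+"),
            ("chr1", 10, 50, ".", 0, "+"), ("chr1", 30, 60, ".", 0, "-"),
            ("chr1", 35, 60, ".", 0, "-"), ("chr2", 5, 25, ".", 0, "+"),
            ("chr2", 5, 25, ".", 0, "-"), ("chr2", 5, 25, ".", 0, "-"),
            ("chr1", 12, 40, ".", 0, "+"), ("chr1", 10, 42, ".", 0, "+"),
        ])
        counts = exo.reads_to_5prime(reads)
        assert counts["count"].sum() == 10  # conservation
        fwd_chr1 = counts[(counts.chrom == "chr1") & (counts.strand == "+")]
        assert dict(zip(fwd_chr1.pos, fwd_chr1["count"])) == {10: 4, 12: 1}
        rev_chr1 = counts[(counts.chrom == "chr1") & (counts.strand == "-")]
        assert dict(zip(rev_chr1.pos, rev_chr1["count"])) == {59: 2}
        rev_chr2 = counts[(counts.chrom == "chr2") & (counts.strand == "-")]
        assert dict(zip(rev_chr2.pos, rev_chr2["count"])) == {24: 2}


class TestCallPeaks:
    def _counts(self, positions_counts, strand="+", chrom="chr1"):
        return pd.DataFrame([(chrom, p, strand, c) for p, c in positions_counts],
                            columns=["chrom", "pos", "strand", "count"])

    def test_single_pile_single_peak_at_mode(self):
        counts = self._counts([(995, 3), (1000, 20), (1005, 4)])
        peaks = exo.call_peaks(counts, "+")
        assert len(peaks) == 1
        assert abs(peaks.iloc[0]["mode"] - 1000) <= 2

    def test_two_piles_hundred_bp_apart(self):
        counts = self._counts([(1000, 15), (1100, 15)])
        peaks = exo.call_peaks(counts, "+")
        assert len(peaks) == 2

    def test_recall_on_generated_sites(self):
        _, _, truth = synth.gen_strand_peaks(50, 10, 0, CHROM_SIZES, seed=1)
        reads = synth.gen_exo_reads(truth, 10, 40, 30, 3.0, seed=2)
        counts = exo.reads_to_5prime(reads)
        pk_f = exo.call_peaks(counts, "+")
        pk_r = exo.call_peaks(counts, "-")
        regions, _, _ = exo.pair_peaks(pk_f, pk_r, max_dist_bp=20)
        mids = (regions["start"] + regions["end"]) // 2
        hits = 0
        for _, site in truth.iterrows():
            near = regions["chrom"].eq(site.chrom) & (abs(mids - site.pos) <= 15)
            hits += int(near.any())
        assert hits / len(truth) >= 0.95


class TestPairPeaks:
    def test_simple_pair_region_between_midpoints(self):
        left = _bed([("chr1", 95, 105, "L", 1.0, "+")])
        right = _bed([("chr1", 105, 115, "R", 2.0, "-")])
        regions, ul, ur = exo.pair_peaks(left, right, 20)
        assert len(regions) == 1
        assert (regions.loc[0, "start"], regions.loc[0, "end"]) == (100, 110)
        assert regions.loc[0, "score"] == 3.0
        assert len(ul) == len(ur) == 0

    def test_too_distant_midpoints_not_paired(self):
        left = _bed([("chr1", 95, 105, "L", 1.0, "+")])
        right = _bed([("chr1", 125, 135, "R", 1.0, "-")])
        regions, ul, ur = exo.pair_peaks(left, right, 20)
        assert len(regions) == 0 and len(ul) == 1 and len(ur) == 1

    def test_generator_offset_ten_pairs_fully(self):
        fwd, rev, truth = synth.gen_strand_peaks(60, 10, 0, CHROM_SIZES, seed=3)
        regions, _, _ = exo.pair_peaks(fwd, rev, 20)
        assert len(regions) == len(truth)

    def test_generator_offset_thirty_pairs_nothing(self):
        fwd, rev, _ = synth.gen_strand_peaks(60, 30, 0, CHROM_SIZES, seed=4)
        regions, _, _ = exo.pair_peaks(fwd, rev, 20)
        assert len(regions) == 0

    def test_each_peak_used_at_most_once(self):
        left = _bed([("chr1", 95, 105, "L1", 1.0, "+"),
                     ("chr1", 99, 109, "L2", 1.0, "+")])
        right = _bed([("chr1", 105, 115, "R", 1.0, "-")])
        regions, ul, _ = exo.pair_peaks(left, right, 20)
        assert len(regions) == 1 and len(ul) == 1
        assert len(regions) <= min(len(left), len(right))

    def test_orientation_requirement_toggle(self):
        left = _bed([("chr1", 195, 205, "L", 1.0, "+")])   # mid 200
        right = _bed([("chr1", 185, 195, "R", 1.0, "-")])  # mid 190, upstream
        strict, _, _ = exo.pair_peaks(left, right, 20, require_order=True)
        relaxed, _, _ = exo.pair_peaks(left, right, 20, require_order=False)
        assert len(strict) == 0 and len(relaxed) == 1


class TestChromBinDensity:
    def test_empty_input_all_zero(self):
        regions = pd.DataFrame(columns=["chrom", "start", "end", "score"])
        out = exo.chrom_bin_density(regions, CHROM_SIZES, bins_per_chrom=10)
        assert out["count"].sum() == 0
        assert len(out) == 20

    def test_point_mass_in_single_bin(self):
        regions = pd.DataFrame({"chrom": ["chr1"] * 3, "start": [1000] * 3,
                                "end": [1010] * 3, "score": [1.0, 2.0, 3.0]})
        out = exo.chrom_bin_density(regions, CHROM_SIZES, bins_per_chrom=10)
        nz = out[out["count"] > 0]
        assert len(nz) == 1 and nz.iloc[0]["count"] == 3

    def test_matches_bruteforce_and_top_n(self):
        rng = np.random.default_rng(5)
        n = 200
        chroms = rng.choice(list(CHROM_SIZES), n)
        starts = np.array([rng.integers(0, CHROM_SIZES[c] - 10) for c in chroms])
        regions = pd.DataFrame({"chrom": chroms, "start": starts,
                                "end": starts + 10,
                                "score": rng.random(n)})
        top = 120
        out = exo.chrom_bin_density(regions, CHROM_SIZES, bins_per_chrom=50,
                                    top_n=top)
        assert out["count"].sum() == top
        kept = regions.sort_values("score", ascending=False).head(top)
        for chrom, size in CHROM_SIZES.items():
            mids = ((kept.loc[kept.chrom == chrom, "start"]
                     + kept.loc[kept.chrom == chrom, "end"]) // 2).to_numpy()
            expected = np.histogram(mids, bins=np.linspace(0, size, 51))[0]
            got = out.loc[out.chrom == chrom, "count"].to_numpy()
            np.testing.assert_array_equal(got, expected)


class TestTssDistances:
    TSS = pd.DataFrame({"chrom": ["chr1", "chr1", "chr2"],
                        "pos": [1000, 5000, 2000]})

    def test_region_at_tss_distance_zero(self):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [995],
                                "end": [1005], "score": [1.0]})
        out = exo.tss_distance_cdf(regions, self.TSS)
        assert out["distances"][0] == 0

    def test_single_tss_distance(self):
        regions = pd.DataFrame({"chrom": ["chr2"], "start": [1495],
                                "end": [1505], "score": [1.0]})
        out = exo.tss_distance_cdf(regions, self.TSS)
        assert out["distances"][0] == 500

    def test_cdf_properties_and_bruteforce(self):
        rng = np.random.default_rng(6)
        n = 100
        chroms = rng.choice(list(CHROM_SIZES), n)
        starts = np.array([rng.integers(0, CHROM_SIZES[c] - 10) for c in chroms])
        regions = pd.DataFrame({"chrom": chroms, "start": starts,
                                "end": starts + 10, "score": 1.0})
        out = exo.tss_distance_cdf(regions, self.TSS, chrom_sizes=CHROM_SIZES,
                                   seed=7)
        # brute-force nearest-TSS scan
        expected = []
        for c, s in zip(chroms, starts):
            mid = s + 5
            cand = self.TSS.loc[self.TSS.chrom == c, "pos"]
            expected.append(min(abs(cand - mid)))
        np.testing.assert_array_equal(out["distances"], np.sort(expected))
        cdf = out["cdf"]
        assert (np.diff(cdf) >= 0).all() and cdf[-1] == 1.0
        assert len(out["random_distances"]) == n
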