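"""Sliding-window genotyping, block smoothing, binning and map diagnostics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aioseq.binmap import (
    HET,
    P1,
    P2,
    Block,
    GenotypeTrack,
    breakpoint_stats,
    build_bins,
    collinearity,
    exclude_samples,
    interval_matrix,
    smooth_blocks,
    tracks_from_calls,
    window_genotype,
)

MB = 1_000_000


def track(sample, spans, chrom="chr1"):
    """spans: list of (length_bp, genotype); converted to tiling blocks."""
    blocks, start = [], 1
    for length, g in spans:
        blocks.append(Block(start, start + length - 1, g))
        start += length
    return GenotypeTrack(sample, {chrom: blocks})


def alternating_track(sample, n_breakpoints, block_len=MB, chrom="chr1"):
    genos = [P1, P2]
    spans = [(block_len, genos[i % 2]) for i in range(n_breakpoints + 1)]
    return track(sample, spans, chrom)


class TestWindowGenotype:
    def test_pure_p1_single_block(self):
        pos = np.arange(1, 16) * 1000
        blocks, low = window_genotype(pos, [P1] * 15, chrom_length=20_000)
        assert blocks == [Block(1, 20_000, P1)] and not low

    def test_mixed_window_is_het(self):
        calls = [P2] * 7 + [P1] * 8  # f = 7/15 ~ 0.47, inside the band
        pos = np.arange(1, 16) * 1000
        blocks, _ = window_genotype(pos, calls, chrom_length=20_000)
        assert blocks == [Block(1, 20_000, HET)]

    def test_fewer_calls_than_window_majority_vote(self):
        blocks, low = window_genotype([100, 200], [P1, P1], chrom_length=5_000)
        assert low and blocks == [Block(1, 5_000, P1)]

    def test_band_boundaries_inclusive(self):
        # f exactly 0.3 -> P1; f exactly 0.7 -> P2 (window of 10)
        pos = np.arange(1, 11) * 10
        b_lo, _ = window_genotype(pos, [P2] * 3 + [P1] * 7, window_size=10,
                                  chrom_length=200)
        b_hi, _ = window_genotype(pos, [P2] * 7 + [P1] * 3, window_size=10,
                                  chrom_length=200)
        assert b_lo[0].genotype == P1 and b_hi[0].genotype == P2

    def test_crossover_localized_within_window_span(self, rng):
        """One true crossover with 1% call error lands within a window-span."""
        n, true_x = 400, 2_000_000
        pos = np.sort(rng.choice(np.arange(1, 4 * MB), size=n, replace=False))
        calls = np.where(pos < true_x, P1, P2)
        flip = rng.random(n) < 0.01
        calls = np.where(flip, np.where(calls == P1, P2, P1), calls)
        blocks, _ = window_genotype(pos, calls, chrom_length=4 * MB)
        t = GenotypeTrack("s", {"chr1": blocks})
        sm = smooth_blocks(t)
        hom = [b for b in sm.blocks["chr1"] if b.genotype in (P1, P2)]
        assert hom[0].genotype == P1 and hom[-1].genotype == P2
        boundary = hom[0].end
        window_span = 15 * (4 * MB / n)
        assert abs(boundary - true_x) < window_span

    def test_input_validation(self):
        with pytest.raises(ValueError):
            window_genotype([1, 2], [P1], chrom_length=10)
        with pytest.raises(ValueError):
            window_genotype([], [], chrom_length=10)
        with pytest.raises(ValueError):
            window_genotype([1], ["bogus"], chrom_length=10)


class TestSmoothBlocks:
    def test_short_het_between_same_homozygotes_absorbed(self):
        t = track("s", [(2 * MB, P1), (300_000, HET), (3 * MB, P1)])
        sm = smooth_blocks(t)
        assert sm.blocks["chr1"] == [Block(1, 5_300_000, P1)]
        assert t.breakpoints == 2 and sm.breakpoints == 0

    def test_half_mb_boundary_is_kept(self):
        t = track("s", [(2 * MB, P1), (600_000, HET), (3 * MB, P1)])
        assert smooth_blocks(t).blocks["chr1"] == t.blocks["chr1"]
        # exactly 0.5 Mb is NOT "< 0.5 Mb"
        t2 = track("s", [(2 * MB, P1), (500_000, HET), (3 * MB, P1)])
        assert smooth_blocks(t2).blocks["chr1"] == t2.blocks["chr1"]

    def test_differing_flanks_untouched(self):
        t = track("s", [(2 * MB, P1), (300_000, HET), (3 * MB, P2)])
        assert smooth_blocks(t).blocks["chr1"] == t.blocks["chr1"]

    def test_short_homozygous_inside_het_absorbed(self):
        t = track("s", [(2 * MB, HET), (200_000, P2), (2 * MB, HET)])
        assert smooth_blocks(t).blocks["chr1"] == [Block(1, 4_200_000, HET)]

    def test_terminal_blocks_never_reassigned(self):
        t = track("s", [(100_000, HET), (3 * MB, P1), (100_000, P2)])
        assert smooth_blocks(t).blocks["chr1"] == t.blocks["chr1"]

    def test_spurious_island_removed_before_bridging(self):
        """A tiny hom island inside HET near a true boundary must not drag
        the boundary: the smallest block is corrected first."""
        t = track(
            "s",
            [(5 * MB, P2), (300_000, HET), (80_000, P2), (4 * MB, HET)],
        )
        sm = smooth_blocks(t)
        assert sm.blocks["chr1"] == [
            Block(1, 5 * MB, P2),
            Block(5 * MB + 1, 9_380_000, HET),
        ]

    @given(
        st.lists(
            st.tuples(
                st.sampled_from([P1, P2, HET]),
                st.integers(min_value=50_000, max_value=2 * MB),
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_fixpoint_idempotent_and_monotone(self, spans):
        t = track("s", [(length, g) for g, length in spans])
        sm = smooth_blocks(t)
        assert sm.breakpoints <= t.breakpoints
        again = smooth_blocks(sm)
        assert again.blocks == sm.blocks
        # fixpoint: no remaining eligible sandwiched short block
        blks = sm.blocks["chr1"]
        for left, mid, right in zip(blks, blks[1:], blks[2:]):
            if mid.length >= 500_000:
                continue
            if mid.genotype == HET:
                assert not (left.genotype == right.genotype != HET)
            else:
                assert not (left.genotype == right.genotype == HET)


class TestExcludeSamples:
    def test_strictly_greater_threshold(self):
        keep = alternating_track("keep", 300)
        drop = alternating_track("drop", 301)
        retained, report = exclude_samples([keep, drop], 300)
        assert [t.sample for t in retained] == ["keep"]
        assert report.set_index("sample")["excluded"].to_dict() == {
            "keep": False,
            "drop": True,
        }

    def test_population_with_outliers(self):
        tracks = [alternating_track(f"s{i}", 30) for i in range(110)]
        tracks += [alternating_track(f"x{i}", 350, block_len=50_000) for i in range(6)]
        retained, report = exclude_samples(tracks, 300)
        assert len(retained) == 110 and report["excluded"].sum() == 6


def oracle_bins(tracks, chrom_lengths, interval):
    """Independent bin count: per-interval genotype by direct bp tally,
    then adjacent column-uniqueness."""
    n_bins = 0
    columns = {}
    for chrom, length in chrom_lengths.items():
        cols = []
        prev_by_track = {t.sample: None for t in tracks}
        start = 1
        while start <= length:
            end = min(start + interval - 1, length)
            col = []
            for t in tracks:
                tally = {P1: 0, P2: 0, HET: 0}
                for b in t.blocks[chrom]:
                    lo, hi = max(b.start, start), min(b.end, end)
                    if hi >= lo:
                        tally[b.genotype] += hi - lo + 1
                best = max(tally.values())
                winners = [g for g in (P1, P2, HET) if tally[g] == best]
                g = (
                    prev_by_track[t.sample]
                    if len(winners) > 1 and prev_by_track[t.sample] in winners
                    else winners[0]
                )
                prev_by_track[t.sample] = g
                col.append(g)
            cols.append(tuple(col))
            start = end + 1
        columns[chrom] = cols
        n_bins += sum(1 for i, c in enumerate(cols) if i == 0 or c != cols[i - 1])
    return n_bins, columns


class TestBuildBins:
    def test_no_crossovers_one_bin_per_chromosome(self):
        t1 = track("a", [(MB, P1)])
        t2 = track("b", [(MB, P2)])
        bm = build_bins([t1, t2], {"chr1": MB}, 100_000)
        assert bm.n_bins == 1
        assert bm.matrix[0].tolist() == [P1, P2]

    def test_single_crossover_snaps_to_grid(self):
        # crossover at 330 kb: the 300-400 kb cell is majority-P2, so the
        # changed interval starts at the grid cell containing the breakpoint
        t = track("a", [(330_000, P1), (670_000, P2)])
        bm = build_bins([t], {"chr1": MB}, 100_000)
        assert bm.bins[["start", "end"]].values.tolist() == [
            [1, 300_000],
            [300_001, MB],
        ]
        assert bm.matrix.loc["a"].tolist() == [P1, P2]

    def test_majority_tie_goes_to_preceding_interval(self):
        # exact tie at 350 kb in the 300-400 kb cell -> stays with P1
        t = track("a", [(350_000, P1), (650_000, P2)])
        bm = build_bins([t], {"chr1": MB}, 100_000)
        assert bm.bins[["start", "end"]].values.tolist() == [
            [1, 400_000],
            [400_001, MB],
        ]

    def test_interval_larger_than_chromosome(self):
        t = track("a", [(50_000, P1)])
        bm = build_bins([t], {"chr1": 50_000}, 100_000)
        assert bm.n_bins == 1 and bm.bins["end"].iloc[0] == 50_000

    def test_bin_count_matches_column_uniqueness_oracle(self, rng):
        chrom_lengths = {"chr1": 3 * MB, "chr2": 2 * MB}
        tracks = []
        for i in range(8):
            t = GenotypeTrack(f"s{i}", {})
            blocks = {}
            for chrom, L in chrom_lengths.items():
                cuts = np.sort(rng.choice(np.arange(2, L), size=rng.integers(0, 6), replace=False))
                edges = [1, *cuts.tolist(), L]
                genos = rng.choice([P1, P2, HET], size=len(edges) - 1)
                blks = []
                for j in range(len(edges) - 1):
                    s = edges[j] if j == 0 else edges[j]
                    e = edges[j + 1] - 1 if j < len(edges) - 2 else L
                    blks.append(Block(s if j == 0 else blks[-1].end + 1, e, str(genos[j])))
                # merge duplicates genotype-adjacent for a valid track
                merged = [blks[0]]
                for b in blks[1:]:
                    if merged[-1].genotype == b.genotype:
                        merged[-1] = Block(merged[-1].start, b.end, b.genotype)
                    else:
                        merged.append(b)
                blocks[chrom] = merged
            tracks.append(GenotypeTrack(f"s{i}", blocks))
        bm = build_bins(tracks, chrom_lengths, 100_000)
        n_oracle, cols_oracle = oracle_bins(tracks, chrom_lengths, 100_000)
        assert bm.n_bins == n_oracle

    def test_bins_reconstruct_interval_resolution_track(self):
        t1 = track("a", [(330_000, P1), (400_000, HET), (270_000, P2)])
        t2 = track("b", [(MB, P2)])
        lens = {"chr1": MB}
        bm = build_bins([t1, t2], lens, 100_000)
        imat = interval_matrix([t1, t2], lens, 100_000)["chr1"]
        # expand each bin back over its member intervals
        for sample in ("a", "b"):
            rebuilt = []
            for k, brow in bm.bins.iterrows():
                n_cells = (brow["end"] - brow["start"] + 1 + 99_999) // 100_000
                rebuilt += [bm.matrix.loc[sample, k]] * n_cells
            assert rebuilt == imat[sample].tolist()

    def test_bins_partition_each_chromosome(self):
        t = track("a", [(330_000, P1), (670_000, P2)])
        bm = build_bins([t], {"chr1": MB}, 100_000)
        assert bm.bins["start"].iloc[0] == 1
        assert bm.bins["end"].iloc[-1] == MB
        assert (
            bm.bins["start"].iloc[1:].to_numpy()
            == bm.bins["end"].iloc[:-1].to_numpy() + 1
        ).all()


class TestBreakpointStats:
    def test_published_population_mean(self):
        """110 lines carrying 3780 breakpoints average 34.4 per line."""
        counts = [35] * 40 + [34] * 70  # 40*35 + 70*34 = 3780
        tracks = [
            alternating_track(f"s{i}", c, block_len=100_000)
            for i, c in enumerate(counts)
        ]
        stats = breakpoint_stats(tracks)
        assert stats["total"] == 3780
        assert stats["n_samples"] == 110
        assert stats["mean_display"] == 34.4

    def test_single_sample_no_breakpoints(self):
        stats = breakpoint_stats([track("s", [(MB, P1)])])
        assert stats["total"] == 0 and stats["mean"] == 0.0

    def test_counts_match_construction(self):
        tracks = [alternating_track(f"s{i}", k) for i, k in enumerate([0, 3, 7])]
        stats = breakpoint_stats(tracks)
        assert stats["per_sample"]["breakpoints"].tolist() == [0, 3, 7]


class TestCollinearity:
    def test_perfectly_linear_map(self):
        phys = np.linspace(0, 100, 20)
        assert collinearity(2.0 * phys, phys) == pytest.approx(1.0)

    def test_reversed_order(self):
        phys = np.linspace(0, 100, 20)
        assert collinearity(2.0 * (100 - phys), phys) == pytest.approx(-1.0)

    def test_jittered_map_near_closed_form(self, rng):
        phys = np.linspace(0, 100, 400)
        sigma = 10.0
        gen = 2.0 * phys + rng.normal(0, sigma, phys.size)
        expected = 1.0 / np.sqrt(1.0 + sigma**2 / (4.0 * phys.var()))
        # 3-sigma band from the Fisher-z sampling variance
        se = (1 - expected**2) / np.sqrt(phys.size - 3)
        assert collinearity(gen, phys) == pytest.approx(expected, abs=3 * se)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            collinearity([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            collinearity([1, 2], [1, 2])


class TestTracksFromCalls:
    def test_long_table_to_tracks(self, rng):
        import pandas as pd

        pos = np.arange(1, 61) * 10_000
        calls = np.where(pos < 300_000, P1, P2)
        df = pd.DataFrame(
            dict(chrom="chr1", pos=pos, sample="s1", call=calls)
        )
        # missing calls are ignored
        df.loc[5, "call"] = "."
        tracks = tracks_from_calls(df, {"chr1": 700_000})
        assert len(tracks) == 1
        blks = tracks[0].blocks["chr1"]
        assert blks[0].genotype == P1 and blks[-1].genotype == P2
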