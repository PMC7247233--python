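"""Recombination breakpoint detection and bin-marker map construction.

Pipeline for low-coverage genotype calls from a backcross-derived mapping
population (e.g. BC₁F₄ by single-seed descent):

1. ``window_genotype`` — a window of 15 consecutive informative SNP calls
   slides one SNP at a time along each chromosome; the fraction of P2 calls
   scores the window P1 (≤ 0.3), P2 (≥ 0.7) or HET (in between).  Runs of
   identical window calls become genotype blocks whose boundaries sit at the
   midpoint between the flanking discordant SNPs.
2. ``smooth_blocks`` — sub-0.5-Mb HET blocks sandwiched by homozygous blocks
   of one genotype (or sub-0.5-Mb homozygous blocks sandwiched by HET) are
   reassigned to the surrounding genotype, suppressing false double
   crossovers; applied to fixpoint.
3. ``exclude_samples`` — lines with > 300 breakpoints (highly heterozygous
   or noisy) are removed.
4. ``build_bins`` — chromosomes are cut into 100-kb intervals, each (line,
   interval) takes the majority-coverage genotype, and adjacent intervals
   whose genotype column is identical across the whole population merge into
   a single bin marker.

All physical spans are 1-based inclusive bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Block",
    "GenotypeTrack",
    "BinMatrix",
    "window_genotype",
    "smooth_blocks",
    "exclude_samples",
    "build_bins",
    "interval_matrix",
    "breakpoint_stats",
    "collinearity",
    "tracks_from_calls",
]

P1, P2, HET = "P1", "P2", "HET"
_GENOTYPES = (P1, P2, HET)


@dataclass(frozen=True)
class Block:
    """A constant-genotype physical span, 1-based inclusive."""

    start: int
    end: int
    genotype: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"block end {self.end} < start {self.start}")
        if self.genotype not in _GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _merge_adjacent(blocks: list[Block]) -> list[Block]:
    merged: list[Block] = []
    for b in blocks:
        if merged and merged[-1].genotype == b.genotype:
            merged[-1] = Block(merged[-1].start, b.end, b.genotype)
        else:
            merged.append(b)
    return merged


def _check_tiling(blocks: list[Block]) -> None:
    for a, b in zip(blocks, blocks[1:]):
        if b.start != a.end + 1:
            raise ValueError("blocks must tile the span without gaps/overlaps")


@dataclass
class GenotypeTrack:
    """One line's ordered genotype blocks per chromosome."""

    sample: str
    blocks: dict[str, list[Block]] = field(default_factory=dict)
    low_confidence: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for chrom, blks in self.blocks.items():
            if not blks:
                raise ValueError(f"{self.sample}/{chrom}: empty block list")
            _check_tiling(blks)

    @property
    def breakpoints(self) -> int:
        """Total adjacent block boundaries across chromosomes."""
        return sum(len(b) - 1 for b in self.blocks.values())

    def breakpoint_positions(self, chrom: str) -> list[int]:
        """Boundary coordinates (end of the left block) on one chromosome."""
        return [b.end for b in self.blocks[chrom][:-1]]


def window_genotype(
    positions,
    calls,
    window_size: int = 15,
    het_band: tuple[float, float] = (0.3, 0.7),
    chrom_length: int | None = None,
) -> tuple[list[Block], bool]:
    """Sliding-window genotype blocks for one sample-chromosome.

    ``positions`` are ordered 1-based SNP coordinates; ``calls`` the matching
    P1/P2 calls.  Each window of ``window_size`` consecutive calls is scored
    by its fraction f of P2 calls: f ≥ upper ⇒ P2, f ≤ lower ⇒ P1, else HET.
    Each SNP takes the call of the window centred on it; runs of identical
    per-SNP calls become blocks with boundaries midway between the flanking
    discordant SNPs.  The first/last block extend to 1 / ``chrom_length``.

    Returns ``(blocks, low_confidence)`` — with fewer calls than the window
    the chromosome collapses to a single majority-vote block flagged
    low-confidence.
    """
    pos = np.asarray(positions, dtype=np.int64)
    arr = np.asarray(calls)
    if pos.size != arr.size:
        raise ValueError("positions and calls must have equal length")
    if pos.size == 0:
        raise ValueError("no calls on chromosome")
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be ordered")
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    lower, upper = het_band
    if not 0 <= lower < upper <= 1:
        raise ValueError("het_band must satisfy 0 <= lower < upper <= 1")
    is_p2 = (arr == P2).astype(float)
    if not np.all((arr == P1) | (arr == P2)):
        raise ValueError("calls must be P1 or P2 (drop missing beforehand)")
    end = int(chrom_length) if chrom_length is not None else int(pos[-1])

    n = pos.size
    if n < window_size:
        frac = is_p2.mean()
        geno = P2 if frac >= upper else P1 if frac <= lower else HET
        return [Block(1, end, geno)], True

    # fraction of P2 per window; window i covers calls [i, i+window_size)
    csum = np.concatenate(([0.0], np.cumsum(is_p2)))
    frac = (csum[window_size:] - csum[:-window_size]) / window_size
    wcall = np.where(frac >= upper, P2, np.where(frac <= lower, P1, HET))

    # per-SNP call: the window centred on the SNP, clipped at the ends
    centre_offset = (window_size - 1) // 2
    idx = np.clip(np.arange(n) - centre_offset, 0, n - window_size)
    snp_call = wcall[idx]

    blocks: list[Block] = []
    start = 1
    run_start = 0
    for j in range(1, n + 1):
        if j == n or snp_call[j] != snp_call[run_start]:
            if j == n:
                stop = end
            else:
                stop = int((pos[j - 1] + pos[j]) // 2)
            blocks.append(Block(start, stop, str(snp_call[run_start])))
            start = stop + 1
            run_start = j
    return _merge_adjacent(blocks), False


def smooth_blocks(track: GenotypeTrack, min_block: int = 500_000) -> GenotypeTrack:
    """Correct sub-``min_block`` blocks sandwiched by a uniform surround.

    A HET block shorter than ``min_block`` flanked on both sides by
    homozygous blocks of the SAME genotype takes that genotype; a homozygous
    block shorter than ``min_block`` flanked on both sides by HET becomes
    HET.  Blocks at chromosome ends (one flank) are never touched.  The rule
    is applied iteratively until nothing changes; the result never has more
    breakpoints than the input.

    When several blocks are eligible at once the SHORTEST is corrected first
    (leftmost on ties): the least-supported feature goes first, so a tiny
    spurious homozygous island inside a heterozygous tract is removed before
    it can bridge the surrounding blocks and drag a true boundary with it.
    """

    def _eligible(cur: list[Block], i: int) -> str | None:
        mid, left, right = cur[i], cur[i - 1], cur[i + 1]
        if mid.length >= min_block:
            return None
        if (
            mid.genotype == HET
            and left.genotype == right.genotype
            and left.genotype in (P1, P2)
        ):
            return left.genotype
        if (
            mid.genotype in (P1, P2)
            and left.genotype == HET
            and right.genotype == HET
        ):
            return HET
        return None

    new_blocks: dict[str, list[Block]] = {}
    for chrom, blks in track.blocks.items():
        cur = list(blks)
        while True:
            candidates = [
                (cur[i].length, i, tgt)
                for i in range(1, len(cur) - 1)
                if (tgt := _eligible(cur, i)) is not None
            ]
            if not candidates:
                break
            _, i, target = min(candidates)
            mid = cur[i]
            cur = cur[:i] + [Block(mid.start, mid.end, target)] + cur[i + 1:]
            cur = _merge_adjacent(cur)
        new_blocks[chrom] = cur
    return GenotypeTrack(track.sample, new_blocks, set(track.low_confidence))


def exclude_samples(
    tracks: list[GenotypeTrack], max_breakpoints: int = 300
) -> tuple[list[GenotypeTrack], pd.DataFrame]:
    """Drop lines with strictly more than ``max_breakpoints`` breakpoints."""
    report = pd.DataFrame(
        dict(
            sample=[t.sample for t in tracks],
            breakpoints=[t.breakpoints for t in tracks],
        )
    )
    report["excluded"] = report["breakpoints"] > max_breakpoints
    retained = [t for t in tracks if t.breakpoints <= max_breakpoints]
    return retained, report


def _interval_edges(length: int, interval: int) -> list[tuple[int, int]]:
    """Cut [1, length] into consecutive ``interval``-bp cells (last may be short)."""
    edges = []
    start = 1
    while start <= length:
        edges.append((start, min(start + interval - 1, length)))
        start += interval
    return edges


def _cell_genotype(blks: list[Block], start: int, end: int, prev: str | None) -> str:
    """Majority-coverage genotype of one interval; ties go to ``prev``."""
    cover = dict.fromkeys(_GENOTYPES, 0)
    for b in blks:
        if b.end < start or b.start > end:
            continue
        cover[b.genotype] += min(b.end, end) - max(b.start, start) + 1
    best = max(cover.values())
    winners = [g for g in _GENOTYPES if cover[g] == best]
    if len(winners) > 1 and prev in winners:
        return prev
    return winners[0]


def interval_matrix(
    tracks: list[GenotypeTrack],
    chrom_lengths: dict[str, int],
    interval: int = 100_000,
) -> dict[str, pd.DataFrame]:
    """Genotype of every (line, interval) cell, per chromosome.

    Returns ``{chrom: DataFrame}`` where rows are intervals (columns
    ``start``, ``end`` plus one column per line).
    """
    if not tracks:
        raise ValueError("no tracks")
    out: dict[str, pd.DataFrame] = {}
    for chrom, length in chrom_lengths.items():
        cells = _interval_edges(length, interval)
        data: dict[str, list] = {"start": [c[0] for c in cells],
                                 "end": [c[1] for c in cells]}
        for t in tracks:
            blks = t.blocks.get(chrom)
            if blks is None:
                raise ValueError(f"{t.sample}: no blocks for {chrom}")
            prev: str | None = None
            col = []
            for start, end in cells:
                g = _cell_genotype(blks, start, end, prev)
                col.append(g)
                prev = g
            data[t.sample] = col
        out[chrom] = pd.DataFrame(data)
    return out


@dataclass
class BinMatrix:
    """Population × bin genotype matrix with physical bin spans."""

    bins: pd.DataFrame      # chrom, start, end, length
    matrix: pd.DataFrame    # rows = lines, columns = bin index
    interval: int

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def to_tsv(self, path) -> None:
        wide = self.bins.copy()
        for sample in self.matrix.index:
            wide[sample] = self.matrix.loc[sample].to_numpy()
        wide.to_csv(path, sep="\t", index=False)


def build_bins(
    tracks: list[GenotypeTrack],
    chrom_lengths: dict[str, int],
    interval: int = 100_000,
) -> BinMatrix:
    """Merge adjacent intervals with identical population genotype columns.

    Adjacent ``interval``-bp cells whose genotype vector across ALL retained
    lines is identical collapse into one bin marker.
    """
    imat = interval_matrix(tracks, chrom_lengths, interval)
    samples = [t.sample for t in tracks]
    bin_rows = []
    geno_cols: list[list[str]] = []
    for chrom in chrom_lengths:
        df = imat[chrom]
        vecs = df[samples].to_numpy()
        start_idx = 0
        for i in range(1, len(df) + 1):
            if i == len(df) or not np.array_equal(vecs[i], vecs[start_idx]):
                bin_rows.append(
                    dict(
                        chrom=chrom,
                        start=int(df["start"].iloc[start_idx]),
                        end=int(df["end"].iloc[i - 1]),
                    )
                )
                geno_cols.append(list(vecs[start_idx]))
                start_idx = i
    bins = pd.DataFrame(bin_rows)
    bins["length"] = bins["end"] - bins["start"] + 1
    matrix = pd.DataFrame(
        np.array(geno_cols).T, index=samples, columns=range(len(bins))
    )
    return BinMatrix(bins, matrix, interval)


def breakpoint_stats(tracks: list[GenotypeTrack]) -> dict:
    """Total and mean breakpoints per line (mean displayed at 1 dp)."""
    from ._display import round_half_up

    if not tracks:
        raise ValueError("no tracks")
    counts = [t.breakpoints for t in tracks]
    total = int(sum(counts))
    mean = total / len(counts)
    return dict(
        total=total,
        n_samples=len(counts),
        mean=mean,
        mean_display=round_half_up(mean, 1),
        per_sample=pd.DataFrame(
            dict(sample=[t.sample for t in tracks], breakpoints=counts)
        ),
    )


def collinearity(genetic_positions, physical_midpoints) -> float:
    """Pearson correlation between genetic (cM) and physical (Mb) positions.

    The standard collinearity diagnostic for a genetic map: r near ±1 means
    marker order on the map follows the physical order.
    """
    g = np.asarray(genetic_positions, dtype=float)
    p = np.asarray(physical_midpoints, dtype=float)
    if g.size != p.size:
        raise ValueError("vectors must have equal length")
    if g.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(g) == 0 or np.ptp(p) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(g, p).statistic)


def tracks_from_calls(
    calls: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window_size: int = 15,
    het_band: tuple[float, float] = (0.3, 0.7),
) -> list[GenotypeTrack]:
    """Run sliding-window genotyping on a long calls table.

    ``calls`` columns: chrom, pos, sample, call (P1/P2/.); missing calls are
    dropped before windowing.  Chromosomes with no informative calls for a
    sample are skipped for that sample.
    """
    informative = calls[calls["call"].isin([P1, P2])]
    tracks = []
    for sample, g in informative.groupby("sample", sort=True):
        blocks: dict[str, list[Block]] = {}
        lowconf: set[str] = set()
        for chrom, gc in g.groupby("chrom", sort=True):
            gc = gc.sort_values("pos")
            blks, low = window_genotype(
                gc["pos"].to_numpy(),
                gc["call"].to_numpy(),
                window_size=window_size,
                het_band=het_band,
                chrom_length=chrom_lengths.get(chrom),
            )
            blocks[chrom] = blks
            if low:
                lowconf.add(chrom)
        tracks.append(GenotypeTrack(str(sample), blocks, lowconf))
    return tracks
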