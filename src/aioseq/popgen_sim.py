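"""Synthetic backcross-selfing (BC₁F₄-style) mapping-population generator.

Produces ground-truthed inputs for the genotype-filtering and bin-map
modules: true per-line genotype mosaics with known crossover positions, and
sparse low-coverage marker calls corrupted by genotyping error and
missingness.

Genealogy model: a donor inbred P1 is crossed to a recurrent inbred P2; the
F1 is backcrossed to P2 (BC₁), then advanced by single-seed-descent selfing
to the requested filial generation.  Every meiosis lays down crossovers as a
Poisson process along each chromosome (no interference), with the expected
count per chromosome per meiosis set in the config.

Low-coverage observation model: at ~1× or less, each marker is sampled by at
most one read, so a heterozygous site reports P1 or P2 with equal
probability (the sliding window later recovers HET from mixed runs);
homozygous sites report the true allele, flipped with the call-error
probability; every call is independently missing with the missing rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .binmap import Block, GenotypeTrack, P1, P2, HET

__all__ = [
    "Chromosome",
    "PopSimConfig",
    "TruthSet",
    "simulate_population",
    "write_truth_json",
    "write_population_vcf",
]


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int  # bp

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("chromosome length must be > 0")


def _default_chromosomes() -> list[Chromosome]:
    # a scaled-down maize-like karyotype: 5 chromosomes of 30 Mb
    return [Chromosome(f"chr{i + 1}", 30_000_000) for i in range(5)]


@dataclass
class PopSimConfig:
    """Population-simulation scenario.

    Defaults emulate the published maize study at reduced genome size:
    110 lines, parental marker density ~1100 SNPs/Mb (≈1.1 SNPs/kb), ~83%
    of calls missing per line (≈0.74× coverage leaves ~190 observed
    SNPs/Mb), 1% call error, one BC₁ meiosis plus three selfing meioses
    (F₄), and ~1 crossover per chromosome per meiosis.
    """

    n_lines: int = 110
    chromosomes: list[Chromosome] = field(default_factory=_default_chromosomes)
    markers_per_mb: float = 1100.0
    crossovers_per_meiosis: float = 1.0     # per chromosome
    n_selfing_generations: int = 3          # BC1F1 -> BC1F4
    call_error: float = 0.01
    missing_rate: float = 0.83
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if not self.chromosomes:
            raise ValueError("need at least one chromosome")
        self.chromosomes = [
            c if isinstance(c, Chromosome) else Chromosome(**c)
            for c in self.chromosomes
        ]
        for name, lo, hi in (
            ("call_error", 0.0, 1.0),
            ("missing_rate", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} must be in [{lo}, {hi}]")
        if self.crossovers_per_meiosis < 0:
            raise ValueError("crossovers_per_meiosis must be >= 0")
        if self.markers_per_mb <= 0:
            raise ValueError("markers_per_mb must be > 0")
        if self.n_selfing_generations < 0:
            raise ValueError("n_selfing_generations must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PopSimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


# --- haplotype algebra ------------------------------------------------------
# A haplotype along one chromosome is (cuts, origins): sorted interior cut
# positions and the parental origin (0 = P1 donor, 1 = P2 recurrent) of each
# resulting segment.


def _simplify(cuts: np.ndarray, origins: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    keep = np.nonzero(origins[1:] != origins[:-1])[0]
    return cuts[keep], np.concatenate((origins[:1], origins[keep + 1]))


def _gamete(
    hap_a: tuple[np.ndarray, np.ndarray],
    hap_b: tuple[np.ndarray, np.ndarray],
    length: int,
    rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One meiotic product: recombine two haplotypes at Poisson crossovers."""
    k = rng.poisson(rate)
    xpos = np.sort(rng.uniform(0, length, k))
    first = rng.integers(2)
    haps = (hap_a, hap_b)
    # segments of the gamete alternate source haplotype at each crossover
    seg_edges = np.concatenate(([0.0], xpos, [float(length)]))
    cuts: list[float] = []
    origins: list[int] = []
    for i in range(len(seg_edges) - 1):
        lo, hi = seg_edges[i], seg_edges[i + 1]
        src_cuts, src_orig = haps[(first + i) % 2]
        j0 = int(np.searchsorted(src_cuts, lo, side="right"))
        j1 = int(np.searchsorted(src_cuts, hi, side="left"))
        inner = src_cuts[j0:j1]
        segs = np.concatenate(([lo], inner, [hi]))
        for t in range(len(segs) - 1):
            if segs[t + 1] <= segs[t]:
                continue
            origins.append(int(src_orig[j0 + t] if j0 + t < len(src_orig) else src_orig[-1]))
            cuts.append(segs[t + 1])
    cuts_arr = np.asarray(cuts[:-1], dtype=float)  # last edge is chromosome end
    orig_arr = np.asarray(origins, dtype=np.int8)
    return _simplify(cuts_arr, orig_arr)


def _line_genotype_blocks(
    hap1: tuple[np.ndarray, np.ndarray],
    hap2: tuple[np.ndarray, np.ndarray],
    length: int,
) -> list[Block]:
    """Diploid genotype blocks (P1/HET/P2) from two haplotypes."""
    cuts = np.unique(np.concatenate((hap1[0], hap2[0])))
    edges = np.concatenate(([0.0], cuts, [float(length)]))
    mids = (edges[:-1] + edges[1:]) / 2
    o1 = hap1[1][np.searchsorted(hap1[0], mids, side="right")]
    o2 = hap2[1][np.searchsorted(hap2[0], mids, side="right")]
    dose = o1.astype(int) + o2.astype(int)  # copies of P2
    geno = np.array([P1, HET, P2], dtype=object)[dose]
    blocks: list[Block] = []
    start = 1
    for i in range(len(mids)):
        stop = int(round(edges[i + 1]))
        stop = max(stop, start)
        if i == len(mids) - 1:
            stop = length
        if blocks and blocks[-1].genotype == geno[i]:
            blocks[-1] = Block(blocks[-1].start, stop, geno[i])
        else:
            blocks.append(Block(start, stop, str(geno[i])))
        start = stop + 1
    # guard against zero-length artefacts from rounding
    return [b for b in blocks if b.end >= b.start]


@dataclass
class TruthSet:
    """True mosaics and crossover positions for every simulated line."""

    config: PopSimConfig
    tracks: list[GenotypeTrack]              # true genotype blocks
    crossovers: dict[str, dict[str, list[int]]]  # sample -> chrom -> boundaries

    def total_crossovers(self) -> int:
        return sum(
            len(v) for per in self.crossovers.values() for v in per.values()
        )


def simulate_population(
    config: PopSimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate the population; returns (marker calls, truth).

    Calls are a long DataFrame (chrom, pos, sample, call) in the dialect the
    bin-map pipeline consumes; marker positions are drawn once and shared by
    all lines.  Identical seeds give identical outputs.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    rate = config.crossovers_per_meiosis

    # shared marker positions per chromosome
    marker_pos: dict[str, np.ndarray] = {}
    for chrom in config.chromosomes:
        n_mark = max(1, min(int(round(chrom.length / 1e6 * config.markers_per_mb)),
                            chrom.length))
        # oversample-and-dedupe beats permuting the whole chromosome
        pos = np.unique(rng.integers(1, chrom.length + 1,
                                     size=int(n_mark * 1.1) + 16))
        while pos.size < n_mark:
            extra = rng.integers(1, chrom.length + 1, size=n_mark)
            pos = np.unique(np.concatenate((pos, extra)))
        if pos.size > n_mark:
            pos = np.sort(rng.choice(pos, size=n_mark, replace=False))
        marker_pos[chrom.name] = pos

    tracks: list[GenotypeTrack] = []
    crossovers: dict[str, dict[str, list[int]]] = {}
    col_chrom: list[np.ndarray] = []
    col_pos: list[np.ndarray] = []
    col_sample: list[np.ndarray] = []
    col_call: list[np.ndarray] = []
    col_true: list[np.ndarray] = []

    for li in range(config.n_lines):
        sample = f"L{li + 1:03d}"
        blocks: dict[str, list[Block]] = {}
        xovers: dict[str, list[int]] = {}
        for chrom in config.chromosomes:
            L = chrom.length
            empty = np.array([], dtype=float)
            hap_p1 = (empty, np.array([0], dtype=np.int8))
            hap_p2 = (empty, np.array([1], dtype=np.int8))
            # F1 = (P1, P2); BC1 = gamete(F1) x P2
            ind = (_gamete(hap_p1, hap_p2, L, rate, rng), hap_p2)
            for _ in range(config.n_selfing_generations):
                ind = (
                    _gamete(ind[0], ind[1], L, rate, rng),
                    _gamete(ind[0], ind[1], L, rate, rng),
                )
            blks = _line_genotype_blocks(ind[0], ind[1], L)
            blocks[chrom.name] = blks
            xovers[chrom.name] = [b.end for b in blks[:-1]]

            # observe markers
            pos = marker_pos[chrom.name]
            edges = np.array([b.end for b in blks], dtype=np.int64)
            geno = np.array([b.genotype for b in blks], dtype=object)
            idx = np.searchsorted(edges, pos, side="left")
            true_g = geno[idx]
            m = pos.size
            obs = np.empty(m, dtype=object)
            het = true_g == HET
            # het sites: a single read shows either allele
            obs[het] = np.where(rng.random(het.sum()) < 0.5, P1, P2)
            hom = ~het
            flip = rng.random(m) < config.call_error
            hp = hom & (true_g == P1)
            hq = hom & (true_g == P2)
            obs[hp] = np.where(flip[hp], P2, P1)
            obs[hq] = np.where(flip[hq], P1, P2)
            missing = rng.random(m) < config.missing_rate
            obs[missing] = "."
            col_chrom.append(np.full(m, chrom.name, dtype=object))
            col_pos.append(pos)
            col_sample.append(np.full(m, sample, dtype=object))
            col_call.append(obs)
            col_true.append(true_g)
        tracks.append(GenotypeTrack(sample, blocks))
        crossovers[sample] = xovers

    calls = pd.DataFrame(
        {
            "chrom": np.concatenate(col_chrom),
            "pos": np.concatenate(col_pos),
            "sample": np.concatenate(col_sample),
            "call": np.concatenate(col_call),
            "true_genotype": np.concatenate(col_true),
        }
    )
    return calls, TruthSet(config, tracks, crossovers)


def write_truth_json(path, truth: TruthSet) -> None:
    payload = {
        "seed": truth.config.seed,
        "config": {
            **{k: v for k, v in asdict(truth.config).items() if k != "chromosomes"},
            "chromosomes": [asdict(c) for c in truth.config.chromosomes],
        },
        "lines": {
            t.sample: {
                chrom: [[b.start, b.end, b.genotype] for b in blks]
                for chrom, blks in t.blocks.items()
            }
            for t in truth.tracks
        },
        "crossovers": truth.crossovers,
        "total_crossovers": truth.total_crossovers(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


_BASES = np.array(["A", "C", "G", "T"])


def write_population_vcf(
    vcf_path,
    calls: pd.DataFrame,
    parent1: str = "P1",
    parent2: str = "P2",
    parent_depth: int = 14,
    mq: float = 60.0,
    qual: float = 60.0,
    seed: int = 0,
) -> None:
    """Write simulated calls as a minimal VCF with both parents and progeny.

    REF is the P1 allele and ALT the P2 allele (random distinct bases);
    parents are homozygous REF/ALT at the given depth; progeny genotypes come
    from the observed calls (``.`` → ./.) at depth 1.  The output exercises
    the parental/progeny filtering module end to end.
    """
    rng = np.random.default_rng(seed)
    samples = sorted(calls["sample"].unique())
    sites = (
        calls[["chrom", "pos"]].drop_duplicates().sort_values(["chrom", "pos"])
    )
    wide = calls.pivot_table(
        index=["chrom", "pos"], columns="sample", values="call", aggfunc="first"
    )
    gt_of = {"P1": "0/0", "P2": "1/1", ".": "./."}
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sites["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join([parent1, parent2] + samples)
            + "\n"
        )
        for chrom, pos in sites.itertuples(index=False):
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            row = wide.loc[(chrom, pos)]
            fields = [
                chrom, str(pos), ".", ref, alt, f"{qual:g}", "PASS",
                f"MQ={mq:g}", "GT:DP",
                f"0/0:{parent_depth}", f"1/1:{parent_depth}",
            ]
            for s in samples:
                call = row.get(s, ".")
                call = "." if pd.isna(call) else call
                dp = 0 if call == "." else 1
                fields.append(f"{gt_of[call]}:{dp}")
            fh.write("\t".join(fields) + "\n")
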