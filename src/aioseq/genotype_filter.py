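"""Parental and progeny SNP filtering for low-coverage mapping populations.

Parental markers are biallelic SNPs at which the two inbred parents are
homozygous for different alleles, each with depth ≥ 4, mapping quality ≥ 60
and QUAL ≥ 60, and which fall outside transposable-element regions given as
a BED mask.  Progeny calls are then restricted to those marker positions:
only homozygous calls matching one of the two parental alleles (again at
MQ ≥ 60, QUAL ≥ 60) are kept — heterozygous or inconsistent calls are
dropped, with heterozygosity inferred later from mixed call runs by the
sliding window in :mod:`aioseq.binmap`.

Coordinates: VCF positions are 1-based; BED intervals are 0-based half-open.
The conversion happens once, at the mask boundary.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "VariantRecord",
    "ParentalMarker",
    "FilterStats",
    "load_bed_mask",
    "records_from_vcf",
    "filter_parental",
    "call_progeny",
    "write_markers",
    "write_calls",
]

logger = logging.getLogger(__name__)

HOM_REF = "hom_ref"
HOM_ALT = "hom_alt"
HET = "het"
MISSING = "missing"


@dataclass
class VariantRecord:
    """A biallelic variant site with per-sample genotype class and depth."""

    chrom: str
    pos: int                      # 1-based
    ref: str
    alt: str
    qual: float
    mq: float
    genotypes: dict[str, str]     # sample -> HOM_REF/HOM_ALT/HET/MISSING
    depths: dict[str, int]
    multiallelic: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")


@dataclass(frozen=True)
class ParentalMarker:
    """A fixed biallelic difference between the two parents."""

    chrom: str
    pos: int
    allele_p1: str
    allele_p2: str

    def __post_init__(self) -> None:
        if self.allele_p1 == self.allele_p2:
            raise ValueError("parental alleles must differ")


@dataclass
class FilterStats:
    """Counts of records rejected per criterion (a record counts once)."""

    counts: Counter = field(default_factory=Counter)

    def reject(self, reason: str) -> None:
        self.counts[reason] += 1

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)


def load_bed_mask(path) -> dict[str, IntervalTree]:
    """Load a BED file (0-based half-open) into per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: need >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end > start:
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def in_mask(mask: dict[str, IntervalTree], chrom: str, pos: int) -> bool:
    """True when 1-based position ``pos`` falls inside a masked interval."""
    tree = mask.get(chrom)
    return bool(tree is not None and tree.overlaps(pos - 1))


def _classify_gt(gt: tuple) -> str:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return MISSING
    if all(a == 0 for a in alleles) and len(alleles) == len(gt):
        return HOM_REF
    if all(a == 1 for a in alleles) and len(alleles) == len(gt):
        return HOM_ALT
    if any(a is None for a in gt):
        return MISSING
    return HET


def records_from_vcf(path, samples: list[str] | None = None):
    """Yield :class:`VariantRecord` from a VCF (plain or bgzipped) via pysam."""
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        names = samples if samples is not None else list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            multi = len(alts) != 1
            genos: dict[str, str] = {}
            depths: dict[str, int] = {}
            for s in names:
                smp = rec.samples[s]
                genos[s] = _classify_gt(tuple(smp.get("GT") or (None,)))
                dp = smp.get("DP")
                depths[s] = int(dp) if dp is not None else 0
            mq = rec.info.get("MQ", 0.0)
            yield VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=alts[0] if alts else ".",
                qual=float(rec.qual) if rec.qual is not None else 0.0,
                mq=float(mq) if mq is not None else 0.0,
                genotypes=genos,
                depths=depths,
                multiallelic=multi,
            )


def filter_parental(
    records,
    parent1: str,
    parent2: str,
    te_mask: dict[str, IntervalTree] | None = None,
    min_depth: int = 4,
    min_mq: float = 60.0,
    min_qual: float = 60.0,
) -> tuple[list[ParentalMarker], FilterStats]:
    """Select fixed parental markers from a variant stream.

    A record is retained when: biallelic; both parents homozygous and for
    different alleles; each parent's depth ≥ ``min_depth``; MQ ≥ ``min_mq``;
    QUAL ≥ ``min_qual``; and the position is outside the TE mask.  Rejection
    reasons are tallied in :class:`FilterStats` (first failing criterion
    counts).  Malformed records are skipped with a logged warning.
    """
    markers: list[ParentalMarker] = []
    stats = FilterStats()
    for rec in records:
        try:
            if rec.multiallelic:
                stats.reject("multiallelic")
                continue
            g1 = rec.genotypes.get(parent1, MISSING)
            g2 = rec.genotypes.get(parent2, MISSING)
            if g1 not in (HOM_REF, HOM_ALT) or g2 not in (HOM_REF, HOM_ALT):
                stats.reject("parent_not_homozygous")
                continue
            if g1 == g2:
                stats.reject("not_polymorphic")
                continue
            if rec.depths.get(parent1, 0) < min_depth or rec.depths.get(parent2, 0) < min_depth:
                stats.reject("parent_depth")
                continue
            if rec.mq < min_mq:
                stats.reject("mapping_quality")
                continue
            if rec.qual < min_qual:
                stats.reject("site_quality")
                continue
            if te_mask is not None and in_mask(te_mask, rec.chrom, rec.pos):
                stats.reject("te_mask")
                continue
            allele = {HOM_REF: rec.ref, HOM_ALT: rec.alt}
            markers.append(
                ParentalMarker(rec.chrom, rec.pos, allele[g1], allele[g2])
            )
        except (AttributeError, KeyError, TypeError) as exc:
            stats.reject("malformed")
            logger.warning("skipping malformed record: %s", exc)
    markers.sort(key=lambda m: (m.chrom, m.pos))
    return markers, stats


def call_progeny(
    records,
    markers: list[ParentalMarker],
    samples: list[str],
    min_mq: float = 60.0,
    min_qual: float = 60.0,
) -> tuple[pd.DataFrame, FilterStats]:
    """Project progeny genotypes onto parental markers.

    At each marker position passing MQ/QUAL in the progeny stream, each
    sample's homozygous call matching the P1 or P2 allele becomes ``P1`` or
    ``P2``; heterozygous, inconsistent or missing calls stay ``.``.  Returns
    a long DataFrame (chrom, pos, sample, call) covering every marker ×
    sample, plus drop tallies.
    """
    marker_at = {(m.chrom, m.pos): m for m in markers}
    stats = FilterStats()
    calls: dict[tuple[str, int], dict[str, str]] = {
        (m.chrom, m.pos): {} for m in markers
    }
    for rec in records:
        m = marker_at.get((rec.chrom, rec.pos))
        if m is None:
            continue
        if rec.mq < min_mq:
            stats.reject("mapping_quality")
            continue
        if rec.qual < min_qual:
            stats.reject("site_quality")
            continue
        allele_of = {HOM_REF: rec.ref, HOM_ALT: rec.alt}
        row = calls[(rec.chrom, rec.pos)]
        for s in samples:
            g = rec.genotypes.get(s, MISSING)
            if g == MISSING:
                continue
            if g == HET:
                stats.reject("heterozygous_call")
                continue
            a = allele_of[g]
            if a == m.allele_p1:
                row[s] = "P1"
            elif a == m.allele_p2:
                row[s] = "P2"
            else:
                stats.reject("inconsistent_allele")
    rows = [
        dict(chrom=m.chrom, pos=m.pos, sample=s,
             call=calls[(m.chrom, m.pos)].get(s, "."))
        for m in markers
        for s in samples
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "sample", "call"]), stats


def write_markers(path, markers: list[ParentalMarker]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tallele_P1\tallele_P2\n")
        for m in markers:
            fh.write(f"{m.chrom}\t{m.pos}\t{m.allele_p1}\t{m.allele_p2}\n")


def write_calls(path, calls: pd.DataFrame) -> None:
    calls.to_csv(path, sep="\t", index=False)
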