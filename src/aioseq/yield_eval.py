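"""Evaluation of demultiplexed sequencing yields and coverage profiles.

Implements the evenness statistics used to judge a pooled lane:

* CV — coefficient of variation of group yields, 100·sd/mean with the
  sample (n−1) standard deviation;
* RE — a sample's relative error versus its expected yield;
* AD — the absolute-deviation (Gb) equivalent of an RE level at the group's
  equal-share expectation (group total / group size);
* pairwise chi-square tests of observed yield pairs against an expected
  ratio (e.g. 5:1 maize:rice), on pseudo-counts of configurable unit;
* per-base coverage histograms against the Poisson expectation, and
  GC-binned mean coverage over 10-kb genome bins.

Expected yields are derived from realized lane totals, not nominal lane
capacity: a 135.0 Gb lane shared by 30 libraries expects 4.5 Gb each.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "cv",
    "cv_from_summary",
    "relative_error",
    "ad_threshold",
    "RatioTestResult",
    "ratio_chisq",
    "pairwise_ratio_tests",
    "yield_report",
    "CoverageProfile",
    "coverage_histogram",
    "gc_binned_coverage",
]


def cv(yields) -> float:
    """Coefficient of variation in percent: 100 × sd(n−1) / mean."""
    y = np.asarray(yields, dtype=float)
    if y.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = y.mean()
    if not mean > 0:
        raise ValueError("CV undefined for non-positive mean")
    return 100.0 * y.std(ddof=1) / mean


def cv_from_summary(mean: float, sd: float) -> float:
    """CV (%) from an already-computed mean ± sd summary."""
    if not mean > 0:
        raise ValueError("CV undefined for non-positive mean")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return 100.0 * sd / mean


def relative_error(yield_gb: float, expected_gb: float) -> float:
    """|observed − expected| / expected."""
    if not expected_gb > 0:
        raise ValueError("expected yield must be > 0")
    return abs(yield_gb - expected_gb) / expected_gb


def ad_threshold(re_level: float, expected_gb: float) -> float:
    """Absolute deviation (Gb) equivalent to an RE level at a given expectation."""
    if not re_level > 0:
        raise ValueError("re_level must be > 0")
    if not expected_gb > 0:
        raise ValueError("expected yield must be > 0")
    return re_level * expected_gb


@dataclass
class RatioTestResult:
    """A pairwise chi-square test of two yields against an expected ratio."""

    id_a: str
    id_b: str
    yield_a: float
    yield_b: float
    ratio_a: float
    ratio_b: float
    unit: float
    statistic: float
    df: int
    pvalue: float

    def passed(self, alpha: float = 0.05) -> bool:
        """True when the observed pair is consistent with the ratio (p > α)."""
        return self.pvalue > alpha


def ratio_chisq(
    yield_a: float,
    yield_b: float,
    ratio_a: float,
    ratio_b: float,
    unit: float = 0.01,
    id_a: str = "a",
    id_b: str = "b",
) -> RatioTestResult:
    """Chi-square goodness-of-fit of two yields against an a:b ratio.

    Yields (Gb) are converted to pseudo-counts at ``unit`` Gb per count; the
    expected counts split the observed total by the ratio; df = 1.  The
    statistic scales with 1/unit, so the unit is recorded in the result.
    """
    if yield_a <= 0 or yield_b <= 0:
        raise ValueError("yields must be > 0")
    if ratio_a <= 0 or ratio_b <= 0:
        raise ValueError("ratio terms must be > 0")
    if not unit > 0:
        raise ValueError("unit must be > 0")
    obs = np.array([yield_a, yield_b]) / unit
    total = obs.sum()
    if not total > 0:
        raise ValueError("zero total")
    exp = total * np.array([ratio_a, ratio_b]) / (ratio_a + ratio_b)
    stat = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return RatioTestResult(
        id_a, id_b, yield_a, yield_b, ratio_a, ratio_b, unit, stat, 1, p
    )


def pairwise_ratio_tests(
    yields_a: dict[str, float] | list[float],
    yields_b: dict[str, float] | list[float],
    ratio_a: float,
    ratio_b: float,
    unit: float = 0.01,
) -> pd.DataFrame:
    """All cross-group pairwise ratio tests (|A| × |B| rows)."""
    if not isinstance(yields_a, dict):
        yields_a = {f"a{i + 1}": y for i, y in enumerate(yields_a)}
    if not isinstance(yields_b, dict):
        yields_b = {f"b{i + 1}": y for i, y in enumerate(yields_b)}
    rows = []
    for (ka, ya), (kb, yb) in itertools.product(yields_a.items(), yields_b.items()):
        r = ratio_chisq(ya, yb, ratio_a, ratio_b, unit, ka, kb)
        rows.append(
            dict(
                id_a=r.id_a, id_b=r.id_b, yield_a=r.yield_a, yield_b=r.yield_b,
                statistic=r.statistic, df=r.df, pvalue=r.pvalue,
                passed=r.passed(),
            )
        )
    return pd.DataFrame(rows)


def yield_report(
    df: pd.DataFrame,
    re_levels: tuple[float, ...] = (0.10, 0.25),
) -> dict:
    """Per-group yield evenness report.

    ``df`` needs columns ``sample_id``, ``group``, ``yield_gb`` and may carry
    ``weight`` (default equal).  Expected yields split each group's realized
    total by weight.  Returns ``{"samples": DataFrame, "groups": DataFrame}``;
    the group table carries mean, sd, CV and, for each RE level r, the count
    of samples with RE < r (strict), the count with RE > max level (strict),
    and the AD (Gb) equivalents at the group's mean expectation.
    """
    required = {"sample_id", "group", "yield_gb"}
    if missing := required - set(df.columns):
        raise ValueError(f"yield table missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError("empty yield table")
    df = df.copy()
    if "weight" not in df.columns:
        df["weight"] = 1.0
    else:
        from ._display import parse_weight

        df["weight"] = df["weight"].map(parse_weight)

    samples = []
    groups = []
    re_levels = tuple(sorted(re_levels))
    for group, g in df.groupby("group", sort=False):
        total = g["yield_gb"].sum()
        expected = total * g["weight"] / g["weight"].sum()
        re = (g["yield_gb"] - expected).abs() / expected
        part = g.assign(expected_gb=expected, relative_error=re)
        samples.append(part)
        mean_expected = total / len(g)
        row = dict(
            group=group,
            n=len(g),
            total_gb=total,
            mean_gb=g["yield_gb"].mean(),
            sd_gb=g["yield_gb"].std(ddof=1) if len(g) > 1 else 0.0,
        )
        row["cv_pct"] = (
            cv(g["yield_gb"]) if len(g) > 1 else 0.0
        )
        for r in re_levels:
            row[f"n_re_lt_{int(r * 100)}"] = int((re < r).sum())
            row[f"ad_{int(r * 100)}_gb"] = ad_threshold(r, mean_expected)
        top = re_levels[-1]
        row[f"n_re_gt_{int(top * 100)}"] = int((re > top).sum())
        groups.append(row)
    return {
        "samples": pd.concat(samples, ignore_index=True),
        "groups": pd.DataFrame(groups),
    }


@dataclass
class CoverageProfile:
    """Per-base coverage histogram with its Poisson reference."""

    levels: np.ndarray        # integer coverage 0..max
    counts: np.ndarray        # bases at each level; sums to genome length
    percent: np.ndarray       # counts as percent of genome
    lam: float                # mean coverage
    poisson_pct: np.ndarray   # Poisson(λ) pmf over the same support, percent

    @property
    def genome_length(self) -> int:
        return int(self.counts.sum())


def coverage_histogram(depths) -> CoverageProfile:
    """Histogram of per-base coverage with a Poisson(λ = mean depth) reference.

    The Poisson curve is the no-bias expectation for shotgun coverage; the
    histogram is reported as percent of genome at each integer depth.
    """
    d = np.asarray(depths)
    if d.size == 0:
        raise ValueError("empty depth vector")
    if np.any(d < 0) or not np.issubdtype(d.dtype, np.integer):
        d = d.astype(float)
        if np.any(d < 0) or np.any(d != np.round(d)):
            raise ValueError("depths must be non-negative integers")
        d = d.astype(np.int64)
    counts = np.bincount(d)
    levels = np.arange(counts.size)
    lam = float(d.mean())
    return CoverageProfile(
        levels=levels,
        counts=counts,
        percent=100.0 * counts / d.size,
        lam=lam,
        poisson_pct=100.0 * stats.poisson.pmf(levels, lam),
    )


def gc_binned_coverage(
    genome: str,
    depths,
    bin_size: int = 10_000,
) -> pd.DataFrame:
    """GC fraction and mean coverage per non-overlapping genome bin.

    The genome is cut into ``bin_size`` bins; a final partial bin is kept if
    at least half-size, otherwise merged into the previous bin.  GC is
    computed over unambiguous A/C/G/T only; a bin with no unambiguous base
    has GC = NaN and ``flagged=True`` (skip it in downstream fits).
    Columns: start, end (0-based half-open), gc, mean_coverage, flagged.
    """
    d = np.asarray(depths, dtype=float)
    n = len(genome)
    if d.size != n:
        raise ValueError(f"genome length {n} != depth vector length {d.size}")
    if n == 0:
        raise ValueError("empty genome")
    edges = list(range(0, n, bin_size)) + [n]
    if len(edges) > 2 and edges[-1] - edges[-2] < bin_size / 2:
        del edges[-2]  # merge short tail into previous bin
    seq = np.frombuffer(genome.upper().encode("ascii"), dtype="S1")
    is_gc = (seq == b"G") | (seq == b"C")
    is_acgt = is_gc | (seq == b"A") | (seq == b"T")
    rows = []
    for start, end in zip(edges[:-1], edges[1:]):
        denom = int(is_acgt[start:end].sum())
        gc = float(is_gc[start:end].sum()) / denom if denom else np.nan
        rows.append(
            dict(
                start=start,
                end=end,
                gc=gc,
                mean_coverage=float(d[start:end].mean()),
                flagged=denom == 0,
            )
        )
    return pd.DataFrame(rows)
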