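"""Fragment-size traces and target-region mass fractions.

An electropherogram trace (Bioanalyzer / Fragment Analyzer CSV export) gives
signal or mass density against fragment length.  The fraction of library mass
inside the size-selection window — 420–520 bp for paired-end 150 bp
sequencing — is the "ratio of target region" that, multiplied by the Qubit
concentration, yields the target region concentration (TRC) used for pooling.

Integration is trapezoidal on the instrument's own grid, with linear
interpolation at the window edges; this matches how instrument software
reports region percentages and is stable under grid refinement.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SizeDistribution",
    "TargetWindow",
    "TraceParseError",
    "load_trace",
    "target_fraction",
    "crop",
    "write_fraction_table",
]

DEFAULT_WINDOW = (420.0, 520.0)


class TraceParseError(ValueError):
    """Raised when a trace file cannot be parsed into a valid distribution."""


@dataclass(frozen=True)
class TargetWindow:
    """A size-selection window [lo, hi] in bp, bounds inclusive."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"require 0 < lo < hi, got [{self.lo}, {self.hi}]")


@dataclass
class SizeDistribution:
    """A library's fragment-length mass density on an ordered size grid."""

    library_id: str
    sizes: np.ndarray
    density: np.ndarray
    _total: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.sizes.ndim != 1 or self.sizes.shape != self.density.shape:
            raise ValueError("sizes and density must be 1-D arrays of equal length")
        if self.sizes.size < 2:
            raise ValueError("a size distribution needs at least 2 points")
        if np.any(np.diff(self.sizes) <= 0):
            raise ValueError("sizes must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density values must be non-negative")
        self._total = float(np.trapezoid(self.density, self.sizes))
        if not self._total > 0:
            raise ValueError("total integrated mass must be > 0")

    @classmethod
    def from_points(cls, library_id: str, sizes, density) -> "SizeDistribution":
        """Build a distribution from possibly unordered (size, density) points."""
        sizes = np.asarray(sizes, dtype=float)
        density = np.asarray(density, dtype=float)
        order = np.argsort(sizes, kind="stable")
        return cls(library_id, sizes[order], density[order])

    @property
    def total_mass(self) -> float:
        return self._total

    @property
    def support(self) -> tuple[float, float]:
        return float(self.sizes[0]), float(self.sizes[-1])


def load_trace(path, library_id: str | None = None) -> SizeDistribution:
    """Load a two-column (size bp, density) CSV trace; a header row is optional.

    Malformed rows raise :class:`TraceParseError` naming the offending line.
    """
    if library_id is None:
        library_id = str(path).rsplit("/", 1)[-1].split(".")[0]
    sizes: list[float] = []
    dens: list[float] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise TraceParseError(f"{path}: line {lineno}: expected 2 columns")
            try:
                s, d = float(row[0]), float(row[1])
            except ValueError:
                if lineno == 1:  # tolerated header row
                    continue
                raise TraceParseError(
                    f"{path}: line {lineno}: non-numeric row {row!r}"
                ) from None
            if d < 0:
                raise TraceParseError(
                    f"{path}: line {lineno}: negative density {d}"
                )
            sizes.append(s)
            dens.append(d)
    if len(sizes) < 2:
        raise TraceParseError(f"{path}: fewer than 2 data points")
    try:
        return SizeDistribution.from_points(library_id, sizes, dens)
    except ValueError as exc:
        raise TraceParseError(f"{path}: {exc}") from exc


def crop(dist: SizeDistribution, min_bp: float) -> SizeDistribution:
    """Drop the portion of a trace below ``min_bp`` (e.g. marker/primer peaks).

    The trace is cut with a linearly interpolated point at ``min_bp`` so
    cropping never shifts mass across the cut.
    """
    lo, hi = dist.support
    if min_bp <= lo:
        return dist
    if min_bp >= hi:
        raise ValueError(f"crop at {min_bp} bp removes the entire trace")
    keep = dist.sizes > min_bp
    edge_d = float(np.interp(min_bp, dist.sizes, dist.density))
    sizes = np.concatenate(([min_bp], dist.sizes[keep]))
    dens = np.concatenate(([edge_d], dist.density[keep]))
    return SizeDistribution(dist.library_id, sizes, dens)


def _integral(dist: SizeDistribution, lo: float, hi: float) -> float:
    """Trapezoidal integral of the density over [lo, hi] clipped to support."""
    a, b = dist.support
    lo, hi = max(lo, a), min(hi, b)
    if hi <= lo:
        return 0.0
    inside = (dist.sizes > lo) & (dist.sizes < hi)
    xs = np.concatenate(([lo], dist.sizes[inside], [hi]))
    ys = np.concatenate(
        (
            [np.interp(lo, dist.sizes, dist.density)],
            dist.density[inside],
            [np.interp(hi, dist.sizes, dist.density)],
        )
    )
    return float(np.trapezoid(ys, xs))


def target_fraction(dist: SizeDistribution, window: TargetWindow) -> float:
    """Fraction of total library mass inside the target window, in [0, 1]."""
    frac = _integral(dist, window.lo, window.hi) / dist.total_mass
    # guard against round-off spilling a hair outside [0, 1]
    return min(max(frac, 0.0), 1.0)


def write_fraction_table(path, dists, window: TargetWindow) -> None:
    """Write a TSV of per-library target fractions."""
    with open(path, "w") as fh:
        fh.write("library_id\ttarget_lo\ttarget_hi\ttarget_fraction\n")
        for dist in dists:
            f = target_fraction(dist, window)
            fh.write(f"{dist.library_id}\t{window.lo:g}\t{window.hi:g}\t{f:.6f}\n")
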