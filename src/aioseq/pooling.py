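"""Target-region-concentration (TRC) pooling design.

The pooling currency of all-in-one sequencing is the target region
concentration: the Qubit concentration of the whole library multiplied by the
fraction of its mass inside the size-selection window.  Libraries are pooled
so that each contributes a target-region mass proportional to its expected
share of the lane's data yield; the pipetted volume of library *i* is then
``mass_i / trc_i``.

All arithmetic is carried at full precision; TRCs and volumes are rounded
half-up to 2 decimals for display only.  (Rounding the TRC before dividing
would shift several worksheet volumes by 0.01 µL.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._display import parse_weight, round_half_up

__all__ = [
    "LibraryQC",
    "PoolPlan",
    "trc",
    "allocate_masses",
    "volumes",
    "expected_yields",
    "design_pool",
    "check_volume_feasibility",
    "read_qc_table",
]


@dataclass
class LibraryQC:
    """One library's QC measurements and its expected-yield weight.

    conc
        Whole-library concentration in ng/µL (fluorometric assay).
    target_fraction
        Fraction of library mass inside the size-selection window, in (0, 1].
    weight
        Expected-data-yield proportion within the pool (any positive scale;
        normalised at pool level).
    available_volume
        Optional volume of library on hand, µL.
    """

    library_id: str
    conc: float
    target_fraction: float
    weight: float = 1.0
    available_volume: float | None = None

    def __post_init__(self) -> None:
        if not self.conc > 0:
            raise ValueError(f"{self.library_id}: conc must be > 0")
        if not 0 < self.target_fraction <= 1:
            raise ValueError(f"{self.library_id}: target_fraction must be in (0, 1]")
        if not self.weight > 0:
            raise ValueError(f"{self.library_id}: weight must be > 0")

    @property
    def trc(self) -> float:
        return trc(self.conc, self.target_fraction)


def trc(conc: float, target_fraction: float) -> float:
    """Target region concentration (ng/µL) = conc × target_fraction."""
    if not conc > 0:
        raise ValueError("conc must be > 0")
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    return conc * target_fraction


def allocate_masses(
    weights,
    reference_mass: float,
    reference_policy: str = "per_max_weight_sample",
) -> np.ndarray:
    """Per-library target-region masses (ng) proportional to weights.

    ``per_max_weight_sample`` gives ``reference_mass`` to the largest-weight
    library (the worksheet idiom "20.0 ng each" under equal weights);
    ``total_pool`` makes the masses sum to ``reference_mass``.
    """
    w = np.asarray([parse_weight(x) for x in np.atleast_1d(weights)], dtype=float)
    if w.size == 0:
        raise ValueError("empty weight list")
    if not reference_mass > 0:
        raise ValueError("reference_mass must be > 0")
    if reference_policy == "per_max_weight_sample":
        return reference_mass * w / w.max()
    if reference_policy == "total_pool":
        return reference_mass * w / w.sum()
    raise ValueError(f"unknown reference_policy {reference_policy!r}")


def volumes(plan_masses, trcs) -> np.ndarray:
    """Pipetting volumes (µL): mass_i / trc_i at full precision."""
    m = np.asarray(plan_masses, dtype=float)
    t = np.asarray(trcs, dtype=float)
    if np.any(m <= 0) or np.any(t <= 0):
        raise ValueError("masses and TRCs must be > 0")
    return m / t


def expected_yields(lane_total: float, weights) -> np.ndarray:
    """Split a lane total (Gb) across libraries in proportion to weights."""
    if not lane_total > 0:
        raise ValueError("lane_total must be > 0")
    w = np.asarray([parse_weight(x) for x in np.atleast_1d(weights)], dtype=float)
    if w.size == 0:
        raise ValueError("empty weight list")
    return lane_total * w / w.sum()


@dataclass
class PoolPlan:
    """A solved pooling plan: per-library TRC, target mass and volume."""

    table: pd.DataFrame  # library_id, conc, target_fraction, weight, trc, target_mass, volume
    reference_mass: float
    reference_policy: str

    @property
    def total_mass(self) -> float:
        return float(self.table["target_mass"].sum())

    @property
    def total_volume(self) -> float:
        return float(self.table["volume"].sum())

    def display(self) -> pd.DataFrame:
        """Worksheet view with half-up 2-dp rounding of TRC and volume."""
        out = self.table.copy()
        out["trc"] = out["trc"].map(lambda x: round_half_up(x, 2))
        out["target_mass"] = out["target_mass"].map(lambda x: round_half_up(x, 1))
        out["volume"] = out["volume"].map(lambda x: round_half_up(x, 2))
        return out

    def scaled(self, k: float) -> "PoolPlan":
        """Scale all masses and volumes by ``k`` (worksheet scale-up/down)."""
        if not k > 0:
            raise ValueError("scale factor must be > 0")
        t = self.table.copy()
        t["target_mass"] *= k
        t["volume"] *= k
        return PoolPlan(t, self.reference_mass * k, self.reference_policy)

    def to_tsv(self, path) -> None:
        self.display().to_csv(path, sep="\t", index=False)


def design_pool(
    qcs: list[LibraryQC],
    reference_mass: float = 20.0,
    reference_policy: str = "per_max_weight_sample",
) -> PoolPlan:
    """Solve the pooling plan for a set of QC'd libraries."""
    if not qcs:
        raise ValueError("no libraries given")
    w = [q.weight for q in qcs]
    masses = allocate_masses(w, reference_mass, reference_policy)
    trcs = np.array([q.trc for q in qcs])
    vols = volumes(masses, trcs)
    table = pd.DataFrame(
        {
            "library_id": [q.library_id for q in qcs],
            "conc": [q.conc for q in qcs],
            "target_fraction": [q.target_fraction for q in qcs],
            "weight": w,
            "trc": trcs,
            "target_mass": masses,
            "volume": vols,
        }
    )
    return PoolPlan(table, reference_mass, reference_policy)


def check_volume_feasibility(
    plan: PoolPlan,
    qcs: list[LibraryQC],
    min_volume: float = 1.0,
) -> list[str]:
    """Warn about volumes exceeding stock or below a pipettable minimum.

    Sub-pipettable volumes get a suggested uniform scale-up factor (the plan
    may be proportionately scaled without changing yield shares).
    """
    avail = {q.library_id: q.available_volume for q in qcs}
    warnings: list[str] = []
    for rec in plan.table.itertuples():
        a = avail.get(rec.library_id)
        if a is not None and rec.volume > a:
            warnings.append(
                f"{rec.library_id}: requires {rec.volume:.2f} µL but only "
                f"{a:.2f} µL available (shortfall {rec.volume - a:.2f} µL)"
            )
        if rec.volume < min_volume:
            factor = min_volume / rec.volume
            warnings.append(
                f"{rec.library_id}: volume {rec.volume:.2f} µL is below the "
                f"pipettable minimum {min_volume:.2f} µL; scale the pool up "
                f"by ≥ {factor:.2f}×"
            )
    return warnings


def read_qc_table(path) -> list[LibraryQC]:
    """Read a QC TSV: library_id, conc_ng_per_ul, target_fraction, weight[, available_volume_ul].

    The target_fraction column may instead hold a path to a trace CSV, in
    which case the caller resolves it via :mod:`aioseq.size_profile`.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"library_id", "conc_ng_per_ul", "target_fraction", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    qcs = []
    for rec in df.itertuples():
        avail = getattr(rec, "available_volume_ul", None)
        qcs.append(
            LibraryQC(
                str(rec.library_id),
                float(rec.conc_ng_per_ul),
                float(rec.target_fraction),
                parse_weight(rec.weight),
                None if avail is None or pd.isna(avail) else float(avail),
            )
        )
    return qcs
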