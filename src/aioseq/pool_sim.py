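"""Stochastic simulator of the all-in-one pooling workflow.

Emulates the chain: true library size distributions and concentrations →
noisy QC measurements → TRC pooling plan (via :mod:`aioseq.pooling`) →
pipetting noise → true pooled target-region masses → competitive lane
sampling → demultiplexed yields.

The lane is a fixed-capacity resource shared by the pooled libraries, so
yields compete: realized yield shares are drawn from a Dirichlet centred on
the true pooled target-mass fractions with a concentration scalar governing
sequencing dispersion (``inf``/None = deterministic shares).  Capacity is
conserved exactly.

The simulator is a calibration instrument for the unexplained dispersion in
observed pool CVs, not a fitted model: the published experiments report
group CVs of roughly 5–11% under equal-weight pooling without decomposing
them into assay, pipetting and lane components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .pooling import LibraryQC, PoolPlan, design_pool
from .yield_eval import cv

__all__ = ["SimConfig", "SimResult", "simulate_pool", "recover_weights", "replicate_cv"]


@dataclass
class SimConfig:
    """Scenario for a simulated pool.

    Defaults resemble a seven-library equal-weight whole-genome pool on a
    ~47 Gb lane: concentrations lognormal around 23 ng/µL, fragment lengths
    lognormal with mode ≈ 470 bp and log-sd 0.6 (which puts ≈ 10–13% of
    library mass in the 420–520 bp window), 5% assay CV, 5% logit-scale
    trace-fraction CV, 2% pipetting CV, Dirichlet concentration 2000.
    """

    n_libraries: int = 7
    weights: list | None = None          # None = equal
    conc_meanlog: float = math.log(23.0)
    conc_sdlog: float = 0.1
    frag_mode_bp: float = 470.0
    frag_mode_cv: float = 0.05           # library-to-library spread of the mode
    frag_sdlog: float = 0.6
    window: tuple[float, float] = (420.0, 520.0)
    conc_noise_cv: float = 0.05          # fluorometric assay
    fraction_noise_cv: float = 0.05      # trace fraction, logit scale
    pipette_cv: float = 0.02
    lane_capacity_gb: float = 46.8
    dirichlet_concentration: float | None = 2000.0
    reference_mass_ng: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_libraries < 1:
            raise ValueError("n_libraries must be >= 1")
        if self.weights is not None and len(self.weights) != self.n_libraries:
            raise ValueError("weights length must equal n_libraries")
        for name in ("conc_noise_cv", "fraction_noise_cv", "pipette_cv",
                     "frag_mode_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.lane_capacity_gb > 0:
            raise ValueError("lane_capacity_gb must be > 0")
        dc = self.dirichlet_concentration
        if dc is not None and not dc > 0:
            raise ValueError("dirichlet_concentration must be > 0 or None")
        lo, hi = self.window
        if not 0 < lo < hi:
            raise ValueError("window must satisfy 0 < lo < hi")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        return cls(**raw)


@dataclass
class SimResult:
    """One simulated pool: truth, measurements, plan and realized yields."""

    config: SimConfig
    truth: pd.DataFrame      # library_id, conc, target_fraction, trc, weight
    measured: pd.DataFrame   # library_id, conc, target_fraction, trc
    plan: PoolPlan
    pooled_mass_ng: np.ndarray   # true target-region mass actually pooled
    yields_gb: np.ndarray
    seed: int = field(default=0)

    @property
    def group_cv_pct(self) -> float:
        return cv(self.yields_gb)

    def yields_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.truth["library_id"],
                "group": "sim",
                "yield_gb": self.yields_gb,
                "weight": self.truth["weight"],
            }
        )


def _lognormal_factor(rng: np.random.Generator, cv_: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with the given CV and unit median."""
    if cv_ == 0:
        return np.ones(size)
    sdlog = math.sqrt(math.log(1.0 + cv_**2))
    return np.exp(rng.normal(0.0, sdlog, size))


def _true_fraction(mode_bp: np.ndarray, sdlog: float, window) -> np.ndarray:
    """Mass fraction of a lognormal fragment distribution inside the window."""
    from scipy.stats import lognorm

    lo, hi = window
    # lognormal with mode m: scale = m * exp(sdlog^2)
    scale = mode_bp * math.exp(sdlog**2)
    return lognorm.cdf(hi, sdlog, scale=scale) - lognorm.cdf(lo, sdlog, scale=scale)


def simulate_pool(config: SimConfig, seed: int | None = None) -> SimResult:
    """Run one pooled-lane simulation; fully reproducible from the seed."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = config.n_libraries
    weights = (
        np.ones(n) / n
        if config.weights is None
        else np.asarray([float(w) for w in config.weights], dtype=float)
    )
    if np.any(weights <= 0):
        raise ValueError("weights must be > 0")
    weights = weights / weights.sum()

    ids = [f"L{i + 1}" for i in range(n)]
    conc_true = np.exp(rng.normal(config.conc_meanlog, config.conc_sdlog, n))
    mode = config.frag_mode_bp * _lognormal_factor(rng, config.frag_mode_cv, n)
    frac_true = _true_fraction(mode, config.frag_sdlog, config.window)
    trc_true = conc_true * frac_true

    # QC measurements: multiplicative noise on concentration, logit-scale
    # Gaussian noise on the trace fraction (keeps it inside (0, 1)).
    conc_meas = conc_true * _lognormal_factor(rng, config.conc_noise_cv, n)
    if config.fraction_noise_cv > 0:
        logit = np.log(frac_true / (1.0 - frac_true))
        logit = logit + rng.normal(0.0, config.fraction_noise_cv, n)
        frac_meas = 1.0 / (1.0 + np.exp(-logit))
    else:
        frac_meas = frac_true.copy()

    qcs = [
        LibraryQC(i, c, f, w)
        for i, c, f, w in zip(ids, conc_meas, frac_meas, weights)
    ]
    plan = design_pool(qcs, config.reference_mass_ng, "per_max_weight_sample")

    vol_planned = plan.table["volume"].to_numpy()
    vol_actual = vol_planned * _lognormal_factor(rng, config.pipette_cv, n)
    pooled_mass = vol_actual * trc_true  # what truly lands in the tube

    shares = pooled_mass / pooled_mass.sum()
    dc = config.dirichlet_concentration
    if dc is not None and np.isfinite(dc):
        shares = rng.dirichlet(dc * shares)
    yields = config.lane_capacity_gb * shares

    truth = pd.DataFrame(
        dict(library_id=ids, conc=conc_true, target_fraction=frac_true,
             trc=trc_true, weight=weights)
    )
    measured = pd.DataFrame(
        dict(library_id=ids, conc=conc_meas, target_fraction=frac_meas,
             trc=conc_meas * frac_meas)
    )
    return SimResult(config, truth, measured, plan, pooled_mass, yields, seed)


def recover_weights(result: SimResult) -> tuple[np.ndarray, float]:
    """Estimate weights as normalized realized yields; report max abs error."""
    y = np.asarray(result.yields_gb, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 libraries")
    est = y / y.sum()
    true_w = result.truth["weight"].to_numpy()
    return est, float(np.abs(est - true_w).max())


def replicate_cv(config: SimConfig, replicates: int, seed: int | None = None) -> pd.DataFrame:
    """Monte-Carlo distribution of the realized group CV over replicates.

    Each replicate reseeds the full pipeline from ``seed + k`` so the whole
    sweep is reproducible from one integer.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    base = config.seed if seed is None else seed
    rows = []
    for k in range(replicates):
        res = simulate_pool(config, seed=base + k)
        est, err = recover_weights(res)
        rows.append(dict(replicate=k, seed=base + k,
                         cv_pct=res.group_cv_pct, max_weight_error=err))
    return pd.DataFrame(rows)


def config_to_yaml(config: SimConfig, path) -> None:
    d = asdict(config)
    d["window"] = list(d["window"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
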