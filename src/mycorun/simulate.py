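"""Synthetic replicate-level growth data calibrated to the printed tables.

No replicate-level or time-course raw data were published for the study
design, only per-substrate summary means.  This module generates datasets
with the structure the analysis assumes — 64 substrates × 8 observation days
× 4 replicates (2,048 running-length rows) and 64 × 4 running-rate rows —
calibrated so that the noiseless mean surface reproduces the printed tables
exactly at each substrate's days-to-highest.

Growth model
------------
Running length follows the simplest curve consistent with the reported
monotone increase and per-substrate plateau day: a linear ramp

    mean_rl(t) = plateau_cm * min(t, plateau_day) / plateau_day

which equals the printed mean exactly at ``plateau_day`` and stays flat
afterwards.  The no-growth control has plateau 0.

Replicate noise is a single multiplicative factor per substrate-replicate,
``max(0, 1 + delta / plateau_cm)`` with ``delta ~ N(0, noise_sd_cm²)``, so at
the plateau day the replicate value is ``plateau_cm + delta`` (additive SD of
``noise_sd_cm``) while within-replicate monotonicity in time is preserved
exactly.  Consumption order of the random stream is fixed: substrate index,
then replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .tables import TIME_GRID, StudyTables, SubstrateComposition

__all__ = [
    "GrowthParams",
    "SimConfig",
    "build_growth_params",
    "growth_curve_mean",
    "generate_rl_dataset",
    "generate_rr_dataset",
    "enumerate_treatments",
]

#: Default replicate standard deviation (cm); matches the spread reported for
#: the study's validation culture (±0.35 cm).
DEFAULT_NOISE_SD_CM = 0.30


@dataclass(frozen=True)
class GrowthParams:
    """Calibrated growth-curve parameters for one substrate."""

    composition: SubstrateComposition
    plateau_cm: float
    plateau_day: Optional[int]  # None for the no-growth control
    noise_sd_cm: float

    def __post_init__(self) -> None:
        if self.plateau_cm < 0 or self.noise_sd_cm < 0:
            raise ValueError("plateau_cm and noise_sd_cm must be nonnegative")
        if self.plateau_day is not None and self.plateau_day <= 0:
            raise ValueError("plateau_day must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-data settings; the defaults are the study's design."""

    seed: int = 0
    n_replicates: int = 4
    noise_sd_cm: float = DEFAULT_NOISE_SD_CM
    time_grid: tuple[int, ...] = field(default=TIME_GRID)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd_cm < 0:
            raise ValueError("noise_sd_cm must be >= 0")


def build_growth_params(tables: StudyTables, sim: SimConfig) -> list[GrowthParams]:
    """One GrowthParams per substrate, calibrated to the printed means."""
    out = []
    for r in tables.frame.itertuples():
        day = None if pd.isna(r.days_to_highest) else int(r.days_to_highest)
        out.append(
            GrowthParams(
                composition=SubstrateComposition(r.bagasse_pct, r.wheatbran_pct, r.beechsawdust_pct),
                plateau_cm=float(r.rl_mean_cm),
                plateau_day=day,
                noise_sd_cm=sim.noise_sd_cm,
            )
        )
    return out


def growth_curve_mean(params: GrowthParams, t: float) -> float:
    """Mean running length (cm) at time ``t`` (days): linear ramp to plateau."""
    if t < 0:
        raise ValueError("time must be nonnegative")
    if params.plateau_day is None or params.plateau_cm == 0:
        return 0.0
    return params.plateau_cm * min(t, params.plateau_day) / params.plateau_day


def _replicate_factors(params: GrowthParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-replicate multiplicative noise factors (draws consumed even when unused)."""
    delta = rng.normal(0.0, params.noise_sd_cm, size=n)
    if params.plateau_cm == 0:
        return np.zeros(n)
    return np.maximum(0.0, 1.0 + delta / params.plateau_cm)


def generate_rl_dataset(tables: StudyTables, sim: SimConfig) -> pd.DataFrame:
    """Replicate-level running-length dataset (default design: 2,048 rows)."""
    rng = np.random.default_rng(sim.seed)
    rows = []
    for params in build_growth_params(tables, sim):
        b, w, s = params.composition.as_tuple()
        factors = _replicate_factors(params, sim.n_replicates, rng)
        for rep in range(1, sim.n_replicates + 1):
            f = factors[rep - 1]
            for t in sim.time_grid:
                rl = growth_curve_mean(params, t) * f if params.plateau_cm > 0 else 0.0
                rows.append((b, w, s, float(t), rep, rl))
    return pd.DataFrame(rows, columns=["bagasse_pct", "wheatbran_pct", "beechsawdust_pct", "time_days", "replicate", "rl_cm"])


def generate_rr_dataset(tables: StudyTables, sim: SimConfig) -> pd.DataFrame:
    """Replicate-level running-rate dataset (default design: 256 rows).

    Each replicate's rate is its running length at the substrate's plateau day
    divided by that day; control rows are 0.
    """
    rng = np.random.default_rng(sim.seed)
    rows = []
    for params in build_growth_params(tables, sim):
        b, w, s = params.composition.as_tuple()
        factors = _replicate_factors(params, sim.n_replicates, rng)
        for rep in range(1, sim.n_replicates + 1):
            if params.plateau_day is None or params.plateau_cm == 0:
                rr = 0.0
            else:
                rr = params.plateau_cm * factors[rep - 1] / params.plateau_day
            rows.append((b, w, s, rep, rr))
    return pd.DataFrame(rows, columns=["bagasse_pct", "wheatbran_pct", "beechsawdust_pct", "replicate", "rr_cm_per_day"])


def enumerate_treatments(tables: StudyTables, time_grid: tuple[int, ...] = TIME_GRID) -> pd.DataFrame:
    """The full factorial treatment list: composition × observation day (512 rows)."""
    rows = [
        (r.bagasse_pct, r.wheatbran_pct, r.beechsawdust_pct, float(t))
        for r in tables.frame.itertuples()
        for t in time_grid
    ]
    return pd.DataFrame(rows, columns=["bagasse_pct", "wheatbran_pct", "beechsawdust_pct", "time_days"])
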