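"""GA optimization of substrate inputs over a trained surrogate.

The genetic algorithm maximizes the surrogate's predicted response in
original units over a box: each component percentage in [0, 100] and, for
the running-length model, running time in [5, 40] days.  Search never
extrapolates outside the design box.  The initial population can be seeded
with the 64 design-grid compositions (at each substrate's days-to-highest
for the time axis), which together with elitism guarantees the returned
optimum is at least as good as every grid point's prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ga import GAConfig, OptimizationOutcome, run_ga
from .mlp import MLPModel
from .tables import StudyTables

__all__ = ["OptimizationQuery", "default_bounds", "optimize_inputs", "format_days"]

COMPONENT_BOUNDS = (0.0, 100.0)
TIME_BOUNDS = (5.0, 40.0)


def default_bounds(n_inputs: int) -> tuple[tuple[float, float], ...]:
    """Design-box bounds: three components, plus time for the 4-input model."""
    if n_inputs == 3:
        return (COMPONENT_BOUNDS,) * 3
    if n_inputs == 4:
        return (COMPONENT_BOUNDS,) * 3 + (TIME_BOUNDS,)
    raise ValueError("surrogates take 3 (rate) or 4 (length) inputs")


@dataclass(frozen=True)
class OptimizationQuery:
    """A trained surrogate, its search box, GA settings, and grid seeding."""

    model: MLPModel
    ga: GAConfig
    grid_seed_tables: Optional[StudyTables] = None  # seed initial population from the design grid

    def __post_init__(self) -> None:
        if len(self.ga.bounds) != self.model.n_inputs:
            raise ValueError(
                f"bounds cover {len(self.ga.bounds)} genes but the model takes {self.model.n_inputs} inputs"
            )


def _grid_points(tables: StudyTables, n_inputs: int) -> np.ndarray:
    """The 64 design compositions; time = days-to-highest (40 for the control)."""
    f = tables.frame
    comps = f[["bagasse_pct", "wheatbran_pct", "beechsawdust_pct"]].to_numpy(dtype=float)
    if n_inputs == 3:
        return comps
    days = f["days_to_highest"].astype(float).fillna(40.0).to_numpy()
    return np.column_stack([comps, days])


def optimize_inputs(query: OptimizationQuery) -> OptimizationOutcome:
    """Maximize the surrogate's original-units prediction over the search box."""
    model = query.model

    def fitness(chrom: np.ndarray) -> float:
        return float(model.predict(chrom.reshape(1, -1))[0])

    initial = None
    if query.grid_seed_tables is not None:
        grid = _grid_points(query.grid_seed_tables, model.n_inputs)
        preds = model.predict(grid)
        # keep the best-predicted grid points (argmax included), leave room for random fill
        n_seed = min(len(grid), max(1, query.ga.population_size - 10))
        initial = grid[np.argsort(preds)[::-1][:n_seed]]
    return run_ga(fitness, query.ga, initial_population=initial)


def format_days(days: float) -> str:
    """Render fractional days as 'Xd Yh' (28.43 -> '28d 10h')."""
    whole = int(days)
    hours = int(round((days - whole) * 24))
    if hours == 24:
        whole, hours = whole + 1, 0
    return f"{whole}d {hours}h"
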