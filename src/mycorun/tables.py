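"""Packaged in-study tables and the running-rate relation.

The study cultured *Lentinula edodes* on 64 growing substrates mixed from
bagasse (B), wheat bran (WB) and beech sawdust (BS), each component dosed as a
percentage of a 10 g aliquot (so the three percentages do *not* sum to 100).
Mycelial running length (RL, cm) was read every 5 days up to day 40; running
rate (RR, cm d⁻¹) is RL divided by running time.

Three printed summary tables are packaged with this module:

* ``table1.csv`` — the 64 compositions and, per substrate, the earliest day on
  which the statistically highest RL was recorded ("days-to-highest"; the
  all-zero control never grows and has no such day).
* ``table2_rl.csv`` — per-substrate mean RL (cm) at that day.
* ``table3_rr.csv`` — per-substrate mean RR (cm d⁻¹).

Mean-separation significance letters from the source tables are kept in a
separate annotation column and are never parsed as numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd

__all__ = [
    "SubstrateComposition",
    "StudyTables",
    "FixtureError",
    "load_study_tables",
    "compute_rr",
    "COMPONENT_LEVELS",
    "TIME_GRID",
]

#: Factor levels actually used in the reported design (percent of a 10 g aliquot).
COMPONENT_LEVELS = (0, 25, 50, 100)

#: Observation days (running time, days after inoculation).
TIME_GRID = (5, 10, 15, 20, 25, 30, 35, 40)


class FixtureError(RuntimeError):
    """Raised when a packaged table fixture is missing or corrupted."""


@dataclass(frozen=True)
class SubstrateComposition:
    """One growing-substrate recipe: component percentages of a 10 g aliquot."""

    bagasse_pct: float
    wheatbran_pct: float
    beechsawdust_pct: float

    def __post_init__(self) -> None:
        for name in ("bagasse_pct", "wheatbran_pct", "beechsawdust_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name}={v!r} outside [0, 100]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.bagasse_pct, self.wheatbran_pct, self.beechsawdust_pct)


@dataclass(frozen=True)
class StudyTables:
    """The three printed summary tables, keyed consistently by substrate.

    ``frame`` holds one row per substrate (64 rows, original order) with columns
    ``substrate, bagasse_pct, wheatbran_pct, beechsawdust_pct, days_to_highest,
    rl_mean_cm, rl_letters, rr_mean_cm_per_day, rr_letters``.  ``days_to_highest``
    is a nullable integer; it is null only for the no-growth control.
    """

    frame: pd.DataFrame

    @property
    def compositions(self) -> list[SubstrateComposition]:
        return [
            SubstrateComposition(r.bagasse_pct, r.wheatbran_pct, r.beechsawdust_pct)
            for r in self.frame.itertuples()
        ]

    def row(self, composition: SubstrateComposition | tuple[float, float, float]) -> pd.Series:
        """Return the table row for one composition."""
        if isinstance(composition, SubstrateComposition):
            composition = composition.as_tuple()
        b, w, s = composition
        m = (
            (self.frame["bagasse_pct"] == b)
            & (self.frame["wheatbran_pct"] == w)
            & (self.frame["beechsawdust_pct"] == s)
        )
        hits = self.frame[m]
        if len(hits) != 1:
            raise KeyError(f"composition {composition} not in the design table")
        return hits.iloc[0]


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("mycorun.data").joinpath(name)
    try:
        with ref.open("r", encoding="utf-8") as fh:
            return pd.read_csv(fh)
    except (FileNotFoundError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FixtureError(f"packaged fixture {name!r} missing or unreadable: {exc}") from exc


def load_study_tables() -> StudyTables:
    """Load and join the three packaged tables into one 64-row frame."""
    t1 = _read_fixture("table1.csv")
    t2 = _read_fixture("table2_rl.csv").rename(columns={"significance_letters": "rl_letters"})
    t3 = _read_fixture("table3_rr.csv").rename(columns={"significance_letters": "rr_letters"})
    for name, t, cols in (
        ("table1.csv", t1, {"substrate", "bagasse_pct", "wheatbran_pct", "beechsawdust_pct", "days_to_highest"}),
        ("table2_rl.csv", t2, {"substrate", "rl_mean_cm"}),
        ("table3_rr.csv", t3, {"substrate", "rr_mean_cm_per_day"}),
    ):
        missing = cols - set(t.columns)
        if missing:
            raise FixtureError(f"{name}: missing columns {sorted(missing)}")
    frame = t1.merge(t2, on="substrate", validate="1:1").merge(t3, on="substrate", validate="1:1")
    if len(frame) != 64:
        raise FixtureError(f"expected 64 substrates, found {len(frame)}")
    frame["days_to_highest"] = frame["days_to_highest"].astype("Int64")
    if (frame["rl_mean_cm"] < 0).any() or (frame["rr_mean_cm_per_day"] < 0).any():
        raise FixtureError("negative mean in packaged tables")
    control = frame["days_to_highest"].isna()
    grew = (frame["rl_mean_cm"] > 0) | (frame["rr_mean_cm_per_day"] > 0)
    if (control & grew).any():
        raise FixtureError("substrate without a days-to-highest entry reports growth")
    return StudyTables(frame=frame)


def compute_rr(rl_cm: float, time_days: Optional[float]) -> float:
    """Running rate (cm d⁻¹) = running length (cm) / running time (d).

    The no-growth control has zero RL and no defined running time; its rate is
    0 by convention (matching the printed tables).  A positive length with a
    nonpositive or undefined time is a domain error.
    """
    if rl_cm < 0:
        raise ValueError(f"running length must be nonnegative, got {rl_cm}")
    if rl_cm == 0:
        return 0.0
    if time_days is None or pd.isna(time_days) or time_days <= 0:
        raise ValueError(f"running time must be positive for nonzero length, got {time_days}")
    return rl_cm / time_days
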