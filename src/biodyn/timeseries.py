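"""Time-series collection during a run.

A :class:`TimeSeriesTable` holds named collectors, each a reducer mapping
the population to one number, evaluated on the operation-frequency clock
(due at iterations 0, f, 2f, ...).  Registered as a standalone engine
operation it snapshots the run into a fixed-schema table with the
iteration index first, exportable to CSV.
"""

from __future__ import annotations

from typing import Callable

import pandas as pd

from .engine import Operation, Simulation


class TimeSeriesTable:
    def __init__(self) -> None:
        self._collectors: dict[str, tuple[Callable, int]] = {}
        self._rows: list[dict] = []

    def register_collector(self, name: str, reducer: Callable, frequency: int = 1) -> None:
        """Register a named reducer evaluated every ``frequency`` iterations."""
        if name in self._collectors or name in ("iteration", "t"):
            raise ValueError(f"collector name {name!r} already registered")
        if frequency < 1:
            raise ValueError("collector frequency must be >= 1")
        self._collectors[name] = (reducer, int(frequency))

    def collect(self, sim: Simulation) -> None:
        row: dict = {"iteration": sim.iteration, "t": sim.time}
        due = False
        for name, (reducer, frequency) in self._collectors.items():
            if sim.iteration % frequency == 0:
                try:
                    row[name] = reducer(sim.population.values())
                except Exception as exc:
                    raise RuntimeError(f"collector {name!r} failed at iteration "
                                       f"{sim.iteration}: {exc}") from exc
                due = True
        if due or not self._collectors:
            self._rows.append(row)

    def as_operation(self, frequency: int = 1) -> Operation:
        return Operation("collect_time_series", "standalone",
                         lambda sim: self.collect(sim), frequency)

    def to_dataframe(self) -> pd.DataFrame:
        columns = ["iteration", "t", *self._collectors]
        frame = pd.DataFrame(self._rows)
        if frame.empty:
            return pd.DataFrame(columns=columns)
        return frame.reindex(columns=columns)

    def export_csv(self, path) -> None:
        """RFC-4180 CSV with a header row; iteration column first."""
        self.to_dataframe().to_csv(path, index=False)
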