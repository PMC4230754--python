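"""Spike event lists and their on-disk formats.

Spikes are exchanged between modules (and exported) as timestamped events
tagged by unit id, with a population manifest mapping unit ids to their
population and type.  On disk an event list is a two-column CSV
(time_s, unit_id) plus a manifest CSV; a parquet container is offered for
large runs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class SpikeEventList:
    """Timestamped spikes tagged by unit id."""
    times: np.ndarray
    unit_ids: np.ndarray
    manifest: pd.DataFrame | None = field(default=None)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.unit_ids = np.asarray(self.unit_ids, dtype=np.int64)
        if len(self.times) != len(self.unit_ids):
            raise ValueError("times and unit_ids must have equal length")

    def __len__(self):
        return len(self.times)

    def sorted(self) -> "SpikeEventList":
        order = np.argsort(self.times, kind="stable")
        return SpikeEventList(self.times[order], self.unit_ids[order],
                              self.manifest)

    def for_unit(self, unit_id: int) -> np.ndarray:
        return np.sort(self.times[self.unit_ids == unit_id])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "unit_id": self.unit_ids})

    def write_csv(self, path, manifest_path=None):
        self.to_frame().to_csv(path, index=False)
        if manifest_path is not None and self.manifest is not None:
            self.manifest.to_csv(manifest_path, index=False)

    def write_parquet(self, path):
        self.to_frame().to_parquet(path, index=False)

    @classmethod
    def read_csv(cls, path, manifest_path=None) -> "SpikeEventList":
        df = pd.read_csv(path)
        manifest = pd.read_csv(manifest_path) if manifest_path else None
        return cls(df["time_s"].to_numpy(), df["unit_id"].to_numpy(),
                   manifest)


def write_edge_list(edges, path):
    """Network description export: one row per connection."""
    pd.DataFrame(edges, columns=["source", "target", "g_max_nS", "delay_s",
                                 "sign"]).to_csv(path, index=False)


def write_timeseries(path, t, columns: dict[str, np.ndarray],
                     decimate: int = 1):
    """Columnar CSV export of synchronised time series (units in the header
    names)."""
    data = {"t_s": np.asarray(t)[::decimate]}
    for name, series in columns.items():
        data[name] = np.asarray(series)[::decimate]
    pd.DataFrame(data).to_csv(Path(path), index=False)
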