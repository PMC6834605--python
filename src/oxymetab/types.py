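"""Shared in-memory containers.

Tabular results (daily rates, driver tables, truth tables, oxygen
structure) are plain pandas DataFrames with documented column names; the
only bespoke container is :class:`SensorSeries`, which pairs one depth's
high-frequency record with its metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class SensorSeries:
    """One depth's timestamped DO / temperature record at fixed cadence.

    Attributes
    ----------
    depth_m : sensor depth, metres below surface (positive down).
    data : DataFrame indexed by timestamp with columns ``do_um`` (uM) and
        ``temp_c`` (degC); strictly increasing index, gaps allowed.
    cadence_min : nominal sampling interval in minutes.
    provenance : free-text origin tag (file name, scenario seed, ...).
    """

    depth_m: float
    data: pd.DataFrame
    cadence_min: int = 10
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.data.index.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate timestamps")

    def __len__(self) -> int:
        return len(self.data)

    def replace_do(self, do_um) -> "SensorSeries":
        """Return a copy with the DO column replaced (same index)."""
        frame = self.data.copy()
        frame["do_um"] = do_um
        return SensorSeries(self.depth_m, frame, self.cadence_min,
                            self.provenance)


@dataclass
class SalinityProfile:
    """One date's depth-resolved mean salinity (already site-averaged)."""

    date: pd.Timestamp
    salinity_by_depth: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.date = pd.Timestamp(self.date)
        if not self.salinity_by_depth:
            raise ValueError("profile needs at least one depth")
        for d, s in self.salinity_by_depth.items():
            if not 0.0 <= s <= 45.0:
                raise ValueError(f"salinity {s} at {d} m outside [0, 45]")
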