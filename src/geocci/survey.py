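"""Clustered survey data: the unit of analysis.

A :class:`SurveyDataset` holds one row per cluster × indicator with the
cluster's reported (displaced) coordinates, urban/rural flag, survey round
and binomial counts (events out of trials).  Clusters where an indicator had
no eligible individuals carry ``trials = 0`` and drop out of that
indicator's model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["INDICATORS", "ClusterRecord", "SurveyDataset"]

#: The eight coverage indicators combined by the CCI, in continuum-of-care
#: order: family planning, antenatal care, skilled birth attendance,
#: immunisation (BCG, DPT3, measles) and case management (ORS, care-seeking
#: for suspected pneumonia).
INDICATORS: tuple[str, ...] = (
    "DFPSm", "ANC4", "SBA", "BCG", "DPT3", "MSL", "ORS", "CAREP",
)

_COLUMNS = ["cluster_id", "x", "y", "urban", "round", "indicator", "events", "trials"]


@dataclass
class ClusterRecord:
    """A single survey cluster (enumeration area)."""

    cluster_id: str
    true_location: tuple[float, float]
    reported_location: tuple[float, float]
    urban: bool
    survey_round: int
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (events, trials) in self.counts.items():
            if not 0 <= events <= trials:
                raise ValueError(
                    f"cluster {self.cluster_id}, indicator {name}: "
                    f"need 0 <= events <= trials, got {events}/{trials}"
                )


class SurveyDataset:
    """Long-format table of cluster × indicator binomial counts."""

    def __init__(self, table: pd.DataFrame, true_locations: pd.DataFrame | None = None):
        missing = [c for c in _COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"survey table missing columns: {missing}")
        bad = table["events"] > table["trials"]
        if bad.any():
            raise ValueError("events must not exceed trials")
        if (table["trials"] < 0).any() or (table["events"] < 0).any():
            raise ValueError("counts must be non-negative")
        self.table = table.reset_index(drop=True)
        #: optional per-cluster true (pre-displacement) locations — synthetic
        #: ground truth only, never used by the models.
        self.true_locations = true_locations

    # -- views ------------------------------------------------------------
    @property
    def cluster_ids(self) -> np.ndarray:
        return self.table["cluster_id"].unique()

    @property
    def n_clusters(self) -> int:
        return self.table["cluster_id"].nunique()

    @property
    def indicators(self) -> list[str]:
        return [i for i in INDICATORS if i in set(self.table["indicator"])]

    def clusters(self) -> pd.DataFrame:
        """One row per cluster: id, reported x/y, urban, round."""
        return (
            self.table.groupby("cluster_id", sort=False)
            .first()[["x", "y", "urban", "round"]]
            .reset_index()
        )

    def for_indicator(self, name: str, positive_trials_only: bool = True) -> pd.DataFrame:
        """Cluster rows for one indicator (by default only trials > 0)."""
        if name not in set(self.table["indicator"]):
            raise KeyError(f"indicator {name!r} not present in dataset")
        sub = self.table[self.table["indicator"] == name]
        if positive_trials_only:
            sub = sub[sub["trials"] > 0]
        return sub.reset_index(drop=True)

    def subset_clusters(self, cluster_ids) -> "SurveyDataset":
        keep = self.table["cluster_id"].isin(set(cluster_ids))
        tl = None
        if self.true_locations is not None:
            tl = self.true_locations[
                self.true_locations["cluster_id"].isin(set(cluster_ids))
            ].reset_index(drop=True)
        return SurveyDataset(self.table[keep].reset_index(drop=True), tl)

    # -- I/O --------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.table[_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SurveyDataset":
        return cls(pd.read_csv(path, dtype={"cluster_id": str}))
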