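"""In-memory cohort dataset: the unit the pipeline stages operate on.

A *point* is one intravascular measurement location (a penetrating vessel
at one depth, or one capillary segment) on one day; it owns the repetition
decay histograms and, for capillaries, the intensity traces.  Points of the
same penetrating vessel share a ``parent_id``; a point keeps the same
``vessel_id`` across days so longitudinal deltas can be aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .plim import DecayHistogram
from .protocol import AcquisitionProtocol, CalibrationParams
from .rbcflux import IntensityTrace

__all__ = ["PointAcquisition", "CohortDataset", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"


@dataclass
class PointAcquisition:
    """Raw data of one measurement point on one day."""

    vessel_id: str
    parent_id: str
    animal_id: str
    cohort: str
    day: int
    depth_um: float
    morphology: str  # "penetrating" | "capillary"
    is_primary_branch: bool = False
    decays: list[DecayHistogram] = field(default_factory=list)
    traces: Optional[list[IntensityTrace]] = None
    truth: Optional[dict] = None


@dataclass
class CohortDataset:
    """All points of an AD/WT cohort experiment plus acquisition metadata."""

    points: list[PointAcquisition]
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    calib: CalibrationParams = field(default_factory=CalibrationParams)
    config: Optional[dict] = None
    schema_version: str = SCHEMA_VERSION

    def __len__(self) -> int:
        return len(self.points)

    def truth_table(self) -> pd.DataFrame:
        """Generator ground truth, one row per point-day (synthetic data)."""
        rows = []
        for p in self.points:
            rec = {
                "vessel_id": p.vessel_id,
                "parent_id": p.parent_id,
                "animal_id": p.animal_id,
                "cohort": p.cohort,
                "day": p.day,
                "depth_um": p.depth_um,
                "morphology": p.morphology,
                "is_primary_branch": p.is_primary_branch,
            }
            if p.truth:
                rec.update(
                    {
                        k: v
                        for k, v in p.truth.items()
                        if not isinstance(v, (list, tuple, dict, np.ndarray))
                    }
                )
            rows.append(rec)
        return pd.DataFrame(rows)
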