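"""Study-region containers shared by the generator, the readers and the
pipeline: analysis areas and the bundle of network + facilities + areas."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .road_network import Facility, RoadNetwork, WeightedCentroid

COVARIATE_COLUMNS = (
    "area_id", "older_share", "high_edu_share", "median_income",
    "area_type", "region", "has_station",
)


@dataclass
class AreaUnit:
    """One analysis unit (emulating a Swedish DeSO of ~1,000-2,000 residents).

    ``area_type`` is the urban / densely_populated / rural class of the
    area's municipality; ``region`` is the administrative-region label used
    as a fixed effect in the disparity models.
    """

    area_id: str
    polygon: Polygon
    area_type: str
    region: str
    older_share: float
    high_edu_share: float
    median_income: float
    has_station: int = 0
    municipality_id: int = 0
    population: float = 0.0
    reportable: bool = True
    centroid: WeightedCentroid | None = None


@dataclass
class SyntheticRegion:
    """A generated (or loaded) study region.

    ``population_grid`` is an (n, 3) array of grid-cell center x, y (meters)
    and head count. ``truth`` records the exact generating parameters
    (seed, covariate gradients, density cutoff, counts) for cross-checks.
    """

    network: RoadNetwork
    stations: list[Facility]
    hospitals: list[Facility]
    areas: list[AreaUnit]
    population_grid: np.ndarray
    truth: dict = field(default_factory=dict)

    def covariate_frame(self) -> pd.DataFrame:
        return areas_frame(self.areas)


def areas_frame(areas: Sequence[AreaUnit]) -> pd.DataFrame:
    """Covariate table with one row per area, sorted by area_id."""
    rows = [
        {
            "area_id": a.area_id,
            "older_share": a.older_share,
            "high_edu_share": a.high_edu_share,
            "median_income": a.median_income,
            "area_type": a.area_type,
            "region": a.region,
            "has_station": a.has_station,
            "municipality_id": a.municipality_id,
            "population": a.population,
            "reportable": a.reportable,
        }
        for a in sorted(areas, key=lambda a: a.area_id)
    ]
    return pd.DataFrame(rows)
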