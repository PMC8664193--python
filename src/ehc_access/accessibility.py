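"""Per-area accessibility measures via closest-facility routing.

Three measures are composed per analysis area, all in minutes:

* RT  (response time)       = shortest travel time from the nearest
                              ambulance station + a dispatch activation
                              constant (1.4 min urban/densely populated,
                              2.9 min rural);
* TT  (transportation time) = shortest travel time from the nearest
                              emergency department, no additive constants;
* TPT (total prehospital time) = RT + TT + an on-scene constant
                              (13.5 min urban/densely populated, 15.1 rural).

Areas with TPT strictly below one hour are inside the "golden hour".
Each measure is additionally split into quintiles, the 5th quintile being
the most underserviced fifth of areas.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .road_network import Facility, RoadNetwork

logger = logging.getLogger(__name__)

URBAN = "urban"
DENSELY_POPULATED = "densely_populated"
RURAL = "rural"
AREA_TYPES = (URBAN, DENSELY_POPULATED, RURAL)

MEASURES = ("rt", "tt", "tpt")


@dataclass(frozen=True)
class TimeConstants:
    """Fixed time components added on top of routed travel times.

    Defaults are ambulance-service benchmark values: activation (call to
    dispatch) of 1.4 min in urban and densely populated areas and 2.9 min
    in rural areas; on-scene times of 13.5 and 15.1 min respectively; and
    the 60-minute golden-hour threshold.
    """

    activation_urban_dense: float = 1.4
    activation_rural: float = 2.9
    onscene_urban_dense: float = 13.5
    onscene_rural: float = 15.1
    golden_hour: float = 60.0

    def __post_init__(self) -> None:
        for name in (
            "activation_urban_dense", "activation_rural",
            "onscene_urban_dense", "onscene_rural", "golden_hour",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def activation(self, area_type: str) -> float:
        _check_area_type(area_type)
        return self.activation_rural if area_type == RURAL else self.activation_urban_dense

    def onscene(self, area_type: str) -> float:
        _check_area_type(area_type)
        return self.onscene_rural if area_type == RURAL else self.onscene_urban_dense


def _check_area_type(area_type: str) -> None:
    if area_type not in AREA_TYPES:
        raise ValueError(f"unknown area type {area_type!r}; expected one of {AREA_TYPES}")


class ClosestFacility(NamedTuple):
    facility_id: str | None
    travel_min: float  # math.inf when unreachable


def facility_travel_times(
    network: RoadNetwork, facilities: Sequence[Facility]
) -> dict[int, ClosestFacility]:
    """Minimum travel time from any facility to every reachable node.

    One Dijkstra pass per facility (equivalent to a multi-source pass but
    retaining WHICH facility achieves the minimum). Exact ties go to the
    facility with the lowest id: facilities are scanned in ascending id
    order and a later facility replaces an earlier one only on a strictly
    smaller time.
    """
    if not facilities:
        raise ValueError("facility set is empty")
    best: dict[int, ClosestFacility] = {}
    for fac in sorted(facilities, key=lambda f: f.facility_id):
        if fac.snapped_node is None:
            raise ValueError(f"facility {fac.facility_id} is not snapped to the network")
        dist = nx.single_source_dijkstra_path_length(
            network.graph, fac.snapped_node, weight="travel_min"
        )
        for node, t in dist.items():
            cur = best.get(node)
            if cur is None or t < cur.travel_min:
                best[node] = ClosestFacility(fac.facility_id, t)
    return best


def closest_facility(
    network: RoadNetwork, facilities: Sequence[Facility], target_node: int
) -> ClosestFacility:
    """Closest facility (by routed minutes) to one target node."""
    if target_node not in network.graph:
        raise ValueError(f"target node {target_node} not in network")
    table = facility_travel_times(network, facilities)
    return table.get(target_node, ClosestFacility(None, math.inf))


def compute_rt(travel_min: float, area_type: str, constants: TimeConstants) -> float:
    """Response time: station travel time plus the activation constant."""
    if travel_min < 0:
        raise ValueError("travel time must be nonnegative")
    return travel_min + constants.activation(area_type)


def compute_tt(travel_min: float) -> float:
    """Transportation time: emergency-department travel time, unmodified."""
    if travel_min < 0:
        raise ValueError("travel time must be nonnegative")
    return travel_min


def compute_tpt(rt: float, tt: float, area_type: str, constants: TimeConstants) -> float:
    """Total prehospital time: RT + TT + the on-scene constant."""
    if rt < 0 or tt < 0:
        raise ValueError("RT and TT must be nonnegative")
    return rt + tt + constants.onscene(area_type)


def golden_hour_flag(tpt: float, constants: TimeConstants = TimeConstants()) -> bool:
    """True when TPT is strictly below the golden-hour threshold."""
    if tpt < 0:
        raise ValueError("TPT must be nonnegative")
    return tpt < constants.golden_hour


def assign_quintiles(values: Sequence[float], n_groups: int = 5) -> np.ndarray:
    """Rank-based quantile labels 1..n_groups (5 = longest times).

    Values are stably sorted, so ties resolve by input order (callers pass
    records in area-id order); ranks are then split into ``n_groups``
    contiguous blocks whose sizes differ by at most one, the earlier blocks
    taking any remainder.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} values, got {n}")
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=int)
    base, extra = divmod(n, n_groups)
    start = 0
    for g in range(n_groups):
        size = base + (1 if g < extra else 0)
        labels[order[start:start + size]] = g + 1
        start += size
    return labels


@dataclass
class AccessRecord:
    """Accessibility of one analysis area."""

    area_id: str
    rt_min: float
    tt_min: float
    tpt_min: float
    nearest_station: str
    nearest_hospital: str
    within_golden_hour: bool
    quintile_rt: int = 0
    quintile_tt: int = 0
    quintile_tpt: int = 0


def compute_access_table(
    network: RoadNetwork,
    centroid_nodes: Mapping[str, int],
    area_types: Mapping[str, str],
    stations: Sequence[Facility],
    hospitals: Sequence[Facility],
    constants: TimeConstants = TimeConstants(),
) -> pd.DataFrame:
    """Route every area against stations and hospitals and compose measures.

    ``centroid_nodes`` maps area_id -> snapped centroid node. Unreachable
    areas (no route from any facility) are dropped from the returned table
    with a logged warning; the downstream statistics never see them.
    Returns a DataFrame indexed 0..n-1 in ascending area_id order with the
    AccessRecord columns.
    """
    station_table = facility_travel_times(network, stations)
    hospital_table = facility_travel_times(network, hospitals)

    records: list[AccessRecord] = []
    dropped: list[str] = []
    for area_id in sorted(centroid_nodes):
        node = centroid_nodes[area_id]
        s = station_table.get(node)
        h = hospital_table.get(node)
        if s is None or h is None:
            dropped.append(area_id)
            continue
        atype = area_types[area_id]
        rt = compute_rt(s.travel_min, atype, constants)
        tt = compute_tt(h.travel_min)
        tpt = compute_tpt(rt, tt, atype, constants)
        records.append(
            AccessRecord(
                area_id=area_id,
                rt_min=rt,
                tt_min=tt,
                tpt_min=tpt,
                nearest_station=s.facility_id,
                nearest_hospital=h.facility_id,
                within_golden_hour=golden_hour_flag(tpt, constants),
            )
        )
    if dropped:
        logger.warning(
            "%d area(s) unreachable from facilities and excluded: %s",
            len(dropped), ", ".join(dropped[:10]),
        )
    if not records:
        raise ValueError("no area is reachable from the facility sets")

    df = pd.DataFrame([r.__dict__ for r in records])
    if len(df) >= 5:
        for m in MEASURES:
            df[f"quintile_{m}"] = assign_quintiles(df[f"{m}_min"].to_numpy())
    return df
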