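"""Simplified river-network PEC simulator.

A deliberately small emulation of georeferenced catchment exposure models:
a tree-shaped river network with sewage-treatment-plant (STP) discharge
nodes is traversed in topological order, accumulating API load downstream
with optional first-order in-stream decay, and dividing by segment flow to
obtain per-segment concentrations under mean-, low- or high-flow
conditions. Effluent volume is neglected against river flow (the same
dilution-factor convention as the use-based exposure tier). The point is
distributional risk summaries over many segments, not reproduction of any
real catchment.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import InvalidNetworkError, InvalidParameterError, NoDataError

__all__ = [
    "FlowScenario",
    "Segment",
    "StpNode",
    "RiverNetwork",
    "SegmentPecField",
    "propagate",
    "pec_percentiles",
    "BELOW_FLOOR",
]

#: Marker for a percentile below the reporting floor.
BELOW_FLOOR = "<floor"

L_PER_M3 = 1000.0
SECONDS_PER_DAY = 86400.0


class FlowScenario(str, enum.Enum):
    mean = "mean"
    low = "low"
    high = "high"


@dataclass(frozen=True)
class Segment:
    """One river stretch; ``downstream_id=None`` marks an outlet."""

    id: str
    downstream_id: str | None
    flow_mean: float  # m3/s
    flow_min: float
    flow_max: float
    travel_time: float = 0.0  # hours to traverse the segment

    def __post_init__(self):
        if not (self.flow_min > 0 and self.flow_mean > 0 and self.flow_max > 0):
            raise InvalidParameterError(f"segment {self.id}: flows must be > 0")
        if not self.flow_min <= self.flow_mean <= self.flow_max:
            raise InvalidParameterError(
                f"segment {self.id}: need flow_min <= flow_mean <= flow_max")
        if self.travel_time < 0:
            raise InvalidParameterError(f"segment {self.id}: travel_time must be >= 0")

    def flow(self, scenario: FlowScenario) -> float:
        return {FlowScenario.mean: self.flow_mean,
                FlowScenario.low: self.flow_min,
                FlowScenario.high: self.flow_max}[scenario]


@dataclass(frozen=True)
class StpNode:
    """An STP discharging into a segment."""

    segment_id: str
    population: int
    per_capita_use: float           # ug/person/d reaching the sewer
    wastewater_per_capita: float = 200.0  # L/person/d (kept for IO symmetry)
    removal: float = 0.0            # fraction of load eliminated in the STP

    def __post_init__(self):
        if not self.population > 0:
            raise InvalidParameterError("STP population must be > 0")
        if self.per_capita_use < 0:
            raise InvalidParameterError("per_capita_use must be >= 0")
        if not 0.0 <= self.removal <= 1.0:
            raise InvalidParameterError("removal must be in [0, 1]")

    @property
    def load(self) -> float:
        """Discharged load in ug/d after STP removal."""
        return self.population * self.per_capita_use * (1.0 - self.removal)


@dataclass(frozen=True)
class RiverNetwork:
    segments: tuple[Segment, ...]
    stp_nodes: tuple[StpNode, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))
        object.__setattr__(self, "stp_nodes", tuple(self.stp_nodes))
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise InvalidNetworkError("duplicate segment ids")
        known = set(ids)
        for s in self.segments:
            if s.downstream_id is not None and s.downstream_id not in known:
                raise InvalidNetworkError(
                    f"segment {s.id} drains to unknown segment {s.downstream_id}")
        for stp in self.stp_nodes:
            if stp.segment_id not in known:
                raise InvalidNetworkError(f"STP on unknown segment {stp.segment_id}")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise InvalidNetworkError("river topology contains a cycle")
        # a forest: every segment has at most one downstream neighbour by
        # construction, so acyclicity is the only extra condition
        object.__setattr__(self, "_by_id", {s.id: s for s in self.segments})

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(s.id for s in self.segments)
        g.add_edges_from((s.id, s.downstream_id) for s in self.segments
                         if s.downstream_id is not None)
        return g

    def segment(self, seg_id: str) -> Segment:
        return self._by_id[seg_id]

    @property
    def outlets(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.segments if s.downstream_id is None)


@dataclass(frozen=True)
class SegmentPecField:
    """Per-segment concentrations from one propagation run."""

    pec: dict[str, float]        # segment id -> ug/L
    load: dict[str, float]       # segment id -> ug/d at the segment outlet
    flow_scenario: FlowScenario
    decay_rate: float            # 1/h

    def values(self) -> list[float]:
        return list(self.pec.values())


def propagate(network: RiverNetwork,
              flow_scenario: FlowScenario | str = FlowScenario.mean,
              decay_rate: float = 0.0) -> SegmentPecField:
    """Mass-balance pass over the network in topological order.

    For each segment, upstream outlet loads decay first-order over this
    segment's travel time, the local STP load (added near the segment
    outlet) joins undecayed, and the concentration is the outlet load
    divided by the segment's volumetric flow:

        load(s) = sum_upstream load(u) * exp(-decay_rate * travel_time(s))
                  + population * per_capita_use * (1 - removal)
        PEC(s)  = load(s) / flow(s)

    With ``decay_rate=0`` the total outlet load equals the total
    discharged load exactly (mass conservation). Segments with no STP
    upstream have PEC 0.
    """
    scenario = FlowScenario(flow_scenario)
    if decay_rate < 0:
        raise InvalidParameterError("decay_rate must be >= 0")
    local: dict[str, float] = {s.id: 0.0 for s in network.segments}
    for stp in network.stp_nodes:
        local[stp.segment_id] += stp.load
    load: dict[str, float] = {}
    g = network.graph()
    for seg_id in nx.topological_sort(g):
        seg = network.segment(seg_id)
        upstream = sum(load[u] for u in g.predecessors(seg_id))
        load[seg_id] = upstream * math.exp(-decay_rate * seg.travel_time) + local[seg_id]
    # flow m3/s -> L/d: * 1000 L/m3 * 86400 s/d
    pec = {sid: load[sid] / (network.segment(sid).flow(scenario) * L_PER_M3 * SECONDS_PER_DAY)
           for sid in load}
    return SegmentPecField(pec=pec, load=load, flow_scenario=scenario,
                           decay_rate=decay_rate)


def pec_percentiles(field: SegmentPecField,
                    percentiles: Iterable[float] = (1, 5, 25, 50, 75, 95, 99),
                    floor: float = 0.0005) -> dict[float, float | str]:
    """Nearest-rank percentiles over all segments, zeros included.

    Values below ``floor`` (ug/L) are reported as :data:`BELOW_FLOOR`,
    mirroring the reporting cut-off used for graphed PEC distributions.
    """
    values = sorted(field.pec.values())
    if not values:
        raise NoDataError("empty PEC field")
    n = len(values)
    out: dict[float, float | str] = {}
    for p in percentiles:
        p = float(p)
        if not 0.0 < p <= 100.0:
            raise InvalidParameterError("percentiles must be in (0, 100]")
        rank = max(1, math.ceil(p * n / 100.0))
        v = values[min(rank, n) - 1]
        out[p] = v if v >= floor else BELOW_FLOOR
    return out
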