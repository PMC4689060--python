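"""Street networks and ego-centered network-distance service areas.

A residence is snapped to the nearest street edge; single-source shortest
paths then delimit the sub-network reachable within a given network
distance (500 m – 2 km in the study design). Partial edges are cut at the
exact residual distance and the union of reached fragments, buffered by a
small corridor width, forms the neighborhood polygon A with area ν(A).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import shapely
from shapely.geometry import LineString, Point
from shapely.ops import substring, unary_union

__all__ = ["StreetNetwork", "SnapResult", "ServiceArea",
           "snap_to_network", "service_area"]

M2_PER_KM2 = 1e6


@dataclass
class StreetNetwork:
    """Planar street graph with metric node coordinates.

    ``graph`` is an undirected networkx graph whose nodes carry ``x``/``y``
    attributes and whose edges carry ``length`` (m) and ``geometry``
    (shapely LineString). Edge ids are the sorted node pairs, ordered
    lexicographically — used for deterministic tie-breaks.
    """

    graph: nx.Graph
    _edge_index: list = field(default_factory=list, repr=False)
    _tree: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            lo = min(u, v)
            if "geometry" not in data:
                hi = max(u, v)
                data["geometry"] = LineString([self.node_xy(lo),
                                               self.node_xy(hi)])
            else:
                # normalize direction: geometry runs from the lower node id,
                # so fragment offsets have one consistent meaning
                first = data["geometry"].coords[0]
                lx, ly = self.node_xy(lo)
                if (first[0] - lx) ** 2 + (first[1] - ly) ** 2 > 1e-6:
                    data["geometry"] = data["geometry"].reverse()
            if "length" not in data:
                data["length"] = data["geometry"].length
            glen = data["geometry"].length
            if abs(glen - data["length"]) > 0.1:
                raise ValueError(
                    f"edge {(u, v)}: length {data['length']:.2f} differs from "
                    f"geometry length {glen:.2f} by more than 0.1 m")
            if data["length"] <= 0:
                raise ValueError(f"edge {(u, v)} has non-positive length")
        comps = list(nx.connected_components(self.graph))
        comps.sort(key=len, reverse=True)
        for ci, comp in enumerate(comps):
            for node in comp:
                self.graph.nodes[node]["component"] = ci
        self._edge_index = sorted(
            (tuple(sorted((u, v))) for u, v in self.graph.edges), )
        geoms = [self.graph.edges[eid]["geometry"] for eid in self._edge_index]
        self._tree = shapely.STRtree(geoms) if geoms else None

    def node_xy(self, node) -> tuple[float, float]:
        d = self.graph.nodes[node]
        return (d["x"], d["y"])

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def edge_ids(self) -> list:
        return self._edge_index

    def largest_component_frac(self) -> float:
        if self.n_nodes == 0:
            return 0.0
        comp0 = sum(1 for _, d in self.graph.nodes(data=True)
                    if d.get("component") == 0)
        return comp0 / self.n_nodes

    def nodes_of_degree(self, min_degree: int = 3) -> list:
        return [n for n, deg in self.graph.degree if deg >= min_degree]

    def node_coords(self, nodes=None) -> np.ndarray:
        nodes = list(self.graph.nodes) if nodes is None else nodes
        return np.array([self.node_xy(n) for n in nodes], dtype=float).reshape(-1, 2)

    def total_length_m(self) -> float:
        return sum(d["length"] for _, _, d in self.graph.edges(data=True))


@dataclass(frozen=True)
class SnapResult:
    edge_id: tuple
    point: tuple[float, float]
    offset_m: float       # distance along the edge geometry from edge_id[0]
    snap_distance_m: float


def snap_to_network(location, network: StreetNetwork,
                    warn_distance_m: float = 250.0) -> SnapResult:
    """Nearest point on any street edge, with a deterministic tie-break.

    Equidistant edges resolve to the lowest edge id. Snap distances above
    ``warn_distance_m`` raise a warning — such residences sit outside the
    urban fabric the network represents.
    """
    if network._tree is None:
        raise ValueError("network has no edges")
    p = Point(float(location[0]), float(location[1]))
    geoms = [network.graph.edges[eid]["geometry"] for eid in network._edge_index]
    dists = shapely.distance(np.array(geoms, dtype=object), p)
    best_d = dists.min()
    # all edges within numerical tolerance of the optimum, lowest id wins
    cand = [i for i in np.flatnonzero(dists <= best_d + 1e-9)]
    idx = min(cand)
    eid = network._edge_index[idx]
    geom = network.graph.edges[eid]["geometry"]
    offset = geom.project(p)
    snapped = geom.interpolate(offset)
    d = p.distance(snapped)
    if d > warn_distance_m:
        warnings.warn(f"snap distance {d:.0f} m exceeds {warn_distance_m} m: "
                      "location is far from the street network", stacklevel=2)
    return SnapResult(edge_id=eid, point=(snapped.x, snapped.y),
                      offset_m=float(offset), snap_distance_m=float(d))


@dataclass
class ServiceArea:
    """Ego-centered network-distance neighborhood."""

    child_id: str | int | None
    origin: SnapResult
    distance_m: float
    fragments: list          # (edge_id, start_m, end_m) intervals
    reached_length_m: float
    polygon: shapely.Geometry
    area_km2: float


def _node_distances(network: StreetNetwork, origin: SnapResult,
                    cutoff: float) -> dict:
    """Shortest network distance from the snapped origin to every node."""
    u, v = origin.edge_id
    elen = network.graph.edges[origin.edge_id]["length"]
    # scale geometric offset to edge length (they agree within 0.1 m anyway)
    off = origin.offset_m * elen / network.graph.edges[origin.edge_id]["geometry"].length
    sources = {u: min(off, elen), v: min(elen - off, elen)}
    dist = {}
    G = network.graph
    import heapq
    heap = [(d0, n) for n, d0 in sources.items() if d0 <= cutoff]
    heapq.heapify(heap)
    while heap:
        d, n = heapq.heappop(heap)
        if n in dist:
            continue
        dist[n] = d
        for m, data in G[n].items():
            nd = d + data["length"]
            if nd <= cutoff and m not in dist:
                heapq.heappush(heap, (nd, m))
    return dist


def _merge_intervals(ivs):
    ivs = sorted(ivs)
    out = []
    for s, e in ivs:
        if out and s <= out[-1][1] + 1e-9:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def service_area(network: StreetNetwork, origin: SnapResult, distance_m: float,
                 buffer_m: float = 25.0, child_id=None) -> ServiceArea:
    """Network service area: edge fragments within ``distance_m`` of origin.

    Every retained fragment's network distance from the origin is ≤
    ``distance_m``; partial edges are cut at the exact reach point. The
    neighborhood polygon is the union of fragment geometries buffered by
    ``buffer_m``.
    """
    if distance_m <= 0:
        raise ValueError("distance_m must be positive")
    dist = _node_distances(network, origin, distance_m)
    frags = []
    G = network.graph
    for eid in network._edge_index:
        u, v = eid
        L = G.edges[eid]["length"]
        ivs = []
        du, dv = dist.get(u), dist.get(v)
        if du is not None and du < distance_m:
            ivs.append((0.0, min(L, distance_m - du)))
        if dv is not None and dv < distance_m:
            ivs.append((max(0.0, L - (distance_m - dv)), L))
        if eid == origin.edge_id:
            off = origin.offset_m * L / G.edges[eid]["geometry"].length
            ivs.append((max(0.0, off - distance_m), min(L, off + distance_m)))
        for s, e in _merge_intervals(ivs):
            if e - s > 1e-9:
                frags.append((eid, s, e))
    reached = sum(e - s for _, s, e in frags)
    if reached < distance_m / 10.0:
        warnings.warn(f"isolated origin: reachable network length "
                      f"{reached:.0f} m < {distance_m / 10:.0f} m", stacklevel=2)
    geoms = []
    for eid, s, e in frags:
        geom = G.edges[eid]["geometry"]
        L = G.edges[eid]["length"]
        if s <= 1e-9 and e >= L - 1e-9:
            geoms.append(geom)
        else:
            scale = geom.length / L
            geoms.append(substring(geom, s * scale, e * scale))
    if geoms:
        poly = unary_union(geoms).buffer(buffer_m)
    else:
        poly = Point(origin.point).buffer(buffer_m)
    return ServiceArea(child_id=child_id, origin=origin,
                       distance_m=float(distance_m), fragments=frags,
                       reached_length_m=float(reached), polygon=poly,
                       area_km2=poly.area / M2_PER_KM2)
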