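"""File formats: GeoJSON point/line layers (planar metric coordinates,
deliberately CRS-free), ESRI ASCII raster grids with a JSON sidecar for
bandwidth provenance, and the tabular CSVs.

Geographic (lon/lat) input is rejected: every consumer of these files
assumes planar metres, and silent reprojection is out of scope.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .city import DensityRaster
from .intensity import Bandwidth, IntensitySurface, PointPattern, Window
from .network import StreetNetwork

__all__ = ["write_points_geojson", "read_points_geojson",
           "write_network_geojson", "read_network_geojson",
           "write_ascii_grid", "read_ascii_grid",
           "write_surface", "read_surface",
           "write_epochs_csv", "read_epochs_csv"]

NODATA = -9999.0


def _check_planar(coords) -> None:
    arr = np.asarray(coords, dtype=float).reshape(-1, 2)
    if len(arr) and (np.abs(arr[:, 0]) <= 180).all() and \
            (np.abs(arr[:, 1]) <= 90).all():
        raise ValueError(
            "coordinates look geographic (lon/lat); this pipeline is planar "
            "metric only — reproject the data before importing")


def write_points_geojson(pattern: PointPattern, path) -> None:
    feats = [{"type": "Feature", "properties": {"kind": pattern.kind},
              "geometry": {"type": "Point", "coordinates": [float(x), float(y)]}}
             for x, y in pattern.points]
    xmin, ymin, xmax, ymax = pattern.window.bounds
    obj = {"type": "FeatureCollection",
           "properties": {"window_bounds": [xmin, ymin, xmax, ymax],
                          "kind": pattern.kind},
           "features": feats}
    Path(path).write_text(json.dumps(obj))


def read_points_geojson(path, window: Window | None = None) -> PointPattern:
    obj = json.loads(Path(path).read_text())
    pts = []
    kind = obj.get("properties", {}).get("kind", "points")
    for f in obj["features"]:
        geom = f["geometry"]
        if geom["type"] != "Point":
            raise ValueError(f"points layer contains a {geom['type']} geometry")
        pts.append(geom["coordinates"])
    pts = np.asarray(pts, dtype=float).reshape(-1, 2)
    if len(pts):
        _check_planar(pts)
    if window is None:
        b = obj.get("properties", {}).get("window_bounds")
        if b is None:
            raise ValueError("no window bounds stored and none supplied")
        window = Window.rectangle(b[2] - b[0], b[3] - b[1], origin=(b[0], b[1]))
    return PointPattern(kind=kind, points=pts, window=window)


def write_network_geojson(network: StreetNetwork, path) -> None:
    feats = []
    for eid in network.edge_ids:
        data = network.graph.edges[eid]
        coords = [[float(x), float(y)] for x, y in data["geometry"].coords]
        feats.append({"type": "Feature",
                      "properties": {"u": eid[0], "v": eid[1],
                                     "length_m": float(data["length"])},
                      "geometry": {"type": "LineString", "coordinates": coords}})
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}))


def read_network_geojson(path) -> StreetNetwork:
    import networkx as nx
    obj = json.loads(Path(path).read_text())
    G = nx.Graph()
    all_coords = [c for f in obj["features"]
                  for c in f["geometry"]["coordinates"]]
    if all_coords:
        _check_planar(all_coords)
    for f in obj["features"]:
        geom = f["geometry"]
        if geom["type"] != "LineString":
            raise ValueError(f"network layer contains a {geom['type']} geometry")
        coords = np.asarray(geom["coordinates"], dtype=float)
        u, v = f["properties"]["u"], f["properties"]["v"]
        G.add_node(u, x=float(coords[0, 0]), y=float(coords[0, 1]))
        G.add_node(v, x=float(coords[-1, 0]), y=float(coords[-1, 1]))
        G.add_edge(u, v, length=float(f["properties"]["length_m"]),
                   geometry=LineString(coords))
    return StreetNetwork(G)


def write_ascii_grid(values: np.ndarray, origin, cell_size: float, path) -> None:
    """ESRI ASCII raster; row order in the file is north → south."""
    ny, nx = values.shape
    header = (f"ncols {nx}\nnrows {ny}\n"
              f"xllcorner {origin[0]:.6f}\nyllcorner {origin[1]:.6f}\n"
              f"cellsize {cell_size:.6f}\nNODATA_value {NODATA}\n")
    body = np.where(np.isnan(values), NODATA, values)[::-1]
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.8g")


def read_ascii_grid(path) -> tuple[np.ndarray, tuple[float, float], float]:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            k, v = fh.readline().split()
            hdr[k.lower()] = float(v)
        body = np.loadtxt(fh)
    body = np.atleast_2d(body)[::-1]
    nodata = hdr.get("nodata_value", NODATA)
    body = np.where(body == nodata, np.nan, body)
    return body, (hdr["xllcorner"], hdr["yllcorner"]), hdr["cellsize"]


def _bw_to_json(bw: Bandwidth | None):
    if bw is None:
        return None
    return {"form": bw.form, "sigma_m": bw.sigma_m,
            "Sigma": None if bw.Sigma is None else np.asarray(bw.Sigma).tolist(),
            "provenance": bw.provenance}


def _bw_from_json(d):
    if d is None:
        return None
    return Bandwidth(form=d["form"], sigma_m=d["sigma_m"],
                     Sigma=None if d["Sigma"] is None else np.asarray(d["Sigma"]),
                     provenance=d["provenance"])


def write_surface(surface: IntensitySurface, path) -> None:
    """ASCII grid plus a JSON sidecar carrying bandwidth provenance."""
    path = Path(path)
    write_ascii_grid(surface.values, surface.origin, surface.cell_size_m, path)
    sidecar = {"kind": surface.kind, "edge_corrected": surface.edge_corrected,
               "bandwidth": _bw_to_json(surface.bandwidth)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_surface(path) -> IntensitySurface:
    path = Path(path)
    values, origin, cell = read_ascii_grid(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return IntensitySurface(origin=origin, cell_size_m=cell, values=values,
                            bandwidth=_bw_from_json(meta["bandwidth"]),
                            kind=meta["kind"],
                            edge_corrected=meta["edge_corrected"])


def write_density(density: DensityRaster, path) -> None:
    write_ascii_grid(density.values, density.origin, density.cell_size_m, path)


def read_density(path) -> DensityRaster:
    values, origin, cell = read_ascii_grid(path)
    return DensityRaster(origin=origin, cell_size_m=cell,
                         values=np.nan_to_num(values))


def write_epochs_csv(series_list, path) -> None:
    pd.concat([s.to_frame() for s in series_list]).to_csv(path, index=False)


def read_epochs_csv(path) -> list:
    from .cohort import EpochSeries
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for cid, g in df.groupby("child_id", sort=True):
        out.append(EpochSeries(child_id=str(cid),
                               timestamps=pd.DatetimeIndex(g["timestamp"]),
                               counts=g["counts"].to_numpy()))
    return out
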