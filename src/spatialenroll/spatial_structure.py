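"""Contiguity graphs, ICAR structure matrices and centroid distances.

Small-area disease-mapping models share one piece of plumbing: an undirected
contiguity graph over the analysis areas ("neighbouring areas share a common
edge or border") and the graph-Laplacian precision matrix it induces for
intrinsic conditional autoregressive (ICAR / Besag) priors.  This module
builds both from area polygons, plus the centroid distance matrix used by the
spatial scan window and the surface interpolator.

All geometry is planar, in projected kilometre coordinates.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry


@dataclass
class AreaUnit:
    """One small analysis area (a synthetic stand-in for a micro-market of
    roughly 300 households).

    Attributes
    ----------
    area_id : str
        Unique identifier.
    polygon : shapely geometry
        Simple polygon in projected km coordinates.
    centroid : (float, float)
        Centroid (x, y) in km.
    n_insurants, n_diabetics, n_unenrolled : int
        Nested counts: unenrolled diabetics <= diabetics <= insurants.
    """

    area_id: str
    polygon: BaseGeometry
    centroid: tuple[float, float]
    n_insurants: int = 0
    n_diabetics: int = 0
    n_unenrolled: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_unenrolled <= self.n_diabetics <= self.n_insurants):
            raise ValueError(
                f"area {self.area_id}: counts must satisfy "
                "n_unenrolled <= n_diabetics <= n_insurants "
                f"(got {self.n_unenrolled}, {self.n_diabetics}, {self.n_insurants})"
            )


@dataclass
class AdjacencyGraph:
    """Undirected 0/1 contiguity graph over areas.

    ``edges`` contains each unordered pair once, as ``(id_a, id_b)`` with
    ``id_a < id_b`` in input order.  ``components`` partitions the area ids
    into connected components (isolated areas form singleton components).
    """

    area_ids: list[str]
    edges: set[tuple[str, str]]
    components: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        index = {a: i for i, a in enumerate(self.area_ids)}
        canonical = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on area {a}")
            if a not in index or b not in index:
                raise ValueError(f"edge ({a}, {b}) references unknown area")
            canonical.add((a, b) if index[a] < index[b] else (b, a))
        self.edges = canonical
        if not self.components:
            self.components = self._compute_components()

    def _compute_components(self) -> list[list[str]]:
        g = self.to_networkx()
        index = {a: i for i, a in enumerate(self.area_ids)}
        comps = [sorted(c, key=index.__getitem__) for c in nx.connected_components(g)]
        comps.sort(key=lambda c: index[c[0]])
        return comps

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.area_ids)
        g.add_edges_from(self.edges)
        return g

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def neighbors(self, area_id: str) -> list[str]:
        out = []
        for a, b in self.edges:
            if a == area_id:
                out.append(b)
            elif b == area_id:
                out.append(a)
        return sorted(out, key=self.area_ids.index)

    def degree_vector(self) -> np.ndarray:
        index = {a: i for i, a in enumerate(self.area_ids)}
        deg = np.zeros(len(self.area_ids), dtype=int)
        for a, b in self.edges:
            deg[index[a]] += 1
            deg[index[b]] += 1
        return deg

    def adjacency_matrix(self) -> sp.csr_matrix:
        """Sparse symmetric 0/1 adjacency matrix in area_ids order."""
        index = {a: i for i, a in enumerate(self.area_ids)}
        n = len(self.area_ids)
        rows, cols = [], []
        for a, b in self.edges:
            i, j = index[a], index[b]
            rows += [i, j]
            cols += [j, i]
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


@dataclass
class ICARStructure:
    """Graph-Laplacian structure matrix Q = D - W of an ICAR (Besag) prior.

    Q is positive semidefinite with one null eigenvector (the constant) per
    connected component; the prior is made identifiable downstream by a
    sum-to-zero constraint per component.
    """

    area_ids: list[str]
    Q: sp.csr_matrix
    component_indicator: np.ndarray  # (n,) int: component label per area
    isolated: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return int(self.component_indicator.max()) + 1 if len(self.area_ids) else 0

    def dense(self) -> np.ndarray:
        return self.Q.toarray()


def build_adjacency(areas: list[AreaUnit]) -> AdjacencyGraph:
    """Build the contiguity graph: areas are neighbours iff their boundaries
    share a segment of positive length (corner touching does not count).

    Raises ``ValueError`` naming the offending area for invalid polygons.
    """
    if not areas:
        raise ValueError("need at least one area")
    for a in areas:
        if a.polygon is None or not a.polygon.is_valid:
            raise ValueError(f"invalid polygon for area {a.area_id}")

    ids = [a.area_id for a in areas]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate area_id")

    # Use shapely's STRtree for candidate pruning, then test shared-boundary
    # length > 0 for contiguity.
    from shapely.strtree import STRtree

    geoms = [a.polygon for a in areas]
    tree = STRtree(geoms)
    edges: set[tuple[str, str]] = set()
    for i, g in enumerate(geoms):
        for j in tree.query(g):
            j = int(j)
            if j <= i:
                continue
            inter = g.boundary.intersection(geoms[j].boundary)
            if inter.is_empty:
                continue
            if getattr(inter, "length", 0.0) > 0.0:
                edges.add((ids[i], ids[j]))
    return AdjacencyGraph(area_ids=ids, edges=edges)


def icar_structure(graph: AdjacencyGraph) -> ICARStructure:
    """Return the ICAR structure matrix Q = D - W with per-component
    sum-to-zero bookkeeping; rows sum to zero, isolated areas give zero rows
    and are flagged."""
    if graph.n_areas == 0:
        raise ValueError("empty graph")
    W = graph.adjacency_matrix()
    deg = np.asarray(W.sum(axis=1)).ravel()
    Q = sp.diags(deg) - W
    label = np.empty(graph.n_areas, dtype=int)
    index = {a: i for i, a in enumerate(graph.area_ids)}
    for c, comp in enumerate(graph.components):
        for a in comp:
            label[index[a]] = c
    isolated = [a for a, d in zip(graph.area_ids, deg) if d == 0]
    return ICARStructure(
        area_ids=list(graph.area_ids),
        Q=sp.csr_matrix(Q),
        component_indicator=label,
        isolated=isolated,
    )


def centroid_distance_matrix(areas: list[AreaUnit]) -> np.ndarray:
    """Euclidean distance matrix (km) between area centroids.

    Warns if all coordinates look geographic (|x| <= 180, |y| <= 90): the
    models assume a planar projection in km.
    """
    xy = np.array([a.centroid for a in areas], dtype=float)
    if len(xy) and np.all(np.abs(xy[:, 0]) <= 180) and np.all(np.abs(xy[:, 1]) <= 90):
        warnings.warn(
            "centroids look like lon/lat degrees; distances assume a planar "
            "projection in km",
            UserWarning,
            stacklevel=2,
        )
    diff = xy[:, None, :] - xy[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


# ---------------------------------------------------------------------------
# GeoJSON / CSV interchange


def areas_to_geojson(areas: list[AreaUnit], extra: dict[str, dict] | None = None) -> dict:
    """Serialise areas to a GeoJSON FeatureCollection (properties carry
    area_id and counts; ``extra`` maps area_id -> additional properties)."""
    features = []
    for a in areas:
        props = {
            "area_id": a.area_id,
            "n_insurants": a.n_insurants,
            "n_diabetics": a.n_diabetics,
            "n_unenrolled": a.n_unenrolled,
        }
        if extra and a.area_id in extra:
            props.update(extra[a.area_id])
        features.append(
            {
                "type": "Feature",
                "geometry": shapely_mapping(a.polygon),
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}


def areas_from_geojson(doc: dict) -> list[AreaUnit]:
    """Parse a FeatureCollection written by :func:`areas_to_geojson`."""
    if doc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    areas = []
    for feat in doc["features"]:
        geom = shapely_shape(feat["geometry"])
        props = feat.get("properties", {})
        areas.append(
            AreaUnit(
                area_id=str(props["area_id"]),
                polygon=geom,
                centroid=(geom.centroid.x, geom.centroid.y),
                n_insurants=int(props.get("n_insurants", 0)),
                n_diabetics=int(props.get("n_diabetics", 0)),
                n_unenrolled=int(props.get("n_unenrolled", 0)),
            )
        )
    return areas


def write_geojson(path, areas: list[AreaUnit], extra: dict[str, dict] | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(areas_to_geojson(areas, extra), fh)


def read_geojson(path) -> list[AreaUnit]:
    with open(path) as fh:
        return areas_from_geojson(json.load(fh))


def write_edge_list(path, graph: AdjacencyGraph) -> None:
    """Write adjacency as an edge-list CSV (area_id_1, area_id_2)."""
    index = {a: i for i, a in enumerate(graph.area_ids)}
    rows = sorted(graph.edges, key=lambda e: (index[e[0]], index[e[1]]))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["area_id_1", "area_id_2"])
        w.writerows(rows)


def read_edge_list(path, area_ids: list[str]) -> AdjacencyGraph:
    edges = set()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            a, b = row["area_id_1"], row["area_id_2"]
            edges.add((a, b) if a < b else (b, a))
    return AdjacencyGraph(area_ids=list(area_ids), edges=edges)
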