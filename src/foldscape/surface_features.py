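"""Shape-based feature extraction on cortical surfaces.

Folds are connected groups of vertices deeper than an automatically chosen
travel-depth threshold.  Within each fold a fundus -- a branching,
one-vertex-thick curve along the deepest, most curved part -- is extracted by
anchoring the deepest vertices, finding endpoints on the fold rim, and
eroding the fold down to a topology-preserving skeleton that connects them.
Anatomical gyral labels then segment folds into sulci (regions whose opposing
banks carry a protocol label pair) and fundi into sulcal fundi.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import BACKGROUND, LabelField, ScalarField
from .mesh_graph import (
    MeshGraph,
    connected_components,
    hop_distance_from_set,
    is_simple_point,
)

logger = logging.getLogger(__name__)


@dataclass
class FundusConfig:
    """Feature-extraction knobs: anchor threshold in MADs above the median,
    minimum edge separation between anchors/endpoints, and the minimum fold
    size (folds this small or smaller are discarded)."""

    mad_multiplier: float = 2.0
    min_edge_separation: int = 10
    min_fold_size: int = 50

    def __post_init__(self) -> None:
        if min(self.mad_multiplier, self.min_edge_separation, self.min_fold_size) <= 0:
            raise ValueError("all fundus parameters must be positive")


@dataclass
class FoldSet:
    """Per-vertex fold ids (-1 background), fold count, and the threshold used."""

    fold_ids: np.ndarray
    n_folds: int
    threshold: float

    def vertices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_ids == fold)


@dataclass
class SulcusProtocol:
    """Mapping from unordered gyral label pairs to sulcus identifiers.

    Each pair is unique to one sulcus; one sulcus may own several pairs.
    """

    pairs: dict  # frozenset({a, b}) -> sulcus_id
    names: dict = field(default_factory=dict)  # sulcus_id -> name

    def __post_init__(self) -> None:
        for pair, sid in self.pairs.items():
            if len(pair) != 2:
                raise ValueError("label pairs must contain two distinct labels")
            if sid < 0:
                raise ValueError("sulcus ids must be non-negative")

    @property
    def sulcus_ids(self) -> list:
        return sorted(set(self.pairs.values()))

    @property
    def cortical_labels(self) -> list:
        out: set = set()
        for pair in self.pairs:
            out |= set(pair)
        return sorted(out)

    @classmethod
    def from_csv(cls, path) -> "SulcusProtocol":
        df = pd.read_csv(path)
        pairs = {}
        names = {}
        for _, row in df.iterrows():
            pairs[frozenset({int(row["label_a"]), int(row["label_b"])})] = int(row["sulcus_id"])
            if "name" in df.columns:
                names[int(row["sulcus_id"])] = str(row["name"])
        return cls(pairs, names)

    def to_csv(self, path) -> Path:
        rows = []
        for pair, sid in sorted(self.pairs.items(), key=lambda kv: (kv[1], sorted(kv[0]))):
            a, b = sorted(pair)
            rows.append({"label_a": a, "label_b": b, "sulcus_id": sid,
                         "name": self.names.get(sid, "")})
        pd.DataFrame(rows).to_csv(path, index=False)
        return Path(path)


def default_protocol() -> SulcusProtocol:
    """The packaged DKT-style cortical protocol: 25 sulci per hemisphere
    defined by gyral label pairs over 31 cortical regions per hemisphere."""
    with resources.as_file(
        resources.files("foldscape.data").joinpath("dkt_sulcus_protocol.csv")
    ) as p:
        return SulcusProtocol.from_csv(p)


# ---------------------------------------------------------------------------
# depth threshold and folds


def find_depth_threshold(depth: ScalarField, n_bins: int = 100) -> float:
    """Depth separating gyral crowns from folds, from the histogram shape.

    Cortical travel-depth histograms fall steeply from a low-depth mode into
    a long deep tail; the threshold is the first bin past the mode where the
    smoothed histogram stops falling (slope >= 0).
    """
    v = np.asarray(depth.values, dtype=np.float64)
    v = v[np.isfinite(v)]
    if len(v) < 1000:
        raise ValueError("need at least 1000 finite depth values")
    if np.ptp(v) <= 0:
        raise ValueError("depth is constant; no threshold exists")
    hist, edges = np.histogram(v, bins=n_bins, range=(v.min(), v.max()))
    kernel = np.ones(5) / 5.0
    smoothed = np.convolve(hist.astype(np.float64), kernel, mode="same")
    slopes = np.zeros(n_bins)
    slopes[1:-1] = smoothed[2:] - smoothed[:-2]
    mode = int(np.argmax(smoothed))
    for i in range(mode + 1, n_bins - 1):
        if slopes[i] >= 0.0:
            return float(edges[i])
    return float(edges[-2])  # monotone tail: last interior bin edge


def extract_folds(
    mesh,
    graph: MeshGraph,
    depth: ScalarField,
    threshold: float,
    cfg: FundusConfig | None = None,
) -> FoldSet:
    """Connected components of {depth >= threshold}, small ones removed.

    Folds of min_fold_size vertices *or fewer* are dropped; survivors are
    numbered 0..K-1 largest first.
    """
    cfg = cfg or FundusConfig()
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    deep = np.flatnonzero(depth.values >= threshold)
    ids = np.full(len(depth.values), BACKGROUND, dtype=np.int64)
    comps = [c for c in connected_components(graph, deep) if len(c) > cfg.min_fold_size]
    for k, comp in enumerate(comps):
        ids[comp] = k
    return FoldSet(fold_ids=ids, n_folds=len(comps), threshold=float(threshold))


# ---------------------------------------------------------------------------
# anchors, endpoints, skeletons


def find_anchor_vertices(
    values: ScalarField,
    fold,
    graph: MeshGraph,
    cfg: FundusConfig | None = None,
) -> np.ndarray:
    """Deepest fold vertices: value >= median + k * MAD over the nonzero
    values, thinned so no two anchors are within min_edge_separation edges
    (the higher value wins; index breaks ties)."""
    cfg = cfg or FundusConfig()
    fold = np.asarray(sorted(set(int(v) for v in fold)), dtype=np.int64)
    if len(fold) == 0:
        raise ValueError("fold must be non-empty")
    v = values.values[fold]
    nz = v[v != 0]
    if len(nz) == 0:
        return np.zeros(0, dtype=np.int64)
    med = np.median(nz)
    mad = np.median(np.abs(nz - med))
    cutoff = med + cfg.mad_multiplier * mad
    cand = fold[v >= cutoff]
    order = np.lexsort((cand, -values.values[cand]))
    kept: list[int] = []
    for c in cand[order]:
        c = int(c)
        if all(_hops_between(graph, c, k, cfg.min_edge_separation) for k in kept):
            kept.append(c)
    return np.asarray(sorted(kept), dtype=np.int64)


def _hops_between(graph: MeshGraph, a: int, b: int, min_sep: int) -> bool:
    """True when b is strictly more than min_sep edges from a."""
    dist = hop_distance_from_set(graph, [a], cutoff=min_sep)
    return dist[b] == -1


def find_outer_endpoints(
    fold,
    graph: MeshGraph,
    values: ScalarField,
    depth: ScalarField,
    cfg: FundusConfig | None = None,
) -> np.ndarray:
    """Endpoints on the fold rim where a fundus should terminate.

    Tracks start from seed vertices at median fold depth and walk outward
    through concentric (hop-distance) rings toward the rim, always taking the
    highest-value neighbor in the next ring; a track's candidate endpoint is
    the rim vertex it reaches.  Candidates on tracks with a high median value
    (>= the median of all track medians) survive, then close pairs are
    thinned like anchors.
    """
    cfg = cfg or FundusConfig()
    fold_arr = np.asarray(sorted(set(int(v) for v in fold)), dtype=np.int64)
    in_fold = np.zeros(graph.n_vertices, dtype=bool)
    in_fold[fold_arr] = True
    boundary = [
        int(v) for v in fold_arr
        if any(not in_fold[u] for u in graph.neighbors[v])
    ]
    if not boundary:
        raise ValueError("fold has no boundary (it covers the whole closed mesh)")

    d = depth.values[fold_arr]
    med = np.median(d)
    band = max(np.ptp(d) / 100.0, 1e-12)
    seeds = fold_arr[np.abs(d - med) <= band]
    if len(seeds) == 0:
        seeds = fold_arr[[int(np.argmin(np.abs(d - med)))]]
    # concentric rings: hop distance from the fold's edge, walked downhill
    rings = hop_distance_from_set(graph, boundary, within=fold_arr)

    candidates: dict[int, float] = {}
    boundary_set = set(boundary)
    for seed in seeds:
        track = [int(seed)]
        cur = int(seed)
        while cur not in boundary_set:
            nxt = [int(u) for u in graph.neighbors[cur]
                   if in_fold[u] and 0 <= rings[u] < rings[cur]]
            if not nxt:
                break
            cur = max(nxt, key=lambda u: (values.values[u], -u))
            track.append(cur)
        if cur in boundary_set:
            tmed = float(np.median(values.values[track]))
            candidates[cur] = max(candidates.get(cur, -np.inf), tmed)
    if not candidates:
        logger.warning("no endpoint track reached the fold boundary")
        return np.zeros(0, dtype=np.int64)
    medians = np.array(list(candidates.values()))
    keep_level = np.median(medians)
    cand = [v for v, m in candidates.items() if m >= keep_level]
    cand.sort(key=lambda v: (-candidates[v], v))
    kept: list[int] = []
    for c in cand:
        if all(_hops_between(graph, c, k, cfg.min_edge_separation) for k in kept):
            kept.append(c)
    return np.asarray(sorted(kept), dtype=np.int64)


def connect_points_erosion(
    anchors,
    endpoints,
    fold,
    graph: MeshGraph,
    values: ScalarField,
) -> np.ndarray:
    """Erode a fold down to a 1-vertex-thick skeleton through its anchors.

    Simple topological points and curve endpoints are removed iteratively in
    ascending value order (index breaks ties); anchors and endpoints are
    protected absolutely, so the surviving skeleton connects them along
    high-value (deep, curved) paths without changing the fold's topology.
    """
    anchors = set(int(v) for v in anchors)
    endpoints = set(int(v) for v in endpoints)
    protected = anchors | endpoints
    obj = set(int(v) for v in fold)
    if not protected:
        return np.zeros(0, dtype=np.int64)
    if not protected <= obj:
        raise ValueError("anchors and endpoints must lie inside the fold")
    comps = connected_components(graph, obj)
    with_protected = [c for c in comps if protected & set(int(v) for v in c)]
    if len(with_protected) > 1:
        logger.warning(
            "anchors span %d fold components; a skeleton is built per component",
            len(with_protected),
        )
    obj = set(int(v) for c in with_protected for v in c)

    def removable(v: int) -> bool:
        if v in protected or v not in obj:
            return False
        deg = sum(1 for u in graph.neighbors[v] if int(u) in obj)
        if deg == 1:  # curve endpoint
            return True
        return is_simple_point(graph, obj, v)

    heap = [(values.values[v], v) for v in obj if removable(v)]
    heapq.heapify(heap)
    while heap:
        val, v = heapq.heappop(heap)
        if v not in obj or not removable(v):
            continue
        obj.discard(v)
        for u in graph.neighbors[v]:
            u = int(u)
            if u in obj and removable(u):
                heapq.heappush(heap, (values.values[u], u))
    return np.asarray(sorted(obj), dtype=np.int64)


def fundus_likelihood(
    fold, depth: ScalarField, curvature: ScalarField
) -> ScalarField:
    """Per-vertex fundus likelihood inside a fold: the product of min-max
    normalized travel depth and normalized positive mean curvature."""
    fold = np.asarray(sorted(set(int(v) for v in fold)), dtype=np.int64)
    out = np.zeros(len(depth.values))

    def norm(v: np.ndarray) -> np.ndarray:
        rng = np.ptp(v)
        return (v - v.min()) / rng if rng > 0 else np.zeros_like(v)

    d = norm(depth.values[fold])
    c = norm(np.maximum(curvature.values[fold], 0.0))
    out[fold] = d * c
    return ScalarField(out, name="fundus_likelihood")


def extract_fundi(
    mesh,
    graph: MeshGraph,
    folds: FoldSet,
    depth: ScalarField,
    curvature: ScalarField,
    cfg: FundusConfig | None = None,
) -> LabelField:
    """One fundus per fold (fundus id = fold id; background -1)."""
    cfg = cfg or FundusConfig()
    out = np.full(graph.n_vertices, BACKGROUND, dtype=np.int64)
    for k in range(folds.n_folds):
        fold = folds.vertices(k)
        like = fundus_likelihood(fold, depth, curvature)
        anchors = find_anchor_vertices(like, fold, graph, cfg)
        if len(anchors) == 0:
            logger.info("fold %d has no anchors; no fundus extracted", k)
            continue
        try:
            endpoints = find_outer_endpoints(fold, graph, like, depth, cfg)
        except ValueError:
            endpoints = np.zeros(0, dtype=np.int64)
        skel = connect_points_erosion(anchors, endpoints, fold, graph, like)
        out[skel] = k
    return LabelField(out, name="fundus_ids")


# ---------------------------------------------------------------------------
# sulci


def extract_label_boundary(graph: MeshGraph, labels: LabelField, pair) -> np.ndarray:
    """Vertices of either pair label with a neighbor carrying the other label."""
    a, b = sorted(pair)
    lab = labels.labels
    out = []
    for v in range(graph.n_vertices):
        if lab[v] == a and any(lab[u] == b for u in graph.neighbors[v]):
            out.append(v)
        elif lab[v] == b and any(lab[u] == a for u in graph.neighbors[v]):
            out.append(v)
    return np.asarray(out, dtype=np.int64)


def extract_sulci(
    mesh,
    graph: MeshGraph,
    folds: FoldSet,
    labels: LabelField,
    protocol: SulcusProtocol,
) -> LabelField:
    """Segment folds into sulci by protocol label pairs (background -1).

    Within each fold, every protocol pair whose two labels both occur seeds a
    region at the pair's label boundary; vertices join the sulcus of the
    nearest boundary they can reach through vertices labeled with that pair's
    labels (hop distance; ties go to the smaller sulcus id).  This covers
    both protocol cases: a vertex whose label is in a single pair joins that
    pair's sulcus when connected to its boundary, and a vertex whose label is
    shared by several pairs is split by boundary propagation.
    """
    if not protocol.pairs:
        raise ValueError("empty sulcus protocol")
    lab = labels.labels
    if len(lab) != graph.n_vertices:
        raise ValueError("labels are not aligned to the mesh")
    out = np.full(graph.n_vertices, BACKGROUND, dtype=np.int64)
    for k in range(folds.n_folds):
        fold = folds.vertices(k)
        fold_labels = set(int(x) for x in np.unique(lab[fold]) if x >= 0)
        pairs_here = [
            (pair, sid) for pair, sid in sorted(
                protocol.pairs.items(), key=lambda kv: (kv[1], sorted(kv[0]))
            )
            if set(pair) <= fold_labels
        ]
        if not pairs_here:
            continue
        in_fold = np.zeros(graph.n_vertices, dtype=bool)
        in_fold[fold] = True
        best_dist = np.full(graph.n_vertices, np.iinfo(np.int64).max, dtype=np.int64)
        best_sid = np.full(graph.n_vertices, BACKGROUND, dtype=np.int64)
        for pair, sid in pairs_here:
            pa, pb = sorted(pair)
            allowed = in_fold & ((lab == pa) | (lab == pb))
            seeds = [
                int(v) for v in np.flatnonzero(allowed)
                if any(allowed[u] and lab[u] != lab[v] for u in graph.neighbors[v])
            ]
            if not seeds:
                continue
            dist = hop_distance_from_set(graph, seeds, within=np.flatnonzero(allowed))
            reached = dist >= 0
            better = reached & (
                (dist < best_dist)
                | ((dist == best_dist) & (best_sid > sid) & (best_sid != BACKGROUND))
            )
            best_dist[better] = dist[better]
            best_sid[better] = sid
        out[best_sid >= 0] = best_sid[best_sid >= 0]
    return LabelField(out, name="sulcus_ids")


def segment_by_region(fundi: LabelField, sulci: LabelField) -> LabelField:
    """Sulcal fundi: fundus vertices relabeled by their sulcus id (-1 outside)."""
    if len(fundi.labels) != len(sulci.labels):
        raise ValueError("fields are not aligned")
    out = np.where((fundi.labels >= 0) & (sulci.labels >= 0), sulci.labels, BACKGROUND)
    return LabelField(out, name="sulcal_fundus_ids")
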