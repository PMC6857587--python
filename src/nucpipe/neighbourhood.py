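"""Inter-nuclear cohesion statistics on Delaunay neighbour graphs.

For each image, nuclei are nodes at their centroids (µm) and "nearest
neighbours" are the pairs sharing a simplex in the Delaunay triangulation
of the centroids. For every adjacent pair two distances are computed:

* ``centroid_distance_um`` — Euclidean distance between centroids;
* ``edge_distance_um`` — minimum physical distance between the two nuclei's
  boundary voxels (the mask's proxy for the nuclear membranes), with grid
  anisotropy honoured by scaling each axis by its voxel pitch.

Pairs whose centroid distance exceeds a retention radius (default 40 µm)
are discarded; tight colonies therefore show short edge distances and many
retained neighbours, dispersed cultures the opposite. Each unordered pair
contributes once to the pooled statistics, so the per-image mean is a mean
over edges, not over (nucleus, neighbour) incidences.

Degenerate point configurations (co-circular / co-spherical centroids) are
broken by a deterministic per-point jitter — adjacency is then reproducible
across runs and platforms, which matters more here than resolving ties in
any particular direction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from . import density
from .io_core import LabelMask, RunConfig
from .quantify import NucleusRecord, boundary_coords_by_label

logger = logging.getLogger(__name__)

__all__ = [
    "NeighbourGraph",
    "DistanceSummary",
    "delaunay_adjacency",
    "jittered_points",
    "edge_distance",
    "build_graph",
    "summarise_distances",
]

# Entropy constant for the symbolic-perturbation stream; the jitter for a
# point depends only on its index, never on n or on other points.
_JITTER_ENTROPY = 0x5EEDED
_JITTER_REL = 1e-6


def jittered_points(points: np.ndarray) -> np.ndarray:
    """Apply the deterministic tie-breaking jitter used for triangulation.

    Each point is displaced by a uniform offset of magnitude ``1e-6`` times
    the bounding-box diagonal, drawn from a stream seeded by the point's
    index. Exposed so that correctness oracles can test the exact point set
    that was triangulated.
    """
    pts = np.asarray(points, dtype=float)
    span = pts.max(axis=0) - pts.min(axis=0)
    diag = float(np.sqrt((span**2).sum()))
    if diag == 0.0:
        raise ValueError("all points are identical; no triangulation exists")
    eps = _JITTER_REL * diag
    out = pts.copy()
    for i in range(len(pts)):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=_JITTER_ENTROPY, spawn_key=(i,))
        )
        out[i] += eps * rng.uniform(-1.0, 1.0, size=pts.shape[1])
    return out


def delaunay_adjacency(points) -> set[tuple[int, int]]:
    """Unordered index pairs sharing a Delaunay simplex of the centroids.

    Points may be (n, 2) or (n, 3); axes with zero spread (e.g. the z of a
    single-slice image) are dropped so single-slice data is triangulated in
    2D with triangles rather than degenerate tetrahedra. Fewer than two
    points give an empty set; up to dim+1 points are mutually adjacent.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] not in (2, 3):
        raise ValueError(f"expected (n, 2) or (n, 3) points, got {pts.shape}")
    n = len(pts)
    if n < 2:
        return set()
    active = np.ptp(pts, axis=0) > 0
    if not active.any():
        raise ValueError("all points are identical; no triangulation exists")
    work = jittered_points(pts[:, active])
    dim = work.shape[1]
    if dim == 1:
        order = np.argsort(work[:, 0], kind="stable")
        return {
            tuple(sorted((int(order[i]), int(order[i + 1]))))
            for i in range(n - 1)
        }
    if n <= dim + 1:
        return {tuple(sorted(p)) for p in itertools.combinations(range(n), 2)}
    tri = Delaunay(work)
    pairs: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a, b in itertools.combinations(simplex.tolist(), 2):
            pairs.add((a, b) if a < b else (b, a))
    return pairs


def _min_boundary_distance_um(
    coords_a: np.ndarray, coords_b: np.ndarray, voxel_size_um
) -> float:
    """Minimum anisotropy-scaled distance between two boundary-voxel sets.

    Integer index differences are taken first and only then scaled by the
    voxel pitch, so the result is bit-identical to a per-pair scan using
    ``sqrt(((za-zb)*sz)**2 + ...)``.
    """
    s = np.asarray(voxel_size_um, dtype=float)
    a = np.asarray(coords_a, dtype=np.int64)
    b = np.asarray(coords_b, dtype=np.int64)
    best = np.inf
    # chunk the broadcast so large boundaries stay within memory
    step = max(1, int(4e6) // max(len(b), 1))
    for i in range(0, len(a), step):
        d2 = (((a[i : i + step, None, :] - b[None, :, :]) * s) ** 2).sum(axis=-1)
        m = d2.min()
        if m < best:
            best = m
    return float(np.sqrt(best))


def edge_distance(mask: LabelMask, label_a: int, label_b: int) -> float:
    """Minimum membrane-to-membrane distance between two labels, in µm.

    Computed over boundary voxel centres; symmetric by construction. Voxel
    centres of face-touching labels are one pitch apart, so the value is
    bounded below by the voxel pitch — a documented half-pitch-scale bias
    against the true surface distance.
    """
    if label_a == label_b:
        raise ValueError("edge distance requires two distinct labels")
    vox = mask.voxels
    for lab in (label_a, label_b):
        if not (vox == lab).any():
            raise ValueError(f"label {lab} not present in mask")
    by_label = boundary_coords_by_label(mask)
    return _min_boundary_distance_um(
        by_label[int(label_a)], by_label[int(label_b)], mask.voxel_size_um
    )


@dataclass
class NeighbourGraph:
    """Delaunay adjacency over one image's nuclei with both distances."""

    nodes: pd.DataFrame  # label, centroid_z_um, centroid_y_um, centroid_x_um
    edges: pd.DataFrame  # label_a, label_b, centroid_distance_um, edge_distance_um
    radius_um: float
    image_id: str
    replicate_id: str = "R1"

    @property
    def n_nuclei(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_graph(
    records: list[NucleusRecord],
    mask: LabelMask,
    config: RunConfig | None = None,
) -> NeighbourGraph:
    """Neighbour graph for one image.

    Delaunay adjacency on centroids, then both distances per adjacent pair,
    then retention of pairs with centroid distance within ``radius_um``.
    The radius applies to centroid distance: the capture circle is drawn
    around the nucleus centre. With fewer than two nuclei the graph simply
    has no edges.
    """
    config = config or RunConfig()
    if config.border_policy == "exclude":
        records = [r for r in records if not r.touches_border]
    labels = [r.label for r in records]
    centroids = np.array([r.centroid_um for r in records], dtype=float).reshape(-1, 3)
    nodes = pd.DataFrame(
        {
            "label": labels,
            "centroid_z_um": centroids[:, 0] if len(records) else [],
            "centroid_y_um": centroids[:, 1] if len(records) else [],
            "centroid_x_um": centroids[:, 2] if len(records) else [],
        }
    )
    edge_cols = ["label_a", "label_b", "centroid_distance_um", "edge_distance_um"]
    if len(records) < 2:
        logger.info("image %s: %d nuclei, no edges", mask.image_id, len(records))
        return NeighbourGraph(
            nodes=nodes,
            edges=pd.DataFrame(columns=edge_cols),
            radius_um=config.radius_um,
            image_id=mask.image_id,
            replicate_id=mask.replicate_id,
        )

    adjacency = delaunay_adjacency(centroids)
    boundaries = boundary_coords_by_label(mask)
    rows = []
    for i, j in sorted(adjacency):
        cdist = float(np.linalg.norm(centroids[i] - centroids[j]))
        if cdist > config.radius_um:
            continue
        edist = _min_boundary_distance_um(
            boundaries[labels[i]], boundaries[labels[j]], mask.voxel_size_um
        )
        la, lb = sorted((labels[i], labels[j]))
        rows.append((la, lb, cdist, edist))
    edges = pd.DataFrame(rows, columns=edge_cols).sort_values(
        ["label_a", "label_b"], ignore_index=True
    )
    return NeighbourGraph(
        nodes=nodes,
        edges=edges,
        radius_um=config.radius_um,
        image_id=mask.image_id,
        replicate_id=mask.replicate_id,
    )


@dataclass
class DistanceSummary:
    """Pooled edge-distance statistics for one or more images."""

    scope_id: str
    n_nuclei: int
    n_edges: int
    mean_edge_distance_um: float  # NaN when no edges
    mean_defined: bool
    distances_um: np.ndarray  # the (possibly subsampled) pooled distances
    density_grid_um: np.ndarray | None = None
    density: np.ndarray | None = None


def summarise_distances(
    graphs, config: RunConfig | None = None, scope_id: str | None = None
) -> DistanceSummary:
    """Pool per-edge distances across images and summarise.

    Each unordered pair is counted once. When ``config.subsample_n`` is set
    and fewer edges than that exist, all edges are used; otherwise a seeded
    subsample without replacement fixes the sample size — useful when
    density curves are to be compared at matched n across samples. The
    density is a unit-area Gaussian KDE on an explicit grid.
    """
    config = config or RunConfig()
    if isinstance(graphs, NeighbourGraph):
        graphs = [graphs]
    graphs = list(graphs)
    if not graphs:
        raise ValueError("no graphs supplied")
    scope_id = scope_id or graphs[0].replicate_id
    pooled = np.concatenate(
        [g.edges["edge_distance_um"].to_numpy(dtype=float) for g in graphs]
    )
    n_nuclei = sum(g.n_nuclei for g in graphs)
    n_edges = pooled.size
    if n_edges == 0:
        logger.warning("scope %s: zero edges; mean undefined", scope_id)
        return DistanceSummary(
            scope_id=scope_id,
            n_nuclei=n_nuclei,
            n_edges=0,
            mean_edge_distance_um=float("nan"),
            mean_defined=False,
            distances_um=pooled,
        )
    values = pooled
    if config.subsample_n is not None and n_edges > config.subsample_n:
        rng = np.random.default_rng(config.seed)
        values = rng.choice(pooled, size=config.subsample_n, replace=False)
    mean = float(pooled.mean())
    grid = dens = None
    if np.unique(values).size >= 2:
        grid = density.shared_grid(
            [values], config.bandwidth_rule, config.density_grid_points
        )
        dens = density.kde_on_grid(values, grid, config.bandwidth_rule)
    return DistanceSummary(
        scope_id=scope_id,
        n_nuclei=n_nuclei,
        n_edges=n_edges,
        mean_edge_distance_um=mean,
        mean_defined=True,
        distances_um=values,
        density_grid_um=grid,
        density=dens,
    )
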