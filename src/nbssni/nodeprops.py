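"""Node properties usable inside NBS-SNI.

Graph measures (computed from a subject's structural — or optionally
functional — connectivity matrix):

* **closeness centrality** ``C(v) = (n-1) / sum_u d(u, v)``, with the shortest
  distance measured either in hops or along weighted paths;
* **current-flow closeness centrality** (information centrality)
  ``CFCC(v) = (n-1) / sum_u R(v, u)`` with ``R`` the effective resistance of
  the graph seen as a resistor network (weights = conductances);
* **local information dimension (LID)**: minus the slope of the Shannon
  information ``I_v(l) = -(n_v(l)/n) ln(n_v(l)/n)`` of the box population
  around ``v`` against ``ln l``, for box radii from the smallest distance up
  to half the eccentricity of ``v``.

Mesh measures (from a triangulated cortical surface):

* per-vertex Gaussian curvature by angle deficit,
  ``K = (2*pi - sum_i theta_i) / A`` with barycentric vertex area ``A``;
* per-region **intrinsic curvature index**,
  ``ICI_r = (1/4*pi) * sum_{v in r} K_v A_v``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "TriMesh",
    "PropertyMatrix",
    "distance_matrix",
    "closeness",
    "current_flow_closeness",
    "box_counts",
    "local_information_dimension",
    "vertex_curvature",
    "intrinsic_curvature_index",
    "property_matrix",
    "load_mesh",
    "GRAPH_PROPERTIES",
]


# --------------------------------------------------------------------------
# shortest distances

def _edge_lengths(a: np.ndarray, mode: str) -> np.ndarray:
    """Edge length matrix for the requested distance convention."""
    a = np.asarray(a, dtype=float)
    if mode == "hops":
        return (a != 0).astype(float)
    if mode == "weighted":
        # affinity weights -> traversal cost 1/w
        if ((a < 0) & (a != 0)).any():
            raise ValueError("weighted mode requires nonnegative weights")
        with np.errstate(divide="ignore"):
            lengths = np.where(a > 0, 1.0 / np.where(a > 0, a, 1.0), 0.0)
        return lengths
    if mode == "raw":
        return a
    raise ValueError(f"unknown distance mode {mode!r}")


def distance_matrix(a: np.ndarray, mode: str = "hops") -> np.ndarray:
    """All-pairs shortest distances; ``inf`` across components.

    ``mode='hops'`` counts edges crossed; ``mode='weighted'`` accumulates
    edge lengths ``1/w`` (affinity weights treated as conductances);
    ``mode='raw'`` accumulates the weights themselves as costs.
    """
    lengths = _edge_lengths(a, mode)
    graph = csr_matrix(lengths)
    if mode == "hops":
        return shortest_path(graph, method="D", unweighted=True)
    return shortest_path(graph, method="D")


def closeness(a: np.ndarray, mode: str = "hops") -> np.ndarray:
    """Closeness centrality ``(n-1)/sum_u d(u, v)`` per node.

    On a disconnected graph each node is scored within its own connected
    component with an ``(n_comp - 1)`` numerator (a warning is emitted);
    isolated nodes get 0.
    """
    d = distance_matrix(a, mode)
    n = d.shape[0]
    n_comp, labels = connected_components(csr_matrix((np.asarray(a) != 0)),
                                          directed=False)
    if n_comp > 1:
        warnings.warn(
            f"graph has {n_comp} components; closeness computed per component",
            stacklevel=2,
        )
    out = np.zeros(n)
    for comp in range(n_comp):
        idx = np.flatnonzero(labels == comp)
        if idx.size < 2:
            continue  # isolated node -> 0
        sub = d[np.ix_(idx, idx)]
        out[idx] = (idx.size - 1) / sub.sum(axis=0)
    return out


def current_flow_closeness(a: np.ndarray) -> np.ndarray:
    """Current-flow closeness (information) centrality.

    Treats weights as conductances; ``CFCC(v) = (n-1)/sum_u R(v,u)`` with the
    effective resistance ``R`` obtained from the Moore-Penrose pseudoinverse
    of the graph Laplacian.  Requires a connected graph.
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    n_comp, _ = connected_components(csr_matrix((a != 0)), directed=False)
    if n_comp > 1:
        raise ValueError("current-flow closeness undefined on disconnected graphs")
    lap = np.diag(a.sum(axis=1)) - a
    # pinv via the rank-one shift trick: (L + J/n)^-1 - J/n
    j = np.full((n, n), 1.0 / n)
    linv = np.linalg.inv(lap + j) - j
    diag = np.diag(linv)
    resist = diag[:, None] + diag[None, :] - 2 * linv
    return (n - 1) / resist.sum(axis=1)


# --------------------------------------------------------------------------
# local information dimension

def box_counts(
    a: np.ndarray,
    v: int,
    mode: str = "hops",
    n_steps: int = 15,
    dist: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Box populations ``n_v(l)`` around node ``v``.

    Returns ``(ls, counts, degenerate)``.  In hops mode the radii are the
    integers ``1 .. floor(ecc(v)/2)``; in weighted mode they are ``n_steps``
    equally spaced values from the smallest positive distance from ``v`` to
    half its maximum distance.  ``n_v(l)`` counts nodes within distance ``l``
    of ``v`` (including ``v``).  Fewer than 2 distinct radii flags the range
    as degenerate.
    """
    if dist is None:
        dist = distance_matrix(a, mode)[v]
    dv = dist[np.isfinite(dist)]
    ecc = dv.max() if dv.size else 0.0
    if mode == "hops":
        lmax = int(ecc // 2)
        ls = np.arange(1, lmax + 1, dtype=float)
    else:
        pos = dv[dv > 0]
        if pos.size == 0 or ecc <= 0:
            return np.array([]), np.array([]), True
        ls = np.linspace(pos.min(), ecc / 2.0, n_steps)
    if ls.size < 2 or np.unique(ls).size < 2:
        return ls, np.array([(dist <= l).sum() for l in ls], dtype=float), True
    counts = np.array([(dist <= l).sum() for l in ls], dtype=float)
    return ls, counts, False


def _lid_from_boxes(ls: np.ndarray, counts: np.ndarray, n: int) -> float:
    frac = counts / n
    info = np.where(frac > 0, -frac * np.log(np.where(frac > 0, frac, 1.0)), 0.0)
    slope = np.polyfit(np.log(ls), info, 1)[0]
    return -float(slope)


def local_information_dimension(
    a: np.ndarray, mode: str = "hops", n_steps: int = 15
) -> np.ndarray:
    """Local information dimension of every node.

    Nodes with a degenerate radius range (e.g. eccentricity 1 in hops mode)
    get 0 so that downstream statistics stay defined; a warning is emitted.
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    dmat = distance_matrix(a, mode)
    out = np.zeros(n)
    degenerate = []
    for v in range(n):
        ls, counts, bad = box_counts(a, v, mode, n_steps, dist=dmat[v])
        if bad:
            degenerate.append(v)
            continue
        out[v] = _lid_from_boxes(ls, counts, n)
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} node(s) had a degenerate box range; LID set to 0",
            stacklevel=2,
        )
    return out


# --------------------------------------------------------------------------
# mesh curvature

@dataclass
class TriMesh:
    """Triangle mesh: vertices (V, 3) in mm, faces (F, 3) vertex indices."""

    vertices: np.ndarray
    faces: np.ndarray
    region_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("faces reference invalid vertices")
        for f in self.faces:
            if len(set(f)) != 3:
                raise ValueError(f"degenerate face {f}")
        if self.region_labels is not None:
            self.region_labels = np.asarray(self.region_labels, dtype=int)
            if self.region_labels.shape != (len(self.vertices),):
                raise ValueError("region_labels must be one label per vertex")


def load_mesh(path, labels_path=None) -> TriMesh:
    """Load an OFF/PLY ASCII triangle mesh (+ optional per-vertex label file)."""
    import trimesh

    m = trimesh.load(path, process=False)
    labels = None
    if labels_path is not None:
        labels = np.loadtxt(labels_path, dtype=int)
    return TriMesh(vertices=np.asarray(m.vertices), faces=np.asarray(m.faces),
                   region_labels=labels)


def vertex_curvature(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-vertex Gaussian curvature by angle deficit.

    Returns ``(K, A, boundary)``: curvature ``K = (2*pi - sum theta_i)/A``,
    barycentric vertex area ``A`` (one third of incident triangle area), and a
    boolean mask flagging boundary vertices (angle deficit is not a curvature
    estimate there).  The corner angles come from the law of cosines
    ``theta = arccos((l1^2 + l2^2 - k^2) / (2 l1 l2))`` on the triangle edge
    lengths.
    """
    verts, faces = mesh.vertices, mesh.faces
    nv = len(verts)
    angle_sum = np.zeros(nv)
    area = np.zeros(nv)

    tri = verts[faces]  # (F, 3, 3)
    # edge lengths opposite each corner
    e0 = np.linalg.norm(tri[:, 1] - tri[:, 2], axis=1)
    e1 = np.linalg.norm(tri[:, 2] - tri[:, 0], axis=1)
    e2 = np.linalg.norm(tri[:, 0] - tri[:, 1], axis=1)
    if np.any(e0 <= 0) or np.any(e1 <= 0) or np.any(e2 <= 0):
        raise ValueError("mesh has a zero-length edge")
    lens = np.stack([e0, e1, e2], axis=1)  # opposite corner i

    tri_area = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    for corner in range(3):
        k = lens[:, corner]                      # edge opposite the corner
        l1 = lens[:, (corner + 1) % 3]
        l2 = lens[:, (corner + 2) % 3]
        cosang = np.clip((l1**2 + l2**2 - k**2) / (2 * l1 * l2), -1.0, 1.0)
        ang = np.arccos(cosang)
        np.add.at(angle_sum, faces[:, corner], ang)
        np.add.at(area, faces[:, corner], tri_area / 3.0)

    # boundary vertices: touch an edge shared by exactly one face
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = np.zeros(nv, dtype=bool)
    boundary[np.unique(uniq[counts == 1])] = True

    deficit = 2 * np.pi - angle_sum
    with np.errstate(divide="ignore", invalid="ignore"):
        curv = np.where(area > 0, deficit / np.where(area > 0, area, 1.0), 0.0)
    return curv, area, boundary


def intrinsic_curvature_index(
    mesh: TriMesh, region_labels: np.ndarray | None = None
) -> dict[int, float]:
    """Per-region intrinsic curvature index ``(1/4pi) sum_{v in r} K_v A_v``.

    Since ``K_v A_v`` is the angle deficit, this is the summed angle deficit
    of the region's vertices divided by ``4 pi`` (a whole sphere-topology
    mesh gives exactly 1, by Gauss-Bonnet).  Regions with no vertices map
    to 0 with a warning.
    """
    labels = region_labels if region_labels is not None else mesh.region_labels
    if labels is None:
        labels = np.zeros(len(mesh.vertices), dtype=int)
    labels = np.asarray(labels, dtype=int)
    curv, area, _ = vertex_curvature(mesh)
    deficit = curv * area
    out: dict[int, float] = {}
    for r in np.unique(labels):
        out[int(r)] = float(deficit[labels == r].sum() / (4 * np.pi))
    return out


# --------------------------------------------------------------------------
# cohort-level property matrices

@dataclass
class PropertyMatrix:
    """N x n matrix of one node property: rows = subjects, cols = nodes."""

    values: np.ndarray
    property_name: str
    group_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


GRAPH_PROPERTIES = {
    "closeness": lambda a, **kw: closeness(a, mode=kw.get("mode", "weighted")),
    "cfcc": lambda a, **kw: current_flow_closeness(a),
    "lid": lambda a, **kw: local_information_dimension(
        a, mode=kw.get("mode", "weighted"), n_steps=kw.get("n_steps", 15)
    ),
}


def property_matrix(
    subjects,
    prop: str,
    source: str = "structural",
    group_label: str = "",
    **kwargs,
) -> PropertyMatrix:
    """Stack one node property across subjects into an (N, n) matrix.

    ``prop`` is a graph-measure name (``closeness``, ``cfcc``, ``lid``) or
    the name of an anatomical property present on every subject.  Graph
    measures are computed from each subject's ``source`` matrix.
    """
    rows = []
    if prop in GRAPH_PROPERTIES:
        fn = GRAPH_PROPERTIES[prop]
        for s in subjects:
            mat = getattr(s, source)
            rows.append(fn(mat, **kwargs))
    else:
        for s in subjects:
            if prop not in s.anat_props:
                raise KeyError(
                    f"subject {s.id} lacks anatomical property {prop!r}"
                )
            rows.append(s.anat_props[prop])
    return PropertyMatrix(np.vstack(rows), property_name=prop,
                          group_label=group_label)
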