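"""Data model and file I/O for node-aligned multi-representation cohorts.

A case-control study is represented as a :class:`Cohort` of two groups of
:class:`Subject` objects.  Every subject carries a structural connectivity
matrix (sparse, weighted, symmetric, nonnegative -- e.g. white-matter fiber
density) and a functional connectivity matrix (dense, weighted, symmetric --
e.g. resting-state correlations), defined on the *same* node set in the same
order.  Optional anatomical node properties (gray matter volume, intrinsic
curvature index, ...) attach to subjects as named length-``n`` vectors.

Matrices are plain delimited numeric text (whitespace or comma separated,
auto-detected, no header); node tables are delimited text *with* a header.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AlignmentError",
    "DataError",
    "Subject",
    "Cohort",
    "Subnetwork",
    "load_matrix",
    "load_cohort",
    "load_node_table",
    "write_subnetwork",
    "read_subnetwork",
]

#: asymmetry up to this (max |A - A.T|) is silently averaged away
SYMMETRIZE_TOL = 1e-6
#: asymmetry above SYMMETRIZE_TOL but caught on pre-built arrays
SYMMETRY_TOL = 1e-9


class AlignmentError(ValueError):
    """Node sets / dimensions do not line up across subjects or files."""


class DataError(ValueError):
    """A matrix or table contains invalid values (NaN, negative weights, ...)."""


def _validate_square_symmetric(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise AlignmentError(f"{name} matrix must be square, got shape {a.shape}")
    if np.isnan(a).any():
        raise DataError(f"{name} matrix contains NaN entries")
    asym = np.abs(a - a.T).max() if a.size else 0.0
    if asym > SYMMETRIZE_TOL:
        raise DataError(f"{name} matrix asymmetric (max |A-A'| = {asym:.3g})")
    if asym > 0:
        a = (a + a.T) / 2.0
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    return a


@dataclass
class Subject:
    """One individual: node-aligned structural + functional matrices."""

    id: str
    structural: np.ndarray
    functional: np.ndarray
    anat_props: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.structural = _validate_square_symmetric(self.structural, "structural")
        self.functional = _validate_square_symmetric(self.functional, "functional")
        if self.structural.shape != self.functional.shape:
            raise AlignmentError(
                f"subject {self.id}: structural {self.structural.shape} and "
                f"functional {self.functional.shape} dimensions differ"
            )
        if (self.structural < 0).any():
            raise DataError(f"subject {self.id}: negative structural weights")
        for name, vec in self.anat_props.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.n,):
                raise AlignmentError(
                    f"subject {self.id}: property {name!r} has length "
                    f"{vec.shape}, expected ({self.n},)"
                )
            if np.isnan(vec).any():
                raise DataError(f"subject {self.id}: property {name!r} has NaN")
            self.anat_props[name] = vec

    @property
    def n(self) -> int:
        return self.structural.shape[0]


@dataclass
class Cohort:
    """Two labeled groups of node-aligned subjects.

    ``group1`` is the condition (case) group, ``group2`` the control group.
    """

    group1: list[Subject]
    group2: list[Subject]
    node_ids: list[str]
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        for subj in self.subjects:
            if subj.n != n:
                raise AlignmentError(
                    f"subject {subj.id} has {subj.n} nodes, cohort has {n}"
                )
        if len(self.group1) < 2 or len(self.group2) < 2:
            raise AlignmentError("both groups need at least 2 subjects")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 3):
                raise AlignmentError(
                    f"coords shape {self.coords.shape}, expected ({n}, 3)"
                )

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def subjects(self) -> list[Subject]:
        return list(self.group1) + list(self.group2)

    def functional_stack(self, group: int) -> np.ndarray:
        """(N, n, n) array of functional matrices for group 1 or 2."""
        members = self.group1 if group == 1 else self.group2
        return np.stack([s.functional for s in members])


@dataclass(frozen=True)
class Subnetwork:
    """An extracted edge set with provenance.

    Edges are unordered 0-based node-index pairs stored ``(u, v)`` with
    ``u < v``; ``nodes`` is the set of touched endpoints.
    """

    edges: frozenset[tuple[int, int]]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise DataError(f"self-loop edge ({u},{v}) in subnetwork")
            if u > v:
                raise DataError(f"edge ({u},{v}) not stored smaller-index first")

    @classmethod
    def from_pairs(cls, pairs, provenance: dict | None = None) -> "Subnetwork":
        edges = frozenset((min(u, v), max(u, v)) for u, v in pairs)
        return cls(edges=edges, provenance=provenance or {})

    @property
    def nodes(self) -> frozenset[int]:
        return frozenset(i for e in self.edges for i in e)

    def __len__(self) -> int:
        return len(self.edges)

    def sorted_edges(self) -> list[tuple[int, int]]:
        return sorted(self.edges)

    def adjacency(self, n: int) -> np.ndarray:
        a = np.zeros((n, n))
        for u, v in self.edges:
            a[u, v] = a[v, u] = 1.0
        return a


def load_matrix(path: str | Path) -> np.ndarray:
    """Load a dense square numeric matrix from delimited text (no header).

    The delimiter (whitespace vs comma) is auto-detected from the first line.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delimiter = "," if "," in first else None
    try:
        a = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise DataError(f"{path}: could not parse numeric matrix ({exc})") from exc
    if np.isnan(a).any():
        raise DataError(f"{path}: matrix contains NaN entries")
    return a


def load_node_table(path: str | Path, n: int | None = None) -> dict[str, np.ndarray]:
    """Load per-node properties from a delimited table with a header row.

    Returns a map property-name -> length-``n`` vector, row order matching the
    cohort node order.  If ``n`` is given the row count is checked against it.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if n is not None and len(df) != n:
        raise AlignmentError(f"{path}: {len(df)} rows, expected {n} nodes")
    out: dict[str, np.ndarray] = {}
    for col in df.columns:
        vec = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        if np.isnan(vec).any():
            raise DataError(f"{path}: column {col!r} has non-numeric/NaN entries")
        out[str(col)] = vec
    return out


def _load_manifest(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_cohort(manifest: str | Path | Mapping) -> Cohort:
    """Build a validated :class:`Cohort` from a manifest.

    The manifest is a YAML/JSON file (or an equivalent mapping) with keys
    ``group1`` / ``group2`` mapping to lists of
    ``{id, structural, functional, node_table?}`` entries, plus optional
    ``node_ids`` (file, one id per line) and ``coords`` (3-column delimited
    text, mm).  Relative paths resolve against the manifest location.
    """
    if isinstance(manifest, (str, Path)):
        mpath = Path(manifest)
        spec = _load_manifest(mpath)
        base = mpath.parent
    else:
        spec = dict(manifest)
        base = Path(spec.get("base_dir", "."))

    def resolve(p: str) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    groups: dict[str, list[Subject]] = {}
    n_ref: int | None = None
    for gname in ("group1", "group2"):
        members = []
        for entry in spec.get(gname, []):
            sm = load_matrix(resolve(entry["structural"]))
            fm = load_matrix(resolve(entry["functional"]))
            subj = Subject(id=str(entry["id"]), structural=sm, functional=fm)
            if n_ref is None:
                n_ref = subj.n
            elif subj.n != n_ref:
                raise AlignmentError(
                    f"subject {subj.id}: {subj.n}x{subj.n} matrix in a "
                    f"{n_ref}-node cohort"
                )
            if entry.get("node_table"):
                subj.anat_props.update(
                    {
                        k: v
                        for k, v in load_node_table(
                            resolve(entry["node_table"]), n=subj.n
                        ).items()
                    }
                )
            members.append(subj)
        groups[gname] = members

    if n_ref is None:
        raise DataError("manifest lists no subjects")

    if spec.get("node_ids"):
        node_ids = [
            line.strip()
            for line in Path(resolve(spec["node_ids"])).read_text().splitlines()
            if line.strip()
        ]
        if len(node_ids) != n_ref:
            raise AlignmentError(
                f"node_ids file lists {len(node_ids)} ids, cohort has {n_ref} nodes"
            )
    else:
        node_ids = [f"n{i:03d}" for i in range(n_ref)]

    coords = None
    if spec.get("coords"):
        coords = load_matrix(resolve(spec["coords"]))

    return Cohort(
        group1=groups["group1"], group2=groups["group2"],
        node_ids=node_ids, coords=coords,
    )


def write_subnetwork(
    s: Subnetwork,
    node_ids: Sequence[str],
    path: str | Path,
    weights: np.ndarray | None = None,
) -> None:
    """Write a subnetwork as a TSV edge list (deterministic lexicographic order).

    Columns: node_id_u, node_id_v and, when ``weights`` (an n x n matrix) is
    given, the per-edge weight.
    """
    path = Path(path)
    with open(path, "w") as fh:
        header = "node_u\tnode_v" + ("\tweight" if weights is not None else "")
        fh.write(header + "\n")
        for u, v in s.sorted_edges():
            row = f"{node_ids[u]}\t{node_ids[v]}"
            if weights is not None:
                row += f"\t{weights[u, v]:.10g}"
            fh.write(row + "\n")


def read_subnetwork(path: str | Path, node_ids: Sequence[str]) -> Subnetwork:
    """Read an edge-list TSV written by :func:`write_subnetwork`."""
    index = {nid: i for i, nid in enumerate(node_ids)}
    pairs = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("node_u"):
            raise DataError(f"{path}: missing edge-list header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            try:
                pairs.append((index[parts[0]], index[parts[1]]))
            except KeyError as exc:
                raise AlignmentError(f"{path}: unknown node id {exc}") from exc
    return Subnetwork.from_pairs(pairs)
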