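"""Subnetwork extraction engines.

Three case-control extraction methods over edge-wise two-sample statistics:

* **NBS-SNI** -- threshold node-level statistics in each group, combine the
  suprathreshold node sets into a central set, threshold the edge statistics,
  then keep only the suprathreshold edges within hop distance ``d`` of the
  central set (``d=0``: both endpoints central; ``d=1``: at least one
  endpoint central; ``d>1``: grown neighborhoods on the suprathreshold edge
  graph).
* **NBS** -- threshold the edge statistics and keep the largest connected
  component of suprathreshold edges.
* **FDR** -- Benjamini-Hochberg selection over the one-tailed edge p-values,
  every edge treated independently (no component rule).

A fixed-size variant returns subnetworks of exactly ``k_final`` edges for
size-controlled method comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, connected_components

from .cohort import Cohort, Subnetwork
from .nodeprops import property_matrix
from .stats import (
    EdgeStatResult,
    NodeStatResult,
    bh_fdr,
    one_sample_ks_node_test,
    one_sample_node_test,
    two_sample_edge_test,
    two_sample_node_test,
)

__all__ = [
    "ExtractionConfig",
    "CentralNodeSet",
    "suprathreshold_nodes",
    "combine_node_sets",
    "suprathreshold_edges",
    "d_intersection",
    "central_node_set",
    "nbs_sni",
    "nbs",
    "fdr_extract",
    "extract_fixed_size",
]


@dataclass
class ExtractionConfig:
    """Parameters of an NBS-SNI extraction.

    Exactly one of ``t_node`` (statistic-scale threshold: keep stat >= t_node)
    or ``p_node`` (p-value scale: keep p <= p_node) must be set.
    """

    node_property: str = "closeness"
    node_test: str = "one_sample_t"  # one_sample_t | one_sample_ks | two_sample_t
    t_node: float | None = None
    p_node: float | None = None
    node_combine: str = "intersection"  # intersection | group1_only | group2_only | between
    t_edge: float = 0.0
    tail: str = "hyper"
    d: int = 1
    prop_source: str = "structural"
    prop_kwargs: dict = field(default_factory=dict)
    mu0_mode: str = "grand_mean"
    node_tail: str = "greater"
    equal_var: bool = True

    def __post_init__(self) -> None:
        if (self.t_node is None) == (self.p_node is None):
            raise ValueError("set exactly one of t_node / p_node")
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if self.t_edge < 0:
            raise ValueError("t_edge must be >= 0")


@dataclass(frozen=True)
class CentralNodeSet:
    """The 'important actors': combined suprathreshold node indices."""

    nodes: frozenset[int]
    source: str = ""

    def __contains__(self, i: int) -> bool:
        return i in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)


def suprathreshold_nodes(
    r: NodeStatResult, t_node: float | None = None, p_node: float | None = None
) -> frozenset[int]:
    """Node indices passing the statistic- or p-value-scale threshold."""
    if (t_node is None) == (p_node is None):
        raise ValueError("set exactly one of t_node / p_node")
    if t_node is not None:
        keep = r.stat >= t_node
    else:
        keep = r.pvalue <= p_node
    out = frozenset(np.flatnonzero(keep).tolist())
    if not out:
        warnings.warn("no suprathreshold nodes", stacklevel=2)
    return out


def combine_node_sets(s1, s2, mode: str = "intersection") -> CentralNodeSet:
    """Combine the two groups' suprathreshold node sets into the central set."""
    s1, s2 = frozenset(s1), frozenset(s2)
    if mode == "intersection":
        nodes = s1 & s2
    elif mode == "group1_only":
        nodes = s1
    elif mode == "group2_only":
        nodes = s2
    else:
        raise ValueError(f"unknown combine mode {mode!r}")
    if not nodes:
        warnings.warn("central node set is empty", stacklevel=2)
    return CentralNodeSet(nodes=nodes, source=mode)


def suprathreshold_edges(e: EdgeStatResult, t_edge: float) -> frozenset[tuple[int, int]]:
    """Unordered pairs whose tail-signed t statistic is >= t_edge."""
    t = e.tstat
    iu, ju = np.triu_indices_from(t, k=1)
    keep = t[iu, ju] >= t_edge
    return frozenset(zip(iu[keep].tolist(), ju[keep].tolist()))


def _edge_graph(edges, n: int) -> csr_matrix:
    if not edges:
        return csr_matrix((n, n))
    arr = np.array(sorted(edges))
    data = np.ones(len(arr))
    g = csr_matrix((data, (arr[:, 0], arr[:, 1])), shape=(n, n))
    return g + g.T


def d_intersection(
    edges, central: CentralNodeSet | frozenset, d: int, n: int | None = None
) -> Subnetwork:
    """Retain suprathreshold edges within distance ``d`` of the central set.

    ``d=0`` keeps edges with *both* endpoints central; ``d=1`` keeps edges
    touching at least one central node; for ``d>1`` hop distances ``delta``
    from the central set are computed on the suprathreshold edge graph and
    an edge (u, v) is kept iff ``min(delta(u), delta(v)) <= d - 1``.
    """
    cset = central.nodes if isinstance(central, CentralNodeSet) else frozenset(central)
    edges = frozenset((min(u, v), max(u, v)) for u, v in edges)
    prov = {"d": d, "central_size": len(cset)}
    if d == 0:
        keep = {e for e in edges if e[0] in cset and e[1] in cset}
    elif d == 1:
        keep = {e for e in edges if e[0] in cset or e[1] in cset}
    else:
        if n is None:
            n = max((v for e in edges for v in e), default=-1) + 1
            n = max(n, max(cset, default=-1) + 1)
        g = _edge_graph(edges, n)
        delta = np.full(n, np.inf)
        for c in cset:
            if c < n:
                order, preds = breadth_first_order(g, c, return_predecessors=True)
                dist = np.full(n, np.inf)
                dist[c] = 0
                for node in order[1:]:
                    dist[node] = dist[preds[node]] + 1
                delta = np.minimum(delta, dist)
        keep = {e for e in edges if min(delta[e[0]], delta[e[1]]) <= d - 1}
    return Subnetwork(edges=frozenset(keep), provenance=prov)


def _node_result(p_matrix, cfg: ExtractionConfig) -> NodeStatResult:
    if cfg.node_test == "one_sample_t":
        return one_sample_node_test(p_matrix, mu0_mode=cfg.mu0_mode,
                                    tail=cfg.node_tail)
    if cfg.node_test == "one_sample_ks":
        return one_sample_ks_node_test(p_matrix, tail=cfg.node_tail)
    raise ValueError(f"one-sample node test expected, got {cfg.node_test!r}")


def central_node_set(prop1, prop2, cfg: ExtractionConfig) -> CentralNodeSet:
    """Node tests + thresholds + combination, from the two groups' property
    matrices (steps 1-3 of the extraction)."""
    if cfg.node_test == "two_sample_t":
        r = two_sample_node_test(prop1, prop2, tail=cfg.node_tail,
                                 equal_var=cfg.equal_var)
        nodes = suprathreshold_nodes(r, cfg.t_node, cfg.p_node)
        return CentralNodeSet(nodes=nodes, source="between")
    r1 = _node_result(prop1, cfg)
    r2 = _node_result(prop2, cfg)
    s1 = suprathreshold_nodes(r1, cfg.t_node, cfg.p_node)
    s2 = suprathreshold_nodes(r2, cfg.t_node, cfg.p_node)
    return combine_node_sets(s1, s2, cfg.node_combine)


def nbs_sni(
    cohort: Cohort,
    cfg: ExtractionConfig,
    prop_matrices=None,
    edge_result: EdgeStatResult | None = None,
) -> Subnetwork:
    """End-to-end NBS-SNI extraction on a cohort.

    ``prop_matrices`` (a pair of property matrices for group1/group2) and
    ``edge_result`` may be passed to reuse precomputed stages; each subject's
    node property depends only on that subject, so precomputation is safe.
    """
    if prop_matrices is None:
        prop_matrices = (
            property_matrix(cohort.group1, cfg.node_property,
                            source=cfg.prop_source, group_label="group1",
                            **cfg.prop_kwargs),
            property_matrix(cohort.group2, cfg.node_property,
                            source=cfg.prop_source, group_label="group2",
                            **cfg.prop_kwargs),
        )
    central = central_node_set(prop_matrices[0], prop_matrices[1], cfg)
    if edge_result is None:
        edge_result = two_sample_edge_test(
            cohort.functional_stack(1), cohort.functional_stack(2),
            tail=cfg.tail, equal_var=cfg.equal_var,
        )
    edges = suprathreshold_edges(edge_result, cfg.t_edge)
    sub = d_intersection(edges, central, cfg.d, n=cohort.n)
    prov = {
        "method": "nbs-sni",
        "node_property": cfg.node_property,
        "node_test": cfg.node_test,
        "t_node": cfg.t_node,
        "p_node": cfg.p_node,
        "node_combine": cfg.node_combine,
        "t_edge": cfg.t_edge,
        "tail": cfg.tail,
        "d": cfg.d,
        "central_nodes": sorted(central.nodes),
    }
    return Subnetwork(edges=sub.edges, provenance=prov)


def _components(edges, n: int):
    g = _edge_graph(edges, n)
    n_comp, labels = connected_components(g, directed=False)
    comps: dict[int, list] = {}
    for e in edges:
        comps.setdefault(labels[e[0]], []).append(e)
    return list(comps.values())


def nbs(
    edge_result: EdgeStatResult,
    t_edge: float,
    component_rule: str = "largest",
) -> Subnetwork:
    """Canonical network-based statistic: suprathreshold edges, then the
    largest connected component by edge count (ties broken by the smallest
    contained node index), or all components."""
    n = edge_result.tstat.shape[0]
    edges = suprathreshold_edges(edge_result, t_edge)
    prov = {"method": "nbs", "t_edge": t_edge, "tail": edge_result.tail,
            "component_rule": component_rule}
    if not edges:
        return Subnetwork(edges=frozenset(), provenance=prov)
    if component_rule == "all":
        return Subnetwork(edges=frozenset(edges), provenance=prov)
    if component_rule != "largest":
        raise ValueError(f"unknown component rule {component_rule!r}")
    comps = _components(edges, n)
    best = max(comps, key=lambda c: (len(c), -min(v for e in c for v in e)))
    return Subnetwork(edges=frozenset(best), provenance=prov)


def fdr_extract(edge_result: EdgeStatResult, q: float) -> Subnetwork:
    """Edge-independent baseline: BH-FDR over the one-tailed edge p-values."""
    p = edge_result.pvalue
    iu, ju = np.triu_indices_from(p, k=1)
    reject = bh_fdr(p[iu, ju], q)
    edges = frozenset(zip(iu[reject].tolist(), ju[reject].tolist()))
    return Subnetwork(edges=edges, provenance={"method": "fdr", "q": q,
                                               "tail": edge_result.tail})


def extract_fixed_size(
    edge_result: EdgeStatResult,
    central: CentralNodeSet | frozenset | None = None,
    method: str = "nbs",
    k_pre: int = 200,
    k_final: int = 50,
    d: int = 1,
) -> Subnetwork:
    """Size-controlled extraction returning exactly ``k_final`` edges.

    Keep the ``k_pre`` most significant edges, take the largest connected
    component; for the node-informed method additionally apply the
    ``d``-intersection with the central set; then keep the ``k_final``
    largest t scores of what remains.  If fewer edges remain they are all
    returned and the result is flagged ``short=True``.
    """
    if k_pre < k_final:
        raise ValueError("k_pre must be >= k_final")
    t = edge_result.tstat
    n = t.shape[0]
    iu, ju = np.triu_indices_from(t, k=1)
    tvals = t[iu, ju]
    # deterministic top-k: sort by (-t, i, j)
    order = np.lexsort((ju, iu, -tvals))[: min(k_pre, tvals.size)]
    edges = frozenset(zip(iu[order].tolist(), ju[order].tolist()))
    comps = _components(edges, n)
    if comps:
        comp = max(comps, key=lambda c: (len(c), -min(v for e in c for v in e)))
        edges = frozenset(comp)
    if method == "nbs_sni":
        if central is None:
            raise ValueError("nbs_sni fixed-size extraction needs a central set")
        edges = d_intersection(edges, central, d, n=n).edges
    elif method != "nbs":
        raise ValueError(f"unknown method {method!r}")
    ranked = sorted(edges, key=lambda e: (-t[e[0], e[1]], e[0], e[1]))
    keep = ranked[:k_final]
    prov = {"method": f"fixed_size_{method}", "k_pre": k_pre,
            "k_final": k_final, "short": len(keep) < k_final}
    if prov["short"]:
        warnings.warn(
            f"only {len(keep)} edges available for fixed-size extraction",
            stacklevel=2,
        )
    return Subnetwork(edges=frozenset(keep), provenance=prov)
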