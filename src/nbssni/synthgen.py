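"""Generative models for synthetic case-control connectome cohorts.

Structural networks follow a distance-dependent generative model: the
propensity of a connection between regions ``u`` and ``v`` is

    P(u, v) = E(u, v) * K(u, v)

where ``E`` is a three-branch distance kernel fitted to empirical
connection-probability vs Euclidean-distance curves (log-ratio short range,
exponentially cut off power law mid range, power-law decay long range), and
``K`` injects node-level signal: pairs touching a preselected central node
set ``n_c`` draw ``1 + N(mu_nc, sigma_nc)``, all other pairs
``1 + N(0, sigma_nc)`` (negative draws clamped to 0).  Edges are then added
one at a time without replacement, proportionally to ``P``, until the target
edge count is reached, and each edge receives a weight drawn from a
piecewise body + power-law-tail weight density.  Elevating the connection
propensity of ``n_c`` raises those nodes' closeness centrality in both
groups -- they are the planted "important actors".

Functional networks are fully connected symmetric Gaussian matrices: every
pair draws ``N(0, sigma)`` except planted contrast edge sets in the
condition group, which draw ``N(mu_e, sigma)``; with ``sigma = 1`` the
contrast-to-noise ratio of a planted edge equals ``mu_e``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import pdist, squareform

from .cohort import Cohort, Subject

__all__ = [
    "DistanceKernelParams",
    "WeightParams",
    "StructuralGenParams",
    "FunctionalContrastSpec",
    "ScenarioTruth",
    "synthetic_coords",
    "distance_kernel",
    "structural_probability_matrix",
    "EdgeWeightSampler",
    "sample_structural_network",
    "sample_functional_network",
    "generate_cohort",
    "build_embedded_contrast_scenario",
    "build_roc_scenario",
]


# --------------------------------------------------------------------------
# parameters (defaults are the fitted values of the study conditions)

@dataclass(frozen=True)
class DistanceKernelParams:
    """Three-branch distance kernel for connection propensity (distances in mm).

    ``d < d1``:       A1 * log(d - b) / (d - b)
    ``d1 <= d < d2``: A2 * exp(-ell * d) * d**(-eta2)
    ``d >= d2``:      A3 * d**(-eta3)   (decaying long-range branch)

    ``printed_long_range_sign=True`` switches the long-range branch to the
    growing form ``A3 * d**(+eta3)``.
    """

    a1: float = 133.49
    b: float = -899.3
    a2: float = 0.000943
    ell: float = 0.2277
    eta2: float = -3.83
    a3: float = 275.178
    eta3: float = 2.031
    d1: float = 18.0
    d2: float = 39.0
    printed_long_range_sign: bool = False


@dataclass(frozen=True)
class WeightParams:
    """Piecewise edge-weight density: body ``alpha*e^{k w}/w + c`` on
    ``[w_min, w_c)`` and power-law tail ``a_w * w^{-eta_w}`` on
    ``[w_c, w_max]``.  ``w_c=None`` places the crossover at the first
    intersection of the two branches."""

    alpha: float = 0.194
    k: float = 1.038e-6
    c: float = -0.0007
    a_w: float = 627.78
    eta_w: float = 2.99
    w_min: float = 1.0
    w_max: float = 1000.0
    w_c: float | None = None
    grid_size: int = 10_000


@dataclass(frozen=True)
class StructuralGenParams:
    """Everything needed to generate one group's structural networks."""

    coords: np.ndarray
    m_edges: int
    n_c: frozenset[int] = frozenset()
    mu_nc: float = 0.0
    sigma_nc: float = 2.0
    kernel: DistanceKernelParams = field(default_factory=DistanceKernelParams)
    weights: WeightParams = field(default_factory=WeightParams)
    extra_noise: tuple[float, float] | None = None  # folded-normal (mu, sigma)

    def __post_init__(self) -> None:
        n = len(self.coords)
        if self.m_edges > n * (n - 1) // 2:
            raise ValueError("m_edges exceeds the number of node pairs")
        if self.sigma_nc <= 0:
            raise ValueError("sigma_nc must be positive")
        if any(not (0 <= v < n) for v in self.n_c):
            raise ValueError("n_c indices out of range")


@dataclass(frozen=True)
class FunctionalContrastSpec:
    """Planted functional contrasts: disjoint edge sets with their means."""

    contrasts: tuple = ()  # ((frozenset of (u,v) pairs, mu_e), ...)
    sigma: float = 1.0
    group: int = 1

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        seen: set = set()
        norm = []
        for edges, mu in self.contrasts:
            edges = frozenset((min(u, v), max(u, v)) for u, v in edges)
            if seen & edges:
                raise ValueError("contrast edge sets must be disjoint")
            seen |= edges
            norm.append((edges, float(mu)))
        object.__setattr__(self, "contrasts", tuple(norm))

    @property
    def planted(self) -> dict[tuple[int, int], float]:
        return {e: mu for edges, mu in self.contrasts for e in edges}


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground truth of a planted scenario, for scoring extractions."""

    n_c: frozenset[int]
    contrasts: tuple  # ((frozenset edges, cnr), ...)

    @property
    def all_edges(self) -> frozenset[tuple[int, int]]:
        return frozenset(e for edges, _ in self.contrasts for e in edges)

    def edges_at_cnr(self, cnr: float) -> frozenset[tuple[int, int]]:
        out: set = set()
        for edges, mu in self.contrasts:
            if np.isclose(mu, cnr):
                out |= edges
        return frozenset(out)


# --------------------------------------------------------------------------
# coordinates fixture

def synthetic_coords(n: int = 264, seed: int = 264_001) -> np.ndarray:
    """Deterministic synthetic 3-D node coordinates (mm).

    A seeded brain-shaped point cloud: ``n`` points drawn uniformly inside an
    ellipsoid of semi-axes 65 x 85 x 60 mm (left-right, anterior-posterior,
    superior-inferior).  This is a *synthetic* stand-in for a real atlas
    coordinate table; users may substitute real region centroids.
    """
    rng = np.random.default_rng(seed)
    semi = np.array([65.0, 85.0, 60.0])
    pts = []
    while len(pts) < n:
        cand = rng.uniform(-1, 1, size=(4 * n, 3))
        keep = (cand**2).sum(axis=1) <= 1.0
        pts.extend(cand[keep])
    return np.array(pts[:n]) * semi


# --------------------------------------------------------------------------
# structural model

def distance_kernel(d, params: DistanceKernelParams | None = None) -> np.ndarray:
    """Distance-dependent connection propensity ``E(u, v)``; clamped at 0."""
    p = params or DistanceKernelParams()
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    out = np.empty_like(d)
    short = d < p.d1
    mid = (d >= p.d1) & (d < p.d2)
    lng = d >= p.d2
    arg = d[short] - p.b
    out[short] = p.a1 * np.log(arg) / arg
    out[mid] = p.a2 * np.exp(-p.ell * d[mid]) * d[mid] ** (-p.eta2)
    sign = 1.0 if p.printed_long_range_sign else -1.0
    out[lng] = p.a3 * d[lng] ** (sign * p.eta3)
    return np.clip(out, 0.0, None)


def structural_probability_matrix(
    params: StructuralGenParams,
    rng: np.random.Generator,
    e_vec: np.ndarray | None = None,
) -> np.ndarray:
    """One realization of the pairwise connection-propensity matrix
    ``P = E * K`` (+ optional folded-normal extra noise); symmetric, zero
    diagonal, nonnegative.  The ``K`` draws are fresh per call (per network);
    the deterministic kernel vector ``E`` may be passed in precomputed.
    """
    coords = np.asarray(params.coords, dtype=float)
    n = len(coords)
    if e_vec is None:
        e_vec = distance_kernel(pdist(coords), params.kernel)
    evec = e_vec

    iu, ju = np.triu_indices(n, k=1)
    touching = np.isin(iu, list(params.n_c)) | np.isin(ju, list(params.n_c))
    mu = np.where(touching, params.mu_nc, 0.0)
    k = 1.0 + rng.normal(mu, params.sigma_nc)
    k = np.clip(k, 0.0, None)
    pvec = evec * k
    if params.extra_noise is not None:
        mu_x, sig_x = params.extra_noise
        pvec = pvec + np.abs(rng.normal(mu_x, sig_x, size=pvec.size))
    out = squareform(pvec)
    return out


class EdgeWeightSampler:
    """Inverse-CDF sampler for the piecewise edge-weight density.

    The density (body + power-law tail, crossover at their intersection when
    not given) is discretized on a ``grid_size``-point grid over the support
    and normalized numerically.
    """

    def __init__(self, params: WeightParams | None = None):
        p = params or WeightParams()
        self.params = p
        w_c = p.w_c if p.w_c is not None else self._find_crossover(p)
        self.w_c = w_c
        grid = np.linspace(p.w_min, p.w_max, p.grid_size)
        dens = np.where(grid < w_c, self._body(grid, p), self._tail(grid, p))
        if np.any(dens < 0):
            raise ValueError("weight density negative on the support")
        cdf = np.concatenate([[0.0], np.cumsum(
            (dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
        if cdf[-1] <= 0:
            raise ValueError("weight density has zero total mass")
        self.grid = grid
        self.density = dens / cdf[-1]
        self.cdf = cdf / cdf[-1]

    @staticmethod
    def _body(w, p: WeightParams):
        return p.alpha * np.exp(p.k * w) / w + p.c

    @staticmethod
    def _tail(w, p: WeightParams):
        return p.a_w * w ** (-p.eta_w)

    @classmethod
    def _find_crossover(cls, p: WeightParams) -> float:
        f = lambda w: cls._body(w, p) - cls._tail(w, p)
        ws = np.linspace(p.w_min, p.w_max, 4096)
        fv = f(ws)
        sign_change = np.flatnonzero(np.sign(fv[:-1]) != np.sign(fv[1:]))
        if sign_change.size == 0:
            # branches never meet: single-branch density (all body)
            return p.w_max
        i = sign_change[0]
        return float(brentq(f, ws[i], ws[i + 1]))

    def __call__(self, size: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.uniform(0.0, 1.0, size=size)
        return np.interp(u, self.cdf, self.grid)


def sample_structural_network(
    p_matrix: np.ndarray,
    m_edges: int,
    weight_sampler,
    rng: np.random.Generator,
    method: str = "gumbel",
) -> np.ndarray:
    """Sample exactly ``m_edges`` weighted undirected edges without
    replacement, with inclusion sequence proportional to ``P``.

    ``method='sequential'`` renormalizes over the remaining pairs after each
    draw (the literal process); ``'gumbel'`` draws the same distribution in
    one vectorized pass via the Gumbel top-k / exponential-race identity.
    """
    p_matrix = np.asarray(p_matrix, dtype=float)
    n = p_matrix.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    p = p_matrix[iu, ju].astype(float)
    n_pos = np.count_nonzero(p > 0)
    if n_pos < m_edges:
        raise ValueError(
            f"only {n_pos} positive-propensity pairs for {m_edges} edges"
        )
    if method == "gumbel":
        with np.errstate(divide="ignore"):
            keys = np.where(p > 0, np.log(p), -np.inf)
        keys = keys + rng.gumbel(size=p.size)
        keys[p <= 0] = -np.inf
        chosen = np.argpartition(-keys, m_edges - 1)[:m_edges]
    elif method == "sequential":
        p = p.copy()
        chosen = np.empty(m_edges, dtype=int)
        for t in range(m_edges):
            probs = p / p.sum()
            idx = rng.choice(p.size, p=probs)
            chosen[t] = idx
            p[idx] = 0.0
    else:
        raise ValueError(f"unknown sampling method {method!r}")
    w = np.asarray(weight_sampler(m_edges, rng), dtype=float)
    a = np.zeros((n, n))
    a[iu[chosen], ju[chosen]] = w
    return a + a.T


# --------------------------------------------------------------------------
# functional model

def sample_functional_network(
    n: int,
    spec: FunctionalContrastSpec,
    group_member: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """One fully connected symmetric functional matrix.

    ``group_member=True`` marks a subject of the contrast-carrying group:
    planted edges draw ``N(mu_e, sigma)``; everything else (and every entry
    of the other group) draws ``N(0, sigma)``.  Zero diagonal.
    """
    iu, ju = np.triu_indices(n, k=1)
    vals = rng.normal(0.0, spec.sigma, size=iu.size)
    if group_member:
        for (u, v), mu in spec.planted.items():
            # flat position of (u, v), u < v, in the k=1 upper triangle
            vals[u * (2 * n - u - 1) // 2 + (v - u - 1)] += mu
    a = np.zeros((n, n))
    a[iu, ju] = vals
    return a + a.T


# --------------------------------------------------------------------------
# cohorts and prebuilt scenarios

def generate_cohort(
    struct_params: StructuralGenParams,
    func_spec: FunctionalContrastSpec,
    n1: int,
    n2: int,
    rng: np.random.Generator,
    weight_sampler: EdgeWeightSampler | None = None,
    sampling_method: str = "gumbel",
) -> Cohort:
    """Generate a full two-group cohort of paired structural + functional
    networks.  Both groups share the same central node set in the structural
    model; only the group named in ``func_spec.group`` carries the planted
    functional contrasts."""
    if weight_sampler is None:
        weight_sampler = EdgeWeightSampler(struct_params.weights)
    n = len(struct_params.coords)
    e_vec = distance_kernel(pdist(np.asarray(struct_params.coords, float)),
                            struct_params.kernel)
    groups: list[list[Subject]] = [[], []]
    for g, size in ((1, n1), (2, n2)):
        for i in range(size):
            p = structural_probability_matrix(struct_params, rng, e_vec=e_vec)
            sm = sample_structural_network(
                p, struct_params.m_edges, weight_sampler, rng,
                method=sampling_method,
            )
            fm = sample_functional_network(
                n, func_spec, group_member=(g == func_spec.group), rng=rng
            )
            groups[g - 1].append(
                Subject(id=f"g{g}s{i:03d}", structural=sm, functional=fm)
            )
    return Cohort(
        group1=groups[0], group2=groups[1],
        node_ids=[f"n{i:03d}" for i in range(n)],
        coords=np.asarray(struct_params.coords, dtype=float),
    )


def _pick_distinct(rng: np.random.Generator, n: int, k: int, exclude=()) -> list[int]:
    pool = np.setdiff1d(np.arange(n), np.fromiter(exclude, dtype=int,
                                                  count=len(tuple(exclude))))
    return sorted(int(x) for x in rng.choice(pool, size=k, replace=False))


def build_embedded_contrast_scenario(
    rng: np.random.Generator,
    n_per_group: int = 30,
    n: int = 264,
    m_edges: int = 3188,
    mu_nc: float = 1.5,
    sigma_nc: float = 2.0,
    mu_sub: float = 0.6,
    mu_contrast: float = 0.8,
    coords: np.ndarray | None = None,
) -> tuple[Cohort, ScenarioTruth]:
    """The embedded-subcontrast scenario.

    Five central nodes get elevated structural connection propensity
    (``mu_nc``) in both groups.  The condition group's functional networks
    carry a connected planted component: 8 *subcontrast* edges at the lower
    CNR ``mu_sub``, each touching at least one central node (reaching three
    non-central nodes at distance 1), embedded inside 11 *contrast* edges at
    the higher CNR ``mu_contrast`` in the periphery (touching no central
    node).  The weaker subcontrast is the target a node-informed method can
    isolate where a purely edge-based method cannot.
    """
    if coords is None:
        coords = synthetic_coords(n)
    central = _pick_distinct(rng, n, 5)
    extra = _pick_distinct(rng, n, 3, exclude=central)
    periph = _pick_distinct(rng, n, 8, exclude=central + extra)
    c, e, p = central, extra, periph
    sub_edges = [
        (c[0], c[1]), (c[1], c[2]), (c[2], c[3]), (c[3], c[4]),
        (c[0], e[0]), (c[1], e[1]), (c[2], e[2]), (c[4], e[0]),
    ]
    contrast_edges = [
        (e[0], p[0]), (e[0], p[1]), (e[0], p[2]),
        (e[1], p[3]), (e[1], p[4]), (e[1], p[5]),
        (e[2], p[6]), (e[2], p[7]),
        (p[0], p[3]), (p[4], p[6]), (p[1], p[7]),
    ]
    sub_set = frozenset((min(u, v), max(u, v)) for u, v in sub_edges)
    con_set = frozenset((min(u, v), max(u, v)) for u, v in contrast_edges)
    struct = StructuralGenParams(
        coords=coords, m_edges=m_edges, n_c=frozenset(central),
        mu_nc=mu_nc, sigma_nc=sigma_nc,
    )
    func = FunctionalContrastSpec(
        contrasts=((sub_set, mu_sub), (con_set, mu_contrast)), sigma=1.0,
    )
    cohort = generate_cohort(struct, func, n_per_group, n_per_group, rng)
    truth = ScenarioTruth(
        n_c=frozenset(central),
        contrasts=((sub_set, mu_sub), (con_set, mu_contrast)),
    )
    return cohort, truth


def build_roc_scenario(
    mu_nc: float,
    mu_e: float,
    n_per_group: int,
    rng: np.random.Generator,
    n: int = 264,
    m_edges: int = 3188,
    sigma_nc: float = 2.0,
    n_contrast_edges: int = 20,
    extra_noise: tuple[float, float] | None = None,
    coords: np.ndarray | None = None,
) -> tuple[Cohort, ScenarioTruth]:
    """Single-contrast scenario for ROC sweeps.

    Five randomly selected central nodes plus two non-central nodes span a
    connected planted component of ``n_contrast_edges`` functional edges at
    CNR ``mu_e`` (sigma = 1) in the condition group.  ``extra_noise``
    optionally adds folded-normal noise to the structural propensity matrix.
    """
    if coords is None:
        coords = synthetic_coords(n)
    central = _pick_distinct(rng, n, 5)
    extra = _pick_distinct(rng, n, 2, exclude=central)
    comp_nodes = np.array(central + extra)
    k = len(comp_nodes)
    if n_contrast_edges > k * (k - 1) // 2:
        raise ValueError("n_contrast_edges exceeds the component's pair count")
    # connected subgraph: random spanning path + random extra pairs
    order = rng.permutation(k)
    tree = {tuple(sorted((int(comp_nodes[order[i]]), int(comp_nodes[order[i + 1]]))))
            for i in range(k - 1)}
    all_pairs = [
        tuple(sorted((int(comp_nodes[i]), int(comp_nodes[j]))))
        for i in range(k) for j in range(i + 1, k)
    ]
    rest = [pr for pr in all_pairs if pr not in tree]
    idx = rng.choice(len(rest), size=n_contrast_edges - len(tree), replace=False)
    edges = frozenset(tree | {rest[i] for i in idx})
    struct = StructuralGenParams(
        coords=coords, m_edges=m_edges, n_c=frozenset(central),
        mu_nc=mu_nc, sigma_nc=sigma_nc, extra_noise=extra_noise,
    )
    func = FunctionalContrastSpec(contrasts=((edges, mu_e),), sigma=1.0)
    cohort = generate_cohort(struct, func, n_per_group, n_per_group, rng)
    truth = ScenarioTruth(n_c=frozenset(central), contrasts=((edges, mu_e),))
    return cohort, truth
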