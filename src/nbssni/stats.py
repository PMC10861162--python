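"""Statistical primitives for node- and edge-level group testing.

Node tests operate on (N, n) property matrices (rows = subjects); edge tests
operate on stacks of functional connectivity matrices.  Node tests come in a
one-sample flavour (is a node's property significantly above a reference
level *within* a group -- used to find the "important actors" common to both
groups) and a two-sample flavour (does the property differ *between* groups,
e.g. gray matter volume loss in the condition group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NodeStatResult",
    "EdgeStatResult",
    "one_sample_node_test",
    "one_sample_ks_node_test",
    "two_sample_node_test",
    "two_sample_edge_test",
    "bh_fdr",
    "ovl",
]


@dataclass
class NodeStatResult:
    """Per-node test statistic and p-value with tail metadata."""

    stat: np.ndarray
    pvalue: np.ndarray
    test: str
    tail: str
    group_scope: str = ""


@dataclass
class EdgeStatResult:
    """Per-edge two-sample statistics.

    ``tstat`` holds the *tail-signed* statistic: positive values point in the
    direction being tested (``hyper`` = condition > control, ``hypo`` =
    control > condition), so a single ``t >= t_edge`` rule serves both tails.
    ``pvalue`` is the matching one-tailed p.  Both matrices are symmetric
    with zero diagonal.
    """

    tstat: np.ndarray
    pvalue: np.ndarray
    tail: str
    df: float = np.nan


def _tail_p(t: np.ndarray, df, tail: str) -> np.ndarray:
    if tail == "greater":
        return sps.t.sf(t, df)
    if tail == "less":
        return sps.t.cdf(t, df)
    if tail == "two_sided":
        return 2 * sps.t.sf(np.abs(t), df)
    raise ValueError(f"unknown tail {tail!r}")


def one_sample_node_test(
    p_matrix,
    mu0_mode: str = "grand_mean",
    mu0_value: float | None = None,
    tail: str = "greater",
) -> NodeStatResult:
    """Per-node one-sample t test of a property matrix against a null level.

    The null level mu0 is 0 (``mu0_mode='zero'``), the grand mean of the whole
    matrix (``'grand_mean'``, default -- so suprathreshold nodes are the
    significantly above-average actors of that group), or an explicit
    ``mu0_value``.  Zero-variance nodes get stat 0 / p 1 with a warning.
    """
    values = np.atleast_2d(np.asarray(getattr(p_matrix, "values", p_matrix),
                                      dtype=float))
    n_subj = values.shape[0]
    if n_subj < 2:
        raise ValueError("one-sample node test needs at least 2 subjects")
    if mu0_mode == "zero":
        mu0 = 0.0
    elif mu0_mode == "grand_mean":
        mu0 = float(values.mean())
    elif mu0_mode == "value":
        if mu0_value is None:
            raise ValueError("mu0_mode='value' requires mu0_value")
        mu0 = float(mu0_value)
    else:
        raise ValueError(f"unknown mu0_mode {mu0_mode!r}")

    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"{zero_var.sum()} node(s) with zero variance: stat=0, p=1",
            stacklevel=2,
        )
    se = np.where(zero_var, 1.0, sd) / np.sqrt(n_subj)
    t = np.where(zero_var, 0.0, (mean - mu0) / se)
    p = _tail_p(t, n_subj - 1, tail)
    p = np.where(zero_var, 1.0, p)
    return NodeStatResult(stat=t, pvalue=p, test="one_sample_t", tail=tail)


def _dplus(sample: np.ndarray, reference: np.ndarray) -> float:
    """One-sided KS statistic D+ = sup_x (F_ref(x) - F_sample(x)).

    Large when the sample is stochastically larger than the reference.
    """
    ref = np.sort(reference)
    xs = np.unique(np.concatenate([sample, ref]))
    f_samp = np.searchsorted(np.sort(sample), xs, side="right") / sample.size
    f_ref = np.searchsorted(ref, xs, side="right") / ref.size
    return float(np.max(f_ref - f_samp))


def one_sample_ks_node_test(
    p_matrix,
    reference: str = "pooled_empirical",
    tail: str = "greater",
) -> NodeStatResult:
    """Per-node Kolmogorov-Smirnov test against a reference distribution.

    By default each node's N values are compared with the pooled empirical
    distribution of *all* values in the matrix (parameter-free; suited to
    non-normal properties such as the local information dimension).
    ``tail='greater'`` uses the one-sided D+ statistic (node values
    stochastically larger than the reference); ``'two_sided'`` uses the usual
    sup-absolute-difference D.  P-values are the asymptotic
    ``exp(-2 D^2 m n / (m + n))`` for one-sided tails and the two-sample
    Kolmogorov distribution otherwise.
    """
    values = np.atleast_2d(np.asarray(getattr(p_matrix, "values", p_matrix),
                                      dtype=float))
    n_subj, n_nodes = values.shape
    if n_subj < 2:
        raise ValueError("KS node test needs at least 2 subjects")
    if reference == "pooled_empirical":
        ref = values.ravel()
    elif reference == "normal_fit":
        ref = None
    else:
        raise ValueError(f"unknown reference {reference!r}")
    if ref is not None and np.ptp(ref) == 0:
        raise ValueError("pooled reference distribution is constant")

    stat = np.empty(n_nodes)
    pval = np.empty(n_nodes)
    for j in range(n_nodes):
        sample = values[:, j]
        if ref is None:
            mu, sd = values.mean(), values.std(ddof=1)
            if sd == 0:
                raise ValueError("degenerate normal reference (zero sd)")
            cdf = sps.norm(mu, sd).cdf
            srt = np.sort(sample)
            ecdf_hi = np.arange(1, n_subj + 1) / n_subj
            ecdf_lo = np.arange(0, n_subj) / n_subj
            if tail == "greater":
                d = float(np.max(cdf(srt) - ecdf_lo))
            elif tail == "less":
                d = float(np.max(ecdf_hi - cdf(srt)))
            else:
                d = float(
                    max(np.max(cdf(srt) - ecdf_lo), np.max(ecdf_hi - cdf(srt)))
                )
            m = np.inf
        else:
            if tail == "greater":
                d = _dplus(sample, ref)
            elif tail == "less":
                d = _dplus(-sample, -ref)
            else:
                d = max(_dplus(sample, ref), _dplus(-sample, -ref))
            m = ref.size
        stat[j] = d
        en = n_subj if not np.isfinite(m) else n_subj * m / (n_subj + m)
        if tail == "two_sided":
            pval[j] = float(sps.kstwobign.sf(np.sqrt(en) * d))
        else:
            pval[j] = float(np.exp(-2 * en * d * d))
    return NodeStatResult(stat=stat, pvalue=np.clip(pval, 0, 1),
                          test="one_sample_ks", tail=tail)


def two_sample_node_test(
    p1, p2, tail: str = "two_sided", equal_var: bool = True
) -> NodeStatResult:
    """Per-node two-sample t test between groups (pooled variance by default).

    ``tail='greater'`` tests group1 > group2.  Zero-pooled-variance nodes get
    stat 0 / p 1 with a warning.
    """
    v1 = np.atleast_2d(np.asarray(getattr(p1, "values", p1), dtype=float))
    v2 = np.atleast_2d(np.asarray(getattr(p2, "values", p2), dtype=float))
    if v1.shape[0] < 2 or v2.shape[0] < 2:
        raise ValueError("two-sample node test needs >= 2 subjects per group")
    t, df = _two_sample_t(v1, v2, equal_var)
    p = _tail_p(t, df, tail)
    return NodeStatResult(stat=t, pvalue=p, test="two_sample_t", tail=tail,
                          group_scope="between")


def _two_sample_t(x1, x2, equal_var=True):
    """Vectorized two-sample t over axis 0; zero-variance entries give t=0."""
    n1, n2 = x1.shape[0], x2.shape[0]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1)
    v2 = x2.var(axis=0, ddof=1)
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = np.full_like(se, n1 + n2 - 2, dtype=float)
    else:
        se2 = v1 / n1 + v2 / n2
        se = np.sqrt(se2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        df = np.where(np.isfinite(df), df, 1.0)
    zero = se == 0
    if np.any(zero):
        warnings.warn(
            f"{np.count_nonzero(zero)} zero-variance entries: stat set to 0",
            stacklevel=3,
        )
    t = np.where(zero, 0.0, (m1 - m2) / np.where(zero, 1.0, se))
    return t, df


def two_sample_edge_test(
    f1: np.ndarray,
    f2: np.ndarray,
    tail: str = "hyper",
    equal_var: bool = True,
) -> EdgeStatResult:
    """Edge-wise two-sample t test between two stacks of functional matrices.

    ``f1``/``f2`` are (N1, n, n) and (N2, n, n) stacks (or lists) of symmetric
    matrices.  ``tail='hyper'`` tests condition > control per edge,
    ``'hypo'`` tests control > condition; the returned ``tstat`` is signed so
    that the tested direction is positive, and ``pvalue`` is one-tailed.
    """
    x1 = np.asarray(f1, dtype=float) if isinstance(f1, np.ndarray) else \
        np.stack([np.asarray(m, float) for m in f1])
    x2 = np.asarray(f2, dtype=float) if isinstance(f2, np.ndarray) else \
        np.stack([np.asarray(m, float) for m in f2])
    if x1.shape[1:] != x2.shape[1:]:
        raise ValueError("groups are not node-aligned")
    if x1.shape[0] < 2 or x2.shape[0] < 2:
        raise ValueError("edge test needs >= 2 subjects per group")
    if tail not in ("hyper", "hypo"):
        raise ValueError(f"unknown tail {tail!r}")
    n = x1.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    t_flat, df = _two_sample_t(x1[:, iu, ju], x2[:, iu, ju], equal_var)
    if tail == "hypo":
        t_flat = -t_flat
    p_flat = sps.t.sf(t_flat, df)
    t = np.zeros((n, n))
    p = np.ones((n, n))
    t[iu, ju] = t_flat
    t[ju, iu] = t_flat
    p[iu, ju] = p_flat
    p[ju, iu] = p_flat
    dfval = float(df[0]) if df.size else np.nan
    return EdgeStatResult(tstat=t, pvalue=p, tail=tail, df=dfval)


def bh_fdr(pvalues, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean rejection mask at FDR level q."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def ovl(mu1: float, mu2: float, sigma: float) -> float:
    """Overlap coefficient of N(mu1, sigma^2) and N(mu2, sigma^2).

    The shared area of the two densities: ``2 * Phi(-|mu1 - mu2| / (2 sigma))``.
    Equals 1 for identical means; for sigma = 1 it maps a planted
    contrast-to-noise ratio to the overlap with the noise distribution.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(2 * sps.norm.cdf(-abs(mu1 - mu2) / (2 * sigma)))
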