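"""Cross-validated subnetwork-based classification (NBS-predict style).

Within every training fold a subnetwork is extracted (node tests + edge
tests on the training subjects only -- feature selection never sees the test
fold), the functional edge weights of the selected edges are the features of
a binary classifier, and the test-fold accuracy is recorded.  Each selected
edge accumulates the accuracy of the folds that selected it; the accumulated
matrix, averaged over all r*K folds and rescaled to a maximum of 1, is the
edge prediction-weight matrix.  Significance of the mean accuracy is
assessed by re-running the whole procedure under random relabelings of the
subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression, RidgeClassifier, SGDClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .cohort import Cohort, Subnetwork
from .extract import (
    ExtractionConfig,
    central_node_set,
    d_intersection,
    fdr_extract,
    nbs,
    suprathreshold_edges,
)
from .nodeprops import PropertyMatrix, property_matrix
from .stats import EdgeStatResult, _two_sample_t
from scipy import stats as sps

__all__ = [
    "CVConfig",
    "PredictionResult",
    "CLASSIFIERS",
    "make_classifier",
    "run_cv",
    "threshold_edge_weights",
    "permutation_test",
]

#: classifier zoo: library defaults, no hyperparameter optimization
CLASSIFIERS = {
    "logistic": lambda seed: LogisticRegression(max_iter=2000, random_state=seed),
    "ridge": lambda seed: RidgeClassifier(random_state=seed),
    "svm": lambda seed: LinearSVC(random_state=seed),
    "tree": lambda seed: DecisionTreeClassifier(random_state=seed),
    "knn": lambda seed: KNeighborsClassifier(),
    "gnb": lambda seed: GaussianNB(),
    "sgd": lambda seed: SGDClassifier(random_state=seed),
    "lda": lambda seed: LinearDiscriminantAnalysis(),
}


def make_classifier(name_or_estimator, seed: int = 0):
    """Instantiate a classifier from the zoo, or clone a given estimator."""
    if isinstance(name_or_estimator, str):
        try:
            return CLASSIFIERS[name_or_estimator](seed)
        except KeyError:
            raise ValueError(
                f"unknown classifier {name_or_estimator!r}; "
                f"choose from {sorted(CLASSIFIERS)}"
            ) from None
    return clone(name_or_estimator)


@dataclass
class CVConfig:
    """Repeated stratified K-fold configuration."""

    extraction: ExtractionConfig
    method: str = "nbs_sni"  # nbs_sni | nbs | fdr
    q: float = 0.05          # FDR level when method == 'fdr'
    classifier: str = "logistic"
    K: int = 15
    r: int = 25
    seed: int = 0
    balanced_accuracy: bool = False

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.r < 1:
            raise ValueError("r must be >= 1")


@dataclass
class PredictionResult:
    """Per-fold accuracies, their summary, and the edge prediction weights.

    ``mu_performance``/``sigma_performance`` are the mean and SD of the ``r``
    repetition-level mean accuracies.  ``edge_weight`` is an (n, n) symmetric
    matrix in [0, 1] (maximum exactly 1 whenever any edge was ever selected).
    """

    accuracies: np.ndarray          # (r, K)
    mu_performance: float
    sigma_performance: float
    edge_weight: np.ndarray
    selected_counts: np.ndarray     # (r, K) edges selected per fold
    config: CVConfig | None = None


def _pair_indices(n: int):
    return np.triu_indices(n, k=1)


def _edge_result_from_flat(t_flat, p_flat, n, tail) -> EdgeStatResult:
    iu, ju = _pair_indices(n)
    t = np.zeros((n, n))
    p = np.ones((n, n))
    t[iu, ju] = t_flat
    t[ju, iu] = t_flat
    p[iu, ju] = p_flat
    p[ju, iu] = p_flat
    return EdgeStatResult(tstat=t, pvalue=p, tail=tail)


def _select_edges(
    x_train: np.ndarray,
    prop_train: np.ndarray,
    y_train: np.ndarray,
    cfg: CVConfig,
    n: int,
) -> np.ndarray:
    """Training-fold subnetwork extraction; returns a boolean pair mask."""
    ecfg = cfg.extraction
    t_flat, df = _two_sample_t(x_train[y_train == 1], x_train[y_train == 0],
                               ecfg.equal_var)
    if ecfg.tail == "hypo":
        t_flat = -t_flat
    p_flat = sps.t.sf(t_flat, df)
    edge_result = _edge_result_from_flat(t_flat, p_flat, n, ecfg.tail)
    if cfg.method == "nbs_sni":
        p1 = PropertyMatrix(prop_train[y_train == 1], ecfg.node_property, "group1")
        p2 = PropertyMatrix(prop_train[y_train == 0], ecfg.node_property, "group2")
        central = central_node_set(p1, p2, ecfg)
        edges = suprathreshold_edges(edge_result, ecfg.t_edge)
        sub = d_intersection(edges, central, ecfg.d, n=n)
    elif cfg.method == "nbs":
        sub = nbs(edge_result, ecfg.t_edge)
    elif cfg.method == "fdr":
        sub = fdr_extract(edge_result, cfg.q)
    else:
        raise ValueError(f"unknown method {cfg.method!r}")
    iu, ju = _pair_indices(n)
    mask = np.zeros(iu.size, dtype=bool)
    if sub.edges:
        pair_id = {(int(u), int(v)): i for i, (u, v) in enumerate(zip(iu, ju))}
        mask[[pair_id[e] for e in sub.edges]] = True
    return mask


def _accuracy(y_true, y_pred, balanced: bool) -> float:
    if balanced:
        accs = [np.mean(y_pred[y_true == c] == c) for c in np.unique(y_true)]
        return float(np.mean(accs))
    return float(np.mean(y_pred == y_true))


def _run_cv_arrays(
    x: np.ndarray,
    prop: np.ndarray,
    y: np.ndarray,
    cfg: CVConfig,
    rng: np.random.Generator,
) -> PredictionResult:
    n_subj, n_pairs = x.shape
    n = prop.shape[1]
    accs = np.zeros((cfg.r, cfg.K))
    counts = np.zeros((cfg.r, cfg.K), dtype=int)
    weight_sum = np.zeros(n_pairs)
    warned_empty = False
    for rep in range(cfg.r):
        skf = StratifiedKFold(
            n_splits=cfg.K, shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        for fold, (tr, te) in enumerate(skf.split(x, y)):
            mask = _select_edges(x[tr], prop[tr], y[tr], cfg, n)
            counts[rep, fold] = int(mask.sum())
            if mask.any():
                clf = make_classifier(cfg.classifier,
                                      seed=int(rng.integers(0, 2**31 - 1)))
                clf.fit(x[np.ix_(tr, np.flatnonzero(mask))], y[tr])
                y_pred = clf.predict(x[np.ix_(te, np.flatnonzero(mask))])
            else:
                if not warned_empty:
                    warnings.warn("empty subnetwork in a fold; majority-class "
                                  "prediction used", stacklevel=2)
                    warned_empty = True
                maj = np.bincount(y[tr]).argmax()
                y_pred = np.full(te.size, maj)
            acc = _accuracy(y[te], y_pred, cfg.balanced_accuracy)
            accs[rep, fold] = acc
            weight_sum += mask * acc
    rep_means = accs.mean(axis=1)
    mean_weight = weight_sum / (cfg.r * cfg.K)
    if mean_weight.max() > 0:
        mean_weight = mean_weight / mean_weight.max()
    iu, ju = _pair_indices(n)
    ew = np.zeros((n, n))
    ew[iu, ju] = mean_weight
    ew[ju, iu] = mean_weight
    return PredictionResult(
        accuracies=accs,
        mu_performance=float(rep_means.mean()),
        sigma_performance=float(rep_means.std(ddof=1)) if cfg.r > 1 else 0.0,
        edge_weight=ew,
        selected_counts=counts,
        config=cfg,
    )


def _cohort_arrays(cohort: Cohort, cfg: CVConfig):
    ecfg = cfg.extraction
    n = cohort.n
    iu, ju = _pair_indices(n)
    subjects = cohort.subjects
    x = np.stack([s.functional[iu, ju] for s in subjects])
    if cfg.method == "nbs_sni":
        pm = property_matrix(subjects, ecfg.node_property,
                             source=ecfg.prop_source, **ecfg.prop_kwargs)
        prop = pm.values
    else:
        prop = np.zeros((len(subjects), n))
    y = np.array([1] * len(cohort.group1) + [0] * len(cohort.group2))
    return x, prop, y


def run_cv(
    cohort: Cohort,
    cfg: CVConfig,
    rng: np.random.Generator | None = None,
) -> PredictionResult:
    """Repeated stratified K-fold classification with in-fold subnetwork
    feature selection.

    Node properties are computed once per subject (they depend only on that
    subject's own matrices); all *statistics* -- node tests, edge tests,
    thresholds -- are recomputed inside each training fold, so the selected
    feature mask never uses test-fold information.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    x, prop, y = _cohort_arrays(cohort, cfg)
    return _run_cv_arrays(x, prop, y, cfg, rng)


def threshold_edge_weights(
    result: PredictionResult,
    w_min: float,
    degree_percentile: float | None = None,
) -> Subnetwork:
    """Edges whose prediction weight is >= ``w_min``.

    ``degree_percentile`` (e.g. 0.95) optionally keeps only the
    ``ceil((1 - pct) * n)`` highest-degree nodes of the thresholded graph
    and the edges between them, for reporting dense results.
    """
    if not (0 <= w_min <= 1):
        raise ValueError("w_min must be in [0, 1]")
    ew = result.edge_weight
    n = ew.shape[0]
    iu, ju = _pair_indices(n)
    keep = ew[iu, ju] >= w_min
    if w_min == 0:
        keep &= ew[iu, ju] > 0  # "all ever-selected edges"
    edges = set(zip(iu[keep].tolist(), ju[keep].tolist()))
    if degree_percentile is not None:
        deg = np.zeros(n, dtype=int)
        for u, v in edges:
            deg[u] += 1
            deg[v] += 1
        n_keep = int(np.ceil((1.0 - degree_percentile) * n))
        top = set(np.argsort(-deg, kind="stable")[:n_keep].tolist())
        edges = {e for e in edges if e[0] in top and e[1] in top}
    return Subnetwork.from_pairs(
        edges, provenance={"w_min": w_min, "degree_percentile": degree_percentile},
    )


def permutation_test(
    cohort: Cohort,
    cfg: CVConfig,
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
    observed: PredictionResult | None = None,
) -> tuple[float, np.ndarray, PredictionResult]:
    """Permutation significance of the mean CV accuracy.

    Group labels are randomly reassigned (group sizes preserved) and the
    whole nested CV is re-run per permutation; the p-value is the fraction
    of permutations whose mean accuracy reaches the observed one,
    ``#(mu_null >= mu_obs) / n_perm``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    x, prop, y = _cohort_arrays(cohort, cfg)
    if observed is None:
        observed = _run_cv_arrays(x, prop, y, cfg, rng)
    null = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        null[i] = _run_cv_arrays(x, prop, y_perm, cfg, rng).mu_performance
    p = float(np.mean(null >= observed.mu_performance))
    return p, null, observed
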