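"""Polarity-invariant modified k-means over GFP-peak topographies.

Microstate clustering treats a scalp map and its polarity reversal as
the same state: assignment uses the absolute spatial correlation, and
each cluster's template is the dominant eigenvector of the outer-product
sum of its member maps (the polarity-invariant analogue of the mean).
Model order is selected by the predictive-residual cross-validation
criterion, with the explained-variance (GEV) curve reported alongside.
Clustering runs at two levels: per subject (and condition), then on the
pooled subject templates to obtain the group classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import TemplateSet

__all__ = [
    "spatial_correlation",
    "modified_kmeans",
    "gev",
    "choose_k",
    "two_level_clustering",
    "pair_conditions",
    "assign_maps",
    "ClusterFitReport",
]

#: Default restart count for modified k-means.
N_RESTARTS = 50
#: Convergence tolerance on the GEV improvement.
TOL = 1e-6
#: Iteration cap per restart.
MAX_ITER = 300
#: Fraction of peak maps resampled per restart (stability); the winning
#: restart is refit on the full set.
SUBSAMPLE = 0.9


def _zero_mean(maps: np.ndarray) -> np.ndarray:
    return maps - maps.mean(axis=-1, keepdims=True)


def _normalize(maps: np.ndarray) -> np.ndarray:
    m = _zero_mean(np.asarray(maps, dtype=float))
    norms = np.linalg.norm(m, axis=-1, keepdims=True)
    if (norms < 1e-300).any():
        raise ValueError("zero-variance map cannot be normalized")
    return m / norms


def spatial_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation of two topographies across channels.

    Polarity-invariant comparisons take the absolute value of this.
    Raises on zero-variance input.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("topographies must have equal channel counts")
    un = _normalize(u)
    vn = _normalize(v)
    return float(np.clip(un @ vn, -1.0, 1.0))


def _corr_matrix(maps: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """(n_maps, K) spatial correlations; both inputs normalized internally."""
    return _normalize(maps) @ _normalize(templates).T


def assign_maps(maps: np.ndarray, templates: TemplateSet) -> tuple[np.ndarray, np.ndarray]:
    """Winner-takes-all assignment by absolute spatial correlation.

    Returns (labels, abs_corr_of_winner).  Ties break to the lowest
    class index.
    """
    c = _corr_matrix(maps, templates.maps)
    labels = np.argmax(np.abs(c), axis=1)
    fit = np.abs(c)[np.arange(c.shape[0]), labels]
    return labels, fit


def gev(
    maps: np.ndarray,
    templates: TemplateSet,
    assignment: np.ndarray,
    gfp: np.ndarray | None = None,
) -> float:
    """Global explained variance of an assignment.

    GEV = sum_t (GFP_t * corr(map_t, template_{L_t}))^2 / sum_t GFP_t^2,
    with GFP_t the population standard deviation of map t across
    channels (recomputed if not supplied).
    """
    maps = _zero_mean(np.asarray(maps, dtype=float))
    if gfp is None:
        gfp = maps.std(axis=1, ddof=0)
    assignment = np.asarray(assignment, dtype=int)
    corr = np.einsum(
        "nc,nc->n", _normalize(maps), _normalize(templates.maps)[assignment]
    )
    denom = float(np.sum(gfp**2))
    if denom == 0:
        return 0.0
    return float(np.sum((gfp * corr) ** 2) / denom)


def _principal_map(x: np.ndarray) -> np.ndarray:
    """Dominant eigenvector of sum_t x_t x_t' — the polarity-invariant
    centroid — returned zero-mean, unit-norm."""
    # svd on (n, C) is cheaper than forming the C x C scatter for small n
    if x.shape[0] < x.shape[1]:
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        v = vt[0]
    else:
        s = x.T @ x
        w, vecs = np.linalg.eigh(s)
        v = vecs[:, -1]
    v = v - v.mean()
    n = np.linalg.norm(v)
    if n < 1e-300:
        raise ValueError("degenerate cluster: principal map has zero variance")
    return v / n


def _kmeans_once(
    maps_n: np.ndarray,
    gfp: np.ndarray,
    k: int,
    init: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One modified k-means run.  maps_n are normalized peak maps.

    Returns (templates (k, C), labels, gev).
    """
    t = init.copy()
    denom = float(np.sum(gfp**2))
    prev_gev = -np.inf
    labels = np.zeros(maps_n.shape[0], dtype=int)
    for _ in range(max_iter):
        c = maps_n @ t.T
        labels = np.argmax(np.abs(c), axis=1)
        # re-seed empty clusters from the worst-fit map
        fit = np.abs(c)[np.arange(c.shape[0]), labels]
        for j in range(k):
            if not (labels == j).any():
                worst = int(np.argmin(fit))
                t[j] = maps_n[worst]
                labels[worst] = j
                fit[worst] = np.inf  # keep later reseeds off this map
        for j in range(k):
            members = labels == j
            t[j] = _principal_map(maps_n[members] * gfp[members, None])
        c = maps_n @ t.T
        labels = np.argmax(np.abs(c), axis=1)
        corr = np.abs(c)[np.arange(c.shape[0]), labels]
        cur_gev = float(np.sum((gfp * corr) ** 2) / denom) if denom else 0.0
        if cur_gev - prev_gev < tol:
            break
        prev_gev = cur_gev
    return t, labels, cur_gev


def _canonical_partitions(n: int, k: int):
    """All surjective labelings of n items into k unordered groups,
    one canonical representative per partition (first occurrences of
    group indices appear in increasing order)."""
    from itertools import product

    for lab in product(range(k), repeat=n):
        lab = np.asarray(lab)
        seen: list[int] = []
        for x in lab:
            if x not in seen:
                seen.append(int(x))
        if seen == list(range(k)):
            yield lab


def modified_kmeans(
    peaks: np.ndarray,
    k: int,
    n_restarts: int = N_RESTARTS,
    tol: float = TOL,
    seed: int = 0,
    max_iter: int = MAX_ITER,
    subsample: float = SUBSAMPLE,
) -> TemplateSet:
    """Cluster GFP-peak topographies into k polarity-invariant templates.

    Each restart clusters a random ``subsample`` fraction of the peak
    maps (a resampling step that stabilizes the solution), candidates are
    scored by GEV on the full set, and the best candidate is refit on all
    maps to convergence.  Restarts are seeded deterministically.

    Parameters
    ----------
    peaks
        (n_maps, n_channels) topographies at GFP peaks.
    k
        Number of clusters; must not exceed the number of maps.
    """
    peaks = _zero_mean(np.asarray(peaks, dtype=float))
    n, n_ch = peaks.shape
    if k > n:
        raise ValueError(f"k={k} exceeds the number of peak maps {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    gfp_w = peaks.std(axis=1, ddof=0)
    maps_n = _normalize(peaks)
    rng = np.random.default_rng(seed)

    n_sub = max(k, int(round(subsample * n)))
    # Tiny inputs: initialize one run from the centroids of EVERY
    # k-partition.  Each k-means step is monotone in GEV, so the best run
    # is guaranteed to attain the exhaustive-partition optimum.
    inits: list[np.ndarray] | None = None
    if k**n <= 8192:
        inits = [
            np.array([_principal_map(peaks[lab == j]) for j in range(k)])
            for lab in _canonical_partitions(n, k)
        ]
    best: tuple[float, np.ndarray] | None = None
    for r in range(len(inits) if inits is not None else n_restarts):
        if inits is not None:
            idx = np.arange(n)
            init = inits[r]
        elif n_sub < n:
            idx = rng.choice(n, size=n_sub, replace=False)
            init = maps_n[rng.choice(idx, size=k, replace=False)]
        else:
            idx = np.arange(n)
            init = maps_n[rng.choice(idx, size=k, replace=False)]
        t, _, _ = _kmeans_once(
            maps_n[idx], gfp_w[idx], k, init, tol, max_iter
        )
        # score candidate on the full peak set
        c = maps_n @ t.T
        lab = np.argmax(np.abs(c), axis=1)
        corr = np.abs(c)[np.arange(n), lab]
        g_full = float(np.sum((gfp_w * corr) ** 2) / np.sum(gfp_w**2))
        if best is None or g_full > best[0]:
            best = (g_full, t)
    # consensus refit of the winner on the full set
    t, labels, g = _kmeans_once(maps_n, gfp_w, k, best[1], tol, max_iter)
    return TemplateSet(maps=t, gev=g)


@dataclass
class ClusterFitReport:
    """Model-order scan: GEV and cross-validation criterion per k."""

    k_range: tuple[int, ...]
    gev_per_k: np.ndarray
    criterion_per_k: np.ndarray
    chosen_k: int
    n_restarts: int
    seed: int
    templates_per_k: dict[int, TemplateSet]

    def best_templates(self) -> TemplateSet:
        return self.templates_per_k[self.chosen_k]


def _cv_criterion(peaks: np.ndarray, templates: TemplateSet, labels: np.ndarray) -> float:
    """Predictive residual variance penalizing model order.

    sigma2 = sum_t (|x_t|^2 - (a_{L_t}' x_t)^2) / (T (C - 1)), scaled by
    ((C - 1) / (C - 1 - K))^2; smaller is better.  Undefined (inf) when
    K >= C - 1.
    """
    x = _zero_mean(np.asarray(peaks, float))
    n, c = x.shape
    k = templates.k
    if k >= c - 1:
        return np.inf
    a = _normalize(templates.maps)[labels]
    resid = max(0.0, float(np.sum(x**2) - np.sum(np.einsum("nc,nc->n", a, x) ** 2)))
    sigma2 = resid / (n * (c - 1))
    return float(sigma2 * ((c - 1) / (c - 1 - k)) ** 2)


def choose_k(
    peaks: np.ndarray,
    k_range: Sequence[int] = range(1, 13),
    seed: int = 0,
    n_restarts: int = N_RESTARTS,
    force_k: int | None = None,
    parsimony: float = 0.05,
) -> ClusterFitReport:
    """Fit every k in ``k_range`` and select the model order.

    Selection minimizes the cross-validation criterion with a parsimony
    rule: the smallest k whose criterion lies within a relative
    ``parsimony`` tolerance of the minimum is chosen (spatially
    correlated residuals flatten the criterion beyond the true order, so
    the plain argmin over-selects).  The GEV curve is reported for
    inspection, and ``force_k`` overrides the automatic choice (the
    curves are still computed).
    """
    k_range = tuple(int(k) for k in k_range)
    if not k_range:
        raise ValueError("empty k_range")
    gevs, crit = [], []
    templates_per_k: dict[int, TemplateSet] = {}
    for k in k_range:
        ts = modified_kmeans(peaks, k, n_restarts=n_restarts, seed=seed + k)
        labels, _ = assign_maps(peaks, ts)
        gevs.append(ts.gev)
        crit.append(_cv_criterion(peaks, ts, labels))
        templates_per_k[k] = ts
    crit_arr = np.asarray(crit)
    if force_k is not None:
        if force_k not in k_range:
            raise ValueError(f"force_k={force_k} not in k_range")
        chosen = int(force_k)
    else:
        cmin = float(np.min(crit_arr))
        within = np.flatnonzero(crit_arr <= cmin + parsimony * abs(cmin) + 1e-15)
        chosen = int(k_range[int(within[0])])
    return ClusterFitReport(
        k_range=k_range,
        gev_per_k=np.asarray(gevs),
        criterion_per_k=crit_arr,
        chosen_k=chosen,
        n_restarts=n_restarts,
        seed=seed,
        templates_per_k=templates_per_k,
    )


def two_level_clustering(
    subject_peaks: Mapping[object, np.ndarray],
    k: int,
    seed: int = 0,
    n_restarts: int = N_RESTARTS,
) -> tuple[TemplateSet, dict[object, TemplateSet]]:
    """Subject-level then group-level clustering.

    Stage 1 clusters each subject's GFP-peak maps into k templates;
    stage 2 clusters the pooled subject templates (each unit-norm, hence
    equally weighted) into the k group templates with the same
    polarity-invariant algorithm.
    """
    if len(subject_peaks) < 2:
        raise ValueError("two-level clustering needs at least 2 subjects")
    subject_sets: dict[object, TemplateSet] = {}
    for i, (subj, peaks) in enumerate(sorted(subject_peaks.items(), key=lambda x: str(x[0]))):
        subject_sets[subj] = modified_kmeans(
            peaks, k, n_restarts=n_restarts, seed=seed + 1000 * (i + 1)
        )
    pooled = np.vstack([ts.maps for ts in subject_sets.values()])
    group = modified_kmeans(
        pooled, k, n_restarts=n_restarts, seed=seed, subsample=1.0
    )
    return group, subject_sets


def pair_conditions(
    set_a: TemplateSet, set_b: TemplateSet
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one pairing of classes between two template sets.

    Maximizes the total absolute spatial correlation (Hungarian
    algorithm).  Returns ``(pairing, corr_matrix)`` where class i of
    ``set_a`` pairs with class ``pairing[i]`` of ``set_b`` and
    ``corr_matrix`` is the full K x K matrix of absolute correlations.
    """
    if set_a.k != set_b.k:
        raise ValueError("template sets must have equal K")
    c = np.abs(_corr_matrix(set_a.maps, set_b.maps))
    _, cols = linear_sum_assignment(-c)
    return cols, c
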