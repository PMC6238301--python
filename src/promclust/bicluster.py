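"""Base biclustering engines.

Two engines with a common contract (randomized, seedable, returning a
set of coupled row/column clusters):

* ``run_ssvd`` — sparse rank-1 SVD layers with randomized stability
  selection.  Each layer alternates thresholded estimation of the
  left and right singular vectors, with the support size chosen by a
  BIC-type criterion; the layer's row/column support is then the set
  of elements selected in at least ``stability_threshold`` of random
  row/column subsamples whose leading layer matches.  Layers are
  removed by rank-1 deflation on the support and extraction repeats.

* ``kmeans_biclust`` — k-means on the columns (promoters) followed by a
  per-row Welch t-test (inside vs outside each column cluster); rows
  with p below ``alpha`` form the row cluster coupled to that column
  cluster.  A row may join several clusters.

Both operate on an experiments x promoters matrix of values in [0, 1]
but make no use of that range beyond finite-ness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .signal import SignalMatrix
from .stats import welch_t

__all__ = [
    "Bicluster", "BiclusterSolution", "SSVDParams",
    "ssvd_layer", "run_ssvd", "choose_k", "kmeans_biclust",
]


@dataclass(frozen=True)
class Bicluster:
    """A coupled row/column cluster: a coherent submatrix."""

    rows: tuple[int, ...]
    cols: tuple[int, ...]
    score: float  # leading singular value of the submatrix

    def __post_init__(self) -> None:
        if not self.rows or not self.cols:
            raise ValueError("bicluster must have non-empty rows and cols")


@dataclass
class BiclusterSolution:
    biclusters: list[Bicluster]
    n_rows: int
    n_cols: int
    seed: int | None = None
    engine: str = "ssvd"

    @property
    def n_clusters(self) -> int:
        return len(self.biclusters)

    def col_labels(self) -> np.ndarray:
        """Per-column cluster index; -1 for unassigned."""
        lab = np.full(self.n_cols, -1, dtype=int)
        for k, bc in enumerate(self.biclusters):
            lab[list(bc.cols)] = k
        return lab

    @property
    def unassigned_cols(self) -> tuple[int, ...]:
        return tuple(np.flatnonzero(self.col_labels() < 0))

    @property
    def unassigned_rows(self) -> tuple[int, ...]:
        used = set()
        for bc in self.biclusters:
            used.update(bc.rows)
        return tuple(i for i in range(self.n_rows) if i not in used)

    def to_dict(self) -> dict:
        return {
            "engine": self.engine, "seed": self.seed,
            "n_rows": self.n_rows, "n_cols": self.n_cols,
            "biclusters": [
                {"rows": list(bc.rows), "cols": list(bc.cols),
                 "score": bc.score} for bc in self.biclusters
            ],
        }


@dataclass
class SSVDParams:
    subsample_fraction: float = 0.5
    n_subsamples: int = 100
    stability_threshold: float = 0.6
    bic_penalty: float = 2.0       # multiplier on the log(mn) support penalty
    max_alternations: int = 15
    min_score: float = 1e-8        # layer strength below which extraction stops


def _values(matrix) -> np.ndarray:
    if isinstance(matrix, SignalMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=float)


def _bic_threshold(z: np.ndarray, total: int, sigma2: float,
                   penalty: float = 2.0) -> np.ndarray:
    """Hard-threshold ``z`` at the support size minimizing a BIC-type
    criterion; returns the sparse vector.

    ``z`` is the unthresholded update (X v or X^T u).  Every support
    size k is a candidate: keeping the k largest |z| entries leaves a
    residual sum of squares sum_{i>k} z_i^2, traded against
    k * penalty * log(mn), with the noise level ``sigma2`` estimated
    from the dense rank-1 residual of the matrix.  The marginal gain
    of the k-th entry is z_(k)^2, so the rule is an entrywise cut at
    sigma * sqrt(penalty * log(mn)).
    """
    az = np.abs(z)
    if az.max() == 0.0:
        return z
    a = np.sort(az)[::-1]
    n = a.size
    # tail[k] = sum of squares of the killed entries a[k:]
    sq = a * a
    tail = np.concatenate([np.cumsum(sq[::-1])[::-1], [0.0]])
    k = np.arange(1, n + 1)
    rss = tail[1:]
    sigma2 = max(sigma2, 1e-12)
    bic = rss / sigma2 + k * penalty * np.log(max(total, 2))
    k_best = int(k[np.argmin(bic)])
    lam = a[k_best - 1]
    return np.where(az >= lam, z, 0.0)


def _sparse_rank1(x: np.ndarray, params: SSVDParams,
                  rng: np.random.Generator):
    """Sparse leading rank-1 factorisation of ``x``.

    Returns ``(row_support, col_support, score)`` or ``None`` when the
    matrix has no appreciable rank-1 structure.
    """
    m, n = x.shape
    norm = np.linalg.norm(x)
    if norm < params.min_score:
        return None
    # leading right singular vector by power iteration (seeded start)
    v = rng.standard_normal(n)
    v /= np.linalg.norm(v)
    for _ in range(30):
        u = x @ v
        nu = np.linalg.norm(u)
        if nu == 0:
            return None
        u /= nu
        v_new = x.T @ u
        nv = np.linalg.norm(v_new)
        if nv == 0:
            return None
        v_new /= nv
        if np.abs(v_new @ v) > 1 - 1e-10:
            v = v_new
            break
        v = v_new
    total = m * n
    # noise level from the dense rank-1 residual
    u = x @ v
    s0 = np.linalg.norm(u)
    u = u / s0 if s0 > 0 else u
    resid = x - s0 * np.outer(u, v)
    dof = max(total - m - n, 1)
    sigma2 = float(np.sum(resid * resid)) / dof
    prev = (None, None)
    for _ in range(params.max_alternations):
        u_s = _bic_threshold(x @ v, total, sigma2, params.bic_penalty)
        nu = np.linalg.norm(u_s)
        if nu == 0:
            return None
        u = u_s / nu
        v_s = _bic_threshold(x.T @ u, total, sigma2, params.bic_penalty)
        nv = np.linalg.norm(v_s)
        if nv == 0:
            return None
        v = v_s / nv
        sup = (tuple(np.flatnonzero(u_s)), tuple(np.flatnonzero(v_s)))
        if sup == prev:
            break
        prev = sup
    rows = np.flatnonzero(u_s)
    cols = np.flatnonzero(v_s)
    if rows.size == 0 or cols.size == 0:
        return None
    score = float(u @ x @ v)
    if abs(score) < params.min_score:
        return None
    return rows, cols, score


def ssvd_layer(matrix, seed: int | np.random.Generator = 0,
               params: SSVDParams | None = None) -> Bicluster | None:
    """Extract one stable sparse rank-1 bicluster, or ``None``.

    The sparse rank-1 fit is recomputed on ``n_subsamples`` random
    row/column subsamples; subsamples whose leading layer matches the
    full-matrix layer (majority of its selected rows and columns) vote
    on stability, and an element belongs to the layer if it is selected
    in at least ``stability_threshold`` of the matching subsamples that
    contained it.
    """
    x = _values(matrix)
    if not np.isfinite(x).all():
        raise ValueError("matrix contains non-finite values")
    params = params or SSVDParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m, n = x.shape
    full = _sparse_rank1(x, params, rng)
    if full is None:
        return None
    ref_rows = set(int(r) for r in full[0])
    ref_cols = set(int(c) for c in full[1])
    sel_rows = np.zeros(m)
    sel_cols = np.zeros(n)
    inc_rows = np.zeros(m)
    inc_cols = np.zeros(n)
    mr = max(2, int(round(params.subsample_fraction * m)))
    nc = max(2, int(round(params.subsample_fraction * n)))
    for _ in range(params.n_subsamples):
        ridx = rng.choice(m, size=mr, replace=False)
        cidx = rng.choice(n, size=nc, replace=False)
        res = _sparse_rank1(x[np.ix_(ridx, cidx)], params, rng)
        if res is None:
            continue
        got_rows = ridx[res[0]]
        got_cols = cidx[res[1]]
        # a subsample whose leading layer is a *different* structure
        # (e.g. another planted block) says nothing about this layer's
        # stability; only matching subsamples are scored
        row_match = np.mean([r in ref_rows for r in got_rows])
        col_match = np.mean([c in ref_cols for c in got_cols])
        if row_match < 0.5 or col_match < 0.5:
            continue
        inc_rows[ridx] += 1
        inc_cols[cidx] += 1
        sel_rows[got_rows] += 1
        sel_cols[got_cols] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_rows = np.where(inc_rows > 0, sel_rows / np.maximum(inc_rows, 1), 0.0)
        freq_cols = np.where(inc_cols > 0, sel_cols / np.maximum(inc_cols, 1), 0.0)
    rows = np.flatnonzero(freq_rows >= params.stability_threshold)
    cols = np.flatnonzero(freq_cols >= params.stability_threshold)
    if rows.size == 0 or cols.size == 0:
        return None
    sub = x[np.ix_(rows, cols)]
    score = float(np.linalg.svd(sub, compute_uv=False)[0])
    if score < params.min_score:
        return None
    return Bicluster(tuple(int(r) for r in rows), tuple(int(c) for c in cols), score)


def run_ssvd(matrix, max_layers: int = 10, seed: int = 0,
             params: SSVDParams | None = None) -> BiclusterSolution:
    """Repeated layer extraction with rank-1 deflation on the support.

    Columns (and rows) claimed by several layers are reassigned to the
    layer in which their mean original signal over the layer's rows
    (columns) is largest, so the final column sets partition a subset
    of the columns.
    """
    if max_layers < 1:
        raise ValueError("max_layers must be >= 1")
    x = _values(matrix).copy()
    orig = _values(matrix)
    params = params or SSVDParams()
    rng = np.random.default_rng(seed)
    layers: list[Bicluster] = []
    for _ in range(max_layers):
        bc = ssvd_layer(x, rng, params)
        if bc is None:
            break
        layers.append(bc)
        # deflate: subtract the rank-1 fit restricted to the support
        sub = x[np.ix_(bc.rows, bc.cols)]
        u, s, vt = np.linalg.svd(sub, full_matrices=False)
        x[np.ix_(bc.rows, bc.cols)] -= s[0] * np.outer(u[:, 0], vt[0])
    m, n = orig.shape
    # resolve overlaps: each column/row goes to its strongest layer
    col_owner = np.full(n, -1, dtype=int)
    col_strength = np.zeros(n)
    for k, bc in enumerate(layers):
        strength = orig[list(bc.rows)][:, list(bc.cols)].mean(axis=0)
        for c, st in zip(bc.cols, strength):
            if col_owner[c] < 0 or st > col_strength[c]:
                col_owner[c], col_strength[c] = k, st
    row_owner = np.full(m, -1, dtype=int)
    row_strength = np.zeros(m)
    for k, bc in enumerate(layers):
        strength = orig[list(bc.rows)][:, list(bc.cols)].mean(axis=1)
        for r, st in zip(bc.rows, strength):
            if row_owner[r] < 0 or st > row_strength[r]:
                row_owner[r], row_strength[r] = k, st
    final: list[Bicluster] = []
    for k, bc in enumerate(layers):
        rows = tuple(int(r) for r in np.flatnonzero(row_owner == k))
        cols = tuple(int(c) for c in np.flatnonzero(col_owner == k))
        if rows and cols:
            final.append(Bicluster(rows, cols, bc.score))
    return BiclusterSolution(final, m, n, seed=int(seed) if np.isscalar(seed) else None,
                             engine="ssvd")


def choose_k(matrix, k_range: tuple[int, int] = (2, 10), seed: int = 0,
             improvement: float = 0.05) -> int:
    """Elbow choice of k for column k-means.

    Returns the smallest k in ``k_range`` whose relative SSE
    improvement when moving to k+1 falls below ``improvement`` (5% by
    default); the largest k in range when no elbow is found; the
    smallest k when all columns are identical.
    """
    x = _values(matrix).T  # observations = columns (promoters)
    kmin, kmax = k_range
    if kmin > kmax:
        raise ValueError("invalid k_range")
    if np.allclose(x, x[0]):
        return kmin
    if kmin == kmax:
        return kmin
    sse: dict[int, float] = {}
    for k in range(kmin, min(kmax + 1, len(x) - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        km.fit(x)
        sse[k] = float(km.inertia_)
    for k in range(kmin, kmax + 1):
        if k + 1 not in sse or sse[k] == 0:
            break
        if (sse[k] - sse[k + 1]) / sse[k] < improvement:
            return k
    return kmax


def kmeans_biclust(matrix, k: int, alpha: float = 0.001,
                   seed: int = 0) -> BiclusterSolution:
    """k-means on columns + per-row Welch t-test row association.

    Every column is assigned to one of ``k`` column clusters
    (k-means++ initialisation, seeded).  For each column cluster, each
    row is tested (two-sided Welch, inside vs outside); rows with
    p < ``alpha`` join that cluster's row set.  Rows may join several
    clusters; clusters too small to test get an empty row set and are
    dropped (a bicluster needs rows).
    """
    x = _values(matrix)
    m, n = x.shape
    if not 2 <= k <= n:
        raise ValueError("k must be in [2, n_cols]")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(x.T)
    biclusters: list[Bicluster] = []
    for c in range(k):
        cols = np.flatnonzero(labels == c)
        out = np.flatnonzero(labels != c)
        if cols.size < 2 or out.size < 2:
            continue
        rows = []
        for i in range(m):
            t, p = welch_t(x[i, cols], x[i, out])
            if p < alpha and t > 0:
                rows.append(i)
        if not rows:
            continue
        sub = x[np.ix_(rows, cols)]
        score = float(np.linalg.svd(sub, compute_uv=False)[0])
        biclusters.append(Bicluster(tuple(rows), tuple(int(c_) for c_ in cols),
                                    score))
    return BiclusterSolution(biclusters, m, n, seed=seed, engine="kmeans_ttest")
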