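"""Moran's eigenvector maps and the MEMGENE-style spatial genetic regression.

The chain implemented here regresses multilocus genetic structure on
spatial eigenfunctions:

1. ``dps_distance`` — pairwise genetic dissimilarity, 1 minus the
   proportion of shared alleles (Dps).
2. ``pcoa`` — principal coordinates of the genetic distance, the response
   matrix Y for redundancy analysis.
3. ``MoransEigenvectorMaps`` — spatial eigenvectors of the truncated
   (PCNM-style, 4t convention) distance matrix; works for straight-line or
   least-cost distances alike.
4. ``forward_select`` — permutation forward selection with the double
   stopping criterion (marginal p <= alpha AND cumulative adjusted R² below
   the global adjusted R²), gated by a per-class global test.
5. ``MEMGeneRegression`` / ``mgquick`` — redundancy analysis of Y on the
   selected eigenvectors; the orthogonal axes of the fitted values are the
   spatial genetic axes ("MEMGENE axes"), with per-axis shares of explained
   variation and an Ezekiel-adjusted total R².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from .genotypes import MISSING, GenotypeTable

__all__ = [
    "GeneticDistance",
    "MEMBasis",
    "MemGeneResult",
    "dps_distance",
    "pcoa",
    "mem_basis",
    "forward_select",
    "MoransEigenvectorMaps",
    "MEMGeneRegression",
    "mgquick",
    "adjusted_r2",
    "rsq",
]

_EIG_TOL = 1e-10


@dataclass
class GeneticDistance:
    matrix: np.ndarray
    method: str = "Dps"


@dataclass
class MEMBasis:
    """Spatial eigenvectors of a truncated, Gower-centered distance matrix."""

    vectors: np.ndarray        # (n, k), orthonormal columns, zero-sum
    values: np.ndarray         # (k,), sorted descending
    truncation: float
    source: str = "euclidean"  # or "cost"

    @property
    def positive(self) -> np.ndarray:
        return np.flatnonzero(self.values > 0)

    @property
    def negative(self) -> np.ndarray:
        return np.flatnonzero(self.values < 0)


def dps_distance(table: GenotypeTable) -> GeneticDistance:
    """Genetic dissimilarity: 1 - proportion of shared alleles (Dps).

    For a pair, the proportion of shared alleles sums, over loci complete in
    both individuals, the size of the unordered intersection of the two
    allele pairs (0, 1 or 2), divided by twice the number of such loci.
    """
    al = table.alleles
    n, L, _ = al.shape
    if n < 2:
        raise ValueError("need at least two individuals")
    complete = ~(al == MISSING).all(axis=2)          # (n, L)
    srt = np.sort(al, axis=2)
    shared = np.zeros((n, n))
    joint = np.zeros((n, n))
    for j in range(L):
        a = srt[:, j, :]                             # (n, 2) sorted pairs
        both = complete[:, j][:, None] & complete[:, j][None, :]
        # min-matching count between unordered pairs {a1,a2} and {b1,b2}
        eq = a[:, None, :, None] == a[None, :, None, :]   # (n, n, 2, 2)
        same = (a[:, 0] == a[:, 1])                        # homozygote flags
        # shared = sum over distinct alleles of min(count_A, count_B)
        m01 = eq[:, :, 0, 0] | eq[:, :, 0, 1]
        m11 = eq[:, :, 1, 0] | eq[:, :, 1, 1]
        cnt = m01.astype(int) + m11.astype(int)
        # correct double counting when one side is homozygous:
        # e.g. AA vs AB shares 1, but both of AA's slots match A
        hom_i = same[:, None] & ~same[None, :]
        hom_j = ~same[:, None] & same[None, :]
        both_hom = same[:, None] & same[None, :]
        cnt = np.where((hom_i | hom_j) & (cnt == 2), 1, cnt)
        cnt = np.where(both_hom & (cnt > 0), 2, cnt)
        shared += np.where(both, cnt, 0)
        joint += both
    if np.any((joint == 0) & ~np.eye(n, dtype=bool)):
        bad = np.argwhere((joint == 0) & ~np.eye(n, dtype=bool))
        pairs = [tuple(table.individual_id[p] for p in b) for b in bad[:5]]
        raise ValueError(f"pairs with zero jointly complete loci: {pairs}")
    with np.errstate(invalid="ignore", divide="ignore"):
        psa = shared / (2 * joint)
    D = 1.0 - psa
    np.fill_diagonal(D, 0.0)
    return GeneticDistance(matrix=D, method="Dps")


def _gower_center(D: np.ndarray) -> np.ndarray:
    """Gower double-centering of -D^2/2."""
    A = -0.5 * D**2
    rm = A.mean(axis=1, keepdims=True)
    cm = A.mean(axis=0, keepdims=True)
    return A - rm - cm + A.mean()


def pcoa(D: GeneticDistance | np.ndarray):
    """Principal coordinates of a distance matrix.

    Axes with eigenvalue > 1e-10 x the largest are retained; coordinates
    are eigenvectors scaled by sqrt(eigenvalue).  Returns (coordinates,
    eigenvalues).
    """
    M = D.matrix if isinstance(D, GeneticDistance) else np.asarray(D, float)
    G = _gower_center(M)
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if vals[0] <= 0:
        raise ValueError("no positive eigenvalues: degenerate distance matrix")
    keep = vals > _EIG_TOL * vals[0]
    return vecs[:, keep] * np.sqrt(vals[keep]), vals[keep]


def mem_basis(Dspatial: np.ndarray, truncation="auto", source: str = "euclidean") -> MEMBasis:
    """Moran's eigenvector maps from a spatial distance matrix.

    The truncation threshold t defaults to the longest edge of the minimum
    spanning tree of the distances (guaranteeing connectivity); distances
    beyond t are replaced by 4t (the classical PCNM convention), and the
    modified matrix is Gower-centered and eigen-decomposed.  Eigenvectors
    with |eigenvalue| above 1e-10 x the largest are retained, classed as
    positive (broad-scale, positively autocorrelated) or negative by the
    sign of their eigenvalue.
    """
    D = np.asarray(Dspatial, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("Dspatial must be square symmetric")
    n = D.shape[0]
    mst = minimum_spanning_tree(csr_matrix(D))
    t_auto = mst.data.max() if mst.nnz else 0.0
    if truncation == "auto":
        t = float(t_auto)
    else:
        t = float(truncation)
        adj = (D <= t) & ~np.eye(n, dtype=bool)
        n_comp, _ = connected_components(csr_matrix(adj), directed=False)
        if n_comp > 1:
            raise ValueError(
                f"graph disconnected at truncation {t}: {n_comp} components"
            )
    if t <= 0:
        raise ValueError("degenerate configuration: zero truncation distance")
    Dstar = np.where(D <= t, D, 4.0 * t)
    np.fill_diagonal(Dstar, 0.0)
    G = _gower_center(Dstar)
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = np.abs(vals) > _EIG_TOL * np.abs(vals).max()
    return MEMBasis(vectors=vecs[:, keep], values=vals[keep], truncation=t, source=source)


class MoransEigenvectorMaps(BaseEstimator):
    """Spatial eigenvector basis construction as a (fit-only) transformer.

    Parameters
    ----------
    metric : 'euclidean' or 'precomputed'
        Whether ``X`` passed to :meth:`fit` is an (n, 2) coordinate array or
        an (n, n) distance matrix (e.g. least-cost distances).
    truncation : 'auto' or float
        Threshold t of the PCNM construction; 'auto' uses the longest
        minimum-spanning-tree edge.

    Attributes
    ----------
    eigenvectors_ : (n, k) orthonormal spatial eigenvectors
    eigenvalues_ : (k,) descending eigenvalues (sign = Moran's I class)
    truncation_ : the threshold actually used (meters or cost units)
    """

    def __init__(self, metric: str = "euclidean", truncation="auto"):
        self.metric = metric
        self.truncation = truncation

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.metric == "euclidean":
            if X.ndim != 2 or X.shape[1] != 2:
                raise ValueError("expected (n, 2) coordinates")
            D = squareform(pdist(X))
            source = "euclidean"
        elif self.metric == "precomputed":
            D = X
            source = "cost"
        else:
            raise ValueError("metric must be 'euclidean' or 'precomputed'")
        basis = mem_basis(D, truncation=self.truncation, source=source)
        self.basis_ = basis
        self.eigenvectors_ = basis.vectors
        self.eigenvalues_ = basis.values
        self.truncation_ = basis.truncation
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).eigenvectors_


# ---------------------------------------------------------------------------
# R² helpers
# ---------------------------------------------------------------------------


def adjusted_r2(r2: float, n: int, df: int) -> float:
    """Ezekiel adjustment: 1 - (1 - R²)(n - 1)/(n - df - 1)."""
    if n - df - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - df - 1)


def rsq(Y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Multivariate redundancy R² of (column-centered) Y on X.

    Returns (R², rank of the centered predictor matrix).  Handles
    rank-deficient X via an orthonormal column basis.
    """
    Y = np.asarray(Y, float)
    Y = Y - Y.mean(axis=0)
    sst = (Y**2).sum()
    if sst == 0:
        raise ValueError("constant response")
    if X is None or X.size == 0:
        return 0.0, 0
    X = np.asarray(X, float)
    Xc = X - X.mean(axis=0)
    Q, R = np.linalg.qr(Xc)
    diag = np.abs(np.diag(R))
    keep = diag > 1e-9 * max(diag.max(), 1.0)
    Q = Q[:, keep]
    ssf = ((Q.T @ Y) ** 2).sum()
    return float(ssf / sst), int(keep.sum())


# ---------------------------------------------------------------------------
# Forward selection
# ---------------------------------------------------------------------------


def forward_select(
    Y: np.ndarray,
    basis: MEMBasis,
    eigen_class: str = "positive",
    alpha: float = 0.05,
    n_perm: int = 1000,
    random_state=None,
    global_gate: bool = True,
) -> np.ndarray:
    """Permutation forward selection of MEM eigenvectors of one sign class.

    Selection proceeds only if the class-wide global permutation test is
    significant at ``alpha`` (gate against best-of-k anticonservatism).  A
    candidate (scanned in decreasing |eigenvalue| order, ties broken by
    lower index) is added only if (i) its marginal permutation p-value
    against the current residual is <= alpha and (ii) the cumulative
    adjusted R² does not exceed the adjusted R² of the full-class model —
    the classical double stopping criterion.

    Returns indices into ``basis.vectors`` columns (may be empty).
    """
    rng = np.random.default_rng(random_state)
    if eigen_class == "positive":
        cand = basis.positive
    elif eigen_class == "negative":
        cand = basis.negative
    else:
        raise ValueError("eigen_class must be 'positive' or 'negative'")
    if cand.size == 0:
        return np.array([], dtype=int)
    Y = np.asarray(Y, float)
    Y = Y - Y.mean(axis=0)
    n = Y.shape[0]
    sst = (Y**2).sum()
    V = basis.vectors[:, cand]                     # orthonormal, zero-sum
    # scan order: decreasing |eigenvalue|, then lower index
    scan = np.lexsort((cand, -np.abs(basis.values[cand])))
    V = V[:, scan]
    cand = cand[scan]
    k_all = V.shape[1]

    # global class test
    r2_global = ((V.T @ Y) ** 2).sum() / sst
    adj_global = adjusted_r2(r2_global, n, k_all)
    if global_gate:
        hits = 0
        for _ in range(n_perm):
            Yp = Y[rng.permutation(n)]
            if ((V.T @ Yp) ** 2).sum() / sst >= r2_global - 1e-12:
                hits += 1
        if (hits + 1) / (n_perm + 1) > alpha:
            return np.array([], dtype=int)

    selected: list[int] = []
    avail = list(range(k_all))
    R = Y.copy()
    r2_cum = 0.0
    while avail:
        # marginal contribution of each remaining candidate (orthonormal V)
        contrib = (V[:, avail].T @ R).reshape(len(avail), -1)
        delta = (contrib**2).sum(axis=1)
        best_pos = int(np.argmax(delta))          # scan order breaks ties
        best = avail[best_pos]
        v = V[:, best]
        # max-statistic permutation test: the candidate was the best of the
        # remaining scan, so its null distribution is the best of the
        # remaining scan under permutation of the current residual
        Va = V[:, avail]
        ssr = (R**2).sum()
        stat = float(np.sum((v @ R) ** 2)) / ssr
        hits = 0
        for _ in range(n_perm):
            Rp = R[rng.permutation(n)]
            null_max = float(((Va.T @ Rp) ** 2).reshape(len(avail), -1)
                             .sum(axis=1).max()) / ssr
            if null_max >= stat - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
        if p > alpha:
            break
        r2_new = r2_cum + float(np.sum((v @ Y) ** 2)) / sst
        selected.append(best)
        avail.remove(best)
        r2_cum = r2_new
        R = R - np.outer(v, v @ R)
        # adjusted-R² ceiling: once the cumulative adjusted R² reaches the
        # global model's, the crossing variable is the last one kept (the
        # df-penalized global value is a noisy ceiling; dropping the
        # crossing variable would systematically underfit compact models)
        if adjusted_r2(r2_cum, n, len(selected)) > adj_global + 1e-12:
            break
    return cand[np.array(selected, dtype=int)] if selected else np.array([], dtype=int)


# ---------------------------------------------------------------------------
# MEMGENE regression
# ---------------------------------------------------------------------------


@dataclass
class MemGeneResult:
    """Spatial genetic regression output.

    ``axes`` are orthogonal site-score axes of the fitted values (the
    spatial genetic patterns), ordered by their eigenvalues;
    ``axis_proportions`` are each axis's share of the explained variation
    (summing to 1 over retained axes); ``adj_r2`` is the Ezekiel-adjusted
    total proportion of genetic variation explained by space.
    """

    selected_positive: np.ndarray
    selected_negative: np.ndarray
    selected_vectors: np.ndarray   # (n, k) the union design matrix
    coefficients: np.ndarray       # (k, m) RDA coefficients
    axes: np.ndarray               # (n, a)
    axis_eigenvalues: np.ndarray
    axis_proportions: np.ndarray
    r2: float
    adj_r2: float
    p_value: float
    basis: MEMBasis = field(repr=False, default=None)

    @property
    def n_axes(self) -> int:
        return self.axes.shape[1]


class MEMGeneRegression(BaseEstimator):
    """mgQuick-equivalent spatial regression of genetic structure.

    fit(X, y): ``X`` is (n, 2) projected coordinates (or a precomputed
    spatial distance matrix with ``spatial_metric='precomputed'``); ``y`` is
    a GenotypeTable, an (n, n) genetic distance matrix, or an (n, m)
    response matrix (used as-is, no PCoA).

    Parameters
    ----------
    alpha : significance level for forward selection (default 0.05).
    n_perm : permutations for selection and the overall test (default 1000).
    use_negative : 'auto' selects negative-class eigenvectors only when
        their class-wide global test is significant; True/False force.
    axis_cap : optionally cap the number of principal-coordinate response
        axes (speed); None keeps all positive axes.
    random_state : seed for all permutations.

    Attributes (after fit)
    ----------------------
    result_ : MemGeneResult
    axes_, adj_r2_, p_value_ : convenience views of the result.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        n_perm: int = 1000,
        use_negative: str | bool = "auto",
        truncation="auto",
        spatial_metric: str = "euclidean",
        axis_cap: int | None = None,
        random_state=None,
    ):
        self.alpha = alpha
        self.n_perm = n_perm
        self.use_negative = use_negative
        self.truncation = truncation
        self.spatial_metric = spatial_metric
        self.axis_cap = axis_cap
        self.random_state = random_state

    def _response(self, y) -> np.ndarray:
        if isinstance(y, GenotypeTable):
            y = dps_distance(y)
        if isinstance(y, GeneticDistance):
            Y, _ = pcoa(y)
        else:
            y = np.asarray(y, dtype=float)
            if y.ndim == 1:
                y = y[:, None]
            if (
                y.ndim == 2
                and y.shape[0] == y.shape[1]
                and np.allclose(y, y.T, atol=1e-10)
                and np.allclose(np.diag(y), 0, atol=1e-10)
            ):
                Y, _ = pcoa(y)
            else:
                Y = y.copy()
        if self.axis_cap is not None:
            Y = Y[:, : self.axis_cap]
        return Y - Y.mean(axis=0)

    def fit(self, X, y):
        rng = np.random.default_rng(self.random_state)
        Y = self._response(y)
        n = Y.shape[0]
        mem = MoransEigenvectorMaps(
            metric=self.spatial_metric, truncation=self.truncation
        ).fit(X)
        basis = mem.basis_
        sel_pos = forward_select(
            Y, basis, "positive", self.alpha, self.n_perm, rng
        )
        if self.use_negative == "auto" or self.use_negative is True:
            sel_neg = forward_select(
                Y, basis, "negative", self.alpha, self.n_perm, rng
            )
            if self.use_negative == "auto" and sel_neg.size == 0:
                sel_neg = np.array([], dtype=int)
        else:
            sel_neg = np.array([], dtype=int)
        sel = np.concatenate([sel_pos, sel_neg]).astype(int)
        sst = (Y**2).sum()
        if sel.size == 0:
            self.result_ = MemGeneResult(
                selected_positive=sel_pos,
                selected_negative=sel_neg,
                selected_vectors=np.empty((n, 0)),
                coefficients=np.empty((0, Y.shape[1])),
                axes=np.empty((n, 0)),
                axis_eigenvalues=np.array([]),
                axis_proportions=np.array([]),
                r2=0.0,
                adj_r2=0.0,
                p_value=1.0,
                basis=basis,
            )
        else:
            Xs = basis.vectors[:, sel]
            B = Xs.T @ Y                       # orthonormal predictors
            F = Xs @ B                         # fitted values
            U, s, Vt = np.linalg.svd(F, full_matrices=False)
            keep = s**2 > 1e-12 * (s**2).max()
            keep &= np.arange(s.size) < sel.size
            axes = U[:, keep] * s[keep]
            r2 = float((s[keep] ** 2).sum() / sst)
            adj = adjusted_r2(r2, n, sel.size)
            hits = 0
            for _ in range(self.n_perm):
                Yp = Y[rng.permutation(n)]
                if ((Xs.T @ Yp) ** 2).sum() / sst >= r2 - 1e-12:
                    hits += 1
            p = (hits + 1) / (self.n_perm + 1)
            self.result_ = MemGeneResult(
                selected_positive=sel_pos,
                selected_negative=sel_neg,
                selected_vectors=Xs,
                coefficients=B,
                axes=axes,
                axis_eigenvalues=s[keep] ** 2,
                axis_proportions=(s[keep] ** 2) / (s[keep] ** 2).sum(),
                r2=r2,
                adj_r2=adj,
                p_value=p,
                basis=basis,
            )
        self.axes_ = self.result_.axes
        self.adj_r2_ = self.result_.adj_r2
        self.p_value_ = self.result_.p_value
        self.n_features_in_ = 2 if self.spatial_metric == "euclidean" else n
        return self

    def fit_transform(self, X, y):
        return self.fit(X, y).axes_


def mgquick(
    table: GenotypeTable,
    xy: np.ndarray | None = None,
    alpha: float = 0.05,
    n_perm: int = 1000,
    random_state=None,
    **kwargs,
) -> MemGeneResult:
    """Spatial genetic regression on a genotype table (mgQuick equivalent).

    Pipeline: Dps genetic distance -> principal coordinates (response) ->
    MEM basis on straight-line distances -> permutation forward selection
    (positive class; negative class when its global test is significant) ->
    redundancy analysis.  Returns a :class:`MemGeneResult`.
    """
    if xy is None:
        xy = table.xy
    if np.isnan(xy).any():
        raise ValueError("coordinates must be present for all individuals")
    est = MEMGeneRegression(
        alpha=alpha, n_perm=n_perm, random_state=random_state, **kwargs
    ).fit(xy, table)
    return est.result_
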