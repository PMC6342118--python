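"""Two-block variation partitioning by redundancy analysis.

Partitions the adjusted R² of a (possibly multivariate) response into the
unique fraction of each explanatory block, their confounded overlap, and a
residual:

    abc = adjR²(Y ~ X1 ∪ X2)     a = abc − adjR²(Y ~ X2)
    ab  = adjR²(Y ~ X1)          c = abc − adjR²(Y ~ X1)
    bc  = adjR²(Y ~ X2)          b = ab + bc − abc
                                 d = 1 − abc

so that a + b + c = abc and abc + d = 1 hold by construction.  Small
negative adjusted fractions are reported as computed (they are a known
feature of adjusted-R² partitioning, not clipped).

Significance: p(abc) permutes response rows; the partial fractions use
residualized-response permutation (rows of the residual of Y on the
conditioning block are permuted and added back to its fitted values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mem import adjusted_r2, rsq

__all__ = ["VariationPartition", "variation_partition"]


@dataclass
class VariationPartition:
    """Fractions of a two-block partition, Table-4/Table-5 style."""

    abc: float
    a: float
    b: float
    c: float
    d: float
    p_abc: float = np.nan
    p_a: float = np.nan
    p_c: float = np.nan
    label_1: str = "X1"
    label_2: str = "X2"

    def as_row(self) -> dict:
        return {
            "abc": self.abc, "p_abc": self.p_abc,
            "a": self.a, "p_a": self.p_a,
            "c": self.c, "p_c": self.p_c,
            "b": self.b, "d": self.d,
        }


def _fit(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares fitted values of centered Y on centered X."""
    Xc = X - X.mean(axis=0)
    Q, R = np.linalg.qr(Xc)
    diag = np.abs(np.diag(R))
    keep = diag > 1e-9 * max(diag.max(), 1.0)
    Q = Q[:, keep]
    return Q @ (Q.T @ Y)


def variation_partition(
    Y: np.ndarray,
    X1: np.ndarray,
    X2: np.ndarray,
    n_perm: int = 0,
    random_state=None,
    label_1: str = "X1",
    label_2: str = "X2",
) -> VariationPartition:
    """Partition adjusted R² of Y between explanatory blocks X1 and X2.

    Either block may be empty ((n, 0) array) — its R² is then 0.  With
    ``n_perm > 0``, permutation p-values are computed for the full model and
    for each unique fraction (partial tests).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Y = Y - Y.mean(axis=0)
    n = Y.shape[0]
    X1 = np.empty((n, 0)) if X1 is None else np.asarray(X1, float)
    X2 = np.empty((n, 0)) if X2 is None else np.asarray(X2, float)
    X12 = np.hstack([X1, X2])

    r2_1, k1 = rsq(Y, X1)
    r2_2, k2 = rsq(Y, X2)
    r2_12, k12 = rsq(Y, X12)
    ab = adjusted_r2(r2_1, n, k1) if k1 else 0.0
    bc = adjusted_r2(r2_2, n, k2) if k2 else 0.0
    abc = adjusted_r2(r2_12, n, k12) if k12 else 0.0
    a = abc - bc
    c = abc - ab
    b = ab + bc - abc
    d = 1.0 - abc

    p_abc = p_a = p_c = np.nan
    if n_perm > 0:
        rng = np.random.default_rng(random_state)
        if k12:
            hits = 0
            for _ in range(n_perm):
                Yp = Y[rng.permutation(n)]
                r2p, _ = rsq(Yp, X12)
                if r2p >= r2_12 - 1e-12:
                    hits += 1
            p_abc = (hits + 1) / (n_perm + 1)
        if k1:
            p_a = _partial_p(Y, X1, X2, r2_12 - r2_2, n_perm, rng)
        if k2:
            p_c = _partial_p(Y, X2, X1, r2_12 - r2_1, n_perm, rng)
    return VariationPartition(
        abc=abc, a=a, b=b, c=c, d=d,
        p_abc=p_abc, p_a=p_a, p_c=p_c,
        label_1=label_1, label_2=label_2,
    )


def _partial_p(Y, X_test, X_cond, stat_obs, n_perm, rng) -> float:
    """Residualized-response permutation test of X_test given X_cond."""
    n = Y.shape[0]
    if X_cond.shape[1]:
        fit_c = _fit(Y, X_cond)
    else:
        fit_c = np.zeros_like(Y)
    resid = Y - fit_c
    X_both = np.hstack([X_test, X_cond])
    hits = 0
    for _ in range(n_perm):
        Yp = fit_c + resid[rng.permutation(n)]
        r2_full, _ = rsq(Yp, X_both)
        r2_cond, _ = rsq(Yp, X_cond) if X_cond.shape[1] else (0.0, 0)
        if r2_full - r2_cond >= stat_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)
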