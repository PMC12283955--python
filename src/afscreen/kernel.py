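"""The distributional (two-level) Gaussian kernel between patients.

Each patient n contributes a variable-length sample x^(n) of normalized R-R
intervals, viewed as draws from an unknown distribution P^(n).  P^(n) is
represented by the empirical kernel mean embedding

    mu^(n) = (1/d_n) sum_i k(., x_i^(n)),        k(z1, z2) = exp[-(z1-z2)^2 / sigma^2],

and two patients are compared through the squared RKHS distance of their
embeddings, which expands into three kernel double-sums:

    ||mu^(n) - mu^(m)||^2 = (1/d_n^2)  sum_ij k(x_i^(n), x_j^(n))
                          + (1/d_m^2)  sum_ij k(x_i^(m), x_j^(m))
                          - (2/(d_n d_m)) sum_ij k(x_i^(n), x_j^(m)).

The second-level kernel consumed by the SVM is another Gaussian on that
distance, K = exp[-dist^2 / (2 gamma^2)].  Note the deliberate asymmetry of
the printed conventions: the base kernel divides by sigma^2 (no factor 2)
while the second-level kernel divides by 2 gamma^2.  Both bandwidths are free
hyperparameters, so the convention is harmless, and it is kept verbatim for
comparability.

Embeddings are never materialized as functions — every computation routes
through the double-sums above.  The two self-sums depend only on one patient
and sigma, so they are cached (``SelfTermCache``) and a full N x N Gram costs
a single cross-sum per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: squared distances more negative than this indicate an upstream bug rather
#: than floating-point cancellation
_NEG_TOL = 1e-12


@dataclass(frozen=True)
class KernelParams:
    """The two Gaussian bandwidths (unitless; RRi values are unitless)."""

    sigma: float
    gamma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")


def _values(x) -> np.ndarray:
    """Accept an RRiVector or any 1-D array-like of positive reals."""
    arr = np.asarray(getattr(x, "values", x), dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample vector")
    return arr


def _patient_id(x):
    return getattr(x, "patient_id", None) or None


def base_kernel(z1, z2, sigma: float):
    """Gaussian base kernel ``exp[-(z1-z2)^2 / sigma^2]`` (note: no factor 2)."""
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    return np.exp(-((z1 - z2) ** 2) / sigma ** 2)


@dataclass
class SelfTermCache:
    """Cache of per-patient self-sums s_n = (1/d_n^2) sum_ij k(x_i, x_j).

    s_n lies in (0, 1] and equals 1 exactly when all samples coincide.  One
    entry per (sample vector, sigma); the vector is identified by the identity
    of its underlying array (a strong reference is kept), not by patient id —
    ids can legitimately collide across data sources, and a collision here
    would silently corrupt distances.
    """

    _store: dict = field(default_factory=dict)

    def get(self, x, sigma: float) -> float:
        v = _values(x)
        key = (id(v), float(sigma))
        hit = self._store.get(key)
        if hit is not None and hit[0] is v:
            return hit[1]
        s = float(np.exp(-((v[:, None] - v[None, :]) ** 2) / sigma ** 2).mean())
        self._store[key] = (v, s)
        return s

    def __len__(self) -> int:
        return len(self._store)


def _cross_term(xv: np.ndarray, yv: np.ndarray, sigma: float) -> float:
    return float(np.exp(-((xv[:, None] - yv[None, :]) ** 2) / sigma ** 2).mean())


def kme_sq_dist(x, y, sigma: float, cache: SelfTermCache | None = None) -> float:
    """Squared RKHS distance between the empirical embeddings of two samples.

    Symmetric, invariant to permutations of either sample, and non-negative
    (tiny negative round-off is clamped to 0; anything beyond ``1e-12`` in
    magnitude raises, as it signals a bug rather than cancellation noise).
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    cache = cache if cache is not None else SelfTermCache()
    xv, yv = _values(x), _values(y)
    d = cache.get(x, sigma) + cache.get(y, sigma) - 2.0 * _cross_term(xv, yv, sigma)
    if d < -_NEG_TOL:
        raise ArithmeticError(f"squared KME distance {d!r} is negative beyond "
                              f"round-off; upstream kernel computation is broken")
    return max(d, 0.0)


def second_level_kernel(sq_dist, gamma: float):
    """Second-level Gaussian kernel ``exp[-sq_dist / (2 gamma^2)]`` on embedding distances."""
    if not gamma > 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    d = np.asarray(sq_dist, dtype=float)
    if np.any(d < -_NEG_TOL):
        raise ArithmeticError("negative squared distance beyond round-off tolerance")
    return np.exp(-np.maximum(d, 0.0) / (2.0 * gamma ** 2))


@dataclass
class GramMatrix:
    """Pairwise second-level kernel values between a row and a column patient set."""

    values: np.ndarray
    row_ids: list
    col_ids: list
    params: KernelParams

    @property
    def is_square_self(self) -> bool:
        return self.row_ids == self.col_ids


def pairwise_sq_dist(rows, cols, sigma: float,
                     cache: SelfTermCache | None = None) -> np.ndarray:
    """Matrix of squared KME distances between two lists of samples.

    The column samples are concatenated once; each row's cross-sums against
    every column are then obtained from a single vectorized kernel block via
    segment sums, so the cost is one pass over (d_row x total_col_samples)
    per row.  When ``rows is cols`` the result is exactly symmetric with a
    zero diagonal.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if len(rows) == 0 or len(cols) == 0:
        raise ValueError("row and column sets must be non-empty")
    cache = cache if cache is not None else SelfTermCache()
    same = rows is cols

    col_vals = [_values(c) for c in cols]
    lengths = np.array([v.size for v in col_vals])
    concat = np.concatenate(col_vals)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    col_self = np.array([cache.get(c, sigma) for c in cols])
    row_self = col_self if same else np.array([cache.get(r, sigma) for r in rows])

    D = np.empty((len(rows), len(cols)))
    inv_sigma2 = 1.0 / sigma ** 2
    for n, r in enumerate(rows):
        rv = _values(r)
        block = np.exp(-((rv[:, None] - concat[None, :]) ** 2) * inv_sigma2)
        sums = np.add.reduceat(block.sum(axis=0), starts)
        cross = sums / (rv.size * lengths)
        D[n] = row_self[n] + col_self - 2.0 * cross
    if np.any(D < -_NEG_TOL):
        raise ArithmeticError("negative squared distance beyond round-off tolerance")
    np.maximum(D, 0.0, out=D)
    if same:
        D = 0.5 * (D + D.T)
        np.fill_diagonal(D, 0.0)
    return D


def gram(rows, cols, params: KernelParams,
         cache: SelfTermCache | None = None) -> GramMatrix:
    """Gram matrix of the second-level kernel K between two patient sets.

    Entry (n, m) is ``K(mu^(n), mu^(m)) = exp[-||mu^(n)-mu^(m)||^2 / (2 gamma^2)]``.
    A square self-Gram (``rows is cols``) is exactly symmetric with unit
    diagonal and positive semi-definite up to numerical tolerance.
    """
    D = pairwise_sq_dist(rows, cols, params.sigma, cache)
    K = second_level_kernel(D, params.gamma)

    def ids(vs):
        return [_patient_id(v) or f"#{i}" for i, v in enumerate(vs)]

    row_ids = ids(rows)
    col_ids = row_ids if rows is cols else ids(cols)
    return GramMatrix(values=K, row_ids=row_ids, col_ids=col_ids, params=params)
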