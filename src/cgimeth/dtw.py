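"""Partial-boundary dynamic time warping between methylation signatures.

The distance between two signatures with mean-beta vectors ``Y1`` (length m)
and ``Y2`` (length n) is the minimum over admissible warping paths of the sum
of squared differences ``(Y1[w1[k]] - Y2[w2[k]])**2``.  A path starts anywhere
on the first row or first column of the m x n grid (partial initialization),
advances by steps (1,0), (0,1) or (1,1) (monotonicity and continuity), and
ends anywhere on the last row or last column (partial boundary condition).
Free boundaries make the comparison insensitive to how far each profile
extends into the shelves, which differs between CGI+SS of different probe
counts.  Only the beta values enter the cost; genomic positions play no role
in the alignment itself.
"""
from __future__ import annotations

import numpy as np

from .profiles import Signature

try:  # JIT kernel; the pure-NumPy fallback is exact but slower
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _dtw_kernel(y1: np.ndarray, y2: np.ndarray) -> float:  # pragma: no cover
    m, n = y1.shape[0], y2.shape[0]
    D = np.empty((m, n))
    for j in range(n):
        D[0, j] = (y1[0] - y2[j]) ** 2
    for i in range(1, m):
        D[i, 0] = (y1[i] - y2[0]) ** 2
        for j in range(1, n):
            c = (y1[i] - y2[j]) ** 2
            best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            if D[i - 1, j - 1] < best:
                best = D[i - 1, j - 1]
            D[i, j] = c + best
    out = D[m - 1, 0]
    for j in range(n):
        if D[m - 1, j] < out:
            out = D[m - 1, j]
    for i in range(m):
        if D[i, n - 1] < out:
            out = D[i, n - 1]
    return out


def _dtw_python(y1: np.ndarray, y2: np.ndarray) -> tuple[np.ndarray, float]:
    """Reference DP (returns the full table, used for path-length tracking)."""
    m, n = len(y1), len(y2)
    D = np.empty((m, n))
    D[0, :] = (y1[0] - y2) ** 2
    for i in range(1, m):
        D[i, 0] = (y1[i] - y2[0]) ** 2
        for j in range(1, n):
            D[i, j] = (y1[i] - y2[j]) ** 2 + min(D[i - 1, j], D[i, j - 1],
                                                 D[i - 1, j - 1])
    return D, float(min(D[m - 1, :].min(), D[:, n - 1].min()))


def _path_length(D: np.ndarray, y1: np.ndarray, y2: np.ndarray) -> int:
    """Length of one optimal path, backtracked greedily from the best end."""
    m, n = D.shape
    ends = [(m - 1, j) for j in range(n)] + [(i, n - 1) for i in range(m)]
    i, j = min(ends, key=lambda ij: (D[ij], ij))
    length = 1
    while i > 0 and j > 0:  # any first-row/column cell is a free start
        moves = [(D[i - 1, j - 1], i - 1, j - 1), (D[i - 1, j], i - 1, j),
                 (D[i, j - 1], i, j - 1)]
        _, i, j = min(moves, key=lambda t: (t[0], t[1], t[2]))
        length += 1
    return length


def dtw_distance(sig1: Signature | np.ndarray, sig2: Signature | np.ndarray,
                 normalize: bool = False, end_rule: str = "standard") -> float:
    """Partial-boundary DTW distance between two signatures.

    Parameters
    ----------
    normalize
        If True, divide the raw minimum cost by the length of the optimal
        path (default off: the raw sum is the distance used for clustering).
    end_rule
        ``"standard"``: free end on the last row or last column.
        ``"printed"``: end set {n} x [1,n] + [1,m] x {n} taken literally
        (row index n of profile 1, which only exists when n <= m); kept for
        comparison, not used by the pipeline.
    """
    y1 = np.asarray(sig1.Y if isinstance(sig1, Signature) else sig1, dtype=float)
    y2 = np.asarray(sig2.Y if isinstance(sig2, Signature) else sig2, dtype=float)
    if len(y1) == 0 or len(y2) == 0:
        raise ValueError("signatures must be non-empty")
    if end_rule == "printed":
        D, _ = _dtw_python(y1, y2)
        m, n = D.shape
        cands = list(D[:, n - 1])
        if n <= m:
            cands.extend(D[n - 1, :])
        return float(min(cands))
    if end_rule != "standard":
        raise ValueError(f"unknown end_rule {end_rule!r}")
    if normalize:
        D, raw = _dtw_python(y1, y2)
        return raw / _path_length(D, y1, y2)
    if _HAVE_NUMBA:
        return float(_dtw_kernel(y1, y2))
    return _dtw_python(y1, y2)[1]


def dissimilarity_matrix(signatures: list[Signature],
                         symmetrize_tol: float = 1e-12) -> np.ndarray:
    """All-pairs DTW distances, symmetrized, zero diagonal."""
    if len(signatures) < 2:
        raise ValueError("need at least 2 signatures")
    ys = [np.asarray(s.Y, dtype=float) for s in signatures]
    n = len(ys)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij = dtw_distance(ys[i], ys[j])
            dji = dtw_distance(ys[j], ys[i])
            D[i, j] = D[j, i] = dij if abs(dij - dji) <= symmetrize_tol \
                else 0.5 * (dij + dji)
    return D
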