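"""Independent oracles used to validate the package's core numerics.

These deliberately avoid the implementation's code paths: the DTW oracle
enumerates every admissible warping path by depth-first search, and the Cox
oracle maximizes a hand-written partial likelihood with a generic scalar
optimizer.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar


def dtw_brute_force(y1: np.ndarray, y2: np.ndarray) -> float:
    """Minimum path cost by exhaustive enumeration (feasible for m, n <= ~7).

    Admissible paths start on the first row or first column of the m x n
    grid, advance by (1,0), (0,1) or (1,1), and may terminate at any cell of
    the last row or last column.  Branch-and-bound pruning on the running
    cost is exact for the minimum.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    m, n = len(y1), len(y2)
    best = [np.inf]

    def extend(i: int, j: int, cost: float) -> None:
        cost += (y1[i] - y2[j]) ** 2
        if cost >= best[0]:
            return
        if i == m - 1 or j == n - 1:
            best[0] = cost
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < m and j + dj < n:
                extend(i + di, j + dj, cost)

    for j in range(n):
        extend(0, j, 0.0)
    for i in range(1, m):
        extend(i, 0, 0.0)
    return best[0]


def cox_binary_mle(time: np.ndarray, event: np.ndarray, x: np.ndarray) -> float:
    """Partial-likelihood MLE of the log hazard ratio for one binary covariate.

    Assumes no tied event times (Breslow and Efron coincide).  Uses Newton-free
    scalar minimization of the negative log partial likelihood.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    order = np.argsort(time, kind="stable")
    time, event, x = time[order], event[order], x[order]

    def neg_logpl(beta: float) -> float:
        eta = beta * x
        ll = 0.0
        for k in np.where(event == 1)[0]:
            risk = time >= time[k]
            ll += eta[k] - np.log(np.sum(np.exp(eta[risk])))
        return -ll

    res = minimize_scalar(neg_logpl, bounds=(-10, 10), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)
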