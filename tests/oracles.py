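"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: ordinary least squares
is solved from hand-built normal equations with pure-Python Gaussian
elimination, t-tail probabilities are obtained by numerically integrating
the Student-t density written from its gamma-function definition, the
Kaplan-Meier curve is a hand product-limit loop, and the two-sample test is
a permutation resampler.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad


def gaussian_elimination(A, b):
    """Solve A x = b by partial-pivot Gaussian elimination (pure Python)."""
    n = len(b)
    M = [list(map(float, row)) + [float(bi)] for row, bi in zip(A, b)]
    for col in range(n):
        pivot = max(range(col, n), key=lambda r: abs(M[r][col]))
        if abs(M[pivot][col]) == 0.0:
            raise ZeroDivisionError("singular system")
        M[col], M[pivot] = M[pivot], M[col]
        for r in range(col + 1, n):
            f = M[r][col] / M[col][col]
            for c in range(col, n + 1):
                M[r][c] -= f * M[col][c]
    x = [0.0] * n
    for r in range(n - 1, -1, -1):
        s = M[r][n] - sum(M[r][c] * x[c] for c in range(r + 1, n))
        x[r] = s / M[r][r]
    return x


def _matrix_inverse(A):
    n = len(A)
    cols = []
    for j in range(n):
        e = [1.0 if i == j else 0.0 for i in range(n)]
        cols.append(gaussian_elimination(A, e))
    return [[cols[j][i] for j in range(n)] for i in range(n)]


def t_tail_two_sided(t: float, df: int) -> float:
    """2 * P(T >= |t|) by numerical integration of the t density."""
    c = math.exp(math.lgamma((df + 1) / 2.0) - math.lgamma(df / 2.0)) / math.sqrt(
        df * math.pi
    )

    def density(x):
        return c * (1.0 + x * x / df) ** (-(df + 1) / 2.0)

    tail, _ = quad(density, abs(t), math.inf, epsabs=1e-13, epsrel=1e-12)
    return 2.0 * tail


def ols_oracle(X, y):
    """Coefficients, standard errors and two-sided p-values of OLS via
    hand-built normal equations. Returns (beta, se, p) as lists."""
    X = [list(map(float, row)) for row in X]
    y = list(map(float, y))
    n, k = len(X), len(X[0])
    XtX = [[sum(X[r][i] * X[r][j] for r in range(n)) for j in range(k)] for i in range(k)]
    Xty = [sum(X[r][i] * y[r] for r in range(n)) for i in range(k)]
    beta = gaussian_elimination(XtX, Xty)
    resid = [y[r] - sum(X[r][j] * beta[j] for j in range(k)) for r in range(n)]
    df = n - k
    sigma2 = sum(e * e for e in resid) / df
    inv = _matrix_inverse(XtX)
    se = [math.sqrt(sigma2 * inv[i][i]) for i in range(k)]
    p = [t_tail_two_sided(beta[i] / se[i], df) for i in range(k)]
    return beta, se, p


def sse(X, y, beta):
    return sum(
        (yi - sum(xij * bj for xij, bj in zip(row, beta))) ** 2 for row, yi in zip(X, y)
    )


def km_hand(times, events):
    """Product-limit curve computed with an explicit loop.

    Returns (event_times, survival_values). Censored records leave the risk
    set without a step.
    """
    order = sorted(range(len(times)), key=lambda i: (times[i], -events[i]))
    at_risk = len(times)
    s = 1.0
    curve = []
    i = 0
    while i < len(order):
        t = times[order[i]]
        deaths = sum(1 for j in order[i:] if times[j] == t and events[j] == 1)
        removed = sum(1 for j in order[i:] if times[j] == t)
        if deaths > 0:
            s *= 1.0 - deaths / at_risk
            curve.append((t, s))
        at_risk -= removed
        i += removed
    return curve


def permutation_t_pvalue(a, b, n_resamples: int, rng) -> float:
    """Two-sided permutation p-value for the difference in means."""
    a, b = list(map(float, a)), list(map(float, b))
    pooled = np.array(a + b)
    na = len(a)
    observed = abs(np.mean(a) - np.mean(b))
    hits = 0
    for _ in range(n_resamples):
        perm = rng.permutation(pooled)
        if abs(perm[:na].mean() - perm[na:].mean()) >= observed - 1e-15:
            hits += 1
    return (hits + 1) / (n_resamples + 1)


def all_block_permutations(line_ids):
    """Every relabeling of line blocks: maps old id -> new id."""
    ids = sorted(line_ids)
    return [dict(zip(ids, perm)) for perm in itertools.permutations(ids)]
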