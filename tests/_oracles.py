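"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written with explicit loops and elementary
formulas, independent of the package's vectorised implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_sp(
    list_freqs,
    lexicon_freqs,
    mode: str = "lexicon_min",
    n_override: int | None = None,
) -> list[float]:
    """SP per position by explicit scanning and counting."""
    freqs = list(map(float, list_freqs))
    lex = list(map(float, lexicon_freqs))
    n = n_override if n_override is not None else len(freqs)
    f_min = min(lex)
    T = len(lex)
    out: list[float] = [math.nan] * len(freqs)
    i = 0
    while i < len(freqs):
        j = i
        while j + 1 < len(freqs) and freqs[j + 1] == freqs[i]:
            j += 1
        m = j - i + 1
        cur = freqs[i]
        best = None
        for t in range(i):
            if freqs[t] <= cur and (best is None or freqs[t] > best):
                best = freqs[t]
        if best is not None:
            low = best
        elif mode == "first_word" and i > 0:
            low = min(freqs[0], cur)
        elif mode == "first_word":
            low = cur
        else:
            low = f_min
        low = min(low, cur)
        w = cur - low
        C = 0
        for f in lex:
            if low <= f <= cur:
                C += 1
        if C == 0 or w == 0:
            sp = float("-inf")
        else:
            sp = math.log10(math.sqrt(C / T) * w / (m / n))
        for t in range(i, j + 1):
            out[t] = sp
        i = j + 1
    return out


def urn_multinomial_probs(n: int, k: int, alpha: float = 1.0) -> dict[tuple, float]:
    """P(count vector | Dirichlet(alpha)-multinomial) by enumerating every
    bin-assignment sequence through the Polya urn predictive rule."""
    probs: dict[tuple, float] = {}
    for seq in itertools.product(range(k), repeat=n):
        counts = [0] * k
        p = 1.0
        for t, b in enumerate(seq):
            p *= (alpha + counts[b]) / (k * alpha + t)
            counts[b] += 1
        key = tuple(counts)
        probs[key] = probs.get(key, 0.0) + p
    return probs


def multinomial_probs_fixed(n: int, p_ref) -> dict[tuple, float]:
    """P(count vector | fixed multinomial p_ref) by sequence enumeration."""
    k = len(p_ref)
    probs: dict[tuple, float] = {}
    for seq in itertools.product(range(k), repeat=n):
        counts = [0] * k
        p = 1.0
        for b in seq:
            p *= p_ref[b]
            counts[b] += 1
        key = tuple(counts)
        probs[key] = probs.get(key, 0.0) + p
    return probs


def irls_logistic(X, y, n_iter: int = 100, tol: float = 1e-12):
    """Plain logistic regression by iteratively reweighted least squares.

    Returns (beta, loglik)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        beta_new = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return beta, ll


def trapezoid_marginal_loglik(gamma, sigma, X, y, groups, n_grid: int = 200001):
    """Random-intercept marginal log-likelihood by fine-grid trapezoidal
    integration over the Gaussian random effect."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    u = np.linspace(-10 * sigma, 10 * sigma, n_grid)
    dens = np.exp(-0.5 * (u / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    total = 0.0
    for subj in np.unique(groups):
        mask = groups == subj
        eta = X[mask] @ np.asarray(gamma, float)
        ll = (
            y[mask][:, None] * (eta[:, None] + u[None, :])
            - np.logaddexp(0.0, eta[:, None] + u[None, :])
        ).sum(axis=0)
        total += math.log(np.trapezoid(np.exp(ll) * dens, u))
    return total
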