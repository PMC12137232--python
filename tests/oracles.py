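"""Independent brute-force oracles used to validate the package.

Everything here is deliberately naive (triple loops, dense enumeration,
fixed-grid quadrature) and shares no code path with the implementation
it checks.
"""

from __future__ import annotations

import numpy as np


def random_weighted_graph(rng: np.random.Generator, n: int,
                          density: float = 0.4,
                          w_lo: float = 0.1, w_hi: float = 1.0) -> np.ndarray:
    """Random symmetric nonnegative weight matrix, zero diagonal."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                w[i, j] = w[j, i] = rng.uniform(w_lo, w_hi)
    return w


def floyd_warshall_lengths(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths on edge lengths 1/w, by Floyd-Warshall."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def char_path_length_brute(d: np.ndarray) -> float:
    """Mean over nodes of the mean finite distance to the other nodes."""
    n = d.shape[0]
    per = []
    for i in range(n):
        vals = [d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])]
        if vals:
            per.append(sum(vals) / len(vals))
    return sum(per) / len(per)


def clustering_brute(w: np.ndarray) -> np.ndarray:
    """Per-node geometric-mean triangle clustering, O(n^3) enumeration."""
    n = w.shape[0]
    mx = w.max()
    wn = w / mx if mx > 0 else w
    c = np.zeros(n)
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        t = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    t += (wn[i, j] * wn[i, h] * wn[j, h]) ** (1.0 / 3.0)
        t /= 2.0
        c[i] = 2.0 * t / (k * (k - 1))
    return c


def local_efficiency_brute(w: np.ndarray) -> np.ndarray:
    """Per-node weighted local efficiency by explicit subgraph search."""
    n = w.shape[0]
    mx = w.max()
    wn = w / mx if mx > 0 else w
    e = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if wn[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        sub = wn[np.ix_(nbrs, nbrs)]
        d = floyd_warshall_lengths(sub)
        total = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and np.isfinite(d[a, b]) and d[a, b] > 0:
                    total += (wn[i, nbrs[a]] * wn[i, nbrs[b]] / d[a, b]) ** (1.0 / 3.0)
        e[i] = total / (k * (k - 1))
    return e


def global_efficiency_brute(d: np.ndarray) -> float:
    n = d.shape[0]
    per = []
    for i in range(n):
        s = 0.0
        for j in range(n):
            if j != i and np.isfinite(d[i, j]) and d[i, j] > 0:
                s += 1.0 / d[i, j]
        per.append(s / (n - 1))
    return sum(per) / n


def pearson_brute(ts: np.ndarray) -> np.ndarray:
    """Textbook covariance / (sd_i sd_j) correlation matrix."""
    n, k = ts.shape
    means = ts.mean(axis=0)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            xi = ts[:, i] - means[i]
            xj = ts[:, j] - means[j]
            out[i, j] = (xi * xj).sum() / np.sqrt((xi ** 2).sum() * (xj ** 2).sum())
    return out


def jzs_bf_g_quadrature(t: float, n: int, r: float = 0.707,
                        n_grid: int = 20001) -> float:
    """JZS BF10 via the g-mixture representation on a fixed log grid.

    Under H1 the effect prior is the scale mixture delta | g ~ N(0, g)
    with g following the Jeffreys-Zellner-Siow density
    p(g) = r (2 pi)^{-1/2} g^{-3/2} exp(-r^2 / (2 g)); marginalizing g
    gives the Cauchy(0, r) prior.  This route never touches the
    noncentral-t parameterization used by the implementation.
    """
    nu = n - 1
    z = np.linspace(-15.0, 15.0, n_grid)
    g = np.exp(z)
    prior = r / np.sqrt(2 * np.pi) * g ** -1.5 * np.exp(-r ** 2 / (2 * g))
    integrand = ((1 + n * g) ** -0.5
                 * (1 + t ** 2 / ((1 + n * g) * nu)) ** (-(nu + 1) / 2)
                 * prior * g)          # * g: Jacobian of g = exp(z)
    num = np.trapezoid(integrand, z)
    den = (1 + t ** 2 / nu) ** (-(nu + 1) / 2)
    return float(num / den)


def sinusoid_amplitude_dft(x: np.ndarray, tr_s: float, f: float) -> float:
    """Amplitude of the component at frequency f by direct DFT projection."""
    n = len(x)
    tt = np.arange(n) * tr_s
    c = (x * np.exp(-2j * np.pi * f * tt)).sum() * 2.0 / n
    return float(np.abs(c))
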