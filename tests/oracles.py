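"""Independent oracles for the penalized-regression solver tests.

``fista_group_elastic_net`` minimizes the same objective as the package's
block-coordinate-descent path solver but by a different route: global
accelerated proximal gradient (FISTA) on the full coefficient vector,
with its own objective/prox code.  On the tiny instances used in tests it
is run to very tight tolerance so it can serve as the reference solution.
"""

from __future__ import annotations

import numpy as np


def _group_slices(labels):
    labels = np.asarray(labels).astype(str)
    uniques = np.unique(labels)
    return [np.flatnonzero(labels == u) for u in uniques]


def oracle_objective(X, y, beta, alpha, lam, labels=None) -> float:
    """(1/2n)||y - X beta||^2 + lam * sum_g w_g [a||b_g|| + (1-a)/2||b_g||^2]."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.asarray(beta, float)
    n = X.shape[0]
    r = y - X @ beta
    obj = 0.5 * float(r @ r) / n
    slices = (
        [np.array([j]) for j in range(X.shape[1])]
        if labels is None
        else _group_slices(labels)
    )
    for idx in slices:
        w = np.sqrt(len(idx))
        nb = float(np.linalg.norm(beta[idx]))
        obj += lam * w * (alpha * nb + 0.5 * (1 - alpha) * nb * nb)
    return obj


def fista_group_elastic_net(
    X,
    y,
    alpha: float,
    lam: float,
    labels=None,
    n_iter: int = 200_000,
    tol: float = 1e-14,
) -> np.ndarray:
    """Reference minimizer of the group elastic-net objective.

    Expects X and y already centered/standardized the way the solver under
    test sees them (the comparison is in that space).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    slices = (
        [np.array([j]) for j in range(p)] if labels is None else _group_slices(labels)
    )
    weights = [np.sqrt(len(idx)) for idx in slices]
    G = X.T @ X / n
    L = float(np.linalg.eigvalsh(G)[-1]) + 1e-12
    step = 1.0 / L

    def prox(v):
        out = np.empty_like(v)
        for idx, w in zip(slices, weights):
            z = v[idx]
            thr = step * lam * w * alpha
            nz = float(np.linalg.norm(z))
            if nz <= thr:
                out[idx] = 0.0
            else:
                out[idx] = z * (1 - thr / nz) / (1 + step * lam * w * (1 - alpha))
        return out

    beta = np.zeros(p)
    zeta = beta.copy()
    t = 1.0
    Xty = X.T @ y / n
    prev_obj = np.inf
    for it in range(n_iter):
        grad = G @ zeta - Xty
        beta_new = prox(zeta - step * grad)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        zeta = beta_new + ((t - 1) / t_new) * (beta_new - beta)
        beta, t = beta_new, t_new
        if it % 200 == 199:
            obj = oracle_objective(X, y, beta, alpha, lam, labels)
            if prev_obj - obj < tol and prev_obj < np.inf:
                break
            prev_obj = obj
    return beta
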