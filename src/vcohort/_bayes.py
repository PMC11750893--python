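"""Minimal Gaussian-process Bayesian optimizer (expected improvement).

Used for SVM hyper-parameter tuning.  Dimensions are described as
``("log", lo, hi)`` (log10-uniform continuous) or ``("int", lo, hi)``
(uniform integer).  All randomness is driven by one seed, so the search is
fully reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel


def _decode(u: np.ndarray, space) -> list:
    params = []
    for uj, dim in zip(u, space):
        kind, lo, hi = dim
        if kind == "log":
            params.append(float(10.0 ** (lo + uj * (hi - lo))))
        elif kind == "int":
            params.append(int(round(lo + uj * (hi - lo))))
        else:
            raise ValueError(f"unknown dimension kind {kind!r}")
    return params


def gp_minimize(objective, space, n_calls: int = 25, n_initial: int = 8,
                seed: int | None = None, n_candidates: int = 256):
    """Minimize ``objective(params)`` over the search space.

    Returns ``(best_params, best_value, history)`` where history is a list of
    ``(params, value)`` pairs in evaluation order.
    """
    if n_calls < 1:
        raise ValueError("n_calls must be positive")
    rng = np.random.default_rng(seed)
    d = len(space)
    n_initial = min(n_initial, n_calls)
    U = [rng.random(d) for _ in range(n_initial)]
    history = []
    for u in U:
        params = _decode(u, space)
        history.append((params, float(objective(params))))
    ys = [h[1] for h in history]

    kernel = Matern(length_scale=0.3 * np.ones(d), nu=2.5) + WhiteKernel(1e-6)
    while len(history) < n_calls:
        X = np.asarray(U)
        y = np.asarray(ys)
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                      random_state=int(rng.integers(2 ** 31)))
        try:
            gp.fit(X, y)
        except Exception:
            u = rng.random(d)  # GP failure: fall back to a random draw
        else:
            cand = rng.random((n_candidates, d))
            mu, sd = gp.predict(cand, return_std=True)
            best = y.min()
            sd = np.maximum(sd, 1e-12)
            z = (best - mu) / sd
            ei = sd * (z * norm.cdf(z) + norm.pdf(z))
            u = cand[int(np.argmax(ei))]
        U.append(u)
        params = _decode(u, space)
        val = float(objective(params))
        history.append((params, val))
        ys.append(val)

    best_idx = int(np.argmin(ys))
    return history[best_idx][0], ys[best_idx], history
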