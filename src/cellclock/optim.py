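"""Covariance-matrix-adaptation evolution strategy (CMA-ES).

Compact (mu/mu_w, lambda) implementation with rank-one and rank-mu
covariance updates and cumulative step-size adaptation, suitable for
noisy objectives: the caller may evaluate each generation with common
random numbers by keying the objective on the generation seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CMAResult", "cma_minimize"]


@dataclass
class CMAResult:
    x_best: np.ndarray        # best candidate of the final generation
    x_mean: np.ndarray        # final distribution mean
    f_best: float
    n_evaluations: int
    history: list = field(default_factory=list)  # (gen, f_best, f_median, sigma)
    converged: bool = False


def cma_minimize(objective, x0, sigma0: float = 0.3, popsize: int | None = None,
                 max_gens: int = 300, seed: int = 0, f_tol: float = 1e-8,
                 sigma_stop: float = 1e-10) -> CMAResult:
    """Minimize ``objective(x, gen)`` by CMA-ES.

    The objective receives the generation index so that stochastic
    objectives can use common random numbers within a generation and fresh
    draws across generations.
    """
    x0 = np.asarray(x0, dtype=float)
    n = len(x0)
    rng = np.random.default_rng(seed)
    lam = popsize or (4 + int(3 * math.log(n)))
    mu = lam // 2
    w = math.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / np.sum(w ** 2)

    c_sigma = (mu_eff + 2) / (n + mu_eff + 5)
    d_sigma = 1 + 2 * max(0.0, math.sqrt((mu_eff - 1) / (n + 1)) - 1) + c_sigma
    c_c = (4 + mu_eff / n) / (n + 4 + 2 * mu_eff / n)
    c_1 = 2 / ((n + 1.3) ** 2 + mu_eff)
    c_mu = min(1 - c_1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((n + 2) ** 2 + mu_eff))
    chi_n = math.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n * n))

    m = x0.copy()
    sigma = float(sigma0)
    C = np.eye(n)
    p_sigma = np.zeros(n)
    p_c = np.zeros(n)
    B, D = np.eye(n), np.ones(n)
    n_eval = 0
    history = []
    x_best, f_best = m.copy(), math.inf
    prev_best = math.inf
    converged = False

    for gen in range(max_gens):
        # refresh eigendecomposition
        C = (C + C.T) / 2.0
        eigval, B = np.linalg.eigh(C)
        D = np.sqrt(np.maximum(eigval, 1e-20))

        z = rng.standard_normal((lam, n))
        y = z * D[None, :] @ B.T
        xs = m[None, :] + sigma * y
        fs = np.array([objective(x, gen) for x in xs])
        n_eval += lam
        order = np.argsort(fs)
        xs, ys, fs = xs[order], y[order], fs[order]
        x_best, f_best = xs[0].copy(), float(fs[0])
        history.append((gen, float(fs[0]), float(np.median(fs)), sigma))

        y_w = w @ ys[:mu]
        m = m + sigma * y_w
        # step-size path (C^(-1/2) y_w)
        c_inv_half_yw = B @ ((B.T @ y_w) / D)
        p_sigma = (1 - c_sigma) * p_sigma + math.sqrt(
            c_sigma * (2 - c_sigma) * mu_eff) * c_inv_half_yw
        h_sig = (np.linalg.norm(p_sigma)
                 / math.sqrt(1 - (1 - c_sigma) ** (2 * (gen + 1))) / chi_n
                 < 1.4 + 2 / (n + 1))
        p_c = (1 - c_c) * p_c + (math.sqrt(c_c * (2 - c_c) * mu_eff) * y_w
                                 if h_sig else 0.0)
        rank_mu = sum(wi * np.outer(yi, yi) for wi, yi in zip(w, ys[:mu]))
        C = ((1 - c_1 - c_mu) * C
             + c_1 * (np.outer(p_c, p_c) + (0.0 if h_sig else c_c * (2 - c_c)) * C)
             + c_mu * rank_mu)
        sigma *= math.exp(c_sigma / d_sigma * (np.linalg.norm(p_sigma) / chi_n - 1))

        if sigma * D.max() < sigma_stop:
            converged = True
            break
        if gen > 10 and abs(prev_best - fs[0]) < f_tol and sigma < 1e-6:
            converged = True
            break
        prev_best = float(fs[0])

    return CMAResult(x_best=x_best, x_mean=m, f_best=f_best,
                     n_evaluations=n_eval, history=history, converged=converged)
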