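"""Minimal (mu/mu_w, lambda) covariance matrix adaptation evolution strategy.

A compact, seeded implementation of the standard CMA-ES recipe (rank-mu update, cumulative step
length adaptation) for low-dimensional box-bounded searches.  Out-of-bounds samples are folded
back by boundary reflection, which keeps the sampling distribution unbiased near the box edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


def reflect_into_box(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Fold coordinates back into [lo, hi] by repeated reflection at the edges."""
    span = hi - lo
    y = np.where(span > 0, x, np.clip(x, lo, hi))
    with np.errstate(invalid="ignore"):
        t = np.mod(y - lo, 2 * span, where=span > 0, out=np.zeros_like(y))
    folded = np.where(t <= span, t, 2 * span - t)
    return np.where(span > 0, lo + folded, np.clip(x, lo, hi))


@dataclass
class CMAResult:
    x_best: np.ndarray
    f_best: float
    generations: int
    evaluations: int
    trace: np.ndarray          # best-so-far objective per generation
    converged: bool


def cma_es(
    objective: Callable[[np.ndarray], float],
    x0: np.ndarray,
    sigma0: float,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    population: int | None = None,
    max_generations: int = 200,
    tol_stall: float = 1e-6,
    stall_generations: int = 20,
    seed: int | np.random.Generator = 0,
) -> CMAResult:
    """Minimize ``objective`` over a box; fully reproducible for a fixed seed."""
    x0 = np.asarray(x0, float).copy()
    d = x0.size
    if sigma0 <= 0:
        raise ValueError("initial step size must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = population or (4 + int(3 * np.log(d)))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / np.sum(w**2)

    cc = (4 + mu_eff / d) / (d + 4 + 2 * mu_eff / d)
    cs = (mu_eff + 2) / (d + mu_eff + 5)
    c1 = 2 / ((d + 1.3) ** 2 + mu_eff)
    cmu = min(1 - c1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((d + 2) ** 2 + mu_eff))
    damps = 1 + 2 * max(0.0, np.sqrt((mu_eff - 1) / (d + 1)) - 1) + cs
    chi_d = np.sqrt(d) * (1 - 1 / (4 * d) + 1 / (21 * d * d))

    mean = x0.copy()
    sigma = float(sigma0)
    C = np.eye(d)
    ps = np.zeros(d)
    pc = np.zeros(d)

    x_best = mean.copy()
    f_best = np.inf
    trace = []
    evals = 0
    converged = False

    for gen in range(1, max_generations + 1):
        evals_C = np.linalg.eigh(C)
        eigvals = np.maximum(evals_C.eigenvalues, 1e-20)
        B = evals_C.eigenvectors
        D = np.sqrt(eigvals)
        invsqrtC = B @ np.diag(1.0 / D) @ B.T

        z = rng.standard_normal((lam, d))
        xs = mean + sigma * (z * D) @ B.T
        if bounds is not None:
            xs = np.array([reflect_into_box(x, bounds[0], bounds[1]) for x in xs])
        fs = np.array([objective(x) for x in xs])
        evals += lam

        order = np.argsort(fs, kind="stable")
        if fs[order[0]] < f_best:
            f_best = float(fs[order[0]])
            x_best = xs[order[0]].copy()
        trace.append(f_best)

        sel = xs[order[:mu]]
        old_mean = mean
        mean = w @ sel

        y = (mean - old_mean) / sigma
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mu_eff) * (invsqrtC @ y)
        hsig = float(
            np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * gen)) / chi_d < 1.4 + 2 / (d + 1)
        )
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mu_eff) * y
        arts = (sel - old_mean) / sigma
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (1 - hsig) * cc * (2 - cc) * C)
            + cmu * (arts.T * w) @ arts
        )
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chi_d - 1))

        if gen > stall_generations:
            if trace[-stall_generations - 1] - trace[-1] < tol_stall:
                converged = True
                break

    return CMAResult(
        x_best=x_best,
        f_best=float(f_best),
        generations=len(trace),
        evaluations=evals,
        trace=np.array(trace),
        converged=converged,
    )
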