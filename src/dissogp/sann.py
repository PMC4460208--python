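"""Simulated annealing for unbounded continuous minimization.

A Belisle-style annealer: Gaussian random-walk proposals with a step scale
tied to the temperature, Metropolis acceptance, and geometric cooling.  It
exists to provide a *global* starting point for local optimizers from an
arbitrary constant initial vector; the schedule (initial temperature 10,
cooling factor 0.95 applied every 100 evaluations, 10,000 evaluations) is
deliberately generous at the start so parameters tens of units away from
the origin stay reachable.
"""

from __future__ import annotations

import numpy as np

__all__ = ["simulated_annealing"]


def simulated_annealing(objective, x0, seed: int = 0, n_evals: int = 10_000,
                        t0: float = 10.0, cooling: float = 0.95,
                        cool_interval: int = 100,
                        step_floor: float = 0.01) -> tuple[np.ndarray, float]:
    """Minimize ``objective`` from ``x0``; returns (best point, best value).

    Proposal steps are isotropic Gaussians with standard deviation
    ``max(T, step_floor)`` at current temperature T, so early moves explore
    widely and late moves refine.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    f = float(objective(x))
    best_x, best_f = x.copy(), f
    T = float(t0)
    for it in range(n_evals):
        if it > 0 and it % cool_interval == 0:
            T *= cooling
        step = max(T, step_floor)
        cand = x + rng.normal(0.0, step, size=x.shape)
        fc = float(objective(cand))
        if fc <= f or rng.random() < np.exp(-(fc - f) / max(T, 1e-12)):
            x, f = cand, fc
            if f < best_f:
                best_x, best_f = x.copy(), f
    return best_x, best_f
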