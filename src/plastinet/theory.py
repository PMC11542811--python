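"""Analytic theory of optimal fixed random masks.

A classifier needs roughly ``mu`` plastic input->hidden->output paths to reach
criterion (calibrated at mu = 100, the smallest fully-plastic hidden layer
that trains to 95%).  With Bernoulli masks of density ``f0`` (input layer) and
``f1`` (output layer), the expected number of plastic paths is
``f0 * f1 * N_h``, while the expected number of plastic synapses — the energy
proxy — is::

    m(f0, f1) = n_in * N_h * f0 + n_out * N_h * f1

Minimizing ``m`` subject to ``f0 * f1 * N_h = mu`` and ``0 < f_i <= 1``:
substituting ``f0 = mu / (f1 * N_h)`` gives
``m(f1) = mu * n_in / f1 + n_out * N_h * f1``, which is convex in ``f1`` with
unconstrained minimum ``f1 = sqrt(mu * n_in / (N_h * n_out))``.  Clipping to
the box yields::

    f1* = min(1, sqrt(mu * n_in / (N_h * n_out)))
    f0* = mu / (N_h * f1*)

The interior optimum balances the two layer terms exactly.  ``f1* < 1`` first
occurs at ``N_h = mu * n_in / n_out`` (7840 for the default problem, i.e.
~8000 at one significant figure): only above that size is it worth freezing
any hidden-to-output synapses.  For ``N_h`` far above the threshold the
minimal proxy grows like ``sqrt(N_h)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class InfeasibleMaskError(ValueError):
    """Raised when the path constraint cannot be met (N_h < mu)."""


@dataclass(frozen=True)
class MaskProblem:
    """Problem dimensions for mask optimization."""

    N_h: int
    mu: float = 100.0
    n_in: int = 784
    n_out: int = 10

    def __post_init__(self) -> None:
        if min(self.N_h, self.mu, self.n_in, self.n_out) <= 0:
            raise ValueError("all problem dimensions must be positive")


def _check_fraction(name: str, f: float) -> None:
    if not (0 <= f <= 1):
        raise ValueError(f"{name} must lie in [0, 1], got {f}")


def plastic_paths(f0: float, f1: float, N_h: int) -> float:
    """Expected number of plastic input->hidden->output paths, ``f0 * f1 * N_h``."""
    _check_fraction("f0", f0)
    _check_fraction("f1", f1)
    return f0 * f1 * N_h


def proxy_cost(f0: float, f1: float, problem: MaskProblem) -> float:
    """Expected plastic synapse count ``n_in N_h f0 + n_out N_h f1`` (energy proxy)."""
    _check_fraction("f0", f0)
    _check_fraction("f1", f1)
    return problem.n_in * problem.N_h * f0 + problem.n_out * problem.N_h * f1


def optimal_fractions(problem: MaskProblem) -> tuple[float, float, float]:
    """Closed-form minimizer ``(f0*, f1*, m*)`` of the proxy cost under the path constraint."""
    if problem.N_h < problem.mu:
        raise InfeasibleMaskError(
            f"N_h = {problem.N_h} < mu = {problem.mu}: cannot realize {problem.mu} plastic paths"
        )
    f1 = min(1.0, float(np.sqrt(problem.mu * problem.n_in / (problem.N_h * problem.n_out))))
    f0 = problem.mu / (problem.N_h * f1)
    return f0, f1, proxy_cost(f0, f1, problem)


def f1_threshold_size(problem: MaskProblem) -> float:
    """Hidden-layer size above which f1* drops below 1: ``mu * n_in / n_out``."""
    return problem.mu * problem.n_in / problem.n_out


def grid_search_fractions(problem: MaskProblem, resolution: float = 1e-3) -> tuple[float, float, float]:
    """Brute-force minimizer over an f1 grid (independent check of the closed form).

    The constraint pins ``f0 = mu / (f1 * N_h)``, so a dense 1-D sweep over
    feasible ``f1`` values is an exhaustive search of the constrained set.
    """
    f1_grid = np.arange(resolution, 1.0 + resolution / 2, resolution)
    f0_grid = problem.mu / (f1_grid * problem.N_h)
    ok = f0_grid <= 1.0
    if not ok.any():
        raise InfeasibleMaskError(f"no feasible fractions at N_h = {problem.N_h}")
    f1_grid, f0_grid = f1_grid[ok], f0_grid[ok]
    m = problem.n_in * problem.N_h * f0_grid + problem.n_out * problem.N_h * f1_grid
    i = int(np.argmin(m))
    return float(f0_grid[i]), float(f1_grid[i]), float(m[i])


def theory_table(
    sizes, mu: float = 100.0, n_in: int = 784, n_out: int = 10
) -> list[dict[str, float]]:
    """Rows of (N_h, f0*, f1*, m*, plastic paths) over a grid of hidden sizes."""
    rows = []
    for N_h in sizes:
        problem = MaskProblem(N_h=int(N_h), mu=mu, n_in=n_in, n_out=n_out)
        f0, f1, m = optimal_fractions(problem)
        rows.append(
            {
                "N_h": int(N_h),
                "f0_star": f0,
                "f1_star": f1,
                "m_star": m,
                "plastic_paths": plastic_paths(f0, f1, int(N_h)),
            }
        )
    return rows
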