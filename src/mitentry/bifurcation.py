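"""Steady-state and saddle-node analysis of the mitotic-entry network.

The bistable switch is characterised as a function of CDK2-cyclin A
activity (``cyca_cdk2_tot``): over an interval of that parameter the
network has two stable fixed points (a low-CDK1 interphase-like branch
and a high-CDK1 mitotic branch) separated by an unstable one.  The edges
of the interval are saddle-node (SN) points.  The upper SN is the
CDK2-cyclin A threshold above which only the high-CDK1 state exists;
PLK1 inhibition moves this threshold upward, which is what turns a step
change in CycA into a long, variable delay before NEBD.

Fixed points are located by multi-start Newton root finding on a lattice
plus seeded random starts, de-duplicated, and classified by the
eigenvalues of a finite-difference Jacobian.  Saddle nodes are bracketed
on a coarse parameter grid and refined by bisection on the count of
stable fixed points — deliberately brute force rather than pseudo-arclength
continuation, which is unnecessary at this problem size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from mitentry.model import (
    Clamp,
    KineticParameters,
    NetworkState,
    rhs_vector,
)

__all__ = [
    "SteadyStateBranch",
    "SaddleNodeResult",
    "find_fixed_points",
    "steady_states",
    "find_saddle_nodes",
    "settle",
]

#: |Re lambda| below this is reported as indeterminate stability.
EIGENVALUE_MARGIN = 1e-9
#: residual norm (scaled) below which a root is accepted as a fixed point
RESIDUAL_TOL = 1e-8
#: relative state-norm tolerance for de-duplicating fixed points
DEDUP_RTOL = 1e-6


@dataclass(frozen=True)
class SteadyStateBranch:
    """One fixed point at one parameter value."""

    parameter_value: float
    state: NetworkState
    stability: str  # "stable" | "unstable" | "indeterminate"
    eigenvalues: tuple


@dataclass(frozen=True)
class SaddleNodeResult:
    """Bistable-interval edges in ``cyca_cdk2_tot`` for one ``f_plk1``.

    ``bistable`` is False when no bistable interval exists inside the
    scanned bounds; the SN fields are then ``None``.  ``sn_upper`` is the
    threshold above which only the high-CDK1 steady state remains.
    """

    f_plk1: float
    sn_lower: float | None
    sn_upper: float | None
    bistable: bool
    bounds: tuple[float, float]


def _rhs(y: np.ndarray, params: KineticParameters, clamp: Clamp | None) -> np.ndarray:
    return rhs_vector(y, params, clamp)


def _jacobian(y: np.ndarray, params: KineticParameters,
              clamp: Clamp | None) -> np.ndarray:
    n = y.size
    J = np.empty((n, n))
    for j in range(n):
        h = 1e-6 * max(abs(y[j]), 1.0)
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (_rhs(yp, params, clamp) - _rhs(ym, params, clamp)) / (2 * h)
    return J


def _state_scale(params: KineticParameters) -> float:
    return max(params.cdc25_tot, params.cycbcdk1_tot, params.sub_tot,
               params.wee1_tot, params.b55_tot, 1.0)


def _start_points(params: KineticParameters, n_random: int,
                  rng: np.random.Generator) -> list[np.ndarray]:
    lo = np.array([params.cdc25_tot, 0.0, 0.0, params.wee1_tot, params.b55_tot, 0.0])
    hi = np.array([0.0, params.cdc25_tot, params.cycbcdk1_tot, 0.0, 0.01, params.sub_tot])
    mid = 0.5 * (lo + hi)
    starts = [lo, hi, mid]
    totals = np.array([params.cdc25_tot, params.cdc25_tot, params.cycbcdk1_tot,
                       params.wee1_tot, params.b55_tot, params.sub_tot])
    for _ in range(n_random):
        u = rng.random(6)
        y = u * totals
        if y[0] + y[1] > params.cdc25_tot:  # respect the Cdc25 conservation simplex
            s = params.cdc25_tot / (y[0] + y[1]) * rng.random()
            y[0] *= s
            y[1] *= s
        starts.append(y)
    return starts


def find_fixed_points(
    params: KineticParameters,
    clamp: Clamp | None = None,
    n_random_starts: int = 17,
    seed: int = 0,
) -> list[SteadyStateBranch]:
    """All fixed points of the network at the given parameters.

    Multi-start Newton (hybrid Powell) from a small lattice of
    biologically meaningful corners plus seeded random interior points;
    converged roots are kept if their scaled residual is below
    ``RESIDUAL_TOL`` and they respect the state bounds, then de-duplicated
    within ``DEDUP_RTOL`` and classified by Jacobian eigenvalues.
    """
    rng = np.random.default_rng(seed)
    scale = _state_scale(params)
    tol_slack = 1e-6 * scale
    # clamped coordinates are parameters, not unknowns: solve the free ones
    free = np.ones(6, dtype=bool)
    fixed_vals = np.zeros(6)
    if clamp is not None and clamp.v_cdk1 is not None:
        free[2] = False
        fixed_vals[2] = clamp.v_cdk1
    if clamp is not None and clamp.pp2ab55 is not None:
        free[4] = False
        fixed_vals[4] = clamp.pp2ab55

    def embed(x: np.ndarray) -> np.ndarray:
        y = fixed_vals.copy()
        y[free] = x
        return y

    def rhs_free(x: np.ndarray, *args) -> np.ndarray:
        return _rhs(embed(x), *args)[free]

    found: list[np.ndarray] = []
    for y0 in _start_points(params, n_random_starts, rng):
        sol = root(rhs_free, y0[free], args=(params, clamp), method="hybr", tol=1e-12)
        if not sol.success:
            continue
        y = embed(sol.x)
        if np.linalg.norm(_rhs(y, params, clamp)) > RESIDUAL_TOL * scale:
            continue
        if np.any(y < -tol_slack):
            continue
        if y[0] + y[1] > params.cdc25_tot + tol_slack:
            continue
        if (y[2] > params.cycbcdk1_tot + tol_slack
                or y[3] > params.wee1_tot + tol_slack
                or y[4] > params.b55_tot + tol_slack
                or y[5] > params.sub_tot + tol_slack):
            continue
        if any(np.linalg.norm(y - z) <= DEDUP_RTOL * scale for z in found):
            continue
        found.append(y)

    branches = []
    for y in sorted(found, key=lambda v: v[2]):
        J = _jacobian(y, params, clamp)[np.ix_(free, free)]
        eig = np.linalg.eigvals(J)
        lead = float(np.max(eig.real))
        if abs(lead) < EIGENVALUE_MARGIN:
            stability = "indeterminate"
        elif lead < 0:
            stability = "stable"
        else:
            stability = "unstable"
        branches.append(
            SteadyStateBranch(
                parameter_value=params.cyca_cdk2_tot,
                state=NetworkState.from_vector(np.clip(y, 0.0, None)),
                stability=stability,
                eigenvalues=tuple(eig),
            )
        )
    return branches


def steady_states(
    params: KineticParameters,
    parameter_grid: np.ndarray,
    clamp: Clamp | None = None,
    seed: int = 0,
) -> list[SteadyStateBranch]:
    """Fixed points along a grid of CDK2-cyclin A activities.

    Non-convergence at a grid value simply yields no branch entries for
    that value (a recorded gap), never an exception.
    """
    grid = np.asarray(parameter_grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("parameter grid must be non-empty and increasing")
    out: list[SteadyStateBranch] = []
    for value in grid:
        out.extend(find_fixed_points(params.with_(cyca_cdk2_tot=value),
                                     clamp=clamp, seed=seed))
    return out


def _n_stable(params: KineticParameters, value: float, seed: int) -> int:
    fps = find_fixed_points(params.with_(cyca_cdk2_tot=value), seed=seed)
    return sum(1 for fp in fps if fp.stability == "stable")


def find_saddle_nodes(
    params: KineticParameters,
    bounds: tuple[float, float] = (0.02, 8.0),
    n_coarse: int = 33,
    resolution: float | None = None,
    seed: int = 0,
) -> SaddleNodeResult:
    """Edges of the bistable interval in ``cyca_cdk2_tot`` inside ``bounds``.

    A coarse scan counts stable fixed points on ``n_coarse`` grid values;
    bisection then refines the two parameter values where the count
    changes, down to ``resolution`` (default 1e-3 of the bounds width).
    When no grid value is bistable, an explicit no-bistability marker is
    returned rather than raising.  An interval touching a scan bound is
    reported with the bound itself as the edge.
    """
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("bounds must be an increasing interval")
    if resolution is None:
        resolution = 1e-3 * (hi - lo)
    grid = np.linspace(lo, hi, n_coarse)
    counts = [_n_stable(params, v, seed) for v in grid]
    bist = [c >= 2 for c in counts]
    if not any(bist):
        return SaddleNodeResult(params.f_plk1, None, None, False, bounds)

    first = next(i for i, b in enumerate(bist) if b)
    last = len(bist) - 1 - next(i for i, b in enumerate(reversed(bist)) if b)

    if first == 0:
        sn_lower = lo
    else:
        a, b = grid[first - 1], grid[first]
        while b - a > resolution:
            m = 0.5 * (a + b)
            if _n_stable(params, m, seed) >= 2:
                b = m
            else:
                a = m
        sn_lower = 0.5 * (a + b)

    if last == len(grid) - 1:
        sn_upper = hi
    else:
        a, b = grid[last], grid[last + 1]
        while b - a > resolution:
            m = 0.5 * (a + b)
            if _n_stable(params, m, seed) >= 2:
                a = m
            else:
                b = m
        sn_upper = 0.5 * (a + b)

    return SaddleNodeResult(params.f_plk1, float(sn_lower), float(sn_upper),
                            True, bounds)


def settle(
    params: KineticParameters,
    y0: np.ndarray,
    t_max: float = 2000.0,
    clamp: Clamp | None = None,
) -> np.ndarray:
    """Long time-integration from ``y0``; used as the independent check
    that reported stable fixed points are actual attractors."""
    sol = solve_ivp(lambda t, y: _rhs(y, params, clamp), (0.0, t_max), np.asarray(y0, float),
                    method="LSODA", rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"settling integration failed: {sol.message}")
    return sol.y[:, -1]
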