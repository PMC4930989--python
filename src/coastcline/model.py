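"""Two-lineage metapopulation dynamics on a connectivity matrix.

The model tracks the northern-lineage fraction f(j) at each coastal site.
Habitat is saturated (lottery competition): every generation each site is
recolonised by its arriving larval pool, so only the pool's composition
matters and results are invariant to the base fecundity R.  The larval
supply of lineage T at site j is

    L_T(j) = sum_i C[i, j] * f_T(i) * w_T(i)

where w_T(i) is the net fecundity of lineage T at its natal site i: R for
the locally favored lineage and R (1 - delta_w) for the other, with favor
switching at the scenario's break latitude.  The update is

    f'(j) = L_N(j) / (L_N(j) + L_S(j))

with f'(j) = f(j) where the pool is empty (composition, not abundance, is
tracked).  An optional adult-turnover parameter tau in (0, 1] blends old
and settler composition; tau = 1 means non-overlapping generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConnectivityMatrix, FitnessScenario, LineageCline


def fecundity(latitude, lineage: str, scenario: FitnessScenario) -> np.ndarray:
    """Net fecundity of ``lineage`` ("N" or "S") at the given natal latitude(s).

    The favored lineage gets R, the other R (1 - delta_w).  With the
    default orientation the northern lineage is favored at latitudes at or
    north of the break (ties go north).
    """
    lat = np.asarray(latitude, dtype=float)
    north_side = lat >= scenario.break_latitude
    if scenario.north_favored_north:
        favored = north_side if lineage == "N" else ~north_side
    else:
        favored = ~north_side if lineage == "N" else north_side
    return np.where(favored, scenario.R, scenario.R * (1.0 - scenario.delta_w))


def _step(f: np.ndarray, C: np.ndarray, wN: np.ndarray, wS: np.ndarray,
          tau: float = 1.0) -> np.ndarray:
    LN = C.T @ (f * wN)
    LS = C.T @ ((1.0 - f) * wS)
    tot = LN + LS
    if np.any(LN < -1e-15) or np.any(LS < -1e-15):  # impossible given invariants
        raise AssertionError("negative larval supply")
    with np.errstate(invalid="ignore", divide="ignore"):
        settlers = np.where(tot > 0, LN / np.where(tot > 0, tot, 1.0), f)
    fp = (1.0 - tau) * f + tau * settlers
    return np.clip(fp, 0.0, 1.0)


def step_generation(cline: LineageCline, conn: ConnectivityMatrix,
                    scenario: FitnessScenario, tau: float = 1.0) -> LineageCline:
    """Advance the cline by one generation of dispersal, selection and settlement."""
    if cline.grid.n_sites != conn.grid.n_sites:
        raise ValueError("cline and connectivity grids do not match")
    wN = fecundity(conn.grid.latitudes, "N", scenario)
    wS = fecundity(conn.grid.latitudes, "S", scenario)
    return LineageCline(conn.grid, _step(cline.f, conn.C, wN, wS, tau), source="model")


@dataclass
class ModelRun:
    """Outcome of iterating the settlement map."""

    grid: object
    f_final: np.ndarray
    n_generations: int
    converged: bool
    tol: float
    scenario: FitnessScenario
    trajectory: np.ndarray | None = None  # (n_recorded, n_sites) incl. f0
    recorded_generations: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def final_cline(self) -> LineageCline:
        return LineageCline(self.grid, self.f_final, source="model")


def _as_f0(f0, n_sites: int) -> np.ndarray:
    if isinstance(f0, LineageCline):
        f0 = f0.f
    f = np.broadcast_to(np.asarray(f0, dtype=float), (n_sites,)).copy()
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("initial frequencies must lie in [0, 1]")
    return f


def run_to_steady_state(f0, conn: ConnectivityMatrix, scenario: FitnessScenario,
                        tol: float = 1e-8, max_generations: int = 5000,
                        tau: float = 1.0, record_every: int = 0) -> ModelRun:
    """Iterate until max_j |f'(j) - f(j)| < tol or the generation cap.

    Non-convergence is reported through ``converged=False``, never raised.
    ``record_every`` > 0 stores every that-many-th state (plus first and
    last) in ``trajectory``.
    """
    lat = conn.grid.latitudes
    wN = fecundity(lat, "N", scenario)
    wS = fecundity(lat, "S", scenario)
    f = _as_f0(f0, conn.grid.n_sites)
    traj = [f.copy()] if record_every else None
    gens = [0] if record_every else None
    converged = False
    g = 0
    for g in range(1, max_generations + 1):
        fn = _step(f, conn.C, wN, wS, tau)
        delta = np.max(np.abs(fn - f))
        f = fn
        if record_every and (g % record_every == 0):
            traj.append(f.copy())
            gens.append(g)
        if delta < tol:
            converged = True
            break
    else:
        g = max_generations
    if record_every and gens[-1] != g:
        traj.append(f.copy())
        gens.append(g)
    return ModelRun(
        grid=conn.grid, f_final=f, n_generations=g, converged=converged, tol=tol,
        scenario=scenario,
        trajectory=np.array(traj) if traj is not None else None,
        recorded_generations=np.array(gens) if gens is not None else None,
        metadata={"tau": tau, "max_generations": max_generations},
    )


def time_to_event(f0, conn: ConnectivityMatrix, scenario: FitnessScenario,
                  event: str, lineage: str = "S", threshold: float = 1e-3,
                  tol: float = 1e-8, max_generations: int = 5000,
                  tau: float = 1.0) -> float:
    """First generation at which an event holds; ``inf`` if never reached.

    ``event="convergence"``: max site-wise change below ``tol``.
    ``event="loss"``: the maximum over sites of ``lineage``'s fraction
    ("N" or "S") falls below ``threshold``.
    """
    if event not in ("convergence", "loss"):
        raise ValueError("event must be 'convergence' or 'loss'")
    lat = conn.grid.latitudes
    wN = fecundity(lat, "N", scenario)
    wS = fecundity(lat, "S", scenario)
    f = _as_f0(f0, conn.grid.n_sites)

    def lost(fv):
        frac = fv if lineage == "N" else 1.0 - fv
        return np.max(frac) < threshold

    if event == "loss" and lost(f):
        return 0
    if event == "convergence":
        if np.max(np.abs(_step(f, conn.C, wN, wS, tau) - f)) < tol:
            return 0
    for g in range(1, max_generations + 1):
        fn = _step(f, conn.C, wN, wS, tau)
        if event == "loss" and lost(fn):
            return g
        if event == "convergence" and np.max(np.abs(fn - f)) < tol:
            return g
        f = fn
    return float("inf")
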