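"""Mass-balance speciation solving at fixed pH and species distributions.

At a fixed proton concentration [H] = 10**-pH the unknowns are the free
concentrations of the non-proton components.  Every species concentration
follows from the free concentrations,

    c_i = 10**log_beta_i * prod_j f_j**nu_ij * [H]**nu_iH,

and the component mass balances

    T_j = f_j + sum_i nu_ij c_i

are solved by damped Newton-Raphson iteration on log10 f (positivity is
automatic in log space).  The Jacobian is analytic.  The same kernel, with
the proton included as an unknown and a Kw/[H] term in the proton balance,
drives the titration simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .model import SpeciationModel

__all__ = [
    "SolutionState",
    "DistributionDiagram",
    "ConvergenceError",
    "solve_at_ph",
    "distribution",
    "dominant_species",
    "peak",
]

#: relative mass-balance tolerance at convergence
MASS_BALANCE_TOL = 1e-12
MAX_ITER = 200
MAX_LOG_STEP = 1.0  # Newton step clamp, log10 units


class ConvergenceError(RuntimeError):
    """Newton iteration failed to reach the mass-balance tolerance."""

    def __init__(self, message: str, residual_norm: float = float("nan")):
        super().__init__(message)
        self.residual_norm = residual_norm


@dataclass(frozen=True)
class SolutionState:
    """Equilibrium state of one solution composition at one pH."""

    pH: float
    free: Mapping[str, float]            # free concentration per component, mol/L
    species_conc: Mapping[str, float]    # concentration per formed species, mol/L
    converged: bool
    residual_norm: float


@dataclass(frozen=True)
class DistributionDiagram:
    """Percentage of a reference component bound in each species vs pH.

    ``percent`` maps species name -> array aligned with ``pH_grid``; the key
    equal to ``reference`` itself holds the free reference component.  At
    every grid point the curves of all reference-containing species plus the
    free reference sum to 100.
    """

    pH_grid: np.ndarray
    reference: str
    percent: Mapping[str, np.ndarray]
    total_reference: float


class _Compiled:
    """Model flattened to arrays for the Newton kernel.

    Components with zero (or absent) totals are dropped together with every
    species that contains them; their free concentration is exactly zero.
    """

    def __init__(self, model: SpeciationModel, totals: Mapping[str, float]):
        proton = model.proton_id
        unknown = set(totals) - set(model.component_ids)
        if unknown:
            raise KeyError(f"totals name undeclared components: {sorted(unknown)}")
        if any(v < 0 for v in totals.values()):
            raise ValueError("totals must be nonnegative")
        active = [c.id for c in model.components
                  if c.id != proton and totals.get(c.id, 0.0) > 0.0]
        self.proton = proton
        self.comp_ids = active
        self.totals = np.array([totals[c] for c in active], dtype=float)
        dropped = {c.id for c in model.components
                   if c.id != proton and c.id not in active}
        keep = [s for s in model.species
                if not any(s.coeff(c) != 0 for c in dropped)]
        self.species = keep
        self.names = [s.name for s in keep]
        self.logbeta = np.array([s.log_beta for s in keep], dtype=float)
        self.N = np.array([[s.coeff(c) for c in active] for s in keep],
                          dtype=float).reshape(len(keep), len(active))
        self.nH = np.array([s.coeff(proton) for s in keep], dtype=float)
        self.pKw = model.pKw

    def species_conc(self, u: np.ndarray, log_h: float) -> np.ndarray:
        if not self.species:
            return np.empty(0)
        # exponent clip keeps far-from-solution iterates finite (10**308
        # overflows to inf and poisons the damped Newton walk); clipping is
        # inactive anywhere near a physical solution
        exponent = self.logbeta + self.N @ u + self.nH * log_h
        return 10.0 ** np.clip(exponent, -300.0, 250.0)


def _newton_fixed_ph(comp: _Compiled, pH: float, u0: Optional[np.ndarray],
                     tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Damped Newton on log10 free concentrations at fixed pH."""
    n = len(comp.comp_ids)
    if n == 0:
        return np.empty(0), comp.species_conc(np.empty(0), -pH), 0.0, True

    log_h = -pH
    T = comp.totals

    def residual(u: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        f = 10.0 ** u
        c = comp.species_conc(u, log_h)
        bound = comp.N.T @ c if comp.species else np.zeros(n)
        R = f + bound - T
        scale = np.maximum(f + (np.abs(comp.N).T @ c if comp.species else 0.0), T)
        return R, c, float(np.max(np.abs(R) / scale))

    u = np.log10(T / 2.0) if u0 is None else u0.copy()
    R, c, norm = residual(u)
    for _ in range(max_iter):
        if norm < tol:
            return u, c, norm, True
        f = 10.0 ** u
        J = np.diag(f).astype(float)
        if comp.species:
            J += comp.N.T @ (comp.N * c[:, None])
        J *= np.log(10.0)
        try:
            du = np.linalg.solve(J, -R)
        except np.linalg.LinAlgError:
            break
        step = np.clip(du, -MAX_LOG_STEP, MAX_LOG_STEP)
        # damped step: accept the first halving whose scaled norm does not
        # increase (the norm can plateau while overshot species shrink
        # monotonically, so strict decrease is too greedy); if every
        # halving increases it, take the full clamped step anyway
        lam, accepted = 1.0, False
        for _ in range(8):
            u_try = u + lam * step
            R_try, c_try, norm_try = residual(u_try)
            if np.isfinite(norm_try) and norm_try <= norm:
                u, R, c, norm = u_try, R_try, c_try, norm_try
                accepted = True
                break
            lam *= 0.5
        if not accepted:
            u_try = u + step
            R_try, c_try, norm_try = residual(u_try)
            if not np.isfinite(norm_try):
                break
            u, R, c, norm = u_try, R_try, c_try, norm_try
    if norm < tol:
        return u, c, norm, True
    return u, c, norm, False


def solve_at_ph(model: SpeciationModel, totals: Mapping[str, float], pH: float,
                *, tol: float = MASS_BALANCE_TOL, max_iter: int = MAX_ITER,
                warm_start: Optional[SolutionState] = None,
                raise_on_failure: bool = True) -> SolutionState:
    """Solve the component mass balances at fixed pH.

    The proton is treated as known ([H] = 10**-pH on the concentration
    scale, matching a concentration-calibrated glass electrode); its mass
    balance is not part of the system.

    Parameters
    ----------
    totals
        Analytical (total) concentration per component, mol/L.  Components
        absent or zero are excluded together with their species.
    warm_start
        A previously converged state used as the initial guess (e.g. the
        neighbouring point of a pH grid).
    """
    comp = _Compiled(model, totals)
    if not comp.comp_ids:
        raise ValueError("totals must be positive for at least one non-proton component")
    u0 = None
    if warm_start is not None:
        free = [warm_start.free.get(c, 0.0) for c in comp.comp_ids]
        if all(f > 0 for f in free):
            u0 = np.log10(np.array(free))
    u, c, norm, ok = _newton_fixed_ph(comp, pH, u0, tol, max_iter)
    if not ok and u0 is not None:  # retry cold
        u, c, norm, ok = _newton_fixed_ph(comp, pH, None, tol, max_iter)
    if not ok and raise_on_failure:
        raise ConvergenceError(
            f"mass balance did not converge at pH {pH:.4f} "
            f"(scaled residual {norm:.3e})", norm)
    free = {cid: float(10.0 ** ui) for cid, ui in zip(comp.comp_ids, u)}
    free[comp.proton] = 10.0 ** (-pH)
    return SolutionState(float(pH), free,
                         dict(zip(comp.names, map(float, c))), ok, norm)


def ph_grid(ph_min: float, ph_max: float, step: float) -> np.ndarray:
    """Inclusive uniform pH grid; endpoints are always on the grid."""
    if not ph_min < ph_max:
        raise ValueError("pH_min must be < pH_max")
    if not step > 0:
        raise ValueError("step must be positive")
    n = int(round((ph_max - ph_min) / step))
    grid = ph_min + step * np.arange(n + 1)
    return np.round(grid, 10)


def distribution(model: SpeciationModel, totals: Mapping[str, float],
                 ph_min: float = 2.5, ph_max: float = 11.0, step: float = 0.01,
                 reference: str = "Cu") -> DistributionDiagram:
    """Compute a species distribution diagram over a pH grid.

    Each grid point is one fixed-pH solve, warm-started from the previous
    point.  Percentages are 100 * nu_ref,i * c_i / T_ref; the free reference
    component is included under the key ``reference``.
    """
    if reference not in model.component_ids:
        raise KeyError(f"reference component {reference!r} not in model")
    t_ref = totals.get(reference, 0.0)
    if t_ref <= 0:
        raise ValueError(f"total of reference component {reference!r} must be positive")
    grid = ph_grid(ph_min, ph_max, step)
    ref_species = [s.name for s in model.species if s.coeff(reference) != 0]
    nu = {s.name: s.coeff(reference) for s in model.species}
    percent: dict[str, np.ndarray] = {name: np.zeros(len(grid)) for name in ref_species}
    percent[reference] = np.zeros(len(grid))
    state: Optional[SolutionState] = None
    for k, ph in enumerate(grid):
        try:
            state = solve_at_ph(model, totals, float(ph), warm_start=state)
        except ConvergenceError as err:
            raise ConvergenceError(
                f"distribution failed at pH {ph:.4f}: {err}", err.residual_norm) from err
        for name in ref_species:
            c = state.species_conc.get(name, 0.0)
            percent[name][k] = 100.0 * nu[name] * c / t_ref
        percent[reference][k] = 100.0 * state.free[reference] / t_ref
    return DistributionDiagram(grid, reference, percent, t_ref)


def dominant_species(diagram: DistributionDiagram, pH: float) -> str:
    """Name of the complex holding the largest share of the reference at a pH.

    The free reference component is excluded unless the diagram contains no
    complexes at all.  Ties break lexicographically with a warning.
    """
    grid = diagram.pH_grid
    if pH < grid[0] - 1e-12 or pH > grid[-1] + 1e-12:
        raise ValueError(f"pH {pH} outside diagram range [{grid[0]}, {grid[-1]}]")
    k = int(np.argmin(np.abs(grid - pH)))
    candidates = [n for n in diagram.percent if n != diagram.reference]
    if not candidates:
        return diagram.reference
    best = max(v[k] for n, v in diagram.percent.items() if n != diagram.reference)
    winners = sorted(n for n in candidates if diagram.percent[n][k] == best)
    if len(winners) > 1:
        warnings.warn(f"tie at pH {grid[k]:.4f} between {winners}; "
                      "returning lexicographic first", stacklevel=2)
    return winners[0]


def peak(diagram: DistributionDiagram, species: str) -> tuple[float, float]:
    """(pH at maximum, maximum percent) of one species over the grid."""
    if species not in diagram.percent:
        raise KeyError(f"species {species!r} not in diagram")
    values = diagram.percent[species]
    k = int(np.argmax(values))
    return float(diagram.pH_grid[k]), float(values[k])
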