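"""Potentiometric titration simulation.

A titration starts from an initial solution (metal + ligands in their
as-weighed protonation states + strong mineral acid, volume v0) and adds
standardized NaOH.  At each titrant volume v the analytical totals are
diluted by v0/(v0+v) and the pH solves the full proton condition

    T_H(v) = [H] - Kw/[H] + sum_i nu_iH c_i

where T_H collects the titratable protons: strong acid plus the protons
each ligand carries as prepared, minus the added base.  Counterions (Na+,
K+, NO3-) are inert spectators and never enter the balance.

The proton condition is solved by the same damped Newton kernel as the
fixed-pH solver, with log10[H] as an additional unknown and the point
warm-started from its predecessor; the first point (or a Newton failure)
falls back to monotone bracketing of the pH.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .model import SpeciationModel
from .solver import (MASS_BALANCE_TOL, MAX_ITER, MAX_LOG_STEP, ConvergenceError,
                     SolutionState, _Compiled, solve_at_ph)

__all__ = [
    "TitrationProtocol",
    "TitrationCurve",
    "CurveComparison",
    "simulate_titration",
    "compare_curves",
    "design_protocol",
]

# pH window inside which the proton-balance root is bracketed
PH_BRACKET_MARGIN = 1.5


@dataclass(frozen=True)
class TitrationProtocol:
    """The experiment as data: initial solution, titrant, readings.

    ``component_mmol`` holds analytical millimoles of each non-proton
    component in the initial sample; ``initial_protonation`` the number of
    titratable protons each of those components carries as weighed in
    (e.g. 2 for a zwitterionic amino acid relative to its fully
    deprotonated form, 0 for a neutral nucleoside).
    """

    component_mmol: Mapping[str, float]
    acid_mmol: float = 0.0
    initial_protonation: Mapping[str, int] = field(default_factory=dict)
    v0_mL: float = 30.0
    titrant_conc_M: float = 0.20
    v_max_mL: float = 2.0
    n_points: int = 250

    def __post_init__(self) -> None:
        if not self.v0_mL > 0:
            raise ValueError("v0_mL must be positive")
        if not self.titrant_conc_M > 0:
            raise ValueError("titrant_conc_M must be positive")
        if self.n_points < 2:
            raise ValueError("n_points must be at least 2")
        if any(v < 0 for v in self.component_mmol.values()):
            raise ValueError("component_mmol must be nonnegative")

    @property
    def proton_mmol_initial(self) -> float:
        """Total titratable proton content of the initial solution, mmol."""
        return self.acid_mmol + sum(
            self.initial_protonation.get(c, 0) * m
            for c, m in self.component_mmol.items())

    def volumes(self) -> np.ndarray:
        return np.linspace(0.0, self.v_max_mL, self.n_points)

    def totals_at(self, v_mL: float) -> dict[str, float]:
        """Diluted analytical totals (mol/L) at titrant volume v."""
        vtot = self.v0_mL + v_mL
        return {c: m / vtot for c, m in self.component_mmol.items()}

    def proton_total_at(self, v_mL: float) -> float:
        """Diluted titratable proton total (mol/L, may be negative) at v."""
        return (self.proton_mmol_initial - self.titrant_conc_M * v_mL) / (self.v0_mL + v_mL)


@dataclass(frozen=True)
class TitrationCurve:
    """A (volume, pH) point sequence with its generating protocol."""

    volumes_mL: np.ndarray
    pH: np.ndarray
    protocol: TitrationProtocol
    noise_sigma_pH: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes_mL, dtype=float)
        p = np.asarray(self.pH, dtype=float)
        if v.shape != p.shape or v.ndim != 1:
            raise ValueError("volumes and pH must be 1-D arrays of equal length")
        if np.any(np.diff(v) <= 0):
            raise ValueError("volumes must be strictly increasing")
        object.__setattr__(self, "volumes_mL", v)
        object.__setattr__(self, "pH", p)

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.volumes_mL.tolist(), self.pH.tolist()))

    def __len__(self) -> int:
        return len(self.volumes_mL)


@dataclass(frozen=True)
class CurveComparison:
    """Pointwise pH difference of two curves on a common volume grid."""

    volumes_mL: np.ndarray
    delta_pH: np.ndarray
    max_abs_delta: float
    #: (volume, pH of curve a) at the first |delta| above the threshold, or None
    first_divergence: Optional[tuple[float, float]]
    threshold: float


def _proton_balance(comp: _Compiled, state_u: np.ndarray, log_h: float) -> float:
    f_h = 10.0 ** log_h
    c = comp.species_conc(state_u, log_h)
    kw = 10.0 ** (-comp.pKw)
    bound = float(comp.nH @ c) if comp.species else 0.0
    return f_h - kw / f_h + bound


def _solve_point_bracketed(model: SpeciationModel, comp: _Compiled,
                           totals: Mapping[str, float], t_h: float) -> float:
    """Monotone pH bracketing: outer root-find on the proton condition."""
    lo, hi = PH_BRACKET_MARGIN, model.pKw - PH_BRACKET_MARGIN

    def g(ph: float) -> float:
        if comp.comp_ids:
            st = solve_at_ph(model, totals, ph)
            u = np.log10(np.array([st.free[c] for c in comp.comp_ids]))
        else:
            u = np.empty(0)
        return _proton_balance(comp, u, -ph) - t_h

    g_lo, g_hi = g(lo), g(hi)
    if not (g_lo > 0 > g_hi):
        raise ConvergenceError(
            f"proton balance has no root in pH ({lo}, {hi}): "
            f"g({lo})={g_lo:.3e}, g({hi})={g_hi:.3e}")
    return float(brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16))


def _newton_full(comp: _Compiled, t_h: float, x0: np.ndarray,
                 tol: float = MASS_BALANCE_TOL,
                 max_iter: int = MAX_ITER) -> tuple[np.ndarray, float, bool]:
    """Newton on log10 free concentrations of all components incl. the proton.

    Unknown vector x = [u_1..u_n, log10 [H]].
    """
    n = len(comp.comp_ids)
    T = comp.totals
    kw = 10.0 ** (-comp.pKw)

    def residual(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        u, log_h = x[:n], x[n]
        f = 10.0 ** u
        f_h = 10.0 ** log_h
        c = comp.species_conc(u, log_h)
        bound = comp.N.T @ c if comp.species else np.zeros(n)
        h_bound = float(comp.nH @ c) if comp.species else 0.0
        R = np.empty(n + 1)
        R[:n] = f + bound - T
        R[n] = f_h - kw / f_h + h_bound - t_h
        scale = np.empty(n + 1)
        scale[:n] = np.maximum(f + (np.abs(comp.N).T @ c if comp.species else 0.0), T)
        scale[n] = max(f_h + kw / f_h + (float(np.abs(comp.nH) @ c) if comp.species else 0.0),
                       abs(t_h), 1e-14)
        return R, c, float(np.max(np.abs(R) / scale))

    x = x0.copy()
    R, c, norm = residual(x)
    for _ in range(max_iter):
        if norm < tol:
            return x, norm, True
        u, log_h = x[:n], x[n]
        f = 10.0 ** u
        f_h = 10.0 ** log_h
        J = np.zeros((n + 1, n + 1))
        J[:n, :n] = np.diag(f)
        J[n, n] = f_h + kw / f_h
        if comp.species:
            Nfull = np.hstack([comp.N, comp.nH[:, None]])
            J += Nfull.T @ (Nfull * c[:, None])
        J *= np.log(10.0)
        try:
            dx = np.linalg.solve(J, -R)
        except np.linalg.LinAlgError:
            break
        step = np.clip(dx, -MAX_LOG_STEP, MAX_LOG_STEP)
        lam, accepted = 1.0, False
        for _ in range(8):
            x_try = x + lam * step
            R_try, c_try, norm_try = residual(x_try)
            if np.isfinite(norm_try) and norm_try <= norm:
                x, R, c, norm = x_try, R_try, c_try, norm_try
                accepted = True
                break
            lam *= 0.5
        if not accepted:
            x_try = x + step
            R_try, c_try, norm_try = residual(x_try)
            if not np.isfinite(norm_try):
                break
            x, R, c, norm = x_try, R_try, c_try, norm_try
    return x, norm, norm < tol


def simulate_titration(model: SpeciationModel, protocol: TitrationProtocol,
                       volumes_mL: Optional[np.ndarray] = None) -> TitrationCurve:
    """Simulate the exact (noise-free) titration curve for a model.

    Parameters
    ----------
    volumes_mL
        Optional explicit titrant volumes; defaults to the protocol's
        uniform grid.
    """
    volumes = protocol.volumes() if volumes_mL is None else np.asarray(volumes_mL, float)
    totals0 = protocol.totals_at(0.0)
    comp = _Compiled(model, totals0)
    n = len(comp.comp_ids)
    ph_out = np.empty(len(volumes))
    x: Optional[np.ndarray] = None
    for k, v in enumerate(volumes):
        totals = protocol.totals_at(float(v))
        comp.totals = np.array([totals[c] for c in comp.comp_ids])
        t_h = protocol.proton_total_at(float(v))
        ok = False
        if x is not None:
            x_new, _, ok = _newton_full(comp, t_h, x)
            if ok:
                x = x_new
        if not ok:
            try:
                ph = _solve_point_bracketed(model, comp, totals, t_h)
            except ConvergenceError as err:
                raise ConvergenceError(
                    f"titration failed at volume {v:.4f} mL: {err}") from err
            if n:
                st = solve_at_ph(model, totals, ph)
                u = np.log10(np.array([st.free[c] for c in comp.comp_ids]))
            else:
                u = np.empty(0)
            x = np.append(u, -ph)
            x_new, norm, ok = _newton_full(comp, t_h, x)
            if ok:
                x = x_new
            # bracketed root is already accurate; Newton polish is best-effort
        ph_out[k] = -x[n]
    return TitrationCurve(volumes, ph_out, protocol, 0.0)


def titration_state(model: SpeciationModel, protocol: TitrationProtocol,
                    v_mL: float) -> SolutionState:
    """Full equilibrium state (free + species concentrations) at one volume."""
    curve = simulate_titration(model, protocol, np.array([0.0, v_mL])
                               if v_mL > 0 else np.array([v_mL, v_mL + 1e-6]))
    ph = curve.pH[-1 if v_mL > 0 else 0]
    return solve_at_ph(model, protocol.totals_at(v_mL), float(ph))


def compare_curves(a: TitrationCurve, b: TitrationCurve,
                   threshold: float = 0.05) -> CurveComparison:
    """Pointwise pH residuals of two curves on their common volume range.

    Curve ``b`` is linearly interpolated onto the volumes of ``a`` inside
    the overlap.  Reports the maximum |delta pH| and the first point where
    |delta| exceeds ``threshold``.
    """
    lo = max(a.volumes_mL[0], b.volumes_mL[0])
    hi = min(a.volumes_mL[-1], b.volumes_mL[-1])
    if lo > hi:
        raise ValueError("curves have disjoint volume ranges")
    mask = (a.volumes_mL >= lo) & (a.volumes_mL <= hi)
    v = a.volumes_mL[mask]
    pa = a.pH[mask]
    pb = np.interp(v, b.volumes_mL, b.pH)
    delta = pa - pb
    first: Optional[tuple[float, float]] = None
    above = np.nonzero(np.abs(delta) > threshold)[0]
    if above.size:
        k = int(above[0])
        first = (float(v[k]), float(pa[k]))
    return CurveComparison(v, delta, float(np.max(np.abs(delta))), first, threshold)


def design_protocol(model: SpeciationModel,
                    component_mmol: Mapping[str, float],
                    initial_protonation: Mapping[str, int],
                    start_pH: float = 2.5, end_pH: float = 11.0,
                    v0_mL: float = 30.0, titrant_conc_M: float = 0.20,
                    n_points: int = 250) -> TitrationProtocol:
    """Build a protocol whose curve spans [start_pH, end_pH].

    The strong-acid content is chosen so the initial solution sits at
    ``start_pH``, and the final titrant volume so the last point sits at
    ``end_pH`` (both found from the proton condition of the given model).
    """
    comp = _Compiled(model, {c: m / v0_mL for c, m in component_mmol.items()})

    def required_proton_total(ph: float, v: float) -> float:
        vtot = v0_mL + v
        totals = {c: m / vtot for c, m in component_mmol.items()}
        comp.totals = np.array([totals[c] for c in comp.comp_ids])
        if comp.comp_ids:
            st = solve_at_ph(model, totals, ph)
            u = np.log10(np.array([st.free[c] for c in comp.comp_ids]))
        else:
            u = np.empty(0)
        return _proton_balance(comp, u, -ph)

    ligand_mmol = sum(initial_protonation.get(c, 0) * m
                      for c, m in component_mmol.items())
    acid_mmol = required_proton_total(start_pH, 0.0) * v0_mL - ligand_mmol

    def g(v: float) -> float:
        return (acid_mmol + ligand_mmol - titrant_conc_M * v) \
            - required_proton_total(end_pH, v) * (v0_mL + v)

    v_hi = 1.0
    while g(v_hi) > 0 and v_hi < 1e4:
        v_hi *= 2.0
    v_max = float(brentq(g, 0.0, v_hi, xtol=1e-10))
    return TitrationProtocol(dict(component_mmol), float(acid_mmol),
                             dict(initial_protonation), v0_mL, titrant_conc_M,
                             v_max, n_points)
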