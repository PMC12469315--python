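"""Stability-constant refinement from titration curves.

Given one or more measured (volume, pH) curves and a candidate species
model, the overall constants of a chosen subset of species are refined by
Levenberg-Marquardt least squares on the pH residuals

    Sigma = sum_i w_i (pH_obs,i - pH_calc,i)^2

with pH_calc obtained by full titration simulation at the current log beta
vector.  All other constants (ligand protonation, auxiliary binary species,
hydrolysis) stay fixed, as is standard when ternary systems are refined on
top of known binary chemistry.  Asymptotic standard deviations come from
the scaled inverse normal matrix at the optimum.

Model selection among candidate species sets follows the practice of
preferring the largest number of species that refine with low standard
deviations and a low Sigma: species whose sigma exceeds a cap or whose
maximal formation share is below a floor are flagged as rejected, and
candidates are ranked lexicographically by (more accepted species, lower
mean sigma, lower Sigma).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .model import SpeciationModel
from .solver import ConvergenceError, distribution, peak
from .titration import TitrationCurve, simulate_titration

__all__ = ["RefinementSpec", "RefinementResult", "RefinementError",
           "refine", "select_model"]

#: absolute finite-difference step on log beta for the Jacobian (log10 units)
JACOBIAN_STEP = 1e-4
#: convergence tolerances on relative Sigma change and gradient norm
FTOL = 1e-8
GTOL = 1e-8
#: a species must at some pH bind at least this percentage of its reference
#: component to be considered observable
FORMATION_FLOOR_PERCENT = 2.0


class RefinementError(RuntimeError):
    """Divergence or a singular normal matrix during refinement."""


@dataclass(frozen=True)
class RefinementSpec:
    """What to refine: model, free parameters, data and weighting."""

    model: SpeciationModel
    free_parameters: tuple[str, ...]
    curves: tuple[TitrationCurve, ...]
    weighting: str = "unit"  # "unit" or "sigma_pH"

    def __post_init__(self) -> None:
        names = set(self.model.species_names())
        unknown = set(self.free_parameters) - names
        if unknown:
            raise ValueError(f"free parameters not in model: {sorted(unknown)}")
        if not self.curves:
            raise ValueError("at least one curve is required")
        if any(len(c) < 2 for c in self.curves):
            raise ValueError("every curve needs at least 2 points")
        if self.weighting not in ("unit", "sigma_pH"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


@dataclass(frozen=True)
class RefinementResult:
    """Refined constants with uncertainties and the Sigma statistic."""

    log_beta_hat: Mapping[str, float]
    sigma: Mapping[str, float]
    Sigma_stat: float
    n_iterations: int
    converged: bool
    rejected_species: frozenset[str] = frozenset()


def _curve_weights(spec: RefinementSpec) -> list[float]:
    if spec.weighting == "unit":
        return [1.0] * len(spec.curves)
    w = []
    for c in spec.curves:
        if c.noise_sigma_pH <= 0:
            raise ValueError("sigma_pH weighting requires noise_sigma_pH > 0 on every curve")
        w.append(1.0 / c.noise_sigma_pH ** 2)
    return w


class _Objective:
    """Weighted residual vector with per-protocol simulation caching.

    Replicate curves that share a protocol and volume grid need only one
    simulation per parameter vector; the cache also serves the repeated
    base-point evaluations of the finite-difference Jacobian.
    """

    def __init__(self, spec: RefinementSpec):
        self.spec = spec
        self.weights = _curve_weights(spec)
        self.groups: list[tuple[int, ...]] = []
        keys: dict[bytes, int] = {}
        for i, c in enumerate(spec.curves):
            key = repr((c.protocol, c.volumes_mL.tobytes())).encode()
            if key not in keys:
                keys[key] = len(self.groups)
                self.groups.append(())
            self.groups[keys[key]] += (i,)
        self._cache: dict[bytes, np.ndarray] = {}
        self.nfev = 0
        self.n_obs = sum(len(c) for c in spec.curves)
        #: pH-residual magnitude returned when the candidate constants make
        #: the equilibrium problem unsolvable; large enough that the
        #: minimizer always retreats from such a step
        self.penalty = 1e3

    def model_at(self, x: np.ndarray) -> SpeciationModel:
        updates = dict(zip(self.spec.free_parameters, map(float, x)))
        return self.spec.model.replace_log_beta(updates)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        key = np.asarray(x, float).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        model = self.model_at(x)
        pieces = []
        try:
            for group in self.groups:
                rep = self.spec.curves[group[0]]
                calc = simulate_titration(model, rep.protocol, rep.volumes_mL).pH
                for i in group:
                    c = self.spec.curves[i]
                    pieces.append(np.sqrt(self.weights[i]) * (c.pH - calc))
            r = np.concatenate(pieces)
        except ConvergenceError:
            if self.nfev == 0:  # the starting model itself is unsolvable
                raise
            r = np.full(self.n_obs, self.penalty)
        self._cache[key] = r
        self.nfev += 1
        return r

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """Central finite differences with a fixed absolute step."""
        J = np.empty((len(self(x)), len(x)))
        for j in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[j] += JACOBIAN_STEP
            xm[j] -= JACOBIAN_STEP
            J[:, j] = (self(xp) - self(xm)) / (2.0 * JACOBIAN_STEP)
        return J


def refine(spec: RefinementSpec,
           initial: Optional[Mapping[str, float]] = None) -> RefinementResult:
    """Refine the free log beta values of a specification.

    Parameters
    ----------
    initial
        Starting value per free parameter; defaults to the values stored in
        the model.  An empty ``free_parameters`` set evaluates Sigma at the
        model as-is and performs no iterations.
    """
    obj = _Objective(spec)
    if not spec.free_parameters:
        r = obj(np.empty(0))
        return RefinementResult({}, {}, float(r @ r), 0, True)

    x0 = np.array([
        (initial or {}).get(name, spec.model.species_by_name(name).log_beta)
        for name in spec.free_parameters])
    missing = [n for n in spec.free_parameters
               if initial is not None and n not in initial]
    if initial is not None and missing:
        raise ValueError(f"initial values missing for: {missing}")

    try:
        fit = least_squares(obj, x0, jac=obj.jacobian, method="lm",
                            ftol=FTOL, gtol=GTOL, xtol=1e-12)
    except ConvergenceError as err:
        raise RefinementError(f"titration simulation failed during refinement: {err}") from err
    if not fit.success:
        raise RefinementError(f"Levenberg-Marquardt did not converge: {fit.message}")

    r = fit.fun
    sigma_sq = float(r @ r)
    n_obs, n_par = len(r), len(fit.x)
    J = fit.jac
    # a species that never forms under the data's conditions leaves a dead
    # (numerically zero) Jacobian column: its constant is undetermined, so
    # it gets an infinite sigma instead of poisoning the normal matrix
    col_norm = np.linalg.norm(J, axis=0)
    dead = col_norm <= 1e-10 * max(float(col_norm.max()), 1.0)
    sigmas = np.full(n_par, np.inf)
    active = ~dead
    if active.any():
        Ja = J[:, active]
        try:
            cov = np.linalg.inv(Ja.T @ Ja)
        except np.linalg.LinAlgError:
            names = [n for n, a in zip(spec.free_parameters, active) if a]
            raise RefinementError(
                f"singular normal matrix; parameters {names} "
                "are not jointly identifiable") from None
        s2 = sigma_sq / max(n_obs - n_par, 1)
        sigmas[active] = np.sqrt(np.maximum(np.diag(cov) * s2, 0.0))

    return RefinementResult(
        dict(zip(spec.free_parameters, map(float, fit.x))),
        dict(zip(spec.free_parameters, map(float, sigmas))),
        sigma_sq, int(obj.nfev), True)


def _max_formation_percent(model: SpeciationModel, curve: TitrationCurve,
                           species: str) -> float:
    """Peak share of a species relative to the most telling component it contains.

    Evaluated at the initial composition of the curve's protocol over the
    standard pH window (coarse grid; only used for the observability floor).
    """
    sp = model.species_by_name(species)
    totals = curve.protocol.totals_at(0.0)
    refs = [c for c in sp.stoichiometry
            if sp.coeff(c) > 0 and c != model.proton_id and totals.get(c, 0) > 0]
    best = 0.0
    for ref in refs:
        diagram = distribution(model, totals, 2.5, 11.0, 0.05, reference=ref)
        if species in diagram.percent:
            best = max(best, peak(diagram, species)[1])
    return best


def select_model(candidates: Sequence[RefinementSpec],
                 curves: Optional[Sequence[TitrationCurve]] = None,
                 sigma_max: float = 0.1,
                 formation_floor_percent: float = FORMATION_FLOOR_PERCENT,
                 ) -> list[tuple[RefinementSpec, RefinementResult]]:
    """Refine candidate species models and rank them.

    Each candidate is refined on its own curves (or on ``curves`` if
    given).  Free species with sigma above ``sigma_max`` or with a maximal
    formation share below the floor are flagged in ``rejected_species``.
    Ranking is lexicographic: more accepted species first, then lower mean
    sigma, then lower Sigma.
    """
    if not candidates:
        raise ValueError("at least one candidate is required")
    results = []
    n_failed = 0
    for spec in candidates:
        if curves is not None:
            spec = replace(spec, curves=tuple(curves))
        try:
            res = refine(spec)
        except RefinementError:
            n_failed += 1
            continue
        rejected = set()
        for name in spec.free_parameters:
            if res.sigma[name] > sigma_max:
                rejected.add(name)
                continue
            fitted = spec.model.replace_log_beta(res.log_beta_hat)
            if _max_formation_percent(fitted, spec.curves[0], name) < formation_floor_percent:
                rejected.add(name)
        results.append((spec, replace(res, rejected_species=frozenset(rejected))))
    if not results:
        raise RefinementError(f"all {n_failed} candidates failed to converge")

    def rank_key(item: tuple[RefinementSpec, RefinementResult]):
        spec, res = item
        accepted = [n for n in spec.free_parameters if n not in res.rejected_species]
        mean_sigma = (float(np.mean([res.sigma[n] for n in spec.free_parameters]))
                      if spec.free_parameters else 0.0)
        return (-len(accepted), mean_sigma, res.Sigma_stat)

    return sorted(results, key=rank_key)
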