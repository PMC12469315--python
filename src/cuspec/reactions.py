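"""Stepwise equilibrium constants (log Ke) from overall stability constants.

Because every overall constant refers to formation from the same free
components, the equilibrium constant of any component-balanced reaction
between species follows by Hess-type additivity:

    log Ke = sum_products coeff * log beta - sum_reactants coeff * log beta

with free components counting as log beta = 0.  Water appearing in written
reactions is the solvent (activity 1) and is dropped; hydroxo species are
carried with proton stoichiometry -1, so reactions such as
"ML + H2O = ML(OH) + H" balance without a water component.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .model import SpeciationModel

__all__ = [
    "ReactionSpec",
    "ReactionError",
    "parse_reaction",
    "log_ke",
    "stepwise_protonation",
]

_ARROWS = ("⇌", "<=>", "=")
_SOLVENT = "H2O"


class ReactionError(ValueError):
    """Syntax error or component imbalance in a reaction."""


@dataclass(frozen=True)
class ReactionSpec:
    """A reaction as species names with positive integer coefficients."""

    reactants: Mapping[str, int]
    products: Mapping[str, int]

    def __post_init__(self) -> None:
        for side in (self.reactants, self.products):
            for name, coeff in side.items():
                if coeff <= 0:
                    raise ReactionError(f"coefficient of {name!r} must be positive")


def _parse_side(text: str, offset: int) -> dict[str, int]:
    terms: dict[str, int] = {}
    pos = offset
    for raw in text.split("+"):
        term = raw.strip()
        if not term:
            raise ReactionError(f"empty term at position {pos}")
        m = re.fullmatch(r"(\d+)?\s*(\S.*?)", term)
        if m is None:
            raise ReactionError(f"cannot parse term {term!r} at position {pos}")
        coeff = int(m.group(1)) if m.group(1) else 1
        name = m.group(2)
        if name != _SOLVENT:  # solvent water: activity 1, dropped
            terms[name] = terms.get(name, 0) + coeff
        pos += len(raw) + 1
    return terms


def parse_reaction(text: str) -> ReactionSpec:
    """Parse a reaction string such as ``"CuH(Tyr) + H(Tyr) = CuH2(Tyr)2"``.

    Sides are separated by one of ``⇌``, ``<=>`` or ``=``; terms by ``+``
    with an optional integer coefficient prefix.  Whitespace is ignored.
    Species names are kept verbatim; unknown names are only detected later,
    when the reaction is evaluated against a model.
    """
    for arrow in _ARROWS:
        if arrow in text:
            left, right = text.split(arrow, 1)
            if any(a in right for a in _ARROWS):
                raise ReactionError(f"more than one reaction arrow in {text!r}")
            reactants = _parse_side(left, 0)
            products = _parse_side(right, len(left) + len(arrow))
            if not reactants or not products:
                raise ReactionError(f"both sides must be non-empty in {text!r}")
            return ReactionSpec(reactants, products)
    raise ReactionError(f"no reaction arrow (⇌, <=> or =) found in {text!r}")


def _stoich_of(model: SpeciationModel, name: str) -> dict[str, int]:
    """Component stoichiometry of a species name or a free component."""
    if name in model.component_ids:
        return {name: 1}
    try:
        sp = model.species_by_name(name)
    except KeyError:
        raise ReactionError(f"unknown species {name!r}") from None
    return {c: v for c, v in sp.stoichiometry.items() if v != 0}


def _log_beta_of(model: SpeciationModel, name: str) -> float:
    if name in model.component_ids:
        return 0.0  # free components form from themselves
    return model.species_by_name(name).log_beta


def log_ke(model: SpeciationModel, reaction: ReactionSpec) -> float:
    """Equilibrium constant (log10) of a component-balanced reaction.

    Raises :class:`ReactionError` reporting the per-component imbalance if
    the reaction does not balance.
    """
    balance: dict[str, int] = {}
    for side, sign in ((reaction.reactants, -1), (reaction.products, +1)):
        for name, coeff in side.items():
            for comp, nu in _stoich_of(model, name).items():
                balance[comp] = balance.get(comp, 0) + sign * coeff * nu
    imbalance = {c: v for c, v in balance.items() if v != 0}
    if imbalance:
        raise ReactionError(f"reaction not balanced in components: {imbalance}")
    value = 0.0
    for name, coeff in reaction.products.items():
        value += coeff * _log_beta_of(model, name)
    for name, coeff in reaction.reactants.items():
        value -= coeff * _log_beta_of(model, name)
    return float(value)


def log_ke_rounded(model: SpeciationModel, reaction: ReactionSpec,
                   ndigits: int = 2) -> float:
    """log Ke rounded half-even, for comparison with tabulated values."""
    return float(np.round(log_ke(model, reaction), ndigits))


def stepwise_protonation(model: SpeciationModel, ligand: str) -> list[float]:
    """Stepwise protonation constants log K_n of a ligand, highest pKa first.

    From the protonation ladder HL, H2L, ... of overall constants:
    log K1 = log beta_HL, log K2 = log beta_H2L - log beta_HL, etc.
    """
    proton = model.proton_id
    ladder: dict[int, float] = {}
    for sp in model.species:
        stoich = {c: v for c, v in sp.stoichiometry.items() if v != 0}
        n_h = stoich.pop(proton, 0)
        if stoich == {ligand: 1} and n_h >= 1:
            ladder[n_h] = sp.log_beta
    if not ladder:
        raise ReactionError(f"no protonation species for ligand {ligand!r}")
    steps = []
    prev = 0.0
    for n in range(1, max(ladder) + 1):
        if n not in ladder:
            raise ReactionError(f"protonation ladder of {ligand!r} is missing H{n} step")
        steps.append(ladder[n] - prev)
        prev = ladder[n]
    return steps
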