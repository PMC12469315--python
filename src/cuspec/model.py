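"""Speciation models: components, species and overall stability constants.

A speciation model is the list of solution components (metal ions, ligands
and the proton) together with every complex or protonated species that can
form from them.  Each species carries an overall formation constant

    beta = [M_m L_l H_h] / ([M]^m [L]^l [H]^h)

stored as ``log_beta`` (base 10, molar concentration scale).  Hydroxide is
handled with the usual convention OH- == H(-1): hydroxo species carry a
negative proton stoichiometry, which is why hydrolysis constants such as
Cu(OH)2 have negative log beta.

Constants are conditional: they hold at the ionic strength and temperature
recorded on the model and no activity corrections are applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Component",
    "SpeciesDef",
    "SpeciationModel",
    "ModelError",
    "build_model",
    "validate_model",
]

#: default -log10([H][OH]) used when a model does not state its own value;
#: concentration-scale water autoprotolysis product typical of a 0.1 M
#: inert-electrolyte medium near 20-25 C.
DEFAULT_PKW = 13.78


class ModelError(ValueError):
    """Raised when a speciation model violates its invariants."""


@dataclass(frozen=True)
class Component:
    """A solution component: a metal ion, a ligand or the proton.

    ``charge`` is informational only; no charge balance is enforced on
    species (complex charges are bookkeeping, not chemistry, at fixed
    ionic strength).
    """

    id: str
    name: str = ""
    role: str = "ligand"  # one of {"metal", "ligand", "proton"}
    charge: Optional[int] = None

    def __post_init__(self) -> None:
        if self.role not in ("metal", "ligand", "proton"):
            raise ModelError(f"component {self.id!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class SpeciesDef:
    """A complex or protonated species with its overall formation constant.

    ``stoichiometry`` maps component id to a signed integer coefficient;
    hydroxo species have negative proton coefficients.
    """

    name: str
    stoichiometry: Mapping[str, int]
    log_beta: float
    sigma_log_beta: Optional[float] = None

    def __post_init__(self) -> None:
        if not any(v != 0 for v in self.stoichiometry.values()):
            raise ModelError(f"species {self.name!r}: all-zero stoichiometry")
        if self.sigma_log_beta is not None and self.sigma_log_beta < 0:
            raise ModelError(f"species {self.name!r}: negative sigma_log_beta")

    def coeff(self, component_id: str) -> int:
        return int(self.stoichiometry.get(component_id, 0))


@dataclass(frozen=True)
class SpeciationModel:
    """A validated equilibrium model: components, species, medium."""

    components: tuple[Component, ...]
    species: tuple[SpeciesDef, ...]
    pKw: float = DEFAULT_PKW
    temperature_C: float = 20.0
    ionic_strength_M: float = 0.1
    name: str = ""

    # -- convenience accessors -------------------------------------------
    @property
    def component_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.components)

    @property
    def proton_id(self) -> str:
        for c in self.components:
            if c.role == "proton":
                return c.id
        raise ModelError("model has no proton component")

    @property
    def metal_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.components if c.role == "metal")

    def component(self, component_id: str) -> Component:
        for c in self.components:
            if c.id == component_id:
                return c
        raise KeyError(component_id)

    def species_by_name(self, name: str) -> SpeciesDef:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def replace_log_beta(self, updates: Mapping[str, float]) -> "SpeciationModel":
        """Return a copy of the model with some log beta values replaced."""
        unknown = set(updates) - set(self.species_names())
        if unknown:
            raise KeyError(f"unknown species: {sorted(unknown)}")
        new_species = tuple(
            SpeciesDef(s.name, dict(s.stoichiometry), float(updates.get(s.name, s.log_beta)),
                       s.sigma_log_beta)
            for s in self.species
        )
        return SpeciationModel(self.components, new_species, self.pKw,
                               self.temperature_C, self.ionic_strength_M, self.name)

    def drop_species(self, names: Iterable[str]) -> "SpeciationModel":
        """Return a copy of the model without the named species."""
        drop = set(names)
        unknown = drop - set(self.species_names())
        if unknown:
            raise KeyError(f"unknown species: {sorted(unknown)}")
        kept = tuple(s for s in self.species if s.name not in drop)
        return SpeciationModel(self.components, kept, self.pKw,
                               self.temperature_C, self.ionic_strength_M, self.name)


def validate_model(model: SpeciationModel) -> list[str]:
    """Check all model invariants; return a list of violations (empty if valid).

    Violations are reported, never raised, so a caller can present them all
    at once.
    """
    violations: list[str] = []
    ids = [c.id for c in model.components]
    seen = set()
    for cid in ids:
        if cid in seen:
            violations.append(f"duplicate component id {cid!r}")
        seen.add(cid)
    n_protons = sum(1 for c in model.components if c.role == "proton")
    if n_protons != 1:
        violations.append(f"model must have exactly one proton component, found {n_protons}")
    names = set()
    for s in model.species:
        if s.name in names:
            violations.append(f"duplicate species name {s.name!r}")
        names.add(s.name)
        if s.name in seen:
            violations.append(f"species {s.name!r} shadows a component id")
        for cid in s.stoichiometry:
            if cid not in seen:
                violations.append(f"species {s.name!r} references undeclared component {cid!r}")
        if not any(v != 0 for v in s.stoichiometry.values()):
            violations.append(f"species {s.name!r} has all-zero stoichiometry")
    if not model.pKw > 0:
        violations.append(f"pKw must be positive, got {model.pKw}")
    return violations


def build_model(components: Sequence[Component],
                species: Sequence[SpeciesDef],
                pKw: float = DEFAULT_PKW,
                temperature_C: float = 20.0,
                ionic_strength_M: float = 0.1,
                name: str = "") -> SpeciationModel:
    """Assemble and validate a speciation model.

    Raises :class:`ModelError` listing every violation if the inputs do not
    form a valid model.
    """
    model = SpeciationModel(tuple(components), tuple(species), float(pKw),
                            float(temperature_C), float(ionic_strength_M), name)
    violations = validate_model(model)
    if violations:
        raise ModelError("invalid model: " + "; ".join(violations))
    return model
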