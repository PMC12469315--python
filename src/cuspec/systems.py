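"""Bundled equilibrium models for the five Cu(II)/tyrosine systems.

Five ready-made fixtures ship with the package as JSON model files:

========== ==========================================================
Cu_Tyr      binary Cu(II)/tyrosine (protonation + four Cu complexes
            + Cu(OH)2 hydrolysis)
Cu_Tyr_Ado  ternary with adenosine
Cu_Tyr_AMP  ternary with adenosine-5'-monophosphate
Cu_Tyr_ADP  ternary with adenosine-5'-diphosphate
Cu_Tyr_ATP  ternary with adenosine-5'-triphosphate
========== ==========================================================

Each ternary model carries the full constant set needed to speciate that
system: tyrosine protonation, the binary Cu/Tyr complexes, the second
ligand's protonation ladder, its binary Cu complexes, the ternary species
and Cu(OH)2.  All constants are conditional values at 0.1 M KNO3, 20 C,
on the molar concentration scale.
"""

from __future__ import annotations

import functools
from importlib import resources

from .model import SpeciationModel

__all__ = ["SYSTEMS", "bundled_model", "system_components"]

#: bundled system identifiers
SYSTEMS = ("Cu_Tyr", "Cu_Tyr_Ado", "Cu_Tyr_AMP", "Cu_Tyr_ADP", "Cu_Tyr_ATP")

#: titratable protons per formula unit as weighed in, relative to the fully
#: deprotonated component: tyrosine is the zwitterion, adenosine the neutral
#: base, AMP the free acid, ADP and ATP the mono- and di-sodium salts (the
#: sodium counterions are inert).
AS_WEIGHED_PROTONATION = {"Tyr": 2, "Ado": 0, "AMP": 2, "ADP": 2, "ATP": 2}


def _check_system(system: str) -> None:
    if system not in SYSTEMS:
        raise KeyError(f"unknown system {system!r}; choose one of {SYSTEMS}")


def system_components(system: str) -> tuple[str, ...]:
    """Component ids of a bundled system (metal, ligand(s), proton)."""
    _check_system(system)
    if system == "Cu_Tyr":
        return ("Cu", "Tyr", "H")
    return ("Cu", "Tyr", system.rsplit("_", 1)[1], "H")


@functools.lru_cache(maxsize=None)
def bundled_model(system: str) -> SpeciationModel:
    """Load a bundled model; the returned object is immutable and cached."""
    _check_system(system)
    from .io import read_model  # local import to avoid a cycle
    path = resources.files("cuspec.data").joinpath(f"{system}.json")
    with resources.as_file(path) as p:
        return read_model(p)
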