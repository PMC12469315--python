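"""Seeded synthetic titration studies.

Emulates the statistical structure of the potentiometric experiments the
bundled constants came from: ~30 mL initial volume, ~0.20 M NaOH titrant,
C_Cu = 1e-3 M with metal:ligand 1:2 in binary and 1:1:1 in ternary systems,
pH 2.5-11.0, ~250 readings per curve, at least six replicate curves.  The
only stochastic element is i.i.d. Gaussian noise on the pH readings
(burette volumes are treated as exact); the default sigma of 0.005 pH is an
electrode-grade figure chosen here, not a published one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .model import SpeciationModel
from .systems import AS_WEIGHED_PROTONATION, bundled_model, system_components
from .titration import TitrationCurve, TitrationProtocol, design_protocol, simulate_titration

__all__ = ["NoiseModel", "SyntheticStudy", "generate_curve", "generate_study"]

#: analytical metal concentration of the emulated experiments, mol/L
C_METAL = 1e-3
#: metal:ligand ratio used in the binary design
BINARY_LIGAND_RATIO = 2.0


@dataclass(frozen=True)
class NoiseModel:
    """Per-point Gaussian pH noise with a reproducibility seed."""

    sigma_pH: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_pH < 0:
            raise ValueError("sigma_pH must be nonnegative")


@dataclass(frozen=True)
class SyntheticStudy:
    """A reproducible set of replicate curves generated from a known truth."""

    truth: SpeciationModel
    protocol: TitrationProtocol
    curves: tuple[TitrationCurve, ...]
    noise: NoiseModel
    system: str = ""


def generate_curve(model: SpeciationModel, protocol: TitrationProtocol,
                   noise: NoiseModel) -> TitrationCurve:
    """One noisy replicate: exact simulation plus i.i.d. Gaussian pH noise."""
    clean = simulate_titration(model, protocol)
    if noise.sigma_pH == 0:
        return clean
    rng = np.random.default_rng(noise.seed)
    noisy = clean.pH + rng.normal(0.0, noise.sigma_pH, size=len(clean))
    return TitrationCurve(clean.volumes_mL, noisy, protocol, noise.sigma_pH)


def study_design(system: str) -> tuple[dict[str, float], dict[str, int]]:
    """Analytical millimoles and as-weighed protonation for a bundled system."""
    comps = system_components(system)
    v0 = 30.0
    mmol = {"Cu": C_METAL * v0}
    for ligand in comps:
        if ligand in ("Cu", "H"):
            continue
        ratio = BINARY_LIGAND_RATIO if len(comps) == 3 else 1.0
        mmol[ligand] = ratio * C_METAL * v0
    protonation = {c: AS_WEIGHED_PROTONATION[c] for c in mmol if c != "Cu"}
    return mmol, protonation


def generate_study(system: str, n_curves: int, noise: NoiseModel,
                   n_points: int = 250,
                   protocol: Optional[TitrationProtocol] = None) -> SyntheticStudy:
    """Generate a full replicate study for one bundled system.

    Replicate curves share the protocol and differ only in their noise
    seeds, derived deterministically as ``noise.seed + curve index`` so the
    study is reproducible as a whole.
    """
    if n_curves < 1:
        raise ValueError("n_curves must be at least 1")
    truth = bundled_model(system)
    if protocol is None:
        mmol, protonation = study_design(system)
        protocol = design_protocol(truth, mmol, protonation, n_points=n_points)
    curves = tuple(
        generate_curve(truth, protocol, replace(noise, seed=noise.seed + i))
        for i in range(n_curves))
    return SyntheticStudy(truth, protocol, curves, noise, system)
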