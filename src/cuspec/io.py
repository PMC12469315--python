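"""Readers and writers for the package's plain-text formats.

Formats (no binary formats anywhere):

* model JSON: components[], species[] (name, stoich, log_beta, sigma),
  pKw, temperature_C, ionic_strength_M
* titration CSV: two columns ``volume_mL,pH``, one header line
* distribution TSV: first column pH, one column per species, percent with
  four decimals
* refinement report JSON; synthetic-study directory of curve CSVs plus a
  manifest JSON
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .model import Component, SpeciationModel, SpeciesDef, build_model
from .refine import RefinementResult
from .solver import DistributionDiagram
from .synth import NoiseModel, SyntheticStudy
from .titration import TitrationCurve, TitrationProtocol

__all__ = [
    "SchemaError",
    "read_model", "write_model",
    "read_curve", "write_curve",
    "write_distribution", "read_distribution",
    "write_refinement_report",
    "write_study", "read_study",
]

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """A file parsed but does not match the expected schema."""


# --------------------------------------------------------------------------
# model JSON

def _model_to_dict(model: SpeciationModel) -> dict:
    return {
        "name": model.name,
        "pKw": model.pKw,
        "temperature_C": model.temperature_C,
        "ionic_strength_M": model.ionic_strength_M,
        "components": [
            {"id": c.id, "name": c.name, "role": c.role, "charge": c.charge}
            for c in model.components],
        "species": [
            {"name": s.name,
             "stoich": {k: v for k, v in s.stoichiometry.items() if v != 0},
             "log_beta": s.log_beta,
             "sigma": s.sigma_log_beta}
            for s in model.species],
    }


def write_model(model: SpeciationModel, path: PathLike) -> None:
    Path(path).write_text(json.dumps(_model_to_dict(model), indent=1) + "\n")


def read_model(path: PathLike) -> SpeciationModel:
    """Read and validate a model JSON file.

    Schema violations are collected and reported together in a single
    :class:`SchemaError`.
    """
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise SchemaError(f"{path}: not valid JSON at line {err.lineno}: {err.msg}") from err
    problems = [f"missing key {key!r}" for key in ("components", "species", "pKw")
                if key not in raw]
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    components = []
    for i, c in enumerate(raw["components"]):
        if "id" not in c:
            problems.append(f"components[{i}]: missing 'id'")
            continue
        components.append(Component(c["id"], c.get("name", ""),
                                    c.get("role", "ligand"), c.get("charge")))
    species = []
    for i, s in enumerate(raw["species"]):
        missing = [k for k in ("name", "stoich", "log_beta") if k not in s]
        if missing:
            problems.append(f"species[{i}]: missing {missing}")
            continue
        species.append(SpeciesDef(s["name"], {k: int(v) for k, v in s["stoich"].items()},
                                  float(s["log_beta"]), s.get("sigma")))
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    return build_model(components, species, float(raw["pKw"]),
                       float(raw.get("temperature_C", 20.0)),
                       float(raw.get("ionic_strength_M", 0.1)),
                       raw.get("name", ""))


# --------------------------------------------------------------------------
# titration curve CSV

def write_curve(curve: TitrationCurve, path: PathLike) -> None:
    df = pd.DataFrame({"volume_mL": curve.volumes_mL, "pH": curve.pH})
    df.to_csv(path, index=False, float_format="%.9f")


def read_curve(curve_path: PathLike,
               protocol: TitrationProtocol | None = None,
               noise_sigma_pH: float = 0.0) -> TitrationCurve:
    """Read a ``volume_mL,pH`` CSV; volumes must be strictly increasing."""
    df = pd.read_csv(curve_path)
    for col in ("volume_mL", "pH"):
        if col not in df.columns:
            raise SchemaError(f"{curve_path}: missing column {col!r}")
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise SchemaError(f"{curve_path}: non-numeric value in column "
                              f"{col!r} at data row {row}")
        df[col] = numeric
    if df[["volume_mL", "pH"]].isna().any().any():
        raise SchemaError(f"{curve_path}: missing values")
    v = df["volume_mL"].to_numpy()
    decreasing = np.nonzero(np.diff(v) <= 0)[0]
    if decreasing.size:
        raise SchemaError(f"{curve_path}: volumes not strictly increasing "
                          f"at data row {int(decreasing[0]) + 1}")
    if protocol is None:
        protocol = TitrationProtocol(component_mmol={}, v_max_mL=float(v[-1]),
                                     n_points=max(len(v), 2))
    return TitrationCurve(v, df["pH"].to_numpy(), protocol, noise_sigma_pH)


# --------------------------------------------------------------------------
# distribution TSV

def write_distribution(diagram: DistributionDiagram, path: PathLike) -> None:
    cols = {"pH": diagram.pH_grid}
    cols.update({name: diagram.percent[name] for name in diagram.percent})
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_distribution(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --------------------------------------------------------------------------
# refinement report

def write_refinement_report(result: RefinementResult, path: PathLike) -> None:
    report = {
        "log_beta_hat": dict(result.log_beta_hat),
        "sigma": dict(result.sigma),
        "Sigma_stat": result.Sigma_stat,
        "n_iterations": result.n_iterations,
        "converged": result.converged,
        "rejected_species": sorted(result.rejected_species),
    }
    Path(path).write_text(json.dumps(report, indent=1) + "\n")


def format_refinement_table(result: RefinementResult) -> str:
    """Human-readable refinement summary."""
    lines = [f"{'species':<22} {'log beta':>10} {'sigma':>8}"]
    for name, value in result.log_beta_hat.items():
        sig = result.sigma.get(name, float("nan"))
        flag = "  [rejected]" if name in result.rejected_species else ""
        lines.append(f"{name:<22} {value:>10.3f} {sig:>8.3f}{flag}")
    lines.append(f"Sigma = {result.Sigma_stat:.6g}  "
                 f"({result.n_iterations} evaluations, "
                 f"{'converged' if result.converged else 'NOT converged'})")
    return "\n".join(lines)


# --------------------------------------------------------------------------
# synthetic studies

def write_study(study: SyntheticStudy, directory: PathLike) -> None:
    """One CSV per curve plus a manifest JSON describing the generation."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, curve in enumerate(study.curves):
        name = f"curve_{i:02d}.csv"
        write_curve(curve, directory / name)
        names.append(name)
    p = study.protocol
    manifest = {
        "system": study.system,
        "noise": {"sigma_pH": study.noise.sigma_pH, "seed": study.noise.seed},
        "curve_files": names,
        "protocol": {
            "component_mmol": dict(p.component_mmol),
            "acid_mmol": p.acid_mmol,
            "initial_protonation": dict(p.initial_protonation),
            "v0_mL": p.v0_mL,
            "titrant_conc_M": p.titrant_conc_M,
            "v_max_mL": p.v_max_mL,
            "n_points": p.n_points,
        },
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")


def read_study(directory: PathLike) -> tuple[TitrationProtocol, list[TitrationCurve], NoiseModel]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    p = manifest["protocol"]
    protocol = TitrationProtocol(
        {k: float(v) for k, v in p["component_mmol"].items()},
        float(p["acid_mmol"]),
        {k: int(v) for k, v in p["initial_protonation"].items()},
        float(p["v0_mL"]), float(p["titrant_conc_M"]),
        float(p["v_max_mL"]), int(p["n_points"]))
    noise = NoiseModel(float(manifest["noise"]["sigma_pH"]),
                       int(manifest["noise"]["seed"]))
    curves = [read_curve(directory / name, protocol, noise.sigma_pH)
              for name in manifest["curve_files"]]
    return protocol, curves, noise
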