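"""Configuration files, deterministic exports and closed-form test fixtures.

Configs are YAML with the model's default parameters embedded; exports are legacy
ASCII VTK structured-points files (cell data only, written by the package
itself so snapshots stay plain text and byte-reproducible) plus CSV time
series.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tpmsbone import evolution as ev
from tpmsbone.geometry import DesignSpec, PhaseLabel, VoxelRVE
from tpmsbone.simulate import EvolutionConfig, MaterialState, Materials


# ---------------------------------------------------------------- config

def config_to_dict(cfg: EvolutionConfig) -> dict:
    return {
        "design": {
            "kind": cfg.design.kind,
            "weights": list(cfg.design.weights),
            "thickness": cfg.design.thickness,
            "resolution": cfg.design.resolution,
            "edge_length": cfg.design.edge_length,
        },
        "materials": asdict(cfg.materials),
        "degradation": asdict(cfg.degradation),
        "remodeling": asdict(cfg.remodeling),
        "protocol": {
            "applied_strain": cfg.applied_strain,
            "duration": cfg.duration,
            "resorption": cfg.resorption,
            "remodel_interface": cfg.remodel_interface,
            "new_bone_factor": cfg.new_bone_factor,
            "solver_rtol": cfg.solver_rtol,
            "seed": cfg.seed,
        },
    }


def config_from_dict(data: dict) -> EvolutionConfig:
    d = data.get("design", {})
    design = DesignSpec(
        kind=d.get("kind", "S"),
        weights=tuple(d.get("weights", (1.0, 0.0))),
        thickness=d.get("thickness", 0.3),
        resolution=d.get("resolution", 50),
        edge_length=d.get("edge_length", 1.0),
    )
    materials = Materials(**data.get("materials", {}))
    degradation = ev.DegradationParams(**data.get("degradation", {}))
    remodeling = ev.RemodelingParams(**data.get("remodeling", {}))
    proto = data.get("protocol", {})
    return EvolutionConfig(
        design=design, materials=materials, degradation=degradation,
        remodeling=remodeling,
        applied_strain=proto.get("applied_strain", 0.10),
        duration=proto.get("duration", 100),
        resorption=proto.get("resorption", False),
        remodel_interface=proto.get("remodel_interface", True),
        new_bone_factor=proto.get("new_bone_factor", 2.0),
        solver_rtol=proto.get("solver_rtol", 1e-8),
        seed=proto.get("seed", 0),
    )


def save_config(cfg: EvolutionConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def load_config(path) -> EvolutionConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------- VTK

def write_vtk_cells(path, resolution: int, spacing: float,
                    fields: dict[str, np.ndarray]) -> None:
    """Legacy ASCII VTK structured-points file with per-cell scalar fields.

    The payload contains no timestamps, so identical inputs produce
    byte-identical files.
    """
    n = resolution
    lines = [
        "# vtk DataFile Version 3.0",
        "tpmsbone cell state",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {n + 1} {n + 1} {n + 1}",
        "ORIGIN 0 0 0",
        f"SPACING {spacing:.10g} {spacing:.10g} {spacing:.10g}",
        f"CELL_DATA {n ** 3}",
    ]
    for name, arr in fields.items():
        a = np.asarray(arr).reshape(-1)
        if a.size != n**3:
            raise ValueError(f"field {name!r} has wrong size")
        if np.issubdtype(a.dtype, np.integer):
            lines.append(f"SCALARS {name} int 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(" ".join(str(int(v)) for v in a[i:i + 9])
                         for i in range(0, a.size, 9))
        else:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(" ".join(f"{v:.12g}" for v in a[i:i + 9])
                         for i in range(0, a.size, 9))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_cells(path) -> tuple[int, float, dict[str, np.ndarray]]:
    """Read back a file written by :func:`write_vtk_cells`."""
    tokens = Path(path).read_text().splitlines()
    n = None
    spacing = None
    fields: dict[str, np.ndarray] = {}
    i = 0
    while i < len(tokens):
        line = tokens[i]
        if line.startswith("DIMENSIONS"):
            n = int(line.split()[1]) - 1
        elif line.startswith("SPACING"):
            spacing = float(line.split()[1])
        elif line.startswith("SCALARS"):
            _, name, typ, _ = line.split()
            vals: list = []
            i += 2  # skip LOOKUP_TABLE
            while i < len(tokens) and tokens[i] and not tokens[i][0].isalpha() \
                    and tokens[i][0] not in "#":
                vals.extend(tokens[i].split())
                i += 1
            dtype = np.int64 if typ == "int" else float
            fields[name] = np.array(vals, dtype=dtype)
            continue
        i += 1
    if n is None or spacing is None:
        raise ValueError("not a tpmsbone VTK cell file")
    return n, spacing, fields


def export_state(state: MaterialState, path, format: str = "vtk",
                 von_mises: np.ndarray | None = None) -> None:
    """Snapshot the per-element state as VTK cell data or a CSV table."""
    n = state.rve.resolution
    fields = {
        "phase": state.labels.astype(np.int64),
        "E": state.E,
        "beta": state.beta,
        "rho": state.rho,
    }
    if von_mises is not None:
        fields["von_mises"] = von_mises
    if format == "vtk":
        write_vtk_cells(path, n, state.rve.spacing, fields)
    elif format == "csv":
        pd.DataFrame({k: np.asarray(v).reshape(-1) for k, v in fields.items()}
                     ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown export format {format!r}")


def export_record(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


# ---------------------------------------------------------------- fixtures

@dataclass(frozen=True)
class Fixture:
    """A small grid with a closed-form expected apparent modulus."""

    name: str
    rve: VoxelRVE
    modulus: np.ndarray
    nu: float
    expected_modulus: float
    formula: str


def make_homogeneous_cube(n: int, E: float = 1350.0, nu: float = 0.3,
                          edge_length: float = 1.0) -> Fixture:
    """Single-phase cube; apparent modulus equals the material modulus."""
    if n < 1:
        raise ValueError("n must be at least 1")
    labels = np.full((n, n, n), PhaseLabel.TISSUE, dtype=np.int8)
    rve = VoxelRVE(labels, edge_length=edge_length)
    return Fixture("homogeneous_cube", rve, np.full(n**3, float(E)), nu,
                   float(E), "E_app = E")


def make_series_laminate(n: int, E1: float, E2: float,
                         edge_length: float = 1.0) -> Fixture:
    """Two equal-thickness layers stacked along the loading (z) axis.

    At nu = 0 the layers act in series, so the apparent modulus is the
    harmonic (Reuss) mean 2 E1 E2 / (E1 + E2).
    """
    if n % 2:
        raise ValueError("n must be even")
    labels = np.full((n, n, n), PhaseLabel.TISSUE, dtype=np.int8)
    rve = VoxelRVE(labels, edge_length=edge_length)
    E = np.empty((n, n, n))
    E[:, :, : n // 2] = E1
    E[:, :, n // 2:] = E2
    expected = 2.0 * E1 * E2 / (E1 + E2)
    return Fixture("series_laminate", rve, E.reshape(-1), 0.0,
                   expected, "E_app = 2 E1 E2 / (E1 + E2) at nu = 0")
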