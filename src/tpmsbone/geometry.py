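"""TPMS level-set geometry and three-phase voxelization.

One cubic unit cell of a triply periodic minimal surface (TPMS) is mapped
onto a regular N x N x N voxel grid.  Elements whose level-set value lies
inside a thin band around the surface are labeled scaffold, a slightly
wider band yields the interfacial (cartilage-like) layer, and everything
else is tissue.  The exact band convention is not unique a priori;
:func:`calibrate_shell_convention` scans a small candidate set and selects
the convention that reproduces a reference element census for all three
surface types simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
from scipy import ndimage

TWO_PI = 2.0 * np.pi


class PhaseLabel(IntEnum):
    SCAFFOLD = 0
    INTERFACE = 1
    TISSUE = 2


def surface_s(x, y, z):
    """Schwarz P level set: cos x + cos y + cos z."""
    return np.cos(x) + np.cos(y) + np.cos(z)


def surface_f(x, y, z):
    """Fischer-Koch S level set."""
    return (
        np.cos(2 * x) * np.sin(y) * np.cos(z)
        + np.cos(2 * y) * np.sin(z) * np.cos(x)
        + np.cos(2 * z) * np.sin(x) * np.cos(y)
    )


def surface_l(x, y, z):
    """Lidinoid level set (with its +0.15 offset constant)."""
    return (
        0.5
        * (
            np.sin(2 * x) * np.cos(y) * np.sin(z)
            + np.sin(2 * y) * np.cos(z) * np.sin(x)
            + np.sin(2 * z) * np.cos(x) * np.sin(y)
        )
        - 0.5
        * (
            np.cos(2 * x) * np.cos(2 * y)
            + np.cos(2 * y) * np.cos(2 * z)
            + np.cos(2 * z) * np.cos(2 * x)
        )
        + 0.15
    )


SURFACES = {"S": surface_s, "F": surface_f, "L": surface_l}


@dataclass(frozen=True)
class DesignSpec:
    """A TPMS shell design: surface choice, shell thickness, discretization.

    Parameters
    ----------
    kind:
        ``"S"`` (Schwarz P), ``"F"`` (Fischer-Koch S), ``"L"`` (lidinoid) or
        ``"fused"`` for the linear S/F hybrid ``a*f_S + b*f_F``.
    weights:
        Fusion weights ``(a, b)`` with ``a + b = 1``; only used for
        ``kind="fused"``.
    thickness:
        Dimensionless level-set shell parameter ``t`` (band half-width on
        the raw surface value).
    resolution:
        Voxels per edge; one unit cell spans the whole grid.
    edge_length:
        Physical edge length in mm.
    """

    kind: str = "S"
    weights: tuple[float, float] = (1.0, 0.0)
    thickness: float = 0.3
    resolution: int = 50
    edge_length: float = 1.0

    def __post_init__(self):
        if self.kind not in ("S", "F", "L", "fused"):
            raise ValueError(f"unknown surface kind {self.kind!r}")
        a, b = self.weights
        if a < 0 or b < 0 or abs(a + b - 1.0) > 1e-9:
            raise ValueError("fusion weights must be non-negative and sum to 1")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if self.resolution < 4:
            raise ValueError("resolution must be at least 4")
        if self.edge_length <= 0:
            raise ValueError("edge_length must be positive")

    @property
    def spacing(self) -> float:
        return self.edge_length / self.resolution


def evaluate_surface(point, spec: DesignSpec):
    """Evaluate the design's implicit function at period coordinates.

    ``point`` is a length-3 sequence (or three broadcastable arrays stacked
    on the last axis) in radians; one unit cell spans ``[0, 2*pi)`` per axis.
    """
    x, y, z = np.asarray(point[0]), np.asarray(point[1]), np.asarray(point[2])
    if spec.kind == "fused":
        a, b = spec.weights
        return a * surface_s(x, y, z) + b * surface_f(x, y, z)
    return SURFACES[spec.kind](x, y, z)


@dataclass(frozen=True)
class ShellConvention:
    """Voxel classification rule for the level-set shell.

    ``sample`` selects the per-element scalar: ``"centroid"`` evaluates f at
    the element centroid, ``"trilinear"`` averages the 8 corner-node values
    (the trilinear interpolant at the centroid).  The scaffold band is
    ``|f| <= inner_fraction * t`` and the interface occupies the remaining
    ring up to ``|f| <= outer_fraction * t`` when ``interface="band"``;
    ``"dilate-face"``/``"dilate-vertex"`` instead grow the interface by a
    one-voxel morphological dilation of the scaffold.  ``offset`` shifts the
    period origin (counts are invariant, free-surface mechanics is not).
    """

    sample: str = "trilinear"
    inner_fraction: float = 0.8
    outer_fraction: float = 1.0
    interface: str = "band"
    offset: float = 0.0

    def describe(self) -> str:
        return (
            f"sample={self.sample}, scaffold |f|<={self.inner_fraction:g}t, "
            f"interface={self.interface} (outer {self.outer_fraction:g}t), "
            f"offset={self.offset:g}"
        )


#: Convention recovered by calibrating against the reference 50^3 census
#: of all three surface types jointly (zero residual for each type).
CALIBRATED_CONVENTION = ShellConvention(
    sample="trilinear", inner_fraction=0.8, outer_fraction=1.0,
    interface="band", offset=0.0,
)


@dataclass
class VoxelRVE:
    """Regular voxel grid with a per-element phase label."""

    labels: np.ndarray  # (N, N, N) int8 of PhaseLabel values
    edge_length: float = 1.0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 3 or len(set(self.labels.shape)) != 1:
            raise ValueError("labels must be a cubic 3-d array")

    @property
    def resolution(self) -> int:
        return self.labels.shape[0]

    @property
    def spacing(self) -> float:
        return self.edge_length / self.resolution

    @property
    def element_count(self) -> int:
        return self.labels.size

    def count(self, label: PhaseLabel) -> int:
        return int(np.count_nonzero(self.labels == label))


@dataclass(frozen=True)
class PhaseCensus:
    scaffold_elements: int
    interface_elements: int
    tissue_elements: int
    porosity: float  # percent

    @property
    def total(self) -> int:
        return self.scaffold_elements + self.interface_elements + self.tissue_elements


def _sample_field(spec: DesignSpec, convention: ShellConvention) -> np.ndarray:
    """Per-element level-set scalar on the N^3 grid."""
    n = spec.resolution
    if convention.sample == "centroid":
        c = TWO_PI * (np.arange(n) + 0.5) / n + convention.offset
        grids = np.meshgrid(c, c, c, indexing="ij")
        return evaluate_surface(grids, spec)
    if convention.sample == "trilinear":
        nodes = TWO_PI * np.arange(n + 1) / n + convention.offset
        grids = np.meshgrid(nodes, nodes, nodes, indexing="ij")
        v = evaluate_surface(grids, spec)
        out = np.zeros((n, n, n))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    out += v[dx:n + dx, dy:n + dy, dz:n + dz]
        return out / 8.0
    raise ValueError(f"unknown sampling rule {convention.sample!r}")


def voxelize_shell(
    spec: DesignSpec,
    convention: ShellConvention = CALIBRATED_CONVENTION,
    three_phase: bool = True,
) -> VoxelRVE:
    """Voxelize the level-set shell into a labeled grid.

    With ``three_phase=True`` (default) the calibrated band convention
    labels scaffold, interface and tissue in one pass.  With
    ``three_phase=False`` only the scaffold band is labeled and everything
    else is provisionally tissue (use :func:`grow_interface` afterwards for
    a morphological interface).
    """
    f = np.abs(_sample_field(spec, convention))
    t = spec.thickness
    labels = np.full(f.shape, PhaseLabel.TISSUE, dtype=np.int8)
    scaffold = f <= convention.inner_fraction * t
    if not scaffold.any():
        raise ValueError(
            "degenerate geometry: no scaffold elements at this resolution"
        )
    if three_phase and convention.interface == "band":
        labels[f <= convention.outer_fraction * t] = PhaseLabel.INTERFACE
    labels[scaffold] = PhaseLabel.SCAFFOLD
    rve = VoxelRVE(labels, edge_length=spec.edge_length)
    if three_phase and convention.interface.startswith("dilate"):
        conn = "face" if convention.interface.endswith("face") else "vertex"
        rve = grow_interface(rve, connectivity=conn)
    return rve


_CONNECTIVITY_RANK = {"face": 1, "edge": 2, "vertex": 3}


def grow_interface(rve: VoxelRVE, connectivity: str = "face",
                   periodic: bool = True) -> VoxelRVE:
    """Relabel tissue adjacent to scaffold as interface (one-voxel dilation).

    Scaffold labels are never changed; existing interface labels are kept.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"unknown connectivity {connectivity!r}")
    struct = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    scaffold = rve.labels == PhaseLabel.SCAFFOLD
    if periodic:
        dil = ndimage.binary_dilation(np.pad(scaffold, 1, mode="wrap"), struct)
        dil = dil[1:-1, 1:-1, 1:-1]
    else:
        dil = ndimage.binary_dilation(scaffold, struct)
    labels = rve.labels.copy()
    labels[dil & (labels == PhaseLabel.TISSUE)] = PhaseLabel.INTERFACE
    return VoxelRVE(labels, edge_length=rve.edge_length)


def phase_census(rve: VoxelRVE) -> PhaseCensus:
    """Counts by phase and scaffold porosity (percent of non-scaffold volume)."""
    ns = rve.count(PhaseLabel.SCAFFOLD)
    ni = rve.count(PhaseLabel.INTERFACE)
    nt = rve.count(PhaseLabel.TISSUE)
    porosity = (1.0 - ns / rve.element_count) * 100.0
    return PhaseCensus(ns, ni, nt, porosity)


#: Reference census used for calibration: per surface type, (scaffold
#: elements, tissue elements) on the 50^3 grid at thickness 0.3.
REFERENCE_CENSUS = {
    "S": (16904, 103344),
    "F": (29944, 87648),
    "L": (44512, 72344),
}


@dataclass(frozen=True)
class CalibrationResult:
    convention: ShellConvention
    residuals: dict = field(default_factory=dict)  # kind -> (d_scaffold, d_tissue)

    @property
    def total_mismatch(self) -> int:
        return int(sum(abs(a) + abs(b) for a, b in self.residuals.values()))


def _candidate_conventions() -> list[ShellConvention]:
    cands = []
    for sample in ("centroid", "trilinear"):
        for outer in (1.0, 0.5):
            for inner_frac in (1.0, 0.9, 0.8, 0.75, 0.5):
                inner = outer * inner_frac
                if inner > outer:
                    continue
                ifaces = ["band"] if inner < outer else []
                ifaces += ["dilate-face", "dilate-vertex"]
                for iface in ifaces:
                    cands.append(ShellConvention(sample, inner, outer, iface))
    return cands


def calibrate_shell_convention(
    targets: dict = REFERENCE_CENSUS,
    candidates: list[ShellConvention] | None = None,
    resolution: int = 50,
    thickness: float = 0.3,
) -> CalibrationResult:
    """Scan candidate shell conventions against the reference census.

    Returns the convention minimizing the summed absolute count mismatch
    over all surface types, together with the per-type residuals (which are
    reported even when nonzero rather than silently accepted).
    """
    if candidates is None:
        candidates = _candidate_conventions()
    if not candidates:
        raise ValueError("empty candidate set")
    best = None
    for conv in candidates:
        residuals = {}
        for kind, (sc_target, tis_target) in targets.items():
            spec = DesignSpec(kind=kind, thickness=thickness,
                              resolution=resolution)
            try:
                rve = voxelize_shell(spec, conv)
            except ValueError:
                residuals = None
                break
            cen = phase_census(rve)
            residuals[kind] = (cen.scaffold_elements - sc_target,
                               cen.tissue_elements - tis_target)
        if residuals is None:
            continue
        result = CalibrationResult(conv, residuals)
        if best is None or result.total_mismatch < best.total_mismatch:
            best = result
    if best is None:
        raise ValueError("no candidate convention could be evaluated")
    return best


def fused_spec(a: float, b: float, **kwargs) -> DesignSpec:
    """Convenience constructor for an S/F fusion design."""
    if abs(a - 1.0) < 1e-12:
        return DesignSpec(kind="S", **kwargs)
    if abs(b - 1.0) < 1e-12:
        return DesignSpec(kind="F", **kwargs)
    return DesignSpec(kind="fused", weights=(a, b), **kwargs)
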