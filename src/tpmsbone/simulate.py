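"""Daily coupled degradation-osteogenesis loop on a TPMS RVE.

The procedure has three conceptual steps: (1) apply the compressive
displacement and solve for the stress field, (2) advance the per-element
material state one day at a time under the held load -- scaffold elements
hydrolyze at a stress-accelerated rate, tissue and interface elements
remodel when their daily stimulus leaves the dead zone, fully degraded
scaffold elements convert to tissue -- and (3) measure the apparent
modulus of the evolved state from the stress-strain response.  Because the
load is held throughout, the solve that starts each increment doubles as
the modulus measurement of the previous day's state, so a duration-D run
costs D + 1 linear solves.

The pipeline is fully deterministic: identical configurations reproduce
identical trajectories bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from tpmsbone import evolution as ev
from tpmsbone import fe
from tpmsbone.geometry import (
    CALIBRATED_CONVENTION,
    DesignSpec,
    PhaseLabel,
    ShellConvention,
    VoxelRVE,
    fused_spec,
    voxelize_shell,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Materials:
    """Initial phase moduli (MPa) and the common Poisson ratio."""

    E_scaffold: float = 1350.0
    E_interface: float = 50.0
    E_tissue: float = 10.0
    nu: float = 0.3


@dataclass
class MaterialState:
    """Per-element evolving state on a fixed voxel grid.

    ``labels`` is the *current* phase of each element (scaffold elements
    that fully degrade become tissue).  ``beta`` is meaningful on scaffold
    elements, ``rho`` on remodelable (interface/tissue) elements, and ``E``
    everywhere.
    """

    rve: VoxelRVE
    labels: np.ndarray        # (ne,) int8, current phase
    beta: np.ndarray          # (ne,) normalized molecular weight
    rho: np.ndarray           # (ne,) apparent density g/cm^3
    E: np.ndarray             # (ne,) Young's modulus MPa
    rho_init: np.ndarray
    E_init: np.ndarray

    def copy(self) -> "MaterialState":
        return MaterialState(
            self.rve, self.labels.copy(), self.beta.copy(), self.rho.copy(),
            self.E.copy(), self.rho_init.copy(), self.E_init.copy(),
        )

    @property
    def scaffold_mask(self) -> np.ndarray:
        return self.labels == PhaseLabel.SCAFFOLD

    @property
    def remodelable_mask(self) -> np.ndarray:
        return self.labels != PhaseLabel.SCAFFOLD


def initial_state(
    rve: VoxelRVE,
    materials: Materials = Materials(),
    remodeling: ev.RemodelingParams = ev.RemodelingParams(),
) -> MaterialState:
    """Assign initial moduli, beta = 1 and power-law-consistent densities."""
    labels = rve.labels.reshape(-1).copy()
    ne = labels.size
    E = np.empty(ne)
    E[labels == PhaseLabel.SCAFFOLD] = materials.E_scaffold
    E[labels == PhaseLabel.INTERFACE] = materials.E_interface
    E[labels == PhaseLabel.TISSUE] = materials.E_tissue
    beta = np.ones(ne)
    rho = ev.modulus_to_density(E, remodeling)
    return MaterialState(rve, labels, beta, rho, E, rho.copy(), E.copy())


@dataclass(frozen=True)
class EvolutionConfig:
    """Full specification of one coupled evolution run."""

    design: DesignSpec = DesignSpec()
    materials: Materials = Materials()
    degradation: ev.DegradationParams = ev.DegradationParams()
    remodeling: ev.RemodelingParams = ev.RemodelingParams()
    convention: ShellConvention = CALIBRATED_CONVENTION
    applied_strain: float = 0.10
    duration: int = 100               # days
    resorption: bool = False          # apply the below-dead-zone branch
    remodel_interface: bool = True    # interface follows the tissue law
    new_bone_factor: float = 2.0      # bone-volume threshold x initial E_T
    refresh_stress_between_updates: bool = False
    measurement_days: tuple[int, ...] | None = None  # None: record every day
    solver_rtol: float = 1e-8
    seed: int = 0                     # reserved; the pipeline is deterministic

    def __post_init__(self):
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.applied_strain <= 0:
            raise ValueError("applied strain must be positive")
        if self.measurement_days is not None and any(
            d < 0 or d > self.duration for d in self.measurement_days
        ):
            raise ValueError("measurement days must lie in [0, duration]")


@dataclass
class EvolutionRecord:
    """Per-day time series plus the final state of one run."""

    table: pd.DataFrame
    final_state: MaterialState
    config: EvolutionConfig
    aborted_day: int | None = None


def _metrics_row(day, state: MaterialState, e_app, cfg: EvolutionConfig):
    sc = state.scaffold_mask
    rem = state.remodelable_mask
    ne = state.labels.size
    new_bone_E = cfg.new_bone_factor * cfg.materials.E_tissue
    return {
        "day": day,
        "apparent_modulus": e_app,
        "scaffold_volume_fraction": 100.0 * sc.sum() / ne,
        "scaffold_elements": int(sc.sum()),
        "interface_elements": int((state.labels == PhaseLabel.INTERFACE).sum()),
        "tissue_elements": int((state.labels == PhaseLabel.TISSUE).sum()),
        "mean_beta": float(state.beta[sc].mean()) if sc.any() else float("nan"),
        "bone_volume_elements": int(
            (rem & (state.E > new_bone_E) & (state.E > state.E_init)).sum()
        ),
        "osteo_delta_rho": float((state.rho - state.rho_init)[rem].sum()),
        "osteo_delta_modulus": float((state.E - state.E_init)[rem].sum()),
        "total_tissue_density": float(state.rho[rem].sum()),
    }


def _advance_one_day(state: MaterialState, vm: np.ndarray,
                     cfg: EvolutionConfig) -> None:
    """In-place one-day update of the state given per-element von Mises."""
    deg, rem = cfg.degradation, cfg.remodeling
    sc = state.scaffold_mask
    # hydrolysis on scaffold elements
    state.beta[sc] = ev.update_beta(state.beta[sc], vm[sc], 1.0, deg)
    state.E[sc] = ev.scaffold_modulus(
        state.beta[sc], cfg.materials.E_scaffold, cfg.materials.E_tissue
    )
    # remodeling on tissue (and optionally interface) elements
    target = state.remodelable_mask
    if not cfg.remodel_interface:
        target &= state.labels != PhaseLabel.INTERFACE
    _remodel_masked(state, vm, target, cfg)
    # state change: fully degraded scaffold becomes fresh tissue
    converted = ev.apply_state_change(state.beta, state.labels, sc, deg)
    if converted.any():
        state.labels[converted] = PhaseLabel.TISSUE
        state.E[converted] = cfg.materials.E_tissue
        state.rho[converted] = ev.modulus_to_density(
            cfg.materials.E_tissue, rem
        )
        state.rho_init[converted] = state.rho[converted]
        state.E_init[converted] = state.E[converted]


def run_evolution(cfg: EvolutionConfig) -> EvolutionRecord:
    """Run the daily coupled loop and record per-day metrics.

    Day 0 reports the undegraded state; day ``d`` reports the state after
    ``d`` daily increments, its apparent modulus measured by a fresh
    compression of the updated material field.
    """
    rve = voxelize_shell(cfg.design, cfg.convention)
    state = initial_state(rve, cfg.materials, cfg.remodeling)
    edofs = fe.element_dofs(rve.resolution)
    rows = []
    aborted = None
    u_prev = None
    result = fe.solve_uniaxial(
        rve, state.E, cfg.materials.nu, cfg.applied_strain,
        rtol=cfg.solver_rtol, edofs=edofs,
    )
    rows.append(_metrics_row(0, state, result.apparent_modulus, cfg))
    for day in range(1, cfg.duration + 1):
        try:
            if cfg.refresh_stress_between_updates:
                # split update: degrade on the held stress, then re-solve so
                # remodeling sees the post-degradation field
                _degrade_only(state, result.von_mises, cfg)
                mid = fe.solve_uniaxial(
                    rve, state.E, cfg.materials.nu, cfg.applied_strain,
                    rtol=cfg.solver_rtol, K=None,
                    x0=result.displacements, edofs=edofs,
                )
                _remodel_only(state, mid.von_mises, cfg)
                _convert_only(state, cfg)
            else:
                _advance_one_day(state, result.von_mises, cfg)
            u_prev = result.displacements
            result = fe.solve_uniaxial(
                rve, state.E, cfg.materials.nu, cfg.applied_strain,
                rtol=cfg.solver_rtol, x0=u_prev, edofs=edofs,
            )
        except RuntimeError as exc:  # solver failure: return partial record
            log.error("evolution aborted on day %d: %s", day, exc)
            aborted = day
            break
        rows.append(_metrics_row(day, state, result.apparent_modulus, cfg))
        log.info(
            "day %3d: E_app=%.3f MPa, scaffold %.2f%%, mean beta %.4f",
            day, rows[-1]["apparent_modulus"],
            rows[-1]["scaffold_volume_fraction"], rows[-1]["mean_beta"],
        )
    table = pd.DataFrame(rows)
    if cfg.measurement_days is not None:
        keep = set(cfg.measurement_days) | {0}
        table = table[table.day.isin(keep)].reset_index(drop=True)
    return EvolutionRecord(table, state, cfg, aborted)


def _degrade_only(state, vm, cfg):
    sc = state.scaffold_mask
    state.beta[sc] = ev.update_beta(state.beta[sc], vm[sc], 1.0,
                                    cfg.degradation)
    state.E[sc] = ev.scaffold_modulus(
        state.beta[sc], cfg.materials.E_scaffold, cfg.materials.E_tissue
    )


def _remodel_only(state, vm, cfg):
    target = state.remodelable_mask
    if not cfg.remodel_interface:
        target &= state.labels != PhaseLabel.INTERFACE
    _remodel_masked(state, vm, target, cfg)


def _remodel_masked(state, vm, target, cfg):
    rem = cfg.remodeling
    phi = ev.daily_stimulus(vm[target], rem)
    drho = ev.density_rate(phi, rem)
    if not cfg.resorption:
        drho = np.maximum(drho, 0.0)
    # touch only elements that actually remodel: a zero increment must leave
    # the stored modulus bit-identical (dead zone is an exact fixed point)
    drho = np.asarray(drho)
    active = drho != 0.0
    idx = np.flatnonzero(target)[active]
    if idx.size:
        rho_new = np.clip(state.rho[idx] + drho[active],
                          rem.rho_min, rem.rho_max)
        state.rho[idx] = rho_new
        state.E[idx] = ev.density_to_modulus(rho_new, rem)


def _convert_only(state, cfg):
    converted = ev.apply_state_change(state.beta, state.labels,
                                      state.scaffold_mask, cfg.degradation)
    if converted.any():
        state.labels[converted] = PhaseLabel.TISSUE
        state.E[converted] = cfg.materials.E_tissue
        state.rho[converted] = ev.modulus_to_density(
            cfg.materials.E_tissue, cfg.remodeling
        )
        state.rho_init[converted] = state.rho[converted]
        state.E_init[converted] = state.E[converted]


def measure_apparent_modulus(
    state: MaterialState,
    nu: float = 0.3,
    applied_strain: float = 0.10,
    rtol: float = 1e-8,
) -> float:
    """Fresh uniaxial compression of a frozen state; force/area/strain."""
    result = fe.solve_uniaxial(state.rve, state.E, nu, applied_strain,
                               rtol=rtol)
    return result.apparent_modulus


def fusion_scan(
    ratios: list[tuple[float, float]],
    cfg: EvolutionConfig,
) -> dict[tuple[float, float], EvolutionRecord]:
    """One full evolution per S/F fusion ratio.

    Endpoint ratios (1, 0) and (0, 1) reduce exactly to the pure S-type
    and F-type runs.
    """
    out = {}
    for a, b in ratios:
        design = fused_spec(
            a, b,
            thickness=cfg.design.thickness,
            resolution=cfg.design.resolution,
            edge_length=cfg.design.edge_length,
        )
        out[(a, b)] = run_evolution(replace(cfg, design=design))
    return out
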