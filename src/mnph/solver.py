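"""Transient Pennes bioheat solver on a labeled voxel grid.

The model solved per voxel (tissue i) is

    rho_i c_i dT/dt = div(k_i grad T) + rho_b c_b w_b,i (T_b - T)
                      + Q_m,i + Q_eddy + Q_p * pf(t)

with constant per-tissue properties, a perfusion sink toward arterial blood
temperature T_b, metabolic heat, and external volumetric sources modulated
by the pulse train's on/off power factor pf(t).

Discretization: conservative 7-point finite volumes on the isotropic voxel
grid, harmonic-mean conductivity at faces between different tissues, and
unconditionally stable backward-Euler time stepping.  Each step solves one
symmetric positive-definite sparse system by preconditioned conjugate
gradients; the system matrix is constant in time, so stepping is cheap even
for 80-minute pulsed treatments.  Exterior voxels are excluded from the
unknowns; tissue faces adjacent to exterior (or to the domain boundary)
carry the configured boundary condition per face axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg

from .sources import (AMFExposure, MIONLoading, PulseSchedule, SLPModel,
                      eddy_field, power_factor, q_p_field)
from .tissue import (AXIS_INDEX, BloodProperties, BodyModel, TissueProperties,
                     VoxelGrid, effective_body, voxelize)

logger = logging.getLogger(__name__)


class SolverError(RuntimeError):
    """Raised when a linear solve fails to converge."""


@dataclass(frozen=True)
class BoundaryCondition:
    """Condition applied on tissue faces without a tissue neighbor.

    kind:
        ``"convective"`` — Robin condition with heat-transfer coefficient
        ``heat_transfer_coefficient`` (W/(m^2 K)) toward ``ambient`` (C);
        ``"adiabatic"`` — zero flux;
        ``"fixed"`` — Dirichlet face temperature ``ambient`` (C); ``ambient``
        may be a callable ``f(x, y, z)`` evaluated at face centers.
    """

    kind: str = "convective"
    heat_transfer_coefficient: float = 10.0
    ambient: float | Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray] = 25.0

    def __post_init__(self) -> None:
        if self.kind not in ("convective", "adiabatic", "fixed"):
            raise ValueError(f"unknown boundary kind {self.kind!r}")
        if self.heat_transfer_coefficient < 0:
            raise ValueError("heat_transfer_coefficient must be >= 0")


ADIABATIC = BoundaryCondition(kind="adiabatic")


@dataclass(frozen=True)
class BoundarySet:
    """Boundary condition per face axis.

    For the torso, X and Z faces form the lateral (skin) surface and Y faces
    are the end caps.  Defaults: convective air exposure on the lateral
    surface (h = 10 W/(m^2 K), 25 C ambient) and adiabatic end caps
    (approximating continuation of the body).
    """

    x: BoundaryCondition = field(default_factory=BoundaryCondition)
    y: BoundaryCondition = ADIABATIC
    z: BoundaryCondition = field(default_factory=BoundaryCondition)

    def along(self, axis: int) -> BoundaryCondition:
        return (self.x, self.y, self.z)[axis]

    @classmethod
    def uniform(cls, bc: BoundaryCondition) -> "BoundarySet":
        return cls(x=bc, y=bc, z=bc)


@dataclass(frozen=True)
class SolverConfig:
    """Numerical configuration for the bioheat solver.

    time_step : s, backward-Euler step; must divide the pulse on-block.
    spacing : m, voxel spacing used when the caller does not supply a grid.
    boundaries : per-axis boundary conditions.
    rtol : relative residual tolerance of the conjugate-gradient solves.
    record_every : record per-region extrema every this many steps.
    """

    time_step: float = 10.0
    spacing: float = 0.004
    boundaries: BoundarySet = field(default_factory=BoundarySet)
    rtol: float = 1e-8
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.time_step <= 0:
            raise ValueError("time_step must be > 0")
        if not 0 < self.rtol <= 1e-4:
            raise ValueError("rtol must lie in (0, 1e-4]")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass(frozen=True)
class TemperatureField:
    """Voxel temperatures (C) aligned to a grid; exterior voxels are NaN."""

    grid: VoxelGrid
    values: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")

    def region_max(self, name: str) -> float:
        return float(np.nanmax(self.values[self.grid.region_mask(name)]))

    def region_min(self, name: str) -> float:
        return float(np.nanmin(self.values[self.grid.region_mask(name)]))


@dataclass
class TimeSeriesResult:
    """Per-region temperature extrema traces from a transient simulation."""

    times: np.ndarray
    region_names: tuple[str, ...]
    tmax: np.ndarray            # (n_times, n_regions)
    tmin: np.ndarray
    dt: float
    schedule: PulseSchedule | None = None
    baseline: TemperatureField | None = None
    final: TemperatureField | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def _col(self, region: str) -> int:
        try:
            return self.region_names.index(region)
        except ValueError:
            raise KeyError(f"unknown region {region!r}") from None

    def trace(self, region: str, kind: str = "max") -> np.ndarray:
        """Extremum trace for one region (or a ``'+'``-joined union)."""
        names = region.split("+")
        arr = self.tmax if kind == "max" else self.tmin
        cols = arr[:, [self._col(n) for n in names]]
        return cols.max(axis=1) if kind == "max" else cols.min(axis=1)

    def to_frame(self):
        """Time series as a DataFrame: time_s, then Tmax/Tmin per region."""
        import pandas as pd

        data = {"time_s": self.times}
        for j, name in enumerate(self.region_names):
            data[f"Tmax_{name}"] = self.tmax[:, j]
        for j, name in enumerate(self.region_names):
            data[f"Tmin_{name}"] = self.tmin[:, j]
        return pd.DataFrame(data)


def _props_of(body: BodyModel | Mapping[str, TissueProperties]
              ) -> Mapping[str, TissueProperties]:
    if isinstance(body, BodyModel):
        return body.properties
    return body


class PennesSystem:
    """Assembled discrete Pennes operator for one grid + property set.

    Builds (once) the SPD matrix ``A`` combining conduction, perfusion and
    boundary couplings over the active (non-exterior) voxels, the constant
    load vector (perfusion toward T_b, metabolic heat, boundary ambient
    terms), and the volumetric heat capacity vector.  Time steppers for any
    dt reuse the same structure.
    """

    def __init__(self, grid: VoxelGrid,
                 body: BodyModel | Mapping[str, TissueProperties],
                 blood: BloodProperties | None = None,
                 config: SolverConfig | None = None):
        if isinstance(body, BodyModel) and blood is None:
            blood = body.blood
        if blood is None:
            raise ValueError("blood properties required")
        props = _props_of(body)
        missing = set(grid.region_names) - set(props)
        if missing:
            raise ValueError(f"no properties for regions {sorted(missing)}")
        self.grid = grid
        self.blood = blood
        self.config = config or SolverConfig()
        self._steppers: dict[float, tuple] = {}

        labels = grid.labels
        if np.all(labels < 0):
            raise ValueError("grid has no labeled (tissue) voxels")
        active = labels >= 0
        self.active = active
        self.n = int(active.sum())
        idx = np.full(labels.shape, -1, dtype=np.int64)
        idx[active] = np.arange(self.n)
        self._index = idx

        def lut(attr: str) -> np.ndarray:
            return np.array([getattr(props[n], attr)
                             for n in grid.region_names])

        safe_labels = np.clip(labels, 0, None)
        k3 = np.where(active, lut("conductivity")[safe_labels], 0.0)
        self.mass = (lut("density") * lut("specific_heat"))[labels[active]]
        perf = (blood.perfusion_factor
                * lut("perfusion")[labels[active]])          # W/(m^3 K)
        qm = lut("metabolic_rate")[labels[active]]

        h = grid.spacing
        diag = perf.copy()
        rhs = perf * blood.arterial_temperature + qm
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []

        # conduction between adjacent active voxels: harmonic-mean face
        # conductivity, coupling k_face / h^2 per unit volume
        for ax in range(3):
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[ax] = slice(None, -1)
            sl_b[ax] = slice(1, None)
            ia, ib = idx[tuple(sl_a)], idx[tuple(sl_b)]
            ka, kb = k3[tuple(sl_a)], k3[tuple(sl_b)]
            m = (ia >= 0) & (ib >= 0)
            ia, ib, ka, kb = ia[m], ib[m], ka[m], kb[m]
            g = (2.0 * ka * kb / (ka + kb)) / h ** 2
            rows += [ia, ib]
            cols += [ib, ia]
            vals += [-g, -g]
            np.add.at(diag, ia, g)
            np.add.at(diag, ib, g)

        # boundary faces: active voxel whose neighbor along +/- axis is
        # exterior or outside the array
        coords = [grid.axis_centers(i) for i in range(3)]
        for ax in range(3):
            bc = self.config.boundaries.along(ax)
            if bc.kind == "adiabatic":
                continue
            for sign in (+1, -1):
                nb_active = np.zeros_like(active)
                if sign > 0:
                    sl_dst = [slice(None)] * 3
                    sl_src = [slice(None)] * 3
                    sl_dst[ax] = slice(None, -1)
                    sl_src[ax] = slice(1, None)
                else:
                    sl_dst = [slice(None)] * 3
                    sl_src = [slice(None)] * 3
                    sl_dst[ax] = slice(1, None)
                    sl_src[ax] = slice(None, -1)
                nb_active[tuple(sl_dst)] = active[tuple(sl_src)]
                face = active & ~nb_active
                if not face.any():
                    continue
                vox = idx[face]
                k_vox = k3[face]
                if bc.kind == "convective":
                    hc = bc.heat_transfer_coefficient
                    if hc == 0:
                        continue
                    u = 1.0 / (1.0 / hc + (h / 2.0) / k_vox)
                else:  # fixed face temperature
                    u = 2.0 * k_vox / h
                g_b = u / h
                if callable(bc.ambient):
                    ii, jj, kk = np.nonzero(face)
                    pos = [coords[0][ii], coords[1][jj], coords[2][kk]]
                    pos[ax] = pos[ax] + sign * h / 2.0
                    ambient = np.asarray(bc.ambient(*pos), dtype=float)
                else:
                    ambient = float(bc.ambient)
                np.add.at(diag, vox, g_b)
                np.add.at(rhs, vox, g_b * ambient)

        rows.append(np.arange(self.n))
        cols.append(np.arange(self.n))
        vals.append(diag)
        self.A = sparse.coo_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n)).tocsr()
        self.rhs0 = rhs
        self._diag = diag  # conduction + perfusion + BC couplings
        self._perf = perf
        self._qm = qm
        self.region_voxels = {
            name: np.flatnonzero(labels[active] == i)
            for i, name in enumerate(grid.region_names)
            if np.any(labels[active] == i)}

    # -- linear algebra -----------------------------------------------------

    def _solve(self, M: sparse.csr_matrix, b: np.ndarray, x0: np.ndarray,
               rtol: float, what: str) -> np.ndarray:
        d = M.diagonal()
        precond = sparse.diags(1.0 / d)
        x, info = cg(M, b, x0=x0, rtol=rtol, atol=0.0, M=precond,
                     maxiter=20000)
        if info != 0:
            res = float(np.linalg.norm(b - M @ x) / np.linalg.norm(b))
            raise SolverError(
                f"{what}: CG failed (info={info}, relative residual {res:.3e})")
        return x

    # -- fields <-> vectors --------------------------------------------------

    def to_vector(self, fld: TemperatureField) -> np.ndarray:
        return fld.values[self.active]

    def to_field(self, vec: np.ndarray, time: float) -> TemperatureField:
        out = np.full(self.grid.shape, np.nan)
        out[self.active] = vec
        return TemperatureField(grid=self.grid, values=out, time=time)

    def source_vector(self, q: np.ndarray) -> np.ndarray:
        """Restrict a full 3-D volumetric source (W/m^3) to active voxels."""
        if q.shape != self.grid.shape:
            raise ValueError("source field not aligned with grid")
        return q[self.active]

    # -- steady state --------------------------------------------------------

    def steady_state(self, q_ext: np.ndarray | None = None) -> np.ndarray:
        """Steady solution of the Pennes equation (vector over active voxels).

        With no external sources this is the physiological baseline used as
        the initial condition: perfusion + metabolism balanced against
        boundary losses.
        """
        tb = self.blood.arterial_temperature
        b = self.rhs0 if q_ext is None else self.rhs0 + q_ext
        # pure-conduction singular case: adiabatic everywhere, no perfusion
        if not np.any(self._diag - self._row_conduction() > 1e-300):
            if np.allclose(b, 0.0):
                return np.full(self.n, tb)
            raise SolverError("no steady state: insulated body with net "
                              "nonzero source")
        x0 = np.full(self.n, tb)
        return self._solve(self.A, b, x0, min(self.config.rtol, 1e-10),
                           "steady state")

    def _row_conduction(self) -> np.ndarray:
        # conduction contribution to the diagonal = -(sum of off-diagonals)
        offdiag_sum = np.asarray(self.A.sum(axis=1)).ravel() - self.A.diagonal()
        return -offdiag_sum

    # -- time stepping -------------------------------------------------------

    def _stepper(self, dt: float):
        key = float(dt)
        if key not in self._steppers:
            B = (sparse.diags(self.mass / dt) + self.A).tocsr()
            precond = sparse.diags(1.0 / B.diagonal())
            self._steppers[key] = (B, precond)
        return self._steppers[key]

    def step(self, T: np.ndarray, dt: float,
             q_ext: np.ndarray | None = None) -> np.ndarray:
        """One backward-Euler step; ``q_ext`` is a vector over active voxels."""
        B, precond = self._stepper(dt)
        b = self.mass / dt * T + self.rhs0
        if q_ext is not None:
            b = b + q_ext
        x, info = cg(B, b, x0=T, rtol=self.config.rtol, atol=0.0,
                     M=precond, maxiter=10000)
        if info != 0:
            raise SolverError(f"transient CG failed (info={info})")
        return x

    def advance(self, fld: TemperatureField, dt: float,
                q_ext: np.ndarray | None = None) -> TemperatureField:
        """One implicit step on a TemperatureField.

        ``q_ext`` may be a full 3-D field (W/m^3) or None.
        """
        vec = self.to_vector(fld)
        q = None if q_ext is None else self.source_vector(q_ext)
        return self.to_field(self.step(vec, dt, q), fld.time + dt)

    def region_extrema(self, vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        names = [n for n in self.grid.region_names if n in self.region_voxels]
        mx = np.array([vec[self.region_voxels[n]].max() for n in names])
        mn = np.array([vec[self.region_voxels[n]].min() for n in names])
        return mx, mn

    @property
    def present_regions(self) -> tuple[str, ...]:
        return tuple(n for n in self.grid.region_names
                     if n in self.region_voxels)


# ---------------------------------------------------------------------------
# high-level operations


def steady_state_baseline(body: BodyModel | Mapping[str, TissueProperties],
                          grid: VoxelGrid, config: SolverConfig | None = None,
                          blood: BloodProperties | None = None
                          ) -> TemperatureField:
    """Sourceless steady state (initial condition for treatments)."""
    system = PennesSystem(grid, body, blood=blood, config=config)
    return system.to_field(system.steady_state(), time=0.0)


@dataclass
class SimulationSetup:
    """Prepared, reusable pieces of a treatment simulation.

    Building the sparse operator and the physiological baseline dominates
    setup cost; a duty-cycle sweep reuses one setup across all schedules.
    """

    system: PennesSystem
    grid: VoxelGrid
    body: BodyModel
    exposure: AMFExposure
    q_on: np.ndarray            # eddy + nanoparticle source, active voxels
    baseline: np.ndarray        # steady-state vector


def prepare_simulation(body: BodyModel, exposure: AMFExposure,
                       loading: MIONLoading | None = None,
                       slp: SLPModel | None = None,
                       config: SolverConfig | None = None,
                       grid: VoxelGrid | None = None) -> SimulationSetup:
    """Voxelize, assemble the operator, compute sources and the baseline."""
    config = config or SolverConfig()
    if grid is None:
        body = effective_body(body, config.spacing)
        grid = voxelize(body, config.spacing, merge_superficial=False)
    q = eddy_field(grid, body, exposure)
    if loading is not None and loading.dose_density > 0:
        q = q + q_p_field(grid, loading, slp or SLPModel.default(), exposure)
    system = PennesSystem(grid, body, config=config)
    baseline = system.steady_state()
    return SimulationSetup(system=system, grid=grid, body=body,
                           exposure=exposure,
                           q_on=system.source_vector(q), baseline=baseline)


def run_schedule(setup: SimulationSetup,
                 schedule: PulseSchedule) -> TimeSeriesResult:
    """Run one pulse schedule on a prepared setup.

    Starts from the physiological baseline, applies the on-state source
    multiplied by the pulse power factor (sampled at the left edge of each
    step, exact for block-aligned steps), and records per-region extrema.
    """
    system = setup.system
    config = system.config
    dt = config.time_step
    ratio = schedule.on_block_s / dt
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("time_step must divide the pulse on-block")
    n_steps = int(round(schedule.elapsed_s / dt))
    if abs(n_steps * dt - schedule.elapsed_s) > 1e-6 * schedule.elapsed_s:
        raise ValueError("time_step must divide the elapsed duration")

    T = setup.baseline.copy()
    rec = config.record_every
    n_rec = n_steps // rec + 1
    names = system.present_regions
    tmax = np.empty((n_rec, len(names)))
    tmin = np.empty((n_rec, len(names)))
    times = np.empty(n_rec)
    tmax[0], tmin[0] = system.region_extrema(T)
    times[0] = 0.0
    baseline_field = system.to_field(T, 0.0)

    r = 1
    for s in range(n_steps):
        pf = power_factor(s * dt, schedule)
        q = setup.q_on if pf > 0 else None
        T = system.step(T, dt, q)
        if (s + 1) % rec == 0:
            tmax[r], tmin[r] = system.region_extrema(T)
            times[r] = (s + 1) * dt
            r += 1
    return TimeSeriesResult(times=times[:r], region_names=names,
                            tmax=tmax[:r], tmin=tmin[:r], dt=dt * rec,
                            schedule=schedule, baseline=baseline_field,
                            final=system.to_field(T, n_steps * dt))


def simulate(body: BodyModel, exposure: AMFExposure, schedule: PulseSchedule,
             loading: MIONLoading | None = None, slp: SLPModel | None = None,
             config: SolverConfig | None = None,
             grid: VoxelGrid | None = None) -> TimeSeriesResult:
    """Full treatment simulation: baseline, pulsed sources, extrema traces."""
    setup = prepare_simulation(body, exposure, loading=loading, slp=slp,
                               config=config, grid=grid)
    return run_schedule(setup, schedule)
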