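"""Fluid-structure engine: couples the bundle, the IB transfer operators and
the projection solver into one deterministic time loop.

One macro time step (dt = drive period / 1000) is:

1. evaluate Lagrangian elastic forces at the current bundle configuration
   (stretching + bending + links, with the tip-link rest length including any
   open-gate increment);
2. gating-spring bookkeeping: threshold test on the signed tip-link tensions;
   a newly opened gate starts a kinematic elongation ramp, during which the
   macro step is subcycled so the microsecond-scale stroke of the gating
   spring is resolved by the fluid solver;
3. spread forces to the MAC grid, advance the Navier-Stokes projection step
   with the prescribed wall/side boundary values, interpolate the new
   velocity back to the bundle and move it (basal anchored points follow the
   reticular lamina exactly);
4. record per-step observables (link lengths/tensions, gate states, full
   Lagrangian positions) and field snapshots at configured phases and around
   gate events.

Forces at anchored basal points are not spread to the fluid: their reaction
is carried by the reticular lamina (whose no-slip motion the wall boundary
condition already imposes), not by the endolymph.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field

import numpy as np

from . import elastic, ib
from .fluid import (BoundaryValues, EulerianGrid, FlowState, FluidProps,
                    NavierStokesSolver, vorticity_field)
from .geometry import (BundleConfig, LinkElement, build_bundle,
                       link_endpoint_positions)
from .scenario import Scenario, rl_motion, side_bc

logger = logging.getLogger(__name__)

RECORD_VERSION = 1
_H_FULL = 78.125e-9                 # nominal "78 nm" grid spacing, made to tile 20 x 5 um
_RESOLUTION_DIVISOR = {"full": 1, "half": 2, "quarter": 4}
_BASE_TALLEST_HEIGHT = 4.5e-6       # 5 um gap minus 0.5 um clearance; rows are
                                    # kept fixed when the gap is widened


@dataclass
class Snapshot:
    t: float
    theta_deg: float
    label: str
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    omega: np.ndarray


@dataclass
class GateEvent:
    link_index: int
    kind: str
    t_open: float
    theta_deg: float
    position: tuple[float, float]


@dataclass
class RunRecord:
    """Everything a run produced: resolved configuration plus observables.

    The pipeline is deterministic (no random numbers anywhere), so a record
    can be reproduced bit-identically from its stored configuration.
    """

    scenario: Scenario
    bundle_config: BundleConfig
    grid: EulerianGrid
    times: np.ndarray                 # (n_rec,)
    theta_deg: np.ndarray
    rl_disp: np.ndarray               # (n_rec, 2)
    link_meta: list
    link_length: np.ndarray           # (n_rec, n_links)
    link_tension: np.ndarray
    link_rest: np.ndarray             # includes gate increment
    gate_open: np.ndarray             # (n_rec, n_links) bool
    X_all: np.ndarray                 # (n_rec, n_points, 2)
    row_slices: list                  # [(boundary_id, start, stop), ...]
    X_rest_all: np.ndarray
    rest_arclengths: np.ndarray       # per row
    snapshots: list = field(default_factory=list)
    gate_events: list = field(default_factory=list)
    version: int = RECORD_VERSION

    def analyzed_mask(self) -> np.ndarray:
        t0 = self.scenario.n_transient_cycles * self.scenario.drive.period
        return self.times >= t0 * (1 - 1e-12)

    def row_positions(self, step_index: int) -> dict[str, np.ndarray]:
        return {bid: self.X_all[step_index, a:b] for bid, a, b in self.row_slices}


def grid_for(scenario: Scenario) -> EulerianGrid:
    d = _RESOLUTION_DIVISOR[scenario.resolution]
    h = _H_FULL * d
    nx = int(round(20e-6 / h))
    ny = int(round(scenario.gap_height / h))
    return EulerianGrid(nx=nx, ny=ny, h=h)


def bundle_config_for(scenario: Scenario, base: BundleConfig | None = None) -> BundleConfig:
    """Bundle geometry for a scenario: widening the gap moves the tectorial
    membrane away while keeping the rows unchanged."""
    from dataclasses import replace

    base = base or BundleConfig()
    clearance = scenario.gap_height - _BASE_TALLEST_HEIGHT
    return replace(base, gap_height=scenario.gap_height, tm_clearance=clearance)


class Simulation:
    """Deterministic end-to-end run of one scenario."""

    def __init__(self, scenario: Scenario, bundle_config: BundleConfig | None = None,
                 props: FluidProps | None = None,
                 elastic_params: elastic.ElasticParams | None = None,
                 gate_drive_stiffness: float = 5e4,
                 ramp_substeps: int = 5,
                 with_bundle: bool = True):
        scenario.validate()
        self.scenario = scenario
        self.props = props or FluidProps()
        self.grid = grid_for(scenario)
        self.eparams = elastic_params or elastic.ElasticParams(
            resting_length=(bundle_config or BundleConfig()).lagrangian_spacing)
        self.gate_drive_stiffness = gate_drive_stiffness
        self.ramp_substeps = ramp_substeps

        self.with_bundle = with_bundle
        if with_bundle:
            self.bundle_config = bundle_config_for(scenario, bundle_config)
            self.rows, self.links = build_bundle(self.bundle_config)
            for link in self.links:
                if link.gate is not None:
                    link.gate.threshold = scenario.gate_threshold
        else:
            self.bundle_config = bundle_config_for(scenario, bundle_config)
            self.rows, self.links = [], []
        self.theta0 = [np.zeros(max(r.n_points - 2, 0)) for r in self.rows]

        self.state = FlowState.zeros(self.grid)
        self.step_index = 0
        self._solvers: dict[float, NavierStokesSolver] = {}
        self._bc_cache: dict[float, BoundaryValues] = {}
        # gate bookkeeping
        self._auto_peak = np.zeros(len(self.links))
        self._auto_armed = scenario.gate_trigger == "auto"
        self._ramp: dict | None = None
        self._records: list[dict] = []
        self.snapshots: list[Snapshot] = []
        self.gate_events: list[GateEvent] = []
        self._pending_snapshot_steps: set[int] = set()

        n = scenario.steps_per_cycle // scenario.snapshot_phases_per_cycle
        self._phase_snap_every = max(n, 1)

    # ------------------------------------------------------------------
    def _solver(self, dt: float) -> NavierStokesSolver:
        key = round(dt, 15)
        if key not in self._solvers:
            self._solvers[key] = NavierStokesSolver(
                self.grid, self.props, dt, advection=self.scenario.advection)
        return self._solvers[key]

    def _boundary_values(self, t: float) -> BoundaryValues:
        # consecutive substeps reuse the end-of-step values as start-of-step
        cached = self._bc_cache.get(t)
        if cached is not None:
            return cached
        drive = self.scenario.drive
        _, (vx, vy) = rl_motion(t, drive)
        _, y_u = self.grid.u_face_coords()
        u_side = side_bc(y_u, t, drive, self.props, self.scenario.gap_height)
        bc = BoundaryValues(u_bottom=vx, u_top=0.0, v_wall=vy,
                            u_left=u_side, u_right=u_side, v_side=0.0)
        if len(self._bc_cache) > 4:
            self._bc_cache.clear()
        self._bc_cache[t] = bc
        return bc

    def _gather(self):
        X = np.concatenate([r.X for r in self.rows], axis=0)
        anchored = np.concatenate([r.anchored for r in self.rows])
        return X, anchored

    def _scatter_positions(self, X: np.ndarray):
        k = 0
        for r in self.rows:
            r.X = X[k:k + r.n_points]
            k += r.n_points

    def _prescribed_positions(self, t: float) -> np.ndarray:
        (dx, dy), _ = rl_motion(t, self.scenario.drive)
        Xr = np.concatenate([r.X_rest for r in self.rows], axis=0)
        return Xr + np.array([dx, dy])

    # ------------------------------------------------------------------
    def _lagrangian_forces(self, t: float):
        forces, tensions = elastic.total_force_density(
            self.rows, self.links, self.eparams, t=t, theta0=self.theta0)
        F = np.concatenate(forces, axis=0)
        return F, tensions

    def _apply_ramp_force(self, F: np.ndarray, X: np.ndarray, t: float):
        ramp = self._ramp
        if ramp is None or t > ramp["t_end"] + 1e-18:
            return
        frac = min((t - ramp["t_open"]) / (ramp["t_end"] - ramp["t_open"]), 1.0)
        target = ramp["x_start"] + frac * ramp["stroke"]
        F[ramp["point"]] += self.gate_drive_stiffness * (target - X[ramp["point"]])

    def _substep(self, dt_s: float):
        t0 = self.state.t
        t1 = t0 + dt_s
        X, anchored = self._gather()
        free = ~anchored
        if self.with_bundle:
            F, _ = self._lagrangian_forces(t1)
            self._apply_ramp_force(F, X, t1)
            # anchored basal points are kinematic: their reaction is carried by
            # the reticular lamina, and the wall BC already moves the fluid there
            stencils = ib.PointStencils(X[free], self.grid)
            f_u, f_v = stencils.spread(F[free])
        else:
            f_u = np.zeros(self.grid.u_shape())
            f_v = np.zeros(self.grid.v_shape())
        bc0 = self._boundary_values(t0)
        bc1 = self._boundary_values(t1)
        self.state = self._solver(dt_s).step(self.state, f_u, f_v, bc1, bc0)
        if self.with_bundle:
            U = np.zeros_like(X)
            U[free] = stencils.interpolate(self.state.u, self.state.v)
            X_new = ib.advance_boundary(X, U, dt_s, anchored,
                                        self._prescribed_positions(t1))
            self._scatter_positions(X_new)

    # ------------------------------------------------------------------
    def _gate_bookkeeping(self, t: float):
        if not self.with_bundle or self.scenario.gate_trigger == "disabled":
            return
        sc = self.scenario
        _, tensions = self._lagrangian_forces(t)
        in_transient = t < sc.n_transient_cycles * sc.drive.period - 1e-15
        if self._auto_armed:
            if in_transient:
                self._auto_peak = np.maximum(self._auto_peak, tensions)
                return
            # arm thresholds once, at the start of the analysis window
            for k, link in enumerate(self.links):
                if link.gate is not None:
                    link.gate.threshold = max(
                        sc.gate_auto_fraction * self._auto_peak[k], 1e-30)
            self._auto_armed = False
            logger.info("auto gate thresholds armed: %s",
                        [f"{l.gate.threshold:.3e}" for l in self.links
                         if l.gate is not None])
        for k, link in enumerate(self.links):
            if link.gate is None or link.gate.is_open:
                continue
            elastic.gate_update(link, float(tensions[k]), t)
            if link.gate.is_open:
                self._start_ramp(k, link, t)

    def _start_ramp(self, k: int, link: LinkElement, t: float):
        (bi, pi), (bj, pj) = link.endpoints
        xa = self.rows[bi].X[pi]          # taller-row anchor of the link
        xb = self.rows[bj].X[pj]          # gating-spring end (shorter row tip)
        u = (xb - xa) / np.linalg.norm(xb - xa)
        offset = sum(r.n_points for r in self.rows[:bj]) + pj
        gate = link.gate
        self._ramp = dict(t_open=t, t_end=t + gate.elongation_time,
                          point=offset, x_start=xb.copy(),
                          stroke=gate.extension * u)
        theta = np.degrees(
            (2 * np.pi * self.scenario.drive.frequency * t) % (2 * np.pi))
        self.gate_events.append(GateEvent(k, link.kind, t, theta,
                                          (float(xb[0]), float(xb[1]))))
        logger.info("gate opened: %s at t=%.6e s (phase %.1f deg)",
                    link.kind, t, theta)

    # ------------------------------------------------------------------
    def _record(self):
        sc = self.scenario
        t = self.state.t
        theta = np.degrees((2 * np.pi * sc.drive.frequency * t) % (2 * np.pi))
        (dx, dy), _ = rl_motion(t, sc.drive)
        rec = dict(t=t, theta=theta, rl=(dx, dy))
        if self.with_bundle:
            lengths = np.empty(len(self.links))
            rests = np.empty(len(self.links))
            tens = np.empty(len(self.links))
            opens = np.zeros(len(self.links), dtype=bool)
            for k, link in enumerate(self.links):
                xa, xb = link_endpoint_positions(link, self.rows)
                lengths[k] = np.linalg.norm(xa - xb)
                rests[k] = link.current_rest_length(t)
                tens[k] = link.stiffness * (lengths[k] - rests[k])
                opens[k] = bool(link.gate.is_open) if link.gate else False
            rec.update(lengths=lengths, rests=rests, tensions=tens, opens=opens,
                       X=self._gather()[0].copy())
        self._records.append(rec)

    def _maybe_snapshot(self, step: int):
        label = None
        if (step + 1) % self._phase_snap_every == 0:
            label = "phase"
        if step in self._pending_snapshot_steps:
            self._pending_snapshot_steps.discard(step)
            label = "gate"
        if label is None:
            return
        t = self.state.t
        theta = np.degrees((2 * np.pi * self.scenario.drive.frequency * t)
                           % (2 * np.pi))
        self.snapshots.append(Snapshot(
            t=t, theta_deg=theta, label=label,
            u=self.state.u.copy(), v=self.state.v.copy(), p=self.state.p.copy(),
            omega=vorticity_field(self.state.u, self.state.v, self.grid.h)))

    def _snapshot_now(self, label: str):
        t = self.state.t
        theta = np.degrees((2 * np.pi * self.scenario.drive.frequency * t)
                           % (2 * np.pi))
        self.snapshots.append(Snapshot(
            t=t, theta_deg=theta, label=label,
            u=self.state.u.copy(), v=self.state.v.copy(), p=self.state.p.copy(),
            omega=vorticity_field(self.state.u, self.state.v, self.grid.h)))

    # ------------------------------------------------------------------
    def run(self, n_steps: int | None = None) -> RunRecord:
        sc = self.scenario
        dt = sc.dt
        total = n_steps if n_steps is not None else sc.n_steps
        wall0 = _time.perf_counter()
        while self.step_index < total:
            t0 = self.step_index * dt
            self._gate_bookkeeping(t0)
            ramp_started = (self._ramp is not None
                            and abs(self._ramp["t_open"] - t0) < 1e-18)
            if ramp_started:
                tau = self._ramp["t_end"] - self._ramp["t_open"]
                dt_sub = tau / self.ramp_substeps
                for _ in range(self.ramp_substeps):
                    self._substep(dt_sub)
                self._snapshot_now("gate")
                remainder = dt - tau
                if remainder > 1e-15:
                    self._substep(remainder)
                self._pending_snapshot_steps.update(
                    {self.step_index + 1, self.step_index + 2})
                self._ramp = None
            else:
                nsub = sc.effective_substeps
                for _ in range(nsub):
                    self._substep(dt / nsub)
            self._record()
            self._maybe_snapshot(self.step_index)
            self.step_index += 1
            if self.step_index % sc.steps_per_cycle == 0:
                self._log_cycle(wall0)
        return self._build_record()

    def _log_cycle(self, wall0):
        cyc = self.step_index // self.scenario.steps_per_cycle
        umax = max(np.abs(self.state.u).max(), np.abs(self.state.v).max())
        cfl = umax * self.scenario.dt / self.grid.h
        msg = "cycle %d done: |u|max=%.3e m/s, CFL=%.2e, wall=%.1fs"
        args = [cyc, umax, cfl, _time.perf_counter() - wall0]
        if self.with_bundle and self._records:
            tmax = np.abs(self._records[-1]["tensions"]).max()
            msg += ", |T|max=%.3e N"
            args.append(tmax)
        logger.info(msg, *args)

    # ------------------------------------------------------------------
    def _build_record(self) -> RunRecord:
        recs = self._records
        n = len(recs)
        times = np.array([r["t"] for r in recs])
        theta = np.array([r["theta"] for r in recs])
        rl = np.array([r["rl"] for r in recs])
        if self.with_bundle:
            n_links = len(self.links)
            link_length = np.vstack([r["lengths"] for r in recs])
            link_tension = np.vstack([r["tensions"] for r in recs])
            link_rest = np.vstack([r["rests"] for r in recs])
            gate_open = np.vstack([r["opens"] for r in recs])
            X_all = np.stack([r["X"] for r in recs])
            slices = []
            k = 0
            for r in self.rows:
                slices.append((r.boundary_id, k, k + r.n_points))
                k += r.n_points
            X_rest = np.concatenate([r.X_rest for r in self.rows], axis=0)
            rest_arcs = np.array([r.rest_arclength() for r in self.rows])
            link_meta = [dict(kind=l.kind, endpoints=l.endpoints,
                              rest_length=l.rest_length, stiffness=l.stiffness,
                              gated=l.gate is not None) for l in self.links]
        else:
            link_length = link_tension = link_rest = np.zeros((n, 0))
            gate_open = np.zeros((n, 0), dtype=bool)
            X_all = np.zeros((n, 0, 2))
            slices, link_meta = [], []
            X_rest = np.zeros((0, 2))
            rest_arcs = np.zeros(0)
        return RunRecord(
            scenario=self.scenario, bundle_config=self.bundle_config,
            grid=self.grid, times=times, theta_deg=theta, rl_disp=rl,
            link_meta=link_meta, link_length=link_length,
            link_tension=link_tension, link_rest=link_rest,
            gate_open=gate_open, X_all=X_all, row_slices=slices,
            X_rest_all=X_rest, rest_arclengths=rest_arcs,
            snapshots=self.snapshots, gate_events=self.gate_events)

    # -- checkpointing (macro-step boundaries, no active ramp) ----------
    def get_state(self) -> dict:
        if self._ramp is not None:
            raise RuntimeError("cannot checkpoint during a gating-spring ramp")
        return dict(
            u=self.state.u.copy(), v=self.state.v.copy(), p=self.state.p.copy(),
            t=self.state.t, step_index=self.step_index,
            X=[r.X.copy() for r in self.rows],
            gates=[(bool(l.gate.is_open), l.gate.opened_at, l.gate.threshold)
                   for l in self.links if l.gate is not None],
            auto_peak=self._auto_peak.copy(), auto_armed=self._auto_armed)

    def set_state(self, s: dict):
        self.state = FlowState(s["u"].copy(), s["v"].copy(), s["p"].copy(), s["t"])
        self.step_index = int(s["step_index"])
        for r, X in zip(self.rows, s["X"]):
            r.X = X.copy()
        gated = [l for l in self.links if l.gate is not None]
        for link, (is_open, opened_at, threshold) in zip(gated, s["gates"]):
            link.gate.is_open = bool(is_open)
            link.gate.opened_at = opened_at
            link.gate.threshold = float(threshold)
        self._auto_peak = np.asarray(s["auto_peak"], dtype=float).copy()
        self._auto_armed = bool(s["auto_armed"])


def run_scenario(scenario: Scenario, **kwargs) -> RunRecord:
    """Convenience wrapper: build and run a simulation for ``scenario``."""
    return Simulation(scenario, **kwargs).run()
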