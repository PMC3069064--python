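"""Prescribed boundary motions and the three study scenarios.

The bottom wall (reticular lamina, RL) performs a small orbital oscillation at
200 Hz.  Phase convention: at drive phase theta = omega*t = 180 deg the RL is
displaced maximally rightward (+x) and downward (-y), i.e.

    dx(theta) = -A_h cos(theta),   dy(theta) = +A_v cos(theta + phase_v),

with phase_v = 0 by default (the convention above pins both signs; a nonzero
vertical phase offset turns the trajectory into a genuine ellipse and is
exposed as a config knob, ``orbit_sense`` selecting its sign).  The top wall
(tectorial membrane) is horizontally stationary and shares the RL's vertical
motion, so the gap height never changes.  The side boundaries carry the
analytic oscillatory-channel (Stokes layer) profile of a wall oscillating
under a stationary one.

A half-cycle raised-cosine ramp multiplies the displacement so the flow
starts from rest; velocities are exact time derivatives of the ramped
displacements.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .fluid import FluidProps

SCENARIO_NAMES = ("normal", "widened_gap", "horizontal_only")


class UsageError(ValueError):
    pass


@dataclass(frozen=True)
class DriveSignal:
    frequency: float = 200.0          # Hz
    amp_h: float = 25e-9              # horizontal RL displacement amplitude, m
    amp_v: float = 5e-9               # vertical RL displacement amplitude, m
    orbit_sense: str = "cw"           # sign of any vertical phase offset
    vertical_phase_deg: float = 0.0   # 0 keeps the theta=180 sign convention
    spl_label: str = "98 dB"

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    @property
    def phase_v(self) -> float:
        sign = -1.0 if self.orbit_sense == "ccw" else 1.0
        return sign * np.deg2rad(self.vertical_phase_deg)


def _ramp(t: float, period: float):
    """Raised-cosine ramp over the first half cycle; returns (R, dR/dt)."""
    t_ramp = 0.5 * period
    if t >= t_ramp:
        return 1.0, 0.0
    if t <= 0.0:
        return 0.0, 0.0
    w = np.pi / t_ramp
    return 0.5 * (1.0 - np.cos(w * t)), 0.5 * w * np.sin(w * t)


def rl_motion(t: float, drive: DriveSignal, ramp: bool = True):
    """Displacement and velocity of the reticular lamina at time t.

    Returns ``((dx, dy), (vx, vy))``; the velocity is the exact derivative of
    the ramped displacement, so the motion starts from rest.
    """
    w = drive.omega
    th = w * t
    dx = -drive.amp_h * np.cos(th)
    dy = drive.amp_v * np.cos(th + drive.phase_v)
    vx = drive.amp_h * w * np.sin(th)
    vy = -drive.amp_v * w * np.sin(th + drive.phase_v)
    if ramp:
        R, dR = _ramp(t, drive.period)
        return (R * dx, R * dy), (R * vx + dR * dx, R * vy + dR * dy)
    return (dx, dy), (vx, vy)


def tm_motion(t: float, drive: DriveSignal, ramp: bool = True):
    """Velocity of the tectorial membrane: horizontally fixed, vertically
    identical to the reticular lamina (gap preserved)."""
    _, (vx, vy) = rl_motion(t, drive, ramp)
    return 0.0, vy


def side_bc(y, t: float, drive: DriveSignal, props: FluidProps,
            gap_height: float, ramp: bool = True):
    """Horizontal velocity profile on the side boundaries.

    Analytic oscillatory-channel (Stokes layer) solution for flow between a
    horizontally oscillating bottom wall and a stationary top wall:

        u(y, t) = Re[ U_hat e^{i omega t} sinh(k (H - y)) / sinh(k H) ],
        k = sqrt(i omega / nu),

    which equals the wall velocity at y = 0 and vanishes at y = H.  During the
    start-up ramp the profile amplitude is scaled by the ramp factor (the true
    transient is discarded before analysis).
    """
    w = drive.omega
    nu = props.kinematic_viscosity
    k = np.sqrt(1j * w / nu)
    y = np.asarray(y, dtype=float)
    if np.any(y < -1e-15) or np.any(y > gap_height * (1 + 1e-12)):
        raise ValueError("side_bc: y outside [0, gap_height]")
    # wall displacement phasor: dx(t) = Re[-A_h e^{i omega t}]
    d_hat = -drive.amp_h
    prof = np.sinh(k * (gap_height - y)) / np.sinh(k * gap_height)
    phasor = d_hat * np.exp(1j * w * t) * prof
    if ramp:
        # exact derivative of the ramped displacement profile, so the corner
        # values match the bottom-wall velocity at every instant
        R, dR = _ramp(t, drive.period)
        u = R * np.real(1j * w * phasor) + dR * np.real(phasor)
    else:
        u = np.real(1j * w * phasor)
    return u if u.ndim else float(u)


@dataclass(frozen=True)
class Scenario:
    """A fully specified run: geometry variant plus drive plus numerics."""

    name: str
    gap_height: float
    drive: DriveSignal
    n_cycles: int = 4
    n_transient_cycles: int = 2
    steps_per_cycle: int = 1000          # dt = period / 1000
    resolution: str = "quarter"          # full | half | quarter
    solver_substeps: Optional[int] = None   # None: stability default per resolution
    advection: bool = True
    # gating-spring configuration
    gate_trigger: str = "threshold"      # threshold | auto | disabled
    gate_threshold: float = 26.5e-9      # N, as printed (see docs/methods.md)
    gate_auto_fraction: float = 0.9      # auto: fraction of transient peak tension
    snapshot_phases_per_cycle: int = 8

    @property
    def dt(self) -> float:
        return self.drive.period / self.steps_per_cycle

    @property
    def effective_substeps(self) -> int:
        """Fluid-solver subcycling of one macro step.

        The explicit elastic coupling of the immersed boundary limits the
        stable solver step well below the macro step at the stiffness of
        F-actin rows; the defaults are the empirically determined stable
        counts per grid resolution (finer grids couple the points to less
        fluid inertia per step and need more subcycling).
        """
        if self.solver_substeps is not None:
            return self.solver_substeps
        base = {"quarter": 10, "half": 24, "full": 64}[self.resolution]
        # the stable solver step is absolute; rescale if the macro step differs
        # from the reference period/1000
        scale = 1000.0 / self.steps_per_cycle
        return max(int(np.ceil(base * scale)), 1)

    @property
    def n_steps(self) -> int:
        return self.n_cycles * self.steps_per_cycle

    def validate(self):
        if self.resolution not in ("full", "half", "quarter"):
            raise UsageError(f"unknown resolution {self.resolution!r}")
        if self.gate_trigger not in ("threshold", "auto", "disabled"):
            raise UsageError(f"unknown gate_trigger {self.gate_trigger!r}")
        if self.n_cycles <= self.n_transient_cycles:
            raise UsageError("n_cycles must exceed n_transient_cycles")


_BASE_GAP = 5e-6
_WIDENING = 5e-6


def make_scenario(name: str, **overrides) -> Scenario:
    """Build one of the named scenarios; each variant differs from ``normal``
    in exactly one documented way."""
    if name not in SCENARIO_NAMES:
        raise UsageError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        )
    drive_overrides = {
        k[6:]: overrides.pop(k) for k in list(overrides) if k.startswith("drive_")
    }
    drive = DriveSignal(**drive_overrides)
    gap = _BASE_GAP
    if name == "widened_gap":
        gap = _BASE_GAP + _WIDENING
    if name == "horizontal_only":
        drive = replace(drive, amp_v=0.0)
    gap = overrides.pop("gap_height", gap)
    sc = Scenario(name=name, gap_height=gap, drive=drive, **overrides)
    sc.validate()
    return sc
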