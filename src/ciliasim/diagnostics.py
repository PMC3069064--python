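"""Observables: tip-link traces, row kinematics, vortex detection, transport.

Sign conventions: tip-link "stretch" is measured against the *closed-gate*
rest length (so an open gate shows up as a rest-length offset, not as negative
stretch, and compression plots as negative values throughout).  Row rotation
is the signed angle of the base-to-tip chord relative to its rest direction,
measured in the frame of the reticular lamina; row length change is the
change of the chain's arclength.  Both are invariant under rigid translation,
so lab-frame and lamina-frame computations coincide identically.

The analytic estimates at the end of the module are closed forms: the
Rayleigh impulsively-started-plate vorticity scale for the elongating gating
spring, and the Ca2+ supply bookkeeping (diffusive rate D/l^2 vs the influx
implied by the transduction current).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .fluid import EulerianGrid
from .simulation import RunRecord

ELEMENTARY_CHARGE = 1.602176634e-19


class AnalysisError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# tip-link traces
# ---------------------------------------------------------------------------

@dataclass
class TipLinkTrace:
    kind: str
    link_index: int
    table: pd.DataFrame            # columns: t, theta, stretch, tension, gate_open
    peak_stretch: float
    peak_phase_deg: float
    peak_tension: float


def _quadratic_peak(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through points i-1, i, i+1 (wrapping)."""
    n = len(x)
    im, ip = (i - 1) % n, (i + 1) % n
    y0, y1, y2 = y[im], y[i], y[ip]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return x[i], y[i]
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    dx = x[(i + 1) % n] - x[i] if delta > 0 else x[i] - x[(i - 1) % n]
    dx = abs(dx) if dx != 0 else 0.0
    return x[i] + delta * dx, y1 - 0.25 * (y0 - y2) * delta


def tip_link_trace(record: RunRecord) -> list[TipLinkTrace]:
    """Stretch/tension vs drive phase for each gated tip link, over the
    analyzed (post-transient) cycles."""
    mask = record.analyzed_mask()
    if not np.any(mask):
        raise AnalysisError("no steady cycle available: run is all transient")
    traces = []
    for k, meta in enumerate(record.link_meta):
        if not meta["gated"]:
            continue
        closed_rest = meta["rest_length"]
        stretch = record.link_length[mask, k] - closed_rest
        tens = record.link_tension[mask, k]
        tab = pd.DataFrame(dict(
            t=record.times[mask], theta=record.theta_deg[mask],
            stretch=stretch, tension=tens,
            gate_open=record.gate_open[mask, k]))
        i = int(np.argmax(stretch))
        phase, peak = _quadratic_peak(_unwrap_phase(tab["theta"].to_numpy()),
                                      stretch, i)
        traces.append(TipLinkTrace(
            kind=meta["kind"], link_index=k, table=tab,
            peak_stretch=float(peak), peak_phase_deg=float(phase % 360.0),
            peak_tension=float(np.max(tens))))
    return traces


def _unwrap_phase(theta_deg: np.ndarray) -> np.ndarray:
    return np.degrees(np.unwrap(np.radians(theta_deg)))


def joint_peak_phase(traces: list[TipLinkTrace]) -> float:
    """Circular mean of the per-link peak-stretch phases, in degrees."""
    ang = np.radians([tr.peak_phase_deg for tr in traces])
    return float(np.degrees(np.arctan2(np.mean(np.sin(ang)),
                                       np.mean(np.cos(ang)))) % 360.0)


# ---------------------------------------------------------------------------
# row kinematics
# ---------------------------------------------------------------------------

@dataclass
class RowKinematics:
    boundary_id: str
    table: pd.DataFrame            # t, theta, rotation (rad), length_change (m)
    peak_rotation: float           # max |rotation| over the analyzed window
    peak_length_change: float      # max |length change|


def _chord_angle(X: np.ndarray) -> float:
    chord = X[-1] - X[0]
    return float(np.arctan2(chord[1], chord[0]))


def row_kinematics(record: RunRecord) -> list[RowKinematics]:
    """Rotation about the base insertion and arclength change per row."""
    mask = record.analyzed_mask()
    if not np.any(mask):
        raise AnalysisError("no steady cycle available: run is all transient")
    idx = np.where(mask)[0]
    out = []
    for r, (bid, a, b) in enumerate(record.row_slices):
        Xr = record.X_rest_all[a:b]
        rest_angle = _chord_angle(Xr)
        rest_len = record.rest_arclengths[r]
        rot = np.empty(len(idx))
        dlen = np.empty(len(idx))
        for m, i in enumerate(idx):
            X = record.X_all[i, a:b]
            rot[m] = _chord_angle(X) - rest_angle
            dlen[m] = np.sum(np.linalg.norm(np.diff(X, axis=0), axis=1)) - rest_len
        tab = pd.DataFrame(dict(t=record.times[idx], theta=record.theta_deg[idx],
                                rotation=rot, length_change=dlen))
        out.append(RowKinematics(
            boundary_id=bid, table=tab,
            peak_rotation=float(np.max(np.abs(rot))),
            peak_length_change=float(np.max(np.abs(dlen)))))
    return out


def mean_peak_length_change(kin: list[RowKinematics]) -> float:
    return float(np.mean([k.peak_length_change for k in kin]))


# ---------------------------------------------------------------------------
# vortex detection
# ---------------------------------------------------------------------------

@dataclass
class VortexDetection:
    center: tuple[float, float]
    peak_vorticity: float
    circulation_sign: int


@dataclass
class VortexReport:
    t: float
    theta_deg: float
    detections: list[VortexDetection]
    criterion: dict = field(default_factory=dict)


def _corner_velocities(u: np.ndarray, v: np.ndarray):
    """Average MAC components to cell corners (interior corners exact mean)."""
    nx1, ny = u.shape
    uc = np.empty((nx1, ny + 1))
    uc[:, 1:-1] = 0.5 * (u[:, 1:] + u[:, :-1])
    uc[:, 0] = u[:, 0]
    uc[:, -1] = u[:, -1]
    nx, ny1 = v.shape
    vc = np.empty((nx + 1, ny1))
    vc[1:-1, :] = 0.5 * (v[1:, :] + v[:-1, :])
    vc[0, :] = v[0, :]
    vc[-1, :] = v[-1, :]
    return uc, vc


def detect_vortices(omega: np.ndarray, u: np.ndarray, v: np.ndarray,
                    grid: EulerianGrid, window_halfwidth: float = 1e-6,
                    prominence: float = 0.25,
                    t: float = 0.0, theta_deg: float = 0.0) -> VortexReport:
    """Find closed-streamline eddies around vorticity extrema.

    A candidate is a connected plateau of near-extremal |omega| (above
    ``prominence`` times the field maximum).  Around each candidate centroid
    a square window is cut out, the window-mean velocity is subtracted (so the
    criterion is Galilean invariant and shear-background insensitive), and the
    local streamfunction is tested for a level set that closes around the
    candidate without touching the window edge.  Pure shear produces no
    detections; a solid-body-rotation patch produces exactly one.
    """
    h = grid.h
    uc, vc = _corner_velocities(u, v)
    psi = _corner_streamfunction(u, h)
    absw = np.abs(omega)
    wmax = absw.max()
    detections = []
    if wmax > 0:
        floor = prominence * wmax
        # candidate plateaus: points within rounding of their 3x3-neighborhood
        # maximum (a flat vortex core is one plateau, not many single points)
        local_max = absw >= ndimage.maximum_filter(absw, size=3) * (1 - 1e-6)
        cand = local_max & (absw >= floor)
        # drop plateaus that span the whole field (uniform shear has constant omega)
        labels, n_lab = ndimage.label(cand)
        nwin = max(int(round(window_halfwidth / h)), 2)
        for lab in range(1, n_lab + 1):
            ii, jj = np.where(labels == lab)
            if (ii.min() == 0 and ii.max() == omega.shape[0] - 1) or \
               (jj.min() == 0 and jj.max() == omega.shape[1] - 1):
                continue
            ci = int(round(ii.mean()))
            cj = int(round(jj.mean()))
            if _closed_contour(psi, uc, vc, ci, cj, nwin, h):
                detections.append(VortexDetection(
                    center=(ci * h, cj * h),
                    peak_vorticity=float(omega[ci, cj]),
                    circulation_sign=int(np.sign(omega[ci, cj]))))
    detections = _merge_nearby(detections, window_halfwidth)
    return VortexReport(t=t, theta_deg=theta_deg, detections=detections,
                        criterion=dict(window_halfwidth=window_halfwidth,
                                       prominence=prominence))


def _merge_nearby(detections: list[VortexDetection],
                  radius: float) -> list[VortexDetection]:
    """One eddy, one detection: keep the strongest of any same-signed cluster."""
    kept: list[VortexDetection] = []
    for d in sorted(detections, key=lambda d: -abs(d.peak_vorticity)):
        if any(np.hypot(d.center[0] - k.center[0], d.center[1] - k.center[1])
               < radius and d.circulation_sign == k.circulation_sign
               for k in kept):
            continue
        kept.append(d)
    return kept


def _corner_streamfunction(u: np.ndarray, h: float) -> np.ndarray:
    nx1, ny = u.shape
    psi = np.zeros((nx1, ny + 1))
    psi[:, 1:] = np.cumsum(u * h, axis=1)
    return psi


def _closed_contour(psi, uc, vc, ci, cj, nwin, h) -> bool:
    i0, i1 = max(ci - nwin, 0), min(ci + nwin + 1, psi.shape[0])
    j0, j1 = max(cj - nwin, 0), min(cj + nwin + 1, psi.shape[1])
    w = psi[i0:i1, j0:j1].copy()
    ubar = uc[i0:i1, j0:j1].mean()
    vbar = vc[i0:i1, j0:j1].mean()
    # remove the streamfunction of the window-mean uniform flow
    x = np.arange(i0, i1) * h
    y = np.arange(j0, j1) * h
    w -= ubar * (y[None, :] - y.mean())
    w += vbar * (x[:, None] - x.mean())
    pc = w[ci - i0, cj - j0]
    edge = np.concatenate([w[0, :], w[-1, :], w[:, 0], w[:, -1]])
    if pc >= edge.max():
        level = 0.5 * (pc + edge.max())
        region = w > level
    elif pc <= edge.min():
        level = 0.5 * (pc + edge.min())
        region = w < level
    else:
        return False
    labels, _ = ndimage.label(region)
    lab = labels[ci - i0, cj - j0]
    if lab == 0:
        return False
    sel = labels == lab
    touches = sel[0, :].any() or sel[-1, :].any() or sel[:, 0].any() or sel[:, -1].any()
    return not touches


def vortices_near_gate(record: RunRecord, max_distance: float = 1e-6,
                       phase_window_deg: float = 90.0) -> list[VortexReport]:
    """Vortex reports for snapshots within a quarter cycle after each
    gate-opening event, keeping only detections near the opened gate."""
    reports = []
    for ev in record.gate_events:
        for snap in record.snapshots:
            dt_phase = (snap.t - ev.t_open) * record.scenario.drive.frequency * 360.0
            if not (0.0 <= dt_phase <= phase_window_deg):
                continue
            rep = detect_vortices(snap.omega, snap.u, snap.v, record.grid,
                                  t=snap.t, theta_deg=snap.theta_deg)
            near = [d for d in rep.detections
                    if np.hypot(d.center[0] - ev.position[0],
                                d.center[1] - ev.position[1]) <= max_distance]
            if near:
                reports.append(VortexReport(t=rep.t, theta_deg=rep.theta_deg,
                                            detections=near,
                                            criterion=rep.criterion))
    return reports


# ---------------------------------------------------------------------------
# analytic transport estimates
# ---------------------------------------------------------------------------

def rayleigh_vorticity(A: float, nu: float, tau_o: float) -> float:
    """Vorticity scale of the impulsively elongating gating spring.

    A plate moving at speed A/tau_o sheds vorticity confined to the viscous
    penetration depth sqrt(pi nu tau_o) (Rayleigh's impulsively started
    plate), giving omega ~ (A/tau_o) / sqrt(pi nu tau_o).
    """
    if A <= 0 or nu <= 0 or tau_o <= 0:
        raise ValueError("all arguments must be positive")
    return (A / tau_o) / np.sqrt(np.pi * nu * tau_o)


def critical_elongation_time(A: float = 5e-9, nu: float = 0.7e-6,
                             D: float = 4e-10, l: float = 170e-9) -> float:
    """Elongation time below which the vortex turnover beats diffusion.

    Solves 1/omega(tau) = l^2/D for tau with the Rayleigh vorticity above:
    tau_crit = (A l^2 / (D sqrt(pi nu)))^(2/3).
    """
    return float((A * l**2 / (D * np.sqrt(np.pi * nu))) ** (2.0 / 3.0))


@dataclass(frozen=True)
class TransportEstimates:
    diffusivity: float
    tip_link_length: float
    diffusion_rate: float          # D / l^2, 1/s
    diffusion_time: float          # l^2 / D, s
    ca_influx_rate: float          # ions/s from the transduction current
    tau_crit: float                # s

    def __post_init__(self):
        assert abs(self.diffusion_rate * self.diffusion_time - 1.0) < 1e-12


def transport_estimates(D: float = 4e-10, l: float = 170e-9,
                        total_current: float = 500e-12,
                        ca_concentration: float = 20e-6,
                        k_concentration: float = 160e-3,
                        A: float = 5e-9, nu: float = 0.7e-6) -> TransportEstimates:
    """Order-of-magnitude Ca2+ supply bookkeeping.

    The diffusive supply rate is D/l^2 with l the tip-link length.  The
    required influx is estimated from the total transduction current with the
    carrier split taken proportional to concentration (20 uM Ca2+ against
    160 mM K+) and the divalent charge of Ca2+ accounted for.  The split rule
    is a simple order-of-magnitude assumption — treat the influx number as an
    estimate, not a measurement.
    """
    if min(D, l, total_current, ca_concentration, k_concentration) <= 0:
        raise ValueError("all inputs must be positive")
    ca_fraction = ca_concentration / (ca_concentration + k_concentration)
    ca_current = total_current * ca_fraction
    influx = ca_current / (2.0 * ELEMENTARY_CHARGE)
    return TransportEstimates(
        diffusivity=D, tip_link_length=l,
        diffusion_rate=D / l**2, diffusion_time=l**2 / D,
        ca_influx_rate=influx,
        tau_crit=critical_elongation_time(A=A, nu=nu, D=D, l=l))


# ---------------------------------------------------------------------------
# free-end doubling oracle (1D longitudinal pulse along a rod)
# ---------------------------------------------------------------------------

def free_end_reflection_ratio(n_nodes: int = 400, pulse_nodes: int = 60) -> float:
    """Ratio of free-end to incident displacement for a longitudinal pulse.

    Integrates the 1D wave equation on a rod whose far end is stress-free
    (mirror ghost) with a half-sine displacement pulse driven at the near
    end, using leapfrog at unit Courant number (exact transport).  The
    analytic value of the ratio is 2: at a stress-free end the reflected
    displacement wave superposes in phase with the incident one.
    """
    c = 1.0
    dx = 1.0
    dt = dx / c                     # Courant number 1: exact advection
    n_steps = int(2.2 * n_nodes)
    amp = 1.0
    u_prev = np.zeros(n_nodes + 1)
    u_cur = np.zeros(n_nodes + 1)
    free_end_max = 0.0
    for step in range(n_steps):
        t_new = (step + 1) * dt
        u_next = np.empty_like(u_cur)
        u_next[1:-1] = 2 * u_cur[1:-1] - u_prev[1:-1] + \
            (u_cur[2:] - 2 * u_cur[1:-1] + u_cur[:-2])
        # stress-free far end: ghost mirrors the last interior node
        u_next[-1] = 2 * u_cur[-1] - u_prev[-1] + 2 * (u_cur[-2] - u_cur[-1])
        # driven near end: half-sine displacement pulse
        t_pulse = pulse_nodes * dx / c
        u_next[0] = amp * np.sin(np.pi * t_new / t_pulse) if t_new < t_pulse else 0.0
        free_end_max = max(free_end_max, abs(u_next[-1]))
        u_prev, u_cur = u_cur, u_next
    return free_end_max / amp
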