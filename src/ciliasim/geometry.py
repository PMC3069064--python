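"""Lagrangian geometry of the three-row inner-hair-cell stereocilia bundle.

The bundle lives in a rectangular fluid domain (the subtectorial space between
the reticular lamina below and the tectorial membrane above).  Each stereocilia
row is an ordered chain of Lagrangian points spaced ``r0`` = 75 nm apart, with
a linear diameter taper over the lower third of its height.  Rows are joined by
two gated tip links (upper: tallest-middle, lower: middle-shortest) and six
ungated horizontal top connectors.

Coordinate convention: origin at the bottom-left corner of the fluid rectangle,
x rightward (the direction of "rightward" reticular-lamina displacement),
y upward.  The tallest row sits on the -x side of the bundle so that the
fluid-lag deflection produced by rightward lamina motion tensions the links.
All quantities are SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Raised when a bundle configuration violates one of its invariants."""


@dataclass(frozen=True)
class BundleConfig:
    """Geometric and elastic layout parameters of the bundle and its domain.

    Defaults describe the guinea-pig cochlear apex: a 5 µm high, 20 µm long
    subtectorial gap, 0.5 µm clearance between the tallest row and the
    tectorial membrane, and a Lagrangian lattice of 75 nm.
    """

    domain_length: float = 20e-6
    gap_height: float = 5e-6
    tm_clearance: float = 0.5e-6
    lagrangian_spacing: float = 75e-9          # r0
    base_fraction: float = 1.0 / 3.0
    shaft_diameter: float = 200e-9
    base_diameter: float = 400e-9
    # heights relative to the tallest row (tallest first)
    row_height_ratios: tuple[float, float, float] = (1.0, 0.65, 0.35)
    inter_row_spacing: float = 80e-9
    tip_link_rest_length: float = 170e-9
    link_stiffness: float = 5e-4               # N/m, gating stiffness of links
    n_top_connectors: int = 6
    # number of lattice points the taller attachment sits above the shorter tip
    tip_link_rise_points: int = 2

    @property
    def tallest_height(self) -> float:
        return self.gap_height - self.tm_clearance

    @property
    def row_heights(self) -> tuple[float, float, float]:
        h = self.tallest_height
        return tuple(h * r for r in self.row_height_ratios)

    def validate(self) -> None:
        if self.tallest_height <= 0:
            raise ConfigurationError(
                "gap_height - tm_clearance must be positive "
                f"(got {self.tallest_height:.3e} m)"
            )
        r = self.row_height_ratios
        if not (r[0] > r[1] > r[2] > 0):
            raise ConfigurationError(
                f"row heights must be strictly ordered tallest > middle > shortest, got ratios {r}"
            )
        for name in ("domain_length", "gap_height", "tm_clearance",
                     "lagrangian_spacing", "shaft_diameter", "base_diameter",
                     "inter_row_spacing", "tip_link_rest_length", "link_stiffness"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        r0 = self.lagrangian_spacing
        for i, h in enumerate(self.row_heights):
            n = h / r0
            if abs(n - round(n)) * r0 > r0:
                raise ConfigurationError(
                    f"r0 ({r0:.3g} m) does not divide row {i} height ({h:.3g} m) "
                    "to within one point spacing"
                )
        if self.inter_row_spacing >= self.tip_link_rest_length:
            raise ConfigurationError(
                "inter_row_spacing must be smaller than the tip-link rest length "
                "so an oblique attachment can realize it"
            )

    # -- config-file round trip ------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["row_height_ratios"] = list(self.row_height_ratios)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "BundleConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "row_height_ratios" in d:
            d["row_height_ratios"] = tuple(d["row_height_ratios"])
        return cls(**d)


@dataclass
class LagrangianBoundary:
    """An ordered elastic point chain (one stereocilia row).

    ``X`` holds current positions, ``X_rest`` the construction-time positions.
    ``anchored`` marks basal points that are kinematically tethered to the
    reticular lamina (they follow the prescribed wall motion instead of the
    interpolated fluid velocity).
    """

    boundary_id: str
    X: np.ndarray                    # (n, 2)
    rest_segment_lengths: np.ndarray  # (n-1,)
    local_diameters: np.ndarray       # (n,)
    anchored: np.ndarray              # (n,) bool
    X_rest: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.X_rest is None:
            self.X_rest = self.X.copy()

    @property
    def n_points(self) -> int:
        return self.X.shape[0]

    def arclength(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.X, axis=0), axis=1)))

    def rest_arclength(self) -> float:
        return float(np.sum(self.rest_segment_lengths))


@dataclass
class GateState:
    """Threshold state machine of a tip-link gating spring.

    Once the signed link tension reaches ``threshold`` the gate opens and the
    link rest length ramps up by ``extension`` over ``elongation_time``.  By
    default the open state latches for the rest of the run; an optional
    hysteresis rule recloses the gate when tension falls below
    ``reclose_fraction * threshold``.
    """

    is_open: bool = False
    extension: float = 5e-9           # A, the 5 nm gating-spring elongation
    threshold: float = 26.5e-9        # N (as printed; see docs/methods.md)
    elongation_time: float = 1e-6     # tau_o
    opened_at: Optional[float] = None
    reclose_enabled: bool = False
    reclose_fraction: float = 0.5

    def rest_increment(self, t: float) -> float:
        """Current addition to the tip-link rest length (linear ramp)."""
        if not self.is_open or self.opened_at is None:
            return 0.0
        frac = (t - self.opened_at) / self.elongation_time
        return self.extension * min(max(frac, 0.0), 1.0)


@dataclass
class LinkElement:
    """A tip link or horizontal top connector between two rows.

    Endpoints are (boundary index into the row list, point index).  Tip links
    carry a :class:`GateState`; connectors do not.
    """

    kind: str                          # upper_tip_link | lower_tip_link | top_connector
    endpoints: tuple[tuple[int, int], tuple[int, int]]
    rest_length: float
    stiffness: float
    gate: Optional[GateState] = None

    def current_rest_length(self, t: float) -> float:
        if self.gate is not None:
            return self.rest_length + self.gate.rest_increment(t)
        return self.rest_length


def taper_profile(s, config: BundleConfig):
    """Diameter at height fraction ``s`` of a stereocilium.

    Piecewise linear: ``base_diameter`` at s=0, ``shaft_diameter`` for
    s >= base_fraction, linear in between.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0) or np.any(s_arr > 1):
        raise ValueError(f"height fraction s must lie in [0, 1], got {s}")
    bf = config.base_fraction
    w = np.clip(s_arr / bf, 0.0, 1.0)
    d = config.base_diameter + (config.shaft_diameter - config.base_diameter) * w
    return float(d) if np.isscalar(s) else d


ROW_NAMES = ("tallest", "middle", "shortest")


def build_rows(config: BundleConfig) -> list[LagrangianBoundary]:
    """Construct the three row chains, centered in the domain.

    The middle row sits at x = L/2; the tallest row one inter-row spacing to
    the left, the shortest one to the right.  The two basal points of each row
    (y = 0 and y = r0) are anchored — a clamped base standing in for the
    rootlet insertion into the cuticular plate.
    """
    config.validate()
    r0 = config.lagrangian_spacing
    xc = config.domain_length / 2.0
    s = config.inter_row_spacing
    x_positions = (xc - s, xc, xc + s)
    rows = []
    for name, x0, height in zip(ROW_NAMES, x_positions, config.row_heights):
        n_seg = int(round(height / r0))
        y = np.arange(n_seg + 1) * r0
        X = np.column_stack([np.full(n_seg + 1, x0), y])
        diam = taper_profile(y / height, config)
        anchored = np.zeros(n_seg + 1, dtype=bool)
        anchored[:2] = True
        rows.append(
            LagrangianBoundary(
                boundary_id=name,
                X=X,
                rest_segment_lengths=np.full(n_seg, r0),
                local_diameters=np.asarray(diam, dtype=float),
                anchored=anchored,
            )
        )
    return rows


def attach_links(rows: list[LagrangianBoundary], config: BundleConfig) -> list[LinkElement]:
    """Attach the two gated tip links and the six horizontal top connectors.

    Tip links run from the tip of the shorter member obliquely up to the
    taller member's shaft ``tip_link_rise_points`` lattice points higher; the
    inter-row spacing and rise are chosen so the rest separation equals the
    170 nm tip-link rest length exactly (zero initial extension).
    Connectors are horizontal, three per adjacent-row pair, evenly spread over
    the top 10% of the shorter member.
    """
    r0 = config.lagrangian_spacing
    rise = config.tip_link_rise_points
    links: list[LinkElement] = []

    def tip_link(kind, taller_idx, shorter_idx):
        shorter = rows[shorter_idx]
        taller = rows[taller_idx]
        tip_idx = shorter.n_points - 1
        attach_y = shorter.X_rest[tip_idx, 1] + rise * r0
        taller_idx_pt = int(round(attach_y / r0))
        if taller_idx_pt >= taller.n_points:
            raise ConfigurationError(
                f"{kind}: attachment height {attach_y:.3g} m exceeds the taller row"
            )
        sep = np.linalg.norm(taller.X_rest[taller_idx_pt] - shorter.X_rest[tip_idx])
        if abs(sep - config.tip_link_rest_length) > 1e-12:
            raise ConfigurationError(
                f"{kind}: rest separation {sep:.6g} m does not realize the "
                f"tip-link rest length {config.tip_link_rest_length:.6g} m; "
                "adjust inter_row_spacing or tip_link_rise_points"
            )
        return LinkElement(
            kind=kind,
            endpoints=((taller_idx, taller_idx_pt), (shorter_idx, tip_idx)),
            rest_length=config.tip_link_rest_length,
            stiffness=config.link_stiffness,
            gate=GateState(),
        )

    links.append(tip_link("upper_tip_link", 0, 1))   # tallest <-> middle
    links.append(tip_link("lower_tip_link", 1, 2))   # middle <-> shortest

    n_per_pair = config.n_top_connectors // 2
    for taller_idx, shorter_idx in ((0, 1), (1, 2)):
        shorter = rows[shorter_idx]
        height = shorter.X_rest[-1, 1]
        j_lo = int(np.ceil(0.9 * height / r0))
        j_hi = shorter.n_points - 1
        idxs = np.unique(np.round(np.linspace(j_lo, j_hi, n_per_pair)).astype(int))
        if len(idxs) < n_per_pair:
            raise ConfigurationError(
                "top 10% of the shorter row has too few lattice points for "
                f"{n_per_pair} connectors"
            )
        for j in idxs:
            links.append(
                LinkElement(
                    kind="top_connector",
                    endpoints=((taller_idx, int(j)), (shorter_idx, int(j))),
                    rest_length=config.inter_row_spacing,
                    stiffness=config.link_stiffness,
                    gate=None,
                )
            )
    return links


def build_bundle(config: BundleConfig) -> tuple[list[LagrangianBoundary], list[LinkElement]]:
    """Build the full bundle: three rows plus tip links and connectors."""
    rows = build_rows(config)
    links = attach_links(rows, config)
    return rows, links


def geometry_table(rows: list[LagrangianBoundary]):
    """Plain-text geometry export: one record per Lagrangian point."""
    import pandas as pd

    recs = []
    for row in rows:
        for j in range(row.n_points):
            recs.append(
                dict(
                    boundary_id=row.boundary_id,
                    point=j,
                    x=row.X[j, 0],
                    y=row.X[j, 1],
                    diameter=row.local_diameters[j],
                    anchored=bool(row.anchored[j]),
                )
            )
    return pd.DataFrame.from_records(recs)


def link_endpoint_positions(link: LinkElement, rows: list[LagrangianBoundary]):
    (bi, pi), (bj, pj) = link.endpoints
    return rows[bi].X[pi], rows[bj].X[pj]
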