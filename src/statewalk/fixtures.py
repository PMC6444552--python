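"""Synthetic landscapes and known-parameter reference trajectories.

Everything here is generated programmatically and deterministically from a
``(spec, seed)`` pair, so simulations, resampling and calibration can be
exercised and validated without any external GIS or telemetry data.  The
synthetic rasters emulate the landscape archetypes the simulator targets —
binary river corridors and dendritic (branching river) networks for
aquatic, graded mosaics for terrestrial/semiaquatic walkers — not any real
geography.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point

from .landscape import ResistanceRaster, ShapeSpec, raster_from_shapes, resistance_at
from .movement import Species
from .sim import Trajectory, simulate

__all__ = [
    "SyntheticLandscapeSpec",
    "make_landscape",
    "channel_start",
    "make_reference_trajectory",
]

_KINDS = ("homogeneous", "river_corridor", "dendritic_network", "patches", "graded")


@dataclass(frozen=True)
class SyntheticLandscapeSpec:
    """Recipe for a deterministic synthetic resistance raster.

    kinds
        ``homogeneous`` — all-zero resistance (free space);
        ``river_corridor`` — one meandering zero-resistance channel in an
        impassable (resistance 1) matrix;
        ``dendritic_network`` — a branching binary tree of channels, the
        archetypal river network;
        ``patches`` — zero-resistance discs in a graded matrix;
        ``graded`` — a smooth random resistance field.
    """

    kind: str = "homogeneous"
    extent: tuple[float, float, float, float] = (0.0, 0.0, 3000.0, 3000.0)
    cell_size: float = 10.0
    corridor_width_cells: int = 6
    branch_depth: int = 3
    n_patches: int = 5
    patch_radius: float = 200.0
    matrix_resistance: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown landscape kind {self.kind!r}; choose from {_KINDS}")
        if self.kind in ("river_corridor", "dendritic_network") and self.corridor_width_cells < 2:
            raise ValueError(
                "corridor width below 2 cells cannot satisfy the step-length rule of thumb "
                "(features should be at least twice the maximum step length)"
            )


def _meander_centerline(spec: SyntheticLandscapeSpec) -> LineString:
    """Seeded meandering centerline crossing the extent left to right."""
    xmin, ymin, xmax, ymax = spec.extent
    rng = np.random.default_rng(spec.seed)
    margin = spec.corridor_width_cells * spec.cell_size
    n = max(8, int((xmax - xmin) / spec.cell_size))
    xs = np.linspace(xmin, xmax, n)
    ys = np.empty(n)
    ys[0] = (ymin + ymax) / 2
    drift = 0.0
    amp = spec.cell_size * 1.5
    for i in range(1, n):
        drift = 0.9 * drift + rng.normal(0.0, amp)  # correlated lateral wander
        ys[i] = np.clip(ys[i - 1] + drift, ymin + margin, ymax - margin)
    return LineString(np.column_stack([xs, ys]))


def _dendritic_lines(spec: SyntheticLandscapeSpec) -> list[LineString]:
    """Binary-tree channel skeleton: trunk from the bottom edge, splitting
    at each level; ``branch_depth`` counts levels, so leaves = 2**(depth-1)."""
    xmin, ymin, xmax, ymax = spec.extent
    height = ymax - ymin
    x0 = (xmin + xmax) / 2
    lines: list[LineString] = []
    seg_len = height / (spec.branch_depth + 0.5)

    def grow(x, y, angle, level):
        dx = seg_len * np.cos(angle)
        dy = seg_len * np.sin(angle)
        x1 = np.clip(x + dx, xmin + spec.cell_size, xmax - spec.cell_size)
        y1 = np.clip(y + dy, ymin + spec.cell_size, ymax - spec.cell_size)
        lines.append(LineString([(x, y), (x1, y1)]))
        if level < spec.branch_depth:
            spread = np.pi / 5
            grow(x1, y1, angle + spread, level + 1)
            grow(x1, y1, angle - spread, level + 1)

    grow(x0, ymin, np.pi / 2, 1)
    return lines


def make_landscape(spec: SyntheticLandscapeSpec) -> ResistanceRaster:
    """Build the raster described by ``spec``; deterministic given its seed."""
    xmin, ymin, xmax, ymax = spec.extent
    half_width = spec.corridor_width_cells * spec.cell_size / 2.0

    if spec.kind == "homogeneous":
        ncol = int(np.ceil((xmax - xmin) / spec.cell_size))
        nrow = int(np.ceil((ymax - ymin) / spec.cell_size))
        return ResistanceRaster(np.zeros((nrow, ncol)), xmin, ymin, spec.cell_size)

    if spec.kind == "river_corridor":
        line = _meander_centerline(spec)
        return raster_from_shapes(
            [ShapeSpec(line, resistance=0.0, buffer_width=half_width)],
            background_resistance=1.0,
            extent=spec.extent,
            cell_size=spec.cell_size,
        )

    if spec.kind == "dendritic_network":
        shapes = [
            ShapeSpec(line, resistance=0.0, buffer_width=half_width)
            for line in _dendritic_lines(spec)
        ]
        return raster_from_shapes(shapes, 1.0, spec.extent, spec.cell_size)

    if spec.kind == "patches":
        rng = np.random.default_rng(spec.seed)
        shapes = []
        for _ in range(spec.n_patches):
            cx = rng.uniform(xmin + spec.patch_radius, xmax - spec.patch_radius)
            cy = rng.uniform(ymin + spec.patch_radius, ymax - spec.patch_radius)
            shapes.append(ShapeSpec(Point(cx, cy).buffer(spec.patch_radius), resistance=0.0))
        return raster_from_shapes(
            shapes, spec.matrix_resistance, spec.extent, spec.cell_size
        )

    # graded: smooth seeded random field in [0, 0.95]
    rng = np.random.default_rng(spec.seed)
    ncol = int(np.ceil((xmax - xmin) / spec.cell_size))
    nrow = int(np.ceil((ymax - ymin) / spec.cell_size))
    field_vals = np.zeros((nrow, ncol))
    ys, xs = np.mgrid[0:nrow, 0:ncol]
    for _ in range(12):  # superposed Gaussian bumps
        cx, cy = rng.uniform(0, ncol), rng.uniform(0, nrow)
        sigma = rng.uniform(min(nrow, ncol) / 10, min(nrow, ncol) / 3)
        amp = rng.uniform(-1.0, 1.0)
        field_vals += amp * np.exp(-(((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma**2)))
    lo, hi = field_vals.min(), field_vals.max()
    values = 0.95 * (field_vals - lo) / (hi - lo) if hi > lo else np.zeros_like(field_vals)
    return ResistanceRaster(values, xmin, ymin, spec.cell_size)


def channel_start(raster: ResistanceRaster) -> tuple[float, float]:
    """Center of a zero-resistance cell, preferring one near the grid middle."""
    rows, cols = np.where(raster.values == 0.0)
    if rows.size == 0:
        raise ValueError("raster has no zero-resistance cell")
    mid = np.array([raster.nrow / 2, raster.ncol / 2])
    d2 = (rows - mid[0]) ** 2 + (cols - mid[1]) ** 2
    i = int(np.argmin(d2))
    x = raster.origin_x + (cols[i] + 0.5) * raster.cell_size
    y = raster.origin_y + (raster.nrow - 1 - rows[i] + 0.5) * raster.cell_size
    return (float(x), float(y))


def make_reference_trajectory(
    species: Species,
    landscape_spec: SyntheticLandscapeSpec | None,
    n_steps: int,
    seed: int,
    start: tuple[float, float] | None = None,
) -> tuple[Trajectory, dict]:
    """Simulate a ground-truth track bundled with its generating parameters.

    The returned dict records the exact inputs (per-state parameters,
    transition matrix, landscape spec, seed) so recovery experiments can
    score estimates against known truth.
    """
    raster = make_landscape(landscape_spec) if landscape_spec is not None else None
    if start is None:
        start = channel_start(raster) if raster is not None else (0.0, 0.0)
    traj = simulate(species, n_steps, raster=raster, start=start, seed=seed)
    params = {
        "species": species.name,
        "states": [
            {
                "label": st.label,
                "concentration": st.concentration,
                "max_step_length": st.max_step_length,
                "perceptual_range": st.perceptual_range,
            }
            for st in species.states
        ],
        "transition_matrix": species.transitions.probs.tolist(),
        "landscape": None if landscape_spec is None else landscape_spec.__dict__.copy(),
        "n_steps": n_steps,
        "seed": seed,
        "start": start,
    }
    return traj, params
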