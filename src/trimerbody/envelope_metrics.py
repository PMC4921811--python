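"""Merged-envelope geometry: voxel occupancy, surface area, axes, per-domain areas.

The aligned ensemble's occupied space is merged on a boolean voxel grid ("the
sum of all the volumes into one"): a voxel is occupied when its center lies
within bead radius + probe radius of any selected bead, the probe radius
defaulting to a 1.4 Å water probe. From the merged grid we measure

* surface area — triangulated isosurface of the occupancy field,
* volume — occupied voxel count × spacing³,
* principal axes — full extents of the occupied voxel centers along the
  eigenvectors of their covariance (the "oblate with ~125 and 110 Å axes"
  quantities),
* per-domain areas — one envelope per payload label across all ensemble
  members, plus the merged envelope and the merged/sum overlap ratio.

Numerical note: marching cubes applied directly to a binary field
overestimates smooth surface areas by ~9%, so the field is lightly smoothed
(Gaussian, σ = 0.8 voxel) before the 0.5-level triangulation; this brings
both sphere and box reference solids within 5% of their analytic areas and
converges under grid refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage import measure

from .structure_io import BeadModel, DomainLabel, EmptySelectionError, PAYLOAD_LABELS

DEFAULT_SPACING = 2.0  # Å
DEFAULT_PROBE_RADIUS = 1.4  # Å, water probe convention
DEFAULT_PADDING = 10.0  # Å
_SMOOTH_SIGMA_VOXELS = 0.8


class LatticeMismatchError(ValueError):
    pass


@dataclass
class OccupancyGrid:
    """Boolean voxel grid. ``origin`` is the center of voxel (0,0,0), Å."""

    origin: np.ndarray  # (3,)
    spacing: float
    cells: np.ndarray  # (nx, ny, nz) bool

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.cells = np.asarray(self.cells, dtype=bool)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.cells.ndim != 3 or min(self.cells.shape) < 1:
            raise ValueError("cells must be a non-degenerate 3-D boolean array")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.cells.shape

    @property
    def n_occupied(self) -> int:
        return int(self.cells.sum())

    def occupied_centers(self) -> np.ndarray:
        idx = np.argwhere(self.cells)
        return self.origin + idx * self.spacing

    def same_lattice(self, other: "OccupancyGrid") -> bool:
        return (
            self.cells.shape == other.cells.shape
            and np.isclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin, atol=1e-9)
        )


def bead_bounds(models: list[BeadModel] | BeadModel, padding: float) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned bounding box of the bead *spheres*, grown by `padding` (Å)."""
    if isinstance(models, BeadModel):
        models = [models]
    lo = np.min(
        [(m.positions - m.radii[:, None]).min(axis=0) for m in models], axis=0
    ) - padding
    hi = np.max(
        [(m.positions + m.radii[:, None]).max(axis=0) for m in models], axis=0
    ) + padding
    return lo, hi


def voxelize(
    beads: BeadModel,
    spacing: float = DEFAULT_SPACING,
    padding: float = DEFAULT_PADDING,
    label_filter: set[DomainLabel] | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> OccupancyGrid:
    """Rasterize a bead model onto a boolean occupancy grid.

    A voxel is occupied iff its center lies within (bead radius +
    probe_radius) of any selected bead. Grid bounds default to the bead
    bounding box plus `padding`; pass explicit `bounds` to place several
    models on one shared lattice (required before any grid union or
    cross-architecture ratio).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    model = beads if label_filter is None else beads.select_labels(label_filter)
    if len(model) == 0:
        raise EmptySelectionError("no beads to voxelize")

    lo, hi = bead_bounds(model, padding) if bounds is None else bounds
    dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    origin = lo + spacing / 2.0

    axes = [origin[d] + spacing * np.arange(dims[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    occupied = np.zeros(centers.shape[0], dtype=bool)
    for radius in np.unique(model.radii):
        tree = cKDTree(model.positions[model.radii == radius])
        dist, _ = tree.query(
            centers[~occupied], k=1, distance_upper_bound=radius + probe_radius + 1e-9
        )
        hit = np.isfinite(dist)
        occupied[np.flatnonzero(~occupied)[hit]] = True

    return OccupancyGrid(
        origin=origin, spacing=spacing, cells=occupied.reshape(tuple(dims))
    )


def union_grids(grids: list[OccupancyGrid]) -> OccupancyGrid:
    """Cell-wise OR of grids that share one lattice."""
    if not grids:
        raise ValueError("need at least one grid")
    first = grids[0]
    cells = first.cells.copy()
    for g in grids[1:]:
        if not first.same_lattice(g):
            raise LatticeMismatchError("grids are not on a shared lattice")
        cells |= g.cells
    return OccupancyGrid(origin=first.origin.copy(), spacing=first.spacing, cells=cells)


def surface_area(grid: OccupancyGrid) -> float:
    """Isosurface area (Å²) of the occupancy field.

    The binary field is padded by one empty voxel layer (so the surface
    closes), lightly smoothed, and triangulated at the 0.5 level by marching
    cubes. Deterministic for a fixed grid; 0 for an empty grid.
    """
    if not grid.cells.any():
        return 0.0
    f = np.pad(grid.cells, 2).astype(np.float64)
    f = gaussian_filter(f, sigma=_SMOOTH_SIGMA_VOXELS)
    s = grid.spacing
    verts, faces, _, _ = measure.marching_cubes(f, level=0.5, spacing=(s, s, s))
    return float(measure.mesh_surface_area(verts, faces))


def envelope_volume(grid: OccupancyGrid) -> float:
    """Occupied voxel count × spacing³ (Å³)."""
    return grid.n_occupied * grid.spacing**3


def envelope_axes(grid: OccupancyGrid) -> np.ndarray:
    """Principal-axis extents (Å), sorted descending.

    Eigenvectors of the occupied-voxel-center covariance give the principal
    directions; each extent is the full span (max − min) of the centers
    projected on that direction, plus one voxel spacing. An oblate envelope
    shows one extent clearly below the other two.
    """
    if not grid.cells.any():
        raise ValueError("cannot compute axes of an empty grid")
    centers = grid.occupied_centers()
    centered = centers - centers.mean(axis=0)
    if centers.shape[0] == 1:
        return np.full(3, grid.spacing)
    cov = centered.T @ centered / centers.shape[0]
    _, vecs = np.linalg.eigh(cov)
    proj = centered @ vecs
    extents = proj.max(axis=0) - proj.min(axis=0) + grid.spacing
    return np.sort(extents)[::-1]


@dataclass
class EnvelopeMetrics:
    """The merged-envelope quantities for one architecture."""

    surface_area: float  # Å²
    volume: float  # Å³
    axes: np.ndarray  # (3,) extents Å, descending
    per_domain_area: dict[DomainLabel, float]
    per_domain_mean: float
    per_domain_se: float
    merged_over_sum: float  # merged payload area / sum of per-domain areas

    def to_dict(self) -> dict:
        return {
            "surface_area_A2": self.surface_area,
            "volume_A3": self.volume,
            "axes_A": [float(a) for a in self.axes],
            "per_domain_area_A2": {
                label.name: float(v) for label, v in self.per_domain_area.items()
            },
            "per_domain_mean_A2": self.per_domain_mean,
            "per_domain_se_A2": self.per_domain_se,
            "merged_over_sum": self.merged_over_sum,
        }


def ensemble_payload_beads(ensemble, labels=PAYLOAD_LABELS) -> BeadModel:
    """All payload beads of all configurations, re-keyed to stay unique."""
    blocks = []
    for i, conf in enumerate(ensemble.configurations):
        sub = conf.model.select_labels(labels)
        sub.chain_ids = np.char.add(sub.chain_ids.astype("U4"), "")
        sub.residue_indices = sub.residue_indices + i * 1_000_000
        blocks.append(sub)
    return BeadModel.concatenate(blocks, name="payload-cloud")


def per_domain_areas(
    aligned_ensemble,
    spacing: float = DEFAULT_SPACING,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    padding: float = DEFAULT_PADDING,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[dict[DomainLabel, float], dict]:
    """Surface area explored by each payload domain across the ensemble.

    For each payload label, all of that label's beads from every aligned
    configuration are merged into one envelope and its area measured; the
    all-label merged envelope and the merged/sum overlap ratio are returned
    as diagnostics ("the area is far smaller than the sum of the individual
    areas" when domains overlap).
    """
    all_payload = ensemble_payload_beads(aligned_ensemble)
    if bounds is None:
        bounds = bead_bounds(all_payload, padding)

    label_grids: dict[DomainLabel, OccupancyGrid] = {}
    areas: dict[DomainLabel, float] = {}
    for label in PAYLOAD_LABELS:
        mask = all_payload.labels == int(label)
        if not mask.any():
            continue
        grid = voxelize(
            all_payload.select(mask), spacing=spacing, probe_radius=probe_radius,
            bounds=bounds,
        )
        label_grids[label] = grid
        areas[label] = surface_area(grid)
    if not areas:
        raise EmptySelectionError("ensemble contains no payload beads")

    merged = union_grids(list(label_grids.values()))
    merged_area = surface_area(merged)
    total = sum(areas.values())
    diagnostics = {
        "merged_area": merged_area,
        "sum_of_individual": total,
        "merged_over_sum": merged_area / total if total > 0 else float("nan"),
        "merged_grid": merged,
        "label_grids": label_grids,
    }
    return areas, diagnostics


def symmetry_stats(
    per_domain: dict[DomainLabel, float],
    symmetry_equivalent: list[set[DomainLabel]],
) -> list[tuple[float, float]]:
    """Mean ± standard error of per-domain areas within each equivalence set.

    For the C3-symmetric multi-chain architecture all three payload labels
    are equivalent, so their explored areas are reported as mean ± SE
    (sample SD / √n; 0 for singleton sets).
    """
    out = []
    for group in symmetry_equivalent:
        if not group:
            raise ValueError("symmetry-equivalence sets must be non-empty")
        values = np.array([per_domain[label] for label in group], dtype=float)
        mean = float(values.mean())
        se = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
        out.append((mean, se))
    return out


def compute_envelope_metrics(
    aligned_ensemble,
    spacing: float = DEFAULT_SPACING,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    padding: float = DEFAULT_PADDING,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[EnvelopeMetrics, dict]:
    """Full envelope metrics for one aligned ensemble (payload beads only).

    The envelope is the merged occupied space of the payload domains across
    all configurations; per-domain areas decompose it by label.
    """
    areas, diag = per_domain_areas(
        aligned_ensemble, spacing=spacing, probe_radius=probe_radius,
        padding=padding, bounds=bounds,
    )
    merged = diag["merged_grid"]
    (mean, se), = symmetry_stats(areas, [set(areas)])
    metrics = EnvelopeMetrics(
        surface_area=diag["merged_area"],
        volume=envelope_volume(merged),
        axes=envelope_axes(merged),
        per_domain_area=areas,
        per_domain_mean=mean,
        per_domain_se=se,
        merged_over_sum=diag["merged_over_sum"],
    )
    return metrics, diag
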