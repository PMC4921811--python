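"""Idealized synthetic templates: trimerization core, payload domains.

The templates emulate the building blocks of a trimerbody without requiring
any structure download: a C3-symmetric three-chain core (the role played by
the collagen XVIII trimerization domain), with three N-terminal anchor points
where payload-side linkers attach and three C-terminal anchor points where
the extra tethers of the single-chain tandem format originate; and globular
payload domains standing in for VHH antibody domains (~12–15 kDa single Ig
domains), modelled as uniform bead-filled balls.

All generators are pure functions of their parameters and seed.

Default geometry (synthetic stand-ins, not crystallographic values):
core of three 10-bead chains with both anchor circles at radius 8 Å and an
axial N-to-C offset of 25 Å; payload ball of radius 14 Å with 200 beads of
radius 2.5 Å.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import (
    DEFAULT_BEAD_RADIUS,
    BeadModel,
    DomainLabel,
    write_model_pdb,
)

CORE_CHAIN_IDS = ("A", "B", "C")

# defaults for the idealized geometry (Å / counts)
DEFAULT_ANCHOR_RADIUS = 8.0
DEFAULT_CORE_BEADS_PER_CHAIN = 10
DEFAULT_AXIAL_OFFSET = 25.0
DEFAULT_PAYLOAD_RADIUS = 14.0
DEFAULT_PAYLOAD_BEADS = 200


@dataclass
class CoreTemplate:
    """A trimerization core with three N- and three C-terminal anchors.

    Anchor points are geometric attachment sites (Å), not beads; for ideal
    cores both anchor sets are mapped onto themselves by rotation about the
    symmetry (z) axis.
    """

    model: BeadModel
    n_anchor_points: np.ndarray  # (3, 3) Å
    c_anchor_points: np.ndarray  # (3, 3) Å
    symmetry_order: int = 3

    def __post_init__(self) -> None:
        self.n_anchor_points = np.asarray(self.n_anchor_points, dtype=float).reshape(3, 3)
        self.c_anchor_points = np.asarray(self.c_anchor_points, dtype=float).reshape(3, 3)

    @property
    def n_anchors(self) -> int:
        return self.n_anchor_points.shape[0]

    def symmetry_error(self) -> float:
        """Max displacement (Å) of the anchor sets under a 2π/order rotation.

        Each rotated anchor is matched to its nearest original anchor; zero
        (to round-off) for ideal cores.
        """
        angle = 2.0 * np.pi / self.symmetry_order
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        worst = 0.0
        for anchors in (self.n_anchor_points, self.c_anchor_points):
            rotated = anchors @ rot.T
            d = np.linalg.norm(rotated[:, None, :] - anchors[None, :, :], axis=2)
            worst = max(worst, float(d.min(axis=1).max()))
        return worst

    def validate(self) -> None:
        self.model.validate()
        if self.n_anchor_points.shape != (3, 3) or self.c_anchor_points.shape != (3, 3):
            raise ValueError("core must have exactly 3 N-anchors and 3 C-anchors")


@dataclass
class PayloadTemplate:
    """A globular payload domain with N- and C-terminal attachment points."""

    model: BeadModel
    n_anchor: np.ndarray  # (3,) Å
    c_anchor: np.ndarray  # (3,) Å
    label: DomainLabel = DomainLabel.PAYLOAD_N

    def __post_init__(self) -> None:
        self.n_anchor = np.asarray(self.n_anchor, dtype=float).reshape(3)
        self.c_anchor = np.asarray(self.c_anchor, dtype=float).reshape(3)

    def bounding_radius(self) -> float:
        return self.model.bounding_radius()

    def validate(self) -> None:
        self.model.validate()
        centroid = self.model.positions.mean(axis=0)
        max_dist = float(np.max(np.linalg.norm(self.model.positions - centroid, axis=1)))
        for anchor in (self.n_anchor, self.c_anchor):
            if np.linalg.norm(anchor - centroid) > max_dist + 5.0:
                raise ValueError("anchor lies too far outside the bead cloud")

    def relabelled(self, label: DomainLabel) -> "PayloadTemplate":
        model = BeadModel(
            positions=self.model.positions.copy(),
            radii=self.model.radii.copy(),
            chain_ids=self.model.chain_ids.copy(),
            residue_indices=self.model.residue_indices.copy(),
            labels=np.full(len(self.model), int(label), dtype=np.int64),
            name=self.model.name,
        )
        return PayloadTemplate(model=model, n_anchor=self.n_anchor.copy(),
                               c_anchor=self.c_anchor.copy(), label=label)


def _rotation_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_ideal_core(
    anchor_radius: float = DEFAULT_ANCHOR_RADIUS,
    n_beads_per_chain: int = DEFAULT_CORE_BEADS_PER_CHAIN,
    seed: int = 0,
    axial_offset: float = DEFAULT_AXIAL_OFFSET,
    bead_radius: float = DEFAULT_BEAD_RADIUS,
) -> CoreTemplate:
    """Build an exactly C3-symmetric three-chain core.

    The N-anchors sit 120° apart on a circle of radius ``anchor_radius`` at
    z = +axial_offset/2, the C-anchors on a like circle at z = −axial_offset/2.
    Chain beads run between the two anchors of their chain (recessed one bead
    radius from each anchor so a freshly grown linker bead is not in
    automatic steric conflict), with a small seeded jitter; chains B and C are
    exact 120°/240° rotations of chain A, so the C3 invariant holds to
    round-off by construction.
    """
    if anchor_radius <= 0:
        raise ValueError("anchor_radius must be positive")
    if n_beads_per_chain < 1:
        raise ValueError("n_beads_per_chain must be at least 1")
    rng = np.random.default_rng(seed)

    half = axial_offset / 2.0
    n_anchor0 = np.array([anchor_radius, 0.0, half])
    c_anchor0 = np.array([anchor_radius, 0.0, -half])

    # chain A: beads along the N→C segment, recessed from both anchors
    axis = c_anchor0 - n_anchor0
    length = np.linalg.norm(axis)
    unit = axis / length
    start = n_anchor0 + unit * bead_radius
    end = c_anchor0 - unit * bead_radius
    if n_beads_per_chain == 1:
        base = (start + end)[None, :] / 2.0
    else:
        t = np.linspace(0.0, 1.0, n_beads_per_chain)[:, None]
        base = start[None, :] + t * (end - start)[None, :]
    jitter = rng.normal(scale=0.5, size=base.shape)
    jitter[:, 2] = 0.0  # keep the axial extent exact
    chain_a = base + jitter

    chains, n_anchors, c_anchors = [], [], []
    for k, cid in enumerate(CORE_CHAIN_IDS):
        rot = _rotation_z(2.0 * np.pi * k / 3.0)
        chains.append(
            BeadModel.from_arrays(chain_a @ rot.T, bead_radius, cid, DomainLabel.CORE)
        )
        n_anchors.append(rot @ n_anchor0)
        c_anchors.append(rot @ c_anchor0)

    core = CoreTemplate(
        model=BeadModel.concatenate(chains, name="synthetic-ideal-core"),
        n_anchor_points=np.asarray(n_anchors),
        c_anchor_points=np.asarray(c_anchors),
        symmetry_order=3,
    )
    core.validate()
    return core


def make_sphere_payload(
    radius: float = DEFAULT_PAYLOAD_RADIUS,
    n_beads: int = DEFAULT_PAYLOAD_BEADS,
    seed: int = 0,
    bead_radius: float = DEFAULT_BEAD_RADIUS,
    label: DomainLabel = DomainLabel.PAYLOAD_N,
) -> PayloadTemplate:
    """Idealized globular payload: beads uniformly filling a ball.

    After sampling, the cloud is recentred on its centroid and rescaled (by a
    factor ≤ 1) so every bead center lies within ``radius`` of the centroid.
    The N-terminal anchor sits at the +z pole of the ball surface, the
    C-terminal anchor antipodal at −z.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_beads < 1:
        raise ValueError("n_beads must be at least 1")
    rng = np.random.default_rng(seed)
    directions = rng.normal(size=(n_beads, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    r = radius * rng.random(n_beads) ** (1.0 / 3.0)
    points = directions * r[:, None]
    points -= points.mean(axis=0)
    max_r = np.max(np.linalg.norm(points, axis=1))
    if max_r > radius:
        points *= radius / max_r
    model = BeadModel.from_arrays(points, bead_radius, "P", label, name="synthetic-vhh")
    payload = PayloadTemplate(
        model=model,
        n_anchor=np.array([0.0, 0.0, radius]),
        c_anchor=np.array([0.0, 0.0, -radius]),
        label=label,
    )
    payload.validate()
    return payload


def make_point_payload(label: DomainLabel = DomainLabel.PAYLOAD_N) -> PayloadTemplate:
    """Degenerate payload: one zero-radius bead at the origin, anchors at the
    origin. Useful for analytic reachability oracles."""
    model = BeadModel.from_arrays(
        np.zeros((1, 3)), 0.0, "P", label, name="point-payload"
    )
    return PayloadTemplate(
        model=model, n_anchor=np.zeros(3), c_anchor=np.zeros(3), label=label
    )


def write_core_template_pdb(core: CoreTemplate, path) -> None:
    """Serialize a core template with its anchors as pseudo-beads in chain X."""
    anchors = np.vstack([core.n_anchor_points, core.c_anchor_points])
    anchor_model = BeadModel.from_arrays(anchors, 0.0, "X", DomainLabel.CORE)
    write_model_pdb(BeadModel.concatenate([core.model, anchor_model]), path)


def write_payload_template_pdb(payload: PayloadTemplate, path) -> None:
    """Serialize a payload template with its anchors as pseudo-beads in chain X."""
    anchors = np.vstack([payload.n_anchor, payload.c_anchor])
    anchor_model = BeadModel.from_arrays(anchors, 0.0, "X", payload.label)
    write_model_pdb(BeadModel.concatenate([payload.model, anchor_model]), path)
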