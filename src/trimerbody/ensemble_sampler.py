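"""Rejection sampling of sterically allowed trimerbody configurations.

A trimerbody is a trimerization core with three antigen-binding payload
domains tethered to its three N-terminal anchors by flexible glycine-serine
linkers. Two architectures are compared:

* ``multi_chain`` — three independent payload-linker arms (the intermolecular
  trimerbody assembled from three separate chains);
* ``tandem`` — one polypeptide carrying all three payload-core modules, where
  two *extra* linkers tether the core C-terminus of arm k to the payload of
  arm k+1. These double tethers restrict where the internal and C-terminal
  payloads can go.

Linkers are modelled as freely jointed chains of Cα-like beads with a fixed
virtual bond of 3.8 Å and no angular potential — glycine-serine linkers are
maximally flexible, so bond directions are drawn uniformly on the sphere.
Payload domains are rigid bodies given uniformly random orientations. A
configuration is accepted only if no bead pair clashes (center distance below
``clash_scale`` × sum of radii; beads adjacent in a chain, and payload beads
in the bonded neighborhood of a chain junction, are exempt). For the tandem
extra tethers a bridging chain with both endpoints fixed is grown as a
conditioned chain: each step direction is uniform over the spherical cap
from which the target anchor stays reachable within the remaining contour
length, and the final bead lands within one bond of the target.

This sampler explores the sterically allowed support of each architecture;
it assigns no energies and applies no Rosenbluth-style reweighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import BeadModel, DomainLabel, PAYLOAD_LABELS
from .superposition import RigidTransform
from .synthetic_structures import CoreTemplate, PayloadTemplate

DEFAULT_BOND_LENGTH = 3.8  # Å, Cα virtual bond
# Glycine-serine linkers are thin and maximally flexible: a small bead keeps
# them from threading through domains while leaving the backbone virtual
# angles essentially unrestrained (minimum Cα(i)→Cα(i+2) separation 1.8 Å).
DEFAULT_LINKER_BEAD_RADIUS = 1.0  # Å
DEFAULT_CLASH_SCALE = 0.9
DEFAULT_ENSEMBLE_SIZE = 150
# Payload beads within this many bonds of the attachment anchor are treated
# as the junction's bonded neighborhood: the linker physically enters the
# domain there, so those contacts are chain connectivity, not clashes.
ANCHOR_EXEMPT_BONDS = 2.0

LINKER_CHAIN_IDS = ("D", "E", "F")
PAYLOAD_CHAIN_IDS = ("G", "H", "I")
TETHER_CHAIN_IDS = ("J", "K")


class InvalidArchitectureError(ValueError):
    pass


class SamplingExhaustedError(RuntimeError):
    """Raised when the attempt budget runs out before enough configurations
    are accepted — the architecture is infeasible or over-constrained."""


@dataclass(frozen=True)
class LinkerSpec:
    """A flexible peptide linker: number of residues, virtual bond, bead size."""

    n_residues: int
    bond_length: float = DEFAULT_BOND_LENGTH
    bead_radius: float = DEFAULT_LINKER_BEAD_RADIUS

    def __post_init__(self) -> None:
        if self.n_residues < 0:
            raise ValueError("n_residues must be non-negative")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")

    @property
    def contour_length(self) -> float:
        """Maximum end-to-end reach when bridging two fixed points:
        (n_residues + 1) bonds."""
        return (self.n_residues + 1) * self.bond_length


@dataclass(frozen=True)
class Arm:
    payload: PayloadTemplate
    primary_linker: LinkerSpec


@dataclass
class ArchitectureSpec:
    """Declarative trimerbody topology.

    ``arms`` are ordered; payload labels are assigned N-terminal, internal,
    C-terminal in arm order. ``extra_tethers[k]`` (tandem only) connects the
    core C-anchor of arm k to the payload anchor of arm k+1.
    """

    topology: Literal["multi_chain", "tandem"]
    core: CoreTemplate
    arms: tuple[Arm, Arm, Arm]
    extra_tethers: tuple[LinkerSpec, ...] = ()

    def validate(self) -> None:
        if self.topology not in ("multi_chain", "tandem"):
            raise InvalidArchitectureError(f"unknown topology {self.topology!r}")
        if len(self.arms) != 3:
            raise InvalidArchitectureError("a trimerbody has exactly 3 arms")
        n_extra = len(self.extra_tethers)
        if self.topology == "tandem" and n_extra != 2:
            raise InvalidArchitectureError(
                f"tandem topology requires exactly 2 extra tethers, got {n_extra}"
            )
        if self.topology == "multi_chain" and n_extra != 0:
            raise InvalidArchitectureError(
                f"multi_chain topology takes no extra tethers, got {n_extra}"
            )
        self.core.validate()
        for arm in self.arms:
            arm.payload.validate()


def make_architecture(
    topology: str,
    core: CoreTemplate,
    payloads: Sequence[PayloadTemplate],
    primary_linkers: Sequence[LinkerSpec],
    extra_tethers: Sequence[LinkerSpec] = (),
) -> ArchitectureSpec:
    """Assemble an ArchitectureSpec, relabelling payloads N/I/C in arm order."""
    if len(payloads) != 3 or len(primary_linkers) != 3:
        raise InvalidArchitectureError("need exactly 3 payloads and 3 primary linkers")
    arms = tuple(
        Arm(payload=p.relabelled(lab), primary_linker=l)
        for p, l, lab in zip(payloads, primary_linkers, PAYLOAD_LABELS)
    )
    arch = ArchitectureSpec(
        topology=topology, core=core, arms=arms, extra_tethers=tuple(extra_tethers)
    )
    arch.validate()
    return arch


@dataclass
class Configuration:
    """One accepted, fully labelled trimerbody configuration."""

    model: BeadModel
    payload_transforms: tuple[RigidTransform, ...]
    payload_anchor_positions: np.ndarray  # (3, 3) posed payload anchors, Å
    linker_chains: dict[str, np.ndarray]  # chain id -> (n, 3) bead positions


@dataclass
class Ensemble:
    """N accepted configurations of one architecture plus sampling metadata."""

    configurations: list[Configuration]
    architecture: ArchitectureSpec
    seed: int
    attempts: int
    core_rmsds: np.ndarray | None = None

    @property
    def accepted(self) -> int:
        return len(self.configurations)

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / max(self.attempts, 1)


# ---------------------------------------------------------------------------
# clash detection
# ---------------------------------------------------------------------------

def check_clash(a: BeadModel, b: BeadModel, scale: float = DEFAULT_CLASH_SCALE) -> bool:
    """True iff some bead of `a` and some bead of `b` overlap.

    Overlap means center distance < scale · (radius_a + radius_b).
    Deterministic and symmetric in its arguments.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    return _any_clash(a.positions, a.radii, b.positions, b.radii, scale)


def _any_clash(
    pos_a: np.ndarray,
    rad_a: np.ndarray | float,
    pos_b: np.ndarray,
    rad_b: np.ndarray | float,
    scale: float,
) -> bool:
    if len(pos_a) == 0 or len(pos_b) == 0:
        return False
    d = cdist(pos_a, pos_b)
    ra = np.asarray(rad_a, dtype=float).reshape(-1, 1)
    rb = np.asarray(rad_b, dtype=float).reshape(1, -1)
    return bool(np.any(d < scale * (ra + rb)))


class _ObstacleStack:
    """Growing collection of placed bead blocks, flattened lazily for checks."""

    def __init__(self) -> None:
        self._pos: list[np.ndarray] = []
        self._rad: list[np.ndarray] = []
        self._cache: tuple[np.ndarray, np.ndarray] | None = None

    def push(self, positions: np.ndarray, radii: np.ndarray | float) -> None:
        positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        if positions.shape[0] == 0:
            return
        radii = np.full(positions.shape[0], radii, dtype=float) if np.isscalar(radii) \
            else np.asarray(radii, dtype=float)
        self._pos.append(positions)
        self._rad.append(radii)
        self._cache = None

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if self._cache is None:
            if not self._pos:
                self._cache = (np.empty((0, 3)), np.empty(0))
            else:
                self._cache = (np.concatenate(self._pos), np.concatenate(self._rad))
        return self._cache

    def clashes(self, positions: np.ndarray, radii, scale: float) -> bool:
        obs_pos, obs_rad = self.arrays()
        return _any_clash(positions, radii, obs_pos, obs_rad, scale)


# ---------------------------------------------------------------------------
# chain growth
# ---------------------------------------------------------------------------

def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion (x, y, z, w)."""
    x, y, z, w = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _self_clash(chain: np.ndarray, bead_radius: float, scale: float) -> bool:
    """Any non-adjacent pair of chain beads closer than the clash threshold."""
    n = chain.shape[0]
    if n < 3:
        return False
    d = cdist(chain, chain)
    idx = np.arange(n)
    nonadjacent = np.abs(idx[:, None] - idx[None, :]) >= 2
    return bool(np.any(d[nonadjacent] < scale * 2.0 * bead_radius))


def grow_linker(
    anchor: np.ndarray,
    spec: LinkerSpec,
    obstacles: BeadModel | tuple[np.ndarray, np.ndarray] | None,
    rng: np.random.Generator,
    clash_scale: float = DEFAULT_CLASH_SCALE,
    check_clashes: bool = True,
) -> np.ndarray | None:
    """Grow a freely jointed chain from `anchor`; None signals rejection.

    The first bead sits one bond from the anchor; each subsequent bead one
    bond from its predecessor, in a direction uniform on the sphere. The
    chain is rejected if any bead clashes with the obstacles or with a
    non-adjacent bead of the chain itself.
    """
    anchor = np.asarray(anchor, dtype=float).reshape(3)
    n = spec.n_residues
    if n == 0:
        return np.empty((0, 3))
    if obstacles is None:
        obs_pos, obs_rad = np.empty((0, 3)), np.empty(0)
    elif isinstance(obstacles, BeadModel):
        obs_pos, obs_rad = obstacles.positions, obstacles.radii
    else:
        obs_pos, obs_rad = obstacles

    steps = _unit_vectors(rng, n) * spec.bond_length
    chain = anchor + np.cumsum(steps, axis=0)
    if not check_clashes:
        return chain
    if _any_clash(chain, spec.bead_radius, obs_pos, obs_rad, clash_scale):
        return None
    if _self_clash(chain, spec.bead_radius, clash_scale):
        return None
    return chain


def _cap_directions(
    rng: np.random.Generator, to_target: np.ndarray, b: float, reach: float
) -> np.ndarray:
    """Uniform directions on the spherical caps keeping the target reachable.

    For each row p→target displacement (distance d), the next bead at
    p + b·u must satisfy |p + b·u − target| ≤ reach; valid directions form a
    cap around the target direction with cosθ ≥ (d² + b² − reach²) / (2bd).
    Rows for which every direction qualifies use the whole sphere, so
    conditioning only activates near the reachability boundary.
    """
    m = to_target.shape[0]
    d = np.linalg.norm(to_target, axis=1)
    safe_d = np.where(d < 1e-12, 1.0, d)
    c_min = (d * d + b * b - reach * reach) / (2.0 * b * safe_d)
    c_min = np.clip(c_min, -1.0, 1.0)
    c_min = np.where((d < 1e-12) | (d <= reach - b), -1.0, c_min)
    cos_t = c_min + (1.0 - c_min) * rng.random(m)
    sin_t = np.sqrt(np.maximum(1.0 - cos_t * cos_t, 0.0))
    phi = rng.random(m) * (2.0 * np.pi)

    axis = to_target / safe_d[:, None]
    axis[d < 1e-12] = (0.0, 0.0, 1.0)
    helper = np.zeros_like(axis)
    use_x = np.abs(axis[:, 0]) < 0.9
    helper[use_x, 0] = 1.0
    helper[~use_x, 1] = 1.0
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(axis, e1)
    return (
        cos_t[:, None] * axis
        + (sin_t * np.cos(phi))[:, None] * e1
        + (sin_t * np.sin(phi))[:, None] * e2
    )


def _grow_bridge(
    rng: np.random.Generator,
    start: np.ndarray,
    target: np.ndarray,
    spec: LinkerSpec,
    obstacles: tuple[np.ndarray, np.ndarray],
    payload_block: tuple[np.ndarray, np.ndarray],
    clash_scale: float,
    check_clashes: bool,
    batch: int = 128,
    max_batches: int = 4,
) -> np.ndarray | None:
    """Grow a tether with both endpoints fixed (conditioned chain growth).

    Each step direction is drawn uniformly over the spherical cap of
    directions from which the target anchor remains reachable within the
    remaining contour length; the final step is drawn from the cap that lands
    the last bead within one bond of the target. The support — every
    fixed-bond chain whose partial chains can all still reach the target and
    whose last bead ends within one bond of it — is exactly the support of
    naive grow-and-reject bridging, but no geometric rejection is needed, so
    bridging stays tractable even when the endpoints are far apart relative
    to the chain's random-coil size. The step density is biased toward the
    reachability boundary relative to the true end-conditioned freely jointed
    chain (documented approximation).

    Clashes still reject: candidate chains are grown in vectorized batches
    (pure performance engineering — each candidate follows the scalar rule)
    and the first candidate clearing all clash checks is returned. Every bead
    is checked against the obstacles and non-adjacent self pairs; the final
    bead is chain-adjacent to the payload anchor, so it is exempt from
    clashing with the payload block.
    """
    n, b = spec.n_residues, spec.bond_length
    start = np.asarray(start, dtype=float).reshape(3)
    target = np.asarray(target, dtype=float).reshape(3)
    d0 = float(np.linalg.norm(start - target))
    if n == 0:
        return np.empty((0, 3)) if d0 <= b else None
    if d0 > (n + 1) * b:
        return None
    obs_pos, obs_rad = obstacles
    pay_pos, pay_rad = payload_block

    for _ in range(max_batches):
        pos = np.broadcast_to(start, (batch, 3)).copy()
        chains = np.empty((batch, n, 3))
        for i in range(1, n + 1):
            reach = (n - i + 1) * b if i < n else b
            pos = pos + b * _cap_directions(rng, target - pos, b, reach)
            chains[:, i - 1] = pos
        ok = np.linalg.norm(pos - target, axis=1) <= b * (1 + 1e-9)

        if not check_clashes:
            idx = np.flatnonzero(ok)
            return chains[idx[0]] if idx.size else None

        # self clashes: non-adjacent intra-chain pairs, all candidates at once
        if n >= 3:
            diff = chains[:, :, None, :] - chains[:, None, :, :]
            d2 = np.sum(diff * diff, axis=3)
            ii = np.arange(n)
            nonadj = np.abs(ii[:, None] - ii[None, :]) >= 2
            thr = (clash_scale * 2.0 * spec.bead_radius) ** 2
            ok &= ~np.any(d2[:, nonadj] < thr, axis=1)
        # obstacle clashes, only for still-alive candidates
        alive = np.flatnonzero(ok)
        if alive.size and obs_pos.shape[0]:
            d = cdist(chains[alive].reshape(-1, 3), obs_pos).reshape(alive.size, n, -1)
            thr = clash_scale * (spec.bead_radius + obs_rad)
            ok[alive[np.any(d < thr[None, None, :], axis=(1, 2))]] = False
        # payload clashes (final bead exempt)
        alive = np.flatnonzero(ok)
        if alive.size and pay_pos.shape[0] and n > 1:
            d = cdist(chains[alive, :-1].reshape(-1, 3), pay_pos)
            d = d.reshape(alive.size, n - 1, -1)
            thr = clash_scale * (spec.bead_radius + pay_rad)
            ok[alive[np.any(d < thr[None, None, :], axis=(1, 2))]] = False

        idx = np.flatnonzero(ok)
        if idx.size:
            return chains[idx[0]]
    return None


def place_payload(
    template: PayloadTemplate,
    linker_end: np.ndarray,
    rng: np.random.Generator,
    attach: str = "n",
) -> tuple[np.ndarray, RigidTransform]:
    """Pose a rigid payload: uniformly random orientation, anchor on target.

    The template is rotated by a rotation drawn uniformly from SO(3) (via
    unit quaternions) and translated so the chosen terminal anchor (``"n"``
    or ``"c"``) coincides with `linker_end`. Returns (posed bead positions,
    transform). In the trimerbody constructs the payload precedes its
    trimerization domain in sequence, so configuration sampling attaches the
    primary linker at the payload's C-terminal anchor; the N-terminal anchor
    is where a tandem extra tether arrives.
    """
    linker_end = np.asarray(linker_end, dtype=float).reshape(3)
    anchor = template.n_anchor if attach == "n" else template.c_anchor
    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    rot = _quat_to_matrix(quat)
    translation = linker_end - rot @ anchor
    transform = RigidTransform(rotation=rot, translation=translation)
    return transform.apply(template.model.positions), transform


# ---------------------------------------------------------------------------
# configuration sampling
# ---------------------------------------------------------------------------

def _attempt_configuration(
    arch: ArchitectureSpec,
    rng: np.random.Generator,
    clash_scale: float,
    check_clashes: bool,
    per_arm_retry: bool,
    max_arm_attempts: int,
) -> Configuration | None:
    core = arch.core
    stack = _ObstacleStack()
    stack.push(core.model.positions, core.model.radii)

    linkers: list[np.ndarray] = []
    payload_positions: list[np.ndarray] = []
    transforms: list[RigidTransform] = []
    anchors_posed = np.empty((3, 3))
    tethers: list[np.ndarray] = []

    for k, arm in enumerate(arch.arms):
        tether_spec = None
        donor = None
        if arch.topology == "tandem" and k >= 1:
            tether_spec = arch.extra_tethers[k - 1]
            donor = core.c_anchor_points[k - 1]

        budget = max_arm_attempts if per_arm_retry else 1
        placed = None
        for _ in range(budget):
            placed = _attempt_arm(
                arch, k, arm, stack, rng, clash_scale, check_clashes,
                tether_spec, donor,
            )
            if placed is not None:
                break
        if placed is None:
            return None
        linker, posed, transform, anchor_pos, tether = placed
        stack.push(linker, arm.primary_linker.bead_radius)
        stack.push(posed, arm.payload.model.radii)
        if tether is not None:
            stack.push(tether, tether_spec.bead_radius)
        linkers.append(linker)
        payload_positions.append(posed)
        transforms.append(transform)
        anchors_posed[k] = anchor_pos
        tethers.append(tether)

    return _assemble_configuration(
        arch, linkers, payload_positions, transforms, anchors_posed, tethers
    )


def _junction_filter(
    posed: np.ndarray, radii: np.ndarray, junction: np.ndarray, bond_length: float
) -> tuple[np.ndarray, np.ndarray]:
    """Drop payload beads in the bonded neighborhood of a chain junction.

    Where a linker enters the domain, contacts with the domain's terminal
    residues are chain connectivity, not sterics; beads within
    ANCHOR_EXEMPT_BONDS bonds of the junction are exempt from clash checks
    against that linker.
    """
    keep = np.linalg.norm(posed - junction, axis=1) > ANCHOR_EXEMPT_BONDS * bond_length
    return posed[keep], radii[keep]


def _attempt_arm(
    arch, k, arm, stack, rng, clash_scale, check_clashes, tether_spec, donor
):
    """Place one arm: primary linker, payload, and (tandem arms 2/3) tether.

    Every arm grows its primary linker from the core N-anchor and poses the
    payload with its C-terminal anchor at the linker end (the payload
    precedes its trimerization domain in sequence). Double-tethered arms must
    additionally pass the tether reachability gate — the posed payload
    N-anchor within the extra tether's contour length of the donor core
    C-anchor — and a clash-free bridging tether is then grown between those
    two points.
    """
    core = arch.core
    anchor = core.n_anchor_points[k]
    obs = stack.arrays()
    payload_radii = arm.payload.model.radii

    if tether_spec is None:
        linker = grow_linker(
            anchor, arm.primary_linker, obs, rng,
            clash_scale=clash_scale, check_clashes=check_clashes,
        )
        if linker is None:
            return None
        linker_end = linker[-1] if linker.shape[0] else anchor
        posed, transform = place_payload(arm.payload, linker_end, rng, attach="c")
        anchor_pos = transform.apply(arm.payload.n_anchor)
        if check_clashes:
            if stack.clashes(posed, payload_radii, clash_scale):
                return None
            if linker.shape[0] > 1:
                pay_pos, pay_rad = _junction_filter(
                    posed, payload_radii, linker_end, arm.primary_linker.bond_length
                )
                if _any_clash(
                    pay_pos, pay_rad, linker[:-1],
                    arm.primary_linker.bead_radius, clash_scale,
                ):
                    return None
        return linker, posed, transform, anchor_pos, None

    # --- double-tethered arm ---
    linker = grow_linker(
        anchor, arm.primary_linker, obs, rng,
        clash_scale=clash_scale, check_clashes=check_clashes,
    )
    if linker is None:
        return None
    linker_end = linker[-1] if linker.shape[0] else anchor
    posed, transform = place_payload(arm.payload, linker_end, rng, attach="c")
    anchor_pos = transform.apply(arm.payload.n_anchor)

    # reachability gate: the donor C-anchor must be able to reach the posed
    # payload N-anchor within the tether's contour length — this restricts
    # both where the payload sits and how it is oriented
    if np.linalg.norm(donor - anchor_pos) > tether_spec.contour_length:
        return None

    if check_clashes:
        if stack.clashes(posed, payload_radii, clash_scale):
            return None
        if linker.shape[0] > 1:
            pay_pos, pay_rad = _junction_filter(
                posed, payload_radii, linker_end, arm.primary_linker.bond_length
            )
            if _any_clash(
                pay_pos, pay_rad, linker[:-1],
                arm.primary_linker.bead_radius, clash_scale,
            ):
                return None

    obs_pos, obs_rad = stack.arrays()
    if linker.shape[0]:
        obs_pos = np.concatenate([obs_pos, linker])
        obs_rad = np.concatenate(
            [obs_rad, np.full(linker.shape[0], arm.primary_linker.bead_radius)]
        )
    tether = _grow_bridge(
        rng, donor, anchor_pos, tether_spec,
        obstacles=(obs_pos, obs_rad),
        payload_block=_junction_filter(
            posed, payload_radii, anchor_pos, tether_spec.bond_length
        ),
        clash_scale=clash_scale, check_clashes=check_clashes,
    )
    if tether is None:
        return None
    return linker, posed, transform, anchor_pos, tether


def _assemble_configuration(
    arch, linkers, payload_positions, transforms, anchors_posed, tethers
) -> Configuration:
    blocks = [arch.core.model]
    chains: dict[str, np.ndarray] = {}
    for k in range(3):
        if linkers[k].shape[0]:
            blocks.append(
                BeadModel.from_arrays(
                    linkers[k], arch.arms[k].primary_linker.bead_radius,
                    LINKER_CHAIN_IDS[k], DomainLabel.LINKER,
                )
            )
            chains[LINKER_CHAIN_IDS[k]] = linkers[k]
        payload = arch.arms[k].payload
        blocks.append(
            BeadModel.from_arrays(
                payload_positions[k], payload.model.radii,
                PAYLOAD_CHAIN_IDS[k], PAYLOAD_LABELS[k],
            )
        )
    for k in (1, 2):
        tether = tethers[k]
        if tether is not None and tether.shape[0]:
            blocks.append(
                BeadModel.from_arrays(
                    tether, arch.extra_tethers[k - 1].bead_radius,
                    TETHER_CHAIN_IDS[k - 1], DomainLabel.LINKER,
                )
            )
            chains[TETHER_CHAIN_IDS[k - 1]] = tether
    return Configuration(
        model=BeadModel.concatenate(blocks, name=arch.topology),
        payload_transforms=tuple(transforms),
        payload_anchor_positions=anchors_posed,
        linker_chains=chains,
    )


def sample_configuration(
    arch: ArchitectureSpec,
    rng: np.random.Generator,
    max_inner_attempts: int = 100,
    per_arm_retry: bool = False,
    clash_scale: float = DEFAULT_CLASH_SCALE,
    check_clashes: bool = True,
) -> Configuration | None:
    """Sample one clash-free configuration; None after max_inner_attempts.

    By default whole-configuration rejection: any clash discards all arms.
    With ``per_arm_retry`` each arm is retried independently up to the same
    budget — same sterically allowed support, far fewer wasted draws for the
    double-tethered tandem arms.
    """
    arch.validate()
    for _ in range(max_inner_attempts):
        config = _attempt_configuration(
            arch, rng, clash_scale, check_clashes, per_arm_retry, max_inner_attempts
        )
        if config is not None:
            return config
    return None


def sample_ensemble(
    arch: ArchitectureSpec,
    n_accepted: int = DEFAULT_ENSEMBLE_SIZE,
    seed: int = 0,
    max_total_attempts: int = 2_000_000,
    per_arm_retry: bool = False,
    clash_scale: float = DEFAULT_CLASH_SCALE,
    check_clashes: bool = True,
    max_arm_attempts: int = 300,
) -> Ensemble:
    """Sample an ensemble of `n_accepted` configurations (default 150).

    Reproducible: the ensemble is a pure function of the architecture, the
    seed and the sampler parameters. Raises SamplingExhaustedError if
    `max_total_attempts` configuration attempts are spent first.
    """
    if n_accepted < 1:
        raise ValueError("n_accepted must be at least 1")
    arch.validate()
    rng = np.random.default_rng(seed)
    configurations: list[Configuration] = []
    attempts = 0
    while len(configurations) < n_accepted:
        if attempts >= max_total_attempts:
            raise SamplingExhaustedError(
                f"accepted only {len(configurations)}/{n_accepted} configurations "
                f"after {attempts} attempts; architecture may be over-constrained"
            )
        attempts += 1
        config = _attempt_configuration(
            arch, rng, clash_scale, check_clashes, per_arm_retry, max_arm_attempts
        )
        if config is not None:
            configurations.append(config)
    return Ensemble(
        configurations=configurations,
        architecture=arch,
        seed=seed,
        attempts=attempts,
    )
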