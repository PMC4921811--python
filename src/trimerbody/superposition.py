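"""Least-squares rigid superposition (Kabsch) and ensemble alignment.

Every sampled configuration is rigidly moved so that its trimerization-core
beads best fit a common reference core, putting all ensemble members in one
frame before their occupied volumes are merged. Rotations are constrained to
be proper (determinant +1): reflections would invert chirality.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .structure_io import BeadModel, DomainLabel


class DegenerateInputError(ValueError):
    """Point sets too degenerate (collinear/coincident) for a unique rotation."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation then translation, Å)."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rotation=rot_inv, translation=-rot_inv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying `other` first, then self."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(rotation=np.eye(3), translation=np.zeros(3))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of `mobile` onto `reference`.

    Returns the proper rigid transform minimizing the RMSD between the
    transformed mobile points and the reference points (in correspondence),
    and that minimal RMSD (Å). Requires at least 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"point sets must match: {mobile.shape[0]} vs {reference.shape[0]}"
        )
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 points for a unique superposition")

    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    a = mobile - cm
    b = reference - cr
    cov = a.T @ b
    u, s, vt = np.linalg.svd(cov)
    # degenerate if the points span less than a plane
    scale = max(s[0], 1e-30)
    if s[1] / scale < 1e-9:
        raise DegenerateInputError("input points are collinear or coincident")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = cr - rotation @ cm
    transform = RigidTransform(rotation=rotation, translation=translation)
    moved = transform.apply(mobile)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return transform, rmsd


def align_configuration(configuration, core_reference: BeadModel):
    """Align one configuration's CORE beads onto the reference core.

    The fitted transform is applied to every bead (core, linkers, payloads),
    so internal geometry is untouched. Returns (configuration, rmsd).
    """
    model: BeadModel = configuration.model
    core_mask = model.labels == int(DomainLabel.CORE)
    core_positions = model.positions[core_mask]
    if core_positions.shape[0] != len(core_reference):
        raise ValueError(
            "configuration core bead count does not match the reference core "
            f"({core_positions.shape[0]} vs {len(core_reference)})"
        )
    transform, rmsd = kabsch(core_positions, core_reference.positions)
    moved = model.transformed(transform.rotation, transform.translation)
    return dataclasses.replace(configuration, model=moved), rmsd


def align_ensemble(ensemble, core_reference: BeadModel):
    """Rigidly move every configuration so its core best fits the reference.

    Returns a new ensemble with per-configuration core RMSDs recorded in
    ``core_rmsds``.
    """
    aligned, rmsds = [], []
    for conf in ensemble.configurations:
        moved, rmsd = align_configuration(conf, core_reference)
        aligned.append(moved)
        rmsds.append(rmsd)
    return dataclasses.replace(
        ensemble, configurations=aligned, core_rmsds=np.asarray(rmsds)
    )
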