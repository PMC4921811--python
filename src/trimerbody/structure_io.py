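"""Coarse-grained structure containers and file I/O.

Proteins are represented as *bead models*: each bead is a sphere with a
position (Å), a radius (Å), a chain id, a 1-based residue index and a domain
label saying which architectural role it plays (trimerization core, flexible
linker, or one of the three payload antibody domains, labelled by their
position in the chain: N-terminal, internal, C-terminal).

Reading uses gemmi; real PDB files are coarse-grained either one bead per
residue at the Cα position (``calpha``) or one bead per heavy atom
(``heavy_atom``). Ensembles are written as multi-model PDB files and
occupancy grids as CCP4/MRC density maps, both via gemmi.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

#: Default bead radius (Å) for one-bead-per-residue models; approximates the
#: excluded volume of an average residue at Cα resolution.
DEFAULT_BEAD_RADIUS = 2.5


class DomainLabel(IntEnum):
    """Architectural role of a bead (closed enumeration)."""

    CORE = 0
    LINKER = 1
    PAYLOAD_N = 2
    PAYLOAD_I = 3
    PAYLOAD_C = 4


#: Labels that mark payload (antigen-binding domain) beads, in arm order.
PAYLOAD_LABELS = (DomainLabel.PAYLOAD_N, DomainLabel.PAYLOAD_I, DomainLabel.PAYLOAD_C)

# Residue names used when serializing bead models to PDB and back: standard
# amino-acid codes (so the records stay ATOM, not HETATM), one per label.
_RESNAME = {
    DomainLabel.CORE: "ALA",
    DomainLabel.LINKER: "GLY",
    DomainLabel.PAYLOAD_N: "ASN",
    DomainLabel.PAYLOAD_I: "ILE",
    DomainLabel.PAYLOAD_C: "CYS",
}
_LABEL_FROM_RESNAME = {v: k for k, v in _RESNAME.items()}


class StructureIOError(Exception):
    """Base error for structure reading/writing problems."""


class MissingChainError(StructureIOError):
    pass


class EmptySelectionError(StructureIOError):
    pass


@dataclass(frozen=True)
class Bead:
    """A single coarse-grained sphere."""

    chain_id: str
    residue_index: int
    label: DomainLabel
    position: np.ndarray  # shape (3,), Å
    radius: float  # Å


@dataclass
class BeadModel:
    """An ordered collection of beads stored as parallel numpy arrays.

    Invariants: non-empty, finite coordinates, non-negative radii and unique
    (chain_id, residue_index) pairs — enforced by :meth:`validate`.
    """

    positions: np.ndarray  # (n, 3) float64, Å
    radii: np.ndarray  # (n,) float64, Å
    chain_ids: np.ndarray  # (n,) unicode
    residue_indices: np.ndarray  # (n,) int64
    labels: np.ndarray  # (n,) int64 of DomainLabel values
    name: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4").reshape(-1)
        self.residue_indices = np.asarray(self.residue_indices, dtype=np.int64).reshape(-1)
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        n = len(self)
        if n == 0:
            raise ValueError("BeadModel must contain at least one bead")
        for arr in (self.radii, self.chain_ids, self.residue_indices, self.labels):
            if arr.shape[0] != n:
                raise ValueError("BeadModel arrays have inconsistent lengths")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("bead coordinates must be finite")
        if np.any(self.radii < 0):
            raise ValueError("bead radii must be non-negative")
        keys = list(zip(self.chain_ids.tolist(), self.residue_indices.tolist()))
        if len(set(keys)) != n:
            raise ValueError("(chain_id, residue_index) pairs must be unique")

    # -- container protocol ---------------------------------------------

    def __len__(self) -> int:
        return self.positions.shape[0]

    def __iter__(self) -> Iterator[Bead]:
        for i in range(len(self)):
            yield Bead(
                chain_id=str(self.chain_ids[i]),
                residue_index=int(self.residue_indices[i]),
                label=DomainLabel(int(self.labels[i])),
                position=self.positions[i].copy(),
                radius=float(self.radii[i]),
            )

    @property
    def beads(self) -> list[Bead]:
        return list(self)

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        positions: np.ndarray,
        radius: float | np.ndarray,
        chain_id: str,
        label: DomainLabel,
        start_residue: int = 1,
        name: str = "",
    ) -> "BeadModel":
        """One chain of beads with sequential residue numbering."""
        positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        n = positions.shape[0]
        radii = np.full(n, radius, dtype=float) if np.isscalar(radius) else np.asarray(radius)
        model = cls(
            positions=positions,
            radii=radii,
            chain_ids=np.full(n, chain_id, dtype="U4"),
            residue_indices=np.arange(start_residue, start_residue + n, dtype=np.int64),
            labels=np.full(n, int(label), dtype=np.int64),
            name=name,
        )
        model.validate()
        return model

    @staticmethod
    def concatenate(models: Sequence["BeadModel"], name: str = "") -> "BeadModel":
        if not models:
            raise ValueError("cannot concatenate zero models")
        out = BeadModel(
            positions=np.concatenate([m.positions for m in models]),
            radii=np.concatenate([m.radii for m in models]),
            chain_ids=np.concatenate([m.chain_ids for m in models]),
            residue_indices=np.concatenate([m.residue_indices for m in models]),
            labels=np.concatenate([m.labels for m in models]),
            name=name,
        )
        out.validate()
        return out

    def select(self, mask: np.ndarray, name: str = "") -> "BeadModel":
        mask = np.asarray(mask, dtype=bool)
        out = BeadModel(
            positions=self.positions[mask],
            radii=self.radii[mask],
            chain_ids=self.chain_ids[mask],
            residue_indices=self.residue_indices[mask],
            labels=self.labels[mask],
            name=name or self.name,
        )
        out.validate()
        return out

    def select_labels(self, labels: Iterable[DomainLabel]) -> "BeadModel":
        wanted = {int(l) for l in labels}
        mask = np.isin(self.labels, list(wanted))
        if not mask.any():
            raise EmptySelectionError(f"no beads with labels {sorted(wanted)}")
        return self.select(mask)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BeadModel":
        """Rigidly moved copy: x -> R x + t."""
        out = BeadModel(
            positions=self.positions @ np.asarray(rotation).T + np.asarray(translation),
            radii=self.radii.copy(),
            chain_ids=self.chain_ids.copy(),
            residue_indices=self.residue_indices.copy(),
            labels=self.labels.copy(),
            name=self.name,
        )
        return out

    def bounding_radius(self, center: np.ndarray | None = None) -> float:
        """Max distance of any bead surface from `center` (default centroid)."""
        c = self.positions.mean(axis=0) if center is None else np.asarray(center)
        return float(np.max(np.linalg.norm(self.positions - c, axis=1) + self.radii))


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def read_pdb_coarse(
    path: str | os.PathLike,
    chain_selection: set[str] | None = None,
    scheme: str = "calpha",
    bead_radius: float = DEFAULT_BEAD_RADIUS,
) -> BeadModel:
    """Read a PDB file and coarse-grain it to a bead model.

    ``calpha`` gives one bead per residue at the Cα position; ``heavy_atom``
    gives one bead per non-hydrogen atom. Only the first MODEL is used.
    HETATM records are skipped; among altlocs the highest-occupancy conformer
    is kept (ties broken by file order). Residue ordering, including
    insertion codes, follows the file.
    """
    if scheme not in ("calpha", "heavy_atom"):
        raise ValueError(f"unknown coarse-graining scheme: {scheme!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(f"PDB file not found: {path}")
    structure = gemmi.read_structure(str(path))
    if len(structure) == 0:
        raise StructureIOError(f"no models in {path}")
    model = structure[0]

    present = {ch.name for ch in model}
    if chain_selection is not None:
        missing = set(chain_selection) - present
        if missing:
            raise MissingChainError(
                f"chains {sorted(missing)} not present in {path} (has {sorted(present)})"
            )

    positions, chain_ids, residue_indices = [], [], []
    for chain in model:
        if chain_selection is not None and chain.name not in chain_selection:
            continue
        seen_in_chain: set[int] = set()
        ordinal = 0
        for residue in chain:
            if residue.het_flag == "H":
                continue
            ordinal += 1
            if scheme == "calpha":
                atoms = [a for a in residue if a.name == "CA" and not a.is_hydrogen()]
            else:
                atoms = [a for a in residue if not a.is_hydrogen()]
            # keep the highest-occupancy altloc per atom name (tie: first seen)
            by_name: dict[str, gemmi.Atom] = {}
            for a in atoms:
                prev = by_name.get(a.name)
                if prev is None or a.occ > prev.occ:
                    by_name[a.name] = a
            resnum = residue.seqid.num
            # insertion codes can duplicate numbers; fall back to chain ordinal
            if scheme == "calpha" and resnum in seen_in_chain:
                resnum = ordinal
            for a in by_name.values():
                positions.append([a.pos.x, a.pos.y, a.pos.z])
                chain_ids.append(chain.name)
                residue_indices.append(resnum)
            if scheme == "calpha" and by_name:
                seen_in_chain.add(resnum)

    if not positions:
        raise EmptySelectionError(f"no beads after selection from {path}")

    n = len(positions)
    if scheme == "heavy_atom":
        # each atom becomes its own "residue" for key uniqueness
        residue_indices = list(range(1, n + 1))
    model_out = BeadModel(
        positions=np.asarray(positions),
        radii=np.full(n, bead_radius),
        chain_ids=np.asarray(chain_ids, dtype="U4"),
        residue_indices=np.asarray(residue_indices, dtype=np.int64),
        labels=np.full(n, int(DomainLabel.CORE), dtype=np.int64),
        name=os.path.basename(str(path)),
    )
    model_out.validate()
    return model_out


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _gemmi_model_from_beads(model: BeadModel, serial: int) -> gemmi.Model:
    # gemmi copies chains on add_chain, so each chain is built fully first
    gm = gemmi.Model(serial)
    current_chain = None
    for i in range(len(model)):
        cid = str(model.chain_ids[i])
        if current_chain is None or current_chain.name != cid:
            if current_chain is not None:
                gm.add_chain(current_chain)
            current_chain = gemmi.Chain(cid)
        res = gemmi.Residue()
        res.name = _RESNAME[DomainLabel(int(model.labels[i]))]
        res.seqid = gemmi.SeqId(int(model.residue_indices[i]), " ")
        res.het_flag = "A"  # always ATOM records, even for one-bead chains
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        x, y, z = model.positions[i]
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        atom.occ = 1.0
        atom.b_iso = float(model.radii[i])  # bead radius stashed in B column
        res.add_atom(atom)
        current_chain.add_residue(res)
    if current_chain is not None:
        gm.add_chain(current_chain)
    return gm


def write_model_pdb(model: BeadModel, path: str | os.PathLike) -> None:
    """Write one bead model as a single-model PDB file."""
    st = gemmi.Structure()
    st.name = model.name or "beads"
    st.add_model(_gemmi_model_from_beads(model, 1))
    st.setup_entities()
    st.write_pdb(str(path))


def write_ensemble_pdb(ensemble, path: str | os.PathLike) -> None:
    """Write an ensemble as a multi-model PDB (one MODEL per configuration).

    Chain ids and residue numbering are identical across models, so the file
    round-trips through :func:`read_pdb_coarse` (first model, within the PDB
    coordinate precision of 1e-3 Å).
    """
    configurations = getattr(ensemble, "configurations", ensemble)
    if len(configurations) == 0:
        raise ValueError("cannot write an empty ensemble")
    st = gemmi.Structure()
    st.name = "ensemble"
    for k, conf in enumerate(configurations):
        model = getattr(conf, "model", conf)
        st.add_model(_gemmi_model_from_beads(model, k + 1))
    st.setup_entities()
    st.write_pdb(str(path))


def label_from_resname(resname: str) -> DomainLabel | None:
    """Recover a domain label from the 3-letter code used by the writers."""
    return _LABEL_FROM_RESNAME.get(resname)


# ---------------------------------------------------------------------------
# CCP4/MRC map writing
# ---------------------------------------------------------------------------

def write_grid_map(grid, path: str | os.PathLike) -> None:
    """Write an occupancy grid as a CCP4/MRC map (occupied=1.0, empty=0.0).

    The voxel spacing is encoded in the unit cell; the grid origin (center of
    voxel [0,0,0], Å) is stored in the MRC-2014 ORIGIN header words.
    """
    cells = np.asarray(grid.cells)
    if not cells.any():
        raise ValueError("refusing to write an all-empty grid")
    nx, ny, nz = cells.shape
    spacing = float(grid.spacing)
    fg = gemmi.FloatGrid(nx, ny, nz)
    fg.set_unit_cell(gemmi.UnitCell(nx * spacing, ny * spacing, nz * spacing, 90, 90, 90))
    np.asarray(fg, dtype=np.float32)[...] = cells.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = fg
    ccp4.update_ccp4_header()
    ox, oy, oz = np.asarray(grid.origin, dtype=float)
    ccp4.set_header_float(50, float(ox))
    ccp4.set_header_float(51, float(oy))
    ccp4.set_header_float(52, float(oz))
    ccp4.write_ccp4_map(str(path))
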