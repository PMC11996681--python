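"""Annotated structures and multi-frame trajectories.

The data model is deliberately small: a :class:`Topology` lists atoms with
their entity class (protein / dna / water / ion / other) and covalent
bonds, a :class:`Frame` carries one set of coordinates aligned to that
topology, and a :class:`Trajectory` is an ordered sequence of frames.
PDB multi-MODEL files are the on-disk representation (parsed and written
through gemmi); a plain XYZ-per-frame text reader is provided for
synthetic trajectories.

Distances are Euclidean in Angstrom; with an orthorhombic box the
minimum-image convention is applied per axis.  Triclinic cells are not
supported.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from . import constants


class EntityClass(str, enum.Enum):
    PROTEIN = "protein"
    DNA = "dna"
    WATER = "water"
    ION = "ion"
    OTHER = "other"


class TrajectoryError(ValueError):
    """Malformed or inconsistent trajectory input."""


@dataclass
class AtomRecord:
    """One atom of the topology.

    ``atom_index`` is the 0-based internal index; the original PDB serial
    is kept in ``pdb_serial`` for reporting only.
    """

    atom_index: int
    atom_name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    entity_class: EntityClass
    bonded_to: set[int] = field(default_factory=set)
    pdb_serial: int | None = None

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.residue_name)


@dataclass
class WaterMolecule:
    """Oxygen index plus 0 or 2 hydrogen indices of one water."""

    oxygen_index: int
    hydrogen_indices: tuple[int, ...]


@dataclass
class Topology:
    atoms: list[AtomRecord]
    water_molecules: list[WaterMolecule]
    box: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        for i, atom in enumerate(self.atoms):
            if atom.atom_index != i:
                raise TrajectoryError(
                    f"atom_index must be contiguous from 0; atom {i} has "
                    f"index {atom.atom_index}"
                )
        if self.box is not None:
            if len(self.box) != 3 or any(b <= 0 for b in self.box):
                raise TrajectoryError(f"box lengths must be positive: {self.box}")
        water_atoms = {a.atom_index for a in self.atoms
                       if a.entity_class is EntityClass.WATER}
        covered: set[int] = set()
        h_counts = set()
        for w in self.water_molecules:
            covered.add(w.oxygen_index)
            covered.update(w.hydrogen_indices)
            h_counts.add(len(w.hydrogen_indices))
        if covered != water_atoms:
            raise TrajectoryError(
                "water_molecules must partition exactly the water atoms"
            )
        if not h_counts <= {0, 2} or len(h_counts) > 1:
            raise TrajectoryError(
                f"waters must uniformly have 0 or 2 hydrogens, got counts {sorted(h_counts)}"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def selection(self, entity: EntityClass | str, label: str | None = None) -> "Selection":
        entity = EntityClass(entity)
        idx = {a.atom_index for a in self.atoms if a.entity_class is entity}
        return Selection(frozenset(idx), label or entity.value)

    def heavy_selection(self, entity: EntityClass | str) -> "Selection":
        entity = EntityClass(entity)
        idx = {a.atom_index for a in self.atoms
               if a.entity_class is entity and not a.is_hydrogen}
        return Selection(frozenset(idx), f"{entity.value}_heavy")

    def water_oxygen_indices(self) -> np.ndarray:
        return np.array([w.oxygen_index for w in self.water_molecules], dtype=int)


@dataclass
class Frame:
    positions: np.ndarray  # (n_atoms, 3) Angstrom
    frame_index: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise TrajectoryError("positions must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise TrajectoryError(f"non-finite coordinate in frame {self.frame_index}")


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise TrajectoryError("trajectory needs at least one frame")
        n = self.topology.n_atoms
        for f in self.frames:
            if f.positions.shape[0] != n:
                raise TrajectoryError(
                    f"frame {f.frame_index} has {f.positions.shape[0]} atoms, "
                    f"topology has {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinates(self) -> np.ndarray:
        """Stacked (n_frames, n_atoms, 3) coordinate array."""
        return np.stack([f.positions for f in self.frames])


@dataclass(frozen=True)
class Selection:
    atom_indices: frozenset[int]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "atom_indices", frozenset(self.atom_indices))

    def as_array(self) -> np.ndarray:
        return np.fromiter(sorted(self.atom_indices), dtype=int)

    def __len__(self) -> int:
        return len(self.atom_indices)


# ---------------------------------------------------------------------------
# entity classification and bond inference
# ---------------------------------------------------------------------------

def default_entity_rules() -> dict[str, EntityClass]:
    rules: dict[str, EntityClass] = {}
    for name in constants.WATER_RESIDUE_NAMES:
        rules[name] = EntityClass.WATER
    for name in constants.ION_RESIDUE_NAMES:
        rules[name] = EntityClass.ION
    for name in constants.DNA_RESIDUE_NAMES:
        rules[name] = EntityClass.DNA
    for name in constants.PROTEIN_RESIDUE_NAMES:
        rules[name] = EntityClass.PROTEIN
    return rules


def classify_residue(residue_name: str,
                     entity_rules: Mapping[str, EntityClass] | None = None
                     ) -> EntityClass:
    rules = default_entity_rules()
    if entity_rules:
        rules.update({k: EntityClass(v) for k, v in entity_rules.items()})
    return rules.get(residue_name.strip().upper(), EntityClass.OTHER)


_H_BOND_CUTOFF_A = 1.2    # X-H covalent attachment
_HEAVY_BOND_CUTOFF_A = 1.9


def infer_bonds(atoms: Sequence[AtomRecord], positions: np.ndarray) -> None:
    """Populate ``bonded_to`` in place from a distance heuristic.

    Hydrogens bond to the nearest heavy atom within 1.2 A; heavy-atom
    pairs within 1.9 A and belonging to the same or adjacent residue of
    one chain are covalent.  Good enough for donor/acceptor bookkeeping;
    no bond orders.
    """
    n = len(atoms)
    if n == 0:
        return
    heavy = [a for a in atoms if not a.is_hydrogen]
    hydro = [a for a in atoms if a.is_hydrogen]
    if heavy:
        heavy_pos = positions[[a.atom_index for a in heavy]]
        tree = cKDTree(heavy_pos)
        for h in hydro:
            dist, j = tree.query(positions[h.atom_index], k=1)
            if dist <= _H_BOND_CUTOFF_A:
                partner = heavy[int(j)]
                h.bonded_to.add(partner.atom_index)
                partner.bonded_to.add(h.atom_index)
        for i, j in tree.query_pairs(_HEAVY_BOND_CUTOFF_A):
            a, b = heavy[i], heavy[j]
            if a.chain_id == b.chain_id and abs(a.residue_seq - b.residue_seq) <= 1:
                a.bonded_to.add(b.atom_index)
                b.bonded_to.add(a.atom_index)


def _build_water_molecules(atoms: Sequence[AtomRecord],
                           positions: np.ndarray) -> list[WaterMolecule]:
    """Group water atoms into molecules.

    Hydrogens are attached via the per-residue grouping when possible and
    otherwise to the nearest water oxygen within 1.2 A.
    """
    waters = [a for a in atoms if a.entity_class is EntityClass.WATER]
    by_res: dict[tuple[str, int], list[AtomRecord]] = {}
    for a in waters:
        by_res.setdefault((a.chain_id, a.residue_seq), []).append(a)
    oxygens = [a for a in waters if a.element == "O"]
    if waters and not oxygens:
        raise TrajectoryError("water residues present but no water oxygen found")
    otree = cKDTree(positions[[a.atom_index for a in oxygens]]) if oxygens else None
    assignment: dict[int, list[int]] = {a.atom_index: [] for a in oxygens}
    for key, group in by_res.items():
        group_o = [a for a in group if a.element == "O"]
        group_h = [a for a in group if a.element == "H"]
        if len(group_o) > 1:
            raise TrajectoryError(f"water residue {key} has {len(group_o)} oxygens")
        for h in group_h:
            if group_o:
                oxy = group_o[0]
            else:
                dist, j = otree.query(positions[h.atom_index], k=1)
                if dist > _H_BOND_CUTOFF_A:
                    raise TrajectoryError(
                        f"water hydrogen {h.atom_index} has no oxygen within "
                        f"{_H_BOND_CUTOFF_A} A"
                    )
                oxy = oxygens[int(j)]
            assignment[oxy.atom_index].append(h.atom_index)
            h.bonded_to.add(oxy.atom_index)
            oxy.bonded_to.add(h.atom_index)
    molecules = [WaterMolecule(o, tuple(sorted(hs)))
                 for o, hs in assignment.items()]
    molecules.sort(key=lambda w: w.oxygen_index)
    return molecules


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb_models(path: str,
                    entity_rules: Mapping[str, EntityClass] | None = None,
                    ) -> Trajectory:
    """Read a (multi-MODEL) PDB file into a :class:`Trajectory`.

    One frame per MODEL record (a single frame if none).  Waters are
    detected by residue name (HOH/WAT/SOL/TIP3/OPC by default, extendable
    through ``entity_rules``); covalent bonds are inferred by the distance
    heuristic on the first frame.
    """
    try:
        st = gemmi.read_pdb(str(path), split_chain_on_ter=False)
    except (RuntimeError, ValueError) as exc:
        raise TrajectoryError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise TrajectoryError(f"no models in {path}")
    box = None
    cell = st.cell
    if cell and cell.a > 1.0:
        if not (abs(cell.alpha - 90) < 1e-6 and abs(cell.beta - 90) < 1e-6
                and abs(cell.gamma - 90) < 1e-6):
            raise TrajectoryError(
                "only orthorhombic boxes are supported "
                f"(angles {cell.alpha}, {cell.beta}, {cell.gamma})"
            )
        box = (cell.a, cell.b, cell.c)

    atoms: list[AtomRecord] = []
    model0 = st[0]
    for chain in model0:
        for res in chain:
            cls = classify_residue(res.name, entity_rules)
            for at in res:
                elem = at.element.name if at.element else ""
                atoms.append(AtomRecord(
                    atom_index=len(atoms),
                    atom_name=at.name,
                    element=elem.upper() if elem else _guess_element(at.name),
                    residue_name=res.name.strip().upper(),
                    residue_seq=res.seqid.num,
                    chain_id=chain.name,
                    entity_class=cls,
                    pdb_serial=at.serial,
                ))

    frames: list[Frame] = []
    n0 = len(atoms)
    for mi, model in enumerate(st):
        pos = []
        count = 0
        for chain in model:
            for res in chain:
                for at in res:
                    pos.append((at.pos.x, at.pos.y, at.pos.z))
                    count += 1
        if count != n0:
            raise TrajectoryError(
                f"MODEL {mi + 1} has {count} atoms but MODEL 1 has {n0}"
            )
        frames.append(Frame(np.array(pos), mi))

    infer_bonds(atoms, frames[0].positions)
    waters = _build_water_molecules(atoms, frames[0].positions)
    topology = Topology(atoms, waters, box=box)
    return Trajectory(topology, frames)


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def write_pdb_models(traj: Trajectory, path: str) -> None:
    """Write a trajectory as a multi-MODEL PDB file (3-decimal precision)."""
    st = gemmi.Structure()
    st.name = "hydrodna"
    box = traj.topology.box
    if box is not None:
        st.cell = gemmi.UnitCell(box[0], box[1], box[2], 90, 90, 90)
    # group atoms by chain, then residue, preserving topology order
    chains: dict[str, dict[tuple[str, int, str], list[AtomRecord]]] = {}
    for rec in traj.topology.atoms:
        chains.setdefault(rec.chain_id, {}).setdefault(rec.residue_key(), []).append(rec)
    for frame in traj.frames:
        model = gemmi.Model(frame.frame_index + 1)
        for chain_id, residues in chains.items():
            chain = gemmi.Chain(chain_id)
            for (_, seq, name), recs in residues.items():
                res = gemmi.Residue()
                res.name = name
                res.seqid = gemmi.SeqId(seq, " ")
                res.het_flag = "A"
                for rec in recs:
                    atom = gemmi.Atom()
                    atom.name = rec.atom_name
                    atom.element = gemmi.Element(rec.element)
                    x, y, z = frame.positions[rec.atom_index]
                    atom.pos = gemmi.Position(float(x), float(y), float(z))
                    atom.occ = 1.0
                    atom.b_iso = 0.0
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def read_xyz_frames(path: str, topology: Topology) -> Trajectory:
    """Plain text reader: one frame per block of ``n_atoms`` lines (x y z),
    blocks separated by blank lines or a leading count line."""
    frames: list[Frame] = []
    block: list[list[float]] = []
    n = topology.n_atoms
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 1:  # optional atom-count header
                continue
            if len(parts) < 3:
                raise TrajectoryError(f"line {lineno}: expected x y z, got {line!r}")
            try:
                block.append([float(p) for p in parts[:3]])
            except ValueError as exc:
                raise TrajectoryError(f"line {lineno}: {exc}") from exc
            if len(block) == n:
                frames.append(Frame(np.array(block), len(frames)))
                block = []
    if block:
        raise TrajectoryError(
            f"trailing partial frame of {len(block)} atoms (topology has {n})"
        )
    return Trajectory(topology, frames)


# ---------------------------------------------------------------------------
# distance queries
# ---------------------------------------------------------------------------

def displacement(a: np.ndarray, b: np.ndarray,
                 box: tuple[float, float, float] | None) -> np.ndarray:
    """Pairwise displacement b - a with per-axis minimum image under a box."""
    d = np.asarray(b, float) - np.asarray(a, float)
    if box is not None:
        L = np.asarray(box, float)
        d -= L * np.round(d / L)
    return d


def pairwise_distances(pa: np.ndarray, pb: np.ndarray,
                       box: tuple[float, float, float] | None) -> np.ndarray:
    """(len(pa), len(pb)) distance matrix, minimum-image when boxed."""
    d = pa[:, None, :] - pb[None, :, :]
    if box is not None:
        L = np.asarray(box, float)
        d -= L * np.round(d / L)
    return np.sqrt((d ** 2).sum(axis=-1))


def min_distance(frame: Frame, a: Selection, b: Selection,
                 box: tuple[float, float, float] | None = None) -> float:
    """Minimum pairwise distance (A) between two selections in one frame."""
    if len(a) == 0 or len(b) == 0:
        raise TrajectoryError("min_distance requires non-empty selections")
    pa = frame.positions[a.as_array()]
    pb = frame.positions[b.as_array()]
    if box is None and (len(a) > 64 or len(b) > 64):
        tree = cKDTree(pb)
        dists, _ = tree.query(pa, k=1)
        return float(dists.min())
    return float(pairwise_distances(pa, pb, box).min())
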