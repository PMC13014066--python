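"""Per-frame geometric detection of protein-ligand contacts over a
conformational ensemble, and persistence (occupancy) reporting.

Occupancy of an interaction is the exact fraction of frames in which
its geometric criterion holds. Water-bridged interactions are out of
scope by design: only direct ligand-protein (or ligand-metal)
contacts are detected, and waters (HOH/WAT) are ignored entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import EnsembleError
from .structure import AtomRecord, ResidueID, StructureModel

_WATER = {"HOH", "WAT"}
_POLAR = {"N", "O", "S"}


@dataclass(frozen=True, order=True)
class InteractionKey:
    """Identity of one geometric contact.

    kind is 'hbond', 'metal_coordination' or 'hydrophobic'; for
    hbonds, role says which side donates ('ligand_donor' /
    'ligand_acceptor'); for the other kinds role is ''.
    """

    kind: str
    ligand_atom: str
    chain_id: str
    resseq: int
    icode: str = ""
    role: str = ""

    @property
    def residue_id(self) -> ResidueID:
        return (self.chain_id, self.resseq, self.icode)


@dataclass
class InteractionCriteria:
    """Geometric cutoffs, Angstrom / degrees.

    Defaults follow common practice for heavy-atom contact analysis:
    3.5 A donor-acceptor with a 120 deg angle floor, 2.6 A for metal
    coordination by O/N/S, 4.5 A for apolar carbon-carbon contacts.
    """

    d_hbond: float = 3.5
    theta_hbond: float = 120.0
    d_metal: float = 2.6
    d_hydrophobic: float = 4.5


@dataclass
class Ensemble:
    """Ordered frames sharing one atom inventory plus the ligand/metal
    selections; frame_spacing is metadata only (e.g. ns per frame)."""

    frames: list[StructureModel]
    ligand: ResidueID | str
    metal: tuple[ResidueID, str] | str | None = None
    frame_spacing: float | None = None


@dataclass
class OccupancyTable:
    counts: dict[InteractionKey, int]
    n_frames: int
    threshold: float | None = None

    @property
    def fractions(self) -> dict[InteractionKey, float]:
        return {k: c / self.n_frames for k, c in self.counts.items()}


# ---------------------------------------------------------------------------
# atom bookkeeping

def _resolve_ligand(frame: StructureModel, ligand: ResidueID | str) -> list[AtomRecord]:
    if isinstance(ligand, str):
        atoms = [a for a in frame.atoms if a.resname == ligand]
    else:
        atoms = [a for a in frame.atoms if a.residue_id == tuple(ligand)]
    return atoms


def _resolve_metal(frame: StructureModel, metal) -> AtomRecord | None:
    if metal is None:
        return None
    if isinstance(metal, str):
        for a in frame.atoms:
            if a.resname == metal or (a.element.upper() == metal.upper() and a.is_het):
                return a
        return None
    rid, name = metal
    return frame.atom(tuple(rid), name)


def _neighbors(atoms: Sequence[AtomRecord]) -> list[list[int]]:
    """Covalent neighbour lists by distance (H < 1.3 A, heavy < 1.85 A,
    1.95 A when sulfur is involved)."""
    if not atoms:
        return []
    coords = np.array([a.xyz for a in atoms])
    tree = cKDTree(coords)
    nbrs: list[list[int]] = [[] for _ in atoms]
    for i, j in tree.query_pairs(1.95):
        ei, ej = atoms[i].element.upper(), atoms[j].element.upper()
        d = np.linalg.norm(coords[i] - coords[j])
        if "H" in (ei, ej):
            limit = 1.3
        elif "S" in (ei, ej):
            limit = 1.95
        else:
            limit = 1.85
        if d < limit:
            nbrs[i].append(j)
            nbrs[j].append(i)
    return nbrs


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosv = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def donor_angle(atoms: Sequence[AtomRecord], nbrs: list[list[int]],
                donor_idx: int, acceptor_xyz: np.ndarray) -> float | None:
    """Best hydrogen-bond angle at a donor atom toward an acceptor.

    With explicit hydrogens the D-H...A angle (at H) is used; without,
    the heavy-atom surrogate X-D...A angle (at D, X any heavy
    neighbour) stands in. Returns None if the donor has no neighbours
    at all (angle cannot be assessed; treated as non-donating).
    """
    donor = atoms[donor_idx]
    hs = [atoms[j] for j in nbrs[donor_idx] if atoms[j].element.upper() == "H"]
    if hs:
        return max(_angle(donor.xyz, h.xyz, acceptor_xyz) for h in hs)
    heavies = [atoms[j] for j in nbrs[donor_idx] if atoms[j].element.upper() != "H"]
    if heavies:
        return max(_angle(x.xyz, donor.xyz, acceptor_xyz) for x in heavies)
    return None


def _is_donor_capable(atoms: Sequence[AtomRecord], nbrs: list[list[int]], idx: int) -> bool:
    """Donor if it carries an explicit H, or is a hydroxyl-like
    terminal O (exactly one heavy neighbour)."""
    a = atoms[idx]
    if a.element.upper() not in ("N", "O"):
        return False
    heavy_n = [j for j in nbrs[idx] if atoms[j].element.upper() != "H"]
    has_h = any(atoms[j].element.upper() == "H" for j in nbrs[idx])
    return has_h or (a.element.upper() == "O" and len(heavy_n) == 1)


def _is_apolar_carbon(atoms: Sequence[AtomRecord], nbrs: list[list[int]], idx: int) -> bool:
    if atoms[idx].element.upper() != "C":
        return False
    return not any(atoms[j].element.upper() in _POLAR for j in nbrs[idx])


# ---------------------------------------------------------------------------

def detect_frame_interactions(
    frame: StructureModel,
    ligand: ResidueID | str,
    metal=None,
    criteria: InteractionCriteria | None = None,
) -> set[InteractionKey]:
    """Detect all ligand-protein contacts in one frame.

    Hydrogen bond: donor and acceptor heavy atoms within d_hbond and
    donor angle >= theta_hbond. Metal coordination: ligand O/N/S
    within d_metal of the metal. Hydrophobic: apolar ligand carbon
    within d_hydrophobic of an apolar protein carbon (one key per
    ligand-atom/residue pair).
    """
    crit = criteria or InteractionCriteria()
    lig_atoms = _resolve_ligand(frame, ligand)
    if not lig_atoms:
        warnings.warn("ligand selection matched no atoms", stacklevel=2)
        return set()
    met = _resolve_metal(frame, metal)
    lig_ids = {id(a) for a in lig_atoms}
    met_id = id(met) if met is not None else None

    env = [a for a in frame.atoms
           if id(a) not in lig_ids and id(a) is not met_id
           and a.resname not in _WATER]
    all_atoms = list(lig_atoms) + env
    nbrs = _neighbors(all_atoms)
    n_lig = len(lig_atoms)

    env_heavy = [(i + n_lig, a) for i, a in enumerate(env) if a.element.upper() != "H"]
    keys: set[InteractionKey] = set()

    for li, la in enumerate(lig_atoms):
        if la.element.upper() == "H":
            continue
        lxyz = la.xyz
        for ei, ea in env_heavy:
            d = float(np.linalg.norm(lxyz - ea.xyz))
            # hydrogen bonds
            if (la.element.upper() in _POLAR and ea.element.upper() in _POLAR
                    and d <= crit.d_hbond):
                if _is_donor_capable(all_atoms, nbrs, li):
                    ang = donor_angle(all_atoms, nbrs, li, ea.xyz)
                    if ang is not None and ang >= crit.theta_hbond:
                        keys.add(InteractionKey("hbond", la.name, ea.chain_id,
                                                ea.resseq, ea.icode, "ligand_donor"))
                if _is_donor_capable(all_atoms, nbrs, ei):
                    ang = donor_angle(all_atoms, nbrs, ei, lxyz)
                    if ang is not None and ang >= crit.theta_hbond:
                        keys.add(InteractionKey("hbond", la.name, ea.chain_id,
                                                ea.resseq, ea.icode, "ligand_acceptor"))
            # hydrophobic
            if (d <= crit.d_hydrophobic
                    and _is_apolar_carbon(all_atoms, nbrs, li)
                    and _is_apolar_carbon(all_atoms, nbrs, ei)):
                keys.add(InteractionKey("hydrophobic", la.name, ea.chain_id,
                                        ea.resseq, ea.icode))
        # metal coordination
        if met is not None and la.element.upper() in _POLAR:
            if float(np.linalg.norm(lxyz - met.xyz)) <= crit.d_metal:
                keys.add(InteractionKey("metal_coordination", la.name,
                                        met.chain_id, met.resseq, met.icode))
    return keys


def occupancy(ensemble: Ensemble, criteria: InteractionCriteria | None = None) -> OccupancyTable:
    """Fraction of frames in which each contact holds (exact
    count / n_frames)."""
    if not ensemble.frames:
        raise EnsembleError("ensemble has no frames")
    inv0 = {(a.chain_id, a.resseq, a.icode, a.name) for a in ensemble.frames[0].atoms}
    counts: dict[InteractionKey, int] = {}
    for i, frame in enumerate(ensemble.frames):
        inv = {(a.chain_id, a.resseq, a.icode, a.name) for a in frame.atoms}
        if inv != inv0:
            raise EnsembleError(f"frame {i} atom inventory differs from frame 0")
        for key in detect_frame_interactions(frame, ensemble.ligand,
                                             ensemble.metal, criteria):
            counts[key] = counts.get(key, 0) + 1
    return OccupancyTable(counts=counts, n_frames=len(ensemble.frames))


def report_persistent(
    table: OccupancyTable, min_fraction: float = 0.25
) -> list[tuple[InteractionKey, float]]:
    """Keys with occupancy strictly above ``min_fraction``, most
    persistent first; exact ties broken by key ordering."""
    rows = [(k, c / table.n_frames) for k, c in table.counts.items()
            if c / table.n_frames > min_fraction]
    rows.sort(key=lambda kv: (-kv[1], kv[0]))
    return rows
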