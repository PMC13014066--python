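"""Macromolecular structure handling: PDB I/O, chain extraction, residue
pairing and rigid superposition with iterative outlier rejection.

Coordinates are in Angstrom throughout. Author residue numbering is kept
as read; nothing is renumbered on output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import gemmi
import numpy as np
from Bio import Align

from .errors import (
    ChainNotFoundError,
    DegenerateFitError,
    EmptyInputError,
    PDBParseError,
)

#: residue identifier: (chain_id, resseq, icode)
ResidueID = tuple[str, int, str]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}


@dataclass
class AtomRecord:
    """One atom of a structure model (PDB-style record)."""

    serial: int
    name: str
    element: str
    altloc: str
    resname: str
    chain_id: str
    resseq: int
    icode: str
    xyz: np.ndarray
    occupancy: float = 1.0
    is_het: bool = False

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: xyz must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element symbol is empty")

    @property
    def residue_id(self) -> ResidueID:
        return (self.chain_id, self.resseq, self.icode)

    def copy(self) -> "AtomRecord":
        return replace(self, xyz=self.xyz.copy())


@dataclass
class StructureModel:
    """One MODEL's worth of atoms, ordered as read."""

    model_id: int = 1
    atoms: list[AtomRecord] = field(default_factory=list)

    def copy(self) -> "StructureModel":
        return StructureModel(self.model_id, [a.copy() for a in self.atoms])

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residues(self) -> dict[ResidueID, list[AtomRecord]]:
        """Atoms grouped by residue, in file order."""
        out: dict[ResidueID, list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_id, []).append(a)
        return out

    def polymer_residues(self, chain_id: str) -> dict[ResidueID, list[AtomRecord]]:
        return {
            rid: ats
            for rid, ats in self.residues().items()
            if rid[0] == chain_id and not ats[0].is_het
        }

    def chain_residue_ids(self, chain_id: str) -> list[ResidueID]:
        return list(self.polymer_residues(chain_id))

    def chain_sequence(self, chain_id: str, gap_marker: str = "-") -> str:
        """One-letter sequence of a chain; ``gap_marker`` inserted at
        numbering discontinuities (one marker per missing residue)."""
        res = self.polymer_residues(chain_id)
        out: list[str] = []
        prev: int | None = None
        for (chain, num, icode), ats in res.items():
            if prev is not None and icode == "" and num > prev + 1:
                out.append(gap_marker * (num - prev - 1))
            out.append(_AA3TO1.get(ats[0].resname, "X"))
            prev = num
        return "".join(out)

    def atom(self, rid: ResidueID, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.residue_id == rid and a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms]) if self.atoms else np.empty((0, 3))


@dataclass
class Superposition:
    """Rigid transform mapping mobile coordinates onto a target frame:
    ``x -> x @ rotation.T + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_kept: float = 0.0
    rmsd_all: float = 0.0
    kept_pairs: int = 0
    cycles_run: int = 0

    @classmethod
    def identity(cls) -> "Superposition":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, float) @ self.rotation.T + self.translation

    def inverse(self) -> "Superposition":
        rinv = self.rotation.T
        return Superposition(rinv, -rinv @ self.translation,
                             self.rmsd_kept, self.rmsd_all,
                             self.kept_pairs, self.cycles_run)


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)

def _from_gemmi_model(gm: gemmi.Model, model_id: int) -> StructureModel:
    atoms: list[AtomRecord] = []
    for chain in gm:
        for res in chain:
            is_het = res.het_flag == "H"
            # altloc policy: keep highest occupancy per atom name,
            # ties broken by altloc letter order
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                cur = best.get(at.name)
                if (cur is None or at.occ > cur.occ
                        or (at.occ == cur.occ and (at.altloc or "~") < (cur.altloc or "~"))):
                    best[at.name] = at
            for at in best.values():
                atoms.append(
                    AtomRecord(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name,
                        altloc=at.altloc if at.altloc != "\0" else "",
                        resname=res.name,
                        chain_id=chain.name,
                        resseq=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                        is_het=is_het,
                    )
                )
    return StructureModel(model_id=model_id, atoms=atoms)


def read_pdb(path: str, model_select: int | None = None) -> list[StructureModel]:
    """Read a PDB file into one StructureModel per MODEL record.

    ``model_select`` keeps only the model with that (1-based) number.
    HETATM records are retained with ``is_het`` set; for alternate
    locations the highest-occupancy conformer is kept.
    """
    with open(path) as fh:
        if not fh.read().strip():
            raise EmptyInputError(f"{path}: empty PDB file")
    try:
        st = gemmi.read_pdb(path)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    models = [_from_gemmi_model(m, m.num) for m in st]
    models = [m for m in models if m.atoms]
    if not models:
        raise EmptyInputError(f"{path}: no atoms found")
    if model_select is not None:
        models = [m for m in models if m.model_id == model_select]
        if not models:
            raise PDBParseError(f"{path}: no MODEL {model_select}")
    return models


def write_pdb(models: StructureModel | Sequence[StructureModel], path: str) -> None:
    """Write one or more models as a standard PDB file.

    Round-trips atom names, numbering and coordinates at format
    precision (1e-3 A).
    """
    if isinstance(models, StructureModel):
        models = [models]
    if not models or not any(m.atoms for m in models):
        raise EmptyInputError("refusing to write an empty structure")
    st = gemmi.Structure()
    for model in models:
        gm = gemmi.Model(model.model_id)
        chain_map: dict[str, gemmi.Chain] = {}
        for a in model.atoms:
            ch = chain_map.get(a.chain_id)
            if ch is None:
                ch = gemmi.Chain(a.chain_id)
                chain_map[a.chain_id] = ch
            res = None
            if len(ch) > 0:
                last = ch[len(ch) - 1]
                if (last.seqid.num == a.resseq and last.seqid.icode.strip() == a.icode
                        and last.name == a.resname):
                    res = last
            if res is None:
                res = gemmi.Residue()
                res.name = a.resname
                res.seqid = gemmi.SeqId(a.resseq, a.icode or " ")
                res.het_flag = "H" if a.is_het else "A"
                ch.add_residue(res)
                res = ch[len(ch) - 1]
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.altloc = a.altloc or "\0"
            at.pos = gemmi.Position(*a.xyz)
            at.occ = a.occupancy
            at.serial = a.serial
            res.add_atom(at)
        for ch in chain_map.values():
            gm.add_chain(ch)
        st.add_model(gm)
    st.renumber_models()
    st.write_pdb(path)


# ---------------------------------------------------------------------------
# chain extraction and residue pairing

def extract_chain(model: StructureModel, chain_id: str, keep_het: bool = True) -> StructureModel:
    """Return a model restricted to one chain; het groups of that chain
    kept iff ``keep_het``."""
    if chain_id not in model.chains():
        raise ChainNotFoundError(f"chain {chain_id!r} not in model "
                                 f"(has {model.chains()})")
    atoms = [a.copy() for a in model.atoms
             if a.chain_id == chain_id and (keep_het or not a.is_het)]
    return StructureModel(model.model_id, atoms)


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -2


def pair_residues(a: StructureModel, b: StructureModel) -> list[tuple[ResidueID, ResidueID]]:
    """Pair residues between two models by global sequence alignment.

    Each polymer chain of ``a`` is aligned against the best-scoring
    chain of ``b`` (identity scoring: match +1, mismatch -1, gap -2);
    aligned positions with identical residue identity become pairs,
    so fully dissimilar sequences yield no pairs. Deterministic for
    fixed inputs.
    """
    pairs: list[tuple[ResidueID, ResidueID]] = []
    b_chains = [c for c in b.chains() if b.chain_residue_ids(c)]
    for chain_a in a.chains():
        ids_a = a.chain_residue_ids(chain_a)
        if not ids_a:
            continue
        seq_a = _pure_sequence(a, chain_a)
        best: tuple[float, str] | None = None
        for chain_b in b_chains:
            score = _aligner.score(seq_a, _pure_sequence(b, chain_b))
            if best is None or score > best[0]:
                best = (score, chain_b)
        if best is None:
            continue
        chain_b = best[1]
        ids_b = b.chain_residue_ids(chain_b)
        seq_b = _pure_sequence(b, chain_b)
        aln = _aligner.align(seq_a, seq_b)[0]
        for (sa, ea), (sb, _eb) in zip(*aln.aligned):
            for k in range(ea - sa):
                if seq_a[sa + k] == seq_b[sb + k]:
                    pairs.append((ids_a[sa + k], ids_b[sb + k]))
    if not pairs:
        warnings.warn("no alignable residues between models", stacklevel=2)
    return pairs


def _pure_sequence(m: StructureModel, chain_id: str) -> str:
    return m.chain_sequence(chain_id, gap_marker="")


# ---------------------------------------------------------------------------
# superposition

def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation/translation mapping mobile onto target.

    Returns (R, t) with det(R) = +1 such that mobile @ R.T + t best
    fits target.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ct - r @ cm
    return r, t


def _rmsd(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))


def superpose(
    mobile: StructureModel,
    target: StructureModel,
    pairs: Sequence[tuple[ResidueID, ResidueID]],
    atom_set: str = "backbone",
    cycles: int = 5,
    reject_sigma: float = 2.0,
) -> Superposition:
    """Rigid superposition of mobile onto target over paired residues,
    with iterative outlier rejection.

    ``atom_set`` is "backbone" (N, CA, C, O) or "ca". After each Kabsch
    cycle, atom pairs deviating by more than ``reject_sigma`` times the
    current RMSD are discarded and the fit repeated; iteration stops
    when no pair is removed or ``cycles`` are exhausted. ``rmsd_all``
    reports the final transform's RMSD over all initially paired atoms.
    """
    names = ("CA",) if atom_set == "ca" else BACKBONE_ATOMS
    xm, xt = [], []
    for rid_m, rid_t in pairs:
        for name in names:
            am, at = mobile.atom(rid_m, name), target.atom(rid_t, name)
            if am is not None and at is not None:
                xm.append(am.xyz)
                xt.append(at.xyz)
    xm_all = np.array(xm)
    xt_all = np.array(xt)
    if len(xm_all) < 3:
        raise DegenerateFitError(f"only {len(xm_all)} paired atoms; need >= 3")

    keep = np.ones(len(xm_all), bool)
    cycles_run = 0
    r, t = np.eye(3), np.zeros(3)
    for _ in range(max(1, cycles)):
        r, t = kabsch(xm_all[keep], xt_all[keep])
        cycles_run += 1
        moved = xm_all @ r.T + t
        dev = np.linalg.norm(moved - xt_all, axis=1)
        rmsd = _rmsd(moved[keep], xt_all[keep])
        new_keep = keep & ~(dev > reject_sigma * rmsd)
        if new_keep.sum() < 3:
            raise DegenerateFitError("fewer than 3 pairs survive outlier rejection")
        if new_keep.sum() == keep.sum():
            break
        keep = new_keep
    moved = xm_all @ r.T + t
    return Superposition(
        rotation=r,
        translation=t,
        rmsd_kept=_rmsd(moved[keep], xt_all[keep]),
        rmsd_all=_rmsd(moved, xt_all),
        kept_pairs=int(keep.sum()),
        cycles_run=cycles_run,
    )


def apply_transform(model: StructureModel, sp: Superposition) -> StructureModel:
    """Return a copy of the model with all atoms (het included) moved."""
    out = model.copy()
    if out.atoms:
        moved = sp.apply(out.coords())
        for atom, xyz in zip(out.atoms, moved):
            atom.xyz = xyz
    return out
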