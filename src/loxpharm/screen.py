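"""Pharmacophore screening: ligand feature-point annotation, match-all
alignment against a model, fit scoring, and library ranking.

Matching semantics follow the classic "match all query features"
mode: every required model feature must be assigned a type-compatible
ligand point within its spatial tolerance after the best rigid
alignment; optional features add score when satisfied but never veto.
With excluded-volume checking enabled, a pose placing any ligand
heavy atom inside an excluded sphere is rejected.

The fit score is
    10 x (number of matched features, optional included)
      - sum over matched features of deviation / tolerance,
so more matched features always beat fewer, and smaller deviations
beat larger ones; a non-match scores 0.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .perceive import PharmacophoreModel
from .structure import Superposition, kabsch

_APOLAR_BLOCKERS = {"N", "O", "S", "P"}


@dataclass
class Conformer:
    elements: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)

    def heavy_coords(self) -> np.ndarray:
        mask = [e.upper() != "H" for e in self.elements]
        return self.coords[mask] if any(mask) else np.empty((0, 3))


@dataclass
class LigandPoint:
    """One typed feature point of a ligand conformer."""

    ftype: str                  # HBD | HBA | HYD | NI | METAL
    center: np.ndarray
    source_atoms: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)


@dataclass
class LigandRecord:
    id: str
    smiles: str = ""
    conformers: list[Conformer] = field(default_factory=list)
    label: str = "unknown"      # active | decoy | unknown
    properties: dict = field(default_factory=dict)
    #: precomputed per-conformer feature points (synthetic pseudo-ligands);
    #: when set, annotate_ligand returns these instead of perceiving from
    #: the molecular graph
    feature_points: list[list[LigandPoint]] | None = None


@dataclass
class MatchResult:
    ligand_id: str
    conformer_index: int = -1
    matched: bool = False
    fit_score: float = 0.0
    assignment: dict[str, int] = field(default_factory=dict)
    deviations: dict[str, float] = field(default_factory=dict)
    tolerances: dict[str, float] = field(default_factory=dict)
    transform: Superposition | None = None
    ev_violations: int = 0


# ---------------------------------------------------------------------------
# RDKit-based annotation of real molecules

_SMARTS = {
    "HBD": ["[#7;!H0]", "[#8;!H0]"],
    "HBA": ["[#8]", "[#7;H0;X2]", "[#7;H0;X3;!$([#7]-[#6]=[O,S])]", "[#7;X1]"],
}
_NI_SMARTS = [
    "[CX3](=O)[OX2H1,OX1-]",                 # carboxylic acid / carboxylate
    "c1nnn[nH]1", "c1nnn[n-]1",              # tetrazole
    "[OX2H1,OX1-][NX3][CX3](=[OX1])",        # N-hydroxyurea / hydroxamate N-OH
    "[NX3]([SX4](=O)=O)[CX3](=[OX1])",       # acylsulfonamide
]
_METAL_CAPABLE_SMARTS = [
    "[OX2H1]c1ccccc1[OX2H1]",                # catechol (both OH oxygens)
    "[OX2H1,OX1-][NX3][CX3](=[OX1])",        # N-hydroxyurea / hydroxamate O
]


def _rdkit_mol(ligand: "LigandRecord"):
    from rdkit import Chem
    mol = Chem.MolFromSmiles(ligand.smiles)
    if mol is None:
        return None
    return Chem.AddHs(mol)


def annotate_ligand(ligand: LigandRecord) -> list[list[LigandPoint]]:
    """Typed feature points per conformer.

    Pseudo-ligands with precomputed points return them verbatim.
    Otherwise the SMILES is parsed with RDKit, feature atoms are found
    by SMARTS (donors, acceptors, negative-ionizable groups,
    metal-capable oxygens) plus a connected-component search for
    apolar fragments, and centers are read from each conformer's
    coordinates. Unparsable records yield an empty list with a
    warning.
    """
    if ligand.feature_points is not None:
        return ligand.feature_points
    from rdkit import Chem
    mol = Chem.MolFromSmiles(ligand.smiles)
    if mol is None:
        warnings.warn(f"ligand {ligand.id}: unparsable SMILES; skipped",
                      stacklevel=2)
        return []
    typed_atoms: dict[str, set[tuple[int, ...]]] = {
        "HBD": set(), "HBA": set(), "NI": set(), "METAL": set()}
    for ftype, patterns in _SMARTS.items():
        for smarts in patterns:
            patt = Chem.MolFromSmarts(smarts)
            for match in mol.GetSubstructMatches(patt):
                typed_atoms[ftype].add((match[0],))
    for smarts in _NI_SMARTS:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            typed_atoms["NI"].add(tuple(sorted(match)))
    for smarts in _METAL_CAPABLE_SMARTS:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            for ai in match:
                if mol.GetAtomWithIdx(ai).GetSymbol() == "O":
                    typed_atoms["METAL"].add((ai,))
    hyd_fragments = _apolar_fragments_rdkit(mol)

    out: list[list[LigandPoint]] = []
    for conf in ligand.conformers:
        pts: list[LigandPoint] = []
        for ftype, groups in typed_atoms.items():
            for group in sorted(groups):
                center = np.mean([conf.coords[i] for i in group], axis=0)
                pts.append(LigandPoint(ftype, center, group))
        for frag in hyd_fragments:
            center = np.mean([conf.coords[i] for i in frag], axis=0)
            pts.append(LigandPoint("HYD", center, tuple(frag)))
        out.append(pts)
    return out


def _apolar_fragments_rdkit(mol, min_size: int = 3) -> list[list[int]]:
    """Connected apolar-carbon fragments (>= min_size heavy atoms)."""
    apolar = set()
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C":
            continue
        if any(n.GetSymbol() in _APOLAR_BLOCKERS for n in atom.GetNeighbors()):
            continue
        apolar.add(atom.GetIdx())
    comps = []
    left = set(apolar)
    while left:
        stack = [left.pop()]
        comp = []
        while stack:
            i = stack.pop()
            comp.append(i)
            for n in mol.GetAtomWithIdx(i).GetNeighbors():
                j = n.GetIdx()
                if j in left:
                    left.remove(j)
                    stack.append(j)
        if len(comp) >= min_size:
            comps.append(sorted(comp))
    return comps


def embed_conformers(ligand_id: str, smiles: str, n_conformers: int = 25,
                     seed: int = 2021, label: str = "unknown") -> LigandRecord:
    """Distance-geometry (ETKDG) multi-conformer embedding convenience
    wrapper; the matcher itself is generator-agnostic."""
    from rdkit import Chem
    from rdkit.Chem import AllChem, Descriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        warnings.warn(f"{ligand_id}: unparsable SMILES", stacklevel=2)
        return LigandRecord(id=ligand_id, smiles=smiles, label=label)
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    AllChem.EmbedMultipleConfs(molh, numConfs=n_conformers, params=params)
    molh = Chem.RemoveHs(molh)
    elements = [a.GetSymbol() for a in molh.GetAtoms()]
    conformers = [Conformer(elements, np.array(c.GetPositions()))
                  for c in molh.GetConformers()]
    props = {
        "mw": Descriptors.MolWt(mol),
        "logp": Descriptors.MolLogP(mol),
        "hbd": Descriptors.NumHDonors(mol),
        "hba": Descriptors.NumHAcceptors(mol),
        "charge": Chem.GetFormalCharge(mol),
    }
    return LigandRecord(id=ligand_id, smiles=smiles, conformers=conformers,
                        label=label, properties=props)


# ---------------------------------------------------------------------------
# matching

def compute_fit_score(deviations: Sequence[float], tolerances: Sequence[float]) -> float:
    return 10.0 * len(deviations) - sum(d / t for d, t in zip(deviations, tolerances))


def fit_score(result: MatchResult) -> float:
    """Recompute the fit score from a result's per-feature deviations."""
    if not result.matched:
        return 0.0
    labels = list(result.deviations)
    return compute_fit_score([result.deviations[l] for l in labels],
                             [result.tolerances[l] for l in labels])


def match(
    model: PharmacophoreModel,
    points: Sequence[LigandPoint],
    conformer: Conformer | None = None,
    check_ev: bool = True,
    ligand_id: str = "",
    conformer_index: int = 0,
) -> MatchResult:
    """Match one conformer's feature points against a model.

    Enumerates all injective, type-compatible assignments of required
    features to ligand points; each candidate is rigidly aligned
    (Kabsch on the assigned points; translation-only when fewer than
    three required features pin the frame) and accepted if every
    required deviation is within tolerance and, when ``check_ev``, no
    ligand heavy atom falls inside an excluded volume. Optional
    features are then greedily added when within tolerance. The
    highest-scoring accepted assignment wins; non-match is a result
    with score 0, never an error.
    """
    required = model.required_features()
    if not required:
        raise ValueError("model has no required features; refusing degenerate match-everything screen")
    optional = [f for f in model.features if f.optional]

    by_type_pts: dict[str, list[int]] = {}
    for i, p in enumerate(points):
        by_type_pts.setdefault(p.ftype, []).append(i)
    by_type_req: dict[str, list[int]] = {}
    for i, f in enumerate(required):
        by_type_req.setdefault(f.ftype, []).append(i)

    no_match = MatchResult(ligand_id=ligand_id, conformer_index=conformer_index)
    for ftype, fidx in by_type_req.items():
        if len(by_type_pts.get(ftype, [])) < len(fidx):
            return no_match

    per_type_assignments = []
    for ftype, fidx in by_type_req.items():
        cands = by_type_pts[ftype]
        per_type_assignments.append(
            [list(zip(fidx, perm))
             for perm in itertools.permutations(cands, len(fidx))])

    heavy = conformer.heavy_coords() if conformer is not None else np.empty((0, 3))
    best: MatchResult | None = None
    for combo in itertools.product(*per_type_assignments):
        pairs = [pair for block in combo for pair in block]
        src = np.array([points[pi].center for _fi, pi in pairs])
        dst = np.array([required[fi].center for fi, _pi in pairs])
        if len(pairs) >= 3:
            r, t = kabsch(src, dst)
        else:
            r, t = np.eye(3), dst.mean(axis=0) - src.mean(axis=0)
        sp = Superposition(r, t)
        moved = sp.apply(src)
        devs = np.linalg.norm(moved - dst, axis=1)
        if any(d > required[fi].tolerance for (fi, _pi), d in zip(pairs, devs)):
            continue
        ev_violations = 0
        if check_ev and model.volumes and len(heavy):
            moved_heavy = sp.apply(heavy)
            for vol in model.volumes:
                ev_violations += int(np.sum(
                    np.linalg.norm(moved_heavy - vol.center, axis=1) < vol.radius))
            if ev_violations:
                continue
        assignment = {required[fi].label: pi for fi, pi in pairs}
        deviations = {required[fi].label: float(d)
                      for (fi, _pi), d in zip(pairs, devs)}
        tolerances = {required[fi].label: required[fi].tolerance
                      for fi, _pi in pairs}
        used = {pi for _fi, pi in pairs}
        for f in optional:
            cands = [(float(np.linalg.norm(sp.apply(points[pi].center) - f.center)), pi)
                     for pi in by_type_pts.get(f.ftype, []) if pi not in used]
            cands.sort()
            if cands and cands[0][0] <= f.tolerance:
                d, pi = cands[0]
                used.add(pi)
                assignment[f.label] = pi
                deviations[f.label] = d
                tolerances[f.label] = f.tolerance
        score = compute_fit_score(list(deviations.values()),
                                  list(tolerances.values()))
        if best is None or score > best.fit_score:
            best = MatchResult(ligand_id=ligand_id, conformer_index=conformer_index,
                               matched=True, fit_score=score,
                               assignment=assignment, deviations=deviations,
                               tolerances=tolerances, transform=sp,
                               ev_violations=0)
    return best if best is not None else no_match


def screen_library(
    model: PharmacophoreModel,
    library: Sequence[LigandRecord],
    check_ev: bool = True,
) -> tuple[list[MatchResult], list[str]]:
    """Screen a library; one result per ligand (best conformer).

    Returns (ranked results, skipped ligand ids). Matches are ranked
    by fit score descending with ties broken by ligand id; all
    non-matches follow, score 0, ordered by id.
    """
    results: list[MatchResult] = []
    skipped: list[str] = []
    for ligand in library:
        point_sets = annotate_ligand(ligand)
        n_conf = (len(ligand.feature_points) if ligand.feature_points is not None
                  else len(ligand.conformers))
        if n_conf == 0 or not point_sets:
            skipped.append(ligand.id)
            continue
        best: MatchResult | None = None
        for ci in range(len(point_sets)):
            conf = ligand.conformers[ci] if ci < len(ligand.conformers) else None
            res = match(model, point_sets[ci], conf, check_ev=check_ev,
                        ligand_id=ligand.id, conformer_index=ci)
            if best is None or (res.matched, res.fit_score) > (best.matched, best.fit_score):
                best = res
        results.append(best)
    results.sort(key=lambda r: (not r.matched, -r.fit_score, r.ligand_id))
    return results, skipped
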