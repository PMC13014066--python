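"""Structure-based pharmacophore perception from a protein-ligand
(and optionally metal) complex.

Feature chemistry mirrors the interaction detection used for
occupancy analysis: hydrogen-bond donors/acceptors by distance+angle,
metal-binding by coordination distance, hydrophobic features at
centroids of contiguous apolar ligand fragments, and negative-
ionizable features on a small pattern list (carboxylate, tetrazole,
N-hydroxyurea N-OH, acylsulfonamide) that covers the ionizable
warheads of classic iron-chelating lipoxygenase inhibitors.
Excluded volumes are placed on protein heavy atoms in a shell around
the ligand, skipping atoms already engaged in a feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import EmptyInputError
from .occupancy import (
    InteractionKey,
    _POLAR,
    _is_apolar_carbon,
    _is_donor_capable,
    _neighbors,
    _resolve_ligand,
    _resolve_metal,
    donor_angle,
)
from .structure import AtomRecord, ResidueID, StructureModel, Superposition

FEATURE_PREFIX = {"METAL": "M", "HBD": "D", "HBA": "A", "HYD": "H", "NI": "NI"}
_HALOGENS = {"F", "CL", "BR", "I"}


@dataclass
class PerceptionConfig:
    """Geometric criteria and feature tolerances (Angstrom/degrees)."""

    d_hbond: float = 3.5
    theta_hbond: float = 120.0
    d_metal: float = 2.6
    d_hydrophobic: float = 4.5
    tol_polar: float = 1.5      # HBD / HBA / NI sphere radius
    tol_hyd: float = 1.5
    tol_metal: float = 1.0
    ev_radius: float = 1.2
    ev_shell: tuple[float, float] = (2.0, 5.0)
    min_fragment: int = 3


@dataclass
class Feature:
    """One typed pharmacophore feature."""

    label: str
    ftype: str                      # METAL | HBD | HBA | HYD | NI
    center: np.ndarray
    tolerance: float
    direction: np.ndarray | None = None
    projected_point: np.ndarray | None = None
    optional: bool = False
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)
        if self.direction is not None:
            self.direction = np.asarray(self.direction, float)
        if self.projected_point is not None:
            self.projected_point = np.asarray(self.projected_point, float)
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    def copy(self) -> "Feature":
        return Feature(self.label, self.ftype, self.center.copy(), self.tolerance,
                       None if self.direction is None else self.direction.copy(),
                       None if self.projected_point is None else self.projected_point.copy(),
                       self.optional, list(self.provenance))


@dataclass
class ExcludedVolume:
    center: np.ndarray
    radius: float
    source: tuple | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    def copy(self) -> "ExcludedVolume":
        return ExcludedVolume(self.center.copy(), self.radius, self.source)


@dataclass
class PharmacophoreModel:
    complex_id: str
    features: list[Feature] = field(default_factory=list)
    volumes: list[ExcludedVolume] = field(default_factory=list)
    note: str = ""

    def copy(self) -> "PharmacophoreModel":
        return PharmacophoreModel(self.complex_id,
                                  [f.copy() for f in self.features],
                                  [v.copy() for v in self.volumes], self.note)

    def required_features(self) -> list[Feature]:
        return [f for f in self.features if not f.optional]

    def transformed(self, sp: Superposition) -> "PharmacophoreModel":
        out = self.copy()
        for f in out.features:
            f.center = sp.apply(f.center)
            if f.direction is not None:
                f.direction = f.direction @ sp.rotation.T
            if f.projected_point is not None:
                f.projected_point = sp.apply(f.projected_point)
        for v in out.volumes:
            v.center = sp.apply(v.center)
        return out

    # JSON schema: {complex_id, note, features: [...], volumes: [...]}
    def to_json(self) -> str:
        def vec(x):
            return None if x is None else [float(v) for v in x]
        return json.dumps({
            "complex_id": self.complex_id,
            "note": self.note,
            "features": [{
                "label": f.label, "ftype": f.ftype,
                "center": vec(f.center), "tolerance": f.tolerance,
                "direction": vec(f.direction),
                "projected_point": vec(f.projected_point),
                "optional": f.optional,
                "provenance": [list(p) for p in f.provenance],
            } for f in self.features],
            "volumes": [{"center": vec(v.center), "radius": v.radius,
                         "source": list(v.source) if v.source else None}
                        for v in self.volumes],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PharmacophoreModel":
        d = json.loads(text)
        feats = [Feature(f["label"], f["ftype"], f["center"], f["tolerance"],
                         f.get("direction"), f.get("projected_point"),
                         f.get("optional", False),
                         [tuple(p) for p in f.get("provenance", [])])
                 for f in d["features"]]
        vols = [ExcludedVolume(v["center"], v["radius"],
                               tuple(v["source"]) if v.get("source") else None)
                for v in d.get("volumes", [])]
        return cls(d["complex_id"], feats, vols, d.get("note", ""))


# ---------------------------------------------------------------------------
# ligand-pattern detection on a distance-derived bond graph

def _heavy_neighbors(atoms, nbrs, i):
    return [j for j in nbrs[i] if atoms[j].element.upper() != "H"]


def _terminal_oxygens(atoms, nbrs, i):
    return [j for j in nbrs[i]
            if atoms[j].element.upper() == "O"
            and len(_heavy_neighbors(atoms, nbrs, j)) == 1]


def find_ni_groups(atoms: Sequence[AtomRecord], nbrs: list[list[int]],
                   indices: Sequence[int]) -> list[list[int]]:
    """Negative-ionizable groups among ``indices`` (ligand atoms):
    carboxylate, tetrazole, N-hydroxyurea N-OH, acylsulfonamide.
    Returns lists of member atom indices."""
    idx = set(indices)
    groups: list[list[int]] = []
    claimed: set[int] = set()

    def take(members):
        if not claimed & set(members):
            groups.append(sorted(members))
            claimed.update(members)

    for i in indices:
        el = atoms[i].element.upper()
        if el == "C":
            oxy = [j for j in _terminal_oxygens(atoms, nbrs, i) if j in idx]
            if len(oxy) >= 2:
                take([i] + oxy)          # carboxylate
        elif el == "N":
            term_o = [j for j in nbrs[i] if j in idx
                      and atoms[j].element.upper() == "O"
                      and len(_heavy_neighbors(atoms, nbrs, j)) == 1]
            carbonyl_c = [j for j in _heavy_neighbors(atoms, nbrs, i)
                          if atoms[j].element.upper() == "C"
                          and _terminal_oxygens(atoms, nbrs, j)]
            if term_o and carbonyl_c:
                take([i] + term_o)       # N-hydroxyurea / hydroxamate N-OH
        elif el == "S":
            oxy = [j for j in _terminal_oxygens(atoms, nbrs, i) if j in idx]
            amide_n = [j for j in _heavy_neighbors(atoms, nbrs, i)
                       if atoms[j].element.upper() == "N"
                       and any(atoms[k].element.upper() == "C"
                               and _terminal_oxygens(atoms, nbrs, k)
                               for k in _heavy_neighbors(atoms, nbrs, j))]
            if len(oxy) >= 2 and amide_n:
                take([i] + oxy + amide_n)   # acylsulfonamide
    # tetrazole: 5-cycles with >= 4 nitrogens
    for cyc in _five_cycles(nbrs, idx):
        if sum(1 for k in cyc if atoms[k].element.upper() == "N") >= 4:
            take(cyc)
    return groups


def _five_cycles(nbrs, idx):
    seen = set()
    out = []
    for a in idx:
        for b in nbrs[a]:
            if b not in idx:
                continue
            for c in nbrs[b]:
                if c not in idx or c == a:
                    continue
                for d in nbrs[c]:
                    if d not in idx or d in (a, b):
                        continue
                    for e in nbrs[d]:
                        if e not in idx or e in (a, b, c):
                            continue
                        if a in nbrs[e]:
                            key = frozenset((a, b, c, d, e))
                            if key not in seen:
                                seen.add(key)
                                out.append(sorted(key))
    return out


def apolar_fragments(atoms: Sequence[AtomRecord], nbrs: list[list[int]],
                     indices: Sequence[int], min_size: int = 3) -> list[list[int]]:
    """Connected components of apolar heavy atoms (C/S/halogen, with
    polar-attached carbons removed), at least ``min_size`` atoms."""
    ok = set()
    for i in indices:
        el = atoms[i].element.upper()
        if el in _HALOGENS or el == "S":
            ok.add(i)
        elif el == "C" and _is_apolar_carbon(atoms, nbrs, i):
            ok.add(i)
    comps: list[list[int]] = []
    left = set(ok)
    while left:
        stack = [left.pop()]
        comp = []
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in nbrs[i]:
                if j in left:
                    left.remove(j)
                    stack.append(j)
        if len(comp) >= min_size:
            comps.append(sorted(comp))
    return comps


# ---------------------------------------------------------------------------

def perceive(
    complex_model: StructureModel,
    ligand: ResidueID | str,
    metal=None,
    config: PerceptionConfig | None = None,
    complex_id: str = "complex",
) -> PharmacophoreModel:
    """Perceive a pharmacophore model from one complex.

    Emits one HBD/HBA feature per (ligand atom, protein partner
    residue) contact, one METAL feature per coordinating ligand atom,
    one HYD feature per qualifying apolar fragment and one NI feature
    per ionizable group; directional features store both the unit
    direction and the partner's position. Features are labelled
    deterministically (see :func:`label_features`).
    """
    cfg = config or PerceptionConfig()
    lig_atoms = _resolve_ligand(complex_model, ligand)
    if not lig_atoms:
        raise EmptyInputError("ligand selection matched no atoms")
    met = _resolve_metal(complex_model, metal)
    lig_ids = {id(a) for a in lig_atoms}
    met_id = id(met) if met is not None else None
    env = [a for a in complex_model.atoms
           if id(a) not in lig_ids and id(a) is not met_id
           and a.resname not in ("HOH", "WAT")]
    all_atoms = list(lig_atoms) + env
    nbrs = _neighbors(all_atoms)
    n_lig = len(lig_atoms)
    lig_idx = list(range(n_lig))
    env_heavy = [(n_lig + i, a) for i, a in enumerate(env)
                 if a.element.upper() != "H"]

    features: list[Feature] = []
    engaged: set[int] = set()   # indices (into all_atoms) of partner atoms

    for li in lig_idx:
        la = all_atoms[li]
        el = la.element.upper()
        if el == "H":
            continue
        # hydrogen bonds -> HBD / HBA; collapse to one partner per residue
        hbd_best: dict[ResidueID, tuple[float, int]] = {}
        hba_best: dict[ResidueID, tuple[float, int]] = {}
        for ei, ea in env_heavy:
            if ea.element.upper() not in _POLAR or el not in _POLAR:
                continue
            d = float(np.linalg.norm(la.xyz - ea.xyz))
            if d > cfg.d_hbond:
                continue
            if _is_donor_capable(all_atoms, nbrs, li):
                ang = donor_angle(all_atoms, nbrs, li, ea.xyz)
                if ang is not None and ang >= cfg.theta_hbond:
                    cur = hbd_best.get(ea.residue_id)
                    if cur is None or d < cur[0]:
                        hbd_best[ea.residue_id] = (d, ei)
            if _is_donor_capable(all_atoms, nbrs, ei):
                ang = donor_angle(all_atoms, nbrs, ei, la.xyz)
                if ang is not None and ang >= cfg.theta_hbond:
                    cur = hba_best.get(ea.residue_id)
                    if cur is None or d < cur[0]:
                        hba_best[ea.residue_id] = (d, ei)
        for ftype, best in (("HBD", hbd_best), ("HBA", hba_best)):
            for rid, (_d, ei) in best.items():
                partner = all_atoms[ei]
                vec = partner.xyz - la.xyz
                features.append(Feature(
                    label="", ftype=ftype, center=la.xyz.copy(),
                    tolerance=cfg.tol_polar,
                    direction=vec / np.linalg.norm(vec),
                    projected_point=partner.xyz.copy(),
                    provenance=[rid]))
                engaged.add(ei)
        # metal coordination
        if met is not None and el in _POLAR:
            d = float(np.linalg.norm(la.xyz - met.xyz))
            if d <= cfg.d_metal:
                vec = met.xyz - la.xyz
                features.append(Feature(
                    label="", ftype="METAL", center=la.xyz.copy(),
                    tolerance=cfg.tol_metal,
                    direction=vec / np.linalg.norm(vec),
                    projected_point=met.xyz.copy(),
                    provenance=[met.residue_id]))

    # hydrophobic fragments
    for comp in apolar_fragments(all_atoms, nbrs, lig_idx, cfg.min_fragment):
        coords = np.array([all_atoms[i].xyz for i in comp])
        partners = []
        for ei, ea in env_heavy:
            if not _is_apolar_carbon(all_atoms, nbrs, ei):
                continue
            dmin = float(np.min(np.linalg.norm(coords - ea.xyz, axis=1)))
            if dmin <= cfg.d_hydrophobic:
                partners.append(ei)
        if partners:
            rids = sorted({all_atoms[ei].residue_id for ei in partners})
            features.append(Feature(
                label="", ftype="HYD", center=coords.mean(axis=0),
                tolerance=cfg.tol_hyd, provenance=rids))
            engaged.update(partners)

    # negative-ionizable groups
    for grp in find_ni_groups(all_atoms, nbrs, lig_idx):
        coords = np.array([all_atoms[i].xyz for i in grp
                           if all_atoms[i].element.upper() != "H"])
        features.append(Feature(label="", ftype="NI",
                                center=coords.mean(axis=0),
                                tolerance=cfg.tol_polar))

    # excluded volumes: protein heavy atoms in the ligand shell,
    # skipping atoms already engaged as feature partners
    lig_xyz = np.array([all_atoms[i].xyz for i in lig_idx
                        if all_atoms[i].element.upper() != "H"])
    volumes: list[ExcludedVolume] = []
    for ei, ea in env_heavy:
        if ei in engaged or (met is not None and id(ea) == id(met)):
            continue
        dmin = float(np.min(np.linalg.norm(lig_xyz - ea.xyz, axis=1)))
        if cfg.ev_shell[0] <= dmin <= cfg.ev_shell[1]:
            volumes.append(ExcludedVolume(ea.xyz.copy(), cfg.ev_radius,
                                          (ea.chain_id, ea.resseq, ea.name)))

    model = PharmacophoreModel(complex_id=complex_id, features=features,
                               volumes=volumes)
    return label_features(model)


def label_features(model: PharmacophoreModel) -> PharmacophoreModel:
    """Assign deterministic per-type labels (M1, D1, D2, ...).

    Within a type, features are numbered by distance of their center
    to the metal anchor (the projected point of the first METAL
    feature; origin when no metal), then by coordinates
    lexicographically. Idempotent and independent of input order.
    """
    out = model.copy()
    metal_pos = np.zeros(3)
    metal_feats = [f for f in out.features if f.ftype == "METAL"]
    if metal_feats:
        anchor = min(metal_feats, key=lambda f: tuple(np.round(f.center, 6)))
        metal_pos = (anchor.projected_point if anchor.projected_point is not None
                     else anchor.center)

    def sort_key(f: Feature):
        return (round(float(np.linalg.norm(f.center - metal_pos)), 6),
                tuple(np.round(f.center, 6)))

    counters: dict[str, int] = {}
    for f in sorted(out.features, key=lambda f: (f.ftype, sort_key(f))):
        counters[f.ftype] = counters.get(f.ftype, 0) + 1
        f.label = f"{FEATURE_PREFIX[f.ftype]}{counters[f.ftype]}"
    out.features.sort(key=lambda f: (f.ftype, sort_key(f)))
    return out
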