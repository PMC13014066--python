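"""Synthetic fixtures with planted ground truth.

Every generator is a pure function of its parameters and seed, and
plants geometry with a margin of at least 0.2 A away from every
detection cutoff so boundary conventions never matter. Pseudo-ligands
are minimal atom scaffolds carrying the required chemistry (a
hydroxyl for donor/metal sites, an ether oxygen for acceptors, a
propyl fragment for hydrophobics, a carboxylate for the negative-
ionizable pattern) rather than drug-like molecules: planted truth is
geometric, not chemical.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .perceive import PharmacophoreModel
from .screen import Conformer, LigandPoint, LigandRecord
from .occupancy import Ensemble
from .structure import AtomRecord, ResidueID, StructureModel

_AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# ideal backbone geometry (A / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O, _A_N_CA_CB = 111.2, 116.2, 121.7, 120.8, 110.5

_TOPOLOGY_PHIPSI = {"helix": (-60.0, -45.0), "strand": (-120.0, 120.0)}
_COIL_CHOICES = [(-60.0, -45.0), (-120.0, 120.0), (-75.0, 150.0), (-90.0, 0.0)]


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = bond, angle(b,c,d) =
    angle and dihedral(a,b,c,d) = torsion (degrees)."""
    ang, tor = np.radians(angle), np.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(ang),
                  bond * np.sin(ang) * np.cos(tor),
                  -bond * np.sin(ang) * np.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def make_toy_protein(
    n_res: int,
    topology: str = "helix",
    seed: int = 0,
    sequence: str | None = None,
    chain_id: str = "A",
    start_resseq: int = 1,
) -> StructureModel:
    """Ideal-geometry backbone (N, CA, C, O + CB) built from torsions.

    topology 'helix' uses phi/psi = (-60, -45), 'strand' (-120, 120),
    'coil' draws per-residue angles from a small allowed-region set
    using the seed.
    """
    if n_res < 5:
        raise ValueError("n_res must be >= 5")
    if sequence is not None and len(sequence) != n_res:
        raise ValueError("sequence length must equal n_res")
    rng = np.random.default_rng(seed)
    if topology in _TOPOLOGY_PHIPSI:
        phipsi = [_TOPOLOGY_PHIPSI[topology]] * n_res
    elif topology == "coil":
        phipsi = [_COIL_CHOICES[k] for k in rng.integers(0, len(_COIL_CHOICES), n_res)]
    else:
        raise ValueError(f"unknown topology {topology!r}")

    ns, cas, cs = [], [], []
    n0 = np.zeros(3)
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    th = np.radians(180.0 - _A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([np.cos(th), np.sin(th), 0.0])
    ns.append(n0), cas.append(ca0), cs.append(c0)
    for i in range(1, n_res):
        psi_prev = phipsi[i - 1][1]
        n = place_atom(ns[-1], cas[-1], cs[-1], _B_C_N, _A_CA_C_N, psi_prev)
        ca = place_atom(cas[-1], cs[-1], n, _B_N_CA, _A_C_N_CA, 180.0)
        c = place_atom(cs[-1], n, ca, _B_CA_C, _A_N_CA_C, phipsi[i][0])
        ns.append(n), cas.append(ca), cs.append(c)

    atoms: list[AtomRecord] = []
    serial = itertools.count(1)
    for i in range(n_res):
        resname = _AA1TO3.get(sequence[i], "ALA") if sequence else "ALA"
        o = place_atom(ns[i], cas[i], cs[i], _B_C_O, _A_CA_C_O,
                       phipsi[i][1] + 180.0)
        res_atoms = [("N", "N", ns[i]), ("CA", "C", cas[i]),
                     ("C", "C", cs[i]), ("O", "O", o)]
        if resname != "GLY":
            cb = place_atom(cs[i], ns[i], cas[i], _B_CA_CB, _A_N_CA_CB, -122.0)
            res_atoms.append(("CB", "C", cb))
        for name, element, xyz in res_atoms:
            atoms.append(AtomRecord(next(serial), name, element, "", resname,
                                    chain_id, start_resseq + i, "", xyz.copy()))
    return StructureModel(model_id=1, atoms=atoms)


def make_gapped_pair(
    structure: StructureModel,
    gap_ranges: Sequence[tuple[int, int]],
    perturb_donor: float = 0.0,
    seed: int = 0,
    anchor_pad: int = 4,
    allow_terminal: bool = False,
) -> tuple[StructureModel, StructureModel, StructureModel]:
    """(acceptor with deletions, donor copy, pristine truth).

    The acceptor lacks all residues inside the gap ranges; the donor
    is a complete copy, optionally jittered (Gaussian sigma
    ``perturb_donor`` A) outside the anchor neighbourhoods
    (``anchor_pad`` residues around each gap). Terminal gaps are
    rejected unless ``allow_terminal``.
    """
    chain = structure.chains()[0]
    nums = sorted(rid[1] for rid in structure.chain_residue_ids(chain))
    gaps = sorted(tuple(g) for g in gap_ranges)
    for (a0, a1), (b0, b1) in zip(gaps, gaps[1:]):
        if b0 <= a1:
            raise ValueError("overlapping gap ranges")
    for g0, g1 in gaps:
        if g0 > g1 or g0 < nums[0] or g1 > nums[-1]:
            raise ValueError(f"gap {g0}-{g1} outside chain {nums[0]}-{nums[-1]}")
        if not allow_terminal and (g0 == nums[0] or g1 == nums[-1]):
            raise ValueError(f"terminal gap {g0}-{g1} rejected")

    truth = structure.copy()
    acceptor_atoms = [a.copy() for a in structure.atoms
                      if not any(g0 <= a.resseq <= g1 for g0, g1 in gaps)
                      or a.chain_id != chain]
    acceptor = StructureModel(structure.model_id, acceptor_atoms)
    donor = structure.copy()
    if perturb_donor > 0:
        rng = np.random.default_rng(seed)
        protected = set()
        for g0, g1 in gaps:
            protected.update(range(g0 - anchor_pad, g1 + anchor_pad + 1))
        for a in donor.atoms:
            if a.chain_id == chain and a.resseq not in protected:
                a.xyz = a.xyz + rng.normal(0.0, perturb_donor, 3)
    return acceptor, donor, truth


# ---------------------------------------------------------------------------
# planted complexes

def _hbond_hydrogen(donor: np.ndarray, acceptor: np.ndarray, angle: float) -> np.ndarray:
    """Place H at 0.97 A from the donor so the D-H...A angle equals
    ``angle`` degrees (acceptor assumed along +z from donor)."""
    d = float(np.linalg.norm(acceptor - donor))
    u = (acceptor - donor) / d
    # perpendicular to u
    ref = np.array([1.0, 0.0, 0.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)

    def f(alpha: float) -> float:
        h = donor + 0.97 * (np.cos(alpha) * u + np.sin(alpha) * v)
        v1, v2 = donor - h, acceptor - h
        cosv = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return float(np.degrees(np.arccos(np.clip(cosv, -1, 1)))) - angle

    if abs(f(0.0)) < 1e-9:
        return donor + 0.97 * u
    alpha = brentq(f, 1e-6, np.radians(120.0))
    return donor + 0.97 * (np.cos(alpha) * u + np.sin(alpha) * v)


def make_planted_complex(
    layout: Sequence[dict],
    seed: int = 0,
    spacing: float = 12.0,
) -> tuple[StructureModel, list[dict]]:
    """Toy pocket + pseudo-ligand realizing a list of interactions.

    Each layout entry is {'ftype': 'METAL'|'HBD'|'HBA'|'HYD'|'NI',
    optional 'distance', optional 'angle'}. Sites are placed
    ``spacing`` A apart so interactions cannot cross-talk. Returns the
    complex and the planted truth: one dict per entry with the
    expected feature type, center and partner residue.
    """
    if not layout:
        raise ValueError("layout must be non-empty")
    defaults = {"METAL": (2.2, None), "HBD": (2.9, 160.0),
                "HBA": (2.9, 160.0), "HYD": (4.0, None), "NI": (None, None)}
    atoms: list[AtomRecord] = []
    truth: list[dict] = []
    serial = itertools.count(1)
    lig_res = ("L", 900, "")

    def add(name, element, resname, chain, resseq, xyz, het):
        atoms.append(AtomRecord(next(serial), name, element, "", resname,
                                chain, resseq, "", np.asarray(xyz, float), 1.0, het))

    def add_backbone_stub(resseq, base, direction):
        """Minimal GLY backbone trailing away from ``base``."""
        u = np.asarray(direction, float)
        u = u / np.linalg.norm(u)
        v = np.array([0.57, 0.57, 0.59])
        v = v - (v @ u) * u
        v /= np.linalg.norm(v)
        ca = base + 1.52 * u
        n = ca + 1.46 * (0.7 * u + 0.714 * v)
        c = base
        add("N", "N", "GLY", "P", resseq, n, False)
        add("CA", "C", "GLY", "P", resseq, ca, False)
        return n, ca, c

    for i, entry in enumerate(layout):
        ftype = entry["ftype"]
        if ftype not in defaults:
            raise ValueError(f"unknown feature type {ftype!r}")
        dist = entry.get("distance", defaults[ftype][0])
        angle = entry.get("angle", defaults[ftype][1])
        if dist is not None and dist <= 0:
            raise ValueError("interaction distance must be positive")
        if angle is not None and not (0 < angle <= 180):
            raise ValueError("interaction angle must be in (0, 180]")
        c = np.array([spacing * i, 0.0, 0.0])
        resseq = 10 + i
        label = f"{ftype}{i}"

        if ftype == "METAL":
            fe = c + np.array([0.0, 0.0, dist])
            o = c
            add("FE", "FE", "FE", "L", 901 + i, fe, True)
            add(f"O{i}", "O", "LIG", *lig_res[:2], o, True)
            add(f"H{i}", "H", "LIG", *lig_res[:2], o + np.array([0, 0.97, 0]), True)
            add(f"C{i}A", "C", "LIG", *lig_res[:2], o + np.array([1.43, 0, 0]), True)
            truth.append({"label": label, "ftype": "METAL", "center": o.copy(),
                          "partner": ("L", 901 + i, ""), "ligand_atom": f"O{i}",
                          "partner_atoms": [("L", 901 + i, "", "FE")]})
        elif ftype == "HBD":
            o = c
            a_pos = c + np.array([0.0, 0.0, dist])
            h = _hbond_hydrogen(o, a_pos, angle)
            add(f"O{i}", "O", "LIG", *lig_res[:2], o, True)
            add(f"H{i}", "H", "LIG", *lig_res[:2], h, True)
            add(f"C{i}A", "C", "LIG", *lig_res[:2], o + np.array([-1.43, 0, 0]), True)
            # protein acceptor: carbonyl O of a GLY stub
            cpos = a_pos + np.array([0.0, 1.23, 0.0])
            add("O", "O", "GLY", "P", resseq, a_pos, False)
            add_backbone_stub(resseq, cpos, np.array([0.0, 1.0, 0.3]))
            add("C", "C", "GLY", "P", resseq, cpos, False)
            truth.append({"label": label, "ftype": "HBD", "center": o.copy(),
                          "partner": ("P", resseq, ""), "ligand_atom": f"O{i}",
                          "partner_atoms": [("P", resseq, "", nm)
                                            for nm in ("O", "N", "CA", "C")]})
        elif ftype == "HBA":
            o = c
            add(f"O{i}", "O", "LIG", *lig_res[:2], o, True)
            add(f"C{i}A", "C", "LIG", *lig_res[:2],
                o + 1.43 * np.array([-0.76, 0.65, 0.0]), True)
            add(f"C{i}B", "C", "LIG", *lig_res[:2],
                o + 1.43 * np.array([0.76, 0.65, 0.0]), True)
            npos = c + np.array([0.0, 0.0, dist])
            h = _hbond_hydrogen(npos, o, angle)
            add("N", "N", "GLY", "P", resseq, npos, False)
            add("H", "H", "GLY", "P", resseq, h, False)
            ca = npos + np.array([0.0, 1.46, 0.0])
            add("CA", "C", "GLY", "P", resseq, ca, False)
            add("C", "C", "GLY", "P", resseq, ca + np.array([0.0, 1.52, 0.0]), False)
            add("O", "O", "GLY", "P", resseq, ca + np.array([0.0, 2.75, 0.0]), False)
            truth.append({"label": label, "ftype": "HBA", "center": o.copy(),
                          "partner": ("P", resseq, ""), "ligand_atom": f"O{i}",
                          "partner_atoms": [("P", resseq, "", nm)
                                            for nm in ("N", "H", "CA", "C", "O")]})
        elif ftype == "HYD":
            carbons = [c + np.array([0.0, 1.5 * k, 0.0]) for k in (-1, 0, 1)]
            for k, pos in enumerate(carbons):
                add(f"C{i}{'XYZ'[k]}", "C", "LIG", *lig_res[:2], pos, True)
            cb = c + np.array([0.0, 0.0, dist])
            ca = cb + np.array([0.0, 0.0, 1.53])
            add("CB", "C", "ALA", "P", resseq, cb, False)
            add("CA", "C", "ALA", "P", resseq, ca, False)
            add("N", "N", "ALA", "P", resseq, ca + np.array([1.46, 0, 0]), False)
            add("C", "C", "ALA", "P", resseq, ca + np.array([-1.05, 0, 1.1]), False)
            add("O", "O", "ALA", "P", resseq,
                ca + np.array([-1.05, 0, 2.33]), False)
            truth.append({"label": label, "ftype": "HYD", "center": c.copy(),
                          "partner": ("P", resseq, ""),
                          "ligand_atom": f"C{i}Y",
                          "partner_atoms": [("P", resseq, "", nm)
                                            for nm in ("CB", "CA", "N", "C", "O")]})
        elif ftype == "NI":
            c0 = c
            o1 = c + 1.25 * np.array([0.866, 0.0, 0.5])
            o2 = c + 1.25 * np.array([-0.866, 0.0, 0.5])
            anchor = c + np.array([0.0, 0.0, -1.5])
            add(f"C{i}", "C", "LIG", *lig_res[:2], c0, True)
            add(f"O{i}A", "O", "LIG", *lig_res[:2], o1, True)
            add(f"O{i}B", "O", "LIG", *lig_res[:2], o2, True)
            add(f"C{i}A", "C", "LIG", *lig_res[:2], anchor, True)
            truth.append({"label": label, "ftype": "NI",
                          "center": np.mean([c0, o1, o2], axis=0),
                          "partner": None, "ligand_atom": f"O{i}A",
                          "partner_atoms": []})
    return StructureModel(model_id=1, atoms=atoms), truth


def make_ensemble(
    complex_model: StructureModel,
    truth: Sequence[dict],
    occupancy_spec: dict[str, float],
    n_frames: int,
    seed: int = 0,
    break_shift: float = 8.0,
) -> Ensemble:
    """Frame ensemble in which each planted interaction holds in
    round(fraction * n_frames) frames.

    Contacts are broken by translating the partner residue (or metal)
    away along the interaction axis; unlisted interactions persist in
    every frame. Frame membership is shuffled by seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    by_label = {t["label"]: t for t in truth}
    partners_seen: set = set()
    for label, frac in occupancy_spec.items():
        if label not in by_label:
            raise ValueError(f"unknown interaction label {label!r}")
        if not (0.0 <= frac <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        p = by_label[label]["partner"]
        if p in partners_seen:
            raise ValueError(f"conflicting spec: partner {p} shared")
        partners_seen.add(p)
        if not by_label[label]["partner_atoms"]:
            raise ValueError(f"interaction {label!r} has no movable partner")

    rng = np.random.default_rng(seed)
    schedules: dict[str, np.ndarray] = {}
    for label, frac in occupancy_spec.items():
        n_on = int(round(frac * n_frames))
        on = np.zeros(n_frames, bool)
        on[rng.permutation(n_frames)[:n_on]] = True
        schedules[label] = on

    frames: list[StructureModel] = []
    for j in range(n_frames):
        frame = complex_model.copy()
        for label, on in schedules.items():
            if on[j]:
                continue
            t = by_label[label]
            axis = np.zeros(3)
            pa = t["partner_atoms"][0]
            ref = frame.atom(pa[:3], pa[3])
            axis = ref.xyz - np.asarray(t["center"], float)
            nrm = np.linalg.norm(axis)
            axis = axis / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
            move = {(c, r, ic, nm) for (c, r, ic, nm) in t["partner_atoms"]}
            for a in frame.atoms:
                if (a.chain_id, a.resseq, a.icode, a.name) in move:
                    a.xyz = a.xyz + break_shift * axis
        frames.append(frame)

    metal = None
    for a in complex_model.atoms:
        if a.element.upper() == "FE":
            metal = (a.residue_id, a.name)
            break
    return Ensemble(frames=frames, ligand=("L", 900, ""), metal=metal)


# ---------------------------------------------------------------------------
# screening sets and decoy pools

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def make_screen_set(
    model: PharmacophoreModel,
    n_actives: int = 11,
    n_decoys: int = 500,
    seed: int = 0,
    jitter: float = 0.3,
) -> list[LigandRecord]:
    """Labelled pseudo-ligand library with known match status.

    Actives carry one feature point per model feature, jittered
    within half the feature tolerance and posed under a random rigid
    motion. Decoys are sabotaged actives: a required feature type
    removed entirely, a required-type point displaced far beyond
    tolerance, or an atom planted inside an excluded volume (when the
    model has volumes).
    """
    req = model.required_features()
    if len(req) < 3:
        raise ValueError("model needs >= 3 required features")
    rng = np.random.default_rng(seed)
    req_types = sorted({f.ftype for f in req})
    modes = ["drop", "displace"] + (["ev"] if model.volumes else [])

    def base_points() -> list[LigandPoint]:
        pts = []
        for f in model.features:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = rng.uniform(0.0, min(jitter, 0.45 * f.tolerance))
            pts.append(LigandPoint(f.ftype, f.center + r * u))
        return pts

    def posed(pts: list[LigandPoint], extra_atoms: list[np.ndarray]) -> tuple:
        rot = _random_rotation(rng)
        trans = rng.uniform(-20.0, 20.0, 3)
        new_pts = [LigandPoint(p.ftype, p.center @ rot.T + trans) for p in pts]
        atom_xyz = [p.center @ rot.T + trans for p in pts]
        atom_xyz += [x @ rot.T + trans for x in extra_atoms]
        conf = Conformer(["C"] * len(atom_xyz), np.array(atom_xyz))
        return new_pts, conf

    records: list[LigandRecord] = []
    for i in range(n_actives):
        pts, conf = posed(base_points(), [])
        records.append(LigandRecord(
            id=f"ACT{i:03d}", label="active", conformers=[conf],
            properties={"mw": 12.0 * len(conf.elements), "logp": 0.0,
                        "hbd": 0, "hba": 0, "charge": 0},
            feature_points=[pts]))
    for i in range(n_decoys):
        mode = modes[int(rng.integers(0, len(modes)))]
        pts = base_points()
        extra: list[np.ndarray] = []
        if mode == "drop":
            bad = req_types[int(rng.integers(0, len(req_types)))]
            pts = [p for p in pts if p.ftype != bad]
        elif mode == "displace":
            # collapse every point of the chosen required type onto one
            # far location: a single far point cannot reach its feature
            # while the remaining features pin the frame, and coincident
            # points cannot satisfy two separated features of one type
            bad = req_types[int(rng.integers(0, len(req_types)))]
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            loc = np.mean([f.center for f in model.features], axis=0) + 15.0 * u
            for k, p in enumerate(pts):
                if p.ftype == bad:
                    pts[k] = LigandPoint(p.ftype, loc + rng.normal(0.0, 0.05, 3))
        else:  # ev
            # exact required-feature points only: the canonical
            # assignment is then the single feasible one and its fit is
            # recovered exactly, pinning the planted atom inside the
            # volume; jittered or surplus points would admit poses that
            # slip the atom out
            pts = [LigandPoint(f.ftype, f.center.copy())
                   for f in model.features if not f.optional]
            vol = model.volumes[int(rng.integers(0, len(model.volumes)))]
            extra.append(vol.center.copy())
        pts, conf = posed(pts, extra)
        records.append(LigandRecord(
            id=f"DEC{i:03d}", label="decoy", conformers=[conf],
            properties={"mw": 12.0 * len(conf.elements), "logp": 0.0,
                        "hbd": 0, "hba": 0, "charge": 0,
                        "decoy_mode": mode},
            feature_points=[pts]))
    return records


_POOL_CHAINS = ["C" * k for k in range(1, 9)]
_POOL_SUFFIXES = ["", "O", "N", "C(=O)O", "C(=O)N", "c1ccccc1",
                  "c1ccc(O)cc1", "C(=O)[O-]", "OC", "c1ccncc1"]


def make_decoy_pool(n: int, seed: int = 0) -> list[LigandRecord]:
    """Deterministic pool of small-molecule SMILES with RDKit-computed
    properties, for decoy-selection tests."""
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    smiles = [chain + suf for chain in _POOL_CHAINS for suf in _POOL_SUFFIXES]
    smiles = smiles[:n] if n <= len(smiles) else smiles
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(smiles))
    pool = []
    for k in order:
        smi = smiles[k]
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        pool.append(LigandRecord(
            id=f"POOL{k:03d}", smiles=smi,
            properties={"mw": Descriptors.MolWt(mol),
                        "logp": Descriptors.MolLogP(mol),
                        "hbd": Descriptors.NumHDonors(mol),
                        "hba": Descriptors.NumHAcceptors(mol),
                        "charge": Chem.GetFormalCharge(mol)}))
    return pool
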