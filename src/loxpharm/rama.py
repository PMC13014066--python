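"""Backbone dihedral analysis and Ramachandran classification.

The region maps are deliberately coarse: unions of rectangular
phi/psi boxes per residue class (general, glycine, proline,
pre-proline), with the allowed region obtained by dilating the
favored boxes plus a few extra allowed areas. They capture the
standard favored/allowed/outlier structure of the Ramachandran
diagram but are an approximation, not a re-derivation of any
program's density-based tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structure import StructureModel, ResidueID

#: chain-break threshold on the peptide C-N distance, Angstrom
PEPTIDE_BOND_MAX = 2.0

# boxes: (phi_min, phi_max, psi_min, psi_max), degrees
_REGIONS: dict[str, dict] = {
    "general": {
        "favored": [(-180, -45, 90, 180), (-180, -45, -180, -150),
                    (-160, -45, -75, -5)],
        "allowed_extra": [(30, 100, -25, 60)],   # left-handed helix
        "margin": 20.0,
    },
    "glycine": {
        "favored": [(-180, -45, 90, 180), (-180, -45, -180, -150),
                    (-160, -45, -75, -5), (45, 100, -10, 60),
                    (45, 180, -180, -90), (45, 180, 150, 180)],
        "allowed_extra": [],
        "margin": 25.0,
    },
    "proline": {
        "favored": [(-110, -40, 100, 180), (-110, -40, -60, 0)],
        "allowed_extra": [],
        "margin": 20.0,
    },
    "pre-proline": {
        "favored": [(-180, -45, 90, 180), (-180, -45, -180, -150),
                    (-160, -45, -75, -5)],
        "allowed_extra": [(30, 100, -25, 60)],
        "margin": 20.0,
    },
}


@dataclass
class RamaResult:
    """Per-residue Ramachandran classification plus region fractions."""

    records: list[dict] = field(default_factory=list)
    fractions: dict[str, float] = field(default_factory=dict)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = np.degrees(np.arctan2(y, x))
    return float(ang) if ang > -180.0 else 180.0


def backbone_dihedrals(model: StructureModel) -> list[tuple[ResidueID, float | None, float | None]]:
    """Phi/psi per residue, per chain; None at chain breaks/termini.

    Residues missing a backbone atom are skipped with a warning.
    Consecutive residues count as bonded only when C-N < 2 A.
    """
    out: list[tuple[ResidueID, float | None, float | None]] = []
    for chain_id in model.chains():
        res = model.polymer_residues(chain_id)
        rids = list(res)
        bb: list[dict | None] = []
        for rid in rids:
            names = {a.name: a.xyz for a in res[rid]}
            if not {"N", "CA", "C"} <= names.keys():
                warnings.warn(f"residue {rid} missing backbone atoms; skipped",
                              stacklevel=2)
                bb.append(None)
            else:
                bb.append(names)
        for i, rid in enumerate(rids):
            cur = bb[i]
            if cur is None:
                continue
            prev = bb[i - 1] if i > 0 else None
            nxt = bb[i + 1] if i < len(rids) - 1 else None
            phi = psi = None
            if prev is not None and np.linalg.norm(cur["N"] - prev["C"]) < PEPTIDE_BOND_MAX:
                phi = dihedral(prev["C"], cur["N"], cur["CA"], cur["C"])
            if nxt is not None and np.linalg.norm(nxt["N"] - cur["C"]) < PEPTIDE_BOND_MAX:
                psi = dihedral(cur["N"], cur["CA"], cur["C"], nxt["N"])
            out.append((rid, phi, psi))
    return out


def _in_boxes(phi: float, psi: float, boxes, margin: float = 0.0) -> bool:
    for (p0, p1, q0, q1) in boxes:
        for dphi in (-360.0, 0.0, 360.0):
            for dpsi in (-360.0, 0.0, 360.0):
                if (p0 - margin <= phi + dphi <= p1 + margin
                        and q0 - margin <= psi + dpsi <= q1 + margin):
                    return True
    return False


def residue_class(resname: str, next_resname: str | None) -> str:
    if resname == "GLY":
        return "glycine"
    if resname == "PRO":
        return "proline"
    if next_resname == "PRO":
        return "pre-proline"
    return "general"


def classify_point(phi: float, psi: float, res_class: str = "general") -> str:
    """favored / allowed / outlier for one (phi, psi) point."""
    spec = _REGIONS[res_class]
    if _in_boxes(phi, psi, spec["favored"]):
        return "favored"
    if (_in_boxes(phi, psi, spec["favored"], spec["margin"])
            or _in_boxes(phi, psi, spec["allowed_extra"], spec["margin"])):
        return "allowed"
    return "outlier"


def rama_classify(model: StructureModel) -> RamaResult:
    """Classify every residue with defined phi and psi.

    Chain-terminal residues (or those at breaks) are unclassified and
    excluded from the summary fractions.
    """
    res = model.residues()
    resname = {rid: atoms[0].resname for rid, atoms in res.items()}
    dihedrals = backbone_dihedrals(model)
    next_name: dict[ResidueID, str | None] = {}
    for chain_id in model.chains():
        rids = model.chain_residue_ids(chain_id)
        for i, rid in enumerate(rids):
            next_name[rid] = resname[rids[i + 1]] if i + 1 < len(rids) else None

    records = []
    counts = {"favored": 0, "allowed": 0, "outlier": 0}
    for rid, phi, psi in dihedrals:
        rec = {"residue": rid, "resname": resname[rid], "phi": phi, "psi": psi,
               "class": residue_class(resname[rid], next_name.get(rid)),
               "region": None}
        if phi is not None and psi is not None:
            rec["region"] = classify_point(phi, psi, rec["class"])
            counts[rec["region"]] += 1
        records.append(rec)
    total = sum(counts.values())
    fractions = {k: (v / total if total else 0.0) for k, v in counts.items()}
    return RamaResult(records=records, fractions=fractions)
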