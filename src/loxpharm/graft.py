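"""Reconstruction of unresolved chain segments by grafting from
superposed donor structures.

A gap is a run of residues present in the full construct sequence but
absent from the model. Replacement segments are copied from a donor
that has been superposed onto the target frame; the copied span is
delimited by anchor windows — short stretches flanking the gap where
target and donor backbones overlap best — and the donor segment is
rigidly refitted onto the target anchors before insertion. Junction
geometry and steric clashes are then checked against standard
stereochemical ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import AnchorFailureError, ConsistencyError, IncompleteDonorError
from .structure import (
    BACKBONE_ATOMS,
    AtomRecord,
    StructureModel,
    kabsch,
)

#: Bondi van der Waals radii (A); metals get a generic 2.0
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
_VDW_DEFAULT = 2.0


@dataclass
class GapSpec:
    """One missing region of a chain, plus the donor decision."""

    chain_id: str
    first_missing: int
    last_missing: int
    donor_id: str | None = None
    donor_segment: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.first_missing > self.last_missing:
            raise ValueError("first_missing must be <= last_missing")


@dataclass
class GraftPlanEntry:
    gap: GapSpec
    anchor_pre: tuple[int, int]   # (start, end) resseq window, inclusive
    anchor_post: tuple[int, int]
    window_length: int


@dataclass
class GraftPlan:
    entries: list[GraftPlanEntry] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps([asdict(e) for e in self.entries], indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GraftPlan":
        entries = []
        for d in json.loads(text):
            g = d["gap"]
            entries.append(GraftPlanEntry(
                gap=GapSpec(g["chain_id"], g["first_missing"], g["last_missing"],
                            g.get("donor_id"),
                            tuple(g["donor_segment"]) if g.get("donor_segment") else None),
                anchor_pre=tuple(d["anchor_pre"]),
                anchor_post=tuple(d["anchor_post"]),
                window_length=d["window_length"],
            ))
        return cls(entries)


@dataclass
class JunctionReport:
    junctions: list[dict]
    clashes: list[dict]

    @property
    def n_pass(self) -> int:
        return sum(1 for j in self.junctions if j["ok"])

    @property
    def n_fail(self) -> int:
        return len(self.junctions) - self.n_pass

    @property
    def all_pass(self) -> bool:
        return self.n_fail == 0

    def to_json(self) -> str:
        return json.dumps(
            {"junctions": self.junctions, "clashes": self.clashes,
             "n_pass": self.n_pass, "n_fail": self.n_fail,
             "n_clashes": len(self.clashes)}, indent=1)


# ---------------------------------------------------------------------------

def find_missing_regions(
    model: StructureModel,
    full_sequence: str,
    start_resseq: int = 1,
    chain_id: str | None = None,
) -> list[GapSpec]:
    """Report every full-construct position absent from the model.

    ``full_sequence`` is the one-letter construct sequence beginning at
    author number ``start_resseq``. Observed residues must agree with
    the sequence letter at their position. Gaps (runs of absent
    numbers, including chain termini) are returned sorted.
    """
    if chain_id is None:
        chain_id = model.chains()[0]
    present: dict[int, str] = {}
    for (ch, num, icode), atoms in model.polymer_residues(chain_id).items():
        present[num] = atoms[0].resname
    span = range(start_resseq, start_resseq + len(full_sequence))
    from .structure import _AA3TO1
    for num, resname in present.items():
        if num not in span:
            raise ConsistencyError(
                f"residue {num} outside construct span "
                f"{span.start}..{span.stop - 1}")
        expected = full_sequence[num - start_resseq]
        got = _AA3TO1.get(resname, "X")
        if expected != "X" and got != "X" and got != expected:
            raise ConsistencyError(
                f"residue {num} is {got}, construct says {expected}")
    gaps: list[GapSpec] = []
    run_start: int | None = None
    for num in span:
        if num not in present:
            if run_start is None:
                run_start = num
        elif run_start is not None:
            gaps.append(GapSpec(chain_id, run_start, num - 1))
            run_start = None
    if run_start is not None:
        gaps.append(GapSpec(chain_id, run_start, span.stop - 1))
    return gaps


def _window_coords(model: StructureModel, chain_id: str,
                   start: int, end: int) -> np.ndarray | None:
    """Backbone coordinates for residues start..end, or None if any
    backbone atom is missing."""
    rows = []
    for num in range(start, end + 1):
        for name in BACKBONE_ATOMS:
            at = model.atom((chain_id, num, ""), name)
            if at is None:
                return None
            rows.append(at.xyz)
    return np.array(rows)


def select_anchors(
    target: StructureModel,
    donor: StructureModel,
    gap: GapSpec,
    window_length: int = 4,
    search_span: int = 8,
    donor_chain: str | None = None,
) -> GraftPlanEntry:
    """Choose the anchor windows flanking a gap.

    On each side, among windows of ``window_length`` consecutive
    residues whose near edge lies within ``search_span`` of the gap and
    whose backbone is complete in both structures, the window with the
    lowest target-vs-donor backbone RMSD wins; exact ties go to the
    window closest to the gap. ``donor_segment`` spans from the start
    of the pre-window to the end of the post-window, so the copied
    region may extend beyond the strict gap.
    """
    if donor_chain is None:
        donor_chain = donor.chains()[0]

    def best(side: str) -> tuple[int, int]:
        cands: list[tuple[float, int, tuple[int, int]]] = []
        for off in range(search_span):
            if side == "pre":
                end = gap.first_missing - 1 - off
                win = (end - window_length + 1, end)
                dist = off
            else:
                start = gap.last_missing + 1 + off
                win = (start, start + window_length - 1)
                dist = off
            ct = _window_coords(target, gap.chain_id, *win)
            cd = _window_coords(donor, donor_chain, *win)
            if ct is None or cd is None:
                continue
            rmsd = float(np.sqrt(np.mean(np.sum((ct - cd) ** 2, axis=1))))
            cands.append((round(rmsd, 9), dist, win))
        if not cands:
            raise AnchorFailureError(
                f"no complete {side}-gap anchor window of length "
                f"{window_length} within {search_span} of gap "
                f"{gap.first_missing}-{gap.last_missing}")
        cands.sort(key=lambda c: (c[0], c[1]))
        return cands[0][2]

    pre = best("pre")
    post = best("post")
    gap.donor_segment = (pre[0], post[1])
    return GraftPlanEntry(gap=gap, anchor_pre=pre, anchor_post=post,
                          window_length=window_length)


def _donor_chain_for(donor: StructureModel, seg: tuple[int, int]) -> str:
    best_chain, best_n = donor.chains()[0], -1
    for ch in donor.chains():
        nums = {rid[1] for rid in donor.chain_residue_ids(ch)}
        n = sum(1 for k in range(seg[0], seg[1] + 1) if k in nums)
        if n > best_n:
            best_chain, best_n = ch, n
    return best_chain


def graft(
    target: StructureModel,
    donors: Mapping[str, StructureModel],
    plan: GraftPlan,
) -> StructureModel:
    """Replace each planned segment of the target with donor residues.

    The donor segment is rigidly refitted onto the target anchor
    windows (backbone least squares) before insertion; atoms outside
    the replaced segments are copied untouched.
    """
    if not plan.entries:
        return target.copy()
    entries = sorted(plan.entries, key=lambda e: e.gap.first_missing)
    out_atoms: list[AtomRecord] = [a.copy() for a in target.atoms]

    for entry in entries:
        gap = entry.gap
        if gap.donor_id is None or gap.donor_segment is None:
            raise ValueError("plan entry lacks donor_id/donor_segment")
        donor = donors[gap.donor_id]
        seg = gap.donor_segment
        dch = _donor_chain_for(donor, seg)

        missing = []
        seg_atoms: list[AtomRecord] = []
        for num in range(seg[0], seg[1] + 1):
            res = [a for a in donor.atoms
                   if a.chain_id == dch and a.resseq == num and not a.is_het]
            names = {a.name for a in res}
            if not {"N", "CA", "C"} <= names:
                missing.append(num)
            seg_atoms.extend(res)
        if missing:
            raise IncompleteDonorError(
                f"donor {gap.donor_id!r} chain {dch} incomplete at "
                f"residues {missing}")

        # rigid fit of donor anchors onto target anchors
        dsel, tsel = [], []
        for win in (entry.anchor_pre, entry.anchor_post):
            for num in range(win[0], win[1] + 1):
                for name in BACKBONE_ATOMS:
                    da = donor.atom((dch, num, ""), name)
                    ta = target.atom((gap.chain_id, num, ""), name)
                    if da is not None and ta is not None:
                        dsel.append(da.xyz)
                        tsel.append(ta.xyz)
        if len(dsel) < 3:
            raise AnchorFailureError("fewer than 3 anchor atoms for local fit")
        r, t = kabsch(np.array(dsel), np.array(tsel))

        new_res: list[AtomRecord] = []
        for a in seg_atoms:
            b = a.copy()
            b.chain_id = gap.chain_id
            b.xyz = r @ a.xyz + t
            new_res.append(b)

        # splice: drop target polymer atoms inside the segment, insert donor copy
        kept: list[AtomRecord] = []
        inserted = False
        for a in out_atoms:
            inside = (a.chain_id == gap.chain_id and not a.is_het
                      and seg[0] <= a.resseq <= seg[1])
            past = (a.chain_id == gap.chain_id and not a.is_het
                    and a.resseq > seg[1])
            if (inside or past) and not inserted:
                kept.extend(new_res)
                inserted = True
            if not inside:
                kept.append(a)
        if not inserted:
            kept.extend(new_res)
        out_atoms = kept

    return StructureModel(target.model_id, out_atoms)


def junction_check(
    model: StructureModel,
    plan: GraftPlan,
    ca_range: tuple[float, float] = (2.9, 4.1),
    cn_range: tuple[float, float] = (1.2, 1.5),
    clash_overlap: float = 0.4,
) -> JunctionReport:
    """Report junction geometry and steric clashes of a grafted model.

    At each graft junction the CA-CA and peptide C-N distances must
    fall inside ``ca_range`` / ``cn_range``. A clash is a heavy-atom
    pair from non-adjacent residues closer than the sum of Bondi vdW
    radii minus ``clash_overlap``.
    """
    junctions = []
    for entry in plan.entries:
        seg = entry.gap.donor_segment
        if seg is None:
            continue
        ch = entry.gap.chain_id
        for prev, nxt in ((seg[0] - 1, seg[0]), (seg[1], seg[1] + 1)):
            ca1 = model.atom((ch, prev, ""), "CA")
            ca2 = model.atom((ch, nxt, ""), "CA")
            c1 = model.atom((ch, prev, ""), "C")
            n2 = model.atom((ch, nxt, ""), "N")
            if ca1 is None or ca2 is None or c1 is None or n2 is None:
                continue  # chain terminus: no junction on this side
            d_ca = float(np.linalg.norm(ca1.xyz - ca2.xyz))
            d_cn = float(np.linalg.norm(c1.xyz - n2.xyz))
            ok = (ca_range[0] <= d_ca <= ca_range[1]
                  and cn_range[0] <= d_cn <= cn_range[1])
            junctions.append({"chain": ch, "prev": prev, "next": nxt,
                              "ca_ca": d_ca, "c_n": d_cn, "ok": ok})

    heavy = [a for a in model.atoms if a.element.upper() != "H"]
    clashes = []
    if heavy:
        coords = np.array([a.xyz for a in heavy])
        radii = np.array([VDW_RADII.get(a.element.upper(), _VDW_DEFAULT)
                          for a in heavy])
        tree = cKDTree(coords)
        cutoff = 2 * radii.max() - clash_overlap
        for i, j in tree.query_pairs(cutoff):
            a, b = heavy[i], heavy[j]
            if a.residue_id == b.residue_id:
                continue
            if (a.chain_id == b.chain_id and a.icode == b.icode == ""
                    and abs(a.resseq - b.resseq) <= 1):
                continue  # bonded/peptide neighbours
            d = float(np.linalg.norm(a.xyz - b.xyz))
            limit = radii[i] + radii[j] - clash_overlap
            if d < limit:
                clashes.append({
                    "atom_a": (a.chain_id, a.resseq, a.name),
                    "atom_b": (b.chain_id, b.resseq, b.name),
                    "distance": d,
                    "overlap": float(radii[i] + radii[j] - d),
                })
    return JunctionReport(junctions=junctions, clashes=clashes)
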