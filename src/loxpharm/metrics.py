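"""Virtual-screening validation: property-matched decoy selection,
ROC/AUC and enrichment factor.

The enrichment factor uses the whole-dataset hit-list definition
EF = (TP / n_hits) / (n_actives / n_total): the active fraction in
the hit list relative to the active fraction of the screened library,
so EF = 1 means random retrieval. AUC is the midrank (Mann-Whitney)
area under the ROC of ranked scores; non-matching compounds enter
with score 0 and share a rank.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import UndefinedMetricError
from .perceive import PharmacophoreModel
from .screen import LigandRecord, MatchResult, screen_library


@dataclass
class PropertyWindows:
    """Per-property matching tolerances for decoy selection."""

    mw: float = 25.0
    logp: float = 1.0
    hbd: int = 1
    hba: int = 1
    charge: int = 0        # exact match by default


@dataclass
class EnrichmentReport:
    n_actives: int
    n_decoys: int
    tp: int
    fp: int
    fn: int
    tn: int
    ef: float | None
    auc: float
    roc_points: list[tuple[float, float]]
    results: list[MatchResult] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_actives if self.n_actives else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / self.n_decoys if self.n_decoys else 0.0

    def to_json(self) -> str:
        return json.dumps({
            "n_actives": self.n_actives, "n_decoys": self.n_decoys,
            "TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn,
            "sensitivity": self.sensitivity, "FPR": self.fpr,
            "EF": None if self.ef is None else round(self.ef, 1),
            "AUC": self.auc,
            "roc_points": [[float(a), float(b)] for a, b in self.roc_points],
        }, indent=1)


# ---------------------------------------------------------------------------

def enrichment_factor(tp: int, n_hits: int, n_actives: int, n_total: int) -> float:
    """Whole-dataset enrichment factor (TP/n_hits) / (n_actives/n_total)."""
    if n_hits == 0:
        raise UndefinedMetricError("EF undefined for an empty hit list")
    if n_hits < tp or n_total < n_actives or n_actives == 0:
        raise ValueError("inconsistent confusion counts")
    return (tp / n_hits) / (n_actives / n_total)


def roc_auc(scores: Sequence[tuple[float, bool]]) -> tuple[float, list[tuple[float, float]]]:
    """AUC plus ROC points for (score, is_active) pairs.

    Compounds are ranked by score descending; tied scores share a
    rank (midrank), which makes the trapezoid area equal to the
    normalized Mann-Whitney rank-sum statistic.
    """
    y = np.array([bool(lab) for _s, lab in scores])
    s = np.array([float(sc) for sc, _lab in scores])
    if y.all() or not y.any():
        raise UndefinedMetricError("AUC undefined with a single class")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    pts = [(float(a), float(b)) for a, b in zip(fpr, tpr)]
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return auc, pts


def generate_decoys(
    actives: Sequence[LigandRecord],
    pool: Sequence[LigandRecord],
    windows: PropertyWindows | None = None,
    max_similarity: float = 0.7,
    n_per_active: int = 46,
    seed: int = 0,
) -> list[LigandRecord]:
    """Select property-matched, topologically dissimilar decoys.

    For each active, up to ``n_per_active`` pool members whose MW,
    logP, H-bond donor/acceptor counts and net charge all fall inside
    the windows and whose 2-D path-fingerprint Tanimoto similarity to
    every active is at most ``max_similarity``. Pool order is shuffled
    by ``seed``; duplicates are excluded. A short set is returned
    with a warning when the pool cannot satisfy demand.
    """
    from rdkit import Chem
    from rdkit.DataStructs import TanimotoSimilarity

    win = windows or PropertyWindows()
    active_fps = []
    for a in actives:
        mol = Chem.MolFromSmiles(a.smiles)
        active_fps.append(Chem.RDKFingerprint(mol) if mol is not None else None)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    chosen: list[LigandRecord] = []
    chosen_ids: set[str] = set()
    shortfall = 0
    for active in actives:
        n_taken = 0
        for k in order:
            cand = pool[k]
            if cand.id in chosen_ids or n_taken >= n_per_active:
                continue
            if not _within_windows(active.properties, cand.properties, win):
                continue
            mol = Chem.MolFromSmiles(cand.smiles) if cand.smiles else None
            if mol is not None:
                fp = Chem.RDKFingerprint(mol)
                if any(afp is not None and TanimotoSimilarity(fp, afp) > max_similarity
                       for afp in active_fps):
                    continue
            chosen.append(LigandRecord(cand.id, cand.smiles, cand.conformers,
                                       "decoy", dict(cand.properties),
                                       cand.feature_points))
            chosen_ids.add(cand.id)
            n_taken += 1
        shortfall += n_per_active - n_taken
    if shortfall:
        warnings.warn(f"decoy pool short by {shortfall} candidates", stacklevel=2)
    return chosen


def _within_windows(pa: dict, pb: dict, win: PropertyWindows) -> bool:
    return (abs(pa["mw"] - pb["mw"]) <= win.mw
            and abs(pa["logp"] - pb["logp"]) <= win.logp
            and abs(pa["hbd"] - pb["hbd"]) <= win.hbd
            and abs(pa["hba"] - pb["hba"]) <= win.hba
            and abs(pa["charge"] - pb["charge"]) <= win.charge)


def benchmark(
    model: PharmacophoreModel,
    actives: Sequence[LigandRecord],
    decoys: Sequence[LigandRecord],
    check_ev: bool = True,
) -> EnrichmentReport:
    """Screen actives+decoys and assemble the full enrichment report.

    Matches count as hits; confusion counts, whole-dataset EF and the
    midrank ROC/AUC over fit scores (non-matches scoring 0) are
    computed. Skipped ligands (no conformers) count as non-hits.
    """
    if not actives or not decoys:
        raise ValueError("both actives and decoys must be non-empty")
    is_active = {a.id: True for a in actives}
    is_active.update({d.id: False for d in decoys})
    results, skipped = screen_library(model, list(actives) + list(decoys),
                                      check_ev=check_ev)
    scores: list[tuple[float, bool]] = []
    tp = fp = 0
    for r in results:
        lab = is_active[r.ligand_id]
        scores.append((r.fit_score if r.matched else 0.0, lab))
        if r.matched:
            tp += int(lab)
            fp += int(not lab)
    for lid in skipped:
        scores.append((0.0, is_active[lid]))
    n_a, n_d = len(actives), len(decoys)
    n_hits = tp + fp
    ef = None
    if n_hits:
        ef = enrichment_factor(tp, n_hits, n_a, n_a + n_d)
    else:
        warnings.warn("no hits: EF undefined", stacklevel=2)
    auc, pts = roc_auc(scores)
    return EnrichmentReport(n_actives=n_a, n_decoys=n_d, tp=tp, fp=fp,
                            fn=n_a - tp, tn=n_d - fp, ef=ef, auc=auc,
                            roc_points=pts, results=results)
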