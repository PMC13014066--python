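"""Merging of per-complex pharmacophore models into a consensus model.

Retention logic: a feature group present in every source model becomes
a required consensus feature; one present in a stated smaller number
of models (two of three by default) is kept but marked optional;
anything rarer is dropped. Donor arrows are converted to plain
spheres. Excluded volumes survive only where every model contributes
a mutually overlapping sphere; the merged sphere keeps the smallest
member radius so only space all models agree on stays excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .perceive import ExcludedVolume, Feature, PharmacophoreModel, label_features
from .structure import Superposition


@dataclass
class FeatureGroup:
    ftype: str
    members: list[tuple[int, Feature]]   # (model index, feature)

    @property
    def n_models_present(self) -> int:
        return len({mi for mi, _f in self.members})


@dataclass
class FeatureCorrespondence:
    groups: list[FeatureGroup]
    match_radius: float
    n_models: int


@dataclass
class ConsensusRules:
    """Presence thresholds for feature retention."""

    n_models: int
    required_if_present_in: int | None = None   # default: all models
    optional_if_present_in: int = 2
    convert_donor_vectors: bool = True

    def __post_init__(self) -> None:
        if self.required_if_present_in is None:
            self.required_if_present_in = self.n_models
        if not (self.optional_if_present_in <= self.required_if_present_in):
            raise ValueError("optional threshold must not exceed required threshold")


def align_models(
    models: Sequence[PharmacophoreModel],
    transforms: Sequence[Superposition],
) -> list[PharmacophoreModel]:
    """Express all models in the first model's frame.

    ``transforms[i]`` maps model ``i+1`` onto the reference (from the
    protein superposition that aligned the complexes).
    """
    if len(transforms) != len(models) - 1:
        raise ValueError(f"need {len(models) - 1} transforms, got {len(transforms)}")
    out = [models[0].copy()]
    for model, sp in zip(models[1:], transforms):
        out.append(model.transformed(sp))
    return out


def correspond(
    models: Sequence[PharmacophoreModel],
    match_radius: float = 2.0,
) -> FeatureCorrespondence:
    """Group equivalent features across aligned models.

    Greedy closest-pairs agglomeration per feature type: cross-model
    feature pairs are merged in order of increasing center distance,
    subject to at most one member per source model and all pairwise
    distances within ``match_radius``. Unmatched features remain
    singleton groups.
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    items: list[tuple[int, Feature]] = []
    for mi, m in enumerate(models):
        for f in m.features:
            items.append((mi, f))

    parent = list(range(len(items)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pairs = []
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            (mi, fi), (mj, fj) = items[i], items[j]
            if mi == mj or fi.ftype != fj.ftype:
                continue
            d = float(np.linalg.norm(fi.center - fj.center))
            if d <= match_radius:
                pairs.append((round(d, 9), mi, fi.label, mj, fj.label, i, j))
    pairs.sort()

    for _d, _mi, _li, _mj, _lj, i, j in pairs:
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        members_i = [k for k in range(len(items)) if find(k) == ri]
        members_j = [k for k in range(len(items)) if find(k) == rj]
        model_ids = [items[k][0] for k in members_i + members_j]
        if len(model_ids) != len(set(model_ids)):
            continue
        ok = all(
            float(np.linalg.norm(items[a][1].center - items[b][1].center)) <= match_radius
            for a in members_i for b in members_j)
        if ok:
            parent[rj] = ri

    by_root: dict[int, list[int]] = {}
    for k in range(len(items)):
        by_root.setdefault(find(k), []).append(k)
    groups = [FeatureGroup(ftype=items[ks[0]][1].ftype,
                           members=[items[k] for k in ks])
              for ks in by_root.values()]
    groups.sort(key=lambda g: (g.ftype, -g.n_models_present,
                               tuple(np.round(g.members[0][1].center, 6))))
    return FeatureCorrespondence(groups=groups, match_radius=match_radius,
                                 n_models=len(models))


def build_consensus(
    corr: FeatureCorrespondence,
    rules: ConsensusRules,
    complex_id: str = "consensus",
) -> PharmacophoreModel:
    """Apply the retention rules and merge grouped features.

    Merged center is the member mean; merged tolerance is the largest
    member tolerance plus half the maximal pairwise member distance,
    so every member sphere is covered by the interpolated one.
    """
    if not corr.groups:
        warnings.warn("empty correspondence: consensus model has no features",
                      stacklevel=2)
        return PharmacophoreModel(complex_id=complex_id)
    features: list[Feature] = []
    for g in corr.groups:
        n = g.n_models_present
        if n >= rules.required_if_present_in:
            optional = False
        elif n >= rules.optional_if_present_in:
            optional = True
        else:
            continue
        centers = np.array([f.center for _mi, f in g.members])
        spread = 0.0
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                spread = max(spread, float(np.linalg.norm(centers[i] - centers[j])))
        tol = max(f.tolerance for _mi, f in g.members) + spread / 2.0
        direction = None
        dirs = [f.direction for _mi, f in g.members]
        if all(d is not None for d in dirs):
            mean_dir = np.mean(np.array(dirs), axis=0)
            norm = np.linalg.norm(mean_dir)
            if norm > 1e-9:
                direction = mean_dir / norm
        if g.ftype == "HBD" and rules.convert_donor_vectors:
            direction = None
        provenance = sorted({tuple(p) for _mi, f in g.members for p in f.provenance})
        features.append(Feature(label="", ftype=g.ftype,
                                center=centers.mean(axis=0), tolerance=tol,
                                direction=direction, optional=optional,
                                provenance=provenance))
    return label_features(PharmacophoreModel(complex_id=complex_id,
                                             features=features))


def merge_excluded_volumes(
    models: Sequence[PharmacophoreModel],
) -> list[ExcludedVolume]:
    """Keep only excluded-volume space shared by every model.

    For each volume of the first model, one mutually intersecting
    volume is sought in every other model (pairwise center distance
    strictly below the sum of radii, nearest candidate first, each
    volume used once); the merged sphere has the mean center and the
    smallest member radius.
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    used: list[set[int]] = [set() for _ in models]
    merged: list[ExcludedVolume] = []
    for v0 in models[0].volumes:
        group = [v0]
        picks: list[tuple[int, int]] = []
        ok = True
        for mi in range(1, len(models)):
            cands = []
            for vi, v in enumerate(models[mi].volumes):
                if vi in used[mi]:
                    continue
                if all(float(np.linalg.norm(v.center - g.center)) < v.radius + g.radius
                       for g in group):
                    cands.append((float(np.linalg.norm(v.center - v0.center)), vi, v))
            if not cands:
                ok = False
                break
            cands.sort(key=lambda c: (c[0], c[1]))
            _d, vi, v = cands[0]
            group.append(v)
            picks.append((mi, vi))
        if ok:
            for mi, vi in picks:
                used[mi].add(vi)
            centers = np.array([g.center for g in group])
            merged.append(ExcludedVolume(centers.mean(axis=0),
                                         min(g.radius for g in group)))
    return merged
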