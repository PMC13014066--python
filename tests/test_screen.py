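"""Ligand annotation, match-all matching, fit score and library
screening, with an exhaustive-assignment oracle."""

import itertools

import numpy as np
import pytest

import loxpharm as lp
from loxpharm.screen import Conformer, LigandPoint, LigandRecord, compute_fit_score
from loxpharm.structure import kabsch, Superposition
from loxpharm.synth import make_screen_set

from conftest import rigid_motion


def exhaustive_match(model, points, conformer=None, check_ev=True):
    """Brute-force oracle: enumerate every injective type-compatible
    assignment of required features, apply the same accept rule, and
    return (matched, best_required_only_score)."""
    required = model.required_features()
    by_type_pts = {}
    for i, p in enumerate(points):
        by_type_pts.setdefault(p.ftype, []).append(i)
    heavy = conformer.heavy_coords() if conformer is not None else np.empty((0, 3))
    per_type = []
    for ftype in sorted({f.ftype for f in required}):
        fidx = [i for i, f in enumerate(required) if f.ftype == ftype]
        cands = by_type_pts.get(ftype, [])
        if len(cands) < len(fidx):
            return False, 0.0
        per_type.append([list(zip(fidx, perm))
                         for perm in itertools.permutations(cands, len(fidx))])
    matched, best = False, 0.0
    for combo in itertools.product(*per_type):
        pairs = [p for block in combo for p in block]
        src = np.array([points[pi].center for _fi, pi in pairs])
        dst = np.array([required[fi].center for fi, _pi in pairs])
        if len(pairs) >= 3:
            r, t = kabsch(src, dst)
        else:
            r, t = np.eye(3), dst.mean(axis=0) - src.mean(axis=0)
        moved = src @ r.T + t
        devs = np.linalg.norm(moved - dst, axis=1)
        if any(d > required[fi].tolerance for (fi, _pi), d in zip(pairs, devs)):
            continue
        if check_ev and model.volumes and len(heavy):
            mh = heavy @ r.T + t
            if any(np.any(np.linalg.norm(mh - v.center, axis=1) < v.radius)
                   for v in model.volumes):
                continue
        matched = True
        score = compute_fit_score(
            list(devs), [required[fi].tolerance for fi, _pi in pairs])
        best = max(best, score)
    return matched, best


def _points_at_centers(model, include_optional=True):
    return [LigandPoint(f.ftype, f.center.copy()) for f in model.features
            if include_optional or not f.optional]


class TestMatch:
    def test_exact_points_match_with_zero_deviation(self, consensus_model):
        pts = _points_at_centers(consensus_model)
        res = lp.match(consensus_model, pts)
        assert res.matched
        assert len(res.assignment) == len(consensus_model.features)
        assert max(res.deviations.values()) < 1e-9
        assert res.fit_score == pytest.approx(10.0 * len(consensus_model.features))

    def test_rigid_motion_invariance(self, consensus_model):
        pts = _points_at_centers(consensus_model)
        rot, trans = rigid_motion(5)
        moved = [LigandPoint(p.ftype, rot @ p.center + trans) for p in pts]
        res0 = lp.match(consensus_model, pts)
        res1 = lp.match(consensus_model, moved)
        assert res1.matched == res0.matched
        assert res1.fit_score == pytest.approx(res0.fit_score, abs=1e-6)

    def test_spoiled_point_breaks_match(self, consensus_model):
        pts = _points_at_centers(consensus_model, include_optional=False)
        # collapse all points of one required type far away
        pts = [LigandPoint(p.ftype, p.center + 30.0) if p.ftype == "METAL"
               else p for p in pts]
        res = lp.match(consensus_model, pts)
        assert not res.matched and res.fit_score == 0.0

    def test_missing_required_type_is_nonmatch(self, consensus_model):
        pts = [p for p in _points_at_centers(consensus_model)
               if p.ftype != "HBD"]
        assert not lp.match(consensus_model, pts).matched

    def test_optional_never_vetoes(self, consensus_model):
        pts = _points_at_centers(consensus_model, include_optional=False)
        res = lp.match(consensus_model, pts)
        assert res.matched
        assert len(res.assignment) == len(consensus_model.required_features())

    def test_no_required_features_rejected(self):
        from loxpharm.perceive import PharmacophoreModel
        with pytest.raises(ValueError):
            lp.match(PharmacophoreModel("empty"), [])

    def test_removing_required_feature_is_monotone(self, consensus_model):
        """Match-all semantics: deleting a required feature can convert
        non-matches to matches but never the reverse."""
        lib = make_screen_set(consensus_model, 5, 40, seed=9)
        reduced = consensus_model.copy()
        dropped = next(f.label for f in reduced.features
                       if not f.optional and f.ftype == "HYD")
        reduced.features = [f for f in reduced.features if f.label != dropped]
        for rec in lib:
            pts = rec.feature_points[0]
            full = lp.match(consensus_model, pts, rec.conformers[0])
            part = lp.match(reduced, pts, rec.conformers[0])
            if full.matched:
                assert part.matched

    def test_agrees_with_exhaustive_oracle(self, consensus_model):
        lib = make_screen_set(consensus_model, 8, 40, seed=13)
        for rec in lib:
            pts = rec.feature_points[0]
            got = lp.match(consensus_model, pts, rec.conformers[0])
            want_matched, _ = exhaustive_match(consensus_model, pts,
                                               rec.conformers[0])
            assert got.matched == want_matched, rec.id

    def test_ev_planting_blocks_match_only_when_checked(self, consensus_model):
        pts = _points_at_centers(consensus_model, include_optional=False)
        vol = consensus_model.volumes[0]
        conf = Conformer(["C"] * (len(pts) + 1),
                         np.array([p.center for p in pts] + [vol.center]))
        assert not lp.match(consensus_model, pts, conf, check_ev=True).matched
        assert lp.match(consensus_model, pts, conf, check_ev=False).matched


class TestFitScore:
    def test_formula_six_perfect_features(self):
        assert compute_fit_score([0.0] * 6, [1.5] * 6) == 60.0

    def test_formula_half_tolerance(self):
        assert compute_fit_score([0.75] * 4, [1.5] * 4) == pytest.approx(38.0)

    def test_monotone_in_deviation(self):
        scores = [compute_fit_score([d, 0, 0], [1.5] * 3)
                  for d in np.linspace(0, 1.4, 10)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_fit_score_recompute_matches_result(self, consensus_model):
        pts = _points_at_centers(consensus_model)
        res = lp.match(consensus_model, pts)
        assert lp.fit_score(res) == pytest.approx(res.fit_score)
        from loxpharm.screen import MatchResult
        assert lp.fit_score(MatchResult("x")) == 0.0


class TestScreenLibrary:
    def test_ranking_and_skips(self, consensus_model):
        good = LigandRecord(id="good", feature_points=[
            _points_at_centers(consensus_model)],
            conformers=[Conformer([], np.empty((0, 3)))])
        bad_pts = [LigandPoint(p.ftype, p.center + 25.0) if p.ftype == "METAL"
                   else p for p in _points_at_centers(consensus_model)]
        bad = LigandRecord(id="bad", feature_points=[bad_pts],
                           conformers=[Conformer([], np.empty((0, 3)))])
        empty = LigandRecord(id="none")
        results, skipped = lp.screen_library(consensus_model,
                                             [bad, empty, good])
        assert skipped == ["none"]
        assert [r.ligand_id for r in results] == ["good", "bad"]
        assert results[0].matched and not results[1].matched

    def test_best_conformer_selected(self, consensus_model):
        perfect = _points_at_centers(consensus_model)
        worse = [LigandPoint(p.ftype, p.center + 0.5) for p in perfect]
        rec = LigandRecord(id="two", feature_points=[worse, perfect],
                           conformers=[Conformer([], np.empty((0, 3)))] * 2)
        results, _ = lp.screen_library(consensus_model, [rec])
        assert results[0].conformer_index == 1


class TestAnnotate:
    def test_hydroxyurea_warhead_points(self):
        """An N-hydroxyurea inhibitor exposes donor, metal-capable and
        negative-ionizable points."""
        zileuton = "CC(c1cc2ccccc2s1)N(O)C(N)=O"
        rec = lp.embed_conformers("zileuton", zileuton, n_conformers=1, seed=7)
        assert rec.conformers
        pts = lp.annotate_ligand(rec)[0]
        types = {p.ftype for p in pts}
        assert {"HBD", "METAL", "NI"} <= types

    def test_methane_has_no_points(self):
        rec = lp.embed_conformers("methane", "C", n_conformers=1, seed=7)
        assert lp.annotate_ligand(rec)[0] == []

    def test_carboxylate_single_ni_point(self):
        rec = lp.embed_conformers("butyrate", "CCCC(=O)O", n_conformers=1,
                                  seed=7)
        pts = lp.annotate_ligand(rec)[0]
        ni = [p for p in pts if p.ftype == "NI"]
        assert len(ni) == 1
        group = np.array([rec.conformers[0].coords[i] for i in ni[0].source_atoms])
        assert np.allclose(ni[0].center, group.mean(axis=0))

    def test_unparsable_smiles_warns(self):
        rec = LigandRecord(id="junk", smiles="not-a-smiles")
        with pytest.warns(UserWarning):
            assert lp.annotate_ligand(rec) == []
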