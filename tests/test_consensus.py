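"""Feature correspondence and consensus merging."""

import itertools

import numpy as np
import pytest

import loxpharm as lp
from loxpharm.perceive import ExcludedVolume, Feature, PharmacophoreModel
from loxpharm.structure import Superposition

from conftest import rigid_motion


def _model(mid, feats, vols=()):
    return PharmacophoreModel(
        complex_id=mid,
        features=[Feature(label=f"f{i}", ftype=t, center=np.asarray(c, float),
                          tolerance=1.5)
                  for i, (t, c) in enumerate(feats)],
        volumes=[ExcludedVolume(np.asarray(c, float), r) for c, r in vols])


class TestAlign:
    def test_identity_transforms_noop(self, reference_models):
        out = lp.align_models(reference_models,
                              [Superposition.identity()] * 2)
        for a, b in zip(reference_models, out):
            for fa, fb in zip(a.features, b.features):
                assert np.allclose(fa.center, fb.center)

    def test_rotate_then_align_back(self):
        m = _model("m", [("HBD", (1, 2, 3)), ("HYD", (4, 0, 1))])
        rot, trans = rigid_motion(1)
        moved = m.transformed(Superposition(rot, trans))
        back = lp.align_models([m, moved],
                               [Superposition(rot, trans).inverse()])[1]
        for fa, fb in zip(m.features, back.features):
            assert np.allclose(fa.center, fb.center, atol=1e-9)

    def test_transform_count_mismatch(self, reference_models):
        with pytest.raises(ValueError):
            lp.align_models(reference_models, [Superposition.identity()])

    def test_planted_core_coincides_after_alignment(self):
        core = [("METAL", (0, 0, 0)), ("HBD", (3, 0, 0)), ("HYD", (0, 4, 1))]
        m0 = _model("a", core)
        rot, trans = rigid_motion(8)
        m1 = _model("b", core).transformed(Superposition(rot, trans))
        aligned = lp.align_models([m0, m1],
                                  [Superposition(rot, trans).inverse()])
        corr = lp.correspond(aligned, 2.0)
        assert all(g.n_models_present == 2 for g in corr.groups)


class TestCorrespond:
    def test_identical_models_fully_grouped(self, reference_models):
        same = [reference_models[0].copy() for _ in range(3)]
        corr = lp.correspond(same, 2.0)
        assert all(g.n_models_present == 3 for g in corr.groups)
        assert len(corr.groups) == len(reference_models[0].features)

    def test_lone_feature_is_singleton(self):
        m0 = _model("a", [("HBD", (0, 0, 0)), ("NI", (9, 9, 9))])
        m1 = _model("b", [("HBD", (0.3, 0, 0))])
        corr = lp.correspond([m0, m1], 2.0)
        sizes = sorted(len(g.members) for g in corr.groups)
        assert sizes == [1, 2]

    def test_greedy_matches_brute_force_on_ambiguous_fixture(self):
        """Two close feature pairs: grouping must equal the assignment
        minimizing total center distance (exhaustive oracle)."""
        a = [("HBD", (0.0, 0, 0)), ("HBD", (3.0, 0, 0))]
        b = [("HBD", (1.2, 0, 0)), ("HBD", (3.4, 0, 0))]
        m0, m1 = _model("a", a), _model("b", b)
        corr = lp.correspond([m0, m1], 2.0)

        # oracle: enumerate injective mappings b -> a (or unmatched)
        centers_a = [np.array(c) for _t, c in a]
        centers_b = [np.array(c) for _t, c in b]
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(2)):
            cost, pairs = 0.0, []
            for j, i in enumerate(perm):
                d = np.linalg.norm(centers_a[i] - centers_b[j])
                if d <= 2.0:
                    cost += d
                    pairs.append((i, j))
            if cost < best_cost and len(pairs) == 2:
                best, best_cost = pairs, cost
        got = set()
        for g in corr.groups:
            if len(g.members) == 2:
                ia = [int(f.label[1:]) for mi, f in g.members if mi == 0][0]
                ib = [int(f.label[1:]) for mi, f in g.members if mi == 1][0]
                got.add((ia, ib))
        assert got == set(best)

    def test_types_never_mix(self):
        m0 = _model("a", [("HBD", (0, 0, 0))])
        m1 = _model("b", [("HBA", (0.1, 0, 0))])
        corr = lp.correspond([m0, m1], 2.0)
        assert all(len(g.members) == 1 for g in corr.groups)


class TestBuildConsensus:
    def test_three_identical_single_feature_models(self):
        feats = [("HBD", (1.0, 2.0, 3.0))]
        models = [_model(str(i), feats) for i in range(3)]
        cons = lp.build_consensus(lp.correspond(models, 2.0),
                                  lp.ConsensusRules(3))
        assert len(cons.features) == 1
        f = cons.features[0]
        assert not f.optional
        assert np.allclose(f.center, (1, 2, 3))
        assert f.direction is None   # donor vectors converted to spheres

    def test_membership_partition_matches_counting(self):
        """Randomized membership sets: retained/optional/dropped must
        equal direct set arithmetic on the planted memberships."""
        rng = np.random.default_rng(12)
        n_groups, n_models = 9, 3
        centers = rng.uniform(-40, 40, (n_groups, 3))
        membership = [tuple(sorted(rng.choice(3, size=rng.integers(1, 4),
                                              replace=False)))
                      for _ in range(n_groups)]
        models = []
        for mi in range(n_models):
            feats = [("HYD", tuple(centers[g] + rng.normal(0, 0.2, 3)))
                     for g in range(n_groups) if mi in membership[g]]
            models.append(_model(str(mi), feats))
        cons = lp.build_consensus(lp.correspond(models, 2.0),
                                  lp.ConsensusRules(3))
        expect_required = sum(1 for m in membership if len(m) == 3)
        expect_optional = sum(1 for m in membership if len(m) == 2)
        assert sum(not f.optional for f in cons.features) == expect_required
        assert sum(f.optional for f in cons.features) == expect_optional

    def test_reference_sets_reproduce_published_bookkeeping(self, consensus_model):
        """Three per-complex inventories merge to six features, two of
        them optional (the NI warhead and the shared hydrophobic),
        with every acceptor group dropped."""
        cons = consensus_model
        assert len(cons.features) == 6
        assert sum(f.optional for f in cons.features) == 2
        assert not any(f.ftype == "HBA" for f in cons.features)
        opt_types = sorted(f.ftype for f in cons.features if f.optional)
        assert opt_types == ["HYD", "NI"]
        req_types = sorted(f.ftype for f in cons.features if not f.optional)
        assert req_types == ["HBD", "HYD", "HYD", "METAL"]
        d1 = next(f for f in cons.features if f.ftype == "HBD")
        assert ("B", 673, "") in [tuple(p) for p in d1.provenance]
        assert d1.direction is None

    def test_required_count_bounded_by_min_per_type(self, reference_models):
        cons = lp.build_consensus(lp.correspond(reference_models, 2.0),
                                  lp.ConsensusRules(3))
        for ftype in {f.ftype for f in cons.features}:
            n_req = sum(1 for f in cons.features
                        if f.ftype == ftype and not f.optional)
            n_min = min(sum(1 for f in m.features if f.ftype == ftype)
                        for m in reference_models)
            assert n_req <= n_min

    def test_model_order_invariance(self, reference_models):
        cons_a = lp.build_consensus(lp.correspond(reference_models, 2.0),
                                    lp.ConsensusRules(3))
        reordered = [reference_models[0], reference_models[2],
                     reference_models[1]]
        cons_b = lp.build_consensus(lp.correspond(reordered, 2.0),
                                    lp.ConsensusRules(3))
        sig_a = sorted((f.ftype, f.optional, tuple(np.round(f.center, 6)))
                       for f in cons_a.features)
        sig_b = sorted((f.ftype, f.optional, tuple(np.round(f.center, 6)))
                       for f in cons_b.features)
        assert sig_a == sig_b

    def test_merged_tolerance_covers_spread(self):
        models = [_model(str(i), [("HYD", (0.6 * i, 0, 0))]) for i in range(3)]
        cons = lp.build_consensus(lp.correspond(models, 2.0),
                                  lp.ConsensusRules(3))
        assert cons.features[0].tolerance == pytest.approx(1.5 + 0.6)

    def test_empty_correspondence_warns(self):
        corr = lp.FeatureCorrespondence(groups=[], match_radius=2.0, n_models=3)
        with pytest.warns(UserWarning):
            cons = lp.build_consensus(corr, lp.ConsensusRules(3))
        assert cons.features == []


class TestMergedVolumes:
    def test_identical_sets_survive(self):
        vols = [((0, 0, 0), 1.2), ((5, 0, 0), 1.2)]
        models = [_model(str(i), [("HYD", (9, 9, 9))], vols) for i in range(3)]
        merged = lp.merge_excluded_volumes(models)
        assert len(merged) == 2
        assert all(v.radius == 1.2 for v in merged)

    def test_two_of_three_dropped(self):
        present = [((0, 0, 0), 1.2)]
        models = [_model("a", [], present), _model("b", [], present),
                  _model("c", [], [((30, 0, 0), 1.2)])]
        assert lp.merge_excluded_volumes(models) == []

    def test_seventeen_planted_triples(self, reference_models):
        merged = lp.merge_excluded_volumes(reference_models)
        assert len(merged) == 17

    def test_min_radius_rule(self):
        models = [_model("a", [], [((0, 0, 0), 1.5)]),
                  _model("b", [], [((0.3, 0, 0), 1.0)]),
                  _model("c", [], [((0, 0.3, 0), 2.0)])]
        (v,) = lp.merge_excluded_volumes(models)
        assert v.radius == 1.0
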