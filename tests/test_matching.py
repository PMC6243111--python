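"""Cross-session streamline correspondence, Procrustes, bundle matching."""

import itertools

import numpy as np
import pytest

from peritract import curvegeom as cg
from peritract import matching as mt
from conftest import make_circle, make_helix, make_line, random_rotation


def wiggly(k, n=200, length=60.0):
    """Family of distinct, gently curved test streamlines."""
    t = np.linspace(0, 1, n)
    return cg.Streamline(np.stack([
        length * t,
        10 * np.sin(3 * t + k) + 2 * k,
        5 * np.cos(2 * t + 0.5 * k) + 3 * k,
    ], axis=1))


class TestIndexCorrespondence:
    def test_identical_curves_identity_map(self):
        c = wiggly(0)
        imap = mt.index_correspondence(c, c, 0.5)
        assert not imap.target_reversed
        assert np.array_equal(imap.pairs[:, 0], imap.pairs[:, 1])

    def test_reversed_copy_resolved_to_identity(self):
        c = cg.resample(wiggly(1), 0.5)
        imap = mt.index_correspondence(c, c.reversed(), 0.5)
        assert imap.target_reversed
        n = len(c)
        # identity once the recorded reorientation is applied
        assert np.array_equal(imap.pairs[:, 0] + imap.pairs[:, 1],
                              np.full(len(imap.pairs), n - 1))

    def test_truncated_subcurve_offset(self):
        full = cg.resample(wiggly(2), 0.5)
        inside = (full.s >= 5.0) & (full.s <= 45.0)
        sub = cg.Streamline(full.points[inside])
        imap = mt.index_correspondence(sub, full, 0.5)
        assert len(imap.pairs) == pytest.approx(81, abs=1)
        assert imap.offset == pytest.approx(10, abs=1)
        # matched points nearly coincide spatially
        d = np.linalg.norm(full.points[imap.pairs[:, 1]]
                           - sub.points[imap.pairs[:, 0]], axis=1)
        assert np.median(d) < 0.5

    def test_position_metric_matches_straight_curves(self):
        # feature profiles of straight lines are uninformative; the
        # position metric still recovers the exact overlap
        a = make_line(length=50, n=101)
        b = make_line(length=40, n=81, offset=(5.0, 0, 0))
        imap = mt.index_correspondence(b, a, 0.5, metric="position")
        assert imap.offset == 10
        assert not imap.target_reversed


class TestFeatureDistance:
    def test_self_distance_zero(self):
        c = cg.resample(wiggly(3), 0.5)
        inv = cg.invariants(c)
        imap = mt.index_correspondence(c, c, 0.5)
        assert mt.feature_distance(inv, inv, imap) == pytest.approx(0.0, abs=1e-15)

    def test_rigid_copy_distance_tiny(self, rng):
        c = cg.resample(wiggly(4), 0.5)
        moved = cg.apply_rigid(c, random_rotation(rng), rng.normal(size=3) * 8)
        imap = mt.index_correspondence(c, moved, 0.5)
        d = mt.feature_distance(cg.invariants(c), cg.invariants(moved), imap)
        assert d < 1e-8

    def test_circle_vs_line_hand_value(self):
        # circle kappa = 0.1 vs straight kappa = 0: mean (0.1)^2 = 0.01;
        # torsion undefined on the line contributes nothing
        circle = cg.resample(make_circle(radius=10.0, arc_fraction=0.5), 0.5)
        line = cg.resample(make_line(length=circle.length, n=100), 0.5)
        imap = mt.index_correspondence(circle, line, 0.5)
        d = mt.feature_distance(cg.invariants(circle), cg.invariants(line), imap)
        assert d == pytest.approx(0.01, rel=0.02)

    def test_empty_map_raises(self):
        c = cg.resample(wiggly(5), 0.5)
        inv = cg.invariants(c)
        empty = mt.IndexMap(pairs=np.empty((0, 2), int), target_reversed=False,
                            offset=0)
        with pytest.raises(ValueError):
            mt.feature_distance(inv, inv, empty)


class TestProcrustes:
    def test_identity_on_equal_sets(self, rng):
        p = rng.normal(size=(30, 3))
        res = mt.procrustes(p, p)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(res.translation, 0.0, atol=1e-12)
        assert res.rms < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_known_transform(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.normal(size=(50, 3)) * 10
        rot = random_rotation(rng)
        t = rng.normal(size=3) * 5
        res = mt.procrustes(p, p @ rot.T + t)
        assert np.linalg.norm(res.rotation - rot) < 1e-9
        assert res.rms < 1e-9
        assert res.unique

    def test_noise_residual_matches_expectation(self):
        # E[RMS] = sigma * sqrt(3 - 6/n) after fitting 6 rigid dof in 3D
        rng = np.random.default_rng(7)
        sigma, n = 0.1, 100
        rms = []
        for _ in range(100):
            p = rng.normal(size=(n, 3)) * 10
            q = p + rng.normal(0, sigma, (n, 3))
            rms.append(mt.procrustes(p, q).rms)
        expect = sigma * np.sqrt(3 - 6 / n)
        assert np.mean(rms) == pytest.approx(expect, rel=0.05)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            mt.procrustes(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_flagged_non_unique(self):
        p = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        res = mt.procrustes(p, p)
        assert not res.unique
        assert res.rms < 1e-12


class TestMatchBundles:
    @pytest.fixture()
    def bundle(self):
        return mt.Bundle([wiggly(k) for k in range(6)], session_id="a")

    def test_self_match_is_identity(self, bundle):
        res = mt.match_bundles(bundle, bundle)
        assert len(res.pairs) == 6
        assert all(p.source == p.target for p in res.pairs)
        assert np.allclose(res.global_rotation, np.eye(3), atol=1e-9)
        assert np.allclose(res.global_translation, 0.0, atol=1e-9)

    def test_recovers_rigid_transform(self, bundle, rng):
        rot = random_rotation(rng)
        t = rng.normal(size=3) * 4
        moved = mt.Bundle([cg.apply_rigid(s, rot, t) for s in bundle],
                          session_id="b")
        res = mt.match_bundles(bundle, moved)
        assert len(res.pairs) == 6
        assert np.max(np.abs(res.global_rotation - rot)) < 1e-6
        assert np.max(np.abs(res.global_translation - t)) < 1e-6

    def test_disjoint_geometry_yields_no_match(self):
        helices = mt.Bundle([make_helix(a=3, b=4, turns=1.5)])
        lines = mt.Bundle([make_line(length=40)])
        with pytest.warns(UserWarning):
            res = mt.match_bundles(helices, lines,
                                   mt.MatchParams(ceiling=0.005))
        assert res.pairs == []
        assert res.unmatched_source == [0]

    def test_symmetry_up_to_inversion(self, bundle, rng):
        rot = random_rotation(rng)
        t = rng.normal(size=3) * 3
        moved = mt.Bundle([cg.apply_rigid(s, rot, t) for s in bundle])
        ab = mt.match_bundles(bundle, moved)
        ba = mt.match_bundles(moved, bundle)
        assert np.max(np.abs(ab.global_rotation @ ba.global_rotation
                             - np.eye(3))) < 1e-6

    def test_invariant_to_streamline_ordering(self, bundle):
        perm = [3, 1, 5, 0, 4, 2]
        shuffled = mt.Bundle([bundle.streamlines[i] for i in perm])
        res = mt.match_bundles(shuffled, bundle)
        assert sorted((perm[p.source], p.target) for p in res.pairs) == \
            [(k, k) for k in range(6)]

    def test_greedy_equals_bruteforce_on_random_bundles(self):
        # oracle: exhaustive minimum-total-distance assignment over all
        # permutations, on randomly generated bundle geometries (n <= 8)
        def random_curve(rng, n_pts=80, length=40.0):
            t = np.linspace(0, 1, n_pts)
            coef = rng.uniform(-6, 6, size=(2, 3))
            y = coef[0, 0] * np.sin(2 * t) + coef[0, 1] * np.sin(3 * t + coef[0, 2])
            z = coef[1, 0] * np.cos(2 * t) + coef[1, 1] * np.sin(4 * t + coef[1, 2])
            return cg.Streamline(np.stack([length * t, y, z], axis=1))

        agree, trials = 0, 30
        for trial in range(trials):
            rng = np.random.default_rng(7000 + trial)
            n = int(rng.integers(3, 9))
            src = [cg.resample(random_curve(rng), 1.0) for _ in range(n)]
            perm = rng.permutation(n)
            tgt = [cg.Streamline(src[p].points.copy()) for p in perm]
            dist = np.zeros((n, n))
            for i, a in enumerate(src):
                inv_a = cg.invariants(a)
                for j, b in enumerate(tgt):
                    imap = mt.index_correspondence(a, b, 1.0)
                    dist[i, j] = mt.feature_distance(inv_a, cg.invariants(
                        cg.resample(b, 1.0)), imap)
            greedy = mt._assignment(dist, ceiling=np.inf, optimal=False)
            best_cost = min(sum(dist[i, p[i]] for i in range(n))
                            for p in itertools.permutations(range(n)))
            g_cost = sum(dist[i, j] for i, j in greedy)
            if abs(g_cost - best_cost) < 1e-12:
                agree += 1
        assert agree / trials >= 0.95

    def test_json_serialization_roundtrip(self, bundle, tmp_path):
        import json

        res = mt.match_bundles(bundle, bundle)
        path = tmp_path / "match.json"
        res.to_json(path)
        doc = json.loads(path.read_text())
        assert len(doc["pairs"]) == 6
        assert np.allclose(doc["global_transform"], np.eye(4), atol=1e-9)
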