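"""Relative-growth scoring, plate normalization, classification, Venn regions."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from degronscreen import growth_screen as g
from degronscreen import synthetic_data as sim


def _plate(sizes, induced, media="rich", rep=1, plate_id="P1", strain_map=None):
    sizes = np.asarray(sizes, dtype=float)
    if strain_map is None:
        nrow, ncol = sizes.shape
        strain_map = {
            (r, c): f"s{r * ncol + c}" for r in range(nrow) for c in range(ncol)
        }
    return g.PlateGrid(plate_id, media, induced, rep, sizes, strain_map)


class TestScoreRelativeGrowth:
    def test_identical_plates_score_one(self):
        base = np.full((2, 3), 200.0)
        scores = g.score_relative_growth([_plate(base, True)], [_plate(base, False)])
        assert all(s.raw_ratio == pytest.approx(1.0) for s in scores)

    def test_lethal_strain_scores_zero(self):
        unind = np.full((1, 2), 200.0)
        ind = np.array([[0.0, 200.0]])
        scores = {
            s.strain_id: s.raw_ratio
            for s in g.score_relative_growth([_plate(ind, True)], [_plate(unind, False)])
        }
        assert scores["s0"] == 0.0 and scores["s1"] == pytest.approx(1.0)

    def test_replicates_averaged_before_ratio(self):
        # mean(80, 120) / mean(200, 200) = 0.5 -- hand arithmetic
        i1, i2 = _plate([[80.0]], True, rep=1), _plate([[120.0]], True, rep=2)
        u1, u2 = _plate([[200.0]], False, rep=1), _plate([[200.0]], False, rep=2)
        (score,) = g.score_relative_growth([i1, i2], [u1, u2])
        assert score.raw_ratio == pytest.approx(0.5)
        assert score.n_replicates == 2

    def test_absent_uninduced_flags_not_divides(self):
        unind = np.array([[20.0, 200.0]])  # 20 is under the presence threshold
        ind = np.array([[100.0, 100.0]])
        scores = {
            s.strain_id: s
            for s in g.score_relative_growth([_plate(ind, True)], [_plate(unind, False)])
        }
        assert scores["s0"].absent and np.isnan(scores["s0"].raw_ratio)
        assert scores["s1"].raw_ratio == pytest.approx(0.5)

    def test_mismatched_strain_maps_raise(self):
        a = _plate(np.ones((1, 2)), True)
        b = _plate(np.ones((1, 2)), False, strain_map={(0, 0): "x", (0, 1): "y"})
        with pytest.raises(ValueError, match="strain_map"):
            g.score_relative_growth([a], [b])

    def test_edge_boost_cancels_in_ratio(self):
        """Shared positional effects divide out of the induced/uninduced ratio."""
        cfg = sim.ScreenSimConfig(
            layout=(8, 12), n_strains=96, lethal_fraction=0.0, noise_cv=0.05,
            edge_boost=1.5, seed=13,
        )
        ind, unind, _ = sim.gen_plate_pair(cfg)
        scores = g.normalize_scores(g.score_relative_growth([ind], [unind]))
        edge_ids = {unind.strain_map[p] for p in unind.strain_map
                    if p[0] in (0, 7) or p[1] in (0, 11)}
        edge = [s.normalized_score for s in scores if s.strain_id in edge_ids]
        center = [s.normalized_score for s in scores if s.strain_id not in edge_ids]
        assert abs(np.mean(edge) - np.mean(center)) < 3 * 0.05  # within noise tolerance


class TestNormalizeScores:
    def test_constant_group_normalizes_to_one(self):
        scores = [g.RelativeGrowth(f"s{i}", "rich", 2.0, 2.0, 1, "P1") for i in range(5)]
        out = g.normalize_scores(scores)
        assert all(s.normalized_score == pytest.approx(1.0) for s in out)

    def test_lethal_outlier_excluded_from_plate_median(self):
        # {1.0 x9, 0.0}: the 0 is trimmed, factor = 1.0, lethal stays 0
        scores = [g.RelativeGrowth(f"s{i}", "rich", 1.0, 1.0, 1, "P1") for i in range(9)]
        scores.append(g.RelativeGrowth("dead", "rich", 0.0, 0.0, 1, "P1"))
        out = {s.strain_id: s.normalized_score for s in g.normalize_scores(scores)}
        assert out["s0"] == pytest.approx(1.0)
        assert out["dead"] == 0.0

    def test_systematic_plate_offset_aligns_distributions(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(0.0, 0.1, 200)
        p1 = [g.RelativeGrowth(f"a{i}", "rich", v, v, 1, "P1") for i, v in enumerate(base)]
        p2 = [g.RelativeGrowth(f"b{i}", "rich", 2 * v, 2 * v, 1, "P2") for i, v in enumerate(base)]
        out = g.normalize_scores(p1 + p2)
        n1 = sorted(s.normalized_score for s in out if s.plate_id == "P1")
        n2 = sorted(s.normalized_score for s in out if s.plate_id == "P2")
        # identical underlying values => normalization removes the 2x offset exactly
        np.testing.assert_allclose(n1, n2, rtol=1e-12)

    def test_small_group_skipped_with_warning(self):
        scores = [g.RelativeGrowth("s0", "rich", 0.8, 0.8, 1, "P1")]
        with pytest.warns(UserWarning, match="skipping"):
            out = g.normalize_scores(scores)
        assert out[0].normalized_score == pytest.approx(0.8)


class TestClassifyEssentiality:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (0.45, g.CLASS_SEVERE),  # below 0.5, not below 0.1
            (0.05, g.CLASS_STRINGENT),
            (1.0, g.CLASS_NONE),
            (0.5, g.CLASS_NONE),  # strict inequality at the threshold
            (0.1, g.CLASS_SEVERE),
            (float("nan"), g.CLASS_ABSENT),
        ],
    )
    def test_threshold_classes(self, score, expected):
        (call,) = g.classify_essentiality(
            [g.RelativeGrowth("s", "rich", score, score, 1)]
        )
        assert call.essentiality == expected

    def test_stringent_implies_severe(self):
        (call,) = g.classify_essentiality([g.RelativeGrowth("s", "rich", 0.05, 0.05, 1)])
        assert call.severe

    def test_lowering_threshold_never_adds_severe_strains(self):
        rng = np.random.default_rng(1)
        scores = [
            g.RelativeGrowth(f"s{i}", "rich", v, v, 1)
            for i, v in enumerate(rng.uniform(0, 1.5, 200))
        ]
        severe_at = {}
        for thr in (0.6, 0.5, 0.4, 0.3):
            calls = g.classify_essentiality(scores, permissive=thr)
            severe_at[thr] = {c.strain_id for c in calls if c.severe}
        for hi, lo in itertools.pairwise((0.6, 0.5, 0.4, 0.3)):
            assert severe_at[lo] <= severe_at[hi]


class TestMediaPartition:
    def test_identical_sets_fill_triple_intersection(self):
        s = {"x", "y"}
        part = g.media_partition({"rich": s, "minimal": s, "respiration": s})
        assert part.region("rich", "minimal", "respiration") == s
        assert all(not v for k, v in part.regions.items() if len(k) < 3)

    def test_worked_membership_table(self):
        part = g.media_partition({"A": {"x", "y"}, "B": {"y", "z"}, "C": {"y"}})
        assert part.region("A", "B", "C") == {"y"}
        assert part.exclusive["A"] == {"x"}
        assert part.exclusive["B"] == {"z"}
        assert part.exclusive["C"] == set()

    def test_disjoint_sets_are_all_exclusive(self):
        part = g.media_partition({"A": {"a"}, "B": {"b"}})
        assert part.exclusive == {"A": {"a"}, "B": {"b"}}

    @settings(derandomize=True, max_examples=50, database=None)
    @given(
        sets=st.lists(
            st.sets(st.integers(0, 30), max_size=15), min_size=2, max_size=4
        )
    )
    def test_regions_partition_the_union(self, sets):
        hit_sets = {f"m{i}": s for i, s in enumerate(sets)}
        part = g.media_partition(hit_sets)
        regions = list(part.regions.values())
        union = set().union(*hit_sets.values())
        assert part.union_size == len(union)
        assert set().union(*regions) == union if regions else not union
        for a, b in itertools.combinations(regions, 2):
            assert not (a & b)


class TestColonyPresence:
    def test_strictly_over_threshold(self):
        present, rate = g.colony_presence([51.0, 50.0])
        assert present.tolist() == [True, False] and rate == 0.5

    def test_all_zero_survival(self):
        _, rate = g.colony_presence(np.zeros(10))
        assert rate == 0.0

    def test_survival_counting(self):
        sizes = np.array([100.0] * 92 + [10.0] * 8)
        present, rate = g.colony_presence(sizes)
        assert present.sum() == 92 and rate == pytest.approx(0.92)
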