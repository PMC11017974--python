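import pytest

from conftest import make_colony
from redialab.datamodel import (
    ActivityRecord,
    AttackTrial,
    Colony,
    Extremum,
    PresenceScores,
    RediaRecord,
    Section,
    SizeClass,
    SizeLabel,
    TargetType,
)
from redialab import patterns as pt


def scores_for(extremum, anterior, posterior, embryo):
    return [
        PresenceScores(f"{extremum.value}-{i}", extremum, a, p, e)
        for i, (a, p, e) in enumerate(zip(anterior, posterior, embryo))
    ]


class TestPharynxPattern:
    def test_clear_separation_significant(self):
        colony = make_colony(
            small_rel_pharynx=[0.03, 0.028, 0.027, 0.026],
            large_rel_pharynx=[0.010, 0.011, 0.012, 0.013],
        )
        res = pt.pharynx_pattern(colony)
        assert res.code == "Y"
        assert res.statistics["p_value"] == pytest.approx(1 / 70)

    def test_missing_class_measurements_give_na(self):
        colony = make_colony(
            small_rel_pharynx=[0.03, 0.02], large_rel_pharynx=[None, None]
        )
        assert pt.pharynx_pattern(colony).code == "NA"

    def test_identical_distributions_not_significant(self):
        colony = make_colony(
            small_rel_pharynx=[0.02, 0.02, 0.02], large_rel_pharynx=[0.02, 0.02, 0.02]
        )
        assert pt.pharynx_pattern(colony).code == "N"


class TestAppendagePattern:
    def test_both_appendages_separated(self):
        scores = scores_for(
            Extremum.SMALLEST5, [4] * 5, [4] * 5, [0] * 5
        ) + scores_for(Extremum.LARGEST5, [0] * 5, [0] * 5, [4] * 5)
        res = pt.appendage_pattern(scores)
        assert res.code == "Y"
        assert res.statistics["p_anterior_score"] == pytest.approx(1 / 252)
        assert res.statistics["p_posterior_score"] == pytest.approx(1 / 252)

    def test_one_appendage_only(self):
        scores = scores_for(
            Extremum.SMALLEST5, [4] * 5, [2] * 5, [0] * 5
        ) + scores_for(Extremum.LARGEST5, [0] * 5, [2] * 5, [4] * 5)
        assert pt.appendage_pattern(scores).code == "O"

    def test_no_difference(self):
        scores = scores_for(
            Extremum.SMALLEST5, [3] * 5, [3] * 5, [4] * 5
        ) + scores_for(Extremum.LARGEST5, [3] * 5, [3] * 5, [4] * 5)
        assert pt.appendage_pattern(scores).code == "N"

    def test_missing_group_is_na(self):
        scores = scores_for(Extremum.SMALLEST5, [4] * 5, [4] * 5, [0] * 5)
        assert pt.appendage_pattern(scores).code == "NA"


class TestReproductionCode:
    @pytest.mark.parametrize(
        "embryo,expected",
        [
            ([0, 1, 2, 4, 3], "Y"),
            ([2, 2, 3], "Y?"),
            ([1, 2, 2], "U"),
            ([0, 1, 1], "N"),
        ],
    )
    def test_max_embryo_score_mapping(self, embryo, expected):
        scores = scores_for(
            Extremum.SMALLEST5, [0] * len(embryo), [0] * len(embryo), embryo
        )
        assert pt.reproduction_code(scores).code == expected

    def test_no_smallest_scores_na(self):
        scores = scores_for(Extremum.LARGEST5, [0], [0], [4])
        assert pt.reproduction_code(scores).code == "NA"


class TestPercentSmall:
    def _colony(self, n_small, n_large):
        colony = make_colony(
            small_rel_pharynx=[0.02] * n_small, large_rel_pharynx=[0.01] * n_large
        )
        return colony

    def test_bimodal_percentage(self):
        res = pt.percent_small(self._colony(20, 80), "Y")
        assert res.code == "20%"
        assert res.statistics["pct_small"] == pytest.approx(20.0)

    def test_non_bimodal_is_na(self):
        assert pt.percent_small(self._colony(20, 80), "N*").code == "NA"

    def test_zero_small_warns_in_notes(self):
        res = pt.percent_small(self._colony(0, 50), "Y")
        assert res.code == "0%"
        assert "no small rediae" in res.notes


class TestSpatialDistribution:
    def _colony(self, foot, apical, mid=None):
        colony = Colony(colony_id="C1")
        i = 0
        layout = {Section.FOOT: foot, Section.APICAL: apical}
        if mid:
            layout[Section.MID] = mid
        for section, (n_small, n_large) in layout.items():
            for cls, n in ((SizeClass.SMALL, n_small), (SizeClass.LARGE, n_large)):
                for _ in range(n):
                    i += 1
                    r = RediaRecord(f"r{i}", "C1", section=section,
                                    length_um=100.0, width_um=20.0)
                    r.size_class = cls
                    colony.records.append(r)
        return colony

    def test_disjoint_intervals_anterior_enriched(self):
        res = pt.spatial_distribution(self._colony(foot=(40, 10), apical=(10, 40)))
        assert res.code == "Y"
        assert res.statistics["ci_anterior"] == pytest.approx((0.663, 0.900), abs=5e-4)
        assert res.statistics["ci_apical"] == pytest.approx((0.100, 0.337), abs=5e-4)

    def test_overlapping_intervals(self):
        res = pt.spatial_distribution(self._colony(foot=(8, 2), apical=(2, 8)))
        assert res.code == "O"
        assert res.statistics["ci_anterior"] == pytest.approx((0.444, 0.975), abs=5e-4)

    def test_reverse_gradient(self):
        res = pt.spatial_distribution(self._colony(foot=(10, 40), apical=(40, 10)))
        assert res.code == "N"

    def test_mid_substitutes_for_empty_foot(self):
        res = pt.spatial_distribution(
            self._colony(foot=(0, 0), apical=(10, 40), mid=(40, 10))
        )
        assert res.code == "Y"
        assert res.statistics["anterior_section"] == "mid"

    def test_sections_unavailable(self):
        colony = Colony(colony_id="C1")
        r = RediaRecord("r1", "C1", length_um=100.0, width_um=20.0)
        r.size_class = SizeClass.SMALL
        colony.records.append(r)
        assert pt.spatial_distribution(colony).code == "NA"


class TestActivity:
    def _records(self, small_rel, large_rel, length=100.0):
        recs = []
        for label, rels in ((SizeLabel.SMALL, small_rel), (SizeLabel.LARGE, large_rel)):
            for i, rel in enumerate(rels):
                recs.append(
                    ActivityRecord(
                        f"{label.value}{i}", label,
                        distance_t0_um=rel * length,
                        distance_t15_um=rel * length,
                        body_length_um=length,
                    )
                )
        return recs

    def test_timepoints_averaged(self):
        rec = ActivityRecord("r", SizeLabel.SMALL, 10.0, 20.0, 100.0)
        assert rec.mean_distance_um == pytest.approx(15.0)
        single = ActivityRecord("r", SizeLabel.SMALL, 10.0, None, 100.0)
        assert single.mean_distance_um == pytest.approx(10.0)

    def test_small_shift_not_significant_two_tailed(self):
        recs = self._records([0.10, 0.11, 0.12], [0.02, 0.02, 0.03])
        res = pt.activity_comparison(recs)
        assert res.code == "NS"  # two-tailed exact p = 2/20 = 0.1
        assert res.statistics["p_relative"] == pytest.approx(0.1)
        assert res.statistics["more_active_class"] == "small"

    def test_one_size_class_missing(self):
        recs = self._records([0.1, 0.2], [])
        assert pt.activity_comparison(recs).code == "NA"


class TestAttacks:
    def _trial(self, size, n_attacks, target=TargetType.HETEROSPECIFIC):
        return AttackTrial(f"t-{size.value}-{n_attacks}", size, target, n_attacks, 10)

    def test_large_outnumber_small(self):
        res = pt.attack_summary(
            [self._trial(SizeLabel.LARGE, 2), self._trial(SizeLabel.SMALL, 1)]
        )
        assert res.code == "N"
        assert res.statistics["attacks_small"] == 1

    def test_small_outnumber_large(self):
        res = pt.attack_summary(
            [self._trial(SizeLabel.SMALL, 3), self._trial(SizeLabel.LARGE, 0)]
        )
        assert res.code == "Y"

    def test_no_trials(self):
        assert pt.attack_summary([]).code == "NA"


class TestOutliers:
    def test_worked_fence_example(self):
        res = pt.pharynx_outliers([5, 5, 6, 6, 7, 7, 8, 30])
        assert (res.q1, res.q3) == pytest.approx((5.75, 7.25))
        assert res.upper_fence == pytest.approx(9.5)
        assert res.outlier_ids == ["7"]
        assert res.outlier_fraction == pytest.approx(0.125)

    def test_no_outliers(self):
        res = pt.pharynx_outliers([1, 2, 3, 4])
        assert res.outlier_ids == []
        assert res.outlier_fraction == 0

    def test_too_few_measurements(self):
        with pytest.raises(ValueError):
            pt.pharynx_outliers([1, 2, 3])

    @pytest.mark.parametrize(
        "fraction,expected", [(0.10, "Y"), (0.01, "N"), (0.05, "Y")]
    )
    def test_large_pharynx_flag_threshold_inclusive(self, fraction, expected):
        outl = pt.OutlierResult(1, 2, 1, 3.5, ["x"], fraction, 100)
        assert pt.large_pharynx_flag(outl, 0.05).code == expected
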