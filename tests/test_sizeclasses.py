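"""Size-caste designation: normality screen, default histogram breaks,
trough detection and class assignment.

Histogram breakpoints are checked against values frozen from R 4.3.3's
``hist()`` (Sturges class count + pretty breakpoints), the environment whose
defaults this module reproduces; Shapiro-Wilk values are frozen from R's
``shapiro.test``.
"""

import numpy as np
import pytest

from redialab.config import AnalysisConfig
from redialab.datamodel import SizeClass
from redialab.sizeclasses import (
    assign_size_classes,
    bin_counts,
    default_histogram_breaks,
    detect_bimodality,
    log_volume_normality,
    volume_pattern_code,
)


class TestNormality:
    def test_matches_r_shapiro(self):
        # frozen from R: shapiro.test(log-scale data below)
        x = [5.1, 4.9, 6.2, 5.5, 5.8, 4.7, 6.0, 5.3, 5.9, 5.05]
        res = log_volume_normality(np.exp(x))  # module logs internally
        assert res.W_statistic == pytest.approx(0.9507134338, abs=1e-6)
        assert res.p_value == pytest.approx(0.6769467008, abs=1e-6)
        assert res.n == 10

    def test_too_few_volumes(self):
        with pytest.raises(ValueError):
            log_volume_normality([1.0, 2.0])

    def test_degenerate_equal_volumes(self):
        with pytest.raises(ValueError):
            log_volume_normality([3.0] * 10)


class TestDefaultBreaks:
    # each case frozen from R: hist(v, plot=FALSE)$breaks
    @pytest.mark.parametrize(
        "values,expected",
        [
            (np.linspace(0.3, 9.7, 30), [0, 2, 4, 6, 8, 10]),
            ([0.1, 0.9], [0, 0.5, 1]),
            (np.linspace(2.13, 7.89, 100), [2, 3, 4, 5, 6, 7, 8]),
            (
                [10, 20, 100, 150, 151, 152, 300, 1000, 2000, 2500],
                [0, 500, 1000, 1500, 2000, 2500],
            ),
            (np.linspace(-3.2, 4.8, 57), [-4, -3, -2, -1, 0, 1, 2, 3, 4, 5]),
            (
                np.linspace(0.001, 0.009, 200),
                [0.001, 0.002, 0.003, 0.004, 0.005, 0.006, 0.007, 0.008, 0.009],
            ),
        ],
    )
    def test_matches_r_hist_defaults(self, values, expected):
        assert default_histogram_breaks(values) == pytest.approx(expected)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            default_histogram_breaks([1.0])
        with pytest.raises(ValueError):
            default_histogram_breaks([2.0, 2.0, 2.0])

    def test_every_value_binned_exactly_once(self, rng):
        v = rng.normal(5, 2, size=100)
        breaks = default_histogram_breaks(v)
        counts = bin_counts(v, breaks)
        assert sum(counts) == 100
        assert all(b2 > b1 for b1, b2 in zip(breaks, breaks[1:]))

    def test_right_closed_bins(self):
        # a value on an interior break belongs to the bin it closes
        counts = bin_counts([0.5, 1.0, 1.5, 2.0], [0, 1, 2])
        assert counts == [2, 2]


class TestBimodality:
    def test_separated_mixture_detected_with_cutoff_between_modes(self, rng):
        logv = np.concatenate([rng.normal(1, 0.15, 50), rng.normal(2, 0.15, 50)])
        res = detect_bimodality(10.0**logv, AnalysisConfig())
        assert res.is_bimodal
        assert res.method == "histogram_trough"
        assert 10 < res.cutoff_volume_um3 < 100
        # the trough is the emptiest bin strictly between the two peaks
        p1, p2 = res.peak_bins
        between = res.counts[p1 + 1 : p2]
        assert res.counts[res.trough_bin] == min(between)
        assert p1 < res.trough_bin < p2

    def test_single_mode_rarely_called_bimodal(self):
        calls = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            v = 10.0 ** r.normal(1.5, 0.2, 100)
            calls += detect_bimodality(v, AnalysisConfig()).is_bimodal
        assert calls <= 10

    def test_small_sample_falls_back_to_quartiles(self, rng):
        res = detect_bimodality(10.0 ** rng.normal(1, 0.2, 10), AnalysisConfig())
        assert not res.is_bimodal
        assert res.method == "quartile_fallback"

    def test_manual_override(self):
        res = detect_bimodality([1.0, 2.0, 3.0], manual_cutoff_um3=31.6)
        assert res.is_bimodal and res.method == "manual_override"


class TestAssignment:
    def test_quartile_mode_on_one_to_eight(self):
        from redialab.sizeclasses import BimodalityResult

        fallback = BimodalityResult(False, "quartile_fallback")
        labels = assign_size_classes([1, 2, 3, 4, 5, 6, 7, 8], fallback)
        assert labels[:2] == [SizeClass.SMALL] * 2  # Q1 = 2.75
        assert labels[-2:] == [SizeClass.LARGE] * 2  # Q3 = 6.25
        assert labels[2:6] == [SizeClass.INTERMEDIATE] * 4

    def test_trough_mode_cutoff(self):
        from redialab.sizeclasses import BimodalityResult

        bi = BimodalityResult(True, "histogram_trough", cutoff_volume_um3=31.6)
        labels = assign_size_classes([10, 20, 100], bi)
        assert labels == [SizeClass.SMALL, SizeClass.SMALL, SizeClass.LARGE]

    def test_all_equal_warns_and_labels_small(self):
        from redialab.sizeclasses import BimodalityResult

        with pytest.warns(UserWarning):
            labels = assign_size_classes(
                [5.0, 5.0, 5.0], BimodalityResult(False, "quartile_fallback")
            )
        assert set(labels) == {SizeClass.SMALL}

    def test_empty_input_rejected(self):
        from redialab.sizeclasses import BimodalityResult

        with pytest.raises(ValueError):
            assign_size_classes([], BimodalityResult(False, "quartile_fallback"))

    def test_labels_partition_and_are_monotone(self, rng):
        """Every redia gets a label and no small volume exceeds a large one."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            v = 10.0 ** np.concatenate([r.normal(1, 0.15, 60), r.normal(2, 0.15, 60)])
            bi = detect_bimodality(v, AnalysisConfig())
            labels = assign_size_classes(v, bi)
            assert len(labels) == len(v)
            smalls = [x for x, l in zip(v, labels) if l is SizeClass.SMALL]
            larges = [x for x, l in zip(v, labels) if l is SizeClass.LARGE]
            if smalls and larges:
                assert max(smalls) <= min(larges)


@pytest.mark.parametrize(
    "p,bimodal,expected",
    [(0.001, True, "Y"), (0.001, False, "N*"), (0.30, True, "N"), (0.30, False, "N")],
)
def test_volume_pattern_code(p, bimodal, expected):
    from redialab.sizeclasses import BimodalityResult, NormalityResult

    norm = NormalityResult(0.95, p, 50)
    bi = BimodalityResult(bimodal, "histogram_trough" if bimodal else "quartile_fallback")
    assert volume_pattern_code(norm, bi, alpha=0.05) == expected
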