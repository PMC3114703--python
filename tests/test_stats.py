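"""Stimulation statistic and supporting ANOVA / paired-t comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microloop import (AbundanceSeries, DegenerateDataError, InputError,
                       SimulationParams, make_bundle, one_way_anova,
                       paired_t, stimulation, stimulation_from_values,
                       stimulation_replicates, summarize_stimulation)


def series(counts, treatment="V"):
    return AbundanceSeries(experiment="E", treatment=treatment, replicate=0,
                           variable="bacteria",
                           times=np.array([0.0, 48.0]),
                           counts=np.asarray(counts, float))


class TestStimulation:
    def test_identical_series_give_zero(self):
        s = series([1e6, 2e6])
        t = series([1e6, 2e6], "VF")
        assert stimulation(t, s, 0, 48) == 0.0

    def test_doubling_vs_tripling_gives_plus_100(self):
        v = series([1e6, 2e6])          # +100%
        vf = series([1e6, 3e6], "VF")   # +200%
        assert stimulation(vf, v, 0, 48) == pytest.approx(100.0)

    def test_hand_arithmetic_example(self):
        v = series([2.0e6, 2.6e6])
        vfa = series([1.9e6, 3.1e6], "VFA")
        got = stimulation(vfa, v, 0, 48)
        assert got == pytest.approx(100 * (1.2 / 1.9 - 0.6 / 2.0), abs=1e-9)
        assert round(got, 1) == 33.2

    def test_antisymmetric_under_swap(self):
        v = series([2.0e6, 2.6e6])
        vf = series([1.9e6, 3.1e6], "VF")
        assert stimulation(vf, v, 0, 48) == pytest.approx(
            -stimulation(v, vf, 0, 48))

    @given(a=st.floats(0.1, 10), b=st.floats(0.1, 10))
    @settings(max_examples=30, derandomize=True)
    def test_invariant_to_rescaling_either_series(self, a, b):
        got = stimulation_from_values(1.9e6 * a, 3.1e6 * a,
                                      2.0e6 * b, 2.6e6 * b)
        assert got == pytest.approx(100 * (1.2 / 1.9 - 0.6 / 2.0),
                                    rel=1e-9)

    def test_zero_start_rejected(self):
        with pytest.raises(InputError):
            stimulation_from_values(0.0, 1.0, 1.0, 2.0)

    def test_absolute_mode_differs(self):
        rel = stimulation_from_values(1e6, 2e6, 1e6, 1.5e6, mode="relative")
        ab = stimulation_from_values(1e6, 2e6, 1e6, 1.5e6, mode="absolute")
        assert rel == pytest.approx(50.0)
        assert ab == pytest.approx(50.0)  # equal baselines coincide
        assert stimulation_from_values(2e6, 4e6, 1e6, 1.5e6,
                                       mode="absolute") == \
            pytest.approx(150.0)


class TestOneWayAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        res = one_way_anova([[1, 2, 3]] * 3)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert not res.significant

    def test_two_groups_f_equals_t_squared(self):
        from scipy import stats as sps
        a, b = [1.0, 2.0, 3.0], [2.5, 3.5, 4.5]
        res = one_way_anova([a, b])
        t, _ = sps.ttest_ind(a, b)
        assert res.statistic == pytest.approx(t ** 2, rel=1e-12)

    def test_matches_sum_of_squares_oracle(self):
        """F agrees with a from-scratch SS decomposition."""
        groups = [[1, 2, 3], [2, 3, 4], [6, 7, 8]]
        res = one_way_anova(groups)
        data = np.concatenate(groups).astype(float)
        grand = data.mean()
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(sum((x - np.mean(g)) ** 2 for x in g) for g in groups)
        f_oracle = (ssb / 2) / (ssw / 6)
        assert res.statistic == pytest.approx(f_oracle, rel=1e-12)

    def test_protected_lsd_only_when_omnibus_significant(self):
        sig = one_way_anova([[1, 2, 3], [2, 3, 4], [6, 7, 8]],
                            labels=["a", "b", "c"])
        assert sig.significant and sig.posthoc is not None
        assert sig.posthoc[("a", "c")] < 0.05
        nsig = one_way_anova([[1, 2, 3], [1.1, 2.1, 3.1]])
        assert not nsig.significant and nsig.posthoc is None

    def test_degenerate_groups_rejected(self):
        with pytest.raises(InputError):
            one_way_anova([[1.0], [2.0]])


class TestPairedT:
    def test_equal_samples_give_t_zero_p_one(self):
        res = paired_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_constant_nonzero_difference_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            paired_t([1, 2, 3], [2, 3, 4])

    def test_matches_direct_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 2.0, 4.0, 5.0])
        res = paired_t(x, y)
        d = x - y
        t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(d.size))
        assert res.statistic == pytest.approx(t_oracle, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            paired_t([1, 2], [1, 2, 3])


class TestSummarize:
    @staticmethod
    def _bundles(cv=0.0, seed=0, labels=("LA1", "LA2", "LB1", "LB2")):
        out = []
        for i, label in enumerate(labels):
            params = SimulationParams(mu_b=0.5, delta_v=0.1, graze=0.2,
                                      enrich=0.3, autotroph_boost=0.0,
                                      cv_noise=cv, seed=seed + i)
            out.append(make_bundle(params, replicates=3, label=label,
                                   assay_days=()))
        return out

    def test_identical_treatments_give_all_zero(self, quiet_params):
        import dataclasses
        params = dataclasses.replace(quiet_params, graze=0.0, enrich=0.0,
                                     autotroph_boost=0.0)
        bundle = make_bundle(params, replicates=2, label="LA1",
                             assay_days=())
        table, _ = summarize_stimulation([bundle])
        assert np.allclose(table.stimulation_pct, 0.0, atol=1e-9)

    def test_noise_free_bundles_have_equal_cells_and_flat_contrasts(self):
        table, contrasts = summarize_stimulation(self._bundles())
        by_cell = table.groupby(["treatment", "window"]).stimulation_pct
        # identical generator in every experiment: all cells equal
        assert by_cell.std().max() == pytest.approx(0.0, abs=1e-9)
        # contrasts on identical values: t = 0 (or degenerate/absent)
        for res in contrasts.values():
            assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_per_replicate_values_average_to_summary(self, quiet_bundle):
        res = stimulation_replicates(quiet_bundle, "VF", (0.0, 48.0))
        assert res.stimulation == pytest.approx(
            np.mean(res.per_replicate))
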