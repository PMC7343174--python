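"""Subset enumeration, noise-substitution scan, profiles, time windows."""

import math

import numpy as np
import pytest

import graspid as g
from graspid.errors import ConfigurationError
from graspid.sensitivity import derive_seed, subset_count, time_window_scan


class TestEnumeration:
    def test_full_feature_space_count(self):
        """Sizes 2-14 over 15 features: 32,751 subsets."""
        subsets = g.enumerate_subsets(15, 2, 14)
        assert len(subsets) == 32751
        assert len(set(subsets)) == 32751  # each exactly once

    @pytest.mark.parametrize("n,lo,hi,expected", [(3, 2, 2, 3), (5, 2, 4, 25)])
    def test_small_counts(self, n, lo, hi, expected):
        assert len(g.enumerate_subsets(n, lo, hi)) == expected

    def test_matches_closed_form_for_all_small_n(self):
        for n in range(1, 11):
            for lo in range(1, n + 1):
                for hi in range(lo, n + 1):
                    expected = sum(math.comb(n, s) for s in range(lo, hi + 1))
                    assert len(g.enumerate_subsets(n, lo, hi)) == expected
                    assert subset_count(n, lo, hi) == expected

    def test_deterministic_order(self):
        assert g.enumerate_subsets(4, 2, 3)[:3] == [(0, 1), (0, 2), (0, 3)]

    def test_invalid_bounds(self):
        with pytest.raises(ConfigurationError):
            g.enumerate_subsets(5, 3, 2)
        with pytest.raises(ConfigurationError):
            g.enumerate_subsets(5, 0, 2)


class TestSubsetQuality:
    def test_full_subset_equals_main_pipeline(self, planted_coded, fast_settings):
        """Keeping all features performs no substitution: quality equals the
        plain pipeline run at the same derived seeds."""
        _, ds = planted_coded
        full = tuple(range(ds.n_features))
        q = g.subset_quality(ds, full, settings=fast_settings, n_repeats=2, master_seed=5)
        accs = []
        for repeat in range(2):
            seed = derive_seed(5, full, repeat)
            emb = g.embed(ds, dims=3, perplexity=10, seed=seed, max_iter=300)
            accs.append(g.cross_validate(emb, ds.subjects, seed=seed).mean_accuracy)
        assert q == pytest.approx(np.mean(accs))

    def test_repeatable(self, planted_coded, fast_settings):
        _, ds = planted_coded
        q1 = g.subset_quality(ds, (0, 2), settings=fast_settings, n_repeats=1, master_seed=3)
        q2 = g.subset_quality(ds, (0, 2), settings=fast_settings, n_repeats=1, master_seed=3)
        assert q1 == q2

    def test_noise_only_subset_is_chance(self, fast_settings):
        """A subset of pure-noise features on coded data classifies at
        chance level."""
        informative, ds = ((0, 2, 5), None)
        ds = g.generate_feature_dataset(n_subjects=8, n_trials_per_subject=7,
                                        informative=informative, n_features=8,
                                        n_samples=150, effect_scale=2.0,
                                        structure="coded", seed=1)
        q = g.subset_quality(ds, (1, 3, 4), settings=fast_settings,
                             n_repeats=2, master_seed=0)
        assert abs(q - 1 / 8) < 0.15

    def test_empty_subset_rejected(self, planted_coded):
        _, ds = planted_coded
        with pytest.raises(ConfigurationError):
            g.subset_quality(ds, ())


class TestScan:
    def test_single_object_aggregate_equals_object_table(self, planted_coded, fast_settings):
        _, ds = planted_coded
        subsets = g.enumerate_subsets(8, 2, 2)[:6]
        scan = g.sensitivity_scan({"obj": ds}, subsets=subsets,
                                  settings=fast_settings, n_repeats=1, master_seed=0)
        assert scan.aggregate == scan.per_object["obj"]

    def test_identical_objects_average_to_either(self, planted_coded, fast_settings):
        _, ds = planted_coded
        subsets = [(0, 2), (1, 3)]
        scan = g.sensitivity_scan({"a": ds, "b": ds}, subsets=subsets,
                                  settings=fast_settings, n_repeats=1, master_seed=0)
        for s in subsets:
            assert scan.aggregate[s] == pytest.approx(scan.per_object["a"][s])

    def test_results_independent_of_subset_order(self, planted_coded, fast_settings):
        _, ds = planted_coded
        subsets = [(0, 2), (1, 4), (0, 5)]
        fwd = g.sensitivity_scan({"obj": ds}, subsets=subsets,
                                 settings=fast_settings, n_repeats=1, master_seed=9)
        rev = g.sensitivity_scan({"obj": ds}, subsets=subsets[::-1],
                                 settings=fast_settings, n_repeats=1, master_seed=9)
        assert fwd.aggregate == rev.aggregate

    def test_mismatched_feature_counts_rejected(self, planted_coded, fast_settings):
        import dataclasses

        _, ds = planted_coded
        truncated = dataclasses.replace(
            ds, values=ds.values[:, :5, :], feature_names=ds.feature_names[:5]
        )
        with pytest.raises(ConfigurationError):
            g.sensitivity_scan({"a": ds, "b": truncated},
                               subsets=[(0, 1)], settings=fast_settings)


@pytest.fixture(scope="module")
def small_scan(planted_coded, fast_settings):
    _, ds = planted_coded
    return g.sensitivity_scan({"obj": ds}, settings=fast_settings,
                              n_repeats=1, master_seed=0, min_size=2, max_size=4)


class TestProfilesAndBest:

    def test_min_le_mean_le_max(self, small_scan):
        t = g.size_profile(small_scan).table
        assert (t["min"] <= t["mean"] + 1e-12).all()
        assert (t["mean"] <= t["max"] + 1e-12).all()

    def test_single_subset_size_collapses(self, planted_coded, fast_settings):
        _, ds = planted_coded
        scan = g.sensitivity_scan({"obj": ds}, subsets=[(0, 1, 2)],
                                  settings=fast_settings, n_repeats=1, master_seed=0)
        t = g.size_profile(scan).table
        assert t["max"].iloc[0] == t["mean"].iloc[0] == t["min"].iloc[0]

    def test_best_subset_is_argmax(self, small_scan):
        subset, quality = g.best_subset(small_scan, size=3)
        size3 = {s: q for s, q in small_scan.aggregate.items() if len(s) == 3}
        assert quality == max(size3.values())
        assert size3[subset] == quality

    def test_best_subset_recovers_planted_code(self, planted_coded, fast_settings):
        informative, ds = planted_coded
        scan = g.sensitivity_scan(
            {"obj": ds}, subsets=g.enumerate_subsets(8, 3, 3),
            settings=fast_settings, n_repeats=1, master_seed=0,
        )
        subset, _ = g.best_subset(scan, size=3)
        assert subset == informative

    def test_unscanned_size_rejected(self, small_scan):
        with pytest.raises(ConfigurationError):
            g.best_subset(small_scan, size=7)


class TestTimeWindows:
    def test_window_count(self, planted_coded, fast_settings):
        _, ds = planted_coded  # 150 samples
        tw = time_window_scan(ds, window_width=50, settings=fast_settings,
                              n_repeats=1, master_seed=0)
        assert len(tw) == 3 and list(tw["start"]) == [0, 50, 100]

    def test_full_width_window_equals_plain_pipeline(self, planted_coded, fast_settings):
        _, ds = planted_coded
        tw = time_window_scan(ds, window_width=ds.n_samples,
                              settings=fast_settings, n_repeats=1, master_seed=4)
        assert len(tw) == 1
        seed = derive_seed(4, (0, ds.n_samples), 0)
        emb = g.embed(ds, dims=3, perplexity=10, seed=seed, max_iter=300)
        expected = g.cross_validate(emb, ds.subjects, seed=seed).mean_accuracy
        assert tw["quality"].iloc[0] == pytest.approx(expected)

    def test_planted_interval_is_most_informative(self, fast_settings):
        """Signal confined to one time interval: that window scores best."""
        import dataclasses

        ds = g.generate_feature_dataset(n_subjects=8, n_trials_per_subject=7,
                                        informative=tuple(range(8)), n_features=8,
                                        n_samples=150, effect_scale=2.0,
                                        noise_scale=0.4, structure="coded", seed=2)
        rng = np.random.default_rng(0)
        values = rng.standard_normal(ds.values.shape)
        values[:, :, 50:100] = ds.values[:, :, 50:100]  # keep middle third only
        planted_ds = dataclasses.replace(ds, values=values)
        tw = time_window_scan(planted_ds, window_width=50, settings=fast_settings,
                              n_repeats=2, master_seed=0)
        assert int(tw.loc[tw["quality"].idxmax(), "start"]) == 50

    def test_invalid_width(self, planted_coded):
        _, ds = planted_coded
        with pytest.raises(ConfigurationError):
            time_window_scan(ds, window_width=0)
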