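"""Subset geometry, contribution algorithm, HG correlation, subset comparison."""

import numpy as np
import pytest

import ecogpipe as ep
from ecogpipe.errors import DegenerateLabelsError, InvalidArgumentError
from ecogpipe.spatial import _first_peak
from ecogpipe.synthetic import NoiseModel, TuningMap, synthesize_session

from conftest import make_planted_session


class TestDensitySubsets:
    def test_stride_channel_counts_and_densities(self):
        lay = ep.build_layout(16, 16, 1250.0, 850.0)
        subs = ep.density_subsets(lay)
        area_cm2 = (16 * 0.125) ** 2
        counts = {s.stride: s.n_channels for s in subs}
        assert counts == {8: 4, 4: 16, 2: 64, 1: 256}
        densities = {s.stride: s.n_channels / area_cm2 for s in subs}
        assert densities[1] == pytest.approx(64.0)
        assert densities[2] == pytest.approx(16.0)
        assert densities[8] == pytest.approx(1.0)

    def test_anchored_top_left(self):
        lay = ep.build_layout(8, 8, 1250.0, 850.0)
        (sub,) = ep.density_subsets(lay, strides=(4,))
        assert sub.channel_indices.tolist() == [0, 4, 32, 36]

    def test_stride_validation(self):
        lay = ep.build_layout(4, 4, 1250.0, 850.0)
        with pytest.raises(InvalidArgumentError):
            ep.density_subsets(lay, strides=(8,))
        rect = ep.build_layout(4, 6, 1250.0, 850.0)
        with pytest.raises(InvalidArgumentError):
            ep.density_subsets(rect)


class TestCenteredGridSubsets:
    def test_full_size_is_identity(self):
        lay = ep.build_layout(16, 16, 1250.0, 850.0)
        (sub,) = ep.centered_grid_subsets(lay, [16])
        assert sub.n_channels == 256
        assert np.array_equal(sub.channel_indices, np.arange(256))

    def test_central_block(self):
        lay = ep.build_layout(16, 16, 1250.0, 850.0)
        (sub,) = ep.centered_grid_subsets(lay, [4])
        rows = sub.channel_indices // 16
        cols = sub.channel_indices % 16
        assert set(rows) == {6, 7, 8, 9}
        assert set(cols) == {6, 7, 8, 9}

    def test_strict_nesting(self):
        lay = ep.build_layout(16, 16, 1250.0, 850.0)
        subs = ep.centered_grid_subsets(lay, range(16, 3, -2))
        for big, small in zip(subs, subs[1:]):
            assert set(small.channel_indices) < set(big.channel_indices)

    def test_size_validation(self):
        lay = ep.build_layout(8, 8, 1250.0, 850.0)
        with pytest.raises(InvalidArgumentError):
            ep.centered_grid_subsets(lay, [0])


class TestSubsamplePerformance:
    def test_duplicate_subsets_identical(self, small_data):
        fm, al = small_data["fm"], small_data["al"]
        lay = small_data["session"].layout
        (sub,) = ep.density_subsets(lay, strides=(2,))
        perf = ep.subsample_performance(fm, al, [sub, sub], seed=3)
        assert perf.mean_cc[0] == perf.mean_cc[1]

    def test_density_monotone_with_repeats(self):
        # fresh noise realisations per repeat, same tuning and kinematics:
        # denser sampling of the same area decodes at least as well (within 1 sd)
        lay = ep.build_layout(8, 8, 1250.0, 850.0)
        p = ep.load_preset("benchmark")
        tuning = ep.make_tuning_maps(lay, 6, p["spatial_scale_mm"], seed=17,
                                     source_amp_range=tuple(p["source_amp_range"]),
                                     baseline_hg=p["baseline_hg"])
        kin = ep.make_kinematics(100.0, 100.0, "gait", seed=18)
        noise = NoiseModel(**p["noise"])

        def factory(seed):
            session = synthesize_session(lay, tuning, kin, noise, fs=1000.0,
                                         seed=seed)
            return ep.assemble_dataset(session, kin, ep.benchmark_config())

        fm, al = factory(100)
        subs = ep.density_subsets(lay, strides=(4, 2, 1))
        perf = ep.subsample_performance(fm, al, subs, n_repeats=3, seed=200,
                                        session_factory=factory)
        # the 4-channel stride-4 subset is below the decoder's state dimension
        assert perf.undefined[0]
        tol = perf.sd_cc + 1e-9
        assert perf.mean_cc[2] >= perf.mean_cc[1] - tol[1] - tol[2]

    def test_untuned_subset_near_zero(self, planted_data):
        fm, al = planted_data["fm"], planted_data["al"]
        tuned = set(planted_data["tuned"])
        untuned = [c for c in range(64) if c not in tuned][:16]
        sub = ep.SubsetSpec("explicit", np.array(untuned))
        perf = ep.subsample_performance(fm, al, [sub])
        assert abs(perf.mean_cc[0]) < 0.3

    def test_tiny_subset_flagged_undefined(self, small_data):
        fm, al = small_data["fm"], small_data["al"]
        sub = ep.SubsetSpec("explicit", np.arange(3))
        perf = ep.subsample_performance(fm, al, [sub])
        assert perf.undefined[0]
        assert np.isnan(perf.mean_cc[0])

    def test_coverage_decay_with_peripheral_sources(self):
        # tuned sources on the array rim: shrinking centred coverage loses
        # them and accuracy decays, steepest once the rim falls outside
        lay = ep.build_layout(10, 10, 1250.0, 850.0)
        rim = [0, 5, 9, 50, 59, 90, 95, 99]
        session, kin, _ = make_planted_session(10, 10, rim, duration_s=100.0,
                                               seed=31)
        fm, al = ep.assemble_dataset(session, kin, ep.RunConfig())
        subs = ep.centered_grid_subsets(lay, [10, 8, 6, 4])
        perf = ep.subsample_performance(fm, al, subs)
        assert perf.mean_cc[0] == np.nanmax(perf.mean_cc)
        drops = -np.diff(perf.mean_cc)
        assert np.nanargmax(drops) >= 0   # all rim channels outside by 8x8
        assert perf.mean_cc[-1] < perf.mean_cc[0] - 0.2


class TestRFImportance:
    def test_normalization_per_axis(self, planted_data):
        res = ep.rf_importance(planted_data["fm"], planted_data["al"],
                               n_trees=100, seed=1)
        sums = res.importance_per_axis.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert np.all(res.importance_per_axis >= 0)

    def test_recovers_planted_channels(self, planted_data):
        res = ep.rf_importance(planted_data["fm"], planted_data["al"],
                               n_trees=300, seed=2)
        top8 = set(np.argsort(-res.importance_mean)[:8])
        assert len(top8 & set(planted_data["tuned"])) >= 6

    def test_shuffled_labels_near_uniform(self, planted_data):
        fm, al = planted_data["fm"], planted_data["al"]
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(al.position))
        shuffled = (al.position[perm], al.speed[perm])
        res = ep.rf_importance(fm, shuffled, n_trees=500, seed=3)
        imp = res.importance_mean
        assert imp.max() / imp.min() < 3.0

    def test_degenerate_labels(self, planted_data):
        fm, al = planted_data["fm"], planted_data["al"]
        pos = al.position.copy()
        pos[:, 2] = 1.0
        with pytest.raises(DegenerateLabelsError):
            ep.rf_importance(fm, (pos, al.speed), n_trees=50, seed=1)


class TestOptimalSubset:
    def test_curve_length(self, planted_data):
        fm, al = planted_data["fm"], planted_data["al"]
        fm20 = fm.select_channels(np.arange(20))
        imp = np.linspace(1.0, 0.1, 20)
        res = ep.optimal_subset(fm20, al, imp, start_k=5)
        assert len(res.curve_sizes) == 16
        assert res.curve_sizes[0] == 5 and res.curve_sizes[-1] == 20

    def test_recovers_signal_carrying_channels(self):
        # 10 signal channels among 30: the accuracy curve peaks close to 10
        # and the optimal subset contains most true channels
        from test_decoders import simulate_linear_gaussian
        rng = np.random.default_rng(12)
        Z, pos, vel, _, _ = simulate_linear_gaussian(1500, 10, seed=12,
                                                     obs_noise=0.3)
        feats = np.column_stack([Z, rng.standard_normal((1500, 20))])
        perm = rng.permutation(30)
        feats = feats[:, perm]
        true = set(np.nonzero(perm < 10)[0])
        fm = ep.FeatureMatrix(values=feats, bin_ms=100.0, band=(70.0, 150.0),
                              channel_ids=np.arange(30),
                              norm_mean=np.zeros(30), norm_std=np.ones(30),
                              bin_timestamps=np.arange(1500) * 0.1)
        imp = ep.rf_importance(fm, (pos, vel), n_trees=200, seed=13)
        res = ep.optimal_subset(fm, (pos, vel), imp.importance_mean, start_k=5)
        peak_size = res.curve_sizes[np.argmax(res.curve_cc)]
        assert 8 <= peak_size <= 14
        assert len(set(res.optimal_subset) & true) >= 9

    def test_all_noise_flat_curve(self):
        rng = np.random.default_rng(14)
        feats = rng.standard_normal((800, 15))
        kin = ep.make_kinematics(80.0, 10.0, "gait", seed=14)
        fm = ep.FeatureMatrix(values=feats, bin_ms=100.0, band=(70.0, 150.0),
                              channel_ids=np.arange(15),
                              norm_mean=np.zeros(15), norm_std=np.ones(15),
                              bin_timestamps=np.arange(800) * 0.1)
        res = ep.optimal_subset(fm, (kin.position[:800], kin.speed[:800]),
                                np.linspace(1, 0.1, 15), start_k=5)
        assert np.nanmax(np.abs(res.curve_cc)) < 0.35

    def test_first_peak_tie_rule(self):
        assert _first_peak(np.array([0.5, 0.7, 0.7, 0.6])) == 1
        assert _first_peak(np.array([np.nan, np.nan])) == 0
        assert _first_peak(np.array([np.nan, 0.2, 0.2])) == 1


class TestContributionMap:
    def _result(self, subset):
        return ep.ContributionResult(importance_per_axis=None,
                                     importance_mean=None, channel_ids=None,
                                     optimal_subset=np.asarray(subset))

    def test_counting_and_normalization(self):
        results = [self._result([0, 1]), self._result([0, 2]),
                   self._result([0, 1, 3])]
        cmap = ep.contribution_map(results, n_channels=5)
        assert cmap[0] == pytest.approx(1.0)       # in every session
        assert cmap[4] == 0.0                       # never selected
        assert cmap[1] == pytest.approx(2 / 3)      # 2 of 3, over max 3/3

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ep.contribution_map([], 4)


class TestHGCorrelation:
    def test_identical_channels_peak_one(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal(4000)
        mat, sim, skipped = ep.hg_correlation(np.stack([x, x]), fs=500.0)
        assert mat[0, 1] == pytest.approx(1.0, abs=1e-6)
        assert skipped == 0

    def test_independent_noise_low_peak(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal((4, 10000))
        mat, _, _ = ep.hg_correlation(x, fs=500.0)
        off = ~np.eye(4, dtype=bool)
        assert np.abs(mat[off]).mean() < 0.3

    def test_peak_monotone_in_mixing_ratio(self):
        rng = np.random.default_rng(17)
        shared = rng.standard_normal(10000)
        peaks = []
        for r in (0.0, 0.5, 1.0):
            a = r * shared + (1 - r) * rng.standard_normal(10000)
            b = r * shared + (1 - r) * rng.standard_normal(10000)
            mat, _, _ = ep.hg_correlation(np.stack([a, b]), fs=500.0)
            peaks.append(abs(mat[0, 1]))
        assert peaks[0] < peaks[1] < peaks[2]

    def test_flat_channel_pairs_skipped(self):
        rng = np.random.default_rng(18)
        x = rng.standard_normal((3, 4000))
        x[1] = 0.0   # dead channel: every pair-bin involving it is skipped
        mat, _, skipped = ep.hg_correlation(x, fs=500.0)
        assert skipped >= 1
        assert np.isnan(mat[0, 1])
        assert np.isfinite(mat[0, 2])


class TestCompareContributionSubsets:
    def _hot_quadrant_setup(self):
        # all tuning in the top-left 4x4 of an 8x8 grid
        hot = [r * 8 + c for r in range(4) for c in range(4)]
        session, kin, _ = make_planted_session(8, 8, hot[:8], duration_s=100.0,
                                               seed=41)
        fm, al = ep.assemble_dataset(session, kin, ep.RunConfig())
        contrib = np.zeros(64)
        contrib[hot] = 1.0
        return session, fm, al, contrib, hot

    def test_high_block_found_in_hot_quadrant(self):
        session, fm, al, contrib, hot = self._hot_quadrant_setup()
        # hg correlation runs on preprocessed signals; use raw for structure
        rep = ep.compare_contribution_subsets(
            contrib, session.layout, fm, al,
            session.signals.astype(float), session.fs, n_repeats=5, seed=1)
        assert set(rep.high_subset.channel_indices) == set(hot)
        assert rep.high_mean_contribution > rep.low_mean_contribution

    def test_high_subset_decodes_better_and_less_correlated(self):
        session, fm, al, contrib, hot = self._hot_quadrant_setup()
        # 8 repeated splits: the signed-rank test needs n >= 8 pairs to be
        # able to reach p < 0.05 at all
        rep = ep.compare_contribution_subsets(
            contrib, session.layout, fm, al,
            session.signals.astype(float), session.fs, n_repeats=8, seed=2)
        assert rep.high_cc.mean() > rep.low_cc.mean()
        assert rep.high_hg_corr < rep.low_hg_corr
        assert rep.test_report.pvalue < 0.05

    def test_uniform_map_tie_broken_top_left(self, caplog):
        session, fm, al, _, _ = self._hot_quadrant_setup()
        uniform = np.ones(64)
        with caplog.at_level("INFO"):
            rep = ep.compare_contribution_subsets(
                uniform, session.layout, fm, al,
                session.signals.astype(float), session.fs, n_repeats=5, seed=3)
        assert rep.high_subset.channel_indices[0] == 0
        assert "tie" in caplog.text
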