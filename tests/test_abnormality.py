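import numpy as np
import pytest

from voxnorm.abnormality import (
    ConsistencyError, classify_direction, cluster_filter, fdr_threshold,
    longitudinal_change, representative_slice, score_subject,
    summarize_extent, threshold_map, analyze_stack, AbnormalityResult,
)
from voxnorm.core_io import AnalysisConfig, Modality, Session
from voxnorm.normative import fit_normative_model
from .conftest import make_stack
from .oracles import bh_stepup, flood_fill_filter, quartiles_naive


@pytest.fixture(scope="module")
def fitted_model():
    rng = np.random.default_rng(1)
    vals = rng.uniform(0.4, 0.6, (44, 60))
    return fit_normative_model(make_stack(vals)), vals


class TestScoreSubject:
    def test_median_subject_not_abnormal(self, fitted_model):
        model, vals = fitted_model
        p_one, p_two = score_subject(model, np.median(vals, axis=0))
        # central values sit in the body of the normative law at nearly
        # every voxel (a lumpy KDE can leave the odd mid-range P') ...
        assert np.median(p_two) > 0.8
        assert (p_two > 0.5).mean() > 0.9
        # ... and nothing survives thresholding
        assert not threshold_map(p_two, model.mask, 0.05).any()

    def test_extreme_value_tiny_p(self, fitted_model):
        model, vals = fitted_model
        query = np.median(vals, axis=0)
        query[7] = vals[:, 7].max() + 10 * model.bandwidth[7]
        _, p_two = score_subject(model, query)
        assert p_two[7] < 1e-4

    def test_zero_change_centered_controls(self):
        rng = np.random.default_rng(2)
        changes = rng.standard_normal((44, 30)) * 0.01
        model = fit_normative_model(
            make_stack(changes, session=Session.CHANGE), analysis="LNG")
        p_one, _ = score_subject(model, np.zeros(30))
        assert np.allclose(p_one, 0.5, atol=0.2)  # finite-N CDF wobble
        assert abs(np.median(p_one) - 0.5) < 0.05

    def test_invalid_voxels_propagate_missing(self, rng):
        vals = rng.uniform(0.4, 0.6, (10, 5))
        vals[:, 1] = 0.5
        model = fit_normative_model(make_stack(vals))
        p_one, p_two = score_subject(model, np.full(5, 0.5))
        assert np.isnan(p_one[1]) and np.isnan(p_two[1])
        binary = threshold_map(p_two, model.mask, 0.05)
        assert not binary[1]

    def test_missing_baseline_named_in_error(self, small_cohort):
        from voxnorm.core_io import Group
        sym = small_cohort.stack(Group.CONCUSSED, Session.SYM)
        base = small_cohort.stack(Group.CONCUSSED, Session.BASELINE)
        base_short = base.select_subjects(base.subject_ids[1:])
        with pytest.raises(ValueError, match="conc000"):
            longitudinal_change(sym, base_short)


class TestFdrThreshold:
    def test_stated_example(self):
        detected = fdr_threshold(np.array([0.01, 0.02, 0.5]), 0.05)
        assert detected.tolist() == [True, True, False]

    def test_all_ones_nothing(self):
        assert not fdr_threshold(np.ones(10), 0.05).any()

    def test_single_voxel_reduces_to_plain_level(self):
        assert fdr_threshold(np.array([0.04]), 0.05).tolist() == [True]
        assert fdr_threshold(np.array([0.06]), 0.05).tolist() == [False]

    def test_matches_stepup_oracle_on_random_instances(self, rng):
        for _ in range(120):
            m = int(rng.integers(1, 60))
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3.0)
            q = float(rng.uniform(0.01, 0.2))
            assert np.array_equal(fdr_threshold(p, q), bh_stepup(p, q))

    def test_monotone_in_q(self, rng):
        p = rng.uniform(size=200) ** 2
        low = fdr_threshold(p, 0.01)
        high = fdr_threshold(p, 0.10)
        assert (high | ~low).all()  # detections grow with q

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            fdr_threshold(np.full(4, np.nan), 0.05)


class TestClusterFilter:
    def test_component_sizes_example(self):
        # components of sizes 1, 2, 3, 5 -> 8 voxels survive at min_size 3
        vol = np.zeros((4, 4, 8), dtype=bool)
        vol[0, 0, 0] = True                      # size 1
        vol[2, 2, 0:2] = True                    # size 2
        vol[0, 3, 3:6] = True                    # size 3
        vol[3, 0, 2:7] = True                    # size 5
        out = cluster_filter(vol, min_size=3)
        assert out.sum() == 8

    def test_empty_in_empty_out(self):
        vol = np.zeros((3, 3, 3), dtype=bool)
        assert not cluster_filter(vol, 3).any()

    def test_line_of_four_unchanged(self):
        vol = np.zeros((1, 1, 6), dtype=bool)
        vol[0, 0, 1:5] = True
        assert np.array_equal(cluster_filter(vol, 3), vol)

    @pytest.mark.parametrize("connectivity", [1, 2, 3])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        for _ in range(35):
            vol = rng.uniform(size=(6, 6, 6)) < 0.25
            min_size = int(rng.integers(1, 6))
            assert np.array_equal(
                cluster_filter(vol, min_size, connectivity),
                flood_fill_filter(vol, min_size, connectivity))

    def test_idempotent(self, rng):
        vol = rng.uniform(size=(8, 8, 8)) < 0.3
        once = cluster_filter(vol, 3)
        assert np.array_equal(cluster_filter(once, 3), once)


class TestClassifyDirection:
    def test_tails(self):
        p_one = np.array([0.99, 0.001, 0.5])
        abnormal = np.array([True, True, False])
        direction, pos = classify_direction(p_one, abnormal)
        assert direction.tolist() == [1, -1, 0]
        assert pos == pytest.approx(0.5)

    def test_positive_fraction_two_thirds(self):
        p_one = np.array([0.99, 0.98, 0.01])
        direction, pos = classify_direction(p_one, np.ones(3, dtype=bool))
        assert pos == pytest.approx(2 / 3)

    def test_midrange_abnormal_is_inconsistent(self):
        with pytest.raises(ConsistencyError):
            classify_direction(np.array([0.5]), np.array([True]))

    def test_no_abnormal_gives_missing_fraction(self):
        _, pos = classify_direction(np.array([0.5]), np.array([False]))
        assert np.isnan(pos)


class TestSummarizeExtent:
    def _result(self, subject, abnormal_frac, n=100, positive=1.0):
        n_abn = int(round(abnormal_frac * n))
        p_one = np.full(n, 0.5)
        abnormal = np.zeros(n, dtype=bool)
        abnormal[:n_abn] = True
        n_pos = int(round(positive * n_abn))
        p_one[:n_pos] = 0.99
        p_one[n_pos:n_abn] = 0.001
        direction = np.where(p_one >= 0.975, 1, np.where(p_one <= 0.025, -1, 0))
        direction[~abnormal] = 0
        mask = np.ones((1, 1, n), dtype=bool)
        return AbnormalityResult(
            subject_id=subject, modality=Modality.FA, analysis="CS",
            timepoint=Session.SYM, p_one=p_one,
            p_two=2 * np.minimum(p_one, 1 - p_one), abnormal=abnormal,
            direction=direction, mask=mask, affine=np.eye(4))

    def test_single_subject_quartiles_collapse(self):
        table = summarize_extent([self._result("a", 0.02)])
        row = table.iloc[0]
        assert row.abnormal_pct_median == pytest.approx(2.0)
        assert row.abnormal_pct_q1 == pytest.approx(2.0)
        assert row.abnormal_pct_q3 == pytest.approx(2.0)

    def test_median_of_three(self):
        table = summarize_extent([self._result(s, f)
                                  for s, f in (("a", 0.01), ("b", 0.02),
                                               ("c", 0.03))])
        assert table.iloc[0].abnormal_pct_median == pytest.approx(2.0)

    def test_quartiles_match_order_statistics_oracle(self, rng):
        fracs = rng.uniform(0.01, 0.3, 9)
        table = summarize_extent([self._result(f"s{i}", f)
                                  for i, f in enumerate(fracs)])
        med, q1, q3 = quartiles_naive(100 * np.round(fracs, 2))
        row = table.iloc[0]
        assert row.abnormal_pct_median == pytest.approx(med)
        assert row.abnormal_pct_q1 == pytest.approx(q1)
        assert row.abnormal_pct_q3 == pytest.approx(q3)

    def test_missing_positive_fractions_excluded(self):
        results = [self._result("a", 0.0), self._result("b", 0.1, positive=0.5)]
        row = summarize_extent(results).iloc[0]
        assert row.positive_fraction_median == pytest.approx(0.5)


class TestRepresentativeSlice:
    def test_all_in_one_slice(self):
        maps = []
        for _ in range(4):
            vol = np.zeros((5, 5, 20), dtype=bool)
            vol[1:3, 1:3, 10] = True
            maps.append(vol)
        assert representative_slice(maps) == 10

    def test_matches_exhaustive_mean_rank(self, rng):
        from scipy.stats import rankdata
        maps = [rng.uniform(size=(4, 4, 12)) < 0.15 for _ in range(4)]
        maps = [m for m in maps if m.any()]
        got = representative_slice(maps)
        mean_rank = np.mean([rankdata(m.sum(axis=(0, 1))) for m in maps], axis=0)
        best = max(mean_rank)
        assert mean_rank[got] == best
        assert got == min(np.flatnonzero(mean_rank == best))

    def test_missing_maps_skipped_and_empty_none(self):
        vol = np.zeros((3, 3, 6), dtype=bool)
        vol[0, 0, 4] = True
        assert representative_slice([None, vol, np.zeros_like(vol)]) == 4
        assert representative_slice([None, np.zeros_like(vol)]) is None


class TestEndToEndRecovery:
    def test_injected_clusters_detected(self):
        # 6-SD clusters of >= 10 voxels recovered with high per-cluster
        # sensitivity at default settings
        import warnings
        from voxnorm.core_io import Group
        from voxnorm.synthetic import (InjectionCluster, SyntheticCohortSpec,
                                       generate_cohort)
        clusters = tuple(
            InjectionCluster(center=c, effect_sd=6.0, n_voxels=12,
                             sessions="both", mode="value")
            for c in ((3, 3, 3), (10, 10, 10), (3, 10, 6)))
        spec = SyntheticCohortSpec(shape=(14, 14, 14), n_controls=44,
                                   n_concussed=4, skew_fraction=0.0,
                                   cov_field=0.06, injections=clusters, seed=6)
        cohort = generate_cohort(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_normative_model(
                cohort.stack(Group.CONTROL, Session.BASELINE))
        results = analyze_stack(model, cohort.stack(Group.CONCUSSED, Session.SYM),
                                "CS", Session.SYM)
        truth = cohort.truth_mask("CS", Session.SYM)[cohort.mask]
        sens = np.mean([(r.abnormal & truth).sum() / truth.sum()
                        for r in results])
        assert sens > 0.9
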