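import numpy as np
import pandas as pd
import pytest

from qmoaks import (
    FieldParams,
    LesionParams,
    ReaderParams,
    ValidationError,
    build_normative,
    generate_controls,
    generate_progression_cohort,
    make_grid_atlas,
    make_mean_field,
    score_cohort,
    simulate_sq_reader,
)
from qmoaks.cohort import TRUTH_COLUMNS
from qmoaks.scoring import band


@pytest.fixture(scope="module")
def atlas():
    return make_grid_atlas((4, 4))


class TestMeanField:
    def test_zero_amplitude_constant(self, atlas):
        params = FieldParams(grid_shape=(4, 4), spatial_amplitude=0.0)
        field = make_mean_field(atlas, params, seed=1)
        np.testing.assert_allclose(field, params.base_mean)

    def test_same_seed_identical(self, atlas):
        params = FieldParams(grid_shape=(4, 4))
        np.testing.assert_array_equal(
            make_mean_field(atlas, params, 5), make_mean_field(atlas, params, 5)
        )

    def test_different_seed_differs(self, atlas):
        params = FieldParams(grid_shape=(4, 4))
        assert not np.array_equal(
            make_mean_field(atlas, params, 5), make_mean_field(atlas, params, 6)
        )

    def test_amplitude_bound(self):
        # amplitude 0.3 around base 2.2 stays inside [1.9, 2.5] by construction
        atlas = make_grid_atlas((16, 16))
        params = FieldParams(grid_shape=(16, 16), base_mean=2.2, spatial_amplitude=0.3)
        for seed in range(5):
            field = make_mean_field(atlas, params, seed)
            assert field.min() >= 1.9 and field.max() <= 2.5

    def test_grid_mismatch_rejected(self, atlas):
        with pytest.raises(ValidationError, match="expected"):
            make_mean_field(atlas, FieldParams(grid_shape=(5, 5)), 1)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            FieldParams(base_mean=-1.0)
        with pytest.raises(ValidationError):
            FieldParams(noise_sd=-0.1)
        with pytest.raises(ValidationError):
            FieldParams(base_mean=0.2, spatial_amplitude=0.3)


class TestControls:
    def test_noise_free_limit_equals_field(self, atlas):
        params = FieldParams(grid_shape=(4, 4), subject_scale_sd=0.0, noise_sd=0.0)
        maps, field = generate_controls(5, atlas, params, seed=2)
        for m in maps:
            np.testing.assert_array_equal(m.thickness, field)

    def test_clamped_at_zero(self, atlas):
        params = FieldParams(
            grid_shape=(4, 4), base_mean=0.02, spatial_amplitude=0.0,
            subject_scale_sd=0.0, noise_sd=0.05,
        )
        maps, _ = generate_controls(20, atlas, params, seed=3)
        stacked = np.concatenate([m.thickness for m in maps])
        assert stacked.min() == 0.0  # some draws went negative and were clamped

    def test_invalid_n_rejected(self, atlas):
        with pytest.raises(ValidationError):
            generate_controls(0, atlas, FieldParams(grid_shape=(4, 4)), 1)

    def test_prefix_stability(self, atlas):
        # growing the cohort must not reshuffle earlier knees
        params = FieldParams(grid_shape=(4, 4))
        small, _ = generate_controls(5, atlas, params, seed=4)
        large, _ = generate_controls(10, atlas, params, seed=4)
        for a, b in zip(small, large):
            np.testing.assert_array_equal(a.thickness, b.thickness)

    def test_sample_mean_near_truth(self, atlas):
        params = FieldParams(grid_shape=(4, 4))
        maps, field = generate_controls(500, atlas, params, seed=8)
        stack = np.vstack([m.thickness for m in maps])
        se = stack.std(axis=0, ddof=1) / np.sqrt(len(maps))
        within = np.abs(stack.mean(axis=0) - field) <= 3 * se
        assert within.mean() >= 0.99


class TestProgressionCohort:
    def _params(self, **kwargs):
        defaults = dict(
            region_probs={"cMF": 1.0},
            center=(1.5, 1.5),
            initial_radius=1.3,
            initial_depth_fraction=0.6,
            radius_growth_per_year=0.0,
            depth_growth_per_year=0.0,
        )
        defaults.update(kwargs)
        return LesionParams(**defaults)

    def _field(self, **kwargs):
        defaults = dict(grid_shape=(4, 4), subject_scale_sd=0.0, noise_sd=0.0)
        defaults.update(kwargs)
        return FieldParams(**defaults)

    def test_truth_schema_and_bounds(self, atlas):
        cohort = generate_progression_cohort(
            4, atlas, self._field(), self._params(), [0, 12, 24], seed=1
        )
        assert tuple(cohort.truth.columns) == TRUTH_COLUMNS
        assert len(cohort.truth) == 4 * 3 * 10
        assert cohort.truth["true_thqcm_pct"].between(0, 100).all()
        assert (
            cohort.truth["true_dqcm_pct"] <= cohort.truth["true_thqcm_pct"] + 1e-12
        ).all()

    def test_static_lesion_constant_truth(self, atlas):
        cohort = generate_progression_cohort(
            3, atlas, self._field(), self._params(), [0, 12, 24], seed=2
        )
        for (_, _), group in cohort.truth.groupby(["knee_id", "region"]):
            assert group["true_thqcm_pct"].nunique() == 1
            assert group["true_dqcm_pct"].nunique() == 1

    def test_flat_full_depth_disc_gives_exact_denuded_fraction(self, atlas):
        # disc of radius 1.2 at grid point (0,0) covers exactly 3/16 landmarks
        lesion = self._params(
            center=(0.0, 0.0), initial_radius=1.2, initial_depth_fraction=1.0,
            depth_profile="flat",
        )
        cohort = generate_progression_cohort(2, atlas, self._field(), lesion, [0], seed=3)
        in_region = cohort.truth[cohort.truth["region"] == "cMF"]
        np.testing.assert_allclose(in_region["true_dqcm_pct"], 100 * 3 / 16)
        np.testing.assert_allclose(in_region["true_thqcm_pct"], 100 * 3 / 16)

    def test_deeper_only_mode(self, atlas):
        lesion = self._params(
            depth_profile="flat", initial_depth_fraction=0.4,
            depth_growth_per_year=0.25, radius_growth_per_year=0.0,
        )
        cohort = generate_progression_cohort(
            3, atlas, self._field(), lesion, [0, 12, 24], seed=4
        )
        in_region = cohort.truth[cohort.truth["region"] == "cMF"]
        for _, group in in_region.groupby("knee_id"):
            group = group.sort_values("visit_month")
            areas = group["true_thqcm_pct"].to_numpy()
            thick = group["true_thctab_mm"].to_numpy()
            assert np.all(np.diff(areas) <= 1e-12)  # area fixed by the disc
            assert np.all(np.diff(thick) < 0)  # thickness strictly decreasing

    def test_truth_matches_independent_rescoring(self, atlas):
        # rebuild the normative model from the returned truth field and
        # re-score the noise-free maps: fractions must agree to 1e-9
        field_params = self._field(subject_scale_sd=0.05, noise_sd=0.04)
        cohort = generate_progression_cohort(
            5, atlas, field_params, self._params(center=None), [0, 12], seed=5
        )
        from qmoaks import NormativeModel

        model = NormativeModel(normative_mean=cohort.truth_field, n_controls=0)
        rescored = score_cohort(cohort.noise_free_maps, atlas, model)
        np.testing.assert_allclose(
            rescored["thqcm_pct"].to_numpy(),
            cohort.truth["true_thqcm_pct"].to_numpy(),
            atol=1e-9,
        )
        np.testing.assert_allclose(
            rescored["thctab_mm"].to_numpy(),
            cohort.truth["true_thctab_mm"].to_numpy(),
            atol=1e-9,
        )

    def test_visit_validation(self, atlas):
        with pytest.raises(ValidationError):
            generate_progression_cohort(2, atlas, self._field(), self._params(), [], 1)
        with pytest.raises(ValidationError):
            generate_progression_cohort(2, atlas, self._field(), self._params(), [12, 0], 1)

    def test_determinism(self, atlas):
        kwargs = dict(center=None)
        a = generate_progression_cohort(3, atlas, self._field(noise_sd=0.05), self._params(**kwargs), [0, 12], 6)
        b = generate_progression_cohort(3, atlas, self._field(noise_sd=0.05), self._params(**kwargs), [0, 12], 6)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        for x, y in zip(a.maps, b.maps):
            np.testing.assert_array_equal(x.thickness, y.thickness)


class TestReader:
    def _truth(self, pcts, visits=(0,)):
        rows = []
        for knee, pct_by_visit in pcts.items():
            for month, pct in zip(visits, pct_by_visit):
                rows.append(
                    {
                        "knee_id": knee,
                        "visit_month": month,
                        "region": "cMF",
                        "true_thqcm_pct": pct,
                        "true_dqcm_pct": 0.0,
                        "true_thctab_mm": 2.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_identity_reader_reports_true_bands(self):
        truth = self._truth({"k1": [0.0], "k2": [5.0], "k3": [50.0], "k4": [90.0]})
        records = simulate_sq_reader(truth, ReaderParams.identity(), seed=1)
        th = {r.knee_id: r.score for r in records if r.measure == "ThMCM"}
        assert th == {"k1": 0.0, "k2": 1.0, "k3": 2.0, "k4": 3.0}

    def test_forced_band_shift(self):
        confusion = np.eye(4)
        confusion[1] = [0, 0, 1, 0]  # all band-1 mass reported as band 2
        truth = self._truth({f"k{i}": [5.0] for i in range(20)})
        records = simulate_sq_reader(truth, ReaderParams(confusion), seed=2)
        assert all(r.score == 2.0 for r in records if r.measure == "ThMCM")

    def test_overcall_bias_raises_mean_band(self):
        truth = self._truth({f"k{i}": [50.0] for i in range(1000)})
        biased = simulate_sq_reader(truth, ReaderParams.with_overcall(0.3), seed=3)
        reported = np.array([r.score for r in biased if r.measure == "ThMCM"])
        assert reported.mean() >= 2.0  # true band everywhere
        assert (reported == 3.0).mean() == pytest.approx(0.3, abs=0.05)

    def test_within_grade_emission(self):
        # fraction rises 40 -> 60 within band 2: +0.5 with sensitivity 1
        truth = self._truth({"k1": [40.0, 60.0]}, visits=(0, 12))
        records = simulate_sq_reader(
            truth, ReaderParams.identity(within_grade_sensitivity=1.0), seed=4
        )
        followup = [r for r in records if r.measure == "ThMCM" and r.visit_month == 12]
        assert followup[0].score == 0.5

    def test_non_stochastic_confusion_rejected(self):
        bad = np.eye(4) * 0.5
        with pytest.raises(ValidationError, match="sum to 1"):
            ReaderParams(bad)

    def test_true_band_and_reported_round_trip(self):
        truth = self._truth({"k1": [12.0]})
        records = simulate_sq_reader(truth, ReaderParams.identity(), seed=5)
        th = [r for r in records if r.measure == "ThMCM"][0]
        assert th.score == band(12.0)
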