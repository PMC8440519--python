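"""Synthetic-cohort generator: determinism, planted-effect fidelity, confounds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from concord.cohort import (
    CohortSpec,
    PlantedEffect,
    generate_cohort,
    generate_network_timeseries,
    generate_qc_volumes,
    generate_symptoms,
    edge_index_map,
)
from concord.contrast import ChangeCategory
from concord import qc


def _spec(**kw) -> CohortSpec:
    base = dict(n_per_group_per_dataset=50, n_datasets=2, n_features=20, seed=3)
    base.update(kw)
    return CohortSpec(**base)


class TestGenerateCohort:
    def test_same_seed_bit_identical(self):
        spec = _spec(effect_plan=(PlantedEffect(0, ChangeCategory.COMMON_DECREASE, 1.0),))
        m1, c1, _ = generate_cohort(spec)
        m2, c2, _ = generate_cohort(spec)
        assert m1.values.equals(m2.values)
        assert c1.equals(c2)

    def test_different_seed_differs(self):
        m1, _, _ = generate_cohort(_spec(seed=1))
        m2, _, _ = generate_cohort(_spec(seed=2))
        assert not m1.values.equals(m2.values)

    def test_planted_common_decrease_magnitude(self):
        # HC mean - patient mean converges to the planted magnitude at n=500/group
        spec = _spec(
            n_per_group_per_dataset=250,
            effect_plan=(PlantedEffect(0, ChangeCategory.COMMON_DECREASE, 1.0),),
            asd_scale=1.0,
        )
        mm, cov, _ = generate_cohort(spec)
        g = cov["group"]
        f0 = mm.values.iloc[:, 0]
        se3 = 3 * np.sqrt(2 / 500)
        assert f0[g == "HC"].mean() - f0[g == "SZ"].mean() == pytest.approx(1.0, abs=se3)
        assert f0[g == "HC"].mean() - f0[g == "ASD"].mean() == pytest.approx(1.0, abs=se3)

    def test_asd_scale_halves_asd_shift(self):
        spec = _spec(
            n_per_group_per_dataset=250,
            effect_plan=(PlantedEffect(0, ChangeCategory.COMMON_INCREASE, 1.0),),
            asd_scale=0.5,
        )
        mm, cov, truth = generate_cohort(spec)
        g = cov["group"]
        f0 = mm.values.iloc[:, 0]
        se3 = 3 * np.sqrt(2 / 500)
        assert f0[g == "ASD"].mean() - f0[g == "HC"].mean() == pytest.approx(0.5, abs=se3)
        assert truth.asd_weaker[0] is True

    def test_unique_categories_have_opposite_signs(self):
        spec = _spec(
            n_per_group_per_dataset=250,
            effect_plan=(
                PlantedEffect(0, ChangeCategory.SZ_UNIQUE_DECREASE, 1.0),
                PlantedEffect(1, ChangeCategory.ASD_UNIQUE_DECREASE, 1.0),
            ),
        )
        mm, cov, _ = generate_cohort(spec)
        g = cov["group"]
        v = mm.values
        # SZ-unique decrease: SZ below HC, ASD above HC
        assert v.iloc[:, 0][g == "SZ"].mean() < v.iloc[:, 0][g == "HC"].mean()
        assert v.iloc[:, 0][g == "ASD"].mean() > v.iloc[:, 0][g == "HC"].mean()
        # ASD-unique decrease: mirrored
        assert v.iloc[:, 1][g == "ASD"].mean() < v.iloc[:, 1][g == "HC"].mean()
        assert v.iloc[:, 1][g == "SZ"].mean() > v.iloc[:, 1][g == "HC"].mean()

    def test_null_generator_has_no_group_separation(self):
        mm, cov, truth = generate_cohort(_spec(n_per_group_per_dataset=250))
        assert truth.categories == {}
        g = cov["group"].to_numpy()
        diffs = (
            mm.values[g == "HC"].mean(axis=0) - mm.values[g == "SZ"].mean(axis=0)
        ).to_numpy()
        assert np.all(np.abs(diffs) < 4 * np.sqrt(2 / 500))

    def test_confounds_recoverable_when_planted(self):
        spec = _spec(site_shift_sd=1.0, age_slope_sd=0.5, n_features=30)
        mm, cov, _ = generate_cohort(spec)
        age_r = np.array(
            [stats.pearsonr(cov["age"], mm.values.iloc[:, j])[0] for j in range(30)]
        )
        assert np.abs(age_r).max() > 0.2
        ds_means = mm.values.groupby(cov["dataset"]).mean()
        assert (ds_means.iloc[0] - ds_means.iloc[1]).abs().max() > 0.5

    def test_dataset_kinds_restrict_groups(self):
        spec = _spec(dataset_kinds=("SZ", "ASD"))
        _, cov, _ = generate_cohort(spec)
        assert set(cov[cov["dataset"] == "ds00"]["group"]) == {"HC", "SZ"}
        assert set(cov[cov["dataset"] == "ds01"]["group"]) == {"HC", "ASD"}

    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_per_group_per_dataset=0),
            dict(n_datasets=1),
            dict(asd_scale=0.0),
            dict(asd_scale=1.5),
            dict(noise_sd=0.0),
            dict(motion_outlier_fraction=1.0),
            dict(symptom_coupling=((99, 1.0),)),
        ],
    )
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(ValueError):
            _spec(**kw)

    def test_duplicate_effect_features_rejected(self):
        plan = (
            PlantedEffect(0, ChangeCategory.COMMON_DECREASE, 1.0),
            PlantedEffect(0, ChangeCategory.COMMON_INCREASE, 1.0),
        )
        with pytest.raises(ValueError, match="distinct"):
            _spec(effect_plan=plan)


class TestNetworkTimeseries:
    def test_planted_edge_correlation_recovered(self):
        spec = _spec(
            n_per_group_per_dataset=50,
            n_networks=10,
            n_timepoints=200,
            effect_plan=(PlantedEffect(0, ChangeCategory.COMMON_DECREASE, 1.0),),
            asd_scale=1.0,
        )
        series, cov = generate_network_timeseries(spec, base_edge_r=0.5, edge_scale=0.3)
        i, j = edge_index_map(10)[0]
        r_by_group = {g: [] for g in ("HC", "SZ", "ASD")}
        for sid, ts in series.items():
            r = np.corrcoef(ts.series[i], ts.series[j])[0, 1]
            r_by_group[cov.loc[sid, "group"]].append(r)
        assert np.mean(r_by_group["HC"]) == pytest.approx(0.5, abs=0.05)
        # common decrease lowers the patient-edge correlation below HC
        assert np.mean(r_by_group["SZ"]) < np.mean(r_by_group["HC"]) - 0.1

    def test_identity_covariance_gives_null_fnc(self):
        spec = _spec(n_networks=8, n_timepoints=300)
        series, _ = generate_network_timeseries(spec)
        offdiag = []
        for ts in list(series.values())[:30]:
            r = np.corrcoef(ts.series)
            offdiag.append(r[np.triu_indices(8, k=1)])
        assert abs(np.mean(offdiag)) < 0.02

    def test_motion_outlier_carries_large_transition(self):
        spec = _spec(motion_outlier_fraction=0.2, n_networks=5, n_timepoints=150, seed=9)
        series, cov = generate_network_timeseries(spec)
        outliers = cov.index[cov["motion_trans_mm"] > 3.0]
        assert len(outliers) > 0
        for sid in outliers:
            assert np.abs(series[sid].motion).max() > 3.0

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            generate_network_timeseries(_spec(n_timepoints=2))


class TestQCVolumes:
    def test_all_good_volumes_pass_screen(self):
        vols, labels = generate_qc_volumes(n_good=12, n_bad=0, seed=1)
        masks = {f"s{i}": qc.individual_mask_fmri(v) for i, v in enumerate(vols)}
        _, passers, _ = qc.iterate_group_mask(masks)
        assert len(passers) == 12

    def test_translated_volume_fails_whole_mask_correlation(self):
        vols, labels = generate_qc_volumes(n_good=15, n_bad=1, seed=2)
        masks = [qc.individual_mask_fmri(v) for v in vols]
        grp = qc.group_mask(masks[:15])  # group support from the good ones
        _, _, r_whole = qc.slab_correlations(masks[15], grp)
        assert r_whole < 0.8

    def test_identical_volumes_correlate_perfectly(self):
        vols, _ = generate_qc_volumes(n_good=1, n_bad=0, seed=3)
        mask = qc.individual_mask_fmri(vols[0])
        r = qc.slab_correlations(mask, mask)
        assert r == pytest.approx((1.0, 1.0, 1.0))

    def test_truth_labels_match_screen(self):
        vols, labels = generate_qc_volumes(n_good=20, n_bad=2, seed=4)
        masks = {f"s{i:02d}": qc.individual_mask_fmri(v) for i, v in enumerate(vols)}
        _, passers, _ = qc.iterate_group_mask(masks)
        expected = {f"s{i:02d}" for i, good in enumerate(labels) if good}
        assert set(passers) == expected

    def test_zero_volumes_rejected(self):
        with pytest.raises(ValueError):
            generate_qc_volumes(0, 0)


class TestSymptoms:
    def _cohort(self, n=200):
        return generate_cohort(_spec(n_per_group_per_dataset=n, n_features=5, seed=11))

    def test_negative_coupling_recovered(self):
        mm, cov, _ = self._cohort()
        table = generate_symptoms(mm, cov, [(0, -0.5)], noise_sd=1.0, seed=0, group="SZ")
        merged = table.join(mm.values["f0000"])
        r, p = stats.pearsonr(merged["f0000"], merged["score"])
        assert r < 0
        assert p < 0.01

    def test_zero_coupling_uncorrelated(self):
        mm, cov, _ = self._cohort()
        table = generate_symptoms(mm, cov, [(0, 0.0)], noise_sd=1.0, seed=0, group="ASD")
        merged = table.join(mm.values["f0000"])
        r, _ = stats.pearsonr(merged["f0000"], merged["score"])
        assert abs(r) < 0.15

    def test_noise_free_strong_coupling_is_deterministic(self):
        mm, cov, _ = self._cohort(n=50)
        table = generate_symptoms(mm, cov, [(2, 2.0)], noise_sd=0.0, seed=0, group="SZ")
        merged = table.join(mm.values["f0002"])
        r, _ = stats.pearsonr(merged["f0002"], merged["score"])
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_hc_group_rejected(self):
        mm, cov, _ = self._cohort(n=20)
        with pytest.raises(ValueError):
            generate_symptoms(mm, cov, [(0, 1.0)], noise_sd=1.0, group="HC")
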