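"""Z-scoring, mixed-model associations, FDR-thresholded group maps."""

import numpy as np
import pandas as pd
import pytest

from eispec.stats import (
    DegenerateROIError,
    association_model,
    regional_group_map,
    zscore_vs_controls,
)


def make_table(
    n_ctrl=10, n_pat=10, n_roi=8, slope_tau=0.5, slope_ab=0.0, noise=0.5,
    subj_sd=1.0, seed=0,
):
    """Mixed-model test data with known fixed effects and subject intercepts."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_ctrl + n_pat):
        group = "control" if i < n_ctrl else "patient"
        intercept = rng.normal(0, subj_sd)
        for r in range(n_roi):
            tau = rng.normal(1.6, 0.3)
            ab = rng.normal(2.0, 0.3)
            y = intercept + slope_tau * tau + slope_ab * ab + rng.normal(0, noise)
            rows.append(
                dict(subject_id=f"s{i:02d}", group=group, roi=f"roi{r}",
                     tau_suvr=tau, ab_suvr=ab, y=y)
            )
    return pd.DataFrame(rows)


class TestZscore:
    def test_controls_self_standardize(self, tiny_cohort):
        tp = tiny_cohort.true_params
        z = zscore_vs_controls(tp, "tau_e_ms")
        ctrl = tp[tp.group == "control"].assign(z=z[tp.group == "control"])
        per_roi = ctrl.groupby("roi").z.agg(["mean", "std"])
        assert np.allclose(per_roi["mean"], 0.0, atol=1e-12)
        assert np.allclose(per_roi["std"], 1.0, atol=1e-12)

    def test_affine_invariance(self, tiny_cohort):
        # per-ROI z-scores are invariant to any affine rescaling of the measure
        tp = tiny_cohort.true_params.copy()
        z0 = zscore_vs_controls(tp, "tau_e_ms")
        tp["tau_e_ms"] = 3.0 * tp["tau_e_ms"] - 7.0
        z1 = zscore_vs_controls(tp, "tau_e_ms")
        assert np.allclose(z0, z1, atol=1e-10)

    def test_missing_measure_and_no_controls(self, tiny_cohort):
        with pytest.raises(KeyError):
            zscore_vs_controls(tiny_cohort.true_params, "nope")
        pat = tiny_cohort.true_params[tiny_cohort.true_params.group == "patient"]
        with pytest.raises(DegenerateROIError):
            zscore_vs_controls(pat, "tau_e_ms")

    def test_zero_spread_roi_rejected(self, tiny_cohort):
        tp = tiny_cohort.true_params.copy()
        first_roi = tp.roi.iloc[0]
        tp.loc[(tp.group == "control") & (tp.roi == first_roi), "tau_e_ms"] = 10.0
        with pytest.raises(DegenerateROIError, match=first_roi):
            zscore_vs_controls(tp, "tau_e_ms")


class TestAssociationModel:
    def test_recovers_generating_slope(self):
        # defaults give a slope SE of ~0.2; use more ROIs and less noise so
        # the tolerance sits at ~4 sigma of the estimator
        df = make_table(n_roi=40, noise=0.3, slope_tau=0.5, slope_ab=0.0, seed=1)
        res = association_model(df, "y")
        assert res["tau_suvr"].estimate == pytest.approx(0.5, abs=0.15)
        assert res["tau_suvr"].p < 0.01
        assert abs(res["ab_suvr"].t) < 3

    def test_null_predictor_not_significant_on_average(self):
        tvals = [
            association_model(make_table(slope_tau=0.0, seed=s), "y")["tau_suvr"].t
            for s in range(12)
        ]
        assert np.mean(np.abs(tvals)) < 1.5

    def test_per_roi_variance_variant_runs_and_agrees_in_sign(self):
        df = make_table(slope_tau=0.5, seed=2)
        homo = association_model(df, "y", variance="homogeneous")
        het = association_model(df, "y", variance="per_roi")
        assert np.sign(het["tau_suvr"].estimate) == np.sign(homo["tau_suvr"].estimate)
        assert het["tau_suvr"].p < 0.05

    def test_uses_patients_only(self):
        df = make_table(seed=3)
        res = association_model(df, "y")
        assert res.n_subjects == 10  # patients, not all 20

    def test_collinear_predictors_rejected(self):
        df = make_table(seed=4)
        df["ab_suvr"] = 2.0 * df["tau_suvr"]
        with pytest.raises(ValueError):
            association_model(df, "y")

    def test_df_method_normal_gives_smaller_p_shift(self):
        df = make_table(seed=5)
        bw = association_model(df, "y", df_method="between_within")
        nz = association_model(df, "y", df_method="normal")
        assert nz["tau_suvr"].p <= bw["tau_suvr"].p + 1e-12
        with pytest.raises(ValueError):
            association_model(df, "y", df_method="bogus")

    def test_fit_lines_cover_predictor_range(self):
        df = make_table(seed=6)
        res = association_model(df, "y")
        lines = res.fit_lines
        sub = lines[lines.predictor == "tau_suvr"]
        pats = df[df.group == "patient"]
        assert sub.x.min() == pytest.approx(pats.tau_suvr.min())
        assert sub.x.max() == pytest.approx(pats.tau_suvr.max())


class TestBenjaminiHochberg:
    @staticmethod
    def brute_force_bh(pvals, q):
        # literal step-up definition: find the largest k with p_(k) <= k q / m
        p = np.asarray(pvals)
        order = np.argsort(p)
        m = len(p)
        k_star = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * q / m:
                k_star = k
        mask = np.zeros(m, bool)
        mask[order[:k_star]] = True
        return mask

    def test_mask_matches_brute_force_on_toy_vectors(self):
        from statsmodels.stats.multitest import multipletests

        toys = [
            [0.001, 0.01, 0.03, 0.2, 0.9],
            [0.04, 0.045, 0.049, 0.05, 0.051],
            [0.9, 0.8, 0.7],
            [0.001, 0.002],
            list(np.random.default_rng(0).uniform(size=40)),
        ]
        for p in toys:
            got = multipletests(p, alpha=0.10, method="fdr_bh")[0]
            assert np.array_equal(got, self.brute_force_bh(p, 0.10)), p

    def test_toy_vector_keeps_first_three(self):
        from statsmodels.stats.multitest import multipletests

        mask = multipletests([0.001, 0.01, 0.03, 0.2, 0.9], alpha=0.10, method="fdr_bh")[0]
        assert mask.tolist() == [True, True, True, False, False]


class TestRegionalGroupMap:
    def test_detects_shifted_measure(self, tiny_cohort):
        tp = tiny_cohort.true_params.copy()
        tp["z"] = zscore_vs_controls(tp, "tau_e_ms")
        tm = regional_group_map(tp, "z")
        assert set(tm.columns) >= {"t", "p", "significant"}
        assert len(tm) == tp.roi.nunique()
        assert tm.t.mean() > 2  # patients shifted +4 ms
        assert tm.significant.sum() > len(tm) / 2

    def test_matches_scipy_ttest_per_roi(self, tiny_cohort):
        from scipy import stats as sps

        tp = tiny_cohort.true_params
        tm = regional_group_map(tp, "tau_e_ms")
        roi = tp.roi.iloc[0]
        sub = tp[tp.roi == roi]
        t, p = sps.ttest_ind(
            sub[sub.group == "patient"].tau_e_ms, sub[sub.group == "control"].tau_e_ms
        )
        assert tm.loc[roi, "t"] == pytest.approx(t)
        assert tm.loc[roi, "p"] == pytest.approx(p)

    def test_insufficient_group_raises(self, tiny_cohort):
        tp = tiny_cohort.true_params
        solo = tp[(tp.group == "control") | (tp.subject_id == "P000")]
        with pytest.raises(ValueError):
            regional_group_map(solo, "tau_e_ms")
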