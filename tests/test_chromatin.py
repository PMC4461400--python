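"""DNase-qPCR inaccessibility, noise-pair ratios, regressions and PCA."""

import numpy as np
import pandas as pd
import pytest

import burstkit as bk


def _meas(clone, site, treated, untreated):
    return bk.QpcrMeasurement(clone, site, np.asarray(treated), np.asarray(untreated))


class TestInaccessibilityFromCt:
    def test_equal_delta_ct_gives_full_protection(self):
        tgt = _meas("c1", "Nuc-1", [25.0, 25.0, 25.0], [24.0, 24.0, 24.0])
        ref = _meas("c1", "reference", [23.0, 23.0, 23.0], [22.0, 22.0, 22.0])
        res = bk.inaccessibility_from_ct(tgt, ref)
        assert res.inaccessibility == pytest.approx(1.0)
        assert not res.clamped

    def test_one_cycle_extra_digestion_gives_half(self):
        tgt = _meas("c1", "Nuc-1", [25.0, 25.0], [24.0, 24.0])
        ref = _meas("c1", "reference", [22.0, 22.0], [22.0, 22.0])
        res = bk.inaccessibility_from_ct(tgt, ref)
        assert res.inaccessibility == pytest.approx(0.5)

    def test_super_reference_protection_clamped_to_one(self):
        tgt = _meas("c1", "Nuc-1", [24.5, 24.5], [24.0, 24.0])
        ref = _meas("c1", "reference", [23.0, 23.0], [22.0, 22.0])
        res = bk.inaccessibility_from_ct(tgt, ref)
        assert res.inaccessibility == 1.0
        assert res.clamped

    def test_ct_shift_invariance(self):
        rng = np.random.default_rng(0)
        t1, u1 = rng.normal(25, 0.1, 3), rng.normal(24, 0.1, 3)
        t2, u2 = rng.normal(23, 0.1, 3), rng.normal(22.5, 0.1, 3)
        base = bk.inaccessibility_from_ct(
            _meas("c", "HSS", t1, u1), _meas("c", "reference", t2, u2)
        )
        shifted = bk.inaccessibility_from_ct(
            _meas("c", "HSS", t1 + 5, u1 + 5), _meas("c", "reference", t2 + 5, u2 + 5)
        )
        assert shifted.inaccessibility == pytest.approx(base.inaccessibility, rel=1e-12)
        assert shifted.sd == pytest.approx(base.sd, rel=1e-12)

    def test_clone_mismatch_and_replicate_validation(self):
        tgt = _meas("c1", "Nuc-1", [25.0, 25.0], [24.0, 24.0])
        ref = _meas("c2", "reference", [23.0, 23.0], [22.0, 22.0])
        with pytest.raises(ValueError):
            bk.inaccessibility_from_ct(tgt, ref)
        with pytest.raises(ValueError):
            _meas("c1", "Nuc-1", [25.0], [24.0, 24.0])
        with pytest.warns(UserWarning, match="replicates"):
            _meas("c1", "Nuc-1", [25.0, 25.0], [24.0, 24.0])

    def test_missing_untreated_series_in_table(self):
        qpcr = pd.DataFrame(
            {
                "clone_id": ["c1"] * 4,
                "site": ["Nuc-1", "Nuc-1", "reference", "reference"],
                "condition": ["treated", "treated", "treated", "untreated"],
                "replicate": [0, 1, 0, 0],
                "Ct": [25.0, 25.1, 23.0, 22.0],
            }
        )
        with pytest.raises(ValueError, match="untreated"):
            bk.profiles_from_qpcr(qpcr)


class TestNoisePairRatio:
    def _profiles(self):
        return pd.DataFrame(
            {
                "clone_id": ["hi", "lo"],
                "site": ["Nuc-1", "Nuc-1"],
                "inaccessibility": [0.4, 0.4],
                "sd": [0.02, 0.02],
                "clamped": [False, False],
            }
        )

    def test_identical_profiles_ratio_one(self):
        pairs = pd.DataFrame({"high_noise_clone": ["hi"], "low_noise_clone": ["lo"]})
        out = bk.noise_pair_ratio(self._profiles(), pairs, "Nuc-1")
        assert out["ratio"][0] == pytest.approx(1.0)

    def test_missing_clone_recorded_not_raised(self):
        pairs = pd.DataFrame(
            {"high_noise_clone": ["hi", "ghost"], "low_noise_clone": ["lo", "lo"]}
        )
        out = bk.noise_pair_ratio(self._profiles(), pairs, "Nuc-1")
        assert np.isnan(out["ratio"][1])
        assert "ghost" in out["error"][1]
        assert out["ratio"][0] == pytest.approx(1.0)  # batch continued

    def test_cohort_pairs_show_elevated_inaccessibility_in_noisy_clone(
        self, default_cohort
    ):
        # full chain: moments -> clusters -> pairs -> chromatin ratio
        cfg = default_cohort.config
        rows = []
        for c in default_cohort.counts:
            m = c.counts.mean()
            v = c.counts.var(ddof=1)
            rows.append(
                {"clone_id": c.clone_id, "mean": m, "cv": float(np.sqrt(v) / m)}
            )
        summaries = pd.DataFrame(rows)
        labels = bk.cluster_clone_distributions(summaries, k=4)
        pairs = bk.select_noise_pairs(summaries, labels, mean_tol=0.1)
        assert len(pairs) >= 3
        profiles = bk.profiles_from_qpcr(
            bk.generate_chromatin_panel(default_cohort.truth, cfg)
        )
        out = bk.noise_pair_ratio(profiles, pairs, "Nuc-1")
        assert np.nanmedian(out["ratio"]) > 1.0


class TestKineticsAccessibilityRegression:
    def _toy(self):
        rng = np.random.default_rng(3)
        f = 10 ** rng.uniform(-1, 0.3, 12)
        i_vals = 10 ** (-0.8 - 0.6 * np.log10(f) + rng.normal(0, 0.05, 12))
        profiles = pd.DataFrame(
            {
                "clone_id": [f"c{k}" for k in range(12)],
                "site": "Nuc-1",
                "inaccessibility": np.minimum(i_vals, 1.0),
                "sd": 0.01,
                "clamped": False,
            }
        )
        fits = pd.DataFrame(
            {
                "clone_id": [f"c{k}" for k in range(12)],
                "burst_freq": f,
                "burst_size": 10 ** rng.uniform(0.3, 1.5, 12),
            }
        )
        return profiles, fits

    def test_delegates_to_loglog_regression(self):
        profiles, fits = self._toy()
        regs = bk.kinetics_accessibility_regression(profiles, fits, "Nuc-1")
        merged = profiles.merge(fits, on="clone_id")
        direct = bk.loglog_regression(merged["inaccessibility"], merged["burst_freq"])
        assert regs["burst_freq_on_inaccessibility"] == direct

    def test_absent_site_rejected(self):
        profiles, fits = self._toy()
        with pytest.raises(ValueError, match="HSS"):
            bk.kinetics_accessibility_regression(profiles, fits, "HSS")

    def test_nuc1_is_best_predictor_on_default_cohort(
        self, default_cohort, fitted_cohort
    ):
        profiles = bk.profiles_from_qpcr(
            bk.generate_chromatin_panel(default_cohort.truth, default_cohort.config)
        )
        fits = fitted_cohort.table
        r2 = {}
        for site in ("Nuc-1", "HSS", "Nuc-0"):
            reg = bk.kinetics_accessibility_regression(profiles, fits, site)
            headline = reg["burst_freq_on_inaccessibility"]
            r2[site] = headline.r2
            if site == "Nuc-1":
                assert headline.slope < 0
                assert headline.slope_ci[1] < 0  # 95% CI excludes zero
        assert r2["Nuc-1"] > r2["HSS"]
        assert r2["Nuc-1"] > r2["Nuc-0"]

    def test_uncoupled_chromatin_shows_no_association(self):
        rejections = 0
        for seed in range(10):
            cfg = bk.CohortConfig(
                n_clones=20,
                cells_per_clone=50,
                seed=seed,
                chromatin={
                    "Nuc-1": bk.SiteCoupling(-0.8, 0.0, 0.15),
                    "HSS": bk.SiteCoupling(-0.6, 0.0, 0.25),
                    "Nuc-0": bk.SiteCoupling(-0.7, 0.0, 0.30),
                },
            )
            cohort = bk.generate_cohort(cfg)
            profiles = bk.profiles_from_qpcr(
                bk.generate_chromatin_panel(cohort.truth, cfg)
            )
            fits = cohort.truth.rename(columns={})[
                ["clone_id", "burst_freq", "burst_size"]
            ]
            reg = bk.kinetics_accessibility_regression(profiles, fits, "Nuc-1")
            rejections += reg["burst_freq_on_inaccessibility"].p_slope < 0.05
        assert rejections <= 1  # >= 90% of runs show no association


class TestChromatinPca:
    def test_perfectly_correlated_columns_share_loading_magnitude(self):
        rng = np.random.default_rng(5)
        f = 10 ** rng.uniform(-1, 0.3, 15)
        i1 = 10 ** (-0.5 - 0.5 * np.log10(f))
        profiles = pd.DataFrame(
            {
                "clone_id": np.repeat([f"c{k}" for k in range(15)], 2),
                "site": ["Nuc-1", "HSS"] * 15,
                "inaccessibility": np.column_stack([i1, i1**2]).ravel(),
                "sd": 0.0,
                "clamped": False,
            }
        )
        fits = pd.DataFrame(
            {"clone_id": [f"c{k}" for k in range(15)], "burst_freq": f}
        )
        pca = bk.chromatin_pca(profiles, fits)
        load = pca.loadings[:, 0]
        # all three standardized variables are exactly collinear
        assert abs(load[0]) == pytest.approx(abs(load[1]), abs=1e-9)
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_two_variable_closed_form(self):
        # for a 2x2 correlation matrix the top eigenvalue is 1 + |r|
        rng = np.random.default_rng(6)
        f = 10 ** rng.uniform(-1, 0.3, 40)
        i1 = 10 ** (-0.5 - 0.7 * np.log10(f) + rng.normal(0, 0.2, 40))
        profiles = pd.DataFrame(
            {
                "clone_id": [f"c{k}" for k in range(40)],
                "site": "Nuc-1",
                "inaccessibility": np.minimum(i1, 1.0),
                "sd": 0.0,
                "clamped": False,
            }
        )
        fits = pd.DataFrame({"clone_id": [f"c{k}" for k in range(40)], "burst_freq": f})
        pca = bk.chromatin_pca(profiles, fits)
        r = np.corrcoef(
            np.log10(profiles["inaccessibility"]), np.log10(f)
        )[0, 1]
        assert pca.explained_variance_ratio[0] == pytest.approx((1 + abs(r)) / 2, rel=1e-9)

    def test_fractions_sum_to_one_and_row_order_invariance(
        self, default_cohort, fitted_cohort
    ):
        profiles = bk.profiles_from_qpcr(
            bk.generate_chromatin_panel(default_cohort.truth, default_cohort.config)
        )
        fits = fitted_cohort.table
        pca = bk.chromatin_pca(profiles, fits)
        assert pca.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-12)
        shuffled = bk.chromatin_pca(
            profiles.sample(frac=1.0, random_state=1), fits.sample(frac=1.0, random_state=2)
        )
        np.testing.assert_allclose(pca.loadings, shuffled.loadings, atol=1e-9)

    def test_f_axis_aligns_with_nuc1_on_default_cohort(self, default_cohort, fitted_cohort):
        profiles = bk.profiles_from_qpcr(
            bk.generate_chromatin_panel(default_cohort.truth, default_cohort.config)
        )
        pca = bk.chromatin_pca(profiles, fitted_cohort.table)
        load = pd.DataFrame(pca.loadings, index=pca.variables)
        # on the leading component the f axis opposes Nuc-1 inaccessibility
        assert load.loc["log10_burst_freq", 0] * load.loc["log10_I_Nuc-1", 0] < 0

    def test_constant_column_named_in_error(self):
        profiles = pd.DataFrame(
            {
                "clone_id": ["a", "b", "c"],
                "site": "Nuc-1",
                "inaccessibility": [0.5, 0.5, 0.5],
                "sd": 0.0,
                "clamped": False,
            }
        )
        fits = pd.DataFrame({"clone_id": ["a", "b", "c"], "burst_freq": [0.1, 0.5, 1.0]})
        with pytest.raises(ValueError, match="Nuc-1"):
            bk.chromatin_pca(profiles, fits)
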