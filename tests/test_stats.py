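"""Mixed model fit, within-subject permutation scheme, p-value conventions."""

import numpy as np
import pandas as pd
import pytest

from optolfp import (
    fit_model,
    perm_p_value,
    permutation_test,
    permute_labels,
    simulate_response_table,
)
from optolfp.stats import design_matrix


def balanced_table(n_subjects=6, betas=(0.5, 0.3, 0.1, 0.05), subject_sd=0.0,
                   noise_sd=0.0, seed=0):
    """Balanced design with known generating coefficients on standardized scale."""
    rng = np.random.default_rng(seed)
    durations = [1.0, 2.0, 5.0]
    intensities = [0.5, 2.0, 10.0]
    rows = []
    for k in range(n_subjects):
        u = rng.normal(0, subject_sd) if subject_sd > 0 else 0.0
        for d in durations:
            for i in intensities:
                rows.append(dict(subject_id=f"s{k}", duration_ms=d, intensity_mW=i,
                                 _u=u))
    tab = pd.DataFrame(rows)
    X = design_matrix(tab["intensity_mW"].to_numpy(), tab["duration_ms"].to_numpy())
    y = X @ np.asarray(betas) + tab["_u"].to_numpy()
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, y.size)
    tab["amplitude"] = y
    return tab.drop(columns="_u")


class TestFitModel:
    def test_single_subject_rejected(self):
        tab = balanced_table(n_subjects=1)
        with pytest.raises(ValueError, match="2 subjects"):
            fit_model(tab)

    def test_single_factor_level_rejected(self):
        tab = balanced_table()
        tab["duration_ms"] = 1.0
        with pytest.raises(ValueError, match="duration"):
            fit_model(tab)

    def test_noise_free_recovery_is_exact(self):
        # zero random-effect variance, zero noise: GLS reduces to exact algebra
        tab = balanced_table(betas=(0.4, 0.25, 0.1, 0.05))
        from optolfp._lmm import reml_fit

        X = design_matrix(tab["intensity_mW"].to_numpy(), tab["duration_ms"].to_numpy())
        fit = reml_fit(tab["amplitude"].to_numpy(), X,
                       pd.factorize(tab["subject_id"])[0])
        np.testing.assert_allclose(fit.beta, (0.4, 0.25, 0.1, 0.05), atol=1e-6)

    def test_zero_group_variance_matches_ols(self):
        # balanced noisy design without subject effects: REML lambda -> 0 and
        # the fixed effects equal ordinary least squares (the closed form)
        tab = balanced_table(noise_sd=0.1, seed=4)
        from optolfp._lmm import reml_fit

        X = design_matrix(tab["intensity_mW"].to_numpy(), tab["duration_ms"].to_numpy())
        y = tab["amplitude"].to_numpy()
        fit = reml_fit(y, X, pd.factorize(tab["subject_id"])[0])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ols, atol=1e-6)

    def test_fast_engine_agrees_with_statsmodels(self, calib_cfg):
        # dual route: internal profiled-REML solver vs MixedLM on the same table
        tab = simulate_response_table(calib_cfg, 8, seed=3)
        z_fast = fit_model(tab, engine="fast")
        z_sm = fit_model(tab, engine="statsmodels")
        for eff in ("intensity", "duration", "interaction"):
            assert z_fast[eff] == pytest.approx(z_sm[eff], rel=0.01)

    def test_pure_noise_z_is_moderate(self):
        rng_z = []
        for seed in range(5):
            tab = balanced_table(betas=(0, 0, 0, 0), noise_sd=1.0,
                                 n_subjects=10, seed=seed)
            z = fit_model(tab, engine="fast")
            rng_z.extend(abs(v) for v in z.values())
        assert max(rng_z) < 4.0

    def test_categorical_coding_not_silently_accepted(self):
        with pytest.raises(NotImplementedError):
            fit_model(balanced_table(), coding="categorical")


class TestPermuteLabels:
    def test_multisets_preserved_within_subject(self, calib_cfg):
        tab = simulate_response_table(calib_cfg, 4, seed=1)
        rng = np.random.default_rng(0)
        for effect in ("intensity", "duration", "interaction"):
            perm = permute_labels(tab, effect, rng)
            for subj, g in tab.groupby("subject_id"):
                gp = perm[perm.subject_id == subj]
                assert sorted(zip(g.duration_ms, g.intensity_mW)) == sorted(
                    zip(gp.duration_ms, gp.intensity_mW)
                )
                # amplitudes stay attached to their rows
                np.testing.assert_array_equal(
                    g["amplitude"].to_numpy(), gp["amplitude"].to_numpy()
                )

    def test_stratification_fixes_other_factor_per_row(self, calib_cfg):
        tab = simulate_response_table(calib_cfg, 3, seed=2)
        rng = np.random.default_rng(1)
        perm = permute_labels(tab, "intensity", rng)
        np.testing.assert_array_equal(
            tab["duration_ms"].to_numpy(), perm["duration_ms"].to_numpy()
        )

    def test_single_row_per_stratum_is_identity(self):
        # one intensity observation per (subject, duration): nothing to permute
        tab = pd.DataFrame(
            dict(subject_id=f"s{k}", duration_ms=d,
                 intensity_mW=0.5 if k % 2 else 10.0, amplitude=0.1 * k + d)
            for k in range(4) for d in (1.0, 2.0)
        )
        rng = np.random.default_rng(3)
        perm = permute_labels(tab, "intensity", rng)
        pd.testing.assert_frame_equal(tab, perm)

    def test_fixed_seed_reproducible(self, calib_cfg):
        tab = simulate_response_table(calib_cfg, 4, seed=1)
        a = permute_labels(tab, "interaction", np.random.default_rng(9))
        b = permute_labels(tab, "interaction", np.random.default_rng(9))
        pd.testing.assert_frame_equal(a, b)


class TestPermutationTest:
    def test_add_one_p_floor(self):
        # observed more extreme than all permuted statistics
        assert perm_p_value(np.zeros(10_000), 5.0) == pytest.approx(1 / 10_001)

    def test_all_as_extreme_gives_p_one(self):
        assert perm_p_value(np.full(100, 2.0), 2.0) == 1.0

    def test_identity_permutations_give_p_one(self):
        # one row per (subject, duration) stratum: every permutation is the
        # identity, so every permuted z equals the observed z
        rng = np.random.default_rng(7)
        rows = [
            dict(subject_id=f"s{k}", duration_ms=d,
                 intensity_mW=0.5 if k % 2 else 10.0,
                 amplitude=rng.uniform(0.2, 1.0))
            for k in range(6) for d in (1.0, 2.0, 5.0)
        ]
        tab = pd.DataFrame(rows)
        res = permutation_test(tab, "intensity", n_permutations=50, seed=0)
        assert res.p_value == 1.0

    def test_bit_reproducible(self, calib_cfg):
        tab = simulate_response_table(calib_cfg, 6, seed=5)
        a = permutation_test(tab, "duration", n_permutations=60, seed=11)
        b = permutation_test(tab, "duration", n_permutations=60, seed=11)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.perm_z, b.perm_z)

    def test_strong_effect_hits_the_floor(self, calib_cfg):
        tab = simulate_response_table(calib_cfg, 8, seed=3)
        res = permutation_test(tab, "intensity", n_permutations=200, seed=2)
        assert res.p_value == pytest.approx(1 / 201)
        assert res.significant
        assert res.normalized_z > 2.0

    def test_p_value_bounds(self, calib_cfg):
        tab = simulate_response_table(calib_cfg, 5, seed=9, intensity_weight=0.0)
        res = permutation_test(tab, "intensity", n_permutations=99, seed=4)
        assert 1 / 100 <= res.p_value <= 1.0
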