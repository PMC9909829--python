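"""Feature extraction: windows, Fourier projections, curve fits, tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adtherm.features import (
    FeatureConfig,
    FeatureTable,
    META_COLUMNS,
    apply_normalization,
    extract_features,
    feature_names,
    fit_exponential_decay,
    fit_lumped_pennes,
    fourier_coefficients,
    integrate_control,
    normalize_features,
    pixel_feature_vector,
    relaxation_segment,
)
from adtherm.simulate import (
    LumpedModel,
    Protocol,
    ThermalSignal,
    simulate_cohort,
    simulate_signal,
)

from conftest import noiseless, small_cohort_config


def make_signal(times, temps, heat_end=0):
    return ThermalSignal(np.asarray(times, float), np.asarray(temps, float), heat_end)


# ---------------------------------------------------------------- windows


class TestRelaxationSegment:
    def test_default_protocol_gives_500_samples_from_zero(self, benign_lumped, protocol):
        signal = simulate_signal(benign_lumped, protocol)
        seg = relaxation_segment(signal)
        assert len(seg) == 500
        assert seg.times[0] == 0.0

    def test_empty_segment_rejected(self):
        sig = make_signal([0, 1, 2], [1, 2, 3], heat_end=3)
        with pytest.raises(ValueError):
            relaxation_segment(sig)

    def test_idempotent_on_pure_relaxation(self, benign_lumped, protocol):
        seg = relaxation_segment(simulate_signal(benign_lumped, protocol))
        again = relaxation_segment(seg)
        assert np.array_equal(seg.times, again.times)
        assert np.array_equal(seg.temperatures, again.temperatures)


# ---------------------------------------------------------------- Fourier


def fourier_projection_oracle(x, harmonics):
    """Direct Riemann-sum projection onto cos/sin over one period."""
    n = len(x)
    k = np.arange(n)
    a0 = x.mean()
    a = np.array([2 / n * np.sum(x * np.cos(2 * np.pi * h * k / n)) for h in range(1, harmonics + 1)])
    b = np.array([2 / n * np.sum(x * np.sin(2 * np.pi * h * k / n)) for h in range(1, harmonics + 1)])
    return a0, a, b


class TestFourierCoefficients:
    def test_constant_signal(self):
        sig = make_signal(np.arange(100) / 10, np.full(100, 3.7))
        ff = fourier_coefficients(sig, harmonics=4, detrend=True)
        assert ff.a0 == pytest.approx(3.7, abs=1e-9)
        assert np.all(np.abs(ff.a) < 1e-9)
        assert np.all(np.abs(ff.b) < 1e-9)

    def test_single_cosine_one_period(self):
        n = 200
        t = np.arange(n) / n * 20.0  # one period P = 20 s
        sig = make_signal(t, np.cos(2 * np.pi * t / 20.0))
        ff = fourier_coefficients(sig, harmonics=5, detrend=False)
        assert ff.a[0] == pytest.approx(1.0, abs=1e-6)
        assert abs(ff.a0) < 1e-6
        assert np.all(np.abs(ff.a[1:]) < 1e-6)
        assert np.all(np.abs(ff.b) < 1e-6)

    def test_matches_direct_projection_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=500)
        sig = make_signal(np.arange(500) / 10, x)
        ff = fourier_coefficients(sig, harmonics=8, detrend=False)
        a0, a, b = fourier_projection_oracle(x, 8)
        assert abs(ff.a0 - a0) < 1e-8
        assert np.abs(ff.a - a).max() < 1e-8
        assert np.abs(ff.b - b).max() < 1e-8

    def test_too_few_samples_rejected(self):
        sig = make_signal(np.arange(10) / 10, np.zeros(10))
        with pytest.raises(ValueError):
            fourier_coefficients(sig, harmonics=8)


# ---------------------------------------------------------------- decay fit


def decay_grid_oracle(t, y, n_grid=4001):
    """Dense rate grid with an exact linear solve per candidate (lstsq)."""
    lams = np.geomspace(1e-4, 10.0, n_grid)
    best = None
    for lam in lams:
        design = np.column_stack([np.ones_like(t), np.exp(-lam * t)])
        coef, res, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(res[0]) if len(res) else float(((design @ coef - y) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, lam, coef)
    return best  # (rss, lambda, (t_eq, amplitude))


def profile_interval(t, y, alpha=0.05, n_grid=2001):
    """95% profile-likelihood interval for the rate from the grid oracle."""
    lams = np.geomspace(1e-4, 10.0, n_grid)
    rss = np.empty(n_grid)
    for i, lam in enumerate(lams):
        design = np.column_stack([np.ones_like(t), np.exp(-lam * t)])
        coef, res, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss[i] = float(res[0]) if len(res) else float(((design @ coef - y) ** 2).sum())
    dof = len(t) - 3
    crit = stats.f.ppf(1 - alpha, 1, dof)
    cutoff = rss.min() * (1 + crit / dof)
    inside = lams[rss <= cutoff]
    return inside.min(), inside.max()


class TestExponentialDecayFit:
    def test_exact_on_model_class(self):
        t = np.arange(500) / 10.0
        sig = make_signal(t, 37.0 + 7.0 * np.exp(-0.1 * t))
        fit = fit_exponential_decay(sig)
        assert fit.converged
        assert abs(fit.lambda_hat - 0.1) < 1e-6
        assert abs(fit.amplitude_hat - 7.0) < 1e-6
        assert abs(fit.t_eq_hat - 37.0) < 1e-6

    def test_constant_signal_unidentifiable(self):
        sig = make_signal(np.arange(100) / 10, np.full(100, 34.0))
        fit = fit_exponential_decay(sig)
        assert not fit.converged
        assert abs(fit.amplitude_hat) < 1e-9

    def test_noisy_estimate_within_oracle_interval(self):
        rng = np.random.default_rng(5)
        t = np.arange(500) / 10.0
        y = 34.0 + 7.0 * np.exp(-0.021 * t) + rng.normal(0, 0.05, 500)
        fit = fit_exponential_decay(make_signal(t, y))
        lo, hi = profile_interval(t, y)
        assert lo <= fit.lambda_hat <= hi

    def test_non_finite_rejected(self):
        y = np.ones(10)
        y[3] = np.nan
        with pytest.raises(ValueError):
            fit_exponential_decay(make_signal(np.arange(10.0), y))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_decay(make_signal([0, 1, 2], [3, 2, 1]))


# ---------------------------------------------------------------- lumped fit


class TestLumpedPennesFit:
    def test_self_consistency_noiseless(self, benign_lumped, protocol):
        signal = simulate_signal(benign_lumped, protocol)
        fit = fit_lumped_pennes(signal, protocol)
        assert fit.converged
        assert abs(fit.lambda_p_hat - benign_lumped.decay_rate) / benign_lumped.decay_rate < 1e-6
        assert abs(fit.g_hat - benign_lumped.forcing_gain) / benign_lumped.forcing_gain < 1e-6
        assert abs(fit.t_eq_hat - benign_lumped.equilibrium_temp) < 1e-6

    def test_zero_drive_recovered(self, protocol):
        model = LumpedModel(equilibrium_temp=34.0, decay_rate=0.05, forcing_gain=0.0)
        fit = fit_lumped_pennes(simulate_signal(model, protocol), protocol)
        assert abs(fit.g_hat) < 1e-6

    def test_noisy_recovery_matches_grid_oracle(self, benign_lumped, protocol):
        """Bias and spread over replicates agree with an independent grid search.

        The oracle profiles the rate on a dense grid with an lstsq solve of
        the piecewise-response design; agreement is required within
        Monte-Carlo error of the replicate means.
        """
        n_rep = 200
        t = protocol.times()
        hd = protocol.heat_duration
        heating = t < hd

        def oracle_lambda(y):
            lams = np.geomspace(5e-3, 0.2, 600)
            best = (np.inf, None)
            for lam in lams:
                phi = np.empty_like(t)
                phi[heating] = -np.expm1(-lam * t[heating]) / lam
                phi[~heating] = (-np.expm1(-lam * hd) / lam) * np.exp(
                    -lam * (t[~heating] - hd)
                )
                design = np.column_stack([np.ones_like(t), phi])
                coef, res, *_ = np.linalg.lstsq(design, y, rcond=None)
                rss = float(res[0]) if len(res) else float(((design @ coef - y) ** 2).sum())
                if rss < best[0]:
                    best = (rss, lam)
            return best[1]

        rng = np.random.default_rng(2024)
        ours, oracle = [], []
        clean = simulate_signal(benign_lumped, protocol).temperatures
        for _ in range(n_rep):
            y = clean + rng.normal(0, 0.05, len(t))
            sig = ThermalSignal(t, y, protocol.heat_end_index)
            ours.append(fit_lumped_pennes(sig, protocol).lambda_p_hat)
            oracle.append(oracle_lambda(y))
        ours, oracle = np.array(ours), np.array(oracle)
        mc_err = ours.std(ddof=1) / np.sqrt(n_rep)
        assert abs(ours.mean() - oracle.mean()) < 3 * mc_err + 1e-4  # grid pitch slack
        assert abs(ours.std(ddof=1) - oracle.std(ddof=1)) < 0.5 * ours.std(ddof=1)


# ---------------------------------------------------------------- vectors


class TestPixelFeatureVector:
    def test_default_feature_count_is_44(self, benign_lumped, protocol):
        fv = pixel_feature_vector(simulate_signal(benign_lumped, protocol), protocol)
        assert len(fv) == 44 == FeatureConfig().n_features
        assert list(fv) == feature_names()

    def test_identical_signals_identical_vectors(self, benign_lumped, protocol):
        rng = np.random.default_rng(1)
        sig = simulate_signal(benign_lumped, protocol, 0.05, rng)
        assert pixel_feature_vector(sig, protocol) == pixel_feature_vector(sig, protocol)

    def test_entries_match_component_recomputation(self, benign_lumped, protocol):
        rng = np.random.default_rng(9)
        sig = simulate_signal(benign_lumped, protocol, 0.05, rng)
        fv = pixel_feature_vector(sig, protocol)
        ff = fourier_coefficients(sig, 8, "relaxation", True)
        assert fv["fourier_relax_a0"] == ff.a0
        assert fv["fourier_relax_a3"] == ff.a[2]
        d = fit_exponential_decay(relaxation_segment(sig))
        assert fv["decay_lambda"] == d.lambda_hat
        p = fit_lumped_pennes(sig, protocol, decay_init=d)
        assert fv["pennes_lambda_p"] == p.lambda_p_hat
        assert fv["baseline_c"] == sig.temperatures[0]
        assert fv["peak_c"] == sig.temperatures.max()


# ------------------------------------------------------- control integration


def _small_tables(config):
    records = simulate_cohort(config)
    site, control = extract_features(records, config.protocol)
    return records, site, control


class TestIntegrateControl:
    def test_identical_grids_integrate_to_zero(self):
        config = noiseless(small_cohort_config(), delta_base_mean=0.0, lambda_ratio=1.0)
        _, site, control = _small_tables(config)
        integrated = integrate_control(site, control)
        assert np.abs(integrated.features.to_numpy()).max() < 1e-9

    def test_malignant_baseline_feature_is_plus_one(self):
        """Noiseless +1 degC elevation survives integration exactly."""
        config = noiseless(small_cohort_config(malignancy_prevalence=1.0))
        _, site, control = _small_tables(config)
        integrated = integrate_control(site, control)
        assert np.allclose(integrated.data["baseline_c"], 1.0, atol=1e-9)

    def test_matches_subtraction_oracle(self):
        config = small_cohort_config(seed=4)
        _, site, control = _small_tables(config)
        integrated = integrate_control(site, control)
        feats = site.feature_columns
        for mass_id in site.data["mass_id"].unique():
            site_block = site.data[site.data.mass_id == mass_id][feats].to_numpy()
            ctrl_mean = control.data[control.data.mass_id == mass_id][feats].mean().to_numpy()
            got = integrated.data[integrated.data.mass_id == mass_id][feats].to_numpy()
            assert np.allclose(got, site_block - ctrl_mean, atol=1e-12)

    def test_missing_control_grid_rejected(self):
        config = small_cohort_config()
        _, site, control = _small_tables(config)
        trimmed = FeatureTable(
            control.data[control.data.mass_id != site.data.mass_id.iloc[0]].copy(), "raw"
        )
        with pytest.raises(ValueError, match="control grid"):
            integrate_control(site, trimmed)


# ---------------------------------------------------------------- z-scoring


class TestNormalization:
    def test_zscore_properties(self):
        config = small_cohort_config(seed=6)
        _, site, control = _small_tables(config)
        table = integrate_control(site, control)
        normalized, stats_ = normalize_features(table)
        values = normalized.features
        nonzero = [c for c in values.columns if c not in stats_.zero_variance]
        assert np.abs(values[nonzero].mean()).max() < 1e-12
        assert np.abs(values[nonzero].std(ddof=1) - 1).max() < 1e-12

    def test_two_row_closed_form(self):
        df = pd.DataFrame(
            {
                "dog_id": ["d", "d"],
                "mass_id": ["m1", "m2"],
                "pixel_row": [0, 0],
                "pixel_col": [0, 0],
                "label": ["benign", "malignant"],
                "f": [1.0, 3.0],
            }
        )
        normalized, _ = normalize_features(FeatureTable(df, "control-integrated"))
        # sample (n-1) convention: s.d. of [1, 3] is sqrt(2)
        assert np.allclose(normalized.data["f"], [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_held_out_rows_use_training_stats(self):
        config = small_cohort_config(seed=8)
        _, site, control = _small_tables(config)
        table = integrate_control(site, control)
        masses = table.data.mass_id.unique()
        train = FeatureTable(table.data[table.data.mass_id != masses[0]].copy(), table.state)
        test = FeatureTable(table.data[table.data.mass_id == masses[0]].copy(), table.state)
        _, stats_ = normalize_features(train)
        got = apply_normalization(test, stats_)
        feats = table.feature_columns
        manual = (test.data[feats] - stats_.means) / stats_.sds.replace(0.0, 1.0)
        assert np.allclose(got.data[feats].to_numpy(), manual.to_numpy(), equal_nan=True)

    def test_zero_variance_flagged_and_zeroed(self):
        df = pd.DataFrame(
            {
                "dog_id": ["d"] * 4,
                "mass_id": ["m1", "m1", "m2", "m2"],
                "pixel_row": [0, 1, 0, 1],
                "pixel_col": [0, 0, 0, 0],
                "label": ["benign"] * 2 + ["malignant"] * 2,
                "flat": [2.0, 2.0, 2.0, 2.0],
                "varies": [1.0, 2.0, 3.0, 4.0],
            }
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            normalized, stats_ = normalize_features(FeatureTable(df, "control-integrated"))
        assert stats_.zero_variance == ("flat",)
        assert np.all(normalized.data["flat"] == 0.0)


def test_metadata_columns_come_first(toy_cohort_config):
    records = simulate_cohort(toy_cohort_config)
    site, _ = extract_features(records, toy_cohort_config.protocol)
    assert list(site.data.columns[: len(META_COLUMNS)]) == META_COLUMNS
    assert len(site.data) == len(records) * toy_cohort_config.protocol.n_pixels
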