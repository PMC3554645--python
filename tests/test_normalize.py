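import dataclasses

import numpy as np
import pytest

import urimir as u
from urimir.normalize import (
    CorrectedPanel,
    DeltaPosterior,
    SpeciesSkipped,
    fit_paired_delta,
    paired_differences,
)

from conftest import FAST, toy_panel_frame


def pair_panel(d_values, base=25.0):
    """Toy single-plate panel whose paired differences equal ``d_values``."""
    rows = []
    pairs = []
    for j, d in enumerate(d_values):
        e, r = f"e{j}", f"r{j}"
        rows.append(("m", e, "p1", 1, base + d, "mirna"))
        rows.append(("m", r, "p1", 1, base, "mirna"))
        pairs.append((e, r))
    return toy_panel_frame(rows), pairs


class TestPlateEffects:
    def test_noiseless_two_plate_contrast(self):
        rows = []
        for rep in range(1, 7):
            rows.append(("UniSp3", "s1", "pA", rep, 20.0, "spike_cal"))
            rows.append(("UniSp3", "s1", "pB", rep, 21.0, "spike_cal"))
        pe = u.estimate_plate_effects(toy_panel_frame(rows), settings=FAST, seed=1)
        contrast = pe.beta[:, pe.plate_ids.index("pB")] - pe.beta[:, pe.plate_ids.index("pA")]
        assert abs(contrast.mean() - 1.0) < 1e-3
        assert contrast.std() < 1e-3

    def test_single_plate_rejected(self):
        rows = [("UniSp3", "s1", "pA", rep, 20.0, "spike_cal") for rep in range(1, 7)]
        with pytest.raises(ValueError, match="2 plates"):
            u.estimate_plate_effects(toy_panel_frame(rows), settings=FAST, seed=1)

    def test_recovers_simulated_plate_shifts(self, small_fitted):
        # 24 plates: posterior means track the planted shifts
        panel, _, truth, pe, _, _ = small_fitted
        est = pe.beta_mean()
        true = truth.plate_shift.reindex(pe.plate_ids).to_numpy()
        true = true - true.mean()
        rmse = np.sqrt(np.mean((est - true) ** 2))
        post_sd = pe.beta.std(axis=0).mean()
        assert np.corrcoef(est, true)[0, 1] > 0.9
        assert rmse < 3 * post_sd

    def test_sum_to_zero_constraint(self, small_fitted):
        *_, pe, _, _ = small_fitted
        np.testing.assert_allclose(pe.beta.sum(axis=1), 0.0, atol=1e-9)

    def test_seeded_run_is_bit_reproducible(self):
        rows = []
        rng = np.random.default_rng(4)
        for p in ("pA", "pB", "pC"):
            for rep in range(1, 7):
                rows.append(("UniSp3", "s1", p, rep, 20 + rng.normal(0, 0.3), "spike_cal"))
        panel = toy_panel_frame(rows)
        pe1 = u.estimate_plate_effects(panel, settings=FAST, seed=9)
        pe2 = u.estimate_plate_effects(panel, settings=FAST, seed=9)
        np.testing.assert_array_equal(pe1.beta, pe2.beta)
        np.testing.assert_array_equal(pe1.sigma, pe2.sigma)


class TestCorrectCq:
    def test_zero_draws_leave_raw_unchanged(self):
        panel, _ = pair_panel([1.0, 2.0])
        c = CorrectedPanel.identity(panel, n_draws=100)
        np.testing.assert_array_equal(
            c.point_corrected(), panel.wells["cq"].to_numpy(float)
        )

    def test_constant_beta_shifts_all_wells(self):
        panel, _ = pair_panel([1.0])
        beta = np.full((50, 1), 0.7)
        c = CorrectedPanel(panel, beta, panel.plates)
        np.testing.assert_allclose(
            c.point_corrected(), panel.wells["cq"].to_numpy(float) - 0.7
        )

    def test_draw_variance_equals_beta_variance(self, rng):
        panel, _ = pair_panel([1.0])
        beta = rng.normal(0, 0.4, size=(2000, 1))
        c = CorrectedPanel(panel, beta, panel.plates)
        draws = c.well_draws(np.array([0]))
        assert np.isclose(draws.var(), beta.var(), rtol=1e-9)

    def test_unknown_plate_rejected(self):
        panel, _ = pair_panel([1.0])
        with pytest.raises(ValueError, match="plate ids"):
            CorrectedPanel(panel, np.zeros((10, 1)), ["other_plate"])


class TestPairedDelta:
    def test_conjugate_closed_form_with_fixed_sigma(self):
        d_values = [0.8, 1.4, 2.1, 1.9, 2.6, 1.2, 2.2, 1.8]
        panel, pairs = pair_panel(d_values)
        c = CorrectedPanel.identity(panel, n_draws=40000)
        sigma = 0.5
        post = fit_paired_delta(c, pairs, "m", seed=3, sigma_fixed=sigma)
        jn = len(d_values)
        exact_mean = np.mean(d_values)
        exact_sd = sigma / np.sqrt(jn)
        mcse = exact_sd / np.sqrt(post.draws.size)
        assert abs(post.draws.mean() - exact_mean) < 3 * mcse
        assert abs(post.draws.std() - exact_sd) < 3 * exact_sd / np.sqrt(2 * post.draws.size)

    def test_noiseless_truth_recovered(self):
        panel, pairs = pair_panel([2.0, 2.0, 2.0])
        c = CorrectedPanel.identity(panel, n_draws=4000)
        post = fit_paired_delta(c, pairs, "m", seed=1)
        assert abs(post.draws.mean() - 2.0) < 1e-4

    def test_two_observations_center_on_their_mean(self):
        # d = {1, 3}: the posterior is centered at 2 under vague priors
        panel, pairs = pair_panel([1.0, 3.0])
        c = CorrectedPanel.identity(panel, n_draws=20000)
        post = fit_paired_delta(c, pairs, "m", seed=2)
        assert abs(np.median(post.draws) - 2.0) < 0.05
        fixed = fit_paired_delta(c, pairs, "m", seed=2, sigma_fixed=1.0)
        assert abs(fixed.draws.mean() - 2.0) < 3 * (1.0 / np.sqrt(2)) / np.sqrt(20000)

    def test_incomplete_pairs_dropped_and_skipped(self):
        panel, pairs = pair_panel([1.0, 3.0])
        # censor every experimental well
        w = panel.wells.copy()
        w.loc[w.sample_id.str.startswith("e"), "detected"] = False
        panel2 = u.CqPanelSet(w, panel.cutoff)
        c = CorrectedPanel.identity(panel2, n_draws=100)
        with pytest.raises(SpeciesSkipped):
            fit_paired_delta(c, pairs, "m", seed=1)

    def test_experimental_shift_moves_posterior_by_same_amount(self):
        d_values = [1.1, 0.6, 1.4, 0.8, 1.2, 1.0]
        panel, pairs = pair_panel(d_values)
        c = CorrectedPanel.identity(panel, n_draws=20000)
        m0 = fit_paired_delta(c, pairs, "m", seed=5).draws.mean()
        w = panel.wells.copy()
        exp_rows = w.sample_id.str.startswith("e")
        w.loc[exp_rows, "cq"] = w.loc[exp_rows, "cq"] + 0.9
        c2 = CorrectedPanel.identity(u.CqPanelSet(w, panel.cutoff), n_draws=20000)
        m1 = fit_paired_delta(c2, pairs, "m", seed=5).draws.mean()
        assert abs((m1 - m0) - 0.9) < 0.01

    def test_prior_bounds_sensitivity_is_negligible(self):
        d_values = [1.1, 0.6, 1.4, 0.8, 1.2, 1.0, 0.4, 1.6]
        panel, pairs = pair_panel(d_values)
        c = CorrectedPanel.identity(panel, n_draws=20000)
        means = []
        for f in (0.5, 1.0, 2.0):
            s = dataclasses.replace(
                u.McmcSettings(), loc_prior_sd=1e3 * f, sd_prior_upper=100.0 * f
            )
            means.append(fit_paired_delta(c, pairs, "m", settings=s, seed=7).draws.mean())
        assert max(means) - min(means) < 0.05

    def test_seeded_fit_is_bit_reproducible(self):
        panel, pairs = pair_panel([1.0, 2.0, 3.0])
        c = CorrectedPanel.identity(panel, n_draws=1000)
        a = fit_paired_delta(c, pairs, "m", seed=42).draws
        b = fit_paired_delta(c, pairs, "m", seed=42).draws
        np.testing.assert_array_equal(a, b)


class TestDeltaDelta:
    def test_zero_spike_leaves_draws_unchanged(self, rng):
        dm = DeltaPosterior("m", rng.normal(2, 0.3, 1000), 5)
        ds = DeltaPosterior("UniSp3", np.zeros(1000), 5)
        np.testing.assert_array_equal(u.delta_delta(dm, ds), dm.draws)

    def test_independent_draw_variances_add(self, rng):
        a = rng.normal(0, 0.5, 200000)
        b = rng.normal(0, 0.3, 200000)
        dd = u.delta_delta(DeltaPosterior("m", a, 5), DeltaPosterior("s", b, 5))
        assert np.isclose(dd.var(), a.var() + b.var(), rtol=0.02)

    def test_length_mismatch_needs_rng(self, rng):
        dm = DeltaPosterior("m", np.zeros(100), 5)
        ds = DeltaPosterior("s", np.zeros(50), 5)
        with pytest.raises(ValueError, match="mismatch"):
            u.delta_delta(dm, ds)
        assert len(u.delta_delta(dm, ds, rng=rng)) == 100


class TestSummarize:
    def test_pseudo_p_by_direct_count(self):
        s = u.summarize_posterior(np.array([0.1, 0.2, 0.3, -0.1]))
        assert s.pseudo_p == pytest.approx(0.5)

    def test_symmetric_draws_give_p_near_one(self, rng):
        s = u.summarize_posterior(rng.normal(0, 1, 20000))
        assert s.pseudo_p > 0.95

    def test_fold_change_of_two_cycles(self):
        s = u.summarize_posterior(np.full(2000, 2.0))
        assert s.fc == pytest.approx(0.25)
        assert s.degenerate

    def test_report_row_shape_matches_published_format(self):
        # published rows print fold change, a 95% CrI and a pseudocontour p,
        # e.g. "0.07  0.01-0.42  0.0030"
        rng = np.random.default_rng(0)
        s = u.summarize_posterior(rng.normal(3.8, 1.3, 4000), species_id="hsa-miR-323b-5p")
        row = s.row()
        assert set(row) >= {"miRNA", "fold_change", "fc_cri_low", "fc_cri_high", "p"}
        assert 0 < row["fc_cri_low"] < row["fold_change"] < row["fc_cri_high"]
        assert 0 < row["p"] <= 1

    def test_fc_interval_is_transformed_cq_interval(self, rng):
        s = u.summarize_posterior(rng.normal(1, 0.5, 5000))
        assert s.fc_cri_low == pytest.approx(2.0**-s.cri_high)
        assert s.fc_cri_high == pytest.approx(2.0**-s.cri_low)
        assert s.cri_low < s.cri_high
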