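import numpy as np
import pandas as pd
import pytest
from scipy.linalg import subspace_angles

import urimir as u
from conftest import toy_panel_frame


def make_matrix(rng, d=20, n=40, k=3, noise=0.3, load_scale=2.0):
    W = rng.normal(0, load_scale, (d, k))
    Z = rng.normal(0, 1, (n, k))
    X = (Z @ W.T + rng.normal(0, noise, (n, d)) + rng.normal(0, 1, d)).T
    return pd.DataFrame(
        X, index=[f"sp{i}" for i in range(d)], columns=[f"s{j}" for j in range(n)]
    ), Z


class TestCorrectedMatrix:
    def test_subtracts_plate_spike_mean(self):
        panel = toy_panel_frame(
            [("UniSp3", "s1", "p1", r, 20.0, "spike_cal") for r in range(1, 4)]
            + [("m1", "s1", "p1", 1, 25.0, "mirna")]
        )
        mat = u.corrected_matrix(panel)
        assert mat.loc["m1", "s1"] == pytest.approx(5.0)

    def test_duplicate_wells_averaged(self):
        panel = toy_panel_frame(
            [("UniSp3", "s1", "p1", 1, 20.0, "spike_cal"),
             ("m1", "s1", "p1", 1, 24.0, "mirna"),
             ("m1", "s1", "p1", 2, 26.0, "mirna")]
        )
        assert u.corrected_matrix(panel).loc["m1", "s1"] == pytest.approx(5.0)

    def test_undetected_cell_is_missing(self):
        panel = toy_panel_frame(
            [("UniSp3", "s1", "p1", 1, 20.0, "spike_cal"),
             ("m1", "s1", "p1", 1, np.nan, "mirna")]
        )
        assert np.isnan(u.corrected_matrix(panel).loc["m1", "s1"])

    def test_plate_without_spike_rejected(self):
        panel = toy_panel_frame([("m1", "s1", "p1", 1, 25.0, "mirna")])
        with pytest.raises(ValueError, match="spike"):
            u.corrected_matrix(panel)


class TestPpcaFit:
    def test_complete_data_subspace_matches_svd(self, rng):
        mat, _ = make_matrix(rng, d=20, n=40, k=5)
        fit = u.fit_ppca(mat, k=5, tol=1e-12, max_iter=20000, seed=1)
        Xc = mat.to_numpy().T - mat.to_numpy().T.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        assert subspace_angles(fit.loadings.to_numpy(), Vt[:5].T).max() < 1e-6
        assert np.all(np.diff(fit.loglik_trace) >= -1e-6 * np.abs(fit.loglik_trace[:-1]))

    def test_noiseless_rank_one(self, rng):
        z = rng.normal(0, 1, 15)
        w = rng.normal(0, 1, 9)
        mat = pd.DataFrame(np.outer(w, z))
        fit = u.fit_ppca(mat, k=1, tol=1e-12, max_iter=3000, seed=0)
        assert fit.sigma2 < 1e-8
        r = np.corrcoef(fit.scores.to_numpy()[:, 0], z - z.mean())[0, 1]
        assert abs(r) > 1 - 1e-6

    def test_mask_and_recover_imputation(self, rng):
        noise = 0.3
        mat, _ = make_matrix(rng, d=30, n=60, k=5, noise=noise)
        hide = rng.random(mat.shape) < 0.10
        fit = u.fit_ppca(mat.mask(hide), k=5, tol=1e-8, max_iter=5000, seed=2)
        held = mat.to_numpy()[hide]
        imp = fit.imputed.to_numpy()[hide]
        assert np.median(np.abs(held - imp)) < noise

    def test_sample_order_invariance(self, rng):
        mat, _ = make_matrix(rng, d=15, n=30, k=3)
        fit1 = u.fit_ppca(mat, k=3, tol=1e-10, max_iter=10000, seed=5)
        perm = rng.permutation(mat.columns)
        fit2 = u.fit_ppca(mat[perm], k=3, tol=1e-10, max_iter=10000, seed=5)
        ang = subspace_angles(fit1.loadings.to_numpy(), fit2.loadings.to_numpy())
        assert ang.max() < 1e-5

    def test_high_missing_rows_dropped(self, rng):
        mat, _ = make_matrix(rng, d=10, n=20, k=2)
        mat.iloc[0, :15] = np.nan
        fit = u.fit_ppca(mat, k=2, tol=1e-7, max_iter=2000, seed=1)
        assert fit.dropped_species == ["sp0"]
        assert "sp0" not in fit.loadings.index

    def test_k_out_of_range_rejected(self, rng):
        mat, _ = make_matrix(rng, d=5, n=8, k=2)
        with pytest.raises(ValueError):
            u.fit_ppca(mat, k=6)


class TestPairProximity:
    def test_coincident_pair_members_give_zero_ratio(self, rng):
        pts = np.repeat(rng.normal(0, 1, (6, 3)), 2, axis=0)
        scores = pd.DataFrame(pts, index=[f"s{i}" for i in range(12)])
        pid = pd.Series(np.repeat([f"p{j}" for j in range(6)], 2), index=scores.index)
        pp = u.pair_proximity_statistic(scores, pid, n_permutations=300, seed=1)
        assert pp.ratio == pytest.approx(0.0)
        assert pp.p_value < 0.05

    def test_shuffled_labels_behave_like_null(self, rng):
        pts = rng.normal(0, 1, (20, 4))
        scores = pd.DataFrame(pts, index=[f"s{i}" for i in range(20)])
        pid = pd.Series(
            rng.permutation(np.repeat([f"p{j}" for j in range(10)], 2)), index=scores.index
        )
        pp = u.pair_proximity_statistic(scores, pid, n_permutations=500, seed=2)
        assert 0.7 < pp.ratio < 1.3
        assert pp.p_value > 0.01

    def test_planted_pair_structure_detected(self):
        design = u.SimulationDesign(
            n_pairs=8, n_mirna=40, pair_sd=2.0, well_sd=0.15, plate_sd=0.3,
            missing_rate=0.0, frac_differential=0.0, seed=17,
        )
        panel, annotations, _ = u.simulate_panel_experiment(design)
        mat = u.corrected_matrix(panel)
        fit = u.fit_ppca(mat, k=3, tol=1e-7, max_iter=3000, seed=3)
        pid = pd.Series({a.sample_id: a.pair_id for a in annotations})
        pp = u.pair_proximity_statistic(fit.scores, pid, n_permutations=500, seed=4)
        assert pp.ratio < 1.0
        assert pp.p_value < 0.05
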