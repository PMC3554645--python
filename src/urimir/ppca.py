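"""Probabilistic PCA with EM on spike-corrected Cq profiles.

The model is the isotropic latent linear Gaussian factor model
x = W z + mu + eps with z ~ N(0, I_k) and eps ~ N(0, sigma^2 I).  EM handles
missing entries by taking expectations only over each sample's observed
coordinates, which simultaneously estimates the principal subspace and
imputes the missing Cq values.  On complete data the maximum-likelihood
subspace coincides with the span of the top-k principal components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CqPanelSet

log = logging.getLogger("urimir")


def corrected_matrix(panel: CqPanelSet) -> pd.DataFrame:
    """Species x sample matrix of spike-corrected Cq with missing entries.

    Each well's Cq minus the mean spike-calibrator Cq of its plate; duplicate
    wells of a (species, sample) cell are averaged; undetected cells are NaN.
    A plate without detected spike wells is an error.
    """
    w = panel.wells
    spikes = w[(w["well_class"] == "spike_cal") & w["detected"]]
    spike_mean = spikes.groupby("plate_id")["cq"].mean()
    missing = sorted(set(panel.plates) - set(spike_mean.index))
    if missing:
        raise ValueError(f"plates without detected spike-calibrator wells: {missing}")
    m = w[(w["well_class"] == "mirna") & w["detected"]].copy()
    m["corrected"] = m["cq"].to_numpy() - spike_mean.reindex(m["plate_id"]).to_numpy()
    mat = m.groupby(["species_id", "sample_id"])["corrected"].mean().unstack()
    all_species = sorted(w.loc[w["well_class"] == "mirna", "species_id"].unique())
    return mat.reindex(index=all_species, columns=panel.samples)


@dataclass
class PpcaFit:
    """Result of an EM PPCA fit."""

    scores: pd.DataFrame          # sample x k (posterior mean latents, centered)
    loadings: pd.DataFrame        # species x k
    mean: pd.Series               # per-species mean
    sigma2: float
    loglik_trace: np.ndarray
    imputed: pd.DataFrame         # species x sample, missing cells filled in
    converged: bool
    n_iter: int
    dropped_species: list[str] = field(default_factory=list)


def _e_quantities(Xz, mask, W, sigma2):
    """Batched per-sample E-step pieces over observed coordinates.

    Returns (M, rhs) with M_i = W_o^T W_o + sigma2 I and rhs_i = W_o^T x_c,i,
    stacked over samples (masked coordinates contribute zero).
    """
    k = W.shape[1]
    Wm = W[None, :, :] * mask[:, :, None]
    M = np.einsum("ndk,ndl->nkl", Wm, Wm) + sigma2 * np.eye(k)[None]
    rhs = np.einsum("ndk,nd->nk", Wm, Xz)
    return M, rhs


def _observed_loglik(Xz, mask, W, sigma2):
    """Observed-data log-likelihood via the Woodbury/determinant lemma."""
    k = W.shape[1]
    n_obs = mask.sum(axis=1)
    M, rhs = _e_quantities(Xz, mask, W, sigma2)
    logdet_m = np.linalg.slogdet(M)[1]
    logdet = logdet_m + (n_obs - k) * np.log(sigma2)
    sol = np.linalg.solve(M, rhs[:, :, None])[:, :, 0]
    quad = ((Xz**2).sum(axis=1) - np.einsum("nk,nk->n", rhs, sol)) / sigma2
    return float(-0.5 * (n_obs * np.log(2 * np.pi) + logdet + quad).sum())


def fit_ppca(
    matrix: pd.DataFrame,
    k: int = 5,
    tol: float = 1e-9,
    max_iter: int = 5000,
    seed: int = 0,
    row_missing_max: float = 0.4,
) -> PpcaFit:
    """Fit PPCA by EM to a species x sample matrix with missing entries.

    Species rows missing in more than ``row_missing_max`` of samples are
    dropped for EM stability.  Variables (species) are centered by the model
    mean; no variance scaling is applied (Cq is already a log2-like scale).
    Convergence: relative log-likelihood change below ``tol``.  The
    log-likelihood is asserted non-decreasing at every iteration.
    """
    frac_missing = matrix.isna().mean(axis=1)
    dropped = sorted(matrix.index[frac_missing > row_missing_max])
    if dropped:
        log.info("fit_ppca: dropped %d species with > %.0f%% missing",
                 len(dropped), 100 * row_missing_max)
    mat = matrix.loc[~matrix.index.isin(dropped)]
    X = mat.to_numpy(dtype=float).T        # samples x species
    n, d = X.shape
    if k < 1 or k > min(n, d):
        raise ValueError(f"k={k} out of range for a {d} x {n} matrix")
    obs_mask = ~np.isnan(X)
    if (obs_mask.sum(axis=1) == 0).any():
        raise ValueError("a sample has no observed values")
    mask = obs_mask.astype(float)
    Xn = np.nan_to_num(X)

    rng = np.random.default_rng(seed)
    mu = np.nanmean(X, axis=0)
    col_sd = np.nanstd(X, axis=0).mean()
    W = rng.normal(0.0, 0.1 * max(col_sd, 1e-3), size=(d, k))
    sigma2 = max(float(np.nanvar(X - mu)), 1e-6)

    eye_k = np.eye(k)
    n_obs_per_var = mask.sum(axis=0)
    ll_trace = []
    converged = False
    it = 0
    Ez = np.zeros((n, k))
    for it in range(1, max_iter + 1):
        # E-step (batched over samples, observed coordinates only)
        Xz = mask * (Xn - mu[None, :])
        M, rhs = _e_quantities(Xz, mask, W, sigma2)
        Minv = np.linalg.inv(M)
        Ez = np.einsum("nkl,nl->nk", Minv, rhs)
        Cov = sigma2 * Minv
        Ezz = Cov + Ez[:, :, None] * Ez[:, None, :]
        # M-step: loadings (per-variable normal equations), then means, noise
        A = np.einsum("nd,nkl->dkl", mask, Ezz) + 1e-12 * eye_k[None]
        b = np.einsum("nd,nk->dk", Xz, Ez)
        W = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        recon = Ez @ W.T
        mu = (mask * (Xn - recon)).sum(axis=0) / n_obs_per_var
        resid = mask * (Xn - mu[None, :] - recon)
        term2 = np.einsum("dk,nkl,dl->nd", W, Cov, W) * mask
        sigma2 = max(float((resid**2 + term2).sum() / mask.sum()), 1e-12)

        Xz = mask * (Xn - mu[None, :])
        ll = _observed_loglik(Xz, mask, W, sigma2)
        if sigma2 <= 1e-10:
            # exact low-rank fit: the likelihood is unbounded as sigma^2 -> 0
            # and round-off dominates, so stop here
            ll_trace.append(ll)
            converged = True
            break
        if ll_trace:
            if ll < ll_trace[-1] - 1e-6 * max(1.0, abs(ll_trace[-1])):
                raise AssertionError(
                    f"EM log-likelihood decreased at iteration {it}: "
                    f"{ll_trace[-1]} -> {ll}"
                )
            if abs(ll - ll_trace[-1]) < tol * max(1.0, abs(ll_trace[-1])):
                ll_trace.append(ll)
                converged = True
                break
        ll_trace.append(ll)
    if not converged:
        log.warning("fit_ppca: no convergence in %d iterations", max_iter)

    # final E-step for scores and imputation
    Xz = mask * (Xn - mu[None, :])
    M, rhs = _e_quantities(Xz, mask, W, sigma2)
    Ez = np.linalg.solve(M, rhs[:, :, None])[:, :, 0]
    imputed = X.copy()
    recon = Ez @ W.T + mu
    imputed[~obs_mask] = recon[~obs_mask]

    scores = pd.DataFrame(
        Ez - Ez.mean(axis=0), index=mat.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    loadings = pd.DataFrame(W, index=mat.index, columns=scores.columns)
    return PpcaFit(
        scores=scores,
        loadings=loadings,
        mean=pd.Series(mu, index=mat.index),
        sigma2=float(sigma2),
        loglik_trace=np.asarray(ll_trace),
        imputed=pd.DataFrame(imputed.T, index=mat.index, columns=mat.columns),
        converged=converged,
        n_iter=it,
        dropped_species=dropped,
    )


@dataclass
class PairProximity:
    """Within- vs between-pair distance in PC space, with a permutation p."""

    ratio: float
    p_value: float
    n_permutations: int


def pair_proximity_statistic(
    scores: pd.DataFrame,
    pair_ids: pd.Series,
    n_permutations: int = 500,
    seed: int = 0,
) -> PairProximity:
    """Quantify pair clustering in PC space.

    Statistic: mean Euclidean distance between samples sharing a pair id,
    divided by the mean distance between samples of different pairs; values
    below 1 indicate that matched pairs cluster.  The p-value permutes the
    pair labels (one-sided, small ratios extreme).  This is a study-artifact
    summary of what published PCA figures show visually; it is not a formal
    cluster test.
    """
    common = scores.index.intersection(pair_ids.index)
    if len(common) < 4 or pair_ids.loc[common].nunique() < 2:
        raise ValueError("need >= 2 pairs with scored samples")
    pts = scores.loc[common].to_numpy(dtype=float)
    labels = pair_ids.loc[common].to_numpy()
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(len(pts), k=1)
    same = (labels[:, None] == labels[None, :])[iu]
    dvec = dist[iu]
    if not same.any() or same.all():
        raise ValueError("pair labels give no within/between contrast")

    def ratio_of(same_mask):
        within = dvec[same_mask].mean()
        between = dvec[~same_mask].mean()
        return within / between if between > 0 else 0.0

    obs = ratio_of(same)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        perm_same = (perm[:, None] == perm[None, :])[iu]
        if ratio_of(perm_same) <= obs:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return PairProximity(ratio=float(obs), p_value=float(p), n_permutations=n_permutations)
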