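"""Two-step Bayesian normalization of qPCR Cq signals with Monte-Carlo
uncertainty propagation into Delta-Delta-Cq fold changes.

Step 1 fits a hierarchical normal model to every replicated control well::

    Cq_{c,p,r} = mu_c + beta_p + eps,   eps ~ Normal(0, sigma_m(c)^2)

where ``c`` indexes replicate cells (the spike-in inter-plate calibrator is
one global cell -- the same synthetic RNA goes into every well, which is what
identifies plate contrasts across samples; each duplicated endogenous
control forms one cell per sample) and ``beta_p`` are plate correction
factors reported under a sum-to-zero constraint.  The model is sampled by
Gibbs with vague priors: Normal(0, loc_prior_sd^2) on locations and a
Jeffreys scale prior (p(sigma) prop. to 1/sigma, truncated at
sd_prior_upper) on noise SDs; a flat-on-sigma prior is available.

Step 2 subtracts the plate-effect draws from the unreplicated signals and,
per matched pair j, forms d_j = Cq(experimental) - Cq(reference); the model
d_j = delta + Normal(0, sigma^2) is sampled exactly, conditional on each
plate-effect draw, so the plate uncertainty propagates into the posterior of
delta (the species' Delta-Cq).  Subtracting the spike calibrator's Delta-Cq
draws gives Delta-Delta-Cq, and fold change FC = 2^-DDCq.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .io import CqPanelSet

log = logging.getLogger("urimir")


@dataclass(frozen=True)
class McmcSettings:
    """Sampler configuration (step-1 Gibbs chains and prior bounds)."""

    chains: int = 4
    iterations: int = 2000       # per chain, including burn-in
    burn_frac: float = 0.5
    rhat_threshold: float = 1.05
    loc_prior_sd: float = 1e3    # Normal(0, 1e6) on location parameters
    sd_prior_upper: float = 100.0
    # "jeffreys": p(sigma) prop. to 1/sigma (the objective scale prior; with
    # few pairs it reproduces the classical t posterior exactly, keeping
    # credible intervals calibrated).  "uniform": flat on sigma.  Both
    # truncated at sd_prior_upper.
    sd_prior: str = "jeffreys"

    def sigma2_shape(self, n: int, location_free: bool) -> float:
        """InvGamma shape for sigma^2 given n residuals.

        ``location_free`` marginalizes one location parameter (one degree of
        freedom) instead of conditioning on it.
        """
        base = n / 2.0 if not location_free else (n - 1) / 2.0
        return base - 0.5 if self.sd_prior == "uniform" else base

    @property
    def kept_draws(self) -> int:
        return self.chains * int(self.iterations * (1 - self.burn_frac))


def split_rhat(chains: np.ndarray) -> float:
    """Split-Rhat convergence diagnostic for draws shaped (chains, iters)."""
    c, n = chains.shape
    half = n // 2
    seqs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = seqs.shape
    means = seqs.mean(axis=1)
    w = seqs.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _sample_trunc_invgamma(shape, scale: np.ndarray, upper2: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Draws of sigma^2 ~ InvGamma(shape, scale) truncated to sigma^2 < upper2.

    ``shape`` may be a scalar or an array broadcastable to ``scale``.  For
    shape <= 0 (possible with only two pairs) the untruncated density is
    improper and the draw falls back to numeric inverse-CDF using the
    exponential integral; otherwise rejection sampling (the truncation almost
    never binds in practice).
    """
    scale = np.asarray(scale, dtype=float)
    shape = np.broadcast_to(np.asarray(shape, dtype=float), scale.shape).copy()
    out = np.empty_like(scale)
    zero = scale <= 0
    out[zero] = 1e-12
    pos = ~zero
    todo = pos & (shape > 1e-8)
    if todo.any():
        vals = scale[todo] / rng.gamma(shape[todo])
        bad = vals >= upper2
        tries = 0
        while bad.any() and tries < 100:
            vals[bad] = scale[todo][bad] / rng.gamma(shape[todo][bad])
            bad = vals >= upper2
            tries += 1
        out[todo] = np.minimum(vals, upper2 * (1 - 1e-12))
    # improper-shape fallback: density prop to (sigma^2)^-1 exp(-scale/sigma^2)
    # on (0, upper2); with t = scale/sigma^2 the CDF inversion uses E1(t)
    for i in np.flatnonzero(pos & (shape <= 1e-8)):
        s = scale[i]
        t_lo = s / upper2                      # corresponds to sigma^2 = upper2
        norm = special.exp1(t_lo) if t_lo > 0 else np.inf
        if not np.isfinite(norm) or norm <= 0:
            out[i] = s / max(rng.gamma(0.5), 1e-12)
            continue
        u = rng.random()
        f = lambda t: special.exp1(t) - (1 - u) * norm
        t_hi = max(t_lo * 10, 50.0)
        while f(t_hi) > 0:
            t_hi *= 10
        out[i] = s / optimize.brentq(f, t_lo, t_hi)
    return np.maximum(out, 1e-12)


# ---------------------------------------------------------------------------
# Step 1: plate effects from replicated wells
# ---------------------------------------------------------------------------

@dataclass
class PlateEffectPosterior:
    """Posterior draws of plate correction factors and replicate noise SDs."""

    plate_ids: list[str]
    beta: np.ndarray            # (n_draws, n_plates), sum-to-zero per draw
    species: list[str]          # replicated species entering the model
    sigma: np.ndarray           # (n_draws, n_species) noise SD draws
    rhat: np.ndarray            # per-plate split-Rhat of beta
    converged: bool = True

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def beta_mean(self) -> np.ndarray:
        return self.beta.mean(axis=0)


def estimate_plate_effects(
    panel: CqPanelSet,
    settings: McmcSettings = McmcSettings(),
    seed: int = 0,
) -> PlateEffectPosterior:
    """Gibbs posterior of plate correction factors from replicated wells.

    Uses detected spike-calibrator and duplicated endogenous-control wells.
    Requires >= 2 plates; every plate in the panel must carry at least one
    replicated well.  Non-convergence (split-Rhat above the threshold) is
    flagged on the result, not fatal.
    """
    w = panel.wells
    plates = panel.plates
    if len(plates) < 2:
        raise ValueError("plate-effect estimation needs >= 2 plates")
    rep = w[w["well_class"].isin(["spike_cal", "endo_control"]) & w["detected"]]
    if rep.empty:
        raise ValueError("no detected replicated control wells")
    missing_plates = sorted(set(plates) - set(rep["plate_id"]))
    if missing_plates:
        raise ValueError(f"plates without replicated control wells: {missing_plates}")

    y = rep["cq"].to_numpy(dtype=float)
    plate_code = {p: i for i, p in enumerate(plates)}
    plate_idx = rep["plate_id"].map(plate_code).to_numpy()
    species = sorted(rep["species_id"].unique())
    spec_code = {s: i for i, s in enumerate(species)}
    spec_idx = rep["species_id"].map(spec_code).to_numpy()
    # replicate cells: global for the spike calibrator, per-sample otherwise
    is_spike = (rep["well_class"] == "spike_cal").to_numpy()
    cell_keys = [
        (s,) if spk else (s, smp)
        for s, smp, spk in zip(rep["species_id"], rep["sample_id"], is_spike)
    ]
    cells = sorted(set(cell_keys), key=str)
    cell_code = {c: i for i, c in enumerate(cells)}
    cell_idx = np.array([cell_code[c] for c in cell_keys])
    n_cells, n_plates, n_species = len(cells), len(plates), len(species)
    n_per_species = np.bincount(spec_idx, minlength=n_species)
    if (n_per_species < 2).any():
        bad = [species[i] for i in np.flatnonzero(n_per_species < 2)]
        raise ValueError(f"replicated species with < 2 wells: {bad}")

    tau0_prec = settings.loc_prior_sd**-2
    upper2 = settings.sd_prior_upper**2
    sig_shapes = np.array(
        [settings.sigma2_shape(int(nm), location_free=False) for nm in n_per_species]
    )
    n_keep = int(settings.iterations * (1 - settings.burn_frac))
    beta_draws = np.empty((settings.chains, n_keep, n_plates))
    sigma_draws = np.empty((settings.chains, n_keep, n_species))

    ss = np.random.SeedSequence(seed)
    for chain, child in enumerate(ss.spawn(settings.chains)):
        rng = np.random.default_rng(child)
        # overdispersed but data-anchored initial values
        mu = np.bincount(cell_idx, weights=y, minlength=n_cells) / np.bincount(
            cell_idx, minlength=n_cells
        )
        mu = mu + rng.normal(0, 0.5, n_cells)
        beta = rng.normal(0, 0.5, n_plates)
        sig2 = np.full(n_species, max(float(np.var(y - mu[cell_idx])), 1e-4))
        for it in range(settings.iterations):
            prec_w = 1.0 / sig2[spec_idx]
            # cell means
            resid = y - beta[plate_idx]
            prec_c = np.bincount(cell_idx, weights=prec_w, minlength=n_cells) + tau0_prec
            num_c = np.bincount(cell_idx, weights=resid * prec_w, minlength=n_cells)
            mu = num_c / prec_c + rng.standard_normal(n_cells) / np.sqrt(prec_c)
            # plate effects
            resid = y - mu[cell_idx]
            prec_p = np.bincount(plate_idx, weights=prec_w, minlength=n_plates) + tau0_prec
            num_p = np.bincount(plate_idx, weights=resid * prec_w, minlength=n_plates)
            beta = num_p / prec_p + rng.standard_normal(n_plates) / np.sqrt(prec_p)
            # recenter the non-identified overall level into the cell means
            shift = beta.mean()
            beta -= shift
            mu += shift
            # per-species replicate noise
            r2 = (y - mu[cell_idx] - beta[plate_idx]) ** 2
            ssq = np.bincount(spec_idx, weights=r2, minlength=n_species)
            sig2 = _sample_trunc_invgamma(sig_shapes, ssq / 2.0, upper2, rng)
            k = it - (settings.iterations - n_keep)
            if k >= 0:
                beta_draws[chain, k] = beta
                sigma_draws[chain, k] = np.sqrt(sig2)

    rhat = np.array([split_rhat(beta_draws[:, :, p]) for p in range(n_plates)])
    converged = bool(np.all(rhat <= settings.rhat_threshold))
    if not converged:
        log.warning("plate-effect Gibbs not converged: max split-Rhat %.3f", rhat.max())
    return PlateEffectPosterior(
        plate_ids=list(plates),
        beta=beta_draws.reshape(-1, n_plates),
        species=species,
        sigma=sigma_draws.reshape(-1, n_species),
        rhat=rhat,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Step 1b: draw-indexed corrected panel
# ---------------------------------------------------------------------------

class CorrectedPanel:
    """A panel together with plate-effect draws.

    Corrected Cq values are draw-indexed (corrected = raw - beta_plate per
    posterior draw); downstream operations consume the draws so plate
    uncertainty is propagated rather than collapsed early.
    """

    def __init__(self, panel: CqPanelSet, beta: np.ndarray, plate_ids: list[str]):
        unknown = sorted(set(panel.plates) - set(plate_ids))
        if unknown:
            raise ValueError(f"plate ids without correction draws: {unknown}")
        self.panel = panel
        self.beta = beta
        self.plate_ids = list(plate_ids)
        code = {p: i for i, p in enumerate(plate_ids)}
        self._well_plate = panel.wells["plate_id"].map(code).to_numpy()

    @classmethod
    def from_plate_effects(cls, panel: CqPanelSet, pe: PlateEffectPosterior) -> "CorrectedPanel":
        return cls(panel, pe.beta, pe.plate_ids)

    @classmethod
    def identity(cls, panel: CqPanelSet, n_draws: int = 4000) -> "CorrectedPanel":
        """No plate correction (all-zero draws); useful for already-flat data."""
        return cls(panel, np.zeros((n_draws, len(panel.plates))), panel.plates)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def _index(self) -> dict[tuple[str, str], np.ndarray]:
        """Cached (species, sample) -> detected well row positions."""
        if not hasattr(self, "_det_index"):
            w = self.panel.wells
            self._raw_cq = w["cq"].to_numpy(dtype=float)
            det = w["detected"].to_numpy()
            groups: dict[tuple[str, str], list[int]] = {}
            for pos, (sp, smp, ok) in enumerate(zip(w["species_id"], w["sample_id"], det)):
                if ok:
                    groups.setdefault((sp, smp), []).append(pos)
            self._det_index = {k: np.asarray(v) for k, v in groups.items()}
        return self._det_index

    def well_draws(self, index: np.ndarray) -> np.ndarray:
        """(n_draws, len(index)) corrected Cq draws for the given well rows."""
        raw = self.panel.wells["cq"].to_numpy(dtype=float)[index]
        return raw[None, :] - self.beta[:, self._well_plate[index]]

    def point_corrected(self) -> np.ndarray:
        """Posterior-mean corrected Cq per well (for reporting only)."""
        return (
            self.panel.wells["cq"].to_numpy(dtype=float)
            - self.beta.mean(axis=0)[self._well_plate]
        )


def correct_cq(panel: CqPanelSet, plate_effects: PlateEffectPosterior) -> CorrectedPanel:
    """Attach plate-effect draws to a panel (step-1 subtraction, draw-wise)."""
    return CorrectedPanel.from_plate_effects(panel, plate_effects)


# ---------------------------------------------------------------------------
# Step 2: paired Delta-Cq posteriors
# ---------------------------------------------------------------------------

@dataclass
class DeltaPosterior:
    """Posterior draws of one species' Delta-Cq (experimental - reference)."""

    species_id: str
    draws: np.ndarray
    n_pairs: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.draws)):
            raise ValueError(f"{self.species_id}: non-finite posterior draws")


class SpeciesSkipped(RuntimeError):
    """Raised when a species has fewer than two complete pairs."""


def _side_stats(corrected: CorrectedPanel, species: str, sample: str):
    """Mean raw Cq and per-draw mean plate correction over detected wells."""
    idx = corrected._index().get((species, sample))
    if idx is None:
        return None
    raw_mean = float(corrected._raw_cq[idx].mean())
    beta_mean = corrected.beta[:, corrected._well_plate[idx]].mean(axis=1)
    return raw_mean, beta_mean


def paired_differences(
    corrected: CorrectedPanel,
    pairs: list[tuple[str, str]],
    species: str,
) -> tuple[np.ndarray, int]:
    """(n_draws, n_complete_pairs) corrected d_j draws, plus dropped count.

    For pair j with samples (E, R): d_j = mean Cq(E wells) - mean Cq(R wells)
    after subtracting the plate-effect draw of each well's plate.  Pairs in
    which either member has no detected well are dropped.
    """
    cols = []
    dropped = 0
    for sample_e, sample_r in pairs:
        e = _side_stats(corrected, species, sample_e)
        r = _side_stats(corrected, species, sample_r)
        if e is None or r is None:
            dropped += 1
            continue
        cols.append((e[0] - r[0]) - (e[1] - r[1]))
    if not cols:
        return np.empty((corrected.n_draws, 0)), dropped
    return np.column_stack(cols), dropped


def fit_paired_delta(
    corrected: CorrectedPanel,
    pairs: list[tuple[str, str]],
    species: str,
    settings: McmcSettings = McmcSettings(),
    seed: int = 0,
    sigma_fixed: float | None = None,
) -> DeltaPosterior:
    """Posterior of delta in d_j = delta + Normal(0, sigma^2), per plate draw.

    Conditional on each plate-effect draw k, sigma^2 is drawn from its
    marginal posterior (location integrated out under the near-flat prior,
    SD truncated at the prior upper bound) and delta from its conjugate
    normal conditional -- an exact sampler for the two-parameter model, so
    the returned draws reflect both pair scatter and plate uncertainty.
    With ``sigma_fixed`` the noise SD is held at that value (used by the
    closed-form conjugate cross-check).
    """
    d, dropped = paired_differences(corrected, pairs, species)
    j = d.shape[1]
    if dropped:
        log.info("fit_paired_delta(%s): dropped %d incomplete pair(s)", species, dropped)
    if j < 2:
        raise SpeciesSkipped(
            f"{species}: only {j} complete pair(s) (need >= 2); {dropped} dropped"
        )
    rng = np.random.default_rng(seed)
    dbar = d.mean(axis=1)
    if sigma_fixed is not None:
        sig2 = np.full(corrected.n_draws, float(sigma_fixed) ** 2)
    else:
        # scatter from the posterior-mean correction: the plate draws enter
        # through the draw-indexed means, so putting their Monte-Carlo noise
        # into the scatter as well would count plate uncertainty twice
        d_point = d.mean(axis=0)
        s = float(((d_point - d_point.mean()) ** 2).sum())
        sig2 = _sample_trunc_invgamma(
            settings.sigma2_shape(j, location_free=True),
            np.full(corrected.n_draws, s / 2.0),
            settings.sd_prior_upper**2, rng,
        )
    prior_prec = settings.loc_prior_sd**-2
    post_prec = j / sig2 + prior_prec
    post_mean = (j * dbar / sig2) / post_prec
    draws = post_mean + rng.standard_normal(corrected.n_draws) / np.sqrt(post_prec)
    return DeltaPosterior(species, draws, n_pairs=j, n_dropped=dropped)


def delta_delta(
    delta_m: DeltaPosterior,
    delta_spike: DeltaPosterior,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw-wise Delta-Delta-Cq: delta_m - delta_spike.

    Chain lengths must match; with an ``rng`` the spike draws are resampled
    to the species' chain length first.
    """
    a, b = delta_m.draws, delta_spike.draws
    if len(a) != len(b):
        if rng is None:
            raise ValueError(
                f"chain length mismatch ({len(a)} vs {len(b)}) and no rng to resample"
            )
        b = rng.choice(b, size=len(a), replace=True)
    return a - b


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    """Reporting summary of a Delta-Delta-Cq posterior."""

    species_id: str
    ddcq_mean: float
    ddcq_se: float
    cri_low: float
    cri_high: float
    fc: float
    fc_cri_low: float
    fc_cri_high: float
    pseudo_p: float
    n_draws: int
    degenerate: bool = False

    def row(self) -> dict:
        return {
            "miRNA": self.species_id,
            "fold_change": self.fc,
            "fc_cri_low": self.fc_cri_low,
            "fc_cri_high": self.fc_cri_high,
            "ddcq_mean": self.ddcq_mean,
            "ddcq_se": self.ddcq_se,
            "ddcq_cri_low": self.cri_low,
            "ddcq_cri_high": self.cri_high,
            "p": self.pseudo_p,
        }


def summarize_posterior(draws: np.ndarray, species_id: str = "") -> PosteriorSummary:
    """Mean, posterior SD, symmetric 95% CrI, fold change and pseudocontour p.

    FC = 2^(-posterior median) (invariant under the monotone transform);
    the FC credible bounds are the transformed Cq bounds with order swapped.
    pseudo_p = 2 * min(P(draws > 0), P(draws < 0)), floored at 2/n_draws --
    the Bayesian analog of a two-sided p-value.
    """
    draws = np.asarray(draws, dtype=float)
    n = len(draws)
    if n == 0:
        raise ValueError("no posterior draws")
    degenerate = bool(np.ptp(draws) == 0)
    mean = float(draws.mean())
    se = float(draws.std(ddof=1)) if n > 1 else 0.0
    lo, med, hi = (float(q) for q in np.quantile(draws, [0.025, 0.5, 0.975]))
    frac_pos = float(np.mean(draws > 0))
    frac_neg = float(np.mean(draws < 0))
    pseudo_p = min(1.0, max(2.0 * min(frac_pos, frac_neg), 2.0 / n))
    return PosteriorSummary(
        species_id=species_id,
        ddcq_mean=mean,
        ddcq_se=se,
        cri_low=lo,
        cri_high=hi,
        fc=float(2.0**-med),
        fc_cri_low=float(2.0**-hi),
        fc_cri_high=float(2.0**-lo),
        pseudo_p=pseudo_p,
        n_draws=n,
        degenerate=degenerate,
    )


def differential_expression(
    corrected: CorrectedPanel,
    pairs: list[tuple[str, str]],
    species_list: list[str],
    spike_species: str,
    settings: McmcSettings = McmcSettings(),
    seed: int = 0,
) -> tuple[dict[str, PosteriorSummary], dict[str, str]]:
    """Fit paired Delta-Cq for each species, subtract the spike calibrator's,
    and summarize.  Returns (summaries by species, skip reasons by species)."""
    ss = np.random.SeedSequence(seed)
    spike_seed, *species_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(species_list) + 1)
    ]
    delta_spike = fit_paired_delta(
        corrected, pairs, spike_species, settings=settings, seed=spike_seed
    )
    summaries: dict[str, PosteriorSummary] = {}
    skipped: dict[str, str] = {}
    for sp, sp_seed in zip(species_list, species_seeds):
        try:
            dm = fit_paired_delta(corrected, pairs, sp, settings=settings, seed=sp_seed)
        except SpeciesSkipped as e:
            skipped[sp] = str(e)
            continue
        dd = delta_delta(dm, delta_spike)
        summaries[sp] = summarize_posterior(dd, species_id=sp)
    return summaries, skipped
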