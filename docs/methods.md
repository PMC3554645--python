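# Methods

## Data model and notation

A panel experiment is a set of wells, each carrying a species identity
(miRNA, endogenous control, spike-in calibrator, dual spike, or blank), a
sample, a plate, a replicate index and a quantification cycle Cq.  Lower Cq
means higher abundance; one cycle ≈ a factor of two.  Signals above a
detection cutoff (default 38 cycles) and empty wells are treated as
not-detected.  Samples are annotated with patient, matched-pair id, clinical
group (N, DN, IMA, PMA) and timepoint; a pair always contains exactly two
patients.

ΔCq for a species is the experimental-minus-reference Cq difference, so
positive ΔCq means lower abundance in the experimental state.  ΔΔCq
subtracts the spike calibrator's ΔCq, and fold change is FC = 2^(−ΔΔCq).

## Detection filter

A species is detected in a sample iff at least one of its wells for that
sample is detected.  The comparison-level filter keeps species detected in
at least `min_fraction` of that comparison's samples; the default is 2/3
with a ≥ comparison (a strict > and other fractions, e.g. 0.75, are
configuration options).  The filter is applied per comparison, not
globally, because different comparisons involve different sample sets.  For
patients contributing two samples, filtering counts samples, not patients.

## Two-step Bayesian normalization

**Step 1 (plate effects).**  All detected replicated control wells enter

    Cq_{c,p,r} = μ_c + β_p + ε,   ε ~ Normal(0, σ²_m(c))

where c indexes replicate cells and m(c) the species.  The spike-in
inter-plate calibrator forms a single global cell: the same synthetic RNA
at the same concentration is pipetted into every plate, which is exactly
what makes plate contrasts identifiable across samples (each plate belongs
to one sample, so per-sample spike means would leave cross-sample plate
contrasts confounded).  Duplicated endogenous controls form one cell per
(species, sample) since their biological level varies by sample.  β is
reported under a sum-to-zero constraint; the non-identified overall level is
recentred into the cell means at every sweep.  Sampling is Gibbs, 4 chains
of 2000 iterations with 50% burn-in; convergence is monitored with
split-R̂ per plate and flagged (not fatal) above 1.05.

**Step 2 (paired ΔCq, draw-indexed).**  For each species and pair j,
d_j = mean Cq of the experimental member's detected wells minus the
reference member's, after subtracting each well's plate-effect *draw* —
so d_j is an array indexed by the step-1 draw k.  Pairs with either member
undetected are dropped (counted and logged); a species with fewer than two
complete pairs is skipped with a reason.  The model is

    d_j = δ + Normal(0, σ²_Δ).

Conditional on each draw k, (σ²_Δ, δ) is sampled *exactly*: σ²_Δ from its
marginal inverse-gamma posterior (location integrated out) and δ from its
conjugate normal conditional.  This is a correct sampler for the
two-parameter model — it passes the closed-form conjugate oracle — and it
implements the two-step Monte-Carlo subtraction cleanly: the returned δ
draws mix over the plate-effect posterior, so normalization uncertainty is
propagated, never collapsed early.  The scatter statistic is computed at
the posterior-mean correction; computing it per draw would add the
sampler's own Monte-Carlo noise to σ²_Δ and count plate uncertainty twice
(measurably deflating false-positive rates below nominal).

**Priors.**  Locations carry Normal(0, 10⁶) priors.  The noise-SD prior is
Jeffreys, p(σ) ∝ 1/σ truncated to (0, 100): with J ≈ 10 pairs it yields the
classical t_{J−1} posterior for δ, keeping 95% credible intervals and
pseudocontour probabilities frequentist-calibrated, which the package
verifies by simulation.  A Uniform(0, 100) SD prior is available
(`McmcSettings(sd_prior="uniform")`) but inflates E[σ²] by (J−1)/(J−4) at
small J and makes the intervals conservative.  Posterior means are stable
to < 0.05 cycles under doubling/halving of either prior bound (tested).

**ΔΔCq and summaries.**  ΔΔCq draws are the draw-wise difference between
the species' and the spike calibrator's δ draws (sharing the step-1 draws,
so common plate noise cancels).  Summaries report the posterior mean, SD
(as SE), 2.5/97.5% quantiles, FC = 2^(−median) (median because it is
invariant under the monotone transform; the FC interval is the transformed
Cq interval with bounds swapped), and the pseudocontour probability
2·min(P(>0), P(<0)) floored at 2/n_draws.  No multiplicity adjustment is
applied by default; Benjamini–Hochberg is available downstream.

**Comparisons.**  Named presets orient experimental vs reference as
DN-vs-N, PMA-vs-IMA (baseline or follow-up, paired by pair id) and
follow-up-vs-baseline within MA patients (paired by patient).  Incremental
PMA-vs-IMA contrasts are draw-wise differences of the two groups'
follow-up-vs-baseline ΔΔCq draws.  Non-detected wells are treated as
missing; a censored-data likelihood is deliberately out of scope.

## Probabilistic PCA

Spike-corrected values (raw Cq minus the plate's mean spike Cq) form a
species × sample matrix with missing entries.  PPCA is the isotropic latent
linear Gaussian model x = Wz + μ + ε fit by EM; expectations run only over
each sample's observed coordinates, so missing cells are handled exactly
and imputed as μ + W·E[z].  Species are model-centered; no variance scaling
(Cq is already a log2-like scale).  Species missing in > 40% of samples are
dropped before fitting (EM stability; configurable).  k defaults to 5
components.  The observed-data log-likelihood is computed every iteration
via the Woodbury identity and asserted non-decreasing; convergence is a
relative change below `tol`.  When σ² reaches its floor (exact low-rank
data) the fit stops, as the likelihood is unbounded there.  On complete
data the ML subspace provably equals the top-k PCA subspace, which the
tests verify to principal angles < 10⁻⁶.

The pair-proximity statistic — mean within-pair distance over mean
between-pair distance in score space, with a label-permutation p-value —
is an artifact-defined quantification of pair clustering that published
analyses of this kind show only visually; output labels it as such.

## Target profiling and enrichment

Consensus targets keep miRNA→gene edges supported by ≥ 2 of 3 databases
(any min_db works; 1 = union, 3 = intersection).  Under the logistic
binding model θ = L/(L+K_d), the bound-site odds are L/K_d, so a fold
change in free miRNA multiplies the odds by FC and the log-odds ratio is
ln(FC) — K_d cancels; a Hill cooperativity coefficient n would scale this
by n and defaults to 1.  Gene-level evidence pools the ΔΔCq posterior means
and SEs of all targeting miRNAs by DerSimonian–Laird: fixed weights 1/se²,
Q-statistic moment estimator τ² = max(0, (Q−(k−1))/(Σw−Σw²/Σw)), random
weights 1/(se²+τ²), normal two-sided p; k = 1 degenerates to the single
study.  Pooling happens on the Cq scale; the pooled value is also reported
as a log-odds via ln(2^(−pooled)).  A gene is called mRNA_down when its
miRNAs are pooled up (pooled ΔΔCq < 0) at p ≤ α and mRNA_up in the mirror
case; α defaults to 0.05 unadjusted and is recorded in output metadata.
Only miRNAs passing the significance screen enter profiling by default.

Enrichment is the exact upper-tail hypergeometric probability P(X ≥ k) for
k selected genes in a pathway of K universe genes, n_sel selected among N.
The universe defaults to the consensus-map genes intersected with the
pathway annotation, plus the selected genes; pathways with fewer than 3
universe genes are skipped.  Results are sorted by p, unadjusted by
default.

## Synthetic data: what it emulates and what it does not

The generator reproduces the technical structure of a two-plate-per-sample
LNA panel study: additive plate shifts (SD 0.5 cycles), 6 spike-calibrator
replicates per plate, duplicated endogenous controls, blank wells, a dual
spike on half the plates, well noise (SD 0.25 cycles), per-(pair, species)
biological effects shared by matched patients (SD 1.0 cycles — this is what
makes pair members cluster in PC space), planted ΔΔCq effects on a fraction
of species (default 10% with |log2 FC| ∈ [1, 3], random sign), right-
censoring at 38 cycles and independent 2% dropout.  Default sizes are 10
pairs × 200 miRNAs — one comparison arm at panel scale.  Base miRNA levels
are drawn from 24–33 cycles so that censoring at 38 is rare, matching a
detection-filtered analysis set.

The target universe is three databases observing a latent edge set (edge
density 2%, sensitivity 0.9, database-specific false edges), a pathway
planted from targets of the differential miRNAs, and random background
pathways over a 1000-gene universe.  The sparse density matters: at
unrealistically dense maps the targets of 20 differential miRNAs cover
nearly every gene and no pathway can be enriched among them.

Not emulated: amplification curves and efficiencies, melt curves,
informative (abundance-dependent) censoring beyond the hard cutoff,
cross-hybridization, plate-position effects, or sign-coherent miRNA
programs.  Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not robustness to
every artifact of real urine qPCR data.

## Numerical choices

Truncated inverse-gamma draws use rejection (the σ < 100 truncation
essentially never binds); the improper-shape edge case (two pairs under
the uniform SD prior) falls back to inverse-CDF via the exponential
integral.  Zero scatter (noiseless data) floors σ² at 10⁻¹².  All seeds
flow through `numpy.random.SeedSequence` spawning, making every stage
bit-reproducible; outputs are written with fixed float formatting so
same-seed reruns are byte-identical.  Enrichment ties break
lexicographically by pathway id.  Calibration studies in the tests and the
acceptance script use 200 replicates of the default design — large enough
that the 95%±3% coverage band and 5%±2% type-I band are binding, small
enough to run in a few minutes on one CPU.

## Known limitations

The two-step (cut) posterior does not feed species data back into the
plate-effect estimates; this matches the pipeline's design but is slightly
conservative relative to a joint model.  Non-detection is treated as
missing-at-random rather than censored-at-cutoff, biasing high-Cq species
toward detected wells.  DerSimonian–Laird ignores the correlation between
miRNA posteriors induced by the shared spike subtraction.  The
pair-proximity permutation test assumes exchangeable samples under the
null, which within-patient repeated samples violate mildly.
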