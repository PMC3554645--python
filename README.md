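# urimir

Bayesian analysis of urinary microRNA qPCR panel experiments in matched
case–control designs, with downstream translation of miRNA fold changes into
gene-level functional predictions and pathway enrichment.

## The problem

Urinary miRNAs are candidate biomarkers for staging diabetic kidney disease,
but qPCR panel data from urine are awkward: signals are weak (many cycles,
right-censored non-detection above a cutoff), every plate carries its own
additive technical shift, and matched case–control sampling induces
correlation between paired patients. `urimir` implements a complete,
uncertainty-honest analysis path for such experiments:

1. **Detection QC** — a species counts as detected in a sample when at least
   one of its wells gives a signal at ≤ 38 cycles (configurable); species
   detected in fewer than 2/3 of a comparison's samples are excluded; blank,
   spike-in and endogenous control wells are audited against their expected
   detection rates.
2. **Two-step Bayesian normalization.** Step 1 fits a hierarchical normal
   model to all replicated control wells,
   `Cq = μ_cell + β_plate + ε`, `ε ~ N(0, σ²_species)`,
   by Gibbs sampling (4 chains, sum-to-zero plate effects, split-R̂
   monitoring), giving posterior draws of per-plate correction factors β.
   Step 2 subtracts the β draws from the unreplicated signals, forms
   per-pair differences `d_j = Cq(experimental) − Cq(reference)` and samples
   `d_j = δ + N(0, σ²_Δ)` exactly, conditional on each plate draw — so plate
   uncertainty propagates by Monte Carlo instead of being collapsed early.
   The spike-in inter-plate calibrator's ΔCq draws are subtracted draw-wise:
   `ΔΔCq = ΔCq(miRNA) − ΔCq(spike)`, and fold change `FC = 2^(−ΔΔCq)`.
   Each species is reported with a posterior mean ± SE, a symmetric 95%
   credible interval, and a pseudocontour probability
   `p = 2·min(P(ΔΔCq>0), P(ΔΔCq<0))` — the Bayesian analog of a two-sided
   p-value.
3. **Probabilistic PCA** (EM, isotropic noise) of spike-corrected Cq
   profiles, tolerating missing entries, with a permutation statistic that
   quantifies whether matched pairs cluster in PC space.
4. **Target profiling** — consensus miRNA→gene edges (≥ 2 of 3 prediction
   databases), the Hill/logistic identity that a fold change FC multiplies
   the bound-site odds θ/(1−θ) = L/K_d by FC (log-odds ratio = ln FC), and
   DerSimonian–Laird random-effects pooling of the ΔΔCq posteriors of all
   miRNAs targeting a gene.
5. **Pathway enrichment** — exact upper-tail hypergeometric tests of the
   predicted target genes against GMT gene sets, unadjusted by default
   (Benjamini–Hochberg optional).

A first-class simulator (`urimir.simulate`) generates whole panel
experiments — plate shifts, spike wells, duplicated controls, blanks,
censoring, matched-pair correlation, planted log2 fold changes and a planted
enriched pathway — so every stage is testable with known ground truth.

## Worked example

```python
import urimir as u

design = u.SimulationDesign(seed=1)          # 10 pairs, 200 miRNAs, 10% differential
panel, annotations, truth = u.simulate_panel_experiment(design)
kept = u.filter_detected(u.detection_matrix(panel))

pe = u.estimate_plate_effects(panel, seed=2)
corrected = u.correct_cq(panel, pe)
pairs = u.build_pairs(annotations, "DN-vs-N")
summaries, _ = u.differential_expression(corrected, pairs, kept, "UniSp3", seed=3)
print(u.summaries_table(summaries).head(3))
```

prints (fold change with its 95% credible bounds and pseudocontour p):

```
              miRNA  fold_change  fc_cri_low  fc_cri_high  ...       p
0  hsa-miR-sim-0018       0.4946      0.4000       0.6038  ...  0.0005
1  hsa-miR-sim-0026       0.2358      0.1958       0.2822  ...  0.0005
2  hsa-miR-sim-0036       0.5039      0.4226       0.6038  ...  0.0005
```

A fold change of 0.24 with CrI (0.20, 0.28) means the species is about
four-fold less abundant in the experimental group, with the interval
carrying both pair-to-pair scatter and plate-normalization uncertainty.  On
this seed all 20 planted differential species are recovered at p ≤ 0.05 and
the ΔΔCq recovery RMSE is 0.118 cycles (`examples/02_normalize_fold_changes.py`).

The `examples/` directory holds one short script per capability (simulation
and QC, normalization, PPCA, target/pathway profiling, and the full
pipeline); each prints the numbers it computes and a line on what they mean.
A thin CLI covers the same path from a shell:

```bash
urimir simulate --seed 1 --out sim/
urimir qc sim/cq_table.tsv
urimir run-all --config config.yaml --seed 1
```

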