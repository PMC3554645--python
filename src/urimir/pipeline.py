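"""End-to-end orchestration: detection QC -> Bayesian normalization ->
fold-change tables -> PPCA -> gene profiling -> pathway enrichment.

Every stage output is a pure function of (inputs, config, seed); rerunning
with the same configuration and seed reproduces the output files byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detection import DEFAULT_MIN_FRACTION, control_qc, detection_matrix, filter_detected
from .enrich import enrich_pathways
from .io import (
    SampleAnnotation,
    annotations_frame,
    read_cq_table,
    read_gmt,
    read_sample_sheet,
    read_target_tables,
)
from .normalize import (
    McmcSettings,
    correct_cq,
    differential_expression,
    estimate_plate_effects,
)
from .ppca import corrected_matrix, fit_ppca, pair_proximity_statistic
from .simulate import SPIKE_CAL
from .targets import consensus_targets, functional_profile, profile_genes

log = logging.getLogger("urimir")

#: named comparison presets: (experimental selector, reference selector,
#: pairing key).  Selectors are (groups, timepoints); pairing "pair" matches
#: the two patients of a matched pair, pairing "patient" matches the two
#: timepoints of one patient.
COMPARISONS = {
    "DN-vs-N": ((("DN",), ("single",)), (("N",), ("single",)), "pair"),
    "baseline-PMA-vs-IMA": ((("PMA",), ("baseline",)), (("IMA",), ("baseline",)), "pair"),
    "followup-PMA-vs-IMA": ((("PMA",), ("followup",)), (("IMA",), ("followup",)), "pair"),
    "followup-vs-baseline-MA": (
        (("IMA", "PMA"), ("followup",)),
        (("IMA", "PMA"), ("baseline",)),
        "patient",
    ),
}


def build_pairs(
    annotations: list[SampleAnnotation], comparison: str
) -> list[tuple[str, str]]:
    """(experimental sample, reference sample) tuples for a named comparison."""
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}; known: {sorted(COMPARISONS)}")
    (eg, et), (rg, rt), key = COMPARISONS[comparison]
    df = annotations_frame(annotations)
    exp = df[df["group"].isin(eg) & df["timepoint"].isin(et)]
    ref = df[df["group"].isin(rg) & df["timepoint"].isin(rt)]
    pairs = []
    if key == "pair":
        for pid in sorted(set(exp["pair_id"]) & set(ref["pair_id"])):
            e = exp[exp["pair_id"] == pid]["sample_id"]
            r = ref[ref["pair_id"] == pid]["sample_id"]
            if len(e) == 1 and len(r) == 1:
                pairs.append((e.iloc[0], r.iloc[0]))
    else:  # within-patient pairing (baseline vs follow-up)
        for pt in sorted(set(exp["patient_id"]) & set(ref["patient_id"])):
            e = exp[exp["patient_id"] == pt]["sample_id"]
            r = ref[ref["patient_id"] == pt]["sample_id"]
            if len(e) == 1 and len(r) == 1:
                pairs.append((e.iloc[0], r.iloc[0]))
    if not pairs:
        raise ValueError(f"comparison {comparison!r} yields no complete pairs")
    return pairs


@dataclass
class RunConfig:
    """Configuration of one end-to-end comparison run."""

    cq_table: str
    sample_sheet: str
    comparison: str = "DN-vs-N"
    target_tables: list[str] = field(default_factory=list)
    gmt: str | None = None
    name_map: str | None = None
    detection_cutoff: float = 38.0
    detection_min_fraction: float = DEFAULT_MIN_FRACTION
    spike_species: str = SPIKE_CAL
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    alpha: float = 0.05
    gene_alpha: float = 0.05
    ppca_components: int = 5
    seed: int = 0
    out_dir: str = "urimir_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        mcmc = McmcSettings(**raw.pop("mcmc", {}))
        cfg = cls(mcmc=mcmc, **raw)
        for p in [cfg.cq_table, cfg.sample_sheet, *cfg.target_tables,
                  *( [cfg.gmt] if cfg.gmt else [] ),
                  *( [cfg.name_map] if cfg.name_map else [] )]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg

    def digest(self) -> str:
        d = asdict(self)
        d.pop("out_dir", None)  # where results land is not analysis state
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def summaries_table(summaries: dict) -> pd.DataFrame:
    """Fold-change results table (miRNA, fold change, 95% CrI, p)."""
    rows = [s.row() for s in summaries.values()]
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["p", "miRNA"], kind="mergesort").reset_index(drop=True)
    return df


def run_comparison(config: RunConfig) -> dict:
    """Run the full pipeline for one comparison; returns the report bundle.

    Writes under ``config.out_dir``: detection_report.tsv, qc_report.tsv,
    mirna_results.tsv, ppca_scores.tsv, gene_profiles.tsv, enrichment.tsv
    and run_metadata.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = read_cq_table(config.cq_table, cutoff=config.detection_cutoff)
    annotations = read_sample_sheet(config.sample_sheet)
    if config.name_map:
        from .io import apply_name_map, read_name_map

        panel = apply_name_map(panel, read_name_map(config.name_map))
    pairs = build_pairs(annotations, config.comparison)
    comparison_samples = sorted({s for pr in pairs for s in pr})

    # detection filter, applied per comparison
    det = detection_matrix(panel)
    kept = filter_detected(det, config.detection_min_fraction, samples=comparison_samples)
    qc = control_qc(panel)
    _write(qc.to_frame(), out / "qc_report.tsv")
    det_report = det.mean(axis=1).rename("detection_fraction").to_frame()
    det_report["kept"] = det_report.index.isin(kept)
    det_report.index.name = "species_id"
    _write(det_report.reset_index(), out / "detection_report.tsv")
    log.info("detection filter kept %d/%d species", len(kept), det.shape[0])

    # two-step Bayesian normalization
    ss = np.random.SeedSequence(config.seed)
    s_plate, s_fit, s_perm = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    pe = estimate_plate_effects(panel, settings=config.mcmc, seed=s_plate)
    corrected = correct_cq(panel, pe)
    summaries, skipped = differential_expression(
        corrected, pairs, kept, config.spike_species, settings=config.mcmc, seed=s_fit
    )
    for sp, reason in skipped.items():
        log.info("skipped %s: %s", sp, reason)
    results = summaries_table(summaries)
    _write(results, out / "mirna_results.tsv")

    # PPCA overview of spike-corrected profiles
    mat = corrected_matrix(panel)
    comparison_mat = mat[ [c for c in mat.columns if c in comparison_samples] ]
    fit = fit_ppca(comparison_mat, k=min(config.ppca_components,
                                         len(comparison_samples) - 1), seed=config.seed)
    scores = fit.scores.copy()
    ann = annotations_frame(annotations).set_index("sample_id")
    scores["pair_id"] = ann.loc[scores.index, "pair_id"]
    scores["group"] = ann.loc[scores.index, "group"]
    scores.index.name = "sample_id"
    _write(scores.reset_index(), out / "ppca_scores.tsv")
    prox = pair_proximity_statistic(fit.scores, ann["pair_id"], seed=s_perm)

    bundle = {
        "detection": det_report,
        "qc": qc,
        "summaries": summaries,
        "results": results,
        "ppca": fit,
        "pair_proximity": prox,
        "skipped": skipped,
    }

    # optional downstream: targets and enrichment
    if config.target_tables:
        dbs = read_target_tables(config.target_tables)
        cmap = consensus_targets(dbs)
        significant = {k: v for k, v in summaries.items() if v.pseudo_p <= config.alpha}
        profiles = profile_genes(significant, cmap, alpha=config.gene_alpha)
        prof_df = pd.DataFrame(
            [
                {"gene_id": g.gene_id, "k_mirnas": g.k_studies,
                 "pooled_ddcq": g.pooled_ddcq, "pooled_se": g.pooled_se,
                 "tau2": g.tau2, "p": g.p, "log_odds": g.log_odds,
                 "direction": g.direction}
                for g in profiles
            ]
        )
        _write(prof_df, out / "gene_profiles.tsv")
        bundle["gene_profiles"] = profiles
        if config.gmt:
            pdb = read_gmt(config.gmt)
            up, down = functional_profile(profiles, alpha=config.gene_alpha)
            selected = up | down
            universe = cmap.genes() & pdb.genes() | selected
            enr = enrich_pathways(selected, pdb, universe=universe)
            enr_df = pd.DataFrame(
                [{"pathway": r.pathway_id, "description": r.description,
                  "p": r.p, "fraction": r.fraction} for r in enr]
            )
            _write(enr_df, out / "enrichment.tsv")
            bundle["enrichment"] = enr

    meta = {
        "package_version": __version__,
        "seed": config.seed,
        "comparison": config.comparison,
        "config_hash": config.digest(),
        "n_pairs": len(pairs),
        "n_species_kept": len(kept),
        "n_species_skipped": len(skipped),
        "plate_gibbs_converged": bool(pe.converged),
        "max_plate_rhat": float(pe.rhat.max()),
        "gene_alpha_note": "gene-level calls use unadjusted p <= alpha",
    }
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    bundle["metadata"] = meta
    return bundle
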