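"""Matched-pair qPCR panel simulator with known ground truth.

The generator emulates the structure of an LNA qPCR panel study of urine
miRNAs: each sample is run on a fixed number of plates, every plate carries
six replicate wells of a spike-in inter-plate calibrator, duplicated
endogenous-control wells and blank wells, plates have additive Cq shifts,
matched pairs share a correlated biological profile, a subset of miRNAs
carries planted log2 fold changes, and signals above a cycle cutoff are
right-censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CqPanelSet, SampleAnnotation

SPIKE_CAL = "UniSp3"
SPIKE_DUAL = "UniSp6"
ENDO_CONTROLS = ("hsa-miR-423-5p", "hsa-miR-103", "hsa-miR-191")


@dataclass(frozen=True)
class SimulationDesign:
    """Study-design parameters of a simulated matched-pair panel experiment.

    Defaults mirror one comparison arm of the study the simulator emulates:
    10 matched pairs profiled on 2 plates per sample, a spike-in calibrator
    run 6 times per plate, duplicated endogenous controls, 10% of miRNAs
    differential with |log2 FC| between 1 and 3, and detection censored at
    38 cycles.
    """

    n_pairs: int = 10
    n_mirna: int = 200
    n_plates_per_sample: int = 2
    spike_replicates_per_plate: int = 6
    endo_control_duplicates: int = 2
    n_blank_per_plate: int = 3
    frac_differential: float = 0.1
    effect_log2fc_range: tuple[float, float] = (1.0, 3.0)
    plate_sd: float = 0.5
    well_sd: float = 0.25
    pair_sd: float = 1.0
    missing_rate: float = 0.02
    censor_cutoff: float = 38.0
    base_cq_range: tuple[float, float] = (24.0, 33.0)
    spike_cq: float = 20.0
    groups: tuple[str, str] = ("DN", "N")  # (experimental, reference)
    include_spike_dual: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("plate_sd", "well_sd", "pair_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.frac_differential <= 1:
            raise ValueError("frac_differential must lie in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_pairs < 1 or self.n_mirna < 1:
            raise ValueError("degenerate design: need >= 1 pair and >= 1 miRNA")


@dataclass
class GroundTruth:
    """What the simulator planted, for recovery checks downstream."""

    true_ddcq: pd.Series          # per miRNA; 0 for non-differential species
    plate_shift: pd.Series        # per plate, additive cycles
    pair_effect: pd.DataFrame     # pair x species biological effect (cycles)
    differential: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species_id": self.true_ddcq.index, "true_ddcq": self.true_ddcq.values,
             "differential": [s in set(self.differential) for s in self.true_ddcq.index]}
        )


def _mirna_names(n: int) -> list[str]:
    return [f"hsa-miR-sim-{i:04d}" for i in range(1, n + 1)]


def simulate_panel_experiment(
    design: SimulationDesign,
) -> tuple[CqPanelSet, list[SampleAnnotation], GroundTruth]:
    """Simulate a full matched-pair panel experiment.

    Generative model for an endogenous well of species m on plate p of the
    sample belonging to pair j::

        Cq = base_m + [true_dCq_m if experimental member] + shift_p
             + pair_effect_{j,m} + Normal(0, well_sd)

    Spike wells share the plate shift but carry no biological terms.  Wells
    with Cq above ``censor_cutoff`` and an independent ``missing_rate``
    fraction of wells are recorded as not detected (empty Cq).
    """
    d = design
    rng = np.random.default_rng(d.seed)

    mirnas = _mirna_names(d.n_mirna)
    base = pd.Series(
        rng.uniform(*d.base_cq_range, size=d.n_mirna), index=mirnas, name="base_cq"
    )
    n_diff = int(round(d.frac_differential * d.n_mirna))
    differential = list(rng.choice(mirnas, size=n_diff, replace=False))
    true_ddcq = pd.Series(0.0, index=mirnas, name="true_ddcq")
    lo, hi = d.effect_log2fc_range
    mag = rng.uniform(lo, hi, size=n_diff)
    sign = rng.choice([-1.0, 1.0], size=n_diff)
    true_ddcq.loc[differential] = mag * sign

    # endogenous control baselines (no condition effect)
    endo_base = {c: rng.uniform(20.0, 26.0) for c in ENDO_CONTROLS}

    pair_ids = [f"pair{j + 1:02d}" for j in range(d.n_pairs)]
    endo_species = list(ENDO_CONTROLS)
    pair_eff = pd.DataFrame(
        rng.normal(0.0, d.pair_sd, size=(d.n_pairs, d.n_mirna + len(endo_species))),
        index=pair_ids,
        columns=mirnas + endo_species,
    )

    exp_group, ref_group = d.groups
    annotations: list[SampleAnnotation] = []
    samples: list[tuple[str, str, bool]] = []  # (sample_id, pair_id, experimental)
    for j, pair in enumerate(pair_ids):
        for role, grp in (("E", exp_group), ("R", ref_group)):
            sid = f"s{j + 1:02d}{role}"
            pid = f"pt{j + 1:02d}{role}"
            annotations.append(SampleAnnotation(sid, pid, pair, grp, "single"))
            samples.append((sid, pair, role == "E"))

    # plates: each sample gets its own plates; miRNA species are split evenly
    # across the per-sample plates (panel 1 / panel 2 layout)
    plate_ids: list[str] = []
    plate_shift_vals: list[float] = []
    panel_of_species = {m: i % d.n_plates_per_sample for i, m in enumerate(mirnas)}
    rows: list[dict] = []
    plate_counter = 0
    for sid, pair, is_exp in samples:
        for panel_idx in range(d.n_plates_per_sample):
            plate_id = f"plate{plate_counter + 1:03d}"
            plate_counter += 1
            shift = rng.normal(0.0, d.plate_sd)
            plate_ids.append(plate_id)
            plate_shift_vals.append(shift)

            def well(species, wclass, rep, level):
                cq = level + rng.normal(0.0, d.well_sd) if level is not None else np.nan
                rows.append(
                    {"species_id": species, "mimat": None, "sample_id": sid,
                     "plate_id": plate_id, "replicate_index": rep, "cq": cq,
                     "well_class": wclass}
                )

            # spike-in calibrator: identical material on every plate
            for r in range(1, d.spike_replicates_per_plate + 1):
                well(SPIKE_CAL, "spike_cal", r, d.spike_cq + shift)
            # dual spike on alternating plates only
            if d.include_spike_dual and plate_counter % 2 == 1:
                well(SPIKE_DUAL, "spike_dual", 1, d.spike_cq + 2.0 + shift)
            # blanks never amplify
            for r in range(1, d.n_blank_per_plate + 1):
                well("BLANK", "blank", r, None)
            # duplicated endogenous controls
            for c in endo_species:
                lvl = endo_base[c] + pair_eff.loc[pair, c] + shift
                for r in range(1, d.endo_control_duplicates + 1):
                    well(c, "endo_control", r, lvl)
            # unreplicated miRNA wells for this panel's species
            for m in mirnas:
                if panel_of_species[m] != panel_idx:
                    continue
                lvl = base[m] + pair_eff.loc[pair, m] + shift
                if is_exp:
                    lvl += true_ddcq[m]
                well(m, "mirna", 1, lvl)

    wells = pd.DataFrame(rows)
    # right-censoring at the cutoff, plus independent dropout
    amplified = wells["cq"].notna()
    censored = amplified & (wells["cq"] > d.censor_cutoff)
    dropout = amplified & (rng.random(len(wells)) < d.missing_rate)
    wells.loc[censored | dropout, "cq"] = np.nan
    wells["detected"] = wells["cq"].notna() & (wells["cq"] <= d.censor_cutoff)

    truth = GroundTruth(
        true_ddcq=true_ddcq,
        plate_shift=pd.Series(plate_shift_vals, index=plate_ids, name="plate_shift"),
        pair_effect=pair_eff,
        differential=differential,
    )
    panel = CqPanelSet(wells.reset_index(drop=True), cutoff=d.censor_cutoff)
    return panel, annotations, truth


def simulate_target_universe(
    n_mirna: int,
    n_gene: int,
    edge_prob: tuple[float, float, float] = (0.02, 0.02, 0.02),
    planted_pathway_size: int = 30,
    seed: int = 0,
    differential_mirnas: list[str] | None = None,
    n_pathways: int = 20,
    db_sensitivity: float = 0.9,
):
    """Simulate three correlated target databases plus pathway gene sets.

    A latent "true" miRNA->gene edge set is observed by each database with
    ``db_sensitivity``, on top of database-specific false edges, so the three
    databases agree more often than independent coin flips would.  One pathway
    is planted from genes targeted by the designated differential miRNAs so
    that enrichment of those targets can be recovered downstream.

    Returns ``(dbs, pathway_db, truth)`` where ``truth`` holds the planted
    pathway id and the differential miRNA list.
    """
    from .io import PathwayDB, TargetDB

    if any(not 0 <= p <= 1 for p in edge_prob):
        raise ValueError("edge probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mirnas = _mirna_names(n_mirna)
    genes = [f"GENE{i:04d}" for i in range(1, n_gene + 1)]
    if differential_mirnas is None:
        differential_mirnas = mirnas[: max(1, n_mirna // 10)]

    base_p = float(np.mean(edge_prob))
    latent = rng.random((n_mirna, n_gene)) < base_p
    dbs = []
    for k, p in enumerate(edge_prob):
        if p >= 1.0:
            obs = np.ones_like(latent)
        elif p <= 0.0:
            obs = np.zeros_like(latent, dtype=bool)
        else:
            keep = latent & (rng.random(latent.shape) < db_sensitivity)
            # database-specific false edges keep the marginal density near p
            fp_rate = max(0.0, (p - base_p * db_sensitivity) / max(1e-12, 1 - base_p))
            false = (~latent) & (rng.random(latent.shape) < fp_rate)
            obs = keep | false
        idx = np.argwhere(obs)
        edges = frozenset((mirnas[i], genes[j]) for i, j in idx)
        dbs.append(TargetDB(f"db{k + 1}", edges))

    # consensus targets of the differential species, used to plant enrichment
    from .targets import consensus_targets

    cmap = consensus_targets(dbs, min_db=2)
    diff_targets = sorted(
        {g for m in differential_mirnas for g in cmap.targets.get(m, set())}
    )
    pdb = PathwayDB()
    planted_id = "PW_PLANTED"
    size = min(planted_pathway_size, max(1, len(diff_targets)))
    if diff_targets:
        members = list(rng.choice(diff_targets, size=size, replace=False))
    else:  # degenerate universe (e.g. edge_prob 0): fall back to random genes
        members = list(rng.choice(genes, size=min(planted_pathway_size, n_gene), replace=False))
    pdb.sets[planted_id] = set(members)
    pdb.descriptions[planted_id] = "planted enriched pathway"
    for i in range(n_pathways - 1):
        pw = f"PW{i + 1:03d}"
        sz = int(rng.integers(10, max(11, min(60, n_gene))))
        pdb.sets[pw] = set(rng.choice(genes, size=min(sz, n_gene), replace=False))
        pdb.descriptions[pw] = "background pathway"
    truth = {"planted_pathway": planted_id, "differential_mirnas": list(differential_mirnas)}
    return dbs, pdb, truth


def write_simulated_study(
    design: SimulationDesign,
    out_dir,
    n_gene: int = 1000,
    edge_prob: tuple[float, float, float] = (0.02, 0.02, 0.02),
    planted_pathway_size: int = 30,
):
    """Simulate a full study and write every pipeline input to ``out_dir``.

    Emits cq_table.tsv, sample_sheet.tsv, truth.tsv, targets_db{1,2,3}.tsv
    and pathways.gmt; returns (paths dict, panel truth, universe truth).
    """
    from pathlib import Path

    from .io import write_cq_table, write_gmt, write_sample_sheet, write_target_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, annotations, truth = simulate_panel_experiment(design)
    dbs, pdb, universe_truth = simulate_target_universe(
        design.n_mirna,
        n_gene,
        edge_prob=edge_prob,
        planted_pathway_size=planted_pathway_size,
        seed=design.seed + 1,
        differential_mirnas=truth.differential,
    )
    paths = {
        "cq_table": out / "cq_table.tsv",
        "sample_sheet": out / "sample_sheet.tsv",
        "truth": out / "truth.tsv",
        "gmt": out / "pathways.gmt",
        "target_tables": [out / f"targets_db{i}.tsv" for i in (1, 2, 3)],
    }
    write_cq_table(panel, paths["cq_table"])
    write_sample_sheet(annotations, paths["sample_sheet"])
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    for db, p in zip(dbs, paths["target_tables"]):
        write_target_table(db, p)
    write_gmt(pdb, paths["gmt"])
    return paths, truth, universe_truth


def null_design(design: SimulationDesign) -> SimulationDesign:
    """The same design with no planted effects (for calibration studies)."""
    return replace(design, frac_differential=0.0)
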