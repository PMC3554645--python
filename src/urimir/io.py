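"""Readers and writers for every table the pipeline touches.

All formats are plain delimited text (tab by default, comma accepted) so that
instrument exports, database dumps and simulated data travel through the same
strict validation path.  The canonical in-memory containers are thin wrappers
around :class:`pandas.DataFrame` / plain dicts.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("urimir")

WELL_CLASSES = ("mirna", "endo_control", "spike_cal", "spike_dual", "blank")
GROUPS = ("N", "DN", "IMA", "PMA")
TIMEPOINTS = ("baseline", "followup", "single")

#: default detection cutoff in cycles: reactions are counted as detected only
#: up to a maximum of 38 cycles.
DEFAULT_CUTOFF = 38.0

CQ_COLUMNS = [
    "species_id",
    "mimat",
    "sample_id",
    "plate_id",
    "replicate_index",
    "cq",
    "well_class",
]

_KEY = ["species_id", "sample_id", "plate_id", "replicate_index"]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates an invariant of the format."""


def _sniff_sep(path: str | Path) -> str:
    """Tab-delimited by default; fall back to comma when the header has no tab."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


# ---------------------------------------------------------------------------
# Cq panel tables
# ---------------------------------------------------------------------------

@dataclass
class CqPanelSet:
    """All wells of a qPCR panel experiment.

    ``wells`` columns: species_id, mimat, sample_id, plate_id,
    replicate_index (int >= 1), cq (float cycles, NaN when no signal),
    well_class, detected (bool: a signal at or below ``cutoff``).
    """

    wells: pd.DataFrame
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        missing = [c for c in CQ_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValidationError(f"panel table missing columns: {missing}")
        if "detected" not in self.wells.columns:
            w = self.wells
            self.wells = w.assign(detected=w["cq"].notna() & (w["cq"] <= self.cutoff))

    @property
    def species(self) -> list[str]:
        return sorted(self.wells["species_id"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.wells["sample_id"].unique())

    @property
    def plates(self) -> list[str]:
        return sorted(self.wells["plate_id"].unique())

    def subset(self, mask) -> "CqPanelSet":
        return CqPanelSet(self.wells[mask].reset_index(drop=True), self.cutoff)

    def of_class(self, *classes: str) -> "CqPanelSet":
        return self.subset(self.wells["well_class"].isin(classes))


def _validate_panel_frame(df: pd.DataFrame, cutoff: float, origin: str) -> pd.DataFrame:
    bad_class = ~df["well_class"].isin(WELL_CLASSES)
    if bad_class.any():
        i = int(np.flatnonzero(bad_class.to_numpy())[0])
        raise ValidationError(
            f"{origin}: unknown well_class {df['well_class'].iloc[i]!r} (row {i + 2})"
        )
    rep = pd.to_numeric(df["replicate_index"], errors="coerce")
    bad_rep = rep.isna() | (rep < 1) | (rep != rep.round())
    if bad_rep.any():
        i = int(np.flatnonzero(bad_rep.to_numpy())[0])
        raise ParseError(
            f"{origin}: replicate_index must be an integer >= 1 (row {i + 2})"
        )
    df["replicate_index"] = rep.astype(int)

    raw_cq = df["cq"]
    cq = pd.to_numeric(raw_cq, errors="coerce")
    # empty fields are legitimate non-detections; anything else non-numeric is not
    nonempty = raw_cq.notna() & (raw_cq.astype(str).str.strip() != "")
    bad_cq = nonempty & cq.isna()
    if bad_cq.any():
        i = int(np.flatnonzero(bad_cq.to_numpy())[0])
        raise ParseError(f"{origin}: malformed cq value {raw_cq.iloc[i]!r} (row {i + 2})")
    if (cq <= 0).any():
        i = int(np.flatnonzero((cq <= 0).to_numpy())[0])
        raise ValidationError(f"{origin}: cq must be positive cycles (row {i + 2})")
    df["cq"] = cq.astype(float)

    dup = df.duplicated(subset=_KEY, keep=False)
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        key = tuple(df.loc[df.index[i], _KEY])
        raise ValidationError(f"{origin}: duplicate well key {key}")
    df["detected"] = df["cq"].notna() & (df["cq"] <= cutoff)
    return df


def read_cq_table(path: str | Path, cutoff: float = DEFAULT_CUTOFF) -> CqPanelSet:
    """Read a raw Cq well table.

    Cq values above ``cutoff`` (or empty) stay in the table but are marked
    not-detected; duplicate (species, sample, plate, replicate) rows are
    rejected.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df = df.replace({"": None})
    missing = [c for c in CQ_COLUMNS if c not in df.columns and c != "mimat"]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if "mimat" not in df.columns:
        df["mimat"] = None
    df = df[CQ_COLUMNS].copy()
    df = _validate_panel_frame(df, cutoff, str(path))
    return CqPanelSet(df.reset_index(drop=True), cutoff)


def write_cq_table(panel: CqPanelSet, path: str | Path) -> None:
    out = panel.wells[CQ_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="")


# ---------------------------------------------------------------------------
# Sample annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    patient_id: str
    pair_id: str
    group: str
    timepoint: str


def read_sample_sheet(path: str | Path) -> list[SampleAnnotation]:
    """Read sample annotations and validate the matched-pair structure."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    return annotations_from_frame(df, origin=str(path))


def annotations_from_frame(df: pd.DataFrame, origin: str = "sample sheet") -> list[SampleAnnotation]:
    need = ["sample_id", "patient_id", "pair_id", "group", "timepoint"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ParseError(f"{origin}: missing columns {missing}")
    bad = ~df["group"].isin(GROUPS)
    if bad.any():
        raise ValidationError(f"{origin}: unknown group {df['group'][bad].iloc[0]!r}")
    bad = ~df["timepoint"].isin(TIMEPOINTS)
    if bad.any():
        raise ValidationError(f"{origin}: unknown timepoint {df['timepoint'][bad].iloc[0]!r}")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{origin}: duplicate sample_id")
    for pair_id, grp in df.groupby("pair_id"):
        n_pat = grp["patient_id"].nunique()
        if n_pat != 2:
            raise ValidationError(
                f"{origin}: pair {pair_id!r} has {n_pat} patients, expected 2"
            )
    return [
        SampleAnnotation(r.sample_id, r.patient_id, r.pair_id, r.group, r.timepoint)
        for r in df.itertuples()
    ]


def annotations_frame(annotations: list[SampleAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([a.__dict__ for a in annotations])


def write_sample_sheet(annotations: list[SampleAnnotation], path: str | Path) -> None:
    annotations_frame(annotations).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# miRNA name map (pre-v18 name -> miRBase v18 name + MIMAT accession)
# ---------------------------------------------------------------------------

DEAD = "DEAD"


@dataclass
class NameMap:
    """old_name -> (current_name, mimat); retired species map to ``DEAD``."""

    entries: dict[str, tuple[str, str | None]] = field(default_factory=dict)

    def __getitem__(self, old: str) -> tuple[str, str | None]:
        return self.entries[old]

    def __contains__(self, old: str) -> bool:
        return old in self.entries


def read_name_map(path: str | Path) -> NameMap:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    need = ["old_name", "current_name", "mimat"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df["old_name"].duplicated().any():
        raise ValidationError(f"{path}: name map must be a function of old_name")
    entries = {
        r.old_name: (r.current_name, r.mimat if r.mimat not in ("", "NA") else None)
        for r in df.itertuples()
    }
    return NameMap(entries)


def write_name_map(nmap: NameMap, path: str | Path) -> None:
    rows = [
        {"old_name": k, "current_name": v[0], "mimat": v[1] if v[1] else "NA"}
        for k, v in nmap.entries.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def apply_name_map(panel: CqPanelSet, nmap: NameMap) -> CqPanelSet:
    """Rename miRNA species to their current names.

    Retired (DEAD) species are dropped with a logged count; names absent from
    the map pass through verbatim with a warning.  Control wells are untouched.
    """
    w = panel.wells.copy()
    is_mirna = w["well_class"] == "mirna"
    unmapped: set[str] = set()
    dead_mask = np.zeros(len(w), dtype=bool)
    new_names = w["species_id"].to_numpy(dtype=object).copy()
    new_mimat = w["mimat"].to_numpy(dtype=object).copy()
    for i, (name, mirna) in enumerate(zip(new_names, is_mirna)):
        if not mirna:
            continue
        if name in nmap:
            cur, mimat = nmap[name]
            if cur == DEAD:
                dead_mask[i] = True
            else:
                new_names[i] = cur
                if mimat is not None:
                    new_mimat[i] = mimat
        else:
            unmapped.add(name)
    if dead_mask.any():
        n_dead = len(set(w["species_id"].to_numpy()[dead_mask]))
        log.info("apply_name_map: dropped %d retired (DEAD) species (%d wells)",
                 n_dead, int(dead_mask.sum()))
    if unmapped:
        log.warning("apply_name_map: %d species not in the name map, kept verbatim: %s",
                    len(unmapped), ", ".join(sorted(unmapped)[:5]))
    w["species_id"] = new_names
    w["mimat"] = new_mimat
    w = w[~dead_mask].reset_index(drop=True)
    return CqPanelSet(w, panel.cutoff)


# ---------------------------------------------------------------------------
# miRNA -> gene target tables
# ---------------------------------------------------------------------------

@dataclass
class TargetDB:
    """One prediction database's miRNA -> gene edge set."""

    db_name: str
    edges: frozenset[tuple[str, str]]


def read_target_table(path: str | Path, db_name: str) -> TargetDB:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    need = ["mirna_id", "gene_id"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    edges = frozenset(zip(df["mirna_id"], df["gene_id"]))
    return TargetDB(db_name, edges)


def read_target_tables(paths: list[str | Path]) -> list[TargetDB]:
    return [read_target_table(p, f"db{i + 1}") for i, p in enumerate(paths)]


def write_target_table(db: TargetDB, path: str | Path) -> None:
    rows = sorted(db.edges)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["mirna_id", "gene_id"])
        w.writerows(rows)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

@dataclass
class PathwayDB:
    """pathway_id -> (description, non-empty gene set)."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return out


def read_gmt(path: str | Path) -> PathwayDB:
    db = PathwayDB()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: GMT line {lineno} has fewer than 3 fields")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if not genes:
                raise ValidationError(f"{path}: GMT line {lineno} has an empty gene set")
            if name in db.sets:
                raise ValidationError(f"{path}: duplicate pathway {name!r}")
            db.sets[name] = set(genes)
            db.descriptions[name] = desc
    return db


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(db.sets):
            genes = sorted(db.sets[name])
            fh.write("\t".join([name, db.descriptions.get(name, "")] + genes) + "\n")
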