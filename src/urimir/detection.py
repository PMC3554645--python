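"""Detection filtering and control quality checks.

A miRNA species is "detected" in a sample when at least one of its wells for
that sample yielded a signal at or below the cycle cutoff.  Downstream
analyses keep only species detected in a sufficient fraction of the samples
entering a comparison (default two thirds).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import CqPanelSet

DEFAULT_MIN_FRACTION = 2.0 / 3.0


def detection_matrix(panel: CqPanelSet) -> pd.DataFrame:
    """Species x sample 0/1 indicator of detection (miRNA wells only)."""
    w = panel.wells[panel.wells["well_class"] == "mirna"]
    if w.empty:
        return pd.DataFrame(dtype=int)
    det = (
        w.groupby(["species_id", "sample_id"])["detected"]
        .any()
        .unstack(fill_value=False)
    )
    return det.astype(int).sort_index(axis=0).sort_index(axis=1)


def filter_detected(
    matrix: pd.DataFrame,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    strict: bool = False,
    samples: list[str] | None = None,
) -> list[str]:
    """Species whose detection fraction meets ``min_fraction``.

    ``strict=True`` switches the comparison from >= to >.  ``samples``
    restricts the computation to the samples of one comparison, matching the
    per-comparison application of the filter.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    if matrix.empty:
        raise ValueError("empty detection matrix")
    if samples is not None:
        missing = [s for s in samples if s not in matrix.columns]
        if missing:
            raise ValueError(f"samples absent from detection matrix: {missing}")
        matrix = matrix[samples]
    frac = matrix.mean(axis=1)
    keep = frac > min_fraction if strict else frac >= min_fraction
    return sorted(matrix.index[keep])


@dataclass
class QCReport:
    """Per-control-class detection rates and per-plate spike dispersion."""

    class_detection: pd.Series      # % of wells detected, per well class
    spike_plate_stats: pd.DataFrame  # plate -> (n, mean, sd) of spike_cal Cq

    def to_frame(self) -> pd.DataFrame:
        out = self.class_detection.rename("detection_pct").to_frame()
        out.index.name = "well_class"
        return out.reset_index()


def control_qc(panel: CqPanelSet) -> QCReport:
    """Detection percentages of control classes and spike Cq spread per plate.

    In a clean experiment blanks detect at 0%, the inter-plate calibrator at
    100%, and a dual spike present on half the plates at roughly 50%.
    """
    w = panel.wells
    ctrl = w[w["well_class"].isin(["blank", "spike_cal", "spike_dual", "endo_control"])]
    if ctrl.empty:
        raise ValueError("panel contains no control wells")
    det = ctrl.groupby("well_class")["detected"].mean() * 100.0
    # spike_dual absent from some plates: count absence as non-detection over
    # all plates so the expected rate for a half-present control is 50%
    if "spike_dual" in det.index:
        n_plates = w["plate_id"].nunique()
        dual = ctrl[ctrl["well_class"] == "spike_dual"]
        per_plate = dual.groupby("plate_id")["detected"].mean()
        det.loc["spike_dual"] = 100.0 * per_plate.reindex(panel.plates, fill_value=0.0).sum() / n_plates
    spike = ctrl[(ctrl["well_class"] == "spike_cal") & ctrl["detected"]]
    stats = (
        spike.groupby("plate_id")["cq"]
        .agg(n="count", mean="mean", sd="std")
        .fillna({"sd": 0.0})
    )
    return QCReport(class_detection=det, spike_plate_stats=stats)
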