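"""Simulation-based calibration of the normalization pipeline.

Runs the full two-step procedure on freshly simulated matched-pair
experiments with known planted Delta-Delta-Cq values and collects, per
species and replicate: the posterior-mean error, the posterior SE, whether
the 95% credible interval covered the truth, and the pseudocontour p.
Aggregates answer three questions -- is the point estimate as accurate as
the posterior claims (RMSE vs SE), do 95% intervals cover 95% of the time,
and are null species flagged at the nominal rate.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .detection import detection_matrix, filter_detected
from .normalize import McmcSettings, correct_cq, differential_expression, estimate_plate_effects
from .pipeline import build_pairs
from .simulate import SPIKE_CAL, SimulationDesign, simulate_panel_experiment


def run_replicate(
    design: SimulationDesign,
    settings: McmcSettings = McmcSettings(),
    seed: int = 0,
) -> pd.DataFrame:
    """One simulate-and-recover replicate; returns a per-species frame."""
    panel, annotations, truth = simulate_panel_experiment(design)
    kept = filter_detected(detection_matrix(panel))
    ss = np.random.SeedSequence(seed)
    s_plate, s_fit = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    pe = estimate_plate_effects(panel, settings=settings, seed=s_plate)
    corrected = correct_cq(panel, pe)
    pairs = build_pairs(annotations, "DN-vs-N")
    summaries, _ = differential_expression(
        corrected, pairs, kept, SPIKE_CAL, settings=settings, seed=s_fit
    )
    rows = []
    for sp, s in summaries.items():
        t = float(truth.true_ddcq[sp])
        rows.append(
            {
                "species_id": sp,
                "true_ddcq": t,
                "error": s.ddcq_mean - t,
                "se": s.ddcq_se,
                "covered": bool(s.cri_low <= t <= s.cri_high),
                "pseudo_p": s.pseudo_p,
                "null": t == 0.0,
                "significant": s.pseudo_p < 0.05,
            }
        )
    return pd.DataFrame(rows)


def calibration_study(
    n_reps: int = 200,
    design: SimulationDesign = SimulationDesign(),
    settings: McmcSettings = McmcSettings(),
    seed: int = 0,
) -> pd.DataFrame:
    """Stack ``run_replicate`` over ``n_reps`` independently seeded runs."""
    ss = np.random.SeedSequence(seed)
    frames = []
    for r, child in enumerate(ss.spawn(n_reps)):
        d_seed, f_seed = (int(c.generate_state(1)[0] % 2**31) for c in child.spawn(2))
        d = dataclasses.replace(design, seed=d_seed)
        frame = run_replicate(d, settings=settings, seed=f_seed)
        frame["replicate"] = r
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def summarize_calibration(study: pd.DataFrame) -> dict:
    """Headline calibration metrics from a ``calibration_study`` frame."""
    null = study[study["null"]]
    return {
        "rmse": float(np.sqrt((study["error"] ** 2).mean())),
        "mean_se": float(study["se"].mean()),
        "rmse_over_mean_se": float(
            np.sqrt((study["error"] ** 2).mean()) / study["se"].mean()
        ),
        "coverage": float(study["covered"].mean()),
        "type1_rate": float(null["significant"].mean()) if len(null) else float("nan"),
        "n_species_reps": int(len(study)),
        "n_null_reps": int(len(null)),
        "n_replicates": int(study["replicate"].nunique()),
    }
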