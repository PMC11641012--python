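"""End-to-end analysis runs: traces in, classification tables and a
reproducible JSON-able report out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from synaptrap.config import RunConfig
from synaptrap.pipeline import (
    CycleClassification,
    ForceExtensionTrace,
    analyze_cycle,
    correct_crosstalk,
    downsample,
    segment_cycles,
)

__all__ = ["AnalysisResult", "run_analyze"]

CATEGORIES = ("i", "ii", "iii", "none")


@dataclass
class AnalysisResult:
    cycles: pd.DataFrame     # one row per pull cycle
    events: pd.DataFrame     # one row per detected rupture event
    report: dict

    def classifications(self) -> pd.DataFrame:
        return self.cycles


def run_analyze(config: RunConfig,
                traces: list[ForceExtensionTrace]) -> AnalysisResult:
    """Classify every cycle of every input trace.

    Deterministic: identical inputs and configuration produce identical
    tables.  The report embeds the full configuration and its hash,
    per-category counts and frequencies, and the median characteristic
    forces.
    """
    if not traces:
        raise ValueError("no input traces")
    states = config.states()
    th = config.thermal()

    cycle_rows: list[dict] = []
    event_rows: list[dict] = []
    global_cycle = 0
    n_excluded = 0
    for trace_id, trace in enumerate(traces):
        trace = downsample(trace, config.downsample_factor)
        trace = correct_crosstalk(trace, config.crosstalk)
        for cycle in segment_cycles(trace, config.min_peak_force_pN,
                                    config.smooth_window):
            cycle.cycle_id = global_cycle
            global_cycle += 1
            if not cycle.analyzable:
                n_excluded += 1
                cycle_rows.append({
                    "cycle_id": cycle.cycle_id, "trace_id": trace_id,
                    "category": "excluded", "F_diss_pN": np.nan,
                    "F_unbind_pN": np.nan, "n_events": 0,
                    "delta_L_nm": "", "peak_force_pN": cycle.peak_force})
                continue
            cls = analyze_cycle(
                cycle, states, th,
                min_drop=config.min_drop_pN, min_jump=config.min_jump_nm,
                window=config.detector_window,
                smooth_window=config.smooth_window,
                min_force=config.min_fit_force_pN,
                residual_threshold=config.residual_threshold_nm,
                fingerprint=config.fingerprint_nm,
                fingerprint_tol=config.fingerprint_tol_nm,
                unbind_threshold=config.unbind_threshold_pN)
            cycle_rows.append(_cycle_row(cls, trace_id, cycle.peak_force))
            for ev in cls.events:
                event_rows.append({
                    "cycle_id": cls.cycle_id, "trace_id": trace_id,
                    "index": ev.index, "force_pN": ev.force,
                    "force_drop_pN": ev.force_drop,
                    "delta_L_nm": ev.delta_L,
                    "from_state": ev.from_state, "to_state": ev.to_state})

    cycles = pd.DataFrame(cycle_rows)
    events = pd.DataFrame(event_rows)
    analyzed = cycles[cycles["category"] != "excluded"]
    counts = {cat: int((analyzed["category"] == cat).sum())
              for cat in CATEGORIES}
    n_analyzed = max(len(analyzed), 1)
    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_traces": len(traces),
        "n_cycles": int(len(cycles)),
        "n_excluded_low_peak": n_excluded,
        "category_counts": counts,
        "category_frequencies": {cat: counts[cat] / n_analyzed
                                 for cat in CATEGORIES},
        "median_F_diss_pN": _safe_median(analyzed["F_diss_pN"]),
        "median_F_unbind_pN": _safe_median(analyzed["F_unbind_pN"]),
    }
    return AnalysisResult(cycles, events, report)


def _cycle_row(cls: CycleClassification, trace_id: int,
               peak_force: float) -> dict:
    deltas = ";".join(f"{ev.delta_L:.3f}" for ev in cls.events)
    return {"cycle_id": cls.cycle_id, "trace_id": trace_id,
            "category": cls.category,
            "F_diss_pN": np.nan if cls.F_diss is None else cls.F_diss,
            "F_unbind_pN": np.nan if cls.F_unbind is None else cls.F_unbind,
            "n_events": len(cls.events), "delta_L_nm": deltas,
            "peak_force_pN": peak_force}


def _safe_median(col: pd.Series) -> float | None:
    vals = col.dropna()
    return float(vals.median()) if len(vals) else None
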