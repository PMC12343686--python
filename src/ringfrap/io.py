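"""CSV dialects shared by the pipeline stages.

Traces:       cell_id, frame_index, time_s, roi_role, intensity (long form)
ROIs:         roi_id, role, center_x_px, center_y_px, diameter_px
Frame times:  frame_index, time_s
Ground truth: one row per cell with realized and condition-level parameters
Normalized:   cell_id, t_s, g (post-bleach frames only)
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .frap import NormalizedTrace
from .imaging import ROI_ROLES, FrapExperiment, RoiSpec


def write_traces(path: str | Path, experiments: Sequence[FrapExperiment]) -> None:
    rows = []
    for exp in experiments:
        for role in ROI_ROLES:
            trace = exp.intensities[role]
            for k, (t, v) in enumerate(zip(exp.times_s, trace)):
                rows.append((exp.cell_id, k, t, role, v))
    df = pd.DataFrame(
        rows, columns=["cell_id", "frame_index", "time_s", "roi_role", "intensity"]
    )
    df.to_csv(path, index=False)


def read_traces(path: str | Path, n_prebleach: int) -> List[FrapExperiment]:
    df = pd.read_csv(path)
    required = {"cell_id", "frame_index", "time_s", "roi_role", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: trace CSV needs columns {sorted(required)}")
    exps = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values(["roi_role", "frame_index"])
        times = None
        intensities = {}
        for role, sub in grp.groupby("roi_role"):
            t = sub["time_s"].to_numpy(dtype=float)
            if times is None:
                times = t
            elif not np.array_equal(times, t):
                raise ValueError(f"{path}: frame times differ between ROIs of {cell_id}")
            intensities[role] = sub["intensity"].to_numpy(dtype=float)
        exps.append(
            FrapExperiment(
                cell_id=str(cell_id),
                times_s=times,
                intensities=intensities,
                bleach_frame_index=n_prebleach,
                n_prebleach=n_prebleach,
            )
        )
    return exps


def write_rois(path: str | Path, rois: Sequence[RoiSpec]) -> None:
    pd.DataFrame(
        {
            "roi_id": [r.roi_id for r in rois],
            "role": [r.role for r in rois],
            "center_x_px": [r.center_x_px for r in rois],
            "center_y_px": [r.center_y_px for r in rois],
            "diameter_px": [r.diameter_px for r in rois],
        }
    ).to_csv(path, index=False)


def read_rois(path: str | Path) -> List[RoiSpec]:
    df = pd.read_csv(path)
    return [
        RoiSpec(
            roi_id=str(row.roi_id),
            role=str(row.role),
            center_x_px=float(row.center_x_px),
            center_y_px=float(row.center_y_px),
            diameter_px=float(row.diameter_px),
        )
        for row in df.itertuples()
    ]


def write_frame_times(path: str | Path, times_s) -> None:
    times_s = np.asarray(times_s, dtype=float)
    pd.DataFrame(
        {"frame_index": np.arange(len(times_s)), "time_s": times_s}
    ).to_csv(path, index=False)


def read_frame_times(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df.sort_values("frame_index")["time_s"].to_numpy(dtype=float)


def write_normalized(path: str | Path, traces: Sequence[NormalizedTrace]) -> None:
    rows = []
    for tr in traces:
        for t, g in zip(tr.t_s, tr.g):
            rows.append((tr.cell_id, t, g))
    pd.DataFrame(rows, columns=["cell_id", "t_s", "g"]).to_csv(path, index=False)


def read_normalized(path: str | Path) -> List[NormalizedTrace]:
    df = pd.read_csv(path)
    traces = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("t_s")
        g = grp["g"].to_numpy(dtype=float)
        traces.append(
            NormalizedTrace(
                cell_id=str(cell_id),
                t_s=grp["t_s"].to_numpy(dtype=float),
                g=g,
                f_norm=np.array([]),  # raw frames not round-tripped
                f0=float("nan"),
                prebleach_mean=float("nan"),
            )
        )
    return traces
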