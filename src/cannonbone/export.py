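"""CSV and plain-text result export.

Interface units are mm, N, MPa and ms, spelled out in each CSV header;
column order is fixed so identical runs reproduce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fea import FractureReport, SimulationResult
from .morphology import BoneModel

__all__ = ["timeseries_frame", "nodal_peak_frame", "write_result_csvs"]


def timeseries_frame(result: SimulationResult) -> pd.DataFrame:
    """Time series at output frames: time, GRF, plate advance, running max stress."""
    return pd.DataFrame(
        {
            "time_ms": result.time_grid * 1e3,
            "grf_n": result.grf_series,
            "plate_position_mm": result.plate_position * 1e3,
            "max_vm_mpa": result.max_vm_series / 1e6,
            "work_j": result.work_series,
            "kinetic_j": result.kinetic_series,
            "strain_j": result.strain_series,
            "contact_j": result.contact_series,
        }
    )


def nodal_peak_frame(model: BoneModel, result: SimulationResult) -> pd.DataFrame:
    """Per-node peak von Mises table with axial station and ray index."""
    n = model.n_nodes
    return pd.DataFrame(
        {
            "node": np.arange(n),
            "ray": model.ray_of_node,
            "station": model.node_positions[:, 0] / model.length,
            "peak_vm_mpa": result.nodal_peak_vm / 1e6,
        }
    )


def write_result_csvs(
    model: BoneModel,
    result: SimulationResult,
    report: FractureReport,
    out_dir,
    stem: str,
) -> list[Path]:
    """Write time-series CSV, nodal peak-stress CSV and the fracture report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    ts = out / f"{stem}_timeseries.csv"
    timeseries_frame(result).to_csv(ts, index=False, float_format="%.9g")
    paths.append(ts)
    npk = out / f"{stem}_nodal_peaks.csv"
    nodal_peak_frame(model, result).to_csv(npk, index=False, float_format="%.9g")
    paths.append(npk)
    rep = out / f"{stem}_fracture.txt"
    rep.write_text(str(report) + "\n")
    paths.append(rep)
    return paths
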