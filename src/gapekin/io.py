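"""Plain-text file formats for traces, FRET series, dwell tables and manifests.

All files are tab-separated with a header row so they open directly in any
spreadsheet or `pandas.read_csv(..., sep="\\t")`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .state_kinetics import DwellRecord
from .synthetic_data import IntensityTrace
from .trace_correction import FretTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_fret_trace",
    "read_fret_trace",
    "write_dwells",
    "read_dwells",
    "write_manifest",
    "read_manifest",
    "load_config",
]


def write_trace(trace: IntensityTrace, path: Path | str) -> None:
    """Write one molecule's two-channel trace: frame, time_s, donor, acceptor."""
    df = pd.DataFrame(
        {
            "frame": range(trace.n_frames),
            "time_s": trace.time_s,
            "donor": trace.donor,
            "acceptor": trace.acceptor,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_trace(
    path: Path | str, molecule_id: str | None = None, condition: str = ""
) -> IntensityTrace:
    df = pd.read_csv(path, sep="\t")
    time = df["time_s"].to_numpy()
    frame_period = float(time[1] - time[0]) if len(time) > 1 else 1.0
    return IntensityTrace(
        molecule_id=molecule_id or Path(path).stem,
        frame_period=frame_period,
        donor=df["donor"].to_numpy(),
        acceptor=df["acceptor"].to_numpy(),
        condition=condition,
    )


def write_fret_trace(fret: FretTrace, path: Path | str) -> None:
    """Write the corrected series: frame, time_s, fret, total."""
    df = pd.DataFrame(
        {
            "frame": range(fret.n_frames),
            "time_s": fret.time_s,
            "fret": fret.efficiency,
            "total": fret.total,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_fret_trace(
    path: Path | str,
    analysis_end: int | None = None,
    molecule_id: str | None = None,
) -> FretTrace:
    df = pd.read_csv(path, sep="\t")
    time = df["time_s"].to_numpy()
    frame_period = float(time[1] - time[0]) if len(time) > 1 else 1.0
    e = df["fret"].to_numpy()
    return FretTrace(
        molecule_id=molecule_id or Path(path).stem,
        frame_period=frame_period,
        efficiency=e,
        raw_efficiency=e,
        total=df["total"].to_numpy(),
        analysis_end=len(e) if analysis_end is None else analysis_end,
    )


def write_dwells(dwells: Sequence[DwellRecord], path: Path | str) -> None:
    df = pd.DataFrame(
        {
            "molecule": [d.molecule_id for d in dwells],
            "state": [d.state for d in dwells],
            "start_s": [d.start_s for d in dwells],
            "duration_s": [d.duration_s for d in dwells],
            "left_censored": [int(d.left_censored) for d in dwells],
            "right_censored": [int(d.right_censored) for d in dwells],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_dwells(path: Path | str) -> list[DwellRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        DwellRecord(
            molecule_id=str(r.molecule),
            state=str(r.state),
            start_s=float(r.start_s),
            duration_s=float(r.duration_s),
            left_censored=bool(r.left_censored),
            right_censored=bool(r.right_censored),
        )
        for r in df.itertuples()
    ]


def write_manifest(manifest: dict, path: Path | str) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path: Path | str) -> dict:
    return json.loads(Path(path).read_text())


def load_config(path: Path | str) -> dict:
    """Load a nested key/value run configuration (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
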