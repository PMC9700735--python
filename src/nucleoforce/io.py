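"""File I/O: delimited-text traces/events/trajectories, TIFF kymographs.

Delimited files are comma-separated with a header row, '.' decimal,
UTF-8.  Kymographs are stored as 16-bit grayscale TIFF with a JSON
sidecar carrying the scan geometry ({"pixel_nm": ..., "line_time_s": ...}).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from nucleoforce.kymo import Kymograph
from nucleoforce.stepfit import ForceClampTrace, UnwrapEvent


def write_trace(trace: ForceClampTrace, path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.time,
            "distance_nm": trace.distance,
            "force_pN": np.full(trace.time.size, trace.force_setpoint),
        }
    ).to_csv(path, index=False)


def read_trace(path, condition: str = "NO_PROTEIN") -> ForceClampTrace:
    try:
        df = pd.read_csv(path)
        return ForceClampTrace(
            time=df["time_s"].to_numpy(),
            distance=df["distance_nm"].to_numpy(),
            force_setpoint=float(df["force_pN"].iloc[0]),
            condition=condition,
        )
    except (KeyError, ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed trace file {path}: {exc}") from exc


def write_events(events: list[UnwrapEvent], path) -> None:
    pd.DataFrame(
        {
            "time_s": [e.time for e in events],
            "size_nm": [e.size for e in events],
            "multiplicity": [e.multiplicity for e in events],
        }
    ).to_csv(path, index=False)


def read_events(path) -> list[UnwrapEvent]:
    try:
        df = pd.read_csv(path)
        return [
            UnwrapEvent(time=float(r.time_s), size=float(r.size_nm),
                        multiplicity=int(r.multiplicity))
            for r in df.itertuples()
        ]
    except (AttributeError, ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed events file {path}: {exc}") from exc


def write_kymograph(kymo: Kymograph, path) -> None:
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, kymo.photons.astype(np.uint16))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"pixel_nm": kymo.pixel_size, "line_time_s": kymo.line_time})
    )


def read_kymograph(path) -> Kymograph:
    import tifffile

    path = Path(path)
    photons = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return Kymograph(
        photons=photons, pixel_size=float(meta["pixel_nm"]),
        line_time=float(meta["line_time_s"]),
    )


def write_trajectory(time, position, path, oligomer: int | None = None) -> None:
    df = pd.DataFrame({"time_s": time, "position_nm": position})
    if oligomer is not None:
        df["oligomer"] = oligomer
    df.to_csv(path, index=False)


def read_trajectory(path):
    try:
        df = pd.read_csv(path)
        olig = int(df["oligomer"].iloc[0]) if "oligomer" in df else None
        return df["time_s"].to_numpy(), df["position_nm"].to_numpy(), olig
    except (KeyError, ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed trajectory file {path}: {exc}") from exc
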