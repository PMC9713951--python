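"""File formats: curve CSV, wavefield array + JSON sidecar, result JSON.

CSV for tabular data, JSON for results and configuration, ``.npz`` with a
JSON sidecar for wavefield movies; no bespoke binary formats.  Units are
stated in column names and sidecar fields (mmHg/ml at boundaries, SI
inside arrays).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import AcquisitionSet
from .wavefield import VelocityMovie, WallGeometry

CURVE_COLUMNS = ["fill_volume_ml", "acquisition", "frequency_hz",
                 "phase_velocity_m_s"]


def write_curves_csv(path, acqset: AcquisitionSet) -> None:
    acqset.to_frame()[CURVE_COLUMNS].to_csv(path, index=False)


def read_curves_csv(path) -> AcquisitionSet:
    df = pd.read_csv(path)
    missing = set(CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"curve CSV {path} is missing columns {sorted(missing)}")
    return AcquisitionSet.from_frame(df)


def write_wavefield(path, movie: VelocityMovie, seed: int | None = None,
                    units: str = "m/s") -> None:
    """``path`` + ``path.with_suffix('.json')`` sidecar with sampling metadata."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), v=movie.v)
    sidecar = {"dx_m": movie.dx, "dt_s": movie.dt, "units": units,
               "axes": (["position", "time"] if movie.is_profile
                        else ["depth", "lateral", "time"]),
               "seed": seed}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_wavefield(path) -> tuple[VelocityMovie, dict]:
    path = Path(path)
    npz = path.with_suffix(".npz")
    sidecar_path = path.with_suffix(".json")
    if not npz.exists():
        raise FileNotFoundError(f"wavefield array not found: {npz}")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"wavefield sidecar not found: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    with np.load(npz) as data:
        v = data["v"]
    return VelocityMovie(v=v, dx=float(sidecar["dx_m"]),
                         dt=float(sidecar["dt_s"])), sidecar


def write_wall_mask(path, wall: WallGeometry) -> None:
    np.savez(Path(path).with_suffix(".npz"), mask=wall.mask,
             dx=wall.dx, dz=wall.dz)


def read_wall_mask(path) -> WallGeometry:
    with np.load(Path(path).with_suffix(".npz")) as data:
        return WallGeometry(mask=data["mask"], dx=float(data["dx"]),
                            dz=float(data["dz"]))


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
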