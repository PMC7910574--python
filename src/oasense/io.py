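"""Config and tidy-CSV input/output.

Configuration files are YAML (or JSON) with ``geometry``, ``load`` and
``sim`` sections; every canonical default is overridable and unknown keys are
rejected. Time series travel as tidy CSV with explicit unit-suffixed column
names; simulation outputs get a JSON metadata sidecar carrying the config
hash and convergence metric.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import MonitoringSession
from .doppler import BFFSeries, DopplerTrace
from .geometry import VesselGeometry, build_default_geometry
from .loads import PressureLoad
from .model import HemoField, ProbeSeries, SimConfig

__all__ = [
    "load_config",
    "default_config_dict",
    "config_hash",
    "write_hemofield_csv",
    "write_probe_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_bff_csv",
    "read_bff_csv",
    "write_session_csv",
    "read_session_csv",
]

_FIELD_MAP = {
    "geometry": (VesselGeometry, build_default_geometry),
    "load": (PressureLoad, PressureLoad),
    "sim": (SimConfig, SimConfig),
}


def default_config_dict() -> dict:
    """The full canonical configuration as a plain dict."""
    out = {}
    for section, (_cls, factory) in _FIELD_MAP.items():
        d = dataclasses.asdict(factory())
        out[section] = {
            k: list(v) if isinstance(v, tuple) else v for k, v in d.items()
        }
    return out


def _build_section(section: str, overrides: dict):
    cls, factory = _FIELD_MAP[section]
    base = dataclasses.asdict(factory())
    unknown = set(overrides) - set(base)
    if unknown:
        raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
    base.update(overrides)
    # tuples serialize as lists; restore
    for k, v in base.items():
        if isinstance(v, list):
            base[k] = tuple(v)
    return cls(**base)


def load_config(path) -> tuple[VesselGeometry, PressureLoad, SimConfig]:
    """Read a YAML/JSON config file; missing sections/keys take defaults.

    Validation happens in the dataclass constructors, so every geometry and
    load invariant is enforced on user-supplied configs.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(data) - set(_FIELD_MAP)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return tuple(
        _build_section(name, data.get(name, {}) or {}) for name in _FIELD_MAP
    )  # type: ignore[return-value]


def config_hash(geometry: VesselGeometry, load: PressureLoad, config: SimConfig) -> str:
    blob = json.dumps(
        {
            "geometry": dataclasses.asdict(geometry),
            "load": dataclasses.asdict(load),
            "sim": dataclasses.asdict(config),
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Simulation outputs
# ---------------------------------------------------------------------------

def write_hemofield_csv(field: HemoField, path, sidecar: dict | None = None) -> None:
    """Long-format field CSV (time_s, x_mm, area, velocity, pressure) + sidecar."""
    nt, nx = field.area_mm2.shape
    df = pd.DataFrame(
        {
            "time_s": np.repeat(field.time_s, nx),
            "x_mm": np.tile(field.x_mm, nt),
            "area_mm2": field.area_mm2.ravel(),
            "velocity_cm_s": field.velocity_cm_s.ravel(),
            "pressure_mmhg": field.pressure_mmhg.ravel(),
        }
    )
    path = Path(path)
    df.to_csv(path, index=False)
    meta = {k: v for k, v in field.metadata.items()}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2, default=float))


def write_probe_csv(series_list, path) -> None:
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": s.time_s,
                    "probe_id": s.location_id,
                    "area_mm2": s.area_mm2,
                    "velocity_cm_s": s.velocity_cm_s,
                    "pressure_mmhg": s.pressure_mmhg,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Doppler traces / BFF series / sessions
# ---------------------------------------------------------------------------

def write_trace_csv(trace: DopplerTrace, path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.time_s,
            "ps_ioa": trace.ps_ioa,
            "ps_eoa": trace.ps_eoa,
            "valid": trace.valid.astype(int),
        }
    ).to_csv(path, index=False)


def read_trace_csv(path) -> DopplerTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("trace needs at least two samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return DopplerTrace(
        fs_hz=fs,
        ps_ioa=df["ps_ioa"].to_numpy(),
        ps_eoa=df["ps_eoa"].to_numpy(),
        valid=df["valid"].to_numpy().astype(bool) if "valid" in df else None,
    )


def write_bff_csv(series: BFFSeries, path) -> None:
    pd.DataFrame(
        {
            "time_s": series.time_s,
            "bff": series.bff,
            "valid": series.valid.astype(int),
        }
    ).to_csv(path, index=False)


def read_bff_csv(path) -> BFFSeries:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    window = float(np.median(np.diff(t))) if len(t) > 1 else 10.0
    return BFFSeries(
        time_s=t,
        bff=df["bff"].to_numpy(float),
        valid=df["valid"].to_numpy().astype(bool),
        window_s=window,
    )


def write_session_csv(session: MonitoringSession, path) -> None:
    session.to_frame().to_csv(path, index=False)


def read_session_csv(path) -> MonitoringSession:
    df = pd.read_csv(path)
    sid = str(df["subject_id"].iloc[0]) if "subject_id" in df else "unknown"
    return MonitoringSession(
        subject_id=sid,
        time_s=df["time_s"].to_numpy(float),
        icp_inv_mmhg=df["icp_inv_mmhg"].to_numpy(float),
        bff=df["bff"].to_numpy(float),
        valid=df["valid"].to_numpy().astype(bool) if "valid" in df else None,
    )
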