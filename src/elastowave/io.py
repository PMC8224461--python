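"""HDF5 container and CSV table I/O.

One HDF5 file holds any subset of ``/displacement``, ``/frames`` and
``/stmap`` datasets; acquisition geometry lives in ``/geometry`` attributes.
Trial tables travel as CSV with columns ``sample_id, trial, speed_mps``.
"""
from __future__ import annotations

from typing import Optional

import h5py
import pandas as pd

from .errors import ConfigurationError
from .types import (
    AcquisitionGeometry,
    ComplexFrameSeries,
    DisplacementField,
    SpatioTemporalMap,
    TrialEnsemble,
)

__all__ = [
    "save_geometry",
    "load_geometry",
    "save_displacement_field",
    "load_displacement_field",
    "save_frames",
    "load_frames",
    "save_stmap",
    "load_stmap",
    "save_trial_table",
    "load_trial_ensembles",
]

_OPTIONAL_ATTRS = (
    "wavelength_lambda0",
    "refractive_index_n",
    "us_center_frequency",
    "sound_speed",
    "push_focus_depth",
)


def save_geometry(h5: h5py.File, geometry: AcquisitionGeometry) -> None:
    g = h5.require_group("geometry")
    for name in ("lateral_positions", "depth_positions"):
        if name in g:
            del g[name]
        g.create_dataset(name, data=getattr(geometry, name))
    g.attrs["frame_rate"] = geometry.frame_rate
    g.attrs["excitation_position"] = geometry.excitation_position
    g.attrs["modality"] = geometry.modality
    g.attrs["axes_units"] = "m; time axis in frames at frame_rate Hz"
    for name in _OPTIONAL_ATTRS:
        val = getattr(geometry, name)
        if val is not None:
            g.attrs[name] = val


def load_geometry(h5: h5py.File) -> AcquisitionGeometry:
    if "geometry" not in h5:
        raise ConfigurationError("container has no /geometry group")
    g = h5["geometry"]
    kwargs = {name: g.attrs.get(name) for name in _OPTIONAL_ATTRS}
    kwargs = {k: (float(v) if v is not None else None) for k, v in kwargs.items()}
    return AcquisitionGeometry(
        lateral_positions=g["lateral_positions"][()],
        depth_positions=g["depth_positions"][()],
        frame_rate=float(g.attrs["frame_rate"]),
        excitation_position=float(g.attrs["excitation_position"]),
        modality=str(g.attrs["modality"]),
        **kwargs,
    )


def save_displacement_field(
    path: str, field: DisplacementField, seed: Optional[int] = None
) -> None:
    with h5py.File(path, "a") as h5:
        if "displacement" in h5:
            del h5["displacement"]
        d = h5.create_dataset("displacement", data=field.values)
        d.attrs["units"] = "m"
        if field.ground_truth_speed is not None:
            d.attrs["ground_truth_speed"] = field.ground_truth_speed
        if seed is not None:
            d.attrs["seed"] = seed
        save_geometry(h5, field.geometry)


def load_displacement_field(path: str) -> DisplacementField:
    with h5py.File(path, "r") as h5:
        geom = load_geometry(h5)
        d = h5["displacement"]
        gts = d.attrs.get("ground_truth_speed")
        return DisplacementField(
            values=d[()],
            geometry=geom,
            ground_truth_speed=float(gts) if gts is not None else None,
        )


def save_frames(path: str, frames: ComplexFrameSeries, seed: Optional[int] = None) -> None:
    with h5py.File(path, "a") as h5:
        if "frames" in h5:
            del h5["frames"]
        d = h5.create_dataset("frames", data=frames.values)
        d.attrs["modality"] = frames.geometry.modality
        if seed is not None:
            d.attrs["seed"] = seed
        save_geometry(h5, frames.geometry)


def load_frames(path: str) -> ComplexFrameSeries:
    with h5py.File(path, "r") as h5:
        geom = load_geometry(h5)
        return ComplexFrameSeries(values=h5["frames"][()], geometry=geom)


def save_stmap(path: str, st_map: SpatioTemporalMap) -> None:
    with h5py.File(path, "a") as h5:
        if "stmap" in h5:
            del h5["stmap"]
        g = h5.create_group("stmap")
        g.create_dataset("values", data=st_map.values)
        g.create_dataset("lateral_positions", data=st_map.lateral_positions)
        g.attrs["frame_rate"] = st_map.frame_rate
        g.attrs["excitation_position"] = st_map.excitation_position
        g.attrs["direction_tag"] = st_map.direction_tag
        g.attrs["units"] = "m"


def load_stmap(path: str) -> SpatioTemporalMap:
    with h5py.File(path, "r") as h5:
        if "stmap" not in h5:
            raise ConfigurationError("container has no /stmap group")
        g = h5["stmap"]
        return SpatioTemporalMap(
            values=g["values"][()],
            lateral_positions=g["lateral_positions"][()],
            frame_rate=float(g.attrs["frame_rate"]),
            excitation_position=float(g.attrs["excitation_position"]),
            direction_tag=str(g.attrs["direction_tag"]),
        )


def save_trial_table(path: str, ensembles: list[TrialEnsemble]) -> None:
    rows = [
        {"sample_id": e.sample_id, "trial": t + 1, "speed_mps": s}
        for e in ensembles
        for t, s in enumerate(e.speeds)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_trial_ensembles(path: str) -> list[TrialEnsemble]:
    df = pd.read_csv(path)
    required = {"sample_id", "trial", "speed_mps"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"trial table needs columns {sorted(required)}")
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        speeds = grp.sort_values("trial")["speed_mps"].to_numpy(dtype=float)
        out.append(TrialEnsemble(sample_id=str(sid), speeds=speeds))
    return out
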