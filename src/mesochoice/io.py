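"""HDF5/CSV/JSON serialization of sessions, decompositions, and reports."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .decompose import Decomposition
from .synth import AreaAtlas, SessionTensor

__all__ = [
    "save_session",
    "load_session",
    "save_decomposition",
    "load_decomposition",
    "trials_to_csv",
    "write_json",
]

_TRIAL_COLUMNS = (
    "stim_onset",
    "left_angle",
    "right_angle",
    "theta",
    "difficulty",
    "choice",
    "correct",
    "first_move_time",
    "first_move_dir",
    "pupil_change",
    "attention_latent",
    "attention",
    "n_frames",
)


def save_session(
    path, tensor: SessionTensor, atlas: AreaAtlas, table: pd.DataFrame
) -> None:
    """One HDF5 container: /dff, /atlas, /trials/<column>, /saccades."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("dff", data=tensor.data, compression="gzip", compression_opts=1)
        d.attrs["frame_rate"] = tensor.frame_rate
        d.attrs["pre_stim"] = tensor.pre_stim
        d.attrs["open_loop"] = tensor.open_loop
        a = f.create_dataset("atlas", data=atlas.label_map)
        a.attrs["pixel_size"] = atlas.pixel_size
        a.attrs["area_names"] = ",".join(atlas.area_names)
        grp = f.create_group("trials")
        for col in _TRIAL_COLUMNS:
            if col not in table:
                continue
            vals = table[col].to_numpy()
            if vals.dtype == object:
                vals = np.array(["" if v is None else str(v) for v in vals], dtype="S16")
            grp.create_dataset(col, data=vals)
        sac = f.create_group("saccades")
        for i, times in enumerate(table["saccade_times"]):
            sac.create_dataset(str(i), data=np.asarray(times, dtype=float))


def load_session(path) -> tuple[SessionTensor, AreaAtlas, pd.DataFrame]:
    with h5py.File(path, "r") as f:
        d = f["dff"]
        tensor = SessionTensor(
            data=d[...],
            frame_rate=float(d.attrs["frame_rate"]),
            pre_stim=float(d.attrs["pre_stim"]),
            open_loop=float(d.attrs["open_loop"]),
        )
        a = f["atlas"]
        atlas = AreaAtlas(
            label_map=a[...],
            area_names=tuple(a.attrs["area_names"].split(",")),
            pixel_size=float(a.attrs["pixel_size"]),
        )
        cols = {}
        for col in f["trials"]:
            vals = f["trials"][col][...]
            if vals.dtype.kind == "S":
                vals = np.array([v.decode() or None for v in vals], dtype=object)
            cols[col] = vals
        n = len(next(iter(cols.values())))
        cols["saccade_times"] = [f["saccades"][str(i)][...] for i in range(n)]
        table = pd.DataFrame(cols)
    return tensor, atlas, table


def save_decomposition(path, decomp: Decomposition) -> None:
    with h5py.File(path, "a") as f:
        if "decomp" in f:
            del f["decomp"]
        g = f.create_group("decomp")
        g.create_dataset("spatial", data=decomp.spatial)
        g.create_dataset("area_ids", data=decomp.component_area)
        g.attrs["area_names"] = ",".join(decomp.area_names)
        g.attrs["ev_total"] = decomp.ev_total
        g.attrs["converged"] = decomp.converged
        t = g.create_group("temporal")
        for i in range(decomp.temporal.shape[0]):
            t.create_dataset(f"trial_{i}", data=decomp.temporal[i])


def load_decomposition(path) -> Decomposition:
    with h5py.File(path, "r") as f:
        g = f["decomp"]
        n_trials = len(g["temporal"])
        temporal = np.stack([g["temporal"][f"trial_{i}"][...] for i in range(n_trials)])
        return Decomposition(
            spatial=g["spatial"][...],
            temporal=temporal,
            component_area=g["area_ids"][...],
            area_names=tuple(g.attrs["area_names"].split(",")),
            ev_total=float(g.attrs["ev_total"]),
            converged=bool(g.attrs["converged"]),
        )


def trials_to_csv(table: pd.DataFrame, path) -> None:
    """Flat CSV export of the trial table (saccade times as ; joined seconds)."""
    out = table.copy()
    out["saccade_times"] = [
        ";".join(f"{t:.4f}" for t in ts) for ts in out["saccade_times"]
    ]
    out.to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, np.bool_):
            return bool(obj)
        return super().default(obj)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, cls=_NumpyEncoder)
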