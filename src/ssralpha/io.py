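"""Readers and writers: HDF5 epoch containers, FieldTrip-style MAT files,
electrode-position text files and long-format TSV exports."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import loadmat, savemat

from .data import Epochs, Montage
from .spectral import MeasureMap

__all__ = [
    "save_epochs_h5", "load_epochs_h5", "save_epochs_fieldtrip_mat",
    "load_fieldtrip_mat", "read_electrode_positions", "measure_maps_to_tsv",
    "write_json",
]


def save_epochs_h5(path, epochs: Epochs, montage: Montage | None = None) -> None:
    """Write epochs (and optionally the montage) to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.attrs["srate"] = float(epochs.srate)
        f.attrs["t0"] = float(epochs.t0)
        f.attrs["units"] = epochs.units
        f.create_dataset("condition", data=np.asarray(epochs.condition, dtype="S"))
        f.create_dataset("channel_names",
                         data=np.asarray(epochs.channel_names, dtype="S"))
        if montage is not None:
            g = f.create_group("montage")
            g.create_dataset("positions", data=montage.positions)
            g.create_dataset("adjacency", data=montage.adjacency)
            g.create_dataset("names", data=np.asarray(montage.names, dtype="S"))


def load_epochs_h5(path) -> tuple[Epochs, Montage | None]:
    with h5py.File(path, "r") as f:
        epochs = Epochs(
            data=f["data"][()],
            srate=float(f.attrs["srate"]),
            condition=np.array([s.decode() for s in f["condition"][()]]),
            channel_names=[s.decode() for s in f["channel_names"][()]],
            t0=float(f.attrs.get("t0", 0.0)),
            units=str(f.attrs.get("units", "a.u.")),
        )
        montage = None
        if "montage" in f:
            g = f["montage"]
            montage = Montage(positions=g["positions"][()],
                              adjacency=g["adjacency"][()],
                              names=[s.decode() for s in g["names"][()]])
    return epochs, montage


def save_epochs_fieldtrip_mat(path, epochs: Epochs) -> None:
    """Write a FieldTrip-style epoched structure (fields: trial, time,
    label, fsample, trialinfo) for interoperability."""
    times = epochs.times
    labels = sorted(set(epochs.condition.tolist()))
    code = {lab: i + 1 for i, lab in enumerate(labels)}
    ft = {
        "trial": np.array([epochs.data[i] for i in range(epochs.n_trials)],
                          dtype=object),
        "time": np.array([times for _ in range(epochs.n_trials)], dtype=object),
        "label": np.array(epochs.channel_names, dtype=object),
        "fsample": float(epochs.srate),
        "trialinfo": np.array([[code[c]] for c in epochs.condition], dtype=float),
        "condition_codes": np.array([[code[lab], lab] for lab in labels], dtype=object),
    }
    savemat(path, {"data": ft})


def _ft_field(struct, *names):
    for name in names:
        if hasattr(struct, name):
            return getattr(struct, name)
    raise KeyError(f"FieldTrip structure lacks any of {names}")


def load_fieldtrip_mat(path, condition_map: dict | None = None,
                       var_name: str | None = None) -> Epochs:
    """Schema-tolerant reader for FieldTrip-style epoched MAT structures.

    Looks for the fields ``trial`` (cell array of channels x samples),
    ``label``, ``fsample`` (or ``time``) and optionally ``trialinfo``;
    ``condition_map`` translates trialinfo codes to condition labels.
    """
    raw = loadmat(path, squeeze_me=True, struct_as_record=False)
    candidates = [v for k, v in raw.items() if not k.startswith("__")]
    struct = None
    if var_name is not None:
        struct = raw[var_name]
    else:
        for v in candidates:
            if hasattr(v, "trial"):
                struct = v
                break
    if struct is None:
        raise ValueError("no FieldTrip-style epoched structure found in MAT file")
    trials = _ft_field(struct, "trial")
    if not isinstance(trials, np.ndarray) or trials.dtype != object:
        trials = np.array([trials], dtype=object) if np.ndim(trials) == 2 else trials
    data = np.stack([np.asarray(tr, dtype=float) for tr in trials])
    labels = [str(lab) for lab in np.atleast_1d(_ft_field(struct, "label"))]
    try:
        srate = float(_ft_field(struct, "fsample"))
    except KeyError:
        t = np.asarray(np.atleast_1d(_ft_field(struct, "time"))[0], dtype=float)
        srate = 1.0 / np.median(np.diff(t))
    try:
        info = np.atleast_2d(np.asarray(_ft_field(struct, "trialinfo"), dtype=float))
        if info.shape[0] != data.shape[0]:
            info = info.T
        codes = info[:, 0].astype(int)
        if condition_map:
            condition = np.array([condition_map[int(c)] for c in codes])
        else:
            condition = np.array([f"cond{c}" for c in codes])
    except KeyError:
        condition = np.array(["unknown"] * data.shape[0])
    return Epochs(data=data, srate=srate, condition=condition, channel_names=labels)


def read_electrode_positions(path) -> tuple[list[str], np.ndarray]:
    """Read a plain-text electrode file (``name x y z`` per line) and
    return names plus unit-normalized positions."""
    names, rows = [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        if len(parts) != 4:
            raise ValueError(f"expected 'name x y z', got: {line!r}")
        names.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    pos = np.asarray(rows, dtype=float)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return names, pos


def measure_maps_to_tsv(path, maps: dict[str, MeasureMap]) -> None:
    """Export measure maps as long-format TSV
    (channel, freq, condition/measure tag, scale, value)."""
    rows = []
    for tag, m in maps.items():
        vals = np.atleast_2d(m.values)
        freqs = m.freqs if m.freqs is not None else [np.nan]
        for ci, ch in enumerate(m.channel_names):
            v = np.atleast_1d(vals[ci])
            for fi, f in enumerate(np.atleast_1d(freqs)):
                rows.append((ch, float(f), tag, m.measure, m.scale, float(v[fi])))
    df = pd.DataFrame(rows, columns=["channel", "freq", "tag", "measure",
                                     "scale", "value"])
    df.to_csv(path, sep="\t", index=False)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
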