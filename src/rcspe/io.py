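"""HDF5 session container.

Layout::

    /eeg, /fnirs_hbo, /fnirs_hbr   groups, each with
        data            (n_trials, n_channels, n_samples) float64
        channel_names   UTF-8 string array
        attrs: fs, t0
    /labels             int array with attrs {"1": "left", "2": "right"}
    /truth              optional group: mixing_eeg, mixing_fnirs,
                        discriminative_sources

Round trips are lossless: arrays are stored uncompressed float64.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .containers import LABEL_NAMES, GroundTruth, MultimodalSession, TrialSet
from .errors import SchemaError

_MODALITIES = ("eeg", "fnirs_hbo", "fnirs_hbr")


def _write_trialset(group: h5py.Group, trials: TrialSet) -> None:
    group.create_dataset("data", data=trials.data)
    group.create_dataset(
        "channel_names",
        data=np.array(trials.channel_names, dtype=h5py.string_dtype("utf-8")),
    )
    group.attrs["fs"] = trials.fs
    group.attrs["t0"] = trials.t0


def _read_trialset(group: h5py.Group, labels: np.ndarray | None) -> TrialSet:
    return TrialSet(
        data=group["data"][()],
        fs=float(group.attrs["fs"]),
        channel_names=[c.decode() if isinstance(c, bytes) else str(c)
                       for c in group["channel_names"][()]],
        t0=float(group.attrs["t0"]),
        labels=labels,
    )


def save_session(session: MultimodalSession, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        for name in _MODALITIES:
            _write_trialset(f.create_group(name), getattr(session, name))
        labels = f.create_dataset("labels", data=session.labels.astype(np.int64))
        for code, name in LABEL_NAMES.items():
            labels.attrs[str(code)] = name
        if session.truth is not None:
            g = f.create_group("truth")
            g.create_dataset("mixing_eeg", data=session.truth.mixing_eeg)
            g.create_dataset("mixing_fnirs", data=session.truth.mixing_fnirs)
            g.create_dataset(
                "discriminative_sources",
                data=session.truth.discriminative_sources.astype(np.int64),
            )


def load_session(path: str | Path) -> MultimodalSession:
    with h5py.File(path, "r") as f:
        missing = [k for k in (*_MODALITIES, "labels") if k not in f]
        if missing:
            raise SchemaError(f"session file missing group(s): {missing}")
        labels = f["labels"][()].astype(int)
        sets = {name: _read_trialset(f[name], labels) for name in _MODALITIES}
        truth = None
        if "truth" in f:
            truth = GroundTruth(
                mixing_eeg=f["truth/mixing_eeg"][()],
                mixing_fnirs=f["truth/mixing_fnirs"][()],
                discriminative_sources=f["truth/discriminative_sources"][()],
            )
    return MultimodalSession(
        eeg=sets["eeg"], fnirs_hbo=sets["fnirs_hbo"], fnirs_hbr=sets["fnirs_hbr"],
        labels=labels, truth=truth,
    )
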