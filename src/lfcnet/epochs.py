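"""Epoch container: trials x channels x samples with per-trial metadata.

``EpochSet`` is the native in-memory exchange object of the pipeline.  On
disk it is a pair of files: a JSON sidecar (``<stem>.json``) carrying the
sampling rate, epoch start time, channel names and the per-trial metadata
table, plus a flat little-endian float32 binary (``<stem>.dat``) holding
the data cube in C order (trial-major, then channel, then sample).  The
split keeps metadata diff-able while the bulk array stays compact.

EDF/EDF+ recordings can be imported through :func:`read_edf_recording`
(requires ``mne``); epochs are then cut with
:func:`lfcnet.preprocessing.segment_epochs`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import CHANNELS

GROUPS = ("guilty", "innocent")
STIMS = ("P", "T", "I")

META_COLUMNS = ("subject", "group", "stim", "rt_ms", "click_ok")


@dataclass
class EpochSet:
    """Set of fixed-length EEG epochs with aligned per-trial metadata.

    Parameters
    ----------
    data:
        Array of shape (n_trials, n_channels, n_samples), microvolts.
    fs:
        Sampling rate in Hz.
    t0:
        Time of the first sample relative to stimulus onset, seconds
        (negative for a pre-stimulus baseline).
    channel_names:
        Channel labels in data order.
    meta:
        One row per trial with at least the columns
        ``subject, group, stim, rt_ms, click_ok``.
    """

    data: np.ndarray
    fs: float
    t0: float
    channel_names: tuple[str, ...] = CHANNELS
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        self.channel_names = tuple(self.channel_names)
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[1]} channels but "
                f"{len(self.channel_names)} names"
            )
        if len(self.meta) == 0:
            self.meta = pd.DataFrame(
                {
                    "subject": ["s0"] * self.n_trials,
                    "group": ["guilty"] * self.n_trials,
                    "stim": ["P"] * self.n_trials,
                    "rt_ms": [np.nan] * self.n_trials,
                    "click_ok": [True] * self.n_trials,
                }
            )
        if len(self.meta) != self.n_trials:
            raise ValueError("meta must have one row per trial")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta missing columns {missing}")
        bad_groups = set(self.meta["group"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown group labels {sorted(bad_groups)}")
        bad_stims = set(self.meta["stim"]) - set(STIMS)
        if bad_stims:
            raise ValueError(f"unknown stimulus labels {sorted(bad_stims)}")
        self.meta = self.meta.reset_index(drop=True)

    # -- basic geometry ------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def time_axis(self) -> np.ndarray:
        """Per-sample times: sample i <-> t0 + i/fs (left-closed grid)."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ValueError(f"channel {name!r} not present") from None

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset trials by boolean mask or integer index, order-preserving."""
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            fs=self.fs,
            t0=self.t0,
            channel_names=self.channel_names,
            meta=self.meta.iloc[mask].reset_index(drop=True),
        )

    def reorder_channels(self, order: tuple[str, ...] = CHANNELS) -> "EpochSet":
        """Return a copy with channels in the requested canonical order.

        Extra channels are dropped; missing ones raise naming the absentees.
        """
        missing = [c for c in order if c not in self.channel_names]
        if missing:
            raise ValueError(f"missing channels from montage: {missing}")
        idx = [self.channel_names.index(c) for c in order]
        return EpochSet(
            data=self.data[:, idx, :],
            fs=self.fs,
            t0=self.t0,
            channel_names=tuple(order),
            meta=self.meta.copy(),
        )


# -- native container ----------------------------------------------------

def write_epochs(epochs: EpochSet, stem: str | Path) -> tuple[Path, Path]:
    """Write the native container: ``<stem>.json`` + ``<stem>.dat``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    jpath, dpath = stem.with_suffix(".json"), stem.with_suffix(".dat")
    meta_records = self_describing_meta(epochs.meta)
    sidecar = {
        "format": "lfcnet-epochs",
        "version": 1,
        "fs": float(epochs.fs),
        "t0": float(epochs.t0),
        "shape": list(epochs.data.shape),
        "dtype": "<f4",
        "order": "C (trial, channel, sample)",
        "channel_names": list(epochs.channel_names),
        "meta": meta_records,
    }
    jpath.write_text(json.dumps(sidecar, indent=1))
    epochs.data.astype("<f4").tofile(dpath)
    return jpath, dpath


def self_describing_meta(meta: pd.DataFrame) -> list[dict]:
    recs = meta.to_dict(orient="records")
    out = []
    for r in recs:
        clean = {}
        for k, v in r.items():
            if isinstance(v, (np.floating, float)):
                v = None if (isinstance(v, float) and np.isnan(v)) or (
                    isinstance(v, np.floating) and np.isnan(v)
                ) else float(v)
            elif isinstance(v, (np.integer,)):
                v = int(v)
            elif isinstance(v, (np.bool_, bool)):
                v = bool(v)
            clean[k] = v
        out.append(clean)
    return out


def read_epochs(stem: str | Path) -> EpochSet:
    """Read the native container written by :func:`write_epochs`.

    Channel order is normalised to the canonical 12-channel montage when
    all 12 electrodes are present.
    """
    stem = Path(stem)
    jpath = stem if stem.suffix == ".json" else stem.with_suffix(".json")
    if not jpath.exists():
        raise FileNotFoundError(jpath)
    sidecar = json.loads(jpath.read_text())
    if sidecar.get("format") != "lfcnet-epochs":
        raise ValueError(f"{jpath} is not an lfcnet epoch container")
    dpath = jpath.with_suffix(".dat")
    shape = tuple(sidecar["shape"])
    data = np.fromfile(dpath, dtype=sidecar["dtype"]).reshape(shape)
    meta = pd.DataFrame(sidecar["meta"])
    if "rt_ms" in meta.columns:
        meta["rt_ms"] = meta["rt_ms"].astype(float)
    epochs = EpochSet(
        data=data,
        fs=sidecar["fs"],
        t0=sidecar["t0"],
        channel_names=tuple(sidecar["channel_names"]),
        meta=meta,
    )
    if set(CHANNELS) <= set(epochs.channel_names):
        epochs = epochs.reorder_channels(CHANNELS)
    return epochs


# -- EDF import ----------------------------------------------------------

def read_edf_recording(path: str | Path):
    """Read a continuous EDF/EDF+ recording.

    Returns ``(data_uV, fs, channel_names, events)`` where ``events`` is a
    list of ``(sample_index, annotation_text)`` taken from the EDF+
    annotations track.  Channels are reordered to the canonical montage;
    extras are dropped; missing montage channels raise, naming them.
    """
    import mne  # optional dependency, imported lazily

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = list(raw.ch_names)
    missing = [c for c in CHANNELS if c not in names]
    if missing:
        raise ValueError(f"missing channels from montage: {missing}")
    idx = [names.index(c) for c in CHANNELS]
    data = raw.get_data()[idx] * 1e6  # mne works in volts
    fs = float(raw.info["sfreq"])
    events = [
        (int(round(onset * fs)), desc)
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
    ]
    return data.astype(np.float32), fs, tuple(CHANNELS), events
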