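"""Segmentation, trial screening, baseline correction, grand averages.

Screening implements the operational rejection rules: clicking errors,
response times above 700 ms, and any sample exceeding +-75 uV on any
channel.  The expert visual check for a P300 in each subject's target
response is replaced by a thresholded peak detector with documented
defaults (peak of the average in 250-600 ms on Pz/P3/Cz above a uV
threshold).

Time convention: epoch sample i corresponds to t0 + i/fs; intervals are
left-closed, right-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epochs import EpochSet

logger = logging.getLogger(__name__)

DEFAULT_RT_MAX_MS = 700.0
DEFAULT_AMP_CRIT_UV = 75.0
DEFAULT_P300_WINDOW = (0.250, 0.600)
DEFAULT_P300_CHANNELS = ("Pz", "P3", "Cz")
DEFAULT_P300_THRESHOLD_UV = 2.0


def segment_epochs(
    recording: np.ndarray,
    fs: float,
    events: list[tuple[int, dict]],
    window: tuple[float, float] = (-0.3, 1.3),
    channel_names: tuple[str, ...] | None = None,
) -> EpochSet:
    """Cut fixed-length epochs around event samples from a continuous array.

    ``events`` is a list of (sample_index, metadata-dict).  Events too
    close to a recording edge are skipped and logged, not fatal.
    """
    recording = np.asarray(recording)
    if recording.ndim != 2:
        raise ValueError("recording must be channels x samples")
    t0, t1 = window
    pre = int(round(-t0 * fs))
    post = int(round(t1 * fs))
    n_total = recording.shape[1]
    arrays, rows = [], []
    for onset, meta in events:
        if onset - pre < 0 or onset + post > n_total:
            logger.warning(
                "event at sample %d skipped: needs samples [%d, %d) of %d",
                onset, onset - pre, onset + post, n_total,
            )
            continue
        arrays.append(recording[:, onset - pre : onset + post])
        rows.append(dict(meta))
    names = channel_names or tuple(f"ch{i}" for i in range(recording.shape[0]))
    data = (
        np.stack(arrays)
        if arrays
        else np.empty((0, recording.shape[0], pre + post), dtype=np.float32)
    )
    return EpochSet(
        data=data, fs=fs, t0=t0, channel_names=names, meta=pd.DataFrame(rows)
    )


@dataclass
class RejectionReport:
    """Per-trial rejection outcomes; ``reasons`` is empty for kept trials."""

    kept: np.ndarray  # boolean per input trial
    reasons: list[list[str]]  # per input trial

    @property
    def n_rejected(self) -> int:
        return int((~self.kept).sum())

    def summary(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rs in self.reasons:
            for r in rs:
                counts[r] = counts.get(r, 0) + 1
        return counts


def reject_trials(
    epochs: EpochSet,
    rt_max_ms: float = DEFAULT_RT_MAX_MS,
    amp_crit_uv: float = DEFAULT_AMP_CRIT_UV,
) -> tuple[EpochSet, RejectionReport]:
    """Drop trials with clicking errors, slow responses, or huge amplitudes.

    A trial survives iff click_ok is true, rt_ms <= rt_max_ms (missing RTs
    pass), and max |amplitude| <= amp_crit_uv on every channel.  Order of
    survivors is preserved; the report lists every rejection with its
    reason(s).  The operation is idempotent.
    """
    if rt_max_ms <= 0 or amp_crit_uv <= 0:
        raise ValueError("rt_max_ms and amp_crit_uv must be positive")
    reasons: list[list[str]] = []
    peak = np.abs(epochs.data).max(axis=(1, 2)) if epochs.n_trials else np.array([])
    for k in range(epochs.n_trials):
        row = epochs.meta.iloc[k]
        r = []
        if not bool(row["click_ok"]):
            r.append("click")
        rt = row["rt_ms"]
        if pd.notna(rt) and rt > rt_max_ms:
            r.append("rt")
        if peak[k] > amp_crit_uv:
            r.append("amplitude")
        reasons.append(r)
    kept = np.array([len(r) == 0 for r in reasons], dtype=bool)
    report = RejectionReport(kept=kept, reasons=reasons)
    if report.n_rejected:
        logger.info(
            "rejected %d/%d trials: %s",
            report.n_rejected, epochs.n_trials, report.summary(),
        )
    return epochs.select(kept), report


def baseline_correct(
    epochs: EpochSet, baseline: tuple[float, float] | None = None
) -> EpochSet:
    """Subtract each trial/channel mean over the baseline interval.

    Default baseline is the full pre-stimulus interval [t0, 0).
    """
    t0 = epochs.t0
    b0, b1 = baseline if baseline is not None else (t0, 0.0)
    t_end = t0 + epochs.n_samples / epochs.fs
    if b0 < t0 - 1e-9 or b1 > t_end + 1e-9 or b1 <= b0:
        raise ValueError(f"baseline ({b0}, {b1}) outside epoch window")
    t = epochs.time_axis
    mask = (t >= b0 - 1e-12) & (t < b1 - 1e-12)
    if not mask.any():
        raise ValueError("baseline interval contains no samples")
    means = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(
        data=epochs.data - means,
        fs=epochs.fs,
        t0=epochs.t0,
        channel_names=epochs.channel_names,
        meta=epochs.meta.copy(),
    )


def grand_average_erp(
    epochs: EpochSet,
    group: str | None = None,
    stim: str | None = None,
    subject: str | None = None,
) -> np.ndarray:
    """Pointwise mean waveform (channels x samples) over selected trials."""
    sel = np.ones(epochs.n_trials, dtype=bool)
    label = []
    if group is not None:
        sel &= (epochs.meta["group"] == group).to_numpy()
        label.append(f"group={group}")
    if stim is not None:
        sel &= (epochs.meta["stim"] == stim).to_numpy()
        label.append(f"stim={stim}")
    if subject is not None:
        sel &= (epochs.meta["subject"] == subject).to_numpy()
        label.append(f"subject={subject}")
    if not sel.any():
        raise ValueError(f"no trials in cell ({', '.join(label) or 'all'})")
    return epochs.data[sel].mean(axis=0)


def p300_present(
    average: np.ndarray,
    epochs_like: EpochSet,
    window: tuple[float, float] = DEFAULT_P300_WINDOW,
    channels: tuple[str, ...] = DEFAULT_P300_CHANNELS,
    threshold_uv: float = DEFAULT_P300_THRESHOLD_UV,
) -> bool:
    """Automated P300 screen on an average waveform.

    True when the peak of the average inside ``window`` on any screening
    channel exceeds ``threshold_uv``.
    """
    t = epochs_like.time_axis
    mask = (t >= window[0]) & (t < window[1])
    for name in channels:
        c = epochs_like.channel(name)
        if float(average[c, mask].max()) > threshold_uv:
            return True
    return False


def screen_subjects_for_p300(
    epochs: EpochSet,
    stim: str = "T",
    **p300_kwargs,
) -> list[str]:
    """Subjects whose target-response average shows no P300 (to exclude)."""
    flagged = []
    for subject in sorted(epochs.meta["subject"].unique()):
        sel = (epochs.meta["subject"] == subject) & (epochs.meta["stim"] == stim)
        if not sel.any():
            continue
        avg = epochs.data[sel.to_numpy()].mean(axis=0)
        if not p300_present(avg, epochs, **p300_kwargs):
            flagged.append(subject)
    return flagged
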