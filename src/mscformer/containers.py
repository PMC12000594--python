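"""Epoched EEG trial container and its portable on-disk format.

A :class:`TrialSet` is the unit of data every pipeline stage consumes and
produces: a dense ``(N, C, T)`` array of epoched multi-channel trials plus
labels and acquisition metadata.  The on-disk form is a single zip file of
``.npy`` buffers and one ``meta.json`` block, written with fixed zip
timestamps so that ``save -> load -> save`` is byte-identical.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["TrialSet", "EpochSpec", "save_trialset", "load_trialset"]

_ZIP_DATE = (1980, 1, 1, 0, 0, 0)


@dataclass
class TrialSet:
    """Epoched multi-channel EEG trials with labels and metadata.

    Parameters
    ----------
    signals : ndarray, shape (N, C, T)
        Trial signals in microvolts (or standardized units downstream).
    labels : ndarray of int, shape (N,)
        Class index per trial, each in ``[0, n_classes)``.
    fs : float
        Sampling rate in Hz (250 for both benchmark datasets).
    channel_names : list of str, length C
    class_names : list of str, length M
    subject_id, session_tag : str
        Free-form acquisition metadata.
    provenance : list of str, length N
        Tag recording where each trial came from (e.g. ``"train"``,
        ``"augmented"``); used by the training protocol's leakage guards.
    """

    signals: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str]
    class_names: list[str]
    subject_id: str = ""
    session_tag: str = ""
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.signals.ndim != 3:
            raise ValueError(
                f"signals must be (n_trials, n_channels, n_samples), got shape {self.signals.shape}"
            )
        if self.signals.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"{self.signals.shape[0]} trials but {self.labels.shape[0]} labels"
            )
        if self.signals.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.signals.shape[1]} channels but {len(self.channel_names)} channel names"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        m = len(self.class_names)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= m):
            raise ValueError(
                f"labels must lie in [0, {m}), found range "
                f"[{self.labels.min()}, {self.labels.max()}]"
            )
        if not self.provenance:
            self.provenance = ["unspecified"] * self.n_trials
        if len(self.provenance) != self.n_trials:
            raise ValueError("provenance must have one tag per trial")

    @property
    def n_trials(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, idx, provenance: str | None = None) -> "TrialSet":
        """Return a new TrialSet restricted to trial indices ``idx``."""
        idx = np.asarray(idx)
        tags = [self.provenance[i] for i in idx] if provenance is None else [provenance] * len(idx)
        return replace(
            self,
            signals=self.signals[idx].copy(),
            labels=self.labels[idx].copy(),
            channel_names=list(self.channel_names),
            class_names=list(self.class_names),
            provenance=tags,
        )

    def with_signals(self, signals: np.ndarray) -> "TrialSet":
        return replace(
            self,
            signals=signals,
            channel_names=list(self.channel_names),
            class_names=list(self.class_names),
            provenance=list(self.provenance),
        )


@dataclass(frozen=True)
class EpochSpec:
    """Epoch window and channel selection.

    ``t_start``/``t_end`` are seconds from trial start; the sample window is
    half-open ``[round(t_start*fs), round(t_start*fs) + (t_end-t_start)*fs)``
    with 0-based indexing. ``channels_keep=None`` keeps every non-EOG channel.
    """

    t_start: float
    t_end: float
    channels_keep: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError(
                f"epoch window must have t_end > t_start, got [{self.t_start}, {self.t_end}]"
            )
        if self.channels_keep is not None:
            object.__setattr__(self, "channels_keep", tuple(self.channels_keep))

    def n_samples(self, fs: float) -> int:
        n = (self.t_end - self.t_start) * fs
        n_int = round(n)
        if abs(n - n_int) > 1e-9 or n_int <= 0:
            raise ValueError(
                f"(t_end - t_start) * fs must be a positive integer, got {n}"
            )
        return n_int

    def sample_window(self, fs: float) -> tuple[int, int]:
        start = round(self.t_start * fs)
        return start, start + self.n_samples(fs)


def _write_array(zf: zipfile.ZipFile, name: str, arr: np.ndarray) -> None:
    buf = io.BytesIO()
    np.save(buf, arr, allow_pickle=False)
    info = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
    info.compress_type = zipfile.ZIP_STORED
    zf.writestr(info, buf.getvalue())


def save_trialset(ts: TrialSet, path) -> None:
    """Write ``ts`` losslessly to ``path`` (numeric arrays bit-exact)."""
    meta = {
        "format": "mscformer-trialset",
        "version": 1,
        "fs": ts.fs,
        "channel_names": list(ts.channel_names),
        "class_names": list(ts.class_names),
        "subject_id": ts.subject_id,
        "session_tag": ts.session_tag,
        "provenance": list(ts.provenance),
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        _write_array(zf, "signals.npy", ts.signals)
        _write_array(zf, "labels.npy", ts.labels)
        info = zipfile.ZipInfo("meta.json", date_time=_ZIP_DATE)
        zf.writestr(info, json.dumps(meta, sort_keys=True, indent=1))


def load_trialset(path) -> TrialSet:
    """Read a container written by :func:`save_trialset`."""
    with zipfile.ZipFile(path, "r") as zf:
        names = set(zf.namelist())
        for required in ("signals.npy", "labels.npy", "meta.json"):
            if required not in names:
                raise ValueError(
                    f"corrupt trial container {path!r}: missing field {required!r}"
                )
        meta = json.loads(zf.read("meta.json"))
        signals = np.load(io.BytesIO(zf.read("signals.npy")), allow_pickle=False)
        labels = np.load(io.BytesIO(zf.read("labels.npy")), allow_pickle=False)
    return TrialSet(
        signals=signals,
        labels=labels,
        fs=meta["fs"],
        channel_names=list(meta["channel_names"]),
        class_names=list(meta["class_names"]),
        subject_id=meta.get("subject_id", ""),
        session_tag=meta.get("session_tag", ""),
        provenance=list(meta.get("provenance", [])),
    )
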