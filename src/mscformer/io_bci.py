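"""Readers for BCI Competition IV-2a/2b recordings.

Sessions are GDF files whose annotation stream carries the trial structure:
``768`` marks trial start, ``769``–``772`` the four motor-imagery cues
(left hand, right hand, feet, tongue), ``783`` an unknown cue (evaluation
sessions), and ``1023`` a rejected-trial marker.  True labels for evaluation
sessions ship separately (MATLAB ``classlabel`` vectors or plain text).

The loaders accept any raw file MNE can read, so the identical code path is
exercisable with programmatically written FIF fixtures.  No band-pass
filtering or artifact removal is applied anywhere; signals are epoched
exactly as stored.
"""

from __future__ import annotations

import numpy as np

from .containers import EpochSpec, TrialSet

__all__ = [
    "load_bci_iv_2a",
    "load_bci_iv_2b",
    "read_labels",
    "epoch_trials",
    "CLASSES_2A",
    "CLASSES_2B",
    "EPOCH_2A",
    "EPOCH_2B",
]

CLASSES_2A = ["left_hand", "right_hand", "feet", "tongue"]
CLASSES_2B = ["left_hand", "right_hand"]

#: benchmark epoch windows: 2-6 s (2a) and 3-7 s (2b) from trial start
EPOCH_2A = EpochSpec(t_start=2.0, t_end=6.0)
EPOCH_2B = EpochSpec(t_start=3.0, t_end=7.0)

_TRIAL_START = "768"
_CUE_CODES = {"769": 0, "770": 1, "771": 2, "772": 3, "783": -1}
_ARTIFACT = "1023"

# cue onset relative to trial start, used when no trial-start events exist
_CUE_DELAY = {4: 2.0, 2: 3.0}


def read_labels(path) -> np.ndarray:
    """Read a true-label vector: MATLAB ``classlabel`` file or plain text.

    Competition label files store classes 1..M; returned labels are 0-based.
    """
    path = str(path)
    if path.endswith(".mat"):
        from scipy.io import loadmat

        mat = loadmat(path)
        key = "classlabel" if "classlabel" in mat else None
        if key is None:
            candidates = [k for k in mat if not k.startswith("__")]
            if len(candidates) != 1:
                raise ValueError(
                    f"cannot identify the label vector in {path!r}; "
                    f"variables found: {candidates}"
                )
            key = candidates[0]
        labels = np.asarray(mat[key]).ravel()
    else:
        labels = np.loadtxt(path).ravel()
    labels = labels.astype(np.int64)
    if labels.size and labels.min() >= 1:
        labels = labels - 1
    return labels


def _read_raw(path):
    import mne

    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    return raw


def _trial_onsets(raw, n_classes: int):
    """Trial-start sample indices, cue-derived labels, and artifact flags.

    Prefers ``768`` trial-start events; falls back to cue events shifted by
    the paradigm's cue delay when a file carries only cues.
    """
    fs = raw.info["sfreq"]
    onsets, descs = [], []
    for ann in raw.annotations:
        onsets.append(ann["onset"])
        descs.append(str(ann["description"]).strip())
    onsets = np.asarray(onsets, dtype=float)

    starts = [t for t, d in zip(onsets, descs) if d == _TRIAL_START]
    cues = [(t, _CUE_CODES[d]) for t, d in zip(onsets, descs) if d in _CUE_CODES]
    artifacts = np.asarray([t for t, d in zip(onsets, descs) if d == _ARTIFACT])

    if starts:
        trial_t = np.asarray(starts)
        cue_labels = np.full(len(starts), -1, dtype=np.int64)
        # attach each cue to the latest trial start at or before it
        for t_cue, lab in cues:
            i = int(np.searchsorted(trial_t, t_cue + 1e-9) - 1)
            if i >= 0:
                cue_labels[i] = lab
    elif cues:
        delay = _CUE_DELAY[n_classes]
        trial_t = np.asarray([t - delay for t, _ in cues])
        cue_labels = np.asarray([lab for _, lab in cues], dtype=np.int64)
    else:
        raise ValueError("no trial-start or cue events found in the recording")

    flagged = np.zeros(len(trial_t), dtype=bool)
    if artifacts.size:
        for t_art in artifacts:
            i = int(np.searchsorted(trial_t, t_art + 1e-9) - 1)
            if i >= 0:
                flagged[i] = True
    return np.round(trial_t * fs).astype(int), cue_labels, flagged


def _select_channels(raw, spec: EpochSpec) -> list[str]:
    available = list(raw.ch_names)
    if spec.channels_keep is None:
        keep = [ch for ch in available if "EOG" not in ch.upper()]
    else:
        missing = [ch for ch in spec.channels_keep if ch not in available]
        if missing:
            raise ValueError(
                f"unknown channel name(s) {missing}; available: {available}"
            )
        keep = list(spec.channels_keep)
    return keep


def epoch_trials(
    raw,
    spec: EpochSpec,
    n_classes: int,
    labels: np.ndarray | None = None,
    exclude_artifacts: bool = False,
):
    """Cut one recording into fixed-length trials.

    Sample window per trial: ``[start + round(t_start*fs), ... + n)`` with
    ``n = (t_end - t_start) * fs``, half-open, 0-based.  Returns
    ``(signals, labels, channel_names, fs)``.
    """
    fs = raw.info["sfreq"]
    keep = _select_channels(raw, spec)
    data = raw.get_data(picks=keep)  # (C, total_samples) in volts for EEG
    onsets, cue_labels, flagged = _trial_onsets(raw, n_classes)

    if labels is not None:
        labels = np.asarray(labels, dtype=np.int64)
        if labels.size != onsets.size:
            raise ValueError(
                f"label count mismatch: recording has {onsets.size} trials "
                f"but the label file supplies {labels.size} labels"
            )
    else:
        if np.any(cue_labels < 0):
            raise ValueError(
                "recording contains unlabeled cues (evaluation session); "
                "pass the competition true-label file"
            )
        labels = cue_labels

    offset, end = spec.sample_window(fs)
    n_samp = end - offset
    sigs, labs = [], []
    for i, start in enumerate(onsets):
        if exclude_artifacts and flagged[i]:
            continue
        lo = start + offset
        hi = lo + n_samp
        if hi > data.shape[1]:
            raise ValueError(
                f"trial {i} window [{lo}, {hi}) exceeds recording length "
                f"{data.shape[1]}"
            )
        sigs.append(data[:, lo:hi])
        labs.append(labels[i])
    return np.asarray(sigs), np.asarray(labs, dtype=np.int64), keep, fs


def load_bci_iv_2a(
    session_path,
    label_path=None,
    spec: EpochSpec = EPOCH_2A,
    subject_id: str = "",
    session_tag: str = "",
    exclude_artifacts: bool = False,
) -> TrialSet:
    """Load one 4-class session into a TrialSet of (22, 1000) trials.

    ``label_path`` supplies true classes (required for evaluation sessions
    whose cues are unknown); training sessions may rely on cue codes.
    Artifact-flagged trials are kept unless ``exclude_artifacts``.
    """
    raw = _read_raw(session_path)
    labels = read_labels(label_path) if label_path is not None else None
    signals, labs, chans, fs = epoch_trials(
        raw, spec, n_classes=4, labels=labels, exclude_artifacts=exclude_artifacts
    )
    return TrialSet(
        signals=signals,
        labels=labs,
        fs=fs,
        channel_names=chans,
        class_names=list(CLASSES_2A),
        subject_id=subject_id,
        session_tag=session_tag or str(session_path),
        provenance=["recorded"] * len(labs),
    )


def load_bci_iv_2b(
    session_paths,
    label_paths=None,
    spec: EpochSpec = EPOCH_2B,
    subject_id: str = "",
    session_tag: str = "",
    exclude_artifacts: bool = False,
) -> TrialSet:
    """Load and concatenate 2-class bipolar sessions into (3, 1000) trials.

    Sessions are concatenated in the order given (the benchmark protocol uses
    sessions 1-3 for training and 4-5 for test).
    """
    session_paths = list(session_paths)
    if not session_paths:
        raise ValueError("empty session list")
    if label_paths is None:
        label_paths = [None] * len(session_paths)
    label_paths = list(label_paths)
    if len(label_paths) != len(session_paths):
        raise ValueError(
            f"{len(session_paths)} sessions but {len(label_paths)} label files"
        )

    all_sigs, all_labs, ref_chans, ref_fs = [], [], None, None
    for path, lab_path in zip(session_paths, label_paths):
        raw = _read_raw(path)
        labels = read_labels(lab_path) if lab_path is not None else None
        signals, labs, chans, fs = epoch_trials(
            raw, spec, n_classes=2, labels=labels, exclude_artifacts=exclude_artifacts
        )
        if ref_fs is None:
            ref_chans, ref_fs = chans, fs
        elif fs != ref_fs:
            raise ValueError(
                f"session {path!r} has fs={fs}, expected {ref_fs}"
            )
        elif chans != ref_chans:
            raise ValueError(
                f"session {path!r} channel names {chans} differ from {ref_chans}"
            )
        all_sigs.append(signals)
        all_labs.append(labs)

    signals = np.concatenate(all_sigs)
    labels = np.concatenate(all_labs)
    return TrialSet(
        signals=signals,
        labels=labels,
        fs=ref_fs,
        channel_names=ref_chans,
        class_names=list(CLASSES_2B),
        subject_id=subject_id,
        session_tag=session_tag or "+".join(str(p) for p in session_paths),
        provenance=["recorded"] * len(labels),
    )
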