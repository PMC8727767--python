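"""Readers and writers for EEG matrices, GCS series and ground-truth sidecars.

The native interchange format is plain text: a tab-separated channels x
samples numeric matrix (one row per channel) with a JSON sidecar carrying
sampling rate, channel labels, start time and the bad-segment mask (as
run-length start/stop sample pairs).  EDF recordings are read through
:mod:`mne` when it is installed.
"""

from __future__ import annotations

import json
from os import PathLike
from pathlib import Path
from typing import Union

import numpy as np

from sibskit.preprocess import EEGRecord, GCSSeries

__all__ = [
    "write_eeg_text",
    "read_eeg_text",
    "read_eeg_edf",
    "read_gcs_series",
    "write_gcs_series",
    "write_ground_truth",
]


def _mask_to_runs(mask: np.ndarray) -> list:
    edges = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
    return [[int(a), int(b)] for a, b in zip(edges[::2], edges[1::2])]


def _runs_to_mask(runs: list, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for a, b in runs:
        mask[a:b] = True
    return mask


def write_eeg_text(rec: EEGRecord, path: Union[str, PathLike]) -> None:
    """Write an EEG record as TSV matrix plus ``<path>.json`` sidecar."""
    path = Path(path)
    np.savetxt(path, rec.signal, delimiter="\t", fmt="%.6g")
    meta = {
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
        "start_time_h": rec.start_time,
        "n_samples": rec.n_samples,
        "bad_runs": _mask_to_runs(rec.bad_mask),
        "units": "uV",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_eeg_text(path: Union[str, PathLike]) -> EEGRecord:
    """Read an EEG record written by :func:`write_eeg_text`."""
    path = Path(path)
    sig = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return EEGRecord(
        signal=sig, fs=float(meta["fs"]),
        channel_labels=meta["channel_labels"],
        start_time=float(meta.get("start_time_h", 0.0)),
        bad_mask=_runs_to_mask(meta.get("bad_runs", []), sig.shape[1]),
    )


def read_eeg_edf(path: Union[str, PathLike], start_time_h: float = 0.0) -> EEGRecord:
    """Read an EDF recording (requires ``mne``); amplitudes converted to uV."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the optional dependency 'mne'") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecord(signal=raw.get_data() * 1e6, fs=float(raw.info["sfreq"]),
                     channel_labels=list(raw.ch_names), start_time=start_time_h)


def read_gcs_series(path: Union[str, PathLike]) -> GCSSeries:
    """Read a two-column delimited file of (hours since admission, GCS score)."""
    arr = np.atleast_2d(np.loadtxt(path, delimiter=None))
    if arr.shape[1] != 2:
        raise ValueError("GCS file must have exactly two columns: hours, score")
    return GCSSeries(timestamps=arr[:, 0], scores=arr[:, 1].astype(int))


def write_gcs_series(gcs: GCSSeries, path: Union[str, PathLike]) -> None:
    np.savetxt(path, np.column_stack([gcs.timestamps, gcs.scores]),
               fmt=["%.6f", "%d"], delimiter="\t")


def write_ground_truth(truth, path: Union[str, PathLike]) -> None:
    """JSON sidecar for a :class:`~sibskit.simulate.BSGroundTruth`."""
    payload = {
        "suppression_fraction": truth.suppression_fraction,
        "seed": truth.seed,
        "suppression_runs": _mask_to_runs(np.asarray(truth.state_path, dtype=bool)),
        "n_samples": int(np.asarray(truth.state_path).size),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
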