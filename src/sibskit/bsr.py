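"""Burst suppression ratio (BSR) and its diagnostics.

The BSR of an EEG section is the proportion of (unmasked) samples whose
rectified amplitude lies below a voltage threshold, default 1 uV, after
collapsing channels to a single consensus series by the per-sample modal
(majority) binary value.  The strict inequality ``|x| < threshold`` is used;
samples exactly at the threshold count as non-suppressed.  BSR is a
continuous quantity in [0, 1]; no categorical burst-suppression label is
ever produced.

Diagnostics:

* ``log_kurtosis`` -- base-10 log of the Pearson (non-excess) kurtosis of
  the pooled per-sample voltages.  Burst suppression is a sparse,
  heavy-tailed signal, so log10-kurtosis scales near-linearly with BSR
  (except at fully isoelectric sections, where the absence of bursts
  collapses the signal back to near-Gaussian noise and low kurtosis).
* ``channel_icc`` -- one-way random-effects single-measure intraclass
  correlation ICC(1,1) of the binary suppression indicators, treating
  samples as targets and channels as raters; quantifies cross-channel
  agreement about suppression.
* ``threshold_sensitivity`` -- recomputes BSR under several thresholds
  (default 1, 5, 10 uV) and reports, per threshold, the Pearson correlation
  of BSR with log10-kurtosis and the concurrent GCS of high-BSR sections;
  supports choosing a threshold that (1) yields high BSR only during
  deepest unresponsiveness and (2) tracks kurtosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from sibskit.preprocess import EEGSection

__all__ = [
    "BSRResult",
    "SensitivityReport",
    "binarize_suppression",
    "channel_consensus",
    "channel_icc",
    "compute_bsr",
    "log_kurtosis",
    "max_bsr_per_patient",
    "threshold_sensitivity",
]


@dataclass
class BSRResult:
    """Per-section suppression statistics."""

    bsr: float
    threshold_uv: float
    per_channel_fraction: np.ndarray
    consensus_series: np.ndarray
    log10_kurtosis: Optional[float]
    icc: Optional[float]
    n_samples_used: int
    icc_variant: str = "ICC(1,1) one-way random, single measure"
    patient_id: Optional[int] = None
    gcs_at_extraction: Optional[int] = None


@dataclass
class SensitivityReport:
    """Per-threshold BSR diagnostics across a set of sections."""

    thresholds: Tuple[float, ...]
    bsr_values: Dict[float, np.ndarray]          # threshold -> BSR per section
    kurtosis_values: np.ndarray                  # per section (threshold-free)
    correlation: Dict[float, float]              # threshold -> Pearson r
    high_bsr_sections: Dict[float, List[dict]]   # threshold -> [{index, bsr, gcs}]
    high_cutoff: float = 0.5


def binarize_suppression(section: EEGSection, threshold_uv: float = 1.0) -> np.ndarray:
    """Channels x samples indicator of rectified amplitude strictly below threshold."""
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    return (np.abs(section.signal) < threshold_uv).astype(np.int8)


def channel_consensus(binary: np.ndarray) -> np.ndarray:
    """Per-sample modal (majority) value across channels.

    With an odd channel count (the 13-channel montage) no ties arise; for
    even counts a tie resolves to 1 (suppression).
    """
    binary = np.asarray(binary)
    if binary.ndim != 2 or binary.shape[0] < 1:
        raise ValueError("need a channels x samples matrix with >= 1 channel")
    nch = binary.shape[0]
    return (2 * binary.sum(axis=0) >= nch).astype(np.int8)


def log_kurtosis(section: EEGSection) -> Optional[float]:
    """log10 of the Pearson (non-excess) kurtosis of pooled unmasked voltages.

    The Gaussian reference value is log10(3) ~ 0.477; a flat (zero-variance)
    signal has undefined kurtosis and returns ``None`` rather than raising.
    """
    keep = ~section.bad_mask
    x = section.signal[:, keep].ravel()
    if x.size <= 3 or np.var(x) == 0.0:
        return None
    k = stats.kurtosis(x, fisher=False, bias=True)
    if not np.isfinite(k) or k <= 0:
        return None
    return float(np.log10(k))


def channel_icc(binary: np.ndarray) -> Optional[float]:
    """One-way random-effects single-measure ICC of a channels x samples matrix.

    Samples are targets, channels are raters:
    ``ICC(1,1) = (MSB - MSW) / (MSB + (k-1) MSW)`` with k channels.  Returns
    ``None`` when between-sample variance is zero (undefined agreement).
    """
    binary = np.asarray(binary, dtype=float)
    if binary.ndim != 2 or binary.shape[0] < 2 or binary.shape[1] < 2:
        raise ValueError("need >= 2 channels and >= 2 samples")
    k, n = binary.shape
    target_means = binary.mean(axis=0)
    grand = binary.mean()
    ssb = k * np.sum((target_means - grand) ** 2)
    ssw = np.sum((binary - target_means) ** 2)
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    if msb == 0.0:
        return None
    return float((msb - msw) / (msb + (k - 1) * msw))


def compute_bsr(section: EEGSection, threshold_uv: float = 1.0) -> BSRResult:
    """Burst suppression ratio of one EEG section.

    BSR is the mean of the cross-channel consensus suppression indicator
    over unmasked samples; per-channel suppression fractions, pooled
    log10-kurtosis and the cross-channel ICC are filled alongside.

    Raises
    ------
    ValueError
        If no usable samples remain after masking.
    """
    binary = binarize_suppression(section, threshold_uv)
    keep = ~section.bad_mask
    if not keep.any():
        raise ValueError("section has zero usable samples after masking")
    binary = binary[:, keep]
    consensus = channel_consensus(binary)
    icc = channel_icc(binary) if binary.shape[0] >= 2 and binary.shape[1] >= 2 else None
    return BSRResult(
        bsr=float(consensus.mean()),
        threshold_uv=float(threshold_uv),
        per_channel_fraction=binary.mean(axis=1),
        consensus_series=consensus,
        log10_kurtosis=log_kurtosis(section),
        icc=icc,
        n_samples_used=int(keep.sum()),
        patient_id=section.patient_id,
        gcs_at_extraction=section.gcs_at_extraction,
    )


def threshold_sensitivity(sections: Sequence[EEGSection],
                          thresholds: Sequence[float] = (1.0, 5.0, 10.0),
                          high_cutoff: float = 0.5) -> SensitivityReport:
    """Threshold calibration diagnostics over a set of sections.

    For each candidate threshold, computes BSR for every section, the
    Pearson correlation of BSR with log10-kurtosis (threshold-free, computed
    once per section), and the list of sections whose BSR exceeds
    ``high_cutoff`` together with their concurrent GCS.
    """
    if len(sections) < 2:
        raise ValueError("sensitivity analysis needs >= 2 sections")
    kurt = np.array([np.nan if (v := log_kurtosis(s)) is None else v
                     for s in sections])
    bsr_values: Dict[float, np.ndarray] = {}
    correlation: Dict[float, float] = {}
    high: Dict[float, List[dict]] = {}
    for thr in thresholds:
        vals = np.array([compute_bsr(s, thr).bsr for s in sections])
        bsr_values[float(thr)] = vals
        ok = np.isfinite(kurt)
        if ok.sum() >= 3 and np.std(vals[ok]) > 0 and np.std(kurt[ok]) > 0:
            correlation[float(thr)] = float(stats.pearsonr(vals[ok], kurt[ok])[0])
        else:
            correlation[float(thr)] = float("nan")
        high[float(thr)] = [
            {"index": i, "bsr": float(v), "gcs": sections[i].gcs_at_extraction}
            for i, v in enumerate(vals) if v > high_cutoff
        ]
    return SensitivityReport(thresholds=tuple(float(t) for t in thresholds),
                             bsr_values=bsr_values, kurtosis_values=kurt,
                             correlation=correlation, high_bsr_sections=high,
                             high_cutoff=high_cutoff)


def max_bsr_per_patient(results: Sequence[BSRResult]) -> pd.Series:
    """Maximum BSR over usable sections, per patient.

    ``results`` are per-section :class:`BSRResult` objects carrying
    ``patient_id``.  Patients contribute only sections that were computed
    (zero-usable-section patients never reach this point and are excluded
    upstream with a warning).
    """
    rows = [(r.patient_id, r.bsr) for r in results if r.patient_id is not None]
    if not rows:
        raise ValueError("no per-patient BSR results supplied")
    df = pd.DataFrame(rows, columns=["patient_id", "bsr"])
    return df.groupby("patient_id")["bsr"].max()
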