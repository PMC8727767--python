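"""Synthetic burst-suppression EEG, GCS trajectories and outcome-linked cohorts.

The generator emulates the statistical structure the downstream analysis
assumes, not physiological EEG:

* **Burst suppression** is a two-state alternating-renewal process.  A common
  per-sample state path (1 = suppression) is drawn with log-normal dwell
  times; the mean suppression and burst dwells are set so the long-run
  suppression fraction equals the requested target.  Suppression samples are
  zero-mean Gaussian noise whose std (default 0.2 uV) keeps the rectified
  amplitude below 1 uV essentially always; burst samples are band-limited
  noise (std default 20 uV) with a small rectified-amplitude floor (default
  15% of the burst std) so that burst samples essentially never fall below
  the 1 uV threshold on any single channel.  Each of the 13 channels copies
  the common state except at rare independently jittered samples.
* **GCS trajectories** are several-times-daily integer scores in 3-15 whose
  minima coincide with declared sedation windows (scores 3-6 inside, 7-15
  outside).
* **Cohorts** draw per-patient maximum GCS and target maximum BSR, then a
  binary outcome from ``logistic(intercept + b_bsr*maxBSR + b_gcs*maxGCS)``,
  recording all ground truth for recovery tests.

All randomness flows from a single seed through :func:`numpy.random.default_rng`
child streams, so outputs are byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from sibskit.cohort import AGE_BIN_MIDPOINTS, COLUMNS, CohortTable
from sibskit.preprocess import EEGRecord, EEGSection, GCSSeries, select_section_times

__all__ = [
    "DEFAULT_CHANNELS",
    "SimParams",
    "BSGroundTruth",
    "SyntheticCohort",
    "simulate_bs_eeg",
    "simulate_gcs_series",
    "simulate_cohort",
    "simulate_mediation_cohort",
]

#: The 13-channel montage common to all patients (10-20 names).
DEFAULT_CHANNELS = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4",
    "P3", "P4", "O1", "O2", "T3", "T4", "Cz",
)


@dataclass(frozen=True)
class SimParams:
    """Generator configuration; defaults are the study conditions.

    Dwell times are log-normal with the given mean (seconds) and log-space
    dispersion sigma.  ``beta_*`` are the log-odds coefficients of the
    outcome model; the defaults mirror the magnitude of the chronic-outcome
    estimates so synthetic cohorts exercise the same effect-size regime.
    """

    n_patients: int = 32
    fs: float = 256.0
    section_duration_s: float = 600.0
    n_channels: int = 13
    channel_labels: Sequence[str] = DEFAULT_CHANNELS
    burst_dwell_s: float = 4.0
    dwell_sigma: float = 0.5
    suppression_noise_uv: float = 0.2
    burst_noise_uv: float = 20.0
    burst_floor_frac: float = 0.15
    channel_jitter: float = 0.001
    burst_band_hz: tuple = (0.5, 30.0)
    intercept: float = -13.0
    beta_bsr: float = 8.0
    beta_gcs: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.burst_dwell_s <= 0 or self.dwell_sigma < 0:
            raise ValueError("dwell parameters must be positive")
        if not 0.0 <= self.channel_jitter <= 1.0:
            raise ValueError("channel_jitter must be a probability")
        if self.fs <= 0 or self.section_duration_s <= 0 or self.n_patients < 1:
            raise ValueError("fs, section_duration_s and n_patients must be positive")


@dataclass
class BSGroundTruth:
    """Oracle for BSR recovery tests: the common state path and its mean."""

    state_path: np.ndarray          # per-sample, 1 = suppression
    suppression_fraction: float
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not np.isclose(self.suppression_fraction, float(np.mean(self.state_path))):
            raise ValueError("suppression_fraction must equal mean(state_path)")


@dataclass
class SyntheticCohort:
    """A simulated cohort plus the ground truth it was generated from."""

    cohort: CohortTable
    truth: pd.DataFrame             # per-patient generating values
    sections: Optional[dict] = None  # patient_id -> list[(EEGSection, BSGroundTruth)]
    gcs: Optional[dict] = None       # patient_id -> GCSSeries
    seed: Optional[int] = None


def _simulate_state_path(n_samples: int, fs: float, target: float,
                         params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Alternating-renewal binary path with long-run suppression fraction ``target``."""
    if target <= 0.0:
        return np.zeros(n_samples, dtype=np.int8)
    if target >= 1.0:
        return np.ones(n_samples, dtype=np.int8)
    mean_burst = params.burst_dwell_s
    mean_supp = mean_burst * target / (1.0 - target)
    sig = params.dwell_sigma
    # log-normal with the requested arithmetic mean
    mu_b = np.log(mean_burst) - sig ** 2 / 2.0
    mu_s = np.log(mean_supp) - sig ** 2 / 2.0
    state = int(rng.random() < target)
    path = np.empty(n_samples, dtype=np.int8)
    i = 0
    while i < n_samples:
        mu = mu_s if state else mu_b
        dwell = int(round(rng.lognormal(mu, sig) * fs))
        dwell = max(dwell, 1)
        path[i:i + dwell] = state
        i += dwell
        state = 1 - state
    return path


def _band_limited_noise(n: int, fs: float, band: tuple, std: float,
                        rng: np.random.Generator) -> np.ndarray:
    low, high = band
    high = min(high, 0.45 * fs)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    s = x.std()
    return x * (std / s) if s > 0 else x


def simulate_bs_eeg(params: SimParams, target_suppression: float,
                    seed: Optional[int] = None):
    """Simulate one multichannel burst-suppression EEG section.

    Parameters
    ----------
    params
        Generator configuration.
    target_suppression
        Long-run proportion of time in suppression, in [0, 1].
    seed
        Overrides ``params.seed`` when given.

    Returns
    -------
    (EEGRecord, BSGroundTruth)
        The signal (channels x samples, uV) and the common state path whose
        mean is the realized suppression fraction.
    """
    params.validate()
    if not 0.0 <= target_suppression <= 1.0:
        raise ValueError(f"target_suppression must be in [0, 1], got {target_suppression}")
    use_seed = params.seed if seed is None else seed
    rng = np.random.default_rng(use_seed)
    n = int(round(params.section_duration_s * params.fs))
    nch = params.n_channels
    path = _simulate_state_path(n, params.fs, target_suppression, params, rng)

    floor = params.burst_floor_frac * params.burst_noise_uv
    # jitter models cross-channel asynchrony around state transitions; a
    # constant path (fully isoelectric or burst-only) has none to jitter
    jitter = params.channel_jitter if path.min() != path.max() else 0.0
    sig = np.empty((nch, n))
    for c in range(nch):
        # per-channel state: common path with rare independent flips
        flips = rng.random(n) < jitter
        ch_state = np.where(flips, 1 - path, path).astype(bool)
        supp = rng.normal(0.0, params.suppression_noise_uv, size=n)
        burst = _band_limited_noise(n, params.fs, params.burst_band_hz,
                                    params.burst_noise_uv, rng)
        burst = burst + floor * np.sign(burst)   # rectified-amplitude floor
        sig[c] = np.where(ch_state, supp, burst)

    labels = list(params.channel_labels)[:nch]
    if len(labels) < nch:
        labels += [f"ch{i}" for i in range(len(labels), nch)]
    rec = EEGRecord(signal=sig, fs=params.fs, channel_labels=labels,
                    start_time=0.0, bad_mask=np.zeros(n, dtype=bool))
    truth = BSGroundTruth(state_path=path,
                          suppression_fraction=float(path.mean()),
                          seed=use_seed)
    return rec, truth


def simulate_gcs_series(duration_h: float,
                        sedation_windows: Sequence[tuple] = (),
                        seed: Optional[int] = None,
                        assessments_per_day: int = 4) -> GCSSeries:
    """Simulate a several-times-daily GCS trajectory.

    Scores inside any sedation window are drawn from {3..6}; outside, from
    {7..15}.  Assessment times are evenly spread with jitter, at
    ``assessments_per_day`` per day (>= 2 enforced).
    """
    if assessments_per_day < 2:
        raise ValueError("need at least 2 assessments per simulated day")
    windows = sorted(tuple(map(float, w)) for w in sedation_windows)
    for lo, hi in windows:
        if not (0.0 <= lo < hi <= duration_h):
            raise ValueError(f"sedation window ({lo}, {hi}) outside record of {duration_h} h")
    for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
        if b0 < a1:
            raise ValueError("sedation windows overlap")
    rng = np.random.default_rng(seed)
    step = 24.0 / assessments_per_day
    base = np.arange(step / 2.0, duration_h, step)
    times = np.clip(base + rng.uniform(-0.3 * step, 0.3 * step, size=base.size),
                    0.0, duration_h)
    times = np.sort(times)
    times += np.arange(times.size) * 1e-9   # guarantee strict increase
    sedated = np.zeros(times.size, dtype=bool)
    for lo, hi in windows:
        sedated |= (times >= lo) & (times <= hi)
    scores = np.where(sedated,
                      rng.integers(3, 7, size=times.size),
                      rng.integers(7, 16, size=times.size))
    return GCSSeries(timestamps=times, scores=scores.astype(int))


def _draw_target_bsr(rng: np.random.Generator) -> float:
    # mixture mirroring the cohort: ~25% deep burst suppression, rest near 0
    if rng.random() < 0.25:
        return float(rng.beta(5.0, 1.5))
    return float(rng.beta(0.4, 4.0))


_AGE_BINS = list(AGE_BIN_MIDPOINTS)


def simulate_cohort(params: SimParams, eeg: bool = False,
                    duration_h: float = 96.0) -> SyntheticCohort:
    """Simulate an outcome-linked cohort.

    For each patient: draw a maximum GCS (uniform 3-15) and a target maximum
    BSR, then binary discharge and chronic outcomes with success probability
    ``logistic(intercept + beta_bsr*maxBSR + beta_gcs*maxGCS)``.  GOSe scores
    are placed on the corresponding side of the median-split cutoffs so that
    downstream dichotomization recovers the generated outcome exactly.

    With ``eeg=True`` each patient also gets a GCS trajectory with a sedation
    window, and one EEG section per selected extraction time; the section at
    the GCS minimum carries the patient's target maximum BSR and the others
    lower suppression.  Ground truth is recorded per patient and per section.
    """
    params.validate()
    root = np.random.default_rng(params.seed)
    seeds = root.integers(0, 2 ** 31 - 1, size=params.n_patients * 4)
    rows, truth_rows = [], []
    sections = {} if eeg else None
    gcs_map = {} if eeg else None
    for i in range(params.n_patients):
        rng = np.random.default_rng(seeds[4 * i])
        pid = i + 1
        max_gcs = int(rng.integers(3, 16))
        tbsr = _draw_target_bsr(rng)
        lp = params.intercept + params.beta_bsr * tbsr + params.beta_gcs * max_gcs
        p = 1.0 / (1.0 + np.exp(-lp))
        y_d = int(rng.random() < p)
        y_c = int(rng.random() < p)
        gose_d = int(rng.integers(3, 5)) if y_d else int(rng.integers(1, 3))
        gose_c = int(rng.integers(5, 9)) if y_c else int(rng.integers(1, 5))
        barb = bool(rng.random() < (0.9 if tbsr > 0.15 else 0.1)) or tbsr > 0.45
        total = int(rng.integers(2, 9))
        usable = int(rng.integers(1, total + 1))
        rows.append({
            "patient_id": pid,
            "age_bin": _AGE_BINS[rng.integers(0, len(_AGE_BINS))],
            "sex": "M" if rng.random() < 0.84 else "F",
            "max_bsr": round(tbsr, 4),
            "max_gcs": max_gcs,
            "gose_discharge": gose_d,
            "days_discharge": int(np.clip(round(rng.normal(22, 10)), 2, 60)),
            "gose_chronic": gose_c,
            "days_chronic": int(np.clip(round(rng.normal(193, 34)), 150, 330)),
            "barbiturates": barb,
            "propofol": bool(rng.random() < 0.5),
            "usable_sections": usable,
            "total_sections": total,
        })
        truth_rows.append({
            "patient_id": pid, "target_max_bsr": tbsr, "max_gcs": max_gcs,
            "p_outcome": p, "y_discharge": y_d, "y_chronic": y_c,
        })
        if eeg:
            mid = duration_h / 2.0
            window = (mid - 12.0, mid + 12.0)
            series = simulate_gcs_series(duration_h, [window], seed=int(seeds[4 * i + 1]))
            gcs_map[pid] = series
            times = select_section_times(series)
            scores = [series.score_at(t) for t in times]
            j_min = int(np.argmin(scores))   # deepest sedation carries max BSR
            per_patient = []
            for j, (t0, score) in enumerate(zip(times, scores)):
                target = tbsr if j == j_min else tbsr * float(rng.uniform(0.0, 0.5))
                rec, gt = simulate_bs_eeg(params, target, seed=int(seeds[4 * i + 2]) + j)
                sec = EEGSection(signal=rec.signal, fs=rec.fs, t0=t0,
                                 duration_s=params.section_duration_s,
                                 gcs_at_extraction=score, bad_mask=rec.bad_mask,
                                 patient_id=pid)
                per_patient.append((sec, gt))
            sections[pid] = per_patient
    df = pd.DataFrame(rows)[COLUMNS]
    df["age_mid"] = df["age_bin"].map(AGE_BIN_MIDPOINTS)
    cohort = CohortTable(df=df, provenance="synthetic")
    return SyntheticCohort(cohort=cohort, truth=pd.DataFrame(truth_rows),
                           sections=sections, gcs=gcs_map, seed=params.seed)


def simulate_mediation_cohort(n: int,
                              alpha_treat: float,
                              beta_treat: float = 0.0,
                              beta_mediator: float = 4.0,
                              beta_gcs: float = 0.3,
                              intercept: float = -3.5,
                              mediator_sd: float = 0.15,
                              p_treat: float = 0.4,
                              seed: Optional[int] = None) -> pd.DataFrame:
    """Simulate a flat table for mediation calibration studies.

    Treatment (sedative flag) is Bernoulli(``p_treat``); the continuous
    mediator (max BSR scale) follows a linear model
    ``m = 0.1 + alpha_treat*t + 0.01*gcs + N(0, mediator_sd)`` and the binary
    outcome a logistic model on treatment, mediator and the max-GCS
    covariate.  ``alpha_treat = 0`` yields a no-mediation world;
    ``beta_treat = 0`` with large ``alpha_treat``/``beta_mediator`` yields
    pure mediation.
    """
    rng = np.random.default_rng(seed)
    t = (rng.random(n) < p_treat).astype(float)
    gcs = rng.integers(3, 16, size=n).astype(float)
    m = 0.1 + alpha_treat * t + 0.01 * gcs + rng.normal(0.0, mediator_sd, size=n)
    lp = intercept + beta_treat * t + beta_mediator * m + beta_gcs * gcs
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-lp))).astype(int)
    return pd.DataFrame({"treatment": t.astype(int), "max_bsr": m,
                         "max_gcs": gcs, "outcome": y})
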