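"""The 20 psychophysiological features, per (subject x condition).

Feature families
----------------
HRV (from the NN-interval series of each block):
    mean_RR, std_RR [ms]; mean_HR, std_HR [bpm]; RMSSD [ms], the root mean
    square of successive NN differences,
    ``sqrt( 1/(n-1) * sum_j (NN_{j+1} - NN_j)^2 )``.

fEMG (from the RMS envelope of each site):
    mean_amp_Corr, mean_amp_Zyg — block-mean envelope minus the mean of the
    2 s pre-block baseline, then z-scored within subject and site across all
    blocks of the session.

SCL (from each filtered skin-conductance block segment X, N samples):
    SCL_mean, SCL_std; mean absolute first/second differences of the raw
    segment (SCL_fd_raw, SCL_sd_raw) and of the within-segment z-scored
    segment (SCL_fd_norm, SCL_sd_norm); counts of maxima/minima whose
    amplitude exceeds 0.05 uS (SCL_n_max, SCL_n_min, and their sum
    SCL_n_extrema); mean amplitudes of the retained maxima/minima
    (SCL_mean_amp_max, SCL_mean_amp_min; minima amplitudes are reported as
    positive drop magnitudes); trapezoidal SCL_integral [uS*s]; and the
    least-squares SCL_slope [uS/s].

The two blocks of each condition are pooled by arithmetic mean into one row
per (subject, condition).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    AlignmentError,
    CompletenessError,
    InsufficientDataError,
)
from .preprocessing import (
    NNSeries,
    Segment,
    bandpass_emg,
    detect_beats,
    lowpass_scl,
    remove_powerline,
    rms_envelope,
    segment_by_timeline,
)
from .synth import EventTimeline, RawRecording

HRV_FEATURES = ("mean_RR", "std_RR", "mean_HR", "std_HR", "RMSSD")
EMG_FEATURES = ("mean_amp_Corr", "mean_amp_Zyg")
SCL_FEATURES = (
    "SCL_mean",
    "SCL_std",
    "SCL_fd_raw",
    "SCL_fd_norm",
    "SCL_sd_raw",
    "SCL_sd_norm",
    "SCL_n_max",
    "SCL_n_min",
    "SCL_n_extrema",
    "SCL_mean_amp_max",
    "SCL_mean_amp_min",
    "SCL_integral",
    "SCL_slope",
)

#: Canonical column order of the feature matrix.
FEATURE_NAMES: tuple[str, ...] = HRV_FEATURES + EMG_FEATURES + SCL_FEATURES

#: Signal family of each feature, for selection-share summaries.
SIGNAL_GROUPS = {name: "HRV" for name in HRV_FEATURES}
SIGNAL_GROUPS.update({name: "fEMG" for name in EMG_FEATURES})
SIGNAL_GROUPS.update({name: "SCL" for name in SCL_FEATURES})


def hrv_features(nn: NNSeries) -> dict:
    """Time-domain HRV statistics of an NN series (needs >= 2 intervals)."""
    if nn.n < 2:
        raise InsufficientDataError(f"HRV features need >= 2 NN intervals, got {nn.n}")
    intervals = np.asarray(nn.intervals, dtype=float)
    hr = 60000.0 / intervals
    diffs = np.diff(intervals)
    rmssd = float(np.sqrt(np.sum(diffs**2) / (nn.n - 1)))
    return {
        "mean_RR": float(np.mean(intervals)),
        "std_RR": float(np.std(intervals, ddof=1)),
        "mean_HR": float(np.mean(hr)),
        "std_HR": float(np.std(hr, ddof=1)),
        "RMSSD": rmssd,
    }


def emg_block_change(segment: Segment) -> float:
    """Block-mean envelope minus pre-block baseline-mean envelope."""
    if len(segment.baseline_samples) == 0:
        raise AlignmentError("EMG segment has an empty baseline window")
    return float(np.mean(segment.samples) - np.mean(segment.baseline_samples))


def zscore_within_subject(values: np.ndarray) -> np.ndarray:
    """Z-score a subject's block values (one site); all-equal input maps to zeros."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise InsufficientDataError("within-subject z-scoring needs >= 2 blocks")
    sd = np.std(x, ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def _extrema_amplitudes(x: np.ndarray) -> tuple[list[float], list[float]]:
    """Amplitudes of local maxima (rises) and minima (drops, positive).

    An extremum is a sign change of the first difference; its amplitude is
    the difference to the preceding opposite extremum, or to the segment's
    first sample for the first extremum.
    """
    d = np.diff(x)
    nz = np.flatnonzero(d != 0)
    max_amps: list[float] = []
    min_amps: list[float] = []
    last_anchor = x[0]
    prev_sign = 0.0
    for i in nz:
        s = np.sign(d[i])
        if prev_sign == 0.0:
            prev_sign = s
            continue
        if s != prev_sign:
            # extremum at sample i (end of the previous monotone run)
            value = x[i]
            if prev_sign > 0:  # rising then falling: a maximum
                max_amps.append(float(value - last_anchor))
            else:
                min_amps.append(float(last_anchor - value))
            last_anchor = value
            prev_sign = s
    return max_amps, min_amps


def scl_features(segment: Segment, amp_threshold: float = 0.05) -> dict:
    """The 13 skin-conductance features of one block segment."""
    x = np.asarray(segment.samples, dtype=float)
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"SCL features need >= 3 samples, got {n}")
    t = np.arange(n) / segment.fs
    mean = float(np.mean(x))
    std = float(np.std(x, ddof=1))
    z = (x - mean) / std if std > 0 else np.zeros_like(x)

    fd_raw = float(np.mean(np.abs(np.diff(x))))
    fd_norm = float(np.mean(np.abs(np.diff(z))))
    sd_raw = float(np.mean(np.abs(x[2:] - x[:-2])))
    sd_norm = float(np.mean(np.abs(z[2:] - z[:-2])))

    max_amps, min_amps = _extrema_amplitudes(x)
    kept_max = [a for a in max_amps if a > amp_threshold]
    kept_min = [a for a in min_amps if a > amp_threshold]

    slope, _, _, _, _ = stats.linregress(t, x)
    return {
        "SCL_mean": mean,
        "SCL_std": std,
        "SCL_fd_raw": fd_raw,
        "SCL_fd_norm": fd_norm,
        "SCL_sd_raw": sd_raw,
        "SCL_sd_norm": sd_norm,
        "SCL_n_max": float(len(kept_max)),
        "SCL_n_min": float(len(kept_min)),
        "SCL_n_extrema": float(len(kept_max) + len(kept_min)),
        "SCL_mean_amp_max": float(np.mean(kept_max)) if kept_max else 0.0,
        "SCL_mean_amp_min": float(np.mean(kept_min)) if kept_min else 0.0,
        "SCL_integral": float(np.trapezoid(x, t)),
        "SCL_slope": float(slope),
    }


def assemble_feature_matrix(block_features: pd.DataFrame) -> pd.DataFrame:
    """Pool per-block feature rows into one row per (subject, condition).

    ``block_features`` must carry ``subject_id``, ``condition`` and every
    canonical feature column; the blocks of a condition are averaged.
    """
    missing = [c for c in FEATURE_NAMES if c not in block_features.columns]
    if missing:
        raise CompletenessError(f"block feature table is missing columns: {missing}")
    if block_features[list(FEATURE_NAMES)].isna().any().any():
        raise CompletenessError("block feature table contains missing values")
    pooled = (
        block_features.groupby(["subject_id", "condition"], sort=False, as_index=False)[
            list(FEATURE_NAMES)
        ].mean()
    )
    pooled.attrs["provenance"] = "raw"
    return pooled


def extract_subject_features(
    recording: RawRecording,
    timeline: EventTimeline,
    *,
    baseline_window: float = 2.0,
    amp_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full per-subject chain: filter, segment, featurise every block.

    Returns one row per stimulation block with ``subject_id``, ``condition``,
    ``block_onset`` and the 20 canonical features.  EMG features are
    z-scored within the subject across all blocks of the session.
    """
    blocks = timeline.blocks
    rows = {name: [] for name in FEATURE_NAMES}

    # --- EMG envelopes -> baseline-corrected block changes -> within-subject z
    for site, column in (("emg_corrugator", "mean_amp_Corr"), ("emg_zygomaticus", "mean_amp_Zyg")):
        samples, fs, _ = recording.channels[site]
        env = rms_envelope(remove_powerline(bandpass_emg(samples, fs), fs), fs)
        segments = segment_by_timeline(env, fs, timeline, baseline_window)
        changes = np.array([emg_block_change(seg) for seg in segments])
        rows[column] = list(zscore_within_subject(changes))

    # --- SCL
    samples, fs, _ = recording.channels["scl"]
    smoothed = lowpass_scl(samples, fs)
    for seg in segment_by_timeline(smoothed, fs, timeline, baseline_window):
        for name, value in scl_features(seg, amp_threshold).items():
            rows[name].append(value)

    # --- HRV
    samples, fs, _ = recording.channels["bvp"]
    nn = detect_beats(samples, fs)
    for onset, offset, _ in blocks:
        block_nn = nn.restrict(onset, offset)
        if block_nn.n < 2:
            raise InsufficientDataError(
                f"block at t={onset} s has {block_nn.n} NN intervals; cannot compute HRV"
            )
        for name, value in hrv_features(block_nn).items():
            rows[name].append(value)

    out = pd.DataFrame(
        {
            "subject_id": recording.subject_id,
            "condition": [b[2] for b in blocks],
            "block_onset": [b[0] for b in blocks],
        }
    )
    for name in FEATURE_NAMES:
        out[name] = rows[name]
    return out


def build_feature_matrix(
    recordings: list[RawRecording],
    timeline: EventTimeline,
    **kwargs,
) -> pd.DataFrame:
    """Extract and pool features for a whole cohort sharing one timeline."""
    per_block = pd.concat(
        [extract_subject_features(rec, timeline, **kwargs) for rec in recordings],
        ignore_index=True,
    )
    return assemble_feature_matrix(per_block)


def feature_matrix_order(matrix: pd.DataFrame) -> pd.DataFrame:
    """Reindex a feature matrix to the canonical column order."""
    cols = ["subject_id", "condition"] + [c for c in FEATURE_NAMES if c in matrix.columns]
    return matrix[cols]
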