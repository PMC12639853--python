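"""Facial-EMG preprocessing: band-pass filtering, event-related epoching,
artifact rejection, envelope extraction, per-trial z-normalization, and
windowed mean amplitudes.

The chain mirrors standard surface-EMG practice for Zygomaticus major
(ZM) and Corrugator supercilii (CS) recordings sampled at 1024 Hz:

1. zero-phase 4th-order Butterworth band-pass, 50-250 Hz;
2. epoching from -800 ms (baseline) to +4000 ms around sentence onset;
3. automated artifact rejection: an epoch is rejected when its peak
   absolute amplitude exceeds a robust (median + k * 1.4826 * MAD)
   threshold over all epochs' peaks, per muscle;
4. full-wave rectification followed by a centered 300 ms moving average
   (shrinking window at the epoch edges);
5. z-normalization against the [-800, 0) ms baseline of the same trial;
6. mean z amplitude over the Listening [0, 1900), Processing
   [1900, 4000) and target [2900, 3400) ms windows (half-open, so
   Listening and Processing partition 0-4000 ms).

Everything after z-normalization is invariant to the raw microvolt scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import uniform_filter1d

logger = logging.getLogger(__name__)

__all__ = [
    "MUSCLES",
    "EMGRecording",
    "Epochs",
    "Envelope",
    "AnalysisWindows",
    "PipelineConfig",
    "bandpass",
    "epoch",
    "detect_artifacts",
    "envelope",
    "znormalize",
    "window_means",
    "process_epochs",
    "difference_scores",
]

MUSCLES = ("zm", "cs")


@dataclass(frozen=True)
class AnalysisWindows:
    """Half-open analysis windows in ms relative to sentence onset."""

    listening: tuple[float, float] = (0.0, 1900.0)
    processing: tuple[float, float] = (1900.0, 4000.0)
    target: tuple[float, float] = (2900.0, 3400.0)

    def __post_init__(self) -> None:
        for w in (self.listening, self.processing, self.target):
            if w[0] >= w[1]:
                raise ValueError("window start must precede end")
        if not (self.processing[0] <= self.target[0]
                and self.target[1] <= self.processing[1]):
            raise ValueError("target window must lie inside processing")


@dataclass(frozen=True)
class PipelineConfig:
    low_hz: float = 50.0
    high_hz: float = 250.0
    filter_order: int = 4
    smooth_ms: float = 300.0
    artifact_threshold_sd: float = 8.0
    baseline_ms: tuple[float, float] = (-800.0, 0.0)
    epoch_span_ms: tuple[float, float] = (-800.0, 4000.0)
    windows: AnalysisWindows = field(default_factory=AnalysisWindows)


@dataclass
class EMGRecording:
    """Continuous two-channel recording in microvolts with event markers.

    events columns: onset_ms, sentence_id, filter, choice (labels carried
    through to the per-trial outputs).
    """

    fs: float
    channels: dict[str, np.ndarray]
    events: pd.DataFrame

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("channels must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))


@dataclass
class Epochs:
    """Stacked event-locked segments: data (n_epochs, n_muscles, n_samples)."""

    fs: float
    times_ms: np.ndarray
    data: np.ndarray
    labels: pd.DataFrame
    muscles: tuple[str, ...] = MUSCLES


@dataclass
class Envelope:
    """Single-trial rectified-smoothed (optionally z-normalized) envelope."""

    fs: float
    times_ms: np.ndarray
    values: np.ndarray
    muscle: str
    filter: str | None = None
    choice: str | None = None
    rejected: bool = False
    is_z: bool = False


def _bandpass_sos(fs: float, low: float, high: float, order: int) -> np.ndarray:
    if fs <= 2 * high:
        raise ValueError("sampling rate must exceed twice the low-pass edge")
    return signal.butter(order, [low, high], btype="bandpass", fs=fs,
                         output="sos")


def bandpass(recording: EMGRecording, low: float = 50.0, high: float = 250.0,
             order: int = 4) -> EMGRecording:
    """Zero-phase band-pass (forward-backward Butterworth); removes DC."""
    sos = _bandpass_sos(recording.fs, low, high, order)
    channels = {k: signal.sosfiltfilt(sos, v) for k, v in recording.channels.items()}
    return EMGRecording(recording.fs, channels, recording.events)


def bandpass_array(data: np.ndarray, fs: float, low: float = 50.0,
                   high: float = 250.0, order: int = 4) -> np.ndarray:
    """Zero-phase band-pass along the last axis of an epoch array.

    Single-precision input is filtered in single precision (the filter is
    realized as second-order sections, which are numerically benign).
    """
    sos = _bandpass_sos(fs, low, high, order)
    if data.dtype == np.float32:
        sos = sos.astype(np.float32)
    return signal.sosfiltfilt(sos, data, axis=-1)


def epoch_times(fs: float, tmin_ms: float, tmax_ms: float) -> np.ndarray:
    n = int(round((tmax_ms - tmin_ms) / 1000.0 * fs))
    return tmin_ms + np.arange(n) / fs * 1000.0


def epoch(recording: EMGRecording, tmin_ms: float = -800.0,
          tmax_ms: float = 4000.0) -> Epochs:
    """Cut one epoch per event; events too close to the recording edges are
    dropped with a logged warning."""
    fs = recording.fs
    times = epoch_times(fs, tmin_ms, tmax_ms)
    n_samp = times.size
    data, kept = [], []
    arrays = [recording.channels[m] for m in MUSCLES]
    total = recording.n_samples
    for i, ev in recording.events.reset_index(drop=True).iterrows():
        start = int(round((ev["onset_ms"] + tmin_ms) / 1000.0 * fs))
        if start < 0 or start + n_samp > total:
            logger.warning("dropping event %s: epoch outside recording", i)
            continue
        data.append([a[start:start + n_samp] for a in arrays])
        kept.append(i)
    if not data:
        raise ValueError("no epochs inside the recording span")
    labels = recording.events.reset_index(drop=True).loc[kept].reset_index(drop=True)
    return Epochs(fs, times, np.asarray(data, dtype=float), labels)


def detect_artifacts(epochs: Epochs, threshold_sd: float = 8.0) -> np.ndarray:
    """Robust peak-amplitude rejection mask (True = rejected).

    Per muscle, an epoch is rejected when its peak absolute amplitude
    exceeds median + threshold_sd * 1.4826 * MAD of all epochs' peaks; a
    trial rejected on either muscle is rejected altogether. Like any
    median/MAD rule this assumes artifacts are a minority (< 50% of
    trials); at higher contamination the threshold itself is corrupted.
    """
    peaks = np.max(np.abs(epochs.data), axis=-1)  # (n_epochs, n_muscles)
    med = np.median(peaks, axis=0)
    mad_sd = 1.4826 * np.median(np.abs(peaks - med), axis=0)
    mask = np.any(peaks > med + threshold_sd * mad_sd, axis=1)
    logger.info("artifact rejection: %d/%d epochs (%.1f%%)",
                mask.sum(), mask.size, 100.0 * mask.mean())
    return mask


def moving_average(x: np.ndarray, n_window: int) -> np.ndarray:
    """Centered moving average along the last axis, window shrinking at the
    edges so every output sample averages only in-range input."""
    ones = np.ones(x.shape[-1])
    counts = uniform_filter1d(ones, n_window, mode="constant", cval=0.0)
    sums = uniform_filter1d(x, n_window, axis=-1, mode="constant", cval=0.0)
    return sums / counts


def envelope_array(data: np.ndarray, fs: float, smooth_ms: float = 300.0) -> np.ndarray:
    """Rectify and smooth along the last axis (300 ms centered window)."""
    n_window = max(1, int(round(smooth_ms / 1000.0 * fs)))
    return moving_average(np.abs(data), n_window)


def envelope(ep: Envelope | np.ndarray, fs: float | None = None,
             times_ms: np.ndarray | None = None, muscle: str = "zm",
             smooth_ms: float = 300.0, **labels) -> Envelope:
    """Single-trial rectified-smoothed envelope (pre-normalization)."""
    if isinstance(ep, Envelope):
        values = envelope_array(ep.values, ep.fs, smooth_ms)
        return replace(ep, values=values)
    if fs is None or times_ms is None:
        raise ValueError("fs and times_ms required for array input")
    return Envelope(fs, np.asarray(times_ms), envelope_array(np.asarray(ep, float), fs, smooth_ms),
                    muscle, **labels)


def znormalize_array(env: np.ndarray, times_ms: np.ndarray,
                     baseline_ms: tuple[float, float] = (-800.0, 0.0)
                     ) -> tuple[np.ndarray, np.ndarray]:
    """z-score each trial's envelope against its own baseline samples.

    Returns (z, degenerate) where degenerate flags trials whose baseline
    SD is zero (those cannot be normalized and must be rejected).
    """
    mask = (times_ms >= baseline_ms[0]) & (times_ms < baseline_ms[1])
    if not mask.any():
        raise ValueError("no baseline samples in epoch")
    base = env[..., mask]
    mean = base.mean(axis=-1, keepdims=True)
    sd = base.std(axis=-1, ddof=1, keepdims=True)
    degenerate = (sd == 0).reshape(env.shape[:-1])
    safe_sd = np.where(sd == 0, 1.0, sd)
    return (env - mean) / safe_sd, degenerate


def znormalize(env: Envelope, baseline_ms: tuple[float, float] = (-800.0, 0.0)) -> Envelope:
    """z-normalize a single-trial envelope against its [-800, 0) ms baseline."""
    z, degenerate = znormalize_array(env.values, env.times_ms, baseline_ms)
    if degenerate.any():
        return replace(env, rejected=True)
    return replace(env, values=z, is_z=True)


def window_mask(times_ms: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    return (times_ms >= window[0]) & (times_ms < window[1])


def window_means(env: Envelope | np.ndarray, windows: AnalysisWindows,
                 times_ms: np.ndarray | None = None) -> dict[str, float]:
    """Mean amplitude over each half-open analysis window."""
    if isinstance(env, Envelope):
        if env.rejected:
            raise ValueError("rejected trial has no window means")
        values, times_ms = env.values, env.times_ms
    else:
        values = np.asarray(env, float)
        if times_ms is None:
            raise ValueError("times_ms required for array input")
    out = {}
    for name in ("listening", "processing", "target"):
        m = window_mask(times_ms, getattr(windows, name))
        out[name] = float(values[..., m].mean(axis=-1))
    return out


def process_epochs(epochs: Epochs, cfg: PipelineConfig = PipelineConfig(),
                   participant: str | None = None,
                   already_filtered: bool = False
                   ) -> tuple[pd.DataFrame, dict]:
    """Run the full envelope pipeline on an epoch stack.

    Returns (amplitudes, log): amplitudes has one row per kept trial and
    muscle with mean_listening / mean_processing / mean_target in z units
    plus the carried trial labels; log records rejection counts.
    """
    data = epochs.data
    if not already_filtered:
        data = bandpass_array(data, epochs.fs, cfg.low_hz, cfg.high_hz,
                              cfg.filter_order)
        filtered = Epochs(epochs.fs, epochs.times_ms, data, epochs.labels,
                          epochs.muscles)
    else:
        filtered = epochs
    artifact = detect_artifacts(filtered, cfg.artifact_threshold_sd)
    env = envelope_array(data, epochs.fs, cfg.smooth_ms)
    # z-scores in double precision regardless of the raw storage dtype
    z, degenerate = znormalize_array(env.astype(np.float64, copy=False),
                                     epochs.times_ms, cfg.baseline_ms)
    rejected = artifact | degenerate.any(axis=1)

    masks = {name: window_mask(epochs.times_ms, getattr(cfg.windows, name))
             for name in ("listening", "processing", "target")}
    labels = epochs.labels
    kept = np.nonzero(~rejected)[0]
    n_mus = len(epochs.muscles)
    frame = {
        "participant": participant,
        "trial": np.repeat(kept, n_mus),
        "muscle": np.tile(np.array(epochs.muscles), kept.size),
    }
    for col in labels.columns:
        if col != "onset_ms":
            frame[col] = np.repeat(labels[col].to_numpy()[kept], n_mus)
    for name, m in masks.items():
        frame[f"mean_{name}"] = z[kept][:, :, m].mean(axis=-1).ravel()
    amplitudes = pd.DataFrame(frame)
    log = {
        "participant": participant,
        "n_trials": int(len(labels)),
        "n_rejected": int(rejected.sum()),
        "rejected_fraction": float(rejected.mean()),
    }
    logger.info("participant %s: rejected %d/%d trials (%.1f%%)",
                participant, log["n_rejected"], log["n_trials"],
                100 * log["rejected_fraction"])
    return amplitudes, log


def difference_scores(amplitudes: pd.DataFrame,
                      value: str = "mean_target") -> pd.DataFrame:
    """Per-participant condition-difference scores on the target window.

    ZM_filter = mean ZM z (Smiling-F) - mean ZM z (Unsmiling-F)
    CS_choice = mean CS z (Unsmile-C) - mean CS z (Smile-C)

    Participants missing any constituent cell are excluded (logged).
    """
    rows = []
    for pid, df in amplitudes.groupby("participant"):
        zm = df[df["muscle"] == "zm"]
        cs = df[df["muscle"] == "cs"]
        cells = {
            "zm_smileF": zm.loc[zm["filter"] == "Smiling-F", value],
            "zm_unsmileF": zm.loc[zm["filter"] == "Unsmiling-F", value],
            "cs_unsmileC": cs.loc[cs["choice"] == "Unsmile-C", value],
            "cs_smileC": cs.loc[cs["choice"] == "Smile-C", value],
        }
        if any(len(v) == 0 for v in cells.values()):
            logger.info("participant %s excluded from difference scores "
                        "(empty condition cell)", pid)
            continue
        rows.append({
            "participant": pid,
            "zm_filter": cells["zm_smileF"].mean() - cells["zm_unsmileF"].mean(),
            "cs_choice": cells["cs_unsmileC"].mean() - cells["cs_smileC"].mean(),
        })
    return pd.DataFrame(rows)
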