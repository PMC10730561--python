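"""Speech-envelope extraction and EEG preprocessing.

The chain mirrors the acquisition pipeline: common-average re-referencing,
zero-phase band-pass filtering (0.5-8 Hz by default), polyphase down-sampling
to the analysis rate (64 Hz), and per-channel z-scoring.  The same chain runs
either on a whole trial (offline analysis) or on a 15-s buffer only
(simulated real-time analysis), where it must not touch samples outside the
buffer.

Speech envelopes are the magnitude of the analytic signal (Hilbert
transform), band-passed, resampled and z-scored with the same settings.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .core_io import (
    COMMON_AVERAGE,
    RECORDING_REFERENCE,
    DegenerateSignalError,
    EEGTrial,
    Envelope,
    ExperimentConfig,
    ParameterError,
    BufferUnderrunError,
)

#: Butterworth order per pass of the zero-phase (forward-backward) filter.
FILTER_ORDER = 3


@dataclass
class Snippet:
    """One analysis window of preprocessed EEG plus matching envelope cuts."""

    eeg: np.ndarray                   # channels x samples at fs_proc
    envelope_segments: tuple[np.ndarray, ...]  # per speaker, z-scored
    window_index: int                 # 1-based
    window_end_s: float
    fs_proc: float


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, population sd 1 (last axis)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateSignalError("zero-variance signal cannot be z-scored")
    return (x - x.mean(axis=-1, keepdims=True)) / sd


def bandpass(x: np.ndarray, fs: float, low: float, high: float) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    if not (0 < low < high < fs / 2):
        raise ParameterError(
            f"band edges must satisfy 0 < {low} < {high} < fs/2 = {fs / 2}"
        )
    sos = sps.butter(FILTER_ORDER, [low, high], btype="bandpass", fs=fs,
                     output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def resample(x: np.ndarray, fs_from: float, fs_to: float) -> np.ndarray:
    """Anti-aliased polyphase rate conversion along the last axis.

    Only down-sampling is supported; the pipeline never up-samples.
    """
    if fs_to >= fs_from:
        raise ParameterError("resample only down-samples (fs_to < fs_from)")
    frac = Fraction(fs_to / fs_from).limit_denominator(1000)
    return sps.resample_poly(np.asarray(x, dtype=float), frac.numerator,
                             frac.denominator, axis=-1)


def rereference_common_average(trial: EEGTrial) -> EEGTrial:
    """Subtract the instantaneous mean across channels from every channel."""
    if trial.reference != RECORDING_REFERENCE:
        raise ParameterError(f"trial already referenced to {trial.reference}")
    if trial.n_channels < 2:
        raise ParameterError("common-average reference needs >= 2 channels")
    data = trial.data - trial.data.mean(axis=0, keepdims=True)
    return EEGTrial(data=data, fs=trial.fs, channel_labels=trial.channel_labels,
                    reference=COMMON_AVERAGE, trial_id=trial.trial_id)


# ---------------------------------------------------------------------------
# Composite pipelines
# ---------------------------------------------------------------------------

def extract_envelope(waveform: np.ndarray, fs_audio: float,
                     config: ExperimentConfig, speaker_id: str = "") -> Envelope:
    """Extract a standardized speech envelope from an audio waveform.

    Fixed pipeline order: analytic signal -> magnitude -> band-pass
    (config.passband_hz) -> resample to config.fs_proc -> z-score.
    """
    waveform = np.asarray(waveform, dtype=float).ravel()
    if len(waveform) < fs_audio:
        raise ParameterError("need at least 1 s of audio")
    if fs_audio <= 2 * config.passband_hz[1]:
        raise ParameterError("audio rate too low for the requested passband")
    env = np.abs(sps.hilbert(waveform))
    env = bandpass(env, fs_audio, *config.passband_hz)
    env = resample(env, fs_audio, config.fs_proc)
    if env.std() == 0:
        raise DegenerateSignalError("envelope has zero variance after resampling")
    return Envelope(values=zscore(env), fs=config.fs_proc, standardized=True,
                    speaker_id=speaker_id)


def preprocess_eeg(trial: EEGTrial, config: ExperimentConfig) -> EEGTrial:
    """Full EEG chain: common average -> band-pass -> resample -> z-score."""
    out = rereference_common_average(trial)
    # channels with no variance left after re-referencing (e.g. duplicated or
    # flat electrodes) would be z-scored float noise; fail instead
    post_sd = out.data.std(axis=-1)
    ref = max(trial.data.std(axis=-1).max(), np.finfo(float).tiny)
    if np.any(post_sd < 1e-10 * ref):
        bad = [lab for lab, sd in zip(trial.channel_labels, post_sd)
               if sd < 1e-10 * ref]
        raise DegenerateSignalError(
            f"no variance after re-referencing in channel(s): {', '.join(bad)}"
        )
    data = bandpass(out.data, trial.fs, *config.passband_hz)
    if trial.fs != config.fs_proc:
        data = resample(data, trial.fs, config.fs_proc)
    data = zscore(data)
    return EEGTrial(data=data, fs=config.fs_proc,
                    channel_labels=trial.channel_labels,
                    reference=COMMON_AVERAGE, trial_id=trial.trial_id)


def preprocess_snippet(buffer: np.ndarray, envelopes: tuple[Envelope, ...],
                       config: ExperimentConfig, window_index: int,
                       window_end_s: float,
                       channel_labels: tuple[str, ...] | None = None) -> Snippet:
    """Preprocess one W-second raw-EEG buffer and cut matching envelope segments.

    The EEG chain uses only samples inside the buffer (causally realizable in
    a streaming loop).  Envelope segments are cut from the stored,
    already-preprocessed envelopes at fs_proc and re-z-scored per snippet.
    """
    buffer = np.asarray(buffer, dtype=float)
    n_expected = int(round(config.window_s * config.fs_acq))
    if buffer.shape[-1] < n_expected:
        raise BufferUnderrunError(
            f"buffer holds {buffer.shape[-1]} samples, window needs {n_expected}"
        )
    labels = channel_labels or tuple(f"ch{i}" for i in range(buffer.shape[0]))
    trial = EEGTrial(data=buffer, fs=config.fs_acq, channel_labels=labels,
                     trial_id=f"snippet-{window_index}")
    eeg = preprocess_eeg(trial, config).data

    start = int(round((window_end_s - config.window_s) * config.fs_proc))
    stop = start + eeg.shape[-1]
    segments = []
    for env in envelopes:
        if env.fs != config.fs_proc:
            raise ParameterError("stored envelopes must be at fs_proc")
        seg = env.values[start:stop]
        if len(seg) != eeg.shape[-1]:
            raise ParameterError("envelope does not cover the snippet window")
        segments.append(zscore(seg))
    return Snippet(eeg=eeg, envelope_segments=tuple(segments),
                   window_index=window_index, window_end_s=window_end_s,
                   fs_proc=config.fs_proc)
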