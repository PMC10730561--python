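"""Simulated real-time decoding: sliding windows, snippet decoders, EMA.

Real-time operation replays the experiment's streaming loop: EEG accumulates
in a W-second buffer (15 s), analysis re-runs every M seconds (1 s), and the
i-th window ends at W + (i-1)M seconds.  A snippet decoder is the same ridge
solve as the offline model restricted to one window:

    D_i = (R_i R_i^T + lambda I)^(-1) R_i S_i^T

and the real-time decoder D_bar is the equal-weight mean of every snippet
decoder over all training trials.  At test time each window yields Pearson
correlations of the reconstruction with both speakers' envelope segments;
the per-speaker correlation sequences are smoothed with an exponential
moving average

    r_hat_i = r_i                               (i = 1)
    r_hat_i = alpha r_i + (1 - alpha) r_hat_{i-1}  (i > 1)

(alpha = 0.1) and the window's decision is the speaker with the larger
smoothed correlation.  Raw correlations are kept alongside for the
attention-switch sensitivity analysis, which by design ignores the EMA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import (
    DegenerateSignalError,
    EEGTrial,
    Envelope,
    ExperimentConfig,
    ParameterError,
    TrialMetadata,
)
from .offline_decoder import (
    Decoder,
    average_decoders,
    build_lagged_design,
    classify_trial,
    fit_ridge_decoder,
    lag_indices,
    pearson,
    reconstruct_envelope,
)
from .preprocessing import Snippet, preprocess_snippet


@dataclass
class WindowSpec:
    """One sliding-window position; index is 1-based, end time in seconds."""

    index: int
    window_s: float
    step_s: float
    end_time_s: float

    def sample_range(self, fs: float) -> tuple[int, int]:
        """Half-open [start, stop) sample range at rate fs."""
        stop = int(round(self.end_time_s * fs))
        return stop - int(round(self.window_s * fs)), stop


@dataclass
class RealtimeDecoder:
    """Averaged snippet decoder D_bar with its provenance count."""

    decoder: Decoder
    provenance: int
    config: ExperimentConfig

    def __post_init__(self) -> None:
        if self.provenance < 1:
            raise ParameterError("provenance must be >= 1")


@dataclass
class CorrelationTrace:
    """Per-window correlations, EMA-smoothed values and decisions for a trial."""

    trial_id: str
    window_indices: np.ndarray
    window_end_s: np.ndarray
    r1_raw: np.ndarray
    r2_raw: np.ndarray
    r1_ema: np.ndarray
    r2_ema: np.ndarray
    decisions: np.ndarray          # 1 or 2 per window
    correct: np.ndarray            # bool per window
    ema_alpha: float
    metadata: TrialMetadata | None = None

    def to_records(self) -> list[dict]:
        return [
            {
                "trial_id": self.trial_id,
                "window_index": int(self.window_indices[k]),
                "window_end_s": float(self.window_end_s[k]),
                "r1_raw": float(self.r1_raw[k]),
                "r2_raw": float(self.r2_raw[k]),
                "r1_ema": float(self.r1_ema[k]),
                "r2_ema": float(self.r2_ema[k]),
                "decision": int(self.decisions[k]),
                "correct": bool(self.correct[k]),
            }
            for k in range(len(self.window_indices))
        ]


# ---------------------------------------------------------------------------
# Window bookkeeping
# ---------------------------------------------------------------------------

def enumerate_windows(duration_s: float, window_s: float, step_s: float,
                      buffer_s: float | None = None) -> list[WindowSpec]:
    """All window positions for a trial: end times W, W+M, ... <= duration.

    Count = floor((duration - W) / M) + 1.  The first window coincides with
    the first full buffer (buffer_s = W in the experiment's configuration).
    """
    if buffer_s is None:
        buffer_s = window_s
    if buffer_s != window_s:
        raise ParameterError("initial buffer must equal the window width")
    if duration_s < window_s:
        raise ParameterError(
            f"trial of {duration_s} s shorter than one {window_s}-s window"
        )
    n = int(np.floor((duration_s - window_s) / step_s + 1e-9)) + 1
    return [
        WindowSpec(index=i + 1, window_s=window_s, step_s=step_s,
                   end_time_s=window_s + i * step_s)
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def fit_snippet_decoder(snippet: Snippet, attended_segment: np.ndarray,
                        lambda_reg: float) -> Decoder:
    """Ridge decoder for one window; same math as the offline fit."""
    lags = lag_indices((0.0, 250.0), snippet.fs_proc)
    return _fit_snippet(snippet, attended_segment, lambda_reg, lags)


def _fit_snippet(snippet: Snippet, attended_segment: np.ndarray,
                 lambda_reg: float, lags: np.ndarray) -> Decoder:
    trial = EEGTrial(
        data=snippet.eeg, fs=snippet.fs_proc,
        channel_labels=tuple(f"ch{i}" for i in range(snippet.eeg.shape[0])),
        reference="common-average", trial_id=f"w{snippet.window_index}",
    )
    design = build_lagged_design(trial, lags)
    return fit_ridge_decoder(design, np.asarray(attended_segment),
                             lambda_reg, snippet.fs_proc)


def train_realtime_decoder(
    training: Sequence[tuple[EEGTrial, tuple[Envelope, Envelope], TrialMetadata]],
    config: ExperimentConfig,
) -> RealtimeDecoder:
    """Average snippet decoders over all windows of all training trials.

    With 14 one-minute trials at W = 15 s, M = 1 s this averages
    14 x 46 = 644 snippet decoders.
    """
    if not training:
        raise ParameterError("empty training set")
    lags = lag_indices(config.lag_range_ms, config.fs_proc)
    decoders: list[Decoder] = []
    for eeg, envs, meta in training:
        if eeg.fs != config.fs_acq:
            raise ParameterError(
                f"trial {meta.trial_id} not at acquisition rate {config.fs_acq}"
            )
        for win in enumerate_windows(eeg.duration_s, config.window_s,
                                     config.step_s, config.buffer_s):
            a, b = win.sample_range(config.fs_acq)
            snip = preprocess_snippet(eeg.data[:, a:b], envs, config,
                                      win.index, win.end_time_s,
                                      eeg.channel_labels)
            att_seg = snip.envelope_segments[meta.attended_speaker - 1]
            decoders.append(_fit_snippet(snip, att_seg, config.lambda_reg, lags))
    return RealtimeDecoder(decoder=average_decoders(decoders),
                           provenance=len(decoders), config=config)


# ---------------------------------------------------------------------------
# EMA and streaming evaluation
# ---------------------------------------------------------------------------

def apply_ema(raw: Sequence[float], alpha: float) -> np.ndarray:
    """Exponential moving average; the first element passes through unchanged."""
    if not (0 < alpha <= 1):
        raise ParameterError("alpha must be in (0, 1]")
    raw = np.asarray(raw, dtype=float)
    if raw.size < 1:
        raise ParameterError("need at least one value")
    out = np.empty_like(raw)
    out[0] = raw[0]
    for i in range(1, len(raw)):
        out[i] = alpha * raw[i] + (1 - alpha) * out[i - 1]
    return out


def stream_decode(eeg: EEGTrial, envelopes: tuple[Envelope, Envelope],
                  metadata: TrialMetadata, rt: RealtimeDecoder,
                  config: ExperimentConfig | None = None) -> CorrelationTrace:
    """Replay the streaming loop over one test trial.

    Every window: preprocess the raw buffer, reconstruct with D_bar,
    correlate with both speakers' envelope segments, smooth each speaker's
    correlation sequence with the EMA, decide for the larger smoothed value.
    EMA state starts fresh at each trial.  A degenerate window contributes
    NaN correlations and counts as incorrect; streaming continues.
    """
    config = config or rt.config
    windows = enumerate_windows(eeg.duration_s, config.window_s,
                                config.step_s, config.buffer_s)
    r1_raw, r2_raw = [], []
    for win in windows:
        a, b = win.sample_range(config.fs_acq)
        try:
            snip = preprocess_snippet(eeg.data[:, a:b], envelopes, config,
                                      win.index, win.end_time_s,
                                      eeg.channel_labels)
            trial = EEGTrial(
                data=snip.eeg, fs=config.fs_proc,
                channel_labels=eeg.channel_labels,
                reference="common-average", trial_id=eeg.trial_id,
            )
            design = build_lagged_design(trial, rt.decoder.lag_samples)
            s_hat = reconstruct_envelope(rt.decoder, design).values
            r1_raw.append(pearson(s_hat, snip.envelope_segments[0]))
            r2_raw.append(pearson(s_hat, snip.envelope_segments[1]))
        except DegenerateSignalError:
            r1_raw.append(float("nan"))
            r2_raw.append(float("nan"))

    r1_raw = np.asarray(r1_raw)
    r2_raw = np.asarray(r2_raw)
    # EMA is applied per speaker independently; NaN windows pass NaN through
    # without poisoning later state.
    r1_ema = _ema_skipnan(r1_raw, config.ema_alpha)
    r2_ema = _ema_skipnan(r2_raw, config.ema_alpha)

    decisions = np.where(np.nan_to_num(r1_ema, nan=-np.inf)
                         > np.nan_to_num(r2_ema, nan=-np.inf), 1, 2)
    both_nan = np.isnan(r1_ema) & np.isnan(r2_ema)
    correct = np.array([
        classify_trial(r1_ema[k], r2_ema[k], metadata.attended_speaker)
        and not both_nan[k]
        for k in range(len(windows))
    ])
    return CorrelationTrace(
        trial_id=metadata.trial_id,
        window_indices=np.array([w.index for w in windows]),
        window_end_s=np.array([w.end_time_s for w in windows]),
        r1_raw=r1_raw, r2_raw=r2_raw, r1_ema=r1_ema, r2_ema=r2_ema,
        decisions=decisions, correct=correct, ema_alpha=config.ema_alpha,
        metadata=metadata,
    )


def _ema_skipnan(raw: np.ndarray, alpha: float) -> np.ndarray:
    """EMA that emits NaN for NaN inputs but keeps smoothing the rest."""
    out = np.full_like(raw, np.nan)
    state = None
    for i, v in enumerate(raw):
        if np.isnan(v):
            continue
        state = v if state is None else alpha * v + (1 - alpha) * state
        out[i] = state
    return out


def window_accuracy(traces: Sequence[CorrelationTrace]) -> dict:
    """Percent of correct windows pooled over trials, plus per-kind splits."""
    if not traces:
        raise ParameterError("no traces to summarize")

    def pct(sel: list[CorrelationTrace]) -> float | None:
        if not sel:
            return None
        total = sum(len(t.correct) for t in sel)
        good = sum(int(t.correct.sum()) for t in sel)
        return 100.0 * good / total

    fixed = [t for t in traces if t.metadata and t.metadata.kind == "fixed"]
    switching = [t for t in traces if t.metadata and t.metadata.kind == "switching"]
    return {
        "all_pct": pct(list(traces)),
        "fixed_pct": pct(fixed),
        "switching_pct": pct(switching),
        "n_windows": sum(len(t.correct) for t in traces),
        "n_trials": len(traces),
    }
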