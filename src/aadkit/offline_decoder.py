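"""Ridge backward (stimulus-reconstruction) decoding with LOOCV.

The backward model maps time-lag-expanded multichannel EEG to the attended
speech envelope:

    S_hat(t) = sum_n sum_tau D(tau, n) R(t + tau, n)

with lags tau spanning 0-250 ms (EEG follows the stimulus, so reconstructing
S(t) uses EEG samples at and after t).  The decoder weights solve the ridge
normal equations

    D = (R R^T + lambda I)^(-1) R S^T

on the lagged design matrix R, with the penalty added to the raw diagonal
(no eigenvalue or trace normalization), so lambda = 10 on z-scored data
means exactly that.

Offline evaluation is leave-one-out over location-fixed trials: the held-out
trial is reconstructed with the element-wise average of the decoders fitted
on every other trial, and classified correct when the reconstruction
correlates more strongly with the attended than the unattended envelope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg

from .core_io import (
    DegenerateSignalError,
    EEGTrial,
    Envelope,
    ExperimentConfig,
    ParameterError,
    TrialMetadata,
)


@dataclass
class Decoder:
    """Ridge backward-model weights: lags x channels."""

    weights: np.ndarray
    lambda_reg: float
    lag_samples: np.ndarray     # ordered non-negative lag indices at fs_proc
    fs_proc: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.lag_samples = np.asarray(self.lag_samples, dtype=int)
        if not np.all(np.isfinite(self.weights)):
            raise ParameterError("decoder weights must be finite")
        if self.weights.shape[0] != len(self.lag_samples):
            raise ParameterError("weight rows must match lag count")


@dataclass
class LaggedDesign:
    """Time-lag-expanded EEG: (lags*channels) x samples, lag-major rows."""

    matrix: np.ndarray
    lag_samples: np.ndarray
    n_channels: int

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


def lag_indices(lag_range_ms: tuple[float, float], fs_proc: float) -> np.ndarray:
    """Sample lags implementing a millisecond lag range at fs_proc.

    0-250 ms at 64 Hz gives lags 0..16 (17 taps): floor(0.250 * 64) + 1.
    """
    lo = int(np.floor(lag_range_ms[0] / 1000.0 * fs_proc))
    hi = int(np.floor(lag_range_ms[1] / 1000.0 * fs_proc))
    return np.arange(lo, hi + 1)


def build_lagged_design(trial: EEGTrial, lag_samples: np.ndarray) -> LaggedDesign:
    """Expand a preprocessed trial into its lagged design matrix.

    Row (tau, n) at output time t holds channel n's sample at t + tau;
    positions past the end of the trial are zero-filled, so the design keeps
    the full trial length.
    """
    lag_samples = np.asarray(lag_samples, dtype=int)
    data = trial.data
    n_ch, n_t = data.shape
    if np.any(lag_samples >= n_t):
        raise ParameterError("lag exceeds trial length")
    if np.any(lag_samples < 0):
        raise ParameterError("lags must be non-negative")
    rows = np.zeros((len(lag_samples) * n_ch, n_t))
    for k, tau in enumerate(lag_samples):
        block = rows[k * n_ch:(k + 1) * n_ch]
        block[:, : n_t - tau] = data[:, tau:]
    return LaggedDesign(matrix=rows, lag_samples=lag_samples, n_channels=n_ch)


def fit_ridge_decoder(design: LaggedDesign, envelope: Envelope | np.ndarray,
                      lambda_reg: float, fs_proc: float = 64.0) -> Decoder:
    """Solve the ridge normal equations for the backward-model weights."""
    s = envelope.values if isinstance(envelope, Envelope) else np.asarray(envelope)
    R = design.matrix
    if len(s) != R.shape[1]:
        raise ParameterError("envelope length must equal design column count")
    if lambda_reg < 0:
        raise ParameterError("lambda must be non-negative")
    A = R @ R.T + lambda_reg * np.eye(R.shape[0])
    b = R @ s
    if lambda_reg == 0:
        # unregularized: fail loudly on rank deficiency instead of returning junk
        if np.linalg.matrix_rank(A) < A.shape[0]:
            raise ParameterError(
                "R R^T is rank-deficient with lambda = 0; use lambda > 0"
            )
    w = linalg.solve(A, b, assume_a="pos")
    return Decoder(weights=w.reshape(len(design.lag_samples), design.n_channels),
                   lambda_reg=lambda_reg, lag_samples=design.lag_samples,
                   fs_proc=fs_proc)


def reconstruct_envelope(decoder: Decoder, design: LaggedDesign) -> Envelope:
    """Apply decoder weights to a lagged design: S_hat = D^T R."""
    if decoder.weights.size != design.matrix.shape[0]:
        raise ParameterError("decoder shape does not match design")
    if not np.array_equal(decoder.lag_samples, design.lag_samples):
        raise ParameterError("decoder and design lag structures differ")
    s_hat = decoder.weights.ravel() @ design.matrix
    return Envelope(values=s_hat, fs=decoder.fs_proc, standardized=False)


def average_decoders(decoders: Sequence[Decoder]) -> Decoder:
    """Element-wise equal-weight mean of decoder weight arrays."""
    if not decoders:
        raise ParameterError("no decoders to average")
    first = decoders[0]
    for d in decoders[1:]:
        if d.weights.shape != first.weights.shape:
            raise ParameterError("decoders have mismatched shapes")
    w = np.mean([d.weights for d in decoders], axis=0)
    return Decoder(weights=w, lambda_reg=first.lambda_reg,
                   lag_samples=first.lag_samples, fs_proc=first.fs_proc)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; NaN when either signal has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def classify_trial(r_speaker1: float, r_speaker2: float,
                   attended: int) -> bool:
    """Correct iff the attended speaker's correlation is strictly larger.

    NaN correlations (degenerate reconstructions) rank below any finite
    value; ties classify as incorrect.
    """
    r1 = -np.inf if np.isnan(r_speaker1) else r_speaker1
    r2 = -np.inf if np.isnan(r_speaker2) else r_speaker2
    r_att, r_unatt = (r1, r2) if attended == 1 else (r2, r1)
    return bool(r_att > r_unatt)


def loocv_evaluate(
    trials: Sequence[tuple[EEGTrial, tuple[Envelope, Envelope], TrialMetadata]],
    config: ExperimentConfig,
    preprocessed: bool = False,
) -> dict:
    """Leave-one-out evaluation over location-fixed trials.

    For each held-out trial the reconstruction uses the averaged weights of
    one ridge decoder per remaining trial, each fitted against its own
    attended envelope.  Returns per-trial correlations, correctness flags and
    the percent accuracy.

    ``trials`` must contain location-fixed trials only (switching trials are
    unsuitable because the attended side changes mid-trial).  Set
    ``preprocessed`` when EEG is already at fs_proc and standardized.
    """
    from .preprocessing import preprocess_eeg

    if len(trials) < 2:
        raise ParameterError("LOOCV needs at least 2 usable trials")
    for _, _, meta in trials:
        if meta.kind != "fixed":
            raise ParameterError(
                f"trial {meta.trial_id} is not location-fixed; exclude it"
            )

    lags = lag_indices(config.lag_range_ms, config.fs_proc)
    designs, per_trial_decoders, usable = [], [], []
    for eeg, envs, meta in trials:
        try:
            proc = eeg if preprocessed else preprocess_eeg(eeg, config)
            design = build_lagged_design(proc, lags)
            att_env = envs[meta.attended_speaker - 1]
            dec = fit_ridge_decoder(design, att_env, config.lambda_reg,
                                    config.fs_proc)
        except DegenerateSignalError:
            import warnings
            warnings.warn(f"trial {meta.trial_id} failed preprocessing; excluded")
            continue
        designs.append(design)
        per_trial_decoders.append(dec)
        usable.append((envs, meta))
    if len(usable) < 2:
        raise ParameterError("fewer than 2 trials survived preprocessing")

    records = []
    n_correct = 0
    for i, (envs, meta) in enumerate(usable):
        others = [d for j, d in enumerate(per_trial_decoders) if j != i]
        avg = average_decoders(others)
        s_hat = reconstruct_envelope(avg, designs[i]).values
        r1 = pearson(s_hat, envs[0].values)
        r2 = pearson(s_hat, envs[1].values)
        ok = classify_trial(r1, r2, meta.attended_speaker)
        n_correct += ok
        records.append({"trial_id": meta.trial_id, "r1": r1, "r2": r2,
                        "attended_speaker": meta.attended_speaker,
                        "correct": ok})
    return {
        "per_trial": records,
        "n_trials": len(usable),
        "n_correct": n_correct,
        "accuracy_pct": 100.0 * n_correct / len(usable),
    }
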