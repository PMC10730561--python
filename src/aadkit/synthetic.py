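"""Forward-model generator: speech-like envelopes and EEG with known truth.

The generator embodies the linear neural-tracking assumption that the
decoders invert: each EEG channel is the attended envelope convolved with a
channel-specific temporal response function (TRF), plus a weaker
contribution from the unattended envelope through a second TRF, plus
additive noise:

    EEG_n(t) = g_att (k_n * S_att)(t) + g_unatt (k'_n * S_unatt)(t) + noise

Attention is modeled purely as the gain difference g_att > g_unatt.  Signals
are synthesized at the 64 Hz analysis rate and up-sampled to the 125 Hz
acquisition rate so that generated trials exercise the full preprocessing
path.

The default dataset replicates the experimental design: 30 one-minute
trials (26 location-fixed + 4 location-switching), 15 attended-left /
15 attended-right, switch times jittered between 27 and 33 s.  Switching
trials model a transient attention lapse: for ``lapse_s`` seconds after the
switch the effective gains swap (the listener has not yet re-engaged the
target), after which tracking resumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .core_io import (
    DEFAULT_CHANNELS,
    EEGTrial,
    Envelope,
    ExperimentConfig,
    ParameterError,
    TrialMetadata,
    write_eeg,
    write_envelope,
    write_metadata,
)
from .preprocessing import bandpass, zscore


@dataclass
class ForwardModel:
    """Linear generative model shared by all trials of a synthetic dataset."""

    trf: np.ndarray                 # lags x channels, attended-stream kernel
    trf_unattended: np.ndarray      # lags x channels, unattended-stream kernel
    gain_attended: float = 1.0
    gain_unattended: float = 0.25
    noise_sd: float = 1.0
    noise_spectrum: str = "one-over-f"   # "white" | "one-over-f"
    lapse_s: float = 8.0            # attention-lapse length after a switch
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain_attended < 0 or self.gain_unattended < 0:
            raise ParameterError("gains must be non-negative")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.noise_spectrum not in ("white", "one-over-f"):
            raise ParameterError("noise_spectrum must be 'white' or 'one-over-f'")


@dataclass
class SyntheticDataset:
    """In-memory dataset: one (EEGTrial, (env1, env2), TrialMetadata) per trial."""

    trials: list[tuple[EEGTrial, tuple[Envelope, Envelope], TrialMetadata]]
    model: ForwardModel
    config: ExperimentConfig

    def fixed(self):
        return [t for t in self.trials if t[2].kind == "fixed"]

    def switching(self):
        return [t for t in self.trials if t[2].kind == "switching"]


# ---------------------------------------------------------------------------
# Primitive generators
# ---------------------------------------------------------------------------

def generate_envelope(duration_s: float, fs_proc: float, seed: int,
                      speaker_id: str = "") -> Envelope:
    """Speech-like random envelope: low-pass-filtered rectified noise.

    Rectified Gaussian noise is band-limited to the 0.5-8 Hz range that
    dominates natural speech envelopes, then z-scored.  Different seeds give
    statistically independent envelopes.
    """
    if duration_s <= 0:
        raise ParameterError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_proc))
    raw = np.abs(rng.standard_normal(n))
    env = bandpass(raw, fs_proc, 0.5, 8.0)
    return Envelope(values=zscore(env), fs=fs_proc, standardized=True,
                    speaker_id=speaker_id)


def generate_trf(n_channels: int = 15, lag_span_ms: tuple[float, float] = (0, 250),
                 fs_proc: float = 64.0, seed: int = 0) -> np.ndarray:
    """Smooth per-channel kernels: damped oscillations, unit peak amplitude."""
    rng = np.random.default_rng(seed)
    n_lags = int(np.floor(lag_span_ms[1] / 1000.0 * fs_proc)) \
        - int(np.floor(lag_span_ms[0] / 1000.0 * fs_proc)) + 1
    t = np.arange(n_lags) / fs_proc
    kernels = np.empty((n_lags, n_channels))
    for ch in range(n_channels):
        f = rng.uniform(2.0, 7.0)            # oscillation frequency, Hz
        decay = rng.uniform(5.0, 15.0)       # 1/s
        phase = rng.uniform(0, 2 * np.pi)
        polarity = rng.choice([-1.0, 1.0])
        k = polarity * np.exp(-decay * t) * np.sin(2 * np.pi * f * t + phase)
        peak = np.abs(k).max()
        if peak == 0:  # phase landed exactly on a zero crossing everywhere
            k = np.exp(-decay * t)
            peak = 1.0
        kernels[:, ch] = k / peak
    return kernels


def _make_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float,
                spectrum: str) -> np.ndarray:
    white = rng.standard_normal(shape)
    if spectrum == "white":
        return white
    # 1/f amplitude shaping in the frequency domain, unit-variance output
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * scale, n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def simulate_trial(env1: Envelope, env2: Envelope, model: ForwardModel,
                   metadata: TrialMetadata,
                   config: ExperimentConfig | None = None,
                   rng: np.random.Generator | None = None) -> EEGTrial:
    """Synthesize one trial of raw EEG at the acquisition rate.

    The attended/unattended roles follow ``metadata.attended_speaker``.  For
    a switching trial the effective gains swap during the attention-lapse
    window [switch, switch + lapse_s); outside it, tracking is normal (the
    listener keeps following the same speaker after the side switch).
    """
    config = config or ExperimentConfig()
    fs = config.fs_proc
    n = int(round(metadata.duration_s * fs))
    if len(env1.values) < n or len(env2.values) < n:
        raise ParameterError("envelopes shorter than the trial duration")
    if rng is None:
        rng = np.random.default_rng(model.seed)

    att, unatt = (env1, env2) if metadata.attended_speaker == 1 else (env2, env1)

    def drive(env: Envelope, trf: np.ndarray) -> np.ndarray:
        d = np.stack([
            np.convolve(env.values[:n], trf[:, ch])[:n]
            for ch in range(trf.shape[1])
        ])
        # unit per-channel variance so gains and noise_sd share one scale:
        # noise_sd is the noise-to-attended-signal amplitude ratio at gain 1
        sd = d.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        return d / sd

    drive_att = drive(att, model.trf)
    drive_unatt = drive(unatt, model.trf_unattended)

    g_att = np.full(n, model.gain_attended)
    g_unatt = np.full(n, model.gain_unattended)
    if metadata.kind == "switching" and model.lapse_s > 0:
        a = int(round(metadata.switch_time_s * fs))
        b = min(n, a + int(round(model.lapse_s * fs)))
        g_att[a:b], g_unatt[a:b] = model.gain_unattended, model.gain_attended

    eeg = g_att * drive_att + g_unatt * drive_unatt
    if model.noise_sd > 0:
        eeg = eeg + model.noise_sd * _make_noise(rng, eeg.shape, fs,
                                                 model.noise_spectrum)

    # up-sample to the acquisition rate so trials run the real resampling path
    from fractions import Fraction
    frac = Fraction(config.fs_acq / fs).limit_denominator(1000)
    raw = sps.resample_poly(eeg, frac.numerator, frac.denominator, axis=-1)
    n_acq = int(round(metadata.duration_s * config.fs_acq))
    raw = raw[:, :n_acq]
    labels = tuple(DEFAULT_CHANNELS[: raw.shape[0]]) \
        if raw.shape[0] <= len(DEFAULT_CHANNELS) \
        else tuple(f"ch{i}" for i in range(raw.shape[0]))
    return EEGTrial(data=raw, fs=config.fs_acq, channel_labels=labels,
                    trial_id=metadata.trial_id)


# ---------------------------------------------------------------------------
# Full experimental design
# ---------------------------------------------------------------------------

def default_forward_model(config: ExperimentConfig, seed: int,
                          n_channels: int = 15, **overrides) -> ForwardModel:
    """Forward model with fresh random TRFs for attended/unattended streams."""
    trf = generate_trf(n_channels, config.lag_range_ms, config.fs_proc, seed)
    trf_un = generate_trf(n_channels, config.lag_range_ms, config.fs_proc,
                          seed + 1)
    return ForwardModel(trf=trf, trf_unattended=trf_un, seed=seed, **overrides)


def generate_dataset(config: ExperimentConfig, seed: int,
                     model: ForwardModel | None = None,
                     n_fixed: int = 26, n_switching: int = 4,
                     duration_s: float = 60.0,
                     out_dir: str | Path | None = None,
                     eeg_format: str = "table") -> SyntheticDataset:
    """Generate the full experimental design with ground-truth metadata.

    Defaults replicate the study: 30 one-minute trials, 26 location-fixed
    and 4 location-switching, sides balanced 15/15, switch times uniform on
    the 1-s grid between 27 and 33 s.  The first 14 fixed trials double as
    the real-time training set.  When ``out_dir`` is given, trials,
    envelopes and a ground-truth manifest are written in the package's file
    formats.
    """
    rng = np.random.default_rng(seed)
    if model is None:
        model = default_forward_model(config, seed)

    n_total = n_fixed + n_switching
    # switching trials sit in the test half of the session (after trial 14),
    # mirroring the experiment's train-then-test session layout
    first_test = min(14, n_fixed) if n_fixed >= 2 else 0
    candidates = np.arange(first_test, n_total)
    switch_pos = set(rng.choice(candidates, size=n_switching, replace=False)
                     .tolist()) if n_switching else set()

    sides = ["left"] * (n_total // 2) + ["right"] * (n_total - n_total // 2)
    sides = [sides[i] for i in rng.permutation(n_total)]

    trials = []
    for idx in range(n_total):
        kind = "switching" if idx in switch_pos else "fixed"
        # mid-trial jitter on a 1-s grid (keeps response times on the
        # analysis resolution): 45-55% of the trial, i.e. 27-33 s at 60 s
        switch = None
        if kind == "switching":
            lo = int(round(0.45 * duration_s))
            hi = int(round(0.55 * duration_s))
            switch = float(rng.integers(lo, hi + 1))
        meta = TrialMetadata(
            trial_id=f"trial{idx + 1:02d}",
            attended_speaker=1,
            attended_side_initial=sides[idx],
            kind=kind,
            duration_s=duration_s,
            switch_time_s=switch,
        )
        env1 = generate_envelope(duration_s, config.fs_proc,
                                 int(rng.integers(2**31)), speaker_id="speaker1")
        env2 = generate_envelope(duration_s, config.fs_proc,
                                 int(rng.integers(2**31)), speaker_id="speaker2")
        eeg = simulate_trial(env1, env2, model, meta, config, rng)
        trials.append((eeg, (env1, env2), meta))

    ds = SyntheticDataset(trials=trials, model=model, config=config)
    if out_dir is not None:
        write_dataset(ds, out_dir, eeg_format=eeg_format)
    return ds


def write_dataset(ds: SyntheticDataset, out_dir: str | Path,
                  eeg_format: str = "table") -> None:
    """Write all trials, envelopes and the ground-truth manifest to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = "edf" if eeg_format == "edf" else "tsv"
    for eeg, (env1, env2), meta in ds.trials:
        write_eeg(eeg, out / f"{meta.trial_id}_eeg.{suffix}", format=eeg_format)
        write_envelope(env1, out / f"{meta.trial_id}_speaker1.tsv")
        write_envelope(env2, out / f"{meta.trial_id}_speaker2.tsv")
    write_metadata([m for _, _, m in ds.trials], out / "manifest.tsv")


def read_dataset(in_dir: str | Path,
                 config: ExperimentConfig | None = None) -> SyntheticDataset:
    """Read a dataset written by write_dataset back into memory."""
    from .core_io import read_eeg, read_envelope, read_metadata

    config = config or ExperimentConfig()
    in_dir = Path(in_dir)
    metas = read_metadata(in_dir / "manifest.tsv")
    trials = []
    for meta in metas:
        edf = in_dir / f"{meta.trial_id}_eeg.edf"
        tsv = in_dir / f"{meta.trial_id}_eeg.tsv"
        eeg = read_eeg(edf) if edf.exists() else read_eeg(tsv)
        env1 = read_envelope(in_dir / f"{meta.trial_id}_speaker1.tsv")
        env2 = read_envelope(in_dir / f"{meta.trial_id}_speaker2.tsv")
        trials.append((eeg, (env1, env2), meta))
    dummy = ForwardModel(trf=np.zeros((1, 1)), trf_unattended=np.zeros((1, 1)))
    return SyntheticDataset(trials=trials, model=dummy, config=config)
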