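"""Domain types, file I/O and configuration shared by every pipeline stage.

The on-disk formats are deliberately plain: EDF or tab-separated tables for
EEG, WAV for audio, single-column TSV for speech envelopes, and TSV for trial
metadata and per-window results.  Tables carry a small ``#``-prefixed sidecar
header (sampling rate, channel labels, reference) so a file is
self-describing without a companion file.

Conventions used throughout the package: user-facing times are in seconds;
internal sample indices are 0-based with half-open ranges.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class AADError(Exception):
    """Base class for all package errors."""


class FormatError(AADError):
    """A file could not be parsed (missing/garbled header, bad encoding)."""


class IngestError(AADError):
    """Parsed data violates an invariant (NaN values, label/row mismatch)."""


class ParameterError(AADError):
    """An argument is outside its valid domain."""


class DegenerateSignalError(AADError):
    """A signal has zero variance where standardization is required."""


class BufferUnderrunError(AADError):
    """A streaming buffer holds fewer samples than one analysis window."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

#: Reference states an EEG trial can be in.
RECORDING_REFERENCE = "recording-reference"
COMMON_AVERAGE = "common-average"

#: The 15 scalp sites (10/20 system) used by the acquisition setup.
DEFAULT_CHANNELS = (
    "Fz", "Cz", "C3", "C4", "P7", "P8", "Pz", "F7",
    "F8", "F3", "F4", "T7", "T8", "P3", "P4",
)


@dataclass
class EEGTrial:
    """Multichannel EEG for one trial: ``data`` is channels x samples."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    reference: str = RECORDING_REFERENCE
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise IngestError("EEG data must be a 2-D channels x samples array")
        if self.data.shape[0] != len(self.channel_labels):
            raise IngestError(
                f"{len(self.channel_labels)} channel labels but "
                f"{self.data.shape[0]} data rows"
            )
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            bad = [
                lab for lab, row in zip(self.channel_labels, self.data)
                if not np.all(np.isfinite(row))
            ]
            raise IngestError(f"non-finite values in channel(s): {', '.join(bad)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Envelope:
    """A speech amplitude envelope at a single rate."""

    values: np.ndarray
    fs: float
    standardized: bool = False
    speaker_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        if self.standardized:
            if abs(self.values.mean()) > 1e-6 or abs(self.values.std() - 1.0) > 1e-6:
                raise IngestError("envelope flagged standardized but is not z-scored")

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fs


@dataclass
class TrialMetadata:
    """Ground-truth labels for one trial of the dichotic-listening task."""

    trial_id: str
    attended_speaker: int
    attended_side_initial: str
    kind: str  # "fixed" | "switching"
    duration_s: float
    switch_time_s: float | None = None

    def __post_init__(self) -> None:
        if self.attended_speaker not in (1, 2):
            raise ParameterError("attended_speaker must be 1 or 2")
        if self.attended_side_initial not in ("left", "right"):
            raise ParameterError("attended_side_initial must be 'left' or 'right'")
        if self.kind not in ("fixed", "switching"):
            raise ParameterError("kind must be 'fixed' or 'switching'")
        if self.kind == "switching":
            if self.switch_time_s is None:
                raise ParameterError("switching trial requires switch_time_s")
            if not (0 < self.switch_time_s < self.duration_s):
                raise ParameterError("switch_time_s must lie inside the trial")
        elif self.switch_time_s is not None:
            raise ParameterError("fixed trial must not carry a switch_time_s")


@dataclass
class ExperimentConfig:
    """All tunable parameters of the decoding pipeline.

    Defaults reproduce the experiment's settings: 125 Hz acquisition,
    common-average reference, 0.5-8 Hz passband, 64 Hz analysis rate, ridge
    penalty lambda = 10 on 0-250 ms lags, 15-s windows advanced by 1 s after
    an initial 15-s buffer, and EMA smoothing with alpha = 0.1.
    """

    passband_hz: tuple[float, float] = (0.5, 8.0)
    fs_acq: float = 125.0
    fs_proc: float = 64.0
    lambda_reg: float = 10.0
    lag_range_ms: tuple[float, float] = (0.0, 250.0)
    window_s: float = 15.0
    step_s: float = 1.0
    buffer_s: float = 15.0
    ema_alpha: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.passband_hz
        if not (0 < low < high):
            raise ParameterError("passband must satisfy 0 < low < high")
        if self.lag_range_ms[0] < 0 or self.lag_range_ms[1] < self.lag_range_ms[0]:
            raise ParameterError("lag range must be non-negative and ordered")
        if not (self.window_s >= self.step_s > 0):
            raise ParameterError("need window_s >= step_s > 0")


# ---------------------------------------------------------------------------
# EEG tables (TSV with '#' sidecar header)
# ---------------------------------------------------------------------------

def write_eeg_table(trial: EEGTrial, path: str | os.PathLike) -> None:
    """Write one trial as a TSV: one row per channel, '#' header lines."""
    with open(path, "w") as fh:
        fh.write(f"# fs={trial.fs!r}\n")
        fh.write(f"# labels={','.join(trial.channel_labels)}\n")
        fh.write(f"# reference={trial.reference}\n")
        fh.write(f"# trial_id={trial.trial_id}\n")
        # %.17g round-trips IEEE doubles exactly
        np.savetxt(fh, trial.data, delimiter="\t", fmt="%.17g")


def _parse_sidecar(path: str | os.PathLike) -> tuple[dict[str, str], int]:
    header: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" not in body:
                raise FormatError(f"malformed header line in {path}: {line.strip()!r}")
            key, _, value = body.partition("=")
            header[key.strip()] = value.strip()
    return header, n_header


def read_eeg_table(path: str | os.PathLike) -> EEGTrial:
    header, n_header = _parse_sidecar(path)
    for key in ("fs", "labels"):
        if key not in header:
            raise FormatError(f"EEG table {path} missing '# {key}=' header")
    try:
        fs = float(header["fs"])
    except ValueError as exc:
        raise FormatError(f"unparseable fs in {path}") from exc
    labels = tuple(s for s in header["labels"].split(",") if s)
    try:
        data = pd.read_csv(path, sep="\t", skiprows=n_header, header=None,
                           dtype=float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"unparseable numeric data in {path}: {exc}") from exc
    return EEGTrial(
        data=data,
        fs=fs,
        channel_labels=labels,
        reference=header.get("reference", RECORDING_REFERENCE),
        trial_id=header.get("trial_id", ""),
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def write_eeg_edf(trial: EEGTrial, path: str | os.PathLike) -> None:
    """Write one trial as a minimal EDF file (16-bit, one data record).

    The whole trial is stored as a single data record, which keeps the
    writer exact for any trial length (no padding).  Amplitudes are scaled
    per channel to the full 16-bit digital range, so the quantization step
    is (max - min) / 65535 in the channel's own units (microvolts).
    """
    data = trial.data
    nch, nsamp = data.shape
    rec_dur = nsamp / trial.fs
    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    span = np.where(phys_max > phys_min, phys_max - phys_min, 1.0)
    dig_min, dig_max = -32768, 32767
    dig = np.round(
        (data - phys_min[:, None]) / span[:, None] * (dig_max - dig_min) + dig_min
    ).astype("<i2")
    # channels with zero span map to dig_min; reader restores phys_min exactly
    flat = np.where((phys_max == phys_min)[:, None], dig_min, dig)

    def f(s: str, w: int) -> bytes:
        b = s.encode("ascii")[:w]
        return b.ljust(w)

    labels = trial.channel_labels
    hdr = b"".join([
        f("0", 8), f("X", 80), f(f"trial_id={trial.trial_id}", 80),
        f("01.01.00", 8), f("00.00.00", 8),
        f(str(256 + 256 * nch), 8), f("", 44),
        f("1", 8),                         # number of data records
        f(f"{rec_dur:.6f}".rstrip("0").rstrip(".")[:8], 8),
        f(str(nch), 4),
        b"".join(f(l, 16) for l in labels),
        b"".join(f("", 80) for _ in labels),      # transducer
        b"".join(f("uV", 8) for _ in labels),
        b"".join(f(f"{v:.6g}", 8) for v in phys_min),
        b"".join(f(f"{v:.6g}", 8) for v in
                 np.where(phys_max > phys_min, phys_max, phys_min + 1.0)),
        b"".join(f(str(dig_min), 8) for _ in labels),
        b"".join(f(str(dig_max), 8) for _ in labels),
        b"".join(f("", 80) for _ in labels),      # prefiltering
        b"".join(f(str(nsamp), 8) for _ in labels),
        b"".join(f("", 32) for _ in labels),
    ])
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(np.asarray(flat, dtype="<i2").tobytes())


def read_eeg_edf(path: str | os.PathLike) -> EEGTrial:
    """Read an EDF file through mne; amplitudes are returned in microvolts."""
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises plain ValueError/OSError on bad files
        raise FormatError(f"could not parse EDF file {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # mne rescales 'uV' physical dimension to volts
    trial_id = ""
    # recover trial_id stashed in the recording-id header field
    with open(path, "rb") as fh:
        rec_id = fh.read(256)[88:168].decode("ascii", "replace").strip()
    if rec_id.startswith("trial_id="):
        trial_id = rec_id[len("trial_id="):]
    return EEGTrial(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        reference=RECORDING_REFERENCE,
        trial_id=trial_id,
    )


def read_eeg(path: str | os.PathLike, format: str | None = None) -> EEGTrial:
    """Read an EEG trial from EDF or a '#'-headed TSV table.

    The format is inferred from the file suffix when not given.
    """
    if format is None:
        format = "edf" if str(path).lower().endswith(".edf") else "table"
    if format == "edf":
        return read_eeg_edf(path)
    if format == "table":
        return read_eeg_table(path)
    raise ParameterError(f"unknown EEG format {format!r}")


def write_eeg(trial: EEGTrial, path: str | os.PathLike,
              format: str | None = None) -> None:
    if format is None:
        format = "edf" if str(path).lower().endswith(".edf") else "table"
    if format == "edf":
        write_eeg_edf(trial, path)
    elif format == "table":
        write_eeg_table(trial, path)
    else:
        raise ParameterError(f"unknown EEG format {format!r}")


# ---------------------------------------------------------------------------
# Audio
# ---------------------------------------------------------------------------

def read_audio(path: str | os.PathLike) -> tuple[np.ndarray, float]:
    """Read a WAV file as float waveform(s) in [-1, 1] at native rate.

    Mono returns shape (n,), stereo returns shape (2, n) with row 0 the left
    ear (= the speaker presented on the left in the dichotic paradigm).
    """
    from scipy.io import wavfile

    try:
        fs, data = wavfile.read(path)
    except Exception as exc:
        raise FormatError(f"could not parse WAV file {path}: {exc}") from exc
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":  # 8-bit WAV is unsigned
        info = np.iinfo(data.dtype)
        data = (data.astype(float) - (info.max + 1) / 2) / ((info.max + 1) / 2)
    else:
        data = data.astype(float)
    if data.ndim == 2:  # scipy gives samples x channels
        data = data.T
    return data, float(fs)


def write_audio(waveform: np.ndarray, fs: float, path: str | os.PathLike) -> None:
    """Write float waveform(s) to WAV (float32); stereo rows = (left, right)."""
    from scipy.io import wavfile

    w = np.asarray(waveform, dtype=np.float32)
    if w.ndim == 2:
        w = w.T
    wavfile.write(path, int(round(fs)), w)


# ---------------------------------------------------------------------------
# Envelopes, metadata, results
# ---------------------------------------------------------------------------

def write_envelope(env: Envelope, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={env.fs!r}\n")
        fh.write(f"# speaker_id={env.speaker_id}\n")
        fh.write(f"# standardized={env.standardized}\n")
        np.savetxt(fh, env.values, fmt="%.17g")


def read_envelope(path: str | os.PathLike) -> Envelope:
    header, n_header = _parse_sidecar(path)
    if "fs" not in header:
        raise FormatError(f"envelope file {path} missing '# fs=' header")
    values = np.loadtxt(path, skiprows=n_header, ndmin=1)
    return Envelope(
        values=values,
        fs=float(header["fs"]),
        standardized=header.get("standardized", "False") == "True",
        speaker_id=header.get("speaker_id", ""),
    )


_META_COLUMNS = ["trial_id", "attended_speaker", "attended_side_initial",
                 "kind", "switch_time_s", "duration_s"]


def write_metadata(metadata: Sequence[TrialMetadata],
                   path: str | os.PathLike) -> None:
    rows = []
    for m in metadata:
        rows.append({
            "trial_id": m.trial_id,
            "attended_speaker": m.attended_speaker,
            "attended_side_initial": m.attended_side_initial,
            "kind": m.kind,
            "switch_time_s": "" if m.switch_time_s is None else m.switch_time_s,
            "duration_s": m.duration_s,
        })
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | os.PathLike) -> list[TrialMetadata]:
    df = pd.read_csv(path, sep="\t", dtype={"trial_id": str})
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"metadata table {path} missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        st = row["switch_time_s"]
        out.append(TrialMetadata(
            trial_id=str(row["trial_id"]),
            attended_speaker=int(row["attended_speaker"]),
            attended_side_initial=str(row["attended_side_initial"]),
            kind=str(row["kind"]),
            duration_s=float(row["duration_s"]),
            switch_time_s=None if pd.isna(st) or st == "" else float(st),
        ))
    return out


#: Column schema for per-window result tables.
RESULT_COLUMNS = ["trial_id", "window_index", "window_end_s",
                  "r1_raw", "r2_raw", "r1_ema", "r2_ema", "decision", "correct"]


def write_results(records: Sequence[dict], path: str | os.PathLike) -> None:
    """Write per-window decoding records as a TSV with a fixed column schema."""
    if not records:
        raise ParameterError("no records to write")
    df = pd.DataFrame(list(records))
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ParameterError(f"records missing fields {sorted(missing)}")
    df = df[RESULT_COLUMNS]
    float_cols = ["window_end_s", "r1_raw", "r2_raw", "r1_ema", "r2_ema"]
    df = df.copy()
    for c in float_cols:
        df[c] = df[c].map(lambda v: repr(float(v)))
    df.to_csv(path, sep="\t", index=False)


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"trial_id": str})
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"results table {path} missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Config files (flat key=value text)
# ---------------------------------------------------------------------------

def read_config(path: str | os.PathLike) -> ExperimentConfig:
    """Read a flat ``key = value`` config file mirroring ExperimentConfig."""
    kwargs: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"malformed config line: {line!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in ("passband_hz", "lag_range_ms"):
                parts = [float(p) for p in value.replace(",", " ").split()]
                if len(parts) != 2:
                    raise FormatError(f"{key} needs two numbers, got {value!r}")
                kwargs[key] = (parts[0], parts[1])
            elif key == "seed":
                kwargs[key] = int(value)
            elif key in ExperimentConfig.__dataclass_fields__:
                kwargs[key] = float(value)
            else:
                raise FormatError(f"unknown config key {key!r}")
    return ExperimentConfig(**kwargs)


def write_config(config: ExperimentConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name in ExperimentConfig.__dataclass_fields__:
            value = getattr(config, name)
            if isinstance(value, tuple):
                value = f"{value[0]},{value[1]}"
            fh.write(f"{name} = {value}\n")
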