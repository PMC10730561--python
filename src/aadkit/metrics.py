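"""Accuracy summaries, binomial chance levels, and switch sensitivity.

Chance level follows the inverse-CDF convention: the bound is 100 k*/n where
k* is the smallest integer with P(X <= k*) >= 0.95 under Binomial(n, p0).
This reproduces the two-alternative bound 65.38% (17/26 at p0 = 0.5) and the
four-alternative behavioral bound 35% (21/60 at p0 = 0.25).

Temporal sensitivity measures how quickly decoding becomes reliably correct
again after the attended side switches mid-trial.  It scans the raw
(un-smoothed) per-window correctness sequence after the switch for the first
run of at least 5 consecutive correct 1-s windows, and reports the time from
the switch to the start of that run; if no such run occurs the time is
capped at the remaining trial duration (30 s for a mid-trial switch in a
one-minute trial).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import ParameterError
from .realtime_decoder import CorrelationTrace


@dataclass
class SensitivityResult:
    """Post-switch recovery time for one location-switching trial."""

    trial_id: str
    response_time_s: float
    capped: bool
    cap_value_s: float


def binomial_chance_level(n: int, p0: float, level: float = 0.95) -> float:
    """Upper chance bound in percent under a binomial null.

    Returns 100 k*/n with k* the smallest integer whose cumulative binomial
    probability reaches ``level``; accuracies strictly above the bound are
    significant at 1 - level.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not (0 < p0 < 1):
        raise ParameterError("p0 must be in (0, 1)")
    if not (0 < level < 1):
        raise ParameterError("level must be in (0, 1)")
    k_star = int(stats.binom.ppf(level, n, p0))
    return 100.0 * k_star / n


def temporal_sensitivity(trace: CorrelationTrace, switch_time_s: float,
                         persistence_s: float = 5.0,
                         cap_s: float | None = None) -> SensitivityResult:
    """Time from the attention switch until decoding is correct for a
    sustained run.

    Correctness here uses the raw correlations (r_attended > r_unattended,
    no EMA).  A decoding outcome counts as genuine only when it stays correct
    for at least ``persistence_s`` consecutive windows; the response time is
    measured from the switch to the start of the first such run, in whole
    windows (1-s resolution at the default step).  Without a qualifying run
    the response time equals the full post-switch duration and is flagged
    capped.
    """
    if trace.metadata is not None:
        attended = trace.metadata.attended_speaker
    else:
        attended = 1
    end_times = np.asarray(trace.window_end_s, dtype=float)
    if switch_time_s <= 0 or switch_time_s >= end_times[-1]:
        raise ParameterError("switch time must lie inside the trial")
    post = end_times > switch_time_s
    if not post.any():
        raise ParameterError("trace has no windows past the switch")

    r_att = trace.r1_raw if attended == 1 else trace.r2_raw
    r_unatt = trace.r2_raw if attended == 1 else trace.r1_raw
    with np.errstate(invalid="ignore"):
        ok = np.nan_to_num(r_att, nan=-np.inf) > np.nan_to_num(r_unatt, nan=-np.inf)
    ok = ok[post]

    step = float(trace.window_end_s[1] - trace.window_end_s[0]) \
        if len(end_times) > 1 else 1.0
    need = int(np.ceil(persistence_s / step))
    cap = cap_s if cap_s is not None else len(ok) * step

    run = 0
    for k, good in enumerate(ok):
        run = run + 1 if good else 0
        if run >= need:
            start_idx = k - need + 1
            return SensitivityResult(
                trial_id=trace.trial_id,
                response_time_s=(start_idx + 1) * step,
                capped=False, cap_value_s=cap,
            )
    # a correct tail shorter than the persistence requirement does not qualify
    return SensitivityResult(trial_id=trace.trial_id, response_time_s=cap,
                             capped=True, cap_value_s=cap)


def summarize(values: Sequence[float]) -> dict:
    """Mean +/- standard error of the mean (sd/sqrt(n), sample sd)."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ParameterError("nothing to summarize")
    n = values.size
    sem = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return {"mean": float(values.mean()), "sem": sem, "n": int(n)}
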