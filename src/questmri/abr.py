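"""Auditory brainstem response (ABR) threshold calling.

An ABR recording is a trial-averaged evoked potential for one
(subject, ear, frequency, sound level).  Hearing threshold at a frequency is
the minimum sound level at which wave 1 (the auditory-nerve deflection at a
fixed post-stimulus latency) is still elicited, probed with levels descending
from 100 dB SPL in 5 or 10 dB steps.  Presence of wave 1 is decided by a
peak-to-trough amplitude criterion relative to the pre-stimulus baseline RMS.

Tested frequencies map onto cochlear place: 4 and 12 kHz probe the apex,
20 and 25 kHz the middle turn, 36 kHz the base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Frequency (kHz) -> cochlear region.
FREQUENCY_REGION = {4: "apex", 12: "apex", 20: "middle", 25: "middle", 36: "base"}

#: Default timing (ms): stimulus onset, wave-1 search window, baseline segment.
STIMULUS_ONSET_MS = 10.0
WAVE1_WINDOW_MS = (11.6, 12.6)
BASELINE_WINDOW_MS = (0.0, 10.0)


@dataclass
class EvokedRecording:
    """Trial-averaged waveform for one (subject, ear, frequency, level)."""

    subject: str
    ear: str
    frequency_khz: float
    level_db: float
    waveform: np.ndarray        # microvolts
    sample_rate_hz: float
    n_trials: int = 1024

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if not np.all(np.isfinite(self.waveform)):
            raise ValueError("waveform must be finite")
        if self.level_db > 100:
            raise ValueError("sound levels above 100 dB SPL are not tested")

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.waveform.size) / self.sample_rate_hz * 1000.0


@dataclass
class ThresholdCall:
    """Outcome of threshold calling for one (subject, ear, frequency)."""

    threshold_db: float | None
    censored: bool
    flags: tuple[str, ...] = ()


def detect_wave1(rec: EvokedRecording, criterion_k: float = 3.0,
                 wave1_window_ms: tuple[float, float] = WAVE1_WINDOW_MS,
                 baseline_window_ms: tuple[float, float] = BASELINE_WINDOW_MS):
    """Decide whether a wave-1 response is present in one recording.

    Present iff the peak-to-trough amplitude inside the wave-1 latency window
    is at least ``criterion_k`` times the baseline RMS (and nonzero, so a
    silent noiseless trace is never called present).

    Returns ``(present, amplitude_uv, latency_ms)`` where latency is the time
    of the in-window peak.
    """
    t = rec.time_ms
    in_window = (t >= wave1_window_ms[0]) & (t <= wave1_window_ms[1])
    in_base = (t >= baseline_window_ms[0]) & (t < baseline_window_ms[1])
    if not in_window.any():
        raise ValueError("wave-1 window lies outside the recorded extent")
    if not in_base.any():
        raise ValueError("baseline window lies outside the recorded extent")
    segment = rec.waveform[in_window]
    baseline_rms = float(np.sqrt(np.mean(rec.waveform[in_base] ** 2)))
    amplitude = float(segment.max() - segment.min())
    latency = float(t[in_window][np.argmax(segment)])
    present = amplitude > 0 and amplitude >= criterion_k * baseline_rms
    return present, amplitude, latency


def call_threshold(recordings, criterion_k: float = 3.0) -> ThresholdCall:
    """Call the hearing threshold from a descending-level series of recordings.

    The threshold is the minimum tested level at which wave 1 is present with
    all higher tested levels also present.  If presence is non-monotone
    (a response missing above a level where one was found), the call is
    flagged and taken from the longest contiguous present-run, preferring the
    run nearest the top of the level sweep.  All-absent series are censored;
    all-present series return the lowest tested level with a "floor" flag.
    """
    recs = sorted(recordings, key=lambda r: -r.level_db)
    if not recs:
        raise ValueError("no recordings supplied")
    levels = np.array([r.level_db for r in recs])
    if np.any(np.diff(levels) >= 0):
        raise ValueError("levels must be strictly descending")
    present = np.array([detect_wave1(r, criterion_k)[0] for r in recs])

    flags: list[str] = []
    if not present.any():
        return ThresholdCall(None, True, ())

    # contiguous runs of present, top (highest level) first
    runs: list[tuple[int, int]] = []
    i = 0
    while i < present.size:
        if present[i]:
            j = i
            while j + 1 < present.size and present[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    if len(runs) > 1 or runs[0][0] != 0:
        flags.append("nonmonotone")
    best = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
    threshold = float(levels[best[1]])
    if present.all():
        flags.append("floor")
    return ThresholdCall(threshold, False, tuple(flags))


def build_threshold_table(recordings, criterion_k: float = 3.0) -> pd.DataFrame:
    """Group recordings by (subject, ear, frequency) and call each threshold."""
    by_key: dict[tuple, list[EvokedRecording]] = {}
    for rec in recordings:
        by_key.setdefault((rec.subject, rec.ear, rec.frequency_khz), []).append(rec)
    rows = []
    for (subject, ear, freq), recs in sorted(by_key.items()):
        call = call_threshold(recs, criterion_k)
        rows.append({
            "subject": subject, "ear": ear, "frequency_khz": freq,
            "threshold_db": np.nan if call.censored else call.threshold_db,
            "censored": call.censored, "flags": ";".join(call.flags),
        })
    return pd.DataFrame(rows)


def threshold_shift(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Per-(subject, ear, frequency) threshold shift in dB (post minus pre).

    A censored post-exposure threshold yields a censored shift bounded below
    by ``100 - pre`` (the shift exceeded the top of the tested range).
    """
    keys = ["subject", "ear", "frequency_khz"]
    merged = pre.merge(post, on=keys, how="outer", suffixes=("_pre", "_post"),
                       indicator=True)
    bad = merged[merged["_merge"] != "both"]
    if len(bad):
        missing = bad[keys].to_dict("records")
        raise KeyError(f"pre/post key mismatch for: {missing}")
    shift = merged["threshold_db_post"] - merged["threshold_db_pre"]
    censored = merged["censored_post"].astype(bool)
    shift = shift.where(~censored, 100.0 - merged["threshold_db_pre"])
    out = merged[keys].copy()
    out["shift_db"] = shift
    out["censored"] = censored.to_numpy()
    out["region"] = [region_of(f) for f in out["frequency_khz"]]
    return out


def region_of(frequency_khz: float) -> str:
    """Map a tested frequency to its cochlear region (apex/middle/base)."""
    key = int(frequency_khz) if float(frequency_khz).is_integer() else frequency_khz
    try:
        return FREQUENCY_REGION[key]
    except KeyError:
        raise ValueError(
            f"frequency {frequency_khz} kHz is not in the tested set "
            f"{sorted(FREQUENCY_REGION)}"
        ) from None


def region_mean_shifts(shifts: pd.DataFrame) -> pd.DataFrame:
    """Mean and SEM of the threshold shift per cochlear region."""
    grouped = shifts.groupby("region")["shift_db"]
    out = grouped.agg(mean_shift_db="mean", n="count",
                      sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)))
    return out.reset_index()


# CSV interchange (long format: one sample per row) -------------------------

def recordings_to_csv(recordings, path) -> None:
    frames = []
    for rec in recordings:
        frames.append(pd.DataFrame({
            "subject": rec.subject, "ear": rec.ear,
            "frequency_khz": rec.frequency_khz, "level_db": rec.level_db,
            "sample_index": np.arange(rec.waveform.size),
            "microvolts": rec.waveform,
            "sample_rate_hz": rec.sample_rate_hz, "n_trials": rec.n_trials,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def recordings_from_csv(path) -> list[EvokedRecording]:
    table = pd.read_csv(path)
    recs = []
    keys = ["subject", "ear", "frequency_khz", "level_db"]
    for key, grp in table.groupby(keys, sort=True):
        grp = grp.sort_values("sample_index")
        recs.append(EvokedRecording(
            subject=str(key[0]), ear=str(key[1]), frequency_khz=float(key[2]),
            level_db=float(key[3]), waveform=grp["microvolts"].to_numpy(),
            sample_rate_hz=float(grp["sample_rate_hz"].iloc[0]),
            n_trials=int(grp["n_trials"].iloc[0]),
        ))
    return recs
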