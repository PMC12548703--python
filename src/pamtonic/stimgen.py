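"""Dichotic stimulus synthesis and sequence generation.

Two brief stimuli compete for attention in a dichotic oddball paradigm: an
800 Hz tone burst (50 ms, 12 ms Hanning rise/fall) in one ear and a short
rising "chirp" (logarithmic frequency sweep, 100 Hz to 9,800 Hz over
14.9 ms, unwindowed) in the other.  Events are assigned to the two ears at
random with onset-to-onset inter-stimulus intervals drawn uniformly from
250-400 ms, and each ear's stream carries infrequent deviant (target)
stimuli attenuated by 15 dB that recur every 3-20 events.

The analysis "time-zero" of each stimulus is the point that triggers the
short-latency PAM reflex: the chirp offset (its highest-frequency
component) for chirps, and the end of the rise time for tone bursts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import chirp as _sweep

__all__ = [
    "StimulusWaveform",
    "SequenceEvent",
    "SequenceSpec",
    "DichoticSequence",
    "make_tone_burst",
    "make_chirp",
    "make_waveform",
    "generate_sequence",
    "render_sequence",
    "write_wav",
    "TONE_BURST",
    "CHIRP",
]

TONE_BURST = "tone_burst"
CHIRP = "chirp"
EARS = ("left", "right")

TONE_FREQ_HZ = 800.0
TONE_DURATION_MS = 50.0
TONE_RISE_MS = 12.0
CHIRP_F0_HZ = 100.0
CHIRP_F1_HZ = 9_800.0
CHIRP_DURATION_MS = 14.9
DEVIANT_LEVEL_DB = -15.0


@dataclass(frozen=True)
class StimulusWaveform:
    """A peak-normalized stimulus waveform with its reflex time-zero offset."""

    samples: np.ndarray
    rate: float
    kind: str
    duration_ms: float
    timezero_offset_ms: float

    def __post_init__(self) -> None:
        n_expected = int(round(self.duration_ms / 1000.0 * self.rate))
        if len(self.samples) != n_expected:
            raise ValueError(
                f"waveform length {len(self.samples)} != round(duration*rate)={n_expected}"
            )
        if not (0.0 <= self.timezero_offset_ms <= self.duration_ms):
            raise ValueError("timezero_offset_ms outside [0, duration_ms]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return self.duration_ms / 1000.0


def make_tone_burst(rate: float) -> StimulusWaveform:
    """Synthesize the 800 Hz, 50 ms tone burst.

    The first and last 12 ms are weighted by the rising and falling halves
    of a 24 ms Hanning window; the plateau is an unwindowed sinusoid.
    Time-zero sits at the end of the rise time (12 ms), where the burst
    first reaches full amplitude.
    """
    if rate < 2 * TONE_FREQ_HZ:
        raise ValueError(
            f"rate {rate} Hz aliases the {TONE_FREQ_HZ} Hz carrier (need >= {2 * TONE_FREQ_HZ})"
        )
    n = int(round(TONE_DURATION_MS / 1000.0 * rate))
    t = np.arange(n) / rate
    x = np.sin(2.0 * np.pi * TONE_FREQ_HZ * t)
    n_rise = int(round(TONE_RISE_MS / 1000.0 * rate))
    win = np.hanning(2 * n_rise)
    x[:n_rise] *= win[:n_rise]
    x[-n_rise:] *= win[-n_rise:]
    x /= np.max(np.abs(x))
    return StimulusWaveform(x, rate, TONE_BURST, TONE_DURATION_MS, TONE_RISE_MS)


def make_chirp(rate: float) -> StimulusWaveform:
    """Synthesize the 14.9 ms rising chirp (100 Hz -> 9,800 Hz).

    The instantaneous frequency rises exponentially in time (logarithmic
    sweep); the waveform is left unwindowed.  Time-zero is the chirp
    offset, where the sweep reaches its highest frequency.
    """
    if rate < 2 * CHIRP_F1_HZ:
        raise ValueError(
            f"rate {rate} Hz aliases the {CHIRP_F1_HZ} Hz sweep endpoint (need >= {2 * CHIRP_F1_HZ})"
        )
    dur_s = CHIRP_DURATION_MS / 1000.0
    n = int(round(CHIRP_DURATION_MS / 1000.0 * rate))
    t = np.arange(n) / rate
    # phi=-90 starts the sweep at zero amplitude (sine phase)
    x = _sweep(t, f0=CHIRP_F0_HZ, t1=dur_s, f1=CHIRP_F1_HZ, method="logarithmic", phi=-90)
    x /= np.max(np.abs(x))
    return StimulusWaveform(x, rate, CHIRP, CHIRP_DURATION_MS, CHIRP_DURATION_MS)


def make_waveform(kind: str, rate: float) -> StimulusWaveform:
    if kind == TONE_BURST:
        return make_tone_burst(rate)
    if kind == CHIRP:
        return make_chirp(rate)
    raise ValueError(f"unknown stimulus kind {kind!r}")


def timezero_offset_s(kind: str) -> float:
    """Latency from stimulus onset to the reflex-triggering time-zero."""
    if kind == TONE_BURST:
        return TONE_RISE_MS / 1000.0
    if kind == CHIRP:
        return CHIRP_DURATION_MS / 1000.0
    raise ValueError(f"unknown stimulus kind {kind!r}")


def stimulus_duration_s(kind: str) -> float:
    if kind == TONE_BURST:
        return TONE_DURATION_MS / 1000.0
    if kind == CHIRP:
        return CHIRP_DURATION_MS / 1000.0
    raise ValueError(f"unknown stimulus kind {kind!r}")


@dataclass(frozen=True)
class SequenceEvent:
    """One stimulus event of a dichotic sequence."""

    onset_s: float
    ear: str
    kind: str
    is_deviant: bool
    level_db_re_standard: float


@dataclass(frozen=True)
class SequenceSpec:
    """Parameters of one dichotic stimulation sequence."""

    n_events: int = 600
    isi_range_s: tuple[float, float] = (0.250, 0.400)
    deviant_gap_range: tuple[int, int] = (3, 20)
    tone_ear: str = "left"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        if self.isi_range_s[0] > self.isi_range_s[1]:
            raise ValueError("isi_range_s min > max")
        if not (1 <= self.deviant_gap_range[0] <= self.deviant_gap_range[1] <= self.n_events):
            raise ValueError("deviant_gap_range must lie within [1, n_events]")
        if self.tone_ear not in EARS:
            raise ValueError(f"tone_ear must be one of {EARS}")

    @property
    def chirp_ear(self) -> str:
        return "right" if self.tone_ear == "left" else "left"


@dataclass(frozen=True)
class DichoticSequence:
    """A timed dichotic event list plus the spec it was generated from."""

    events: tuple[SequenceEvent, ...]
    spec: SequenceSpec

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def first_onset_s(self) -> float:
        return self.events[0].onset_s if self.events else 0.0

    @property
    def duration_s(self) -> float:
        """First event onset to last event offset."""
        if not self.events:
            return 0.0
        last = self.events[-1]
        return last.onset_s + stimulus_duration_s(last.kind) - self.first_onset_s

    def ear_count(self, ear: str) -> int:
        return sum(1 for e in self.events if e.ear == ear)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [e.onset_s for e in self.events],
                "ear": [e.ear for e in self.events],
                "kind": [e.kind for e in self.events],
                "is_deviant": [e.is_deviant for e in self.events],
                "level_db": [e.level_db_re_standard for e in self.events],
            }
        )


def _deviant_positions(rng: np.random.Generator, n_in_ear: int, gap_range: tuple[int, int]) -> set[int]:
    """0-based indices (within one ear's stream) of deviant events.

    Inter-deviant gaps, counting the deviant itself, are uniform integers on
    the closed gap range; the first deviant falls after an initial gap from
    the same distribution.
    """
    lo, hi = gap_range
    positions: set[int] = set()
    pos = 0
    while True:
        pos += int(rng.integers(lo, hi + 1))
        if pos > n_in_ear:
            break
        positions.add(pos - 1)
    return positions


def generate_sequence(spec: SequenceSpec) -> DichoticSequence:
    """Generate one randomized dichotic sequence, deterministic in the seed.

    Ears are assigned i.i.d. equiprobably, inter-stimulus intervals
    (onset-to-onset) are i.i.d. uniform on the ISI range, and deviants are
    placed per ear with uniform integer inter-deviant gaps.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events
    ear_idx = rng.integers(0, 2, size=n)
    isis = rng.uniform(spec.isi_range_s[0], spec.isi_range_s[1], size=max(n - 1, 0))
    onsets = np.concatenate([[0.0], np.cumsum(isis)])

    events: list[SequenceEvent | None] = [None] * n
    for ei, ear in enumerate(EARS):
        stream = np.flatnonzero(ear_idx == ei)
        deviants = _deviant_positions(rng, len(stream), spec.deviant_gap_range)
        if len(stream) < spec.deviant_gap_range[0]:
            warnings.warn(
                f"ear {ear!r} received {len(stream)} events, fewer than the minimum "
                f"deviant gap {spec.deviant_gap_range[0]}; it carries no deviants",
                stacklevel=2,
            )
        kind = TONE_BURST if ear == spec.tone_ear else CHIRP
        for within_pos, global_pos in enumerate(stream):
            dev = within_pos in deviants
            events[global_pos] = SequenceEvent(
                onset_s=float(onsets[global_pos]),
                ear=ear,
                kind=kind,
                is_deviant=dev,
                level_db_re_standard=DEVIANT_LEVEL_DB if dev else 0.0,
            )
    return DichoticSequence(events=tuple(events), spec=spec)  # type: ignore[arg-type]


def render_sequence(
    seq: DichoticSequence, rate: float
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a sequence to a two-channel waveform and a sample-accurate log.

    Channel 0 is the left ear, channel 1 the right.  Deviants are scaled by
    ``10**(-15/20)``.  Same-ear waveform overlap is impossible at the
    paradigm's minimum ISI and is treated as an internal consistency error.
    """
    waveforms = {
        kind: make_waveform(kind, rate)
        for kind in {e.kind for e in seq.events}
    }
    if seq.n_events == 0:
        return np.zeros((int(rate), 2)), pd.DataFrame(
            columns=["onset_s", "onset_sample", "ear", "kind", "is_deviant", "level_db"]
        )

    for ear in EARS:
        onsets = np.array([e.onset_s for e in seq.events if e.ear == ear])
        if len(onsets) >= 2:
            durations = np.array(
                [stimulus_duration_s(e.kind) for e in seq.events if e.ear == ear]
            )
            if np.any(np.diff(onsets) < durations[:-1]):
                raise RuntimeError("internal consistency error: same-ear waveform overlap")

    last = seq.events[-1]
    n_total = int(np.ceil((last.onset_s + stimulus_duration_s(last.kind)) * rate)) + 1
    audio = np.zeros((n_total, 2))
    rows = []
    for e in seq.events:
        w = waveforms[e.kind]
        i0 = int(round(e.onset_s * rate))
        scale = 10.0 ** (e.level_db_re_standard / 20.0)
        audio[i0 : i0 + w.n_samples, 0 if e.ear == "left" else 1] += scale * w.samples
        rows.append(
            {
                "onset_s": e.onset_s,
                "onset_sample": i0,
                "ear": e.ear,
                "kind": e.kind,
                "is_deviant": e.is_deviant,
                "level_db": e.level_db_re_standard,
            }
        )
    return audio, pd.DataFrame(rows)


def write_wav(path, audio: np.ndarray, rate: float) -> None:
    """Write a rendered stereo waveform as 32-bit float WAV."""
    wavfile.write(path, int(rate), audio.astype(np.float32))
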