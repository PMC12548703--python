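"""Synthetic two-muscle EMG study generator with known ground truth.

Each posterior auricular muscle (PAM) is modelled as a latent band-limited
(20-500 Hz) Gaussian source whose instantaneous standard deviation is

    sigma(t) = background_rms * (1 + a * 1[attended == PAM side]) * exp(-t / tau)

i.e. a multiplicative ipsilateral attention gain ``a`` on the tonic
background, decaying exponentially over the listening trial.  Each
stimulus adds a short biphasic reflex deflection (difference of Gaussians)
peaking ``reflex_peak_ms`` after its time-zero, with lognormal per-trial
amplitude variability and an ipsilateral/contralateral drive asymmetry.

The latent source is split onto two unipolar electrodes with opposite
half-amplitude polarity plus shared common-mode noise and 50 Hz power-line
contamination with harmonics (mostly common-mode, with a small
differential fraction that survives the bipolar derivation).  Occasional
high-amplitude artifact bursts hit single electrodes.  Native acquisition
rate is 9,600 Hz so the downstream resampling stage is genuinely
exercised.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as sps

from .stimgen import (
    CHIRP,
    EARS,
    TONE_BURST,
    DichoticSequence,
    SequenceSpec,
    generate_sequence,
    timezero_offset_s,
)

__all__ = [
    "EmgModelParams",
    "Recording",
    "StudyGroundTruth",
    "TrialPlan",
    "simulate_trial",
    "simulate_study",
    "default_params_sampler",
    "save_recording",
    "load_recording",
    "CHANNEL_ROLES",
]

CHANNEL_ROLES = ("pam_left_1", "pam_left_2", "pam_right_1", "pam_right_2", "trigger")

# Fraction of the line-noise amplitude that differs between the two
# electrodes of a pair (and therefore survives the bipolar derivation).
LINE_DIFFERENTIAL_FRACTION = 0.2
LINE_N_HARMONICS = 4  # 50, 100, 150, 200 Hz with 1/k amplitudes


@dataclass(frozen=True)
class EmgModelParams:
    """Generative parameters of one participant's PAM recordings.

    Amplitudes are in arbitrary EMG units relative to ``background_rms``.
    The default chirp reflex is of the order of the tonic background: the
    single-trial reflex is small against ongoing EMG and becomes a
    high-SNR waveform only through averaging, which is what makes it a
    usable reliability and normalization anchor.  The tone-burst reflex
    is essentially absent: the burst's slow 12 ms rise fails to elicit
    the short-latency reflex, so tone-locked averages carry no reliable
    waveform.
    """

    background_rms: float = 1.0
    attention_gain: float = 0.3
    decay_tau_s: float = 150.0
    reflex_amp_chirp: float = 1.5
    reflex_amp_tone: float = 0.05
    reflex_peak_ms: float = 15.0
    reflex_trial_cv: float = 0.3
    ipsi_reflex_gain: float = 1.0
    contra_reflex_gain: float = 0.6
    line_amp: float = 0.5
    common_mode_rms: float = 0.3
    artifact_rate_hz: float = 0.02
    rate: float = 9_600.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "background_rms",
            "attention_gain",
            "reflex_amp_chirp",
            "reflex_amp_tone",
            "reflex_trial_cv",
            "line_amp",
            "common_mode_rms",
            "artifact_rate_hz",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.decay_tau_s <= 0:
            raise ValueError("decay_tau_s must be positive")
        if not (0 < self.reflex_peak_ms < 100):
            raise ValueError("reflex_peak_ms must lie in (0, 100) ms")

    def reflex_amp(self, kind: str) -> float:
        return self.reflex_amp_chirp if kind == CHIRP else self.reflex_amp_tone


@dataclass
class Recording:
    """Multichannel sampled EMG with trigger channel and aligned events."""

    channels: np.ndarray  # (5, n_samples) in CHANNEL_ROLES order
    rate: float
    channel_roles: tuple[str, ...]
    events: pd.DataFrame  # onset_s, ear, kind, is_deviant, level_db, sample

    def __post_init__(self) -> None:
        if self.channels.shape[0] != len(self.channel_roles):
            raise ValueError("channel count does not match channel_roles")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[self.channel_roles.index(role)]
        except ValueError as err:
            raise KeyError(f"missing channel role {role!r}") from err


def _reflex_template(rate: float) -> tuple[np.ndarray, int]:
    """Biphasic difference-of-Gaussians pulse, peak-normalized.

    Returns the template and the index of its (positive) peak so callers
    can align the peak with time-zero + reflex_peak_ms.
    """
    s1 = 0.002  # s, width of positive lobe
    s2 = 0.003  # s, width of (delayed) negative lobe
    delay = 0.005  # s
    t = np.arange(-4 * s1, delay + 4 * s2, 1.0 / rate)
    x = np.exp(-0.5 * (t / s1) ** 2) - 0.8 * np.exp(-0.5 * ((t - delay) / s2) ** 2)
    x /= np.max(np.abs(x))
    return x, int(np.argmax(x))


@lru_cache(maxsize=8)
def _band_sos(rate: float) -> np.ndarray:
    sos = sps.butter(4, [20.0, 500.0], btype="bandpass", fs=rate, output="sos")
    return sos.astype(np.float32)


@lru_cache(maxsize=8)
def _band_noise_gain(rate: float) -> float:
    """RMS gain of the band-limiting filter on unit white noise (= ||h||_2)."""
    imp = np.zeros(int(2 * rate), dtype=np.float32)
    imp[0] = 1.0
    h = sps.sosfilt(_band_sos(rate), imp)
    return float(np.sqrt(np.sum(h.astype(np.float64) ** 2)))


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean lognormal multipliers with the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size)
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=size)


def simulate_trial(
    params: EmgModelParams,
    seq: DichoticSequence,
    attended: str,
    seed: int | None = None,
    pad_s: float = 1.1,
) -> Recording:
    """Simulate one listening trial's five-channel recording.

    ``attended`` is the ear attention is directed to.  Randomness is fully
    determined by ``seed`` (defaulting to ``params.seed``); the reflex,
    noise, line and artifact streams are drawn from independent child
    generators so that e.g. scaling reflex amplitudes leaves the noise
    byte-identical.
    """
    if attended not in EARS:
        raise ValueError(f"attended must be one of {EARS}")
    rate = params.rate
    ss = np.random.SeedSequence(params.seed if seed is None else seed)
    (ss_noise, ss_common, ss_line, ss_reflex, ss_artifact) = ss.spawn(5)
    # SFC64 for the two long sample streams: same statistical quality,
    # roughly twice the throughput of the default generator
    rng_noise = np.random.Generator(np.random.SFC64(ss_noise))
    rng_common = np.random.Generator(np.random.SFC64(ss_common))
    rng_line = np.random.default_rng(ss_line)
    rng_reflex = np.random.default_rng(ss_reflex)
    rng_artifact = np.random.default_rng(ss_artifact)

    last = seq.events[-1]
    n = int(round((last.onset_s + pad_s) * rate))
    t = np.arange(n, dtype=np.float32) / np.float32(rate)

    # --- latent tonic sources, both PAMs at once -------------------------
    # single-precision throughout: EMG-scale dynamics leave ~2 decades of
    # headroom to float32 resolution, and long trials stay affordable
    noise = rng_noise.standard_normal((2, n), dtype=np.float32)
    noise = sps.sosfilt(_band_sos(rate), noise, axis=-1)
    noise /= np.float32(_band_noise_gain(rate))  # unit-RMS band-limited noise
    decay = np.exp(-t / np.float32(params.decay_tau_s))
    sources = np.empty_like(noise)
    for i, side in enumerate(EARS):
        gain = 1.0 + params.attention_gain * (attended == side)
        sources[i] = noise[i] * (np.float32(params.background_rms * gain) * decay)

    # --- stimulus-locked reflexes ---------------------------------------
    template, peak_idx = _reflex_template(rate)
    onsets = np.array([e.onset_s for e in seq.events])
    kinds = [e.kind for e in seq.events]
    ears = np.array([e.ear for e in seq.events])
    dev_scale = np.array(
        [10.0 ** (e.level_db_re_standard / 20.0) for e in seq.events]
    )
    tz = np.array([timezero_offset_s(k) for k in kinds])
    # one lognormal factor per event per PAM, drawn up-front so the noise
    # stream never depends on reflex amplitudes
    factors = _lognormal_factors(rng_reflex, params.reflex_trial_cv, 2 * len(seq.events))
    factors = factors.reshape(2, -1)
    base_amp = np.array([params.reflex_amp(k) for k in kinds])
    peak_samples = np.round((onsets + tz + params.reflex_peak_ms / 1000.0) * rate).astype(int)
    for i, side in enumerate(EARS):
        lat_gain = np.where(ears == side, params.ipsi_reflex_gain, params.contra_reflex_gain)
        amps = base_amp * dev_scale * lat_gain * factors[i]
        template32 = template.astype(np.float32)
        amps32 = amps.astype(np.float32)
        row = sources[i]
        for amp, pk in zip(amps32, peak_samples):
            if amp == 0.0:
                continue
            i0 = pk - peak_idx
            i1 = i0 + len(template32)
            if i0 < 0 or i1 > n:
                continue
            row[i0:i1] += amp * template32

    # --- electrode mixing ------------------------------------------------
    phases = rng_line.uniform(0, 2 * np.pi, size=LINE_N_HARMONICS)
    period = int(rate / 50.0) if (rate % 50.0 == 0) else 0
    if period:  # 50 Hz and harmonics share one exact sample period: tile it
        tp = np.arange(period) / rate
        one = np.zeros(period)
        for k, ph in zip(range(1, LINE_N_HARMONICS + 1), phases):
            one += (params.line_amp / k) * np.sin(2 * np.pi * 50.0 * k * tp + ph)
        line = np.tile(one.astype(np.float32), n // period + 1)[:n]
    else:
        line = np.zeros(n, dtype=np.float32)
        for k, ph in zip(range(1, LINE_N_HARMONICS + 1), phases):
            line += np.float32(params.line_amp / k) * np.sin(
                np.float32(2 * np.pi * 50.0 * k) * t + np.float32(ph)
            )

    channels = np.zeros((5, n), dtype=np.float32)
    # one common-mode draw: it cancels identically in the bipolar
    # derivation, so per-pair independence is unobservable downstream
    common = params.common_mode_rms * rng_common.standard_normal(n, dtype=np.float32)
    for i in range(2):  # left, right PAM pairs
        diff_jitter = rng_line.uniform(-1.0, 1.0, size=2) * LINE_DIFFERENTIAL_FRACTION
        channels[2 * i] = 0.5 * sources[i] + common + np.float32(1.0 + diff_jitter[0]) * line
        channels[2 * i + 1] = (
            -0.5 * sources[i] + common + np.float32(1.0 + diff_jitter[1]) * line
        )

    # --- artifact bursts --------------------------------------------------
    duration_s = n / rate
    n_bursts = rng_artifact.poisson(params.artifact_rate_hz * duration_s)
    for _ in range(n_bursts):
        ch = int(rng_artifact.integers(0, 4))
        start = int(rng_artifact.uniform(0, n))
        dur = int(rng_artifact.uniform(0.050, 0.200) * rate)
        stop = min(start + dur, n)
        amp = rng_artifact.uniform(10.0, 30.0) * params.background_rms
        burst = np.float32(amp) * rng_artifact.standard_normal(stop - start, dtype=np.float32)
        burst *= np.hanning(len(burst)).astype(np.float32)  # taper: bursts are transient
        channels[ch, start:stop] += burst

    events = seq.to_frame()
    events["sample"] = np.round(events["onset_s"] * rate).astype(int)
    channels[4, events["sample"].to_numpy()] = 1.0  # trigger marks
    return Recording(channels=channels, rate=rate, channel_roles=CHANNEL_ROLES, events=events)


@dataclass(frozen=True)
class TrialPlan:
    """Schedule entry for one listening trial."""

    trial_index: int
    attended: str
    tone_ear: str
    sequence_seed: int
    emg_seed: int


@dataclass
class StudyGroundTruth:
    """Everything needed to regenerate a simulated study and score recovery."""

    master_seed: int
    participants: list[str]
    params: dict[str, EmgModelParams]
    schedule: dict[str, list[TrialPlan]]
    sequence_spec: SequenceSpec

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def trial_sequence(self, participant: str, trial_index: int) -> DichoticSequence:
        plan = self.schedule[participant][trial_index]
        spec = replace(self.sequence_spec, tone_ear=plan.tone_ear, seed=plan.sequence_seed)
        return generate_sequence(spec)

    def simulate_recording(self, participant: str, trial_index: int) -> Recording:
        plan = self.schedule[participant][trial_index]
        seq = self.trial_sequence(participant, trial_index)
        return simulate_trial(self.params[participant], seq, plan.attended, seed=plan.emg_seed)

    def iter_recordings(self, participant: str):
        for plan in self.schedule[participant]:
            yield plan, self.simulate_recording(participant, plan.trial_index)

    def to_jsonable(self) -> dict:
        return {
            "master_seed": self.master_seed,
            "participants": self.participants,
            "params": {p: asdict(v) for p, v in self.params.items()},
            "schedule": {
                p: [asdict(plan) for plan in plans] for p, plans in self.schedule.items()
            },
            "sequence_spec": asdict(self.sequence_spec),
        }


def default_params_sampler(rng: np.random.Generator, nominal: EmgModelParams) -> EmgModelParams:
    """Between-participant variation around nominal generative parameters.

    Positive parameters vary lognormally: background RMS (CV 0.4, the
    dominant inter-individual factor for surface PAM amplitude), reflex
    amplitudes (CV 0.4), attention gain and decay constant (CV 0.2).
    """
    def ln(x: float, cv: float) -> float:
        return float(x * _lognormal_factors(rng, cv, 1)[0])

    return replace(
        nominal,
        background_rms=ln(nominal.background_rms, 0.4),
        reflex_amp_chirp=ln(nominal.reflex_amp_chirp, 0.4),
        reflex_amp_tone=ln(nominal.reflex_amp_tone, 0.4),
        attention_gain=ln(nominal.attention_gain, 0.2) if nominal.attention_gain > 0 else 0.0,
        decay_tau_s=ln(nominal.decay_tau_s, 0.2),
    )


def _balanced_schedule(rng: np.random.Generator, n_trials_per_cell: int = 5) -> list[tuple[str, str]]:
    """Pseudo-randomized (attended, tone_ear) order: 5 trials per combination."""
    cells = [
        (att, tone) for att in EARS for tone in EARS for _ in range(n_trials_per_cell)
    ]
    order = rng.permutation(len(cells))
    return [cells[i] for i in order]


def simulate_study(
    n_participants: int = 17,
    master_seed: int = 0,
    nominal_params: EmgModelParams | None = None,
    params_sampler=default_params_sampler,
    sequence_spec: SequenceSpec | None = None,
    n_trials_per_cell: int = 5,
) -> StudyGroundTruth:
    """Lay out a balanced multi-participant study, fully seeded.

    Twenty trials per participant by default: ten attend-left and ten
    attend-right, crossed with the tone-burst ear so each of the four
    (attended, tone ear) combinations occurs five times.  Recordings are
    regenerated on demand from the returned ground truth
    (:meth:`StudyGroundTruth.simulate_recording`), byte-stable in the
    master seed.
    """
    if n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    nominal = nominal_params or EmgModelParams()
    seq_spec = sequence_spec or SequenceSpec()
    root = np.random.SeedSequence(master_seed)
    participant_ss = root.spawn(n_participants)
    participants = [f"P{i:02d}" for i in range(1, n_participants + 1)]
    params: dict[str, EmgModelParams] = {}
    schedule: dict[str, list[TrialPlan]] = {}
    for pid, ss in zip(participants, participant_ss):
        ss_params, ss_order, ss_trials = ss.spawn(3)
        params[pid] = params_sampler(np.random.default_rng(ss_params), nominal)
        cells = _balanced_schedule(np.random.default_rng(ss_order), n_trials_per_cell)
        trial_seeds = ss_trials.generate_state(2 * len(cells)) % (2**31)
        plans = []
        for ti, (att, tone) in enumerate(cells):
            plans.append(
                TrialPlan(
                    trial_index=ti,
                    attended=att,
                    tone_ear=tone,
                    sequence_seed=int(trial_seeds[2 * ti]),
                    emg_seed=int(trial_seeds[2 * ti + 1]),
                )
            )
        schedule[pid] = plans
    return StudyGroundTruth(
        master_seed=master_seed,
        participants=participants,
        params=params,
        schedule=schedule,
        sequence_spec=seq_spec,
    )


def save_recording(rec: Recording, path) -> None:
    """Write a recording as .npz with a JSON sidecar for events/metadata."""
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    np.savez_compressed(path, channels=rec.channels)
    sidecar = {
        "rate": rec.rate,
        "channel_roles": list(rec.channel_roles),
        "events": rec.events.to_dict(orient="list"),
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh)


def load_recording(path) -> Recording:
    path = str(path)
    with np.load(path if path.endswith(".npz") else path + ".npz") as npz:
        channels = npz["channels"]
    with open((path if path.endswith(".npz") else path + ".npz") + ".json") as fh:
        sidecar = json.load(fh)
    return Recording(
        channels=channels,
        rate=float(sidecar["rate"]),
        channel_roles=tuple(sidecar["channel_roles"]),
        events=pd.DataFrame(sidecar["events"]),
    )
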