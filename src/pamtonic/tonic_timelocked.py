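"""Secondary tonic analysis: pre-stimulus amplitude of time-locked rectified
PAM activity around chirps.

A short (10 ms) moving-RMS envelope keeps stimulus-locked components
localized in time.  The envelope is epoched at chirp offsets with 100 ms
pre- and post-stimulus periods, restricted to the trials whose
non-rectified counterparts survived artifact screening.  Per PAM, epochs
are collapsed over chirp side and averaged into a 2 x 2 design (attended
side x chirp kind); the four averages are jointly z-normalized by the
mean and SD of their concatenated pre-stimulus ([-100, 0) ms) samples -
no subtractive baseline correction is applied.  Because the smallest
inter-stimulus interval is 250 ms, the pre-stimulus window is free of
reflex energy, so any toward/away difference there reflects sustained
muscle tone, independent of the reflex itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .epoching import EpochSet
from .preprocess import BipolarRecording
from .stimgen import CHIRP, EARS, timezero_offset_s
from .tonic_ongoing import rms_envelope

__all__ = [
    "rectified_epochs",
    "average_and_normalize",
    "prestim_contrast",
    "PRESTIM_WINDOW_MS",
]

PRESTIM_WINDOW_MS = (-100.0, 0.0)  # half-open [lo, hi)
EPOCH_WINDOW_MS = (-100.0, 100.0)
RMS_WINDOW_S = 0.010


def rectified_epochs(
    rec: BipolarRecording,
    attended_side: str,
    selected_events: dict[str, set[int]],
    deviants: bool = False,
    participant: str = "",
    trial: int = 0,
) -> EpochSet:
    """Chirp-locked [-100, +100] ms epochs of the 10 ms RMS envelope.

    ``selected_events`` maps PAM side to the event indices whose
    non-rectified epochs were selected for that PAM in this trial; only
    those single trials enter the rectified set, enforcing index equality
    with the non-rectified selection.
    """
    rate = rec.rate
    env = rms_envelope(rec.signals, rate, RMS_WINDOW_S)
    n = env.shape[-1]
    lo = int(round(EPOCH_WINDOW_MS[0] / 1000.0 * rate))
    hi = int(round(EPOCH_WINDOW_MS[1] / 1000.0 * rate))
    ev = rec.events
    sel = (ev["kind"] == CHIRP) & (ev["is_deviant"] == bool(deviants))
    ev = ev.loc[sel]
    known = set(ev.index)
    for side, wanted in selected_events.items():
        extra = set(wanted) - known
        if extra:
            raise ValueError(
                f"selected events {sorted(extra)[:5]} for PAM {side!r} are not "
                "chirp events of this trial (rectified/non-rectified index mismatch)"
            )
    tz_offset = timezero_offset_s(CHIRP)
    segments, rows = [], []
    for event_idx, event in ev.iterrows():
        tz = int(round((event["onset_s"] + tz_offset) * rate))
        i0, i1 = tz + lo, tz + hi
        if i0 < 0 or i1 > n:
            continue
        for p, pam_side in enumerate(EARS):
            if int(event_idx) not in selected_events.get(pam_side, set()):
                continue
            segments.append(env[p, i0:i1])
            rows.append(
                {
                    "participant": participant,
                    "pam_side": pam_side,
                    "stim_side": event["ear"],
                    "attended_side": attended_side,
                    "is_deviant": bool(deviants),
                    "trial": trial,
                    "event": int(event_idx),
                }
            )
    data = np.stack(segments) if segments else np.empty((0, hi - lo))
    info = pd.DataFrame(
        rows,
        columns=[
            "participant",
            "pam_side",
            "stim_side",
            "attended_side",
            "is_deviant",
            "trial",
            "event",
        ],
    )
    info["snr_db"] = np.nan
    info["retained"] = True
    info["selected"] = True
    return EpochSet(data=data, info=info, rate=rate, window_ms=EPOCH_WINDOW_MS)


def average_and_normalize(
    epochs: EpochSet, pam_side: str, floor: float = 1e-12
) -> pd.DataFrame:
    """Four jointly z-normalized average waveforms for one PAM.

    Chirp sides are collapsed; cells are (attended side x chirp kind).
    Normalization subtracts the mean and divides by the SD of the
    concatenated pre-stimulus samples of all four averages, preserving
    every relative attention difference within the PAM.

    Returns a tidy frame: pam_side, attended_side, chirp_kind, time_ms,
    amplitude, n_epochs.
    """
    mask_pam = (epochs.info["pam_side"] == pam_side).to_numpy()
    pre = epochs.sample_slice(*PRESTIM_WINDOW_MS)
    averages: dict[tuple[str, str], tuple[np.ndarray, int]] = {}
    for att in EARS:
        for kind, dev in (("standard", False), ("deviant", True)):
            m = (
                mask_pam
                & (epochs.info["attended_side"] == att).to_numpy()
                & (epochs.info["is_deviant"] == dev).to_numpy()
            )
            if not m.any():
                raise ValueError(f"empty cell (attended={att}, chirp={kind}) for PAM {pam_side}")
            averages[(att, kind)] = (epochs.data[m].mean(axis=0), int(m.sum()))
    prestim = np.concatenate([w[pre] for w, _ in averages.values()])
    mu, sd = prestim.mean(), prestim.std()
    if sd <= floor:
        raise ValueError("zero pre-stimulus variability; normalization undefined")
    t = epochs.time_ms
    rows = []
    for (att, kind), (w, n_ep) in averages.items():
        z = (w - mu) / sd
        rows.append(
            pd.DataFrame(
                {
                    "pam_side": pam_side,
                    "attended_side": att,
                    "chirp_kind": kind,
                    "time_ms": t,
                    "amplitude": z,
                    "n_epochs": n_ep,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def prestim_contrast(averages: pd.DataFrame) -> pd.DataFrame:
    """Toward/away mean pre-stimulus amplitudes per participant and chirp kind.

    ``averages`` is the tidy output of :func:`average_and_normalize`
    (optionally concatenated over PAMs and participants, with a
    ``participant`` column).  "Toward" pools each PAM's same-side-attended
    average; "away" the opposite side.  Returns one row per (participant,
    chirp_kind) with columns ``toward`` and ``away`` - the paired t-test
    inputs.
    """
    df = averages.copy()
    if "participant" not in df.columns:
        df["participant"] = ""
    pre = df["time_ms"].between(PRESTIM_WINDOW_MS[0], PRESTIM_WINDOW_MS[1], inclusive="left")
    df = df.loc[pre]
    df["condition"] = np.where(df["pam_side"] == df["attended_side"], "toward", "away")
    out = (
        df.groupby(["participant", "chirp_kind", "condition"])["amplitude"]
        .mean()
        .unstack("condition")
        .reset_index()
    )
    out.columns.name = None
    return out
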