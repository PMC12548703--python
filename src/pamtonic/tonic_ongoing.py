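"""Primary tonic analysis: ongoing rectified PAM amplitude over listening trials.

For each preprocessed bipolar PAM signal the 1 s moving-RMS envelope is
trimmed to a region of interest starting 5 s after the first stimulus
onset and lasting 180 s, split into five consecutive 36 s segments, and
summarized by segment means.  Per PAM and participant all segment values
are pooled; values outside the 2.5th-97.5th percentile range are removed,
the remainder are z-scored (preserving every relative attention effect),
and the normalized amplitudes are categorized by PAM side, the stimulus
type delivered to that side, the attended side, and segment - a
2 x 2 x 2 x 5 table per participant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "rms_envelope",
    "trim_and_segment",
    "remove_percentile_outliers",
    "zscore_within",
    "categorize",
    "first_last_reduce",
]

ROI_START_S = 5.0
ROI_DURATION_S = 180.0
N_SEGMENTS = 5


def rms_envelope(x: np.ndarray, rate: float, window_s: float = 1.0) -> np.ndarray:
    """Centered moving-RMS envelope; edge windows truncate to the signal.

    Output has the same length as the input.  Computed from a cumulative
    sum of squares, so cost is linear in the signal length.
    """
    x = np.asarray(x)
    w = int(round(window_s * rate))
    if w < 2:
        raise ValueError("window must span at least 2 samples")
    n = x.shape[-1]
    if w > n:
        w = n
    # float64 accumulator: a float32 running sum over minutes of samples
    # would lose several significant digits
    csum = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(x * x, axis=-1, dtype=np.float64)],
        axis=-1,
    )
    half = w // 2
    out = np.empty(x.shape, dtype=np.float64)
    # interior: full windows, contiguous difference
    lo, hi = half, n - w + half + 1
    out[..., lo:hi] = (csum[..., w:] - csum[..., : n - w + 1]) / w
    # edges: windows truncated to the signal
    for i in range(0, lo):
        i1 = i - half + w
        out[..., i] = csum[..., i1] / i1
    for i in range(hi, n):
        i0 = i - half
        out[..., i] = (csum[..., n] - csum[..., i0]) / (n - i0)
    return np.sqrt(out)


def trim_and_segment(
    env: np.ndarray,
    rate: float,
    first_onset_s: float,
    roi_start_s: float = ROI_START_S,
    roi_duration_s: float = ROI_DURATION_S,
    n_segments: int = N_SEGMENTS,
) -> np.ndarray:
    """Means of consecutive equal segments of the trimmed envelope.

    The region of interest starts ``roi_start_s`` after the first stimulus
    onset and lasts ``roi_duration_s``; it is split into ``n_segments``
    contiguous non-overlapping blocks (36 s each at the study scale).
    """
    env = np.asarray(env, dtype=float)
    start = int(round((first_onset_s + roi_start_s) * rate))
    seg_len = int(round(roi_duration_s * rate / n_segments))
    stop = start + seg_len * n_segments
    if start < 0 or stop > env.shape[-1]:
        raise ValueError(
            f"envelope too short: need samples [{start}, {stop}), have {env.shape[-1]}"
        )
    roi = env[..., start:stop]
    return roi.reshape(env.shape[:-1] + (n_segments, seg_len)).mean(axis=-1)


def remove_percentile_outliers(
    values: np.ndarray, lower: float = 2.5, upper: float = 97.5
) -> tuple[np.ndarray, np.ndarray]:
    """Drop values strictly outside the [2.5th, 97.5th] percentile range.

    Percentiles use linear interpolation between order statistics; values
    equal to a percentile bound are retained.  Returns (retained values,
    boolean keep-mask over the input).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 pooled values")
    lo, hi = np.percentile(values, [lower, upper], method="linear")
    mask = (values >= lo) & (values <= hi)
    return values[mask], mask


def zscore_within(values: np.ndarray) -> np.ndarray:
    """z-scores over one PAM's pooled retained values (sample SD, n-1)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to z-score")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation; z-scores undefined")
    return (values - values.mean()) / sd


def categorize(seg_df: pd.DataFrame, n_segments: int = N_SEGMENTS) -> pd.DataFrame:
    """Cell means of z-scored segment amplitudes over contributing trials.

    ``seg_df`` is tidy with one row per (trial, PAM, segment) surviving
    value and columns ``pam_side``, ``stim_kind``, ``attended_side``,
    ``segment`` (1-based), ``z``.  Output is the tidy 2 x 2 x 2 x n_segments
    table with column ``z_amplitude``; an empty design cell raises.
    """
    required = {"pam_side", "stim_kind", "attended_side", "segment", "z"}
    missing = required - set(seg_df.columns)
    if missing:
        raise ValueError(f"seg_df missing columns {sorted(missing)}")
    out = (
        seg_df.groupby(["pam_side", "stim_kind", "attended_side", "segment"], sort=True)["z"]
        .mean()
        .rename("z_amplitude")
    )
    full = pd.MultiIndex.from_product(
        [
            sorted(seg_df["pam_side"].unique()),
            sorted(seg_df["stim_kind"].unique()),
            sorted(seg_df["attended_side"].unique()),
            range(1, n_segments + 1),
        ],
        names=["pam_side", "stim_kind", "attended_side", "segment"],
    )
    out = out.reindex(full)
    if out.isna().any():
        empty = out[out.isna()].index.tolist()
        raise ValueError(f"empty design cells: {empty[:4]}{'...' if len(empty) > 4 else ''}")
    return out.reset_index()


def first_last_reduce(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only the first and last time segments as a two-level time factor."""
    first = table["segment"].min()
    last = table["segment"].max()
    out = table[table["segment"].isin([first, last])].copy()
    out["time"] = np.where(out["segment"] == first, "first", "last")
    return out.reset_index(drop=True)
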