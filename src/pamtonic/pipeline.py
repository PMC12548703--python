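"""End-to-end study orchestration: simulate -> preprocess -> certify -> analyze.

A :class:`StudyConfig` is the single source of truth for a run.  The
pipeline simulates a multi-participant study from its master seed,
conditions every trial, screens participants through the half-split
reliability gate, computes the study-level epoch quota (the smallest
count of artifact-free epochs across cells and participants), runs the
ongoing and time-locked tonic analyses with their within-subject
statistics, and writes tidy CSV outputs plus a parameter-recovery report
against the simulation ground truth.  Analysis code never reads the
ground truth; recovery is a separate comparison step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import epoching, reliability, stats, tonic_ongoing, tonic_timelocked
from .preprocess import BipolarRecording, FilterSpec, preprocess_recording
from .stimgen import CHIRP, EARS, TONE_BURST, SequenceSpec
from .synth_emg import EmgModelParams, StudyGroundTruth, simulate_study

logger = logging.getLogger("pamtonic")

__all__ = [
    "StudyConfig",
    "StudyResult",
    "ParticipantBundle",
    "score_detections",
    "run_subject",
    "run_study",
]

DETECTION_WINDOW_S = (0.050, 1.500)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """All tunable parameters of a simulated study run."""

    n_participants: int = 17
    master_seed: int = 0
    n_trials_per_cell: int = 5
    sequence: SequenceSpec = field(default_factory=SequenceSpec)
    emg: EmgModelParams = field(default_factory=EmgModelParams)
    filters: FilterSpec = field(default_factory=FilterSpec)
    roi_start_s: float = 5.0
    roi_duration_s: float = 180.0
    n_segments: int = 5
    alpha: float = 0.05
    n_per_cell: int | None = None  # None: study-level minimum across cells/participants
    gate: bool = True
    analyses: tuple[str, ...] = ("ongoing", "timelocked")
    outdir: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "sequence" in d and isinstance(d["sequence"], dict):
            seq = dict(d["sequence"])
            for key in ("isi_range_s", "deviant_gap_range"):
                if key in seq:
                    seq[key] = tuple(seq[key])
            d["sequence"] = SequenceSpec(**seq)
        if "emg" in d and isinstance(d["emg"], dict):
            d["emg"] = EmgModelParams(**d["emg"])
        if "filters" in d and isinstance(d["filters"], dict):
            flt = dict(d["filters"])
            if "bandpass_hz" in flt:
                flt["bandpass_hz"] = tuple(flt["bandpass_hz"])
            d["filters"] = FilterSpec(**flt)
        if "analyses" in d:
            d["analyses"] = tuple(d["analyses"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# --------------------------------------------------------------------------
# behavioral scoring
# --------------------------------------------------------------------------


def score_detections(
    presses: np.ndarray,
    targets: np.ndarray,
    window_s: tuple[float, float] = DETECTION_WINDOW_S,
) -> tuple[float, int]:
    """Greedy one-to-one matching of button presses to deviant targets.

    A press counts as a hit if it falls within [50, 1500] ms after a
    not-yet-matched target (earliest such target wins); every unmatched
    press is a false alarm.  Returns (hit rate, false-alarm count).
    """
    presses = np.sort(np.asarray(presses, dtype=float))
    targets = np.sort(np.asarray(targets, dtype=float))
    if (presses < 0).any() or (targets < 0).any():
        raise ValueError("times must be nonnegative")
    matched = np.zeros(len(targets), dtype=bool)
    hits = 0
    for press in presses:
        lags = press - targets
        ok = (~matched) & (lags >= window_s[0]) & (lags <= window_s[1])
        idx = np.flatnonzero(ok)
        if len(idx):
            matched[idx[0]] = True
            hits += 1
    hit_rate = hits / len(targets) if len(targets) else np.nan
    false_alarms = len(presses) - hits
    return hit_rate, false_alarms


# --------------------------------------------------------------------------
# per-participant processing
# --------------------------------------------------------------------------


@dataclass
class ParticipantBundle:
    """Everything the study stage needs from one participant's recordings."""

    participant: str
    env_segments: pd.DataFrame  # trial, pam_side, attended_side, stim_kind, segment, amplitude
    chirp_standard: epoching.EpochSet | None
    chirp_deviant: epoching.EpochSet | None
    tone_standard: epoching.EpochSet | None
    rect_standard: epoching.EpochSet | None
    rect_deviant: epoching.EpochSet | None
    reliability_chirp: reliability.ReliabilityReport | None
    reliability_tone: reliability.ReliabilityReport | None

    def retained_cell_counts(self, which: str) -> dict[tuple[str, str, str], int]:
        es = {"standard": self.chirp_standard, "deviant": self.chirp_deviant}[which]
        counts = {}
        for key in es.cell_keys():
            counts[key] = int((es.cell_mask(*key) & es.info["retained"]).sum())
        return counts


def process_participant(
    gt: StudyGroundTruth, participant: str, cfg: StudyConfig
) -> ParticipantBundle:
    """Simulate and condition one participant's 20 trials; epoch and screen.

    Epoching (and hence the reliability screen and the time-locked
    analysis inputs) is skipped when neither the gate nor the
    time-locked analysis requests it, which keeps ongoing-only runs
    cheap.
    """
    need_epochs = cfg.gate or "timelocked" in cfg.analyses
    env_rows = []
    chirp_std_parts, chirp_dev_parts, tone_std_parts = [], [], []
    rect_std_parts, rect_dev_parts = [], []
    for plan, rec in gt.iter_recordings(participant):
        seq = gt.trial_sequence(participant, plan.trial_index)
        pre = preprocess_recording(rec, cfg.filters)
        if "ongoing" in cfg.analyses:
            env = tonic_ongoing.rms_envelope(pre.signals, pre.rate, 1.0)
            segs = tonic_ongoing.trim_and_segment(
                env,
                pre.rate,
                seq.first_onset_s,
                cfg.roi_start_s,
                cfg.roi_duration_s,
                cfg.n_segments,
            )
            for p, pam_side in enumerate(EARS):
                kind = TONE_BURST if plan.tone_ear == pam_side else CHIRP
                for s in range(cfg.n_segments):
                    env_rows.append(
                        {
                            "trial": plan.trial_index,
                            "pam_side": pam_side,
                            "attended_side": plan.attended,
                            "stim_kind": kind,
                            "segment": s + 1,
                            "amplitude": segs[p, s],
                        }
                    )
        if need_epochs:
            common = dict(participant=participant, trial=plan.trial_index)
            chirp_std_parts.append(
                epoching.extract_epochs(pre, CHIRP, plan.attended, deviants=False, **common)
            )
            chirp_dev_parts.append(
                epoching.extract_epochs(pre, CHIRP, plan.attended, deviants=True, **common)
            )
            tone_std_parts.append(
                epoching.extract_epochs(pre, TONE_BURST, plan.attended, deviants=False, **common)
            )
            if "timelocked" in cfg.analyses:
                all_chirps_std = {
                    side: set(
                        pre.events.index[
                            (pre.events["kind"] == CHIRP) & (~pre.events["is_deviant"])
                        ]
                    )
                    for side in EARS
                }
                all_chirps_dev = {
                    side: set(
                        pre.events.index[
                            (pre.events["kind"] == CHIRP) & (pre.events["is_deviant"])
                        ]
                    )
                    for side in EARS
                }
                rect_std_parts.append(
                    tonic_timelocked.rectified_epochs(
                        pre, plan.attended, all_chirps_std, deviants=False, **common
                    )
                )
                rect_dev_parts.append(
                    tonic_timelocked.rectified_epochs(
                        pre, plan.attended, all_chirps_dev, deviants=True, **common
                    )
                )

    chirp_std = chirp_dev = tone_std = rect_std = rect_dev = None
    rel_chirp = rel_tone = None
    if need_epochs:
        def _prep(parts):
            es = epoching.EpochSet.concat(parts)
            es = epoching.detrend_and_baseline(es)
            es = epoching.compute_snr(es)
            return epoching.reject_by_snr(es)

        chirp_std = _prep(chirp_std_parts)
        chirp_dev = _prep(chirp_dev_parts)
        tone_std = _prep(tone_std_parts)
        rel_chirp = reliability.certify_participant(
            chirp_std.subset(chirp_std.info["retained"].to_numpy()), participant
        )
        rel_tone = reliability.certify_participant(
            tone_std.subset(tone_std.info["retained"].to_numpy()), participant
        )
        if rect_std_parts:
            rect_std = epoching.EpochSet.concat(rect_std_parts)
            rect_dev = epoching.EpochSet.concat(rect_dev_parts)
    env_segments = pd.DataFrame(
        env_rows,
        columns=["trial", "pam_side", "attended_side", "stim_kind", "segment", "amplitude"],
    )
    logger.debug(
        "participant %s: %d envelope values, chirp epochs %s",
        participant,
        len(env_segments),
        None if chirp_std is None else len(chirp_std),
    )
    return ParticipantBundle(
        participant=participant,
        env_segments=env_segments,
        chirp_standard=chirp_std,
        chirp_deviant=chirp_dev,
        tone_standard=tone_std,
        rect_standard=rect_std,
        rect_deviant=rect_dev,
        reliability_chirp=rel_chirp,
        reliability_tone=rel_tone,
    )


def _subset_rectified_to_selected(
    rect: epoching.EpochSet, nonrect: epoching.EpochSet
) -> epoching.EpochSet:
    """Keep rectified epochs whose (pam, trial, event) was selected non-rectified."""
    sel = nonrect.info.loc[
        nonrect.info["selected"], ["pam_side", "trial", "event"]
    ]
    selected_keys = set(map(tuple, sel.to_numpy()))
    rect_keys = list(map(tuple, rect.info[["pam_side", "trial", "event"]].to_numpy()))
    missing = selected_keys - set(rect_keys)
    if missing:
        raise ValueError(
            f"{len(missing)} selected non-rectified epochs have no rectified "
            "counterpart (trial index mismatch)"
        )
    mask = np.array([k in selected_keys for k in rect_keys])
    return rect.subset(mask)


# --------------------------------------------------------------------------
# ongoing-tonic study stage
# --------------------------------------------------------------------------


def participant_tonic_table(bundle: ParticipantBundle, cfg: StudyConfig) -> pd.DataFrame:
    """Outlier removal, within-PAM z-scoring, and 2x2x2xS categorization."""
    frames = []
    for pam_side in EARS:
        pool = bundle.env_segments[bundle.env_segments["pam_side"] == pam_side].copy()
        _, keep = tonic_ongoing.remove_percentile_outliers(pool["amplitude"].to_numpy())
        pool = pool.loc[keep].copy()
        pool["z"] = tonic_ongoing.zscore_within(pool["amplitude"].to_numpy())
        frames.append(pool)
    seg_df = pd.concat(frames, ignore_index=True)
    table = tonic_ongoing.categorize(seg_df, cfg.n_segments)
    table.insert(0, "participant", bundle.participant)
    return table


def _anova_input(table: pd.DataFrame, stim_kind: str) -> np.ndarray:
    """(N, 2, 2, 2) array: PAM location x listening condition x time."""
    df = tonic_ongoing.first_last_reduce(table[table["stim_kind"] == stim_kind])
    df["condition"] = np.where(
        df["pam_side"] == df["attended_side"], "toward", "away"
    )
    cube = df.pivot_table(
        index="participant",
        columns=["pam_side", "condition", "time"],
        values="z_amplitude",
    )
    participants = cube.index
    y = np.full((len(participants), 2, 2, 2), np.nan)
    for i_p, pid in enumerate(participants):
        for i_m, pam in enumerate(EARS):
            for i_c, cond in enumerate(("toward", "away")):
                for i_t, tm in enumerate(("first", "last")):
                    y[i_p, i_m, i_c, i_t] = cube.loc[pid, (pam, cond, tm)]
    return y


# --------------------------------------------------------------------------
# study runner
# --------------------------------------------------------------------------


@dataclass
class StudyResult:
    config: StudyConfig
    ground_truth: StudyGroundTruth
    reliability: pd.DataFrame
    included: list[str]
    excluded: list[str]
    n_per_cell_standard: int | None
    n_per_cell_deviant: int | None
    tonic_table: pd.DataFrame | None
    anova: dict[str, stats.RmAnovaResult]
    timelocked_averages: pd.DataFrame | None
    prestim: pd.DataFrame | None
    ttests: dict[str, stats.TTestResult]
    normalization: pd.DataFrame | None
    recovery: pd.DataFrame | None


def run_subject(cfg: StudyConfig, participant: str) -> ParticipantBundle:
    """Single-participant pipeline through preprocessing and the reliability screen."""
    gt = simulate_study(
        n_participants=cfg.n_participants,
        master_seed=cfg.master_seed,
        nominal_params=cfg.emg,
        sequence_spec=cfg.sequence,
        n_trials_per_cell=cfg.n_trials_per_cell,
    )
    if participant not in gt.participants:
        raise KeyError(f"unknown participant {participant!r}")
    return process_participant(gt, participant, cfg)


def run_study(cfg: StudyConfig) -> StudyResult:
    """Full study pipeline; deterministic in the master seed."""
    gt = simulate_study(
        n_participants=cfg.n_participants,
        master_seed=cfg.master_seed,
        nominal_params=cfg.emg,
        sequence_spec=cfg.sequence,
        n_trials_per_cell=cfg.n_trials_per_cell,
    )
    bundles: dict[str, ParticipantBundle] = {}
    reports = []
    for pid in gt.participants:
        logger.info("processing participant %s", pid)
        bundles[pid] = process_participant(gt, pid, cfg)
        if bundles[pid].reliability_chirp is not None:
            reports.append(bundles[pid].reliability_chirp)
    rel_table = reliability.reliability_table(reports) if reports else pd.DataFrame()

    if cfg.gate:
        included = [r.participant for r in reports if r.passed]
        if not included:
            raise RuntimeError(
                "all participants failed the reliability gate; "
                f"cell correlations:\n{rel_table.to_string()}"
            )
    else:
        included = list(gt.participants)
    excluded = [p for p in gt.participants if p not in included]
    logger.info("reliability gate: %d/%d participants included", len(included), gt.n_participants)

    # ---- study-level epoch quota and selection/normalization ------------
    n_std = n_dev = None
    norm_rows = []
    if any(b.chirp_standard is not None for b in bundles.values()) and (
        "timelocked" in cfg.analyses
    ):
        if cfg.n_per_cell is None:
            n_std = min(
                min(bundles[p].retained_cell_counts("standard").values()) for p in included
            )
            n_dev = min(
                min(bundles[p].retained_cell_counts("deviant").values()) for p in included
            )
        else:
            n_std = n_dev = cfg.n_per_cell
        logger.info("epoch quota per cell: %d standard, %d deviant", n_std, n_dev)
        for pid in included:
            b = bundles[pid]
            b.chirp_standard = epoching.select_representative(b.chirp_standard, n_std)
            b.chirp_deviant = epoching.select_representative(b.chirp_deviant, n_dev)
            for pam in EARS:
                b.chirp_standard, b.chirp_deviant, factor = epoching.reflex_normalize(
                    b.chirp_standard, b.chirp_deviant, pam, pid
                )
                norm_rows.append(
                    {"participant": pid, "pam_side": pam, "factor": factor.value}
                )
    normalization = pd.DataFrame(norm_rows) if norm_rows else None

    # ---- ongoing tonic analysis -----------------------------------------
    tonic_table = None
    anova: dict[str, stats.RmAnovaResult] = {}
    if "ongoing" in cfg.analyses:
        tonic_table = pd.concat(
            [participant_tonic_table(bundles[p], cfg) for p in included],
            ignore_index=True,
        )
        if len(included) >= 2:
            for kind in (TONE_BURST, CHIRP):
                y = _anova_input(tonic_table, kind)
                anova[kind] = stats.rm_anova_2x2x2(
                    y, factor_names=("pam_location", "listening_condition", "time")
                )

    # ---- time-locked tonic analysis --------------------------------------
    timelocked_averages = None
    prestim = None
    ttests: dict[str, stats.TTestResult] = {}
    if "timelocked" in cfg.analyses:
        frames = []
        for pid in included:
            b = bundles[pid]
            rect_std = _subset_rectified_to_selected(b.rect_standard, b.chirp_standard)
            rect_dev = _subset_rectified_to_selected(b.rect_deviant, b.chirp_deviant)
            rect = epoching.EpochSet.concat([rect_std, rect_dev])
            for pam in EARS:
                avg = tonic_timelocked.average_and_normalize(rect, pam)
                avg.insert(0, "participant", pid)
                frames.append(avg)
        timelocked_averages = pd.concat(frames, ignore_index=True)
        prestim = tonic_timelocked.prestim_contrast(timelocked_averages)
        if len(included) >= 2:
            for kind in ("standard", "deviant"):
                sub = prestim[prestim["chirp_kind"] == kind]
                ttests[kind] = stats.paired_t(
                    sub["toward"].to_numpy(), sub["away"].to_numpy()
                )

    recovery = _recovery_report(gt, included, tonic_table, prestim)
    result = StudyResult(
        config=cfg,
        ground_truth=gt,
        reliability=rel_table,
        included=included,
        excluded=excluded,
        n_per_cell_standard=n_std,
        n_per_cell_deviant=n_dev,
        tonic_table=tonic_table,
        anova=anova,
        timelocked_averages=timelocked_averages,
        prestim=prestim,
        ttests=ttests,
        normalization=normalization,
        recovery=recovery,
    )
    if cfg.outdir:
        write_outputs(result, cfg.outdir)
    return result


def _recovery_report(
    gt: StudyGroundTruth,
    included: list[str],
    tonic_table: pd.DataFrame | None,
    prestim: pd.DataFrame | None,
) -> pd.DataFrame | None:
    """Per-participant comparison of estimated attention effects to ground truth.

    Computed after the analyses, from their outputs only.
    """
    if tonic_table is None and prestim is None:
        return None
    rows = []
    for pid in included:
        row: dict = {
            "participant": pid,
            "true_attention_gain": gt.params[pid].attention_gain,
            "true_decay_tau_s": gt.params[pid].decay_tau_s,
        }
        if tonic_table is not None:
            tt = tonic_table[tonic_table["participant"] == pid]
            toward = tt.loc[tt["pam_side"] == tt["attended_side"], "z_amplitude"].mean()
            away = tt.loc[tt["pam_side"] != tt["attended_side"], "z_amplitude"].mean()
            first = tt.loc[tt["segment"] == tt["segment"].min(), "z_amplitude"].mean()
            last = tt.loc[tt["segment"] == tt["segment"].max(), "z_amplitude"].mean()
            row["est_toward_minus_away_z"] = toward - away
            row["est_first_minus_last_z"] = first - last
        if prestim is not None:
            ps = prestim[prestim["participant"] == pid]
            row["est_prestim_toward_minus_away"] = (ps["toward"] - ps["away"]).mean()
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# outputs
# --------------------------------------------------------------------------


def write_outputs(result: StudyResult, outdir) -> None:
    """Write tidy CSVs, the resolved config, figures, and a run log."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out / "config.yaml")
    if len(result.reliability):
        result.reliability.to_csv(out / "reliability.csv", index=False)
    if result.tonic_table is not None:
        result.tonic_table.to_csv(out / "tonic_table.csv", index=False)
    for kind, res in result.anova.items():
        res.to_csv(out / f"anova_{kind}.csv")
    if result.timelocked_averages is not None:
        result.timelocked_averages.to_csv(out / "timelocked_averages.csv", index=False)
    if result.prestim is not None:
        result.prestim.to_csv(out / "prestim_contrast.csv", index=False)
    if result.normalization is not None:
        result.normalization.to_csv(out / "normalization_factors.csv", index=False)
    if result.recovery is not None:
        result.recovery.to_csv(out / "recovery.csv", index=False)
    summary = {
        "included": result.included,
        "excluded": result.excluded,
        "n_per_cell_standard": result.n_per_cell_standard,
        "n_per_cell_deviant": result.n_per_cell_deviant,
        "ttests": {
            k: {"t": v.t, "df": v.df, "p": v.p} for k, v in result.ttests.items()
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    try:
        _write_figures(result, out)
    except Exception as err:  # plotting must never sink a run
        logger.warning("figure generation failed: %s", err)


def _write_figures(result: StudyResult, out) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result.tonic_table is not None:
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
        for ax, kind in zip(axes, (TONE_BURST, CHIRP)):
            df = result.tonic_table[result.tonic_table["stim_kind"] == kind]
            grand = (
                df.groupby(["pam_side", "attended_side", "segment"])["z_amplitude"]
                .mean()
                .reset_index()
            )
            for (pam, att), sub in grand.groupby(["pam_side", "attended_side"]):
                ax.plot(sub["segment"], sub["z_amplitude"], marker="o",
                        label=f"{pam} PAM, attend {att}")
            ax.set_title(f"side of {kind.replace('_', ' ')}s")
            ax.set_xlabel("segment")
        axes[0].set_ylabel("tonic amplitude (z)")
        axes[0].legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "tonic_segments.png", dpi=120)
        plt.close(fig)

    if result.timelocked_averages is not None:
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
        for ax, kind in zip(axes, ("standard", "deviant")):
            df = result.timelocked_averages[
                result.timelocked_averages["chirp_kind"] == kind
            ]
            grand = (
                df.groupby(["pam_side", "attended_side", "time_ms"])["amplitude"]
                .mean()
                .reset_index()
            )
            for (pam, att), sub in grand.groupby(["pam_side", "attended_side"]):
                ax.plot(sub["time_ms"], sub["amplitude"], lw=0.8,
                        label=f"{pam} PAM, attend {att}")
            ax.axvline(0, color="k", lw=0.5)
            ax.set_title(f"{kind} chirps")
            ax.set_xlabel("time re chirp offset (ms)")
        axes[0].set_ylabel("rectified amplitude (z re pre-stimulus)")
        axes[0].legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "timelocked_waveforms.png", dpi=120)
        plt.close(fig)
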