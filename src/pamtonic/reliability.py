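"""Half-split reliability screening of time-locked PAM responses.

Each participant's data set is certified by splitting every cell's
standard-stimulus epochs into odd- and even-indexed halves, averaging
each half, and correlating the two averages over the stereotyped reflex
latency range of 5-30 ms.  The participant passes if at least six of the
eight design cells (2 PAMs x 2 stimulus sides x 2 attended sides) reach a
Pearson correlation of 0.4 or higher - which entails that each PAM passes
in at least half of its four conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epoching import REFLEX_WINDOW_MS, EpochSet
from .stimgen import EARS

__all__ = ["ReliabilityReport", "half_split_r", "certify_from_r", "certify_participant"]

R_THRESHOLD = 0.4
MIN_PASSING_CELLS = 6
FAIL_VALUE = -np.inf  # sentinel for undefined r (zero-variance average)


@dataclass(frozen=True)
class ReliabilityReport:
    """Per-participant half-split reliability outcome."""

    participant: str
    r_per_cell: dict[tuple[str, str, str], float]
    n_pass: int
    passed: bool

    def to_row(self) -> dict:
        row: dict = {"participant": self.participant}
        for (pam, stim, att), r in sorted(self.r_per_cell.items()):
            row[f"r_{pam}_{stim}_{att}"] = r
        row["n_pass"] = self.n_pass
        row["passed"] = self.passed
        return row


def half_split_r(cell_data: np.ndarray, window: slice) -> float:
    """Pearson r between odd- and even-indexed epoch averages in a window.

    Epochs are split by 1-based presentation order (odd = 1st, 3rd, ...);
    unequal halves are allowed.  A zero-variance average makes r undefined
    and returns the -inf fail sentinel (distinct from a true r = -1).
    """
    cell_data = np.asarray(cell_data, dtype=float)
    if len(cell_data) < 2:
        raise ValueError("need at least 2 epochs for a half-split")
    odd = cell_data[0::2].mean(axis=0)[window]
    even = cell_data[1::2].mean(axis=0)[window]
    if odd.std() == 0 or even.std() == 0:
        return FAIL_VALUE
    return float(np.corrcoef(odd, even)[0, 1])


def certify_from_r(
    participant: str, r_per_cell: dict[tuple[str, str, str], float]
) -> ReliabilityReport:
    """Apply the 6-of-8-cells-at-r>=0.4 decision rule to computed correlations."""
    if len(r_per_cell) != 8:
        raise ValueError(f"expected 8 design cells, got {len(r_per_cell)}")
    n_pass = sum(1 for r in r_per_cell.values() if r >= R_THRESHOLD)
    return ReliabilityReport(
        participant=participant,
        r_per_cell=dict(r_per_cell),
        n_pass=n_pass,
        passed=n_pass >= MIN_PASSING_CELLS,
    )


def certify_participant(standard_set: EpochSet, participant: str = "") -> ReliabilityReport:
    """Half-split certification from one participant's standard-stimulus epochs.

    Only standard stimuli enter the screen (their trial counts are an
    order of magnitude larger than the deviants').
    """
    if standard_set.info["is_deviant"].any():
        raise ValueError("reliability certification uses standard stimuli only")
    window = standard_set.sample_slice(*REFLEX_WINDOW_MS, closed=True)
    r_per_cell: dict[tuple[str, str, str], float] = {}
    for pam in EARS:
        for stim in EARS:
            for att in EARS:
                mask = standard_set.cell_mask(pam, stim, att)
                if not mask.any():
                    raise ValueError(f"missing design cell ({pam}, {stim}, {att})")
                r_per_cell[(pam, stim, att)] = half_split_r(standard_set.data[mask], window)
    return certify_from_r(participant, r_per_cell)


def reliability_table(reports: list[ReliabilityReport]) -> pd.DataFrame:
    """Study-level reliability CSV layout: one row per participant."""
    return pd.DataFrame([r.to_row() for r in reports])
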