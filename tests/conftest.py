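"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pamtonic.epoching import EpochSet


def make_epoch_set(
    data: np.ndarray,
    rate: float = 4800.0,
    window_ms: tuple[float, float] = (-1000.0, 1000.0),
    pam_side=None,
    stim_side=None,
    attended_side=None,
    is_deviant: bool = False,
    snr_db=None,
    retained=None,
    selected=None,
) -> EpochSet:
    """Assemble an EpochSet from a raw (n_epochs, n_samples) array."""
    n = len(data)

    def col(values, default):
        if values is None:
            return [default] * n
        if np.isscalar(values) or isinstance(values, str):
            return [values] * n
        return list(values)

    info = pd.DataFrame(
        {
            "participant": col(None, "P"),
            "pam_side": col(pam_side, "left"),
            "stim_side": col(stim_side, "left"),
            "attended_side": col(attended_side, "left"),
            "is_deviant": col(is_deviant, False),
            "trial": col(None, 0),
            "event": list(range(n)),
            "snr_db": col(snr_db, np.nan),
            "retained": col(retained, True),
            "selected": col(selected, False),
        }
    )
    return EpochSet(data=np.asarray(data, dtype=float), info=info, rate=rate, window_ms=window_ms)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
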