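"""Epoch extraction, SNR screening, representative selection, normalization."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_epoch_set
from pamtonic import epoching
from pamtonic.epoching import (
    compute_snr,
    detrend_and_baseline,
    extract_epochs,
    reflex_normalize,
    reject_by_snr,
    select_representative,
    snr_retained_mask,
)
from pamtonic.preprocess import BipolarRecording

RATE = 4800.0
N = 9600  # samples in a [-1000, 1000) ms epoch at 4800 Hz


def make_bipolar(n_seconds=6.0, events=None):
    n = int(n_seconds * RATE)
    signals = np.zeros((2, n))
    if events is None:
        events = pd.DataFrame(
            {"onset_s": [2.0], "ear": ["left"], "kind": ["chirp"],
             "is_deviant": [False], "level_db": [0.0], "sample": [int(2.0 * RATE)]}
        )
    return BipolarRecording(signals=signals, rate=RATE, events=events)


class TestExtractEpochs:
    def test_chirp_timezero_index_arithmetic(self):
        rec = make_bipolar()
        rec.signals[0, :] = np.arange(rec.signals.shape[1])
        es = extract_epochs(rec, "chirp", "left")
        tz = int(round((2.0 + 0.0149) * RATE))
        lo = tz + int(round(-1.0 * RATE))
        left = es.subset((es.info["pam_side"] == "left").to_numpy())
        assert left.data[0, 0] == lo
        assert left.data.shape[1] == N

    def test_tone_timezero_at_rise_end(self):
        ev = pd.DataFrame(
            {"onset_s": [2.0], "ear": ["left"], "kind": ["tone_burst"],
             "is_deviant": [False], "level_db": [0.0], "sample": [int(2.0 * RATE)]}
        )
        rec = make_bipolar(events=ev)
        rec.signals[0, :] = np.arange(rec.signals.shape[1])
        es = extract_epochs(rec, "tone_burst", "left")
        tz = int(round((2.0 + 0.012) * RATE))
        left = es.subset((es.info["pam_side"] == "left").to_numpy())
        assert left.data[0, 0] == tz + int(round(-1.0 * RATE))

    def test_boundary_event_dropped_and_counted(self):
        ev = pd.DataFrame(
            {"onset_s": [0.5, 2.0], "ear": ["left", "left"], "kind": ["chirp"] * 2,
             "is_deviant": [False] * 2, "level_db": [0.0] * 2,
             "sample": [int(0.5 * RATE), int(2.0 * RATE)]}
        )
        rec = make_bipolar(events=ev)
        es = extract_epochs(rec, "chirp", "left")
        assert len(es) == 2  # one surviving event x two PAMs
        assert es.n_dropped == 1

    def test_kind_and_deviant_filtering(self):
        ev = pd.DataFrame(
            {"onset_s": [2.0, 2.4], "ear": ["left", "left"], "kind": ["chirp", "chirp"],
             "is_deviant": [False, True], "level_db": [0.0, -15.0],
             "sample": [int(2.0 * RATE), int(2.4 * RATE)]}
        )
        rec = make_bipolar(events=ev)
        assert len(extract_epochs(rec, "chirp", "left", deviants=False)) == 2
        assert len(extract_epochs(rec, "chirp", "left", deviants=True)) == 2
        assert extract_epochs(rec, "tone_burst", "left").data.shape[0] == 0


class TestDetrendAndBaseline:
    def test_ramp_removed(self):
        es = make_epoch_set(np.linspace(0, 5, N)[None, :])
        out = detrend_and_baseline(es)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-9)

    def test_constant_removed(self):
        es = make_epoch_set(np.full((1, N), 3.7))
        out = detrend_and_baseline(es)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-9)

    def test_residual_preserved_on_top_of_ramp(self, rng):
        resid = rng.standard_normal(N)
        resid -= np.polyval(np.polyfit(np.arange(N), resid, 1), np.arange(N))
        es0 = make_epoch_set(resid[None, :])
        base = es0.sample_slice(-250.0, 0.0)
        resid -= resid[base].mean()
        es = make_epoch_set((resid + np.linspace(-2, 2, N) + 5.0)[None, :])
        out = detrend_and_baseline(es)
        np.testing.assert_allclose(out.data[0], resid, atol=1e-8)


class TestSnr:
    def _with_windows(self, pre_vals, post_vals):
        es = make_epoch_set(np.zeros((1, N)))
        pre = es.sample_slice(-250.0, 0.0)
        post = es.sample_slice(0.0, 250.0)
        es.data[0, pre] = pre_vals
        es.data[0, post] = post_vals
        return es

    def test_equal_variances_zero_db(self, rng):
        w = rng.standard_normal(1200)
        es = compute_snr(self._with_windows(w, w))
        assert es.info.loc[0, "snr_db"] == pytest.approx(0.0, abs=1e-9)

    def test_tenfold_post_variance_is_10db(self, rng):
        w = rng.standard_normal(1200)
        es = compute_snr(self._with_windows(w, np.sqrt(10) * w))
        assert es.info.loc[0, "snr_db"] == pytest.approx(10.0, abs=1e-9)

    def test_iid_noise_mean_snr_near_zero(self, rng):
        data = rng.standard_normal((1500, 2400))
        es = make_epoch_set(data, rate=1200.0, window_ms=(-1000.0, 1000.0))
        snrs = compute_snr(es).info["snr_db"].to_numpy()
        # var ratio of two 300-sample windows: log of F(299, 299)
        se = snrs.std() / np.sqrt(len(snrs))
        assert abs(snrs.mean()) < 3 * se + 0.05

    def test_zero_pre_window_variance_rejected(self):
        x = np.zeros((1, N))
        x[0, -100:] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            compute_snr(make_epoch_set(x))


class TestRejectBySnr:
    def test_identical_snrs_all_retained(self):
        mask = snr_retained_mask(np.full(10, 2.5))
        assert mask.all()

    def test_extreme_outlier_rejected(self, rng):
        snrs = np.concatenate([rng.normal(0, 0.5, 999), [50.0]])
        mu, sd = snrs.mean(), snrs.std()
        mask = snr_retained_mask(snrs)
        # direct recomputation oracle
        np.testing.assert_array_equal(mask, np.abs(snrs - mu) <= 3 * sd)
        assert not mask[-1]
        assert mask[:-1].all()

    def test_gaussian_retention_fraction(self, rng):
        snrs = rng.standard_normal(10_000)
        frac = snr_retained_mask(snrs).mean()
        p = 0.9973
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / 10_000)

    def test_requires_two_epochs(self):
        with pytest.raises(ValueError):
            snr_retained_mask(np.array([1.0]))


class TestSelectRepresentative:
    def _set_with_snrs(self, snrs, retained=None):
        n = len(snrs)
        es = make_epoch_set(
            np.zeros((n, N)), snr_db=snrs, retained=retained,
            pam_side="left", stim_side="left", attended_side="left",
        )
        return es

    def test_select_closest_to_mean(self):
        es = self._set_with_snrs([0.0, 1.0, 2.0, 3.0, 4.0])
        out = select_representative(es, 3)
        chosen = sorted(out.info.loc[out.info["selected"], "snr_db"])
        assert chosen == [1.0, 2.0, 3.0]

    def test_tie_broken_by_earlier_index(self):
        es = self._set_with_snrs([1.0, 3.0])
        out = select_representative(es, 1)
        assert out.info.loc[0, "selected"] and not out.info.loc[1, "selected"]

    def test_full_cell_selection_and_idempotence(self):
        es = self._set_with_snrs([0.0, 1.0, 5.0, 2.0])
        out = select_representative(es, 4)
        assert out.info["selected"].all()
        again = select_representative(out, 4)
        pd.testing.assert_frame_equal(again.info, out.info)

    def test_short_cell_raises_with_cell_name(self):
        es = self._set_with_snrs([0.0, 1.0])
        with pytest.raises(ValueError, match="left"):
            select_representative(es, 3)

    def test_rejected_epochs_not_selectable(self):
        es = self._set_with_snrs([0.0, 1.0, 2.0], retained=[True, False, True])
        out = select_representative(es, 2)
        assert not out.info.loc[1, "selected"]


class TestReflexNormalize:
    def _sets(self, scale=1.0):
        data = []
        labels = dict(pam_side=[], stim_side=[], attended_side=[])
        for stim in ("left", "right"):
            for att in ("left", "right"):
                for rep in range(2):
                    x = np.zeros(N)
                    win_start = N // 2 + int(0.005 * RATE)
                    x[win_start + rep] = scale * 2.0  # peak inside [5, 30] ms
                    data.append(x)
                    labels["pam_side"].append("left")
                    labels["stim_side"].append(stim)
                    labels["attended_side"].append(att)
        es = make_epoch_set(np.array(data), selected=True, **labels)
        return es

    def test_factor_and_scaling(self):
        std = self._sets()
        dev = self._sets()
        out_std, out_dev, factor = reflex_normalize(std, dev, "left")
        assert factor.value == pytest.approx(1.0)  # cell averages peak at 2/2
        win = out_std.sample_slice(5.0, 30.0, closed=True)
        pooled = np.concatenate([out_std.data[:, win], out_dev.data[:, win]])
        assert np.abs(pooled).max() == pytest.approx(2.0 / factor.value)

    def test_ratios_preserved_and_scale_invariant(self):
        std1, dev1 = self._sets(), self._sets()
        std2, dev2 = self._sets(2.0), self._sets(2.0)
        a_std, a_dev, f1 = reflex_normalize(std1, dev1, "left")
        b_std, b_dev, f2 = reflex_normalize(std2, dev2, "left")
        assert f2.value == pytest.approx(2 * f1.value)
        np.testing.assert_allclose(a_std.data, b_std.data)
        ratio_before = std1.data[0].max() / std1.data[1].max()
        ratio_after = a_std.data[0].max() / a_std.data[1].max()
        assert ratio_after == pytest.approx(ratio_before)

    def test_no_reflex_energy_rejected(self):
        std = make_epoch_set(
            np.zeros((8, N)),
            pam_side="left",
            stim_side=["left"] * 4 + ["right"] * 4,
            attended_side=["left", "left", "right", "right"] * 2,
            selected=True,
        )
        with pytest.raises(ValueError, match="reliability"):
            reflex_normalize(std, std, "left")


def test_epoch_length_invariant():
    """[-1000, 1000) ms at 4,800 Hz spans 9,600 samples."""
    rec = make_bipolar()
    es = extract_epochs(rec, "chirp", "left")
    assert es.data.shape[1] == 9600
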