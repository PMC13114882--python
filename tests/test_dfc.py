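"""Sliding-window dFC construction and clip alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fmrifuse.dfc import (
    DfcParams,
    align_dfc,
    aligned_length,
    build_dfc_sequence,
    dfc_bundle,
    load_dfc_cache,
    save_dfc_cache,
    window_indices,
    windowed_correlation,
)
from fmrifuse.io import RegionalTimeSeries
from oracles import pearson_oracle


class TestWindowIndices:
    def test_reference_windowing(self):
        wins = window_indices(200, DfcParams(30, 2))
        assert len(wins) == 86
        assert (wins[0].start, wins[0].stop) == (0, 30)
        assert (wins[-1].start, wins[-1].stop) == (170, 200)
        # brute force: every offset whose window fits
        brute = [k for k in range(200) if 2 * k + 30 <= 200]
        assert len(brute) == len(wins)

    def test_boundaries(self):
        assert len(window_indices(30, DfcParams(30, 2))) == 1
        assert len(window_indices(31, DfcParams(30, 2))) == 1
        with pytest.raises(ValueError, match="shorter than window"):
            window_indices(29, DfcParams(30, 2))


class TestWindowedCorrelation:
    def test_identical_and_inverted_series(self, rng):
        x = rng.normal(size=30)
        series = RegionalTimeSeries(np.stack([x, x, -x], axis=1), "a")
        corr = windowed_correlation(series, range(0, 30))
        assert corr[0, 1] == pytest.approx(1.0)
        assert corr[0, 2] == pytest.approx(-1.0)

    def test_matches_pearson_oracle(self, rng):
        block = rng.normal(size=(30, 5))
        series = RegionalTimeSeries(block, "a")
        corr = windowed_correlation(series, range(0, 30))
        np.testing.assert_allclose(corr, pearson_oracle(block), atol=1e-10)

    def test_zero_variance_roi(self):
        values = np.ones((10, 2))
        values[:, 1] = np.arange(10)
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = windowed_correlation(RegionalTimeSeries(values, "a"),
                                        range(0, 10))
        assert corr[0, 0] == 1.0 and corr[0, 1] == 0.0 and corr[1, 0] == 0.0


class TestDfcSequence:
    def test_shape_and_invariants(self, rng):
        series = RegionalTimeSeries(rng.normal(size=(60, 10)), "a")
        seq = build_dfc_sequence(series, DfcParams(30, 2))
        assert seq.data.shape == (16, 10, 10)
        np.testing.assert_array_equal(seq.data, seq.data.transpose(0, 2, 1))
        assert np.all(np.abs(seq.data) <= 1.0)
        for k in range(16):
            np.testing.assert_array_equal(np.diag(seq.data[k]), 1.0)

    def test_single_roi_atlas(self, rng):
        seq = build_dfc_sequence(
            RegionalTimeSeries(rng.normal(size=(40, 1)), "a"), DfcParams(30, 2))
        np.testing.assert_array_equal(seq.data, np.ones((6, 1, 1)))

    def test_stationary_signals_give_stable_slices(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=500)
        noise = rng.normal(size=(500, 2)) * 0.3
        values = np.stack([z + noise[:, 0], z + noise[:, 1],
                           rng.normal(size=500)], axis=1)
        seq = build_dfc_sequence(RegionalTimeSeries(values, "a"),
                                 DfcParams(100, 50))
        spread = seq.data.max(axis=0) - seq.data.min(axis=0)
        assert spread.max() < 0.35  # sampling error only


class TestAlignment:
    def test_start_window_and_length_closed_forms(self):
        assert align_dfc(self._seq(200), t0=10, T=20).k0 == 5
        assert aligned_length(20, 1, 2) == 10
        assert aligned_length(8, 2, 3) == 6  # ceil(16/3)

    @staticmethod
    def _seq(ts, na=3):
        rng = np.random.default_rng(0)
        return build_dfc_sequence(
            RegionalTimeSeries(rng.normal(size=(ts, na)), "a"), DfcParams(30, 2))

    def test_zero_padding_count(self):
        seq = self._seq(60)  # Ls = 16
        aligned = align_dfc(seq, t0=20, T=20, delta=1)  # k0=10, L=10
        assert aligned.k0 == 10 and aligned.n_padded == 4
        np.testing.assert_array_equal(aligned.data[:6], seq.data[10:16])
        np.testing.assert_array_equal(aligned.data[6:], 0.0)

    def test_degenerate_start_past_scan_warns(self):
        seq = self._seq(60)
        with pytest.warns(UserWarning, match="zero-padded"):
            aligned = align_dfc(seq, t0=200, T=4)
        assert aligned.n_padded == aligned.data.shape[0]

    def test_coverage_property(self):
        """Windows k0..k0+L-1 span the clip's volumes when unpadded."""
        seq = self._seq(400)
        for t0 in range(0, 30, 3):
            for T, delta in [(8, 1), (20, 1), (8, 2)]:
                aligned = align_dfc(seq, t0, T, delta)
                if aligned.n_padded:
                    continue
                s, w = 2, 30
                first_vol = aligned.k0 * s
                last_vol = (aligned.k0 + aligned.data.shape[0] - 1) * s + w - 1
                assert first_vol <= t0
                assert last_vol >= t0 + (T - 1) * delta

    def test_override_wins_with_warning(self):
        seq = self._seq(200)
        with pytest.warns(UserWarning, match="L_override"):
            aligned = align_dfc(seq, t0=0, T=20, delta=1, L_override=5)
        assert aligned.data.shape[0] == 5


class TestBundle:
    def test_shared_alignment_across_atlases(self, rng):
        seqs = {
            a: build_dfc_sequence(
                RegionalTimeSeries(rng.normal(size=(120, na)), a), DfcParams(30, 2))
            for a, na in [("x", 12), ("y", 10), ("z", 16)]
        }
        bundle = dfc_bundle(seqs, t0=14, T=20, delta=1)
        ks = {b.k0 for b in bundle.values()}
        ls = {b.data.shape[0] for b in bundle.values()}
        assert ks == {7} and ls == {10}
        single = dfc_bundle(seqs, t0=14, T=20, delta=1, atlases=["y"])
        assert set(single) == {"y"}

    def test_missing_atlas_errors(self, rng):
        seqs = {"x": build_dfc_sequence(
            RegionalTimeSeries(rng.normal(size=(60, 4)), "x"), DfcParams(30, 2))}
        with pytest.raises(KeyError, match="missing dFC"):
            dfc_bundle(seqs, t0=0, T=8, atlases=["x", "y"])


def test_pipeline_matches_straight_loop_reimplementation(rng):
    """Series -> sequence -> aligned subsequence equals an independent
    loop-based reimplementation within 1e-10."""
    values = rng.normal(size=(90, 6))
    params = DfcParams(20, 3)
    seq = build_dfc_sequence(RegionalTimeSeries(values, "a"), params)

    # independent reimplementation
    w, s = 20, 3
    ls = (90 - w) // s + 1
    ref = np.stack([pearson_oracle(values[k * s: k * s + w]) for k in range(ls)])
    np.testing.assert_allclose(seq.data, ref, atol=1e-10)

    t0, T, delta = 13, 10, 2
    aligned = align_dfc(seq, t0, T, delta)
    k0 = t0 // s
    L = -(-(T * delta) // s)
    ref_aligned = np.zeros((L, 6, 6))
    n_copy = min(k0 + L, ls) - k0
    ref_aligned[:n_copy] = ref[k0: k0 + n_copy]
    np.testing.assert_allclose(aligned.data, ref_aligned, atol=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(ts=st.integers(30, 90), na=st.integers(1, 6),
       seed=st.integers(0, 100))
def test_correlation_bounds_symmetry_unit_diag(ts, na, seed):
    values = np.random.default_rng(seed).normal(size=(ts, na))
    seq = build_dfc_sequence(RegionalTimeSeries(values, "a"), DfcParams(30, 2))
    assert np.all(np.abs(seq.data) <= 1.0)
    assert np.abs(seq.data - seq.data.transpose(0, 2, 1)).max() == 0.0
    assert np.abs(np.diagonal(seq.data, axis1=1, axis2=2) - 1.0).max() == 0.0


def test_hdf5_cache_round_trip(tmp_path, rng):
    seq = build_dfc_sequence(
        RegionalTimeSeries(rng.normal(size=(60, 4)), "atl"), DfcParams(30, 2))
    path = tmp_path / "dfc.h5"
    save_dfc_cache(path, "sub1", seq, tr_seconds=2.0, ts=60)
    loaded = load_dfc_cache(path, "sub1", "atl")
    np.testing.assert_array_equal(loaded.data, seq.data)
    assert loaded.params == seq.params
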