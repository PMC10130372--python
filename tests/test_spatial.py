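"""Moving-box concentration and cluster calling, checked against
brute-force window sums and constructed cluster geometries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycoclust.spatial import (
    box_concentration,
    box_concentration_tiled,
    box_counts,
    call_clusters,
    cluster_profile,
    window_px_from_mm,
)
from glycoclust.synthetic import ChannelParams, simulate_channel
from glycoclust.types import ConcentrationMap, SignalMap, TissueMask


def brute_force_counts(mask: np.ndarray, w: int) -> np.ndarray:
    """Independent nested-loop definition of the centred box sum with
    zero padding."""
    h, ww = mask.shape
    r = w // 2
    out = np.zeros((h, ww), dtype=np.int64)
    for i in range(h):
        for j in range(ww):
            out[i, j] = mask[max(0, i - r) : i + r + 1, max(0, j - r) : j + r + 1].sum()
    return out


def _sig(mask):
    mask = np.asarray(mask, bool)
    return SignalMap(mask=mask, threshold=0.0, signal_fraction=float(mask.mean()))


class TestBoxConcentration:
    @pytest.mark.parametrize("w", [3, 9, 31])
    def test_summed_area_table_matches_bruteforce(self, w, rng):
        for _ in range(5):
            mask = rng.random((64, 64)) < 0.2
            counts = box_counts(mask, w)
            assert np.array_equal(counts, brute_force_counts(mask, w))

    def test_single_pixel_window3(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        conc = box_concentration(_sig(mask), 3)
        expected = np.zeros((5, 5))
        expected[1:4, 1:4] = 1 / 9
        assert np.allclose(conc.values, expected)

    def test_all_zero_and_saturation(self):
        zero = box_concentration(_sig(np.zeros((16, 16), bool)), 5)
        assert not zero.values.any()
        full = box_concentration(_sig(np.ones((16, 16), bool)), 5)
        assert full.values[8, 8] == 1.0  # interior pixel fully covered

    def test_window_validation(self):
        sig = _sig(np.zeros((16, 16), bool))
        with pytest.raises(ValueError):
            box_concentration(sig, 4)
        with pytest.raises(ValueError):
            box_concentration(sig, 17)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), w=st.sampled_from([3, 5, 9]))
    def test_tiled_equals_whole_image(self, seed, w):
        mask = np.random.default_rng(seed).random((40, 33)) < 0.3
        whole = box_concentration(_sig(mask), w)
        tiled = box_concentration_tiled(_sig(mask), w, tile_rows=7)
        assert np.array_equal(whole.values, tiled.values)

    def test_window_px_from_mm(self):
        assert window_px_from_mm(1.0, 20.0) == 51
        assert window_px_from_mm(1.0, 10.0) == 101
        assert window_px_from_mm(0.01, 20.0) == 3  # floor at the minimum window


class TestCallClusters:
    def test_two_separated_blobs(self):
        mask = np.zeros((64, 64), bool)
        mask[8:13, 8:13] = True
        mask[48:53, 48:53] = True
        tissue = TissueMask(np.ones((64, 64), bool))
        conc = box_concentration(_sig(mask), 5)
        cm = call_clusters(conc, 0.5, tissue)
        assert cm.regions == 2
        assert cm.clustered_area_fraction > 0

    def test_tau_above_max_is_empty(self):
        tissue = TissueMask(np.ones((16, 16), bool))
        conc = ConcentrationMap(np.full((16, 16), 0.2), 3)
        cm = call_clusters(conc, 0.9, tissue)
        assert cm.regions == 0 and not cm.mask.any()

    def test_area_fraction_monotone_in_tau(self, rng):
        mask = rng.random((64, 64)) < 0.3
        tissue = TissueMask(np.ones((64, 64), bool))
        conc = box_concentration(_sig(mask), 9)
        taus = [0.05, 0.1, 0.2, 0.3, 0.5]
        prof = cluster_profile(conc, taus, tissue, primary_tau=0.1)
        fr = prof.clustered_area_fractions
        assert all(b <= a for a, b in zip(fr, fr[1:]))

    def test_tau_validation(self):
        tissue = TissueMask(np.ones((16, 16), bool))
        conc = ConcentrationMap(np.zeros((16, 16)), 3)
        with pytest.raises(ValueError):
            call_clusters(conc, 0.0, tissue)
        with pytest.raises(ValueError):
            cluster_profile(conc, [0.2, 0.1], tissue)


class TestClusterProfile:
    def _channel_amount(self, chan_params, seed, tau=0.10):
        tissue = TissueMask(np.ones((150, 150), bool))  # 3 x 3 mm at 20 µm/px
        _, truth, _ = simulate_channel(tissue, chan_params, pixel_size=20.0, seed=seed)
        conc = box_concentration(truth, 51)
        prof = cluster_profile(conc, [tau], tissue, primary_tau=tau)
        return truth.signal_fraction, prof.cluster_amount

    def test_clustered_beats_uniform_noise_at_equal_signal(self):
        clustered = ChannelParams(parent_rate=0.7, offspring_per_parent=600, offspring_sd=150.0, uniform_noise_rate=0.0)
        amounts_c, amounts_u, fracs_c, fracs_u = [], [], [], []
        for s in range(10):
            f_c, a_c = self._channel_amount(clustered, seed=s)
            # uniform channel tuned to the same expected signal load
            uniform = ChannelParams(parent_rate=0.0, offspring_per_parent=0, uniform_noise_rate=f_c * 2500.0)
            f_u, a_u = self._channel_amount(uniform, seed=s)
            amounts_c.append(a_c), amounts_u.append(a_u)
            fracs_c.append(f_c), fracs_u.append(f_u)
        assert abs(np.mean(fracs_c) - np.mean(fracs_u)) < 0.25 * max(np.mean(fracs_c), 1e-9)
        assert np.mean(amounts_c) > np.mean(amounts_u)

    def test_broad_clusters_outrank_punctate_at_equal_signal(self):
        # equal expected signal load, different dispersion: the broad channel
        # spreads enough pixels over the 1-mm box to clear tau, the punctate
        # one saturates small footprints
        punctate = ChannelParams(parent_rate=4.0, offspring_per_parent=260, offspring_sd=40.0, uniform_noise_rate=0.0)
        broad = ChannelParams(parent_rate=0.7, offspring_per_parent=900, offspring_sd=200.0, uniform_noise_rate=0.0)
        a_p, a_b, f_p, f_b = [], [], [], []
        for s in range(10):
            fp, ap = self._channel_amount(punctate, seed=100 + s)
            fb, ab = self._channel_amount(broad, seed=200 + s)
            a_p.append(ap), a_b.append(ab), f_p.append(fp), f_b.append(fb)
        assert np.mean(a_b) > np.mean(a_p)
        # cluster amount is therefore not a function of signal amount alone
        assert abs(np.mean(f_b) - np.mean(f_p)) < 0.5 * max(np.mean(f_b), np.mean(f_p))

    def test_empty_signal_gives_zero_profile(self):
        tissue = TissueMask(np.ones((32, 32), bool))
        conc = box_concentration(_sig(np.zeros((32, 32), bool)), 5)
        prof = cluster_profile(conc, [0.05, 0.1], tissue, primary_tau=0.1)
        assert prof.cluster_amount == 0.0
        assert prof.regions == [0, 0]
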