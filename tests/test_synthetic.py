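"""Generator contracts: determinism, tissue geometry, Neyman–Scott truth
structure, and the proportional-hazards outcome model."""

import numpy as np
import pandas as pd
import pytest

from glycoclust.stats import cox_fit
from glycoclust.synthetic import (
    ChannelParams,
    SimulationParams,
    TissueGenerationError,
    make_tissue_mask,
    simulate_channel,
    simulate_cohort,
    simulate_outcome_table,
    simulate_specimen,
)
from glycoclust.types import TissueMask


class TestTissueMask:
    def test_target_fraction_and_connectivity(self):
        mask = make_tissue_mask((256, 256), smoothness=12, target_fraction=0.5, seed=1)
        frac = mask.fraction_of_frame()
        assert 0.45 <= frac <= 0.55
        from skimage.measure import label

        assert label(mask.mask, connectivity=2).max() == 1

    def test_deterministic(self):
        a = make_tissue_mask((128, 128), 8, 0.4, seed=7)
        b = make_tissue_mask((128, 128), 8, 0.4, seed=7)
        assert np.array_equal(a.mask, b.mask)

    def test_extreme_target_never_silently_empty(self):
        try:
            mask = make_tissue_mask((128, 128), smoothness=1, target_fraction=0.99, seed=2)
        except TissueGenerationError:
            return
        assert mask.mask.any()
        assert abs(mask.fraction_of_frame() - 0.99) <= 0.05

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_tissue_mask((128, 128), 8, 1.5, seed=0)


class TestSimulateChannel:
    def test_zero_rates_give_pure_background(self):
        tissue = make_tissue_mask((128, 128), 8, 0.5, seed=1)
        params = ChannelParams(parent_rate=0.0, uniform_noise_rate=0.0)
        img, truth, parents = simulate_channel(tissue, params, pixel_size=20.0, seed=5)
        assert truth.signal_fraction == 0.0
        assert not truth.mask.any()
        assert len(parents) == 0
        assert (img.pixels[tissue.mask] > 0).all()
        assert (img.pixels[~tissue.mask] == 0).all()

    def test_zero_dispersion_puts_offspring_on_parent(self):
        tissue = TissueMask(np.ones((100, 100), bool))
        params = ChannelParams(parent_rate=2.0, offspring_per_parent=50, offspring_sd=0.0, uniform_noise_rate=0.0)
        _, truth, parents = simulate_channel(tissue, params, pixel_size=20.0, seed=3)
        expected = {tuple(np.rint(p).astype(int)) for p in parents}
        got = {tuple(ij) for ij in np.argwhere(truth.mask)}
        assert got == expected

    def test_parent_count_is_poisson_with_stated_mean(self):
        # rate 2 clusters/mm² on a 2 × 2 mm tissue (100 × 100 px at 20 µm)
        tissue = TissueMask(np.ones((100, 100), bool))
        params = ChannelParams(parent_rate=2.0, offspring_per_parent=10, offspring_sd=30.0, uniform_noise_rate=0.0)
        counts = [
            len(simulate_channel(tissue, params, pixel_size=20.0, seed=s)[2]) for s in range(20)
        ]
        se = np.sqrt(8.0 / 20)
        assert abs(np.mean(counts) - 8.0) <= 3 * se

    def test_truth_inside_tissue(self, specimen_all_types):
        for sig in specimen_all_types.truth_signal.values():
            assert not np.any(sig.mask & ~specimen_all_types.tissue.mask)
        assert not np.any(specimen_all_types.cancer_annotation & ~specimen_all_types.tissue.mask)


class TestCohort:
    def test_outcome_table_matches_rendered_cohort(self):
        params = SimulationParams(n_specimens=4, seed=11)
        table = simulate_outcome_table(params)
        bundle = simulate_cohort(params)
        pd.testing.assert_frame_equal(table, bundle.outcomes)
        assert [s.profile for s in bundle.specimens] == list(table["profile"])
        assert [s.heterogeneity_truth for s in bundle.specimens] == list(table["het_truth"])

    def test_cohort_deterministic(self):
        params = SimulationParams(n_specimens=3, seed=21)
        b1 = simulate_cohort(params)
        b2 = simulate_cohort(params)
        pd.testing.assert_frame_equal(b1.outcomes, b2.outcomes)
        for s1, s2 in zip(b1.specimens, b2.specimens):
            assert np.array_equal(s1.channels["marker_a"].pixels, s2.channels["marker_a"].pixels)
            assert np.array_equal(s1.tissue.mask, s2.tissue.mask)

    def test_specimen_draws_independent_of_cohort_size(self):
        small = SimulationParams(n_specimens=3, seed=31)
        big = SimulationParams(n_specimens=8, seed=31)
        t_small = simulate_outcome_table(small)
        t_big = simulate_outcome_table(big)
        pd.testing.assert_frame_equal(t_small, t_big.iloc[:3].reset_index(drop=True))

    def test_beta_recovery_no_censoring(self):
        # log HR ln 3, baseline 0.2, n = 200, censoring pushed beyond reach.
        # The sampling sd of the Breslow MLE for a binary covariate under
        # these conditions is ~0.17 (late risk sets lose the high-hazard
        # group and with it information), so ±0.25 coverage is ~84%; the
        # replicate-count bound reflects that, and the mean must be
        # unbiased.
        devs = []
        for r in range(50):
            params = SimulationParams(
                n_specimens=200, seed=5000 + r, log_hazard_ratio=np.log(3), censoring_horizon=1e9
            )
            df = simulate_outcome_table(params)
            fit = cox_fit(df["time"].values, df["event"].values, (df["het_truth"] >= 2).astype(float).values)
            devs.append(fit.beta_hat - np.log(3))
        assert abs(np.mean(devs)) <= 0.1
        assert np.mean(np.abs(np.asarray(devs)) <= 0.25) >= 0.72

    def test_events_censored_at_horizon(self):
        params = SimulationParams(n_specimens=50, seed=2)
        df = simulate_outcome_table(params)
        assert (df["time"] > 0).all()
        assert df["event"].isin([0, 1]).all()
        assert (df.loc[df["event"] == 0, "time"] == params.censoring_horizon).all()
        assert (df.loc[df["event"] == 1, "time"] < params.censoring_horizon).all()

    def test_minimum_cohort_size(self):
        with pytest.raises(ValueError):
            simulate_cohort(SimulationParams(n_specimens=1, seed=0))
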