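"""Augmenter laws: clipping, Mixup interpolation, noise law, WGAN-GP contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpsrec.augmentation import (
    ClipBounds,
    MixupAugmenter,
    MixupConfig,
    NoiseAugmenter,
    NoiseConfig,
    WGAN_TEST_PRESET,
    WganGpAugmenter,
    WganGpConfig,
    clip_to_bounds,
    mixup_augment,
    mixup_combine,
    noise_augment,
)
from cpsrec.cohort import OUTCOME


class TestClipBounds:
    def test_one_percent_extension(self):
        t = pd.DataFrame({"a": [0.0, 10.0], OUTCOME: [0.0, 100.0]})
        b = ClipBounds.from_table(t)
        assert b.low["a"] == pytest.approx(-0.1)
        assert b.high["a"] == pytest.approx(10.1)
        clipped = clip_to_bounds(pd.DataFrame({"a": [10.4], OUTCOME: [50.0]}), b)
        assert clipped["a"].iloc[0] == pytest.approx(10.1)

    def test_nonnegative_floor_on_cho(self):
        t = pd.DataFrame({"CHO": [0.0, 1.2], OUTCOME: [0.0, 1.0]})
        b = ClipBounds.from_table(t)
        assert b.low["CHO"] == 0.0  # extension would give -0.012; floored
        clipped = clip_to_bounds(pd.DataFrame({"CHO": [-0.05], OUTCOME: [0.5]}), b)
        assert clipped["CHO"].iloc[0] == 0.0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_clip_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        t = pd.DataFrame(rng.normal(0, 5, size=(20, 3)), columns=["a", "b", "CHO"])
        b = ClipBounds.from_table(t.iloc[:10])
        once = clip_to_bounds(t, b)
        pd.testing.assert_frame_equal(clip_to_bounds(once, b), once)

    def test_column_mismatch_rejected(self):
        t = pd.DataFrame({"a": [1.0, 2.0]})
        b = ClipBounds.from_table(pd.DataFrame({"z": [0.0, 1.0]}))
        with pytest.raises(ValueError, match="mismatch"):
            clip_to_bounds(t, b)


class TestMixup:
    def test_lambda_one_is_identity_and_midpoint(self):
        xi = np.array([1.0, 2.0, 3.0])
        xj = np.array([5.0, 6.0, 7.0])
        assert np.array_equal(mixup_combine(xi, xj, 1.0), xi)
        assert np.array_equal(mixup_combine(xi, xj, 0.0), xj)
        zeros, twos = np.zeros(4), np.full(4, 2.0)
        assert np.array_equal(mixup_combine(zeros, twos, 0.5), np.ones(4))

    def test_rows_are_convex_combinations_of_source_pairs(self, small_table):
        synth = mixup_augment(small_table, MixupConfig(n_synthetic=200, seed=3))
        # every synthetic value lies within the columnwise convex hull
        for c in small_table.columns:
            assert synth[c].min() >= small_table[c].min() - 1e-9
            assert synth[c].max() <= small_table[c].max() + 1e-9
        # each row is affine-consistent: one lambda reproduces all columns
        src = small_table.to_numpy()
        row = synth.iloc[0].to_numpy()
        found = False
        for i in range(len(src)):
            for j in range(len(src)):
                if i == j:
                    continue
                denom = src[i] - src[j]
                with np.errstate(divide="ignore", invalid="ignore"):
                    lam = (row - src[j]) / denom
                lam = lam[np.abs(denom) > 1e-9]
                if len(lam) and np.allclose(lam, lam[0], atol=1e-8):
                    found = True
                    break
            if found:
                break
        assert found

    def test_beta_symmetry_monte_carlo(self, small_table):
        """lambda ~ Beta(0.2, 0.2) has mean 0.5; recover lambdas from the
        outcome column and check the sample mean within 3 SE."""
        n = 40_000
        aug = MixupAugmenter(alpha=0.20).fit(small_table.iloc[:2])
        synth = aug.sample(n, seed=5)
        x1, x2 = small_table[OUTCOME].iloc[0], small_table[OUTCOME].iloc[1]
        # recovered value is lambda or 1 - lambda depending on pair order;
        # both are Beta(alpha, alpha), so the mean stays 0.5
        lam = (synth[OUTCOME] - x2) / (x1 - x2)
        sd = np.sqrt(0.25 / (2 * 0.20 + 1))  # Beta(a,a) variance = 1/(4(2a+1))
        assert abs(np.mean(lam) - 0.5) < 3 * sd / np.sqrt(n)

    def test_single_row_rejected_and_seed_determinism(self, small_table):
        with pytest.raises(ValueError, match="at least 2"):
            MixupAugmenter().fit(small_table.head(1)).sample(5)
        a = mixup_augment(small_table, MixupConfig(n_synthetic=50, seed=9))
        b = mixup_augment(small_table, MixupConfig(n_synthetic=50, seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_alpha_validation(self):
        with pytest.raises(ValueError, match="alpha"):
            MixupConfig(alpha=0.0)


class TestNoiseInjection:
    def test_sd_fraction_zero_gives_exact_copies(self, small_table):
        synth = noise_augment(small_table, NoiseConfig(sd_fraction=0.0, n_synthetic=30, seed=1))
        src = {tuple(r) for r in small_table.to_numpy().round(9)}
        assert all(tuple(r) in src for r in synth.to_numpy().round(9))

    def test_zero_variance_column_unperturbed(self):
        t = pd.DataFrame({"c": np.full(20, 7.0), "a": np.arange(20.0),
                          OUTCOME: np.arange(20.0)})
        synth = noise_augment(t, NoiseConfig(n_synthetic=100, seed=2))
        assert (synth["c"] == 7.0).all()

    def test_perturbation_sd_matches_noise_law(self):
        """Empirical SD of (synthetic - source) equals sd_fraction * sigma
        within Monte-Carlo error at 20,000 draws.  The unperturbed outcome
        column identifies each synthetic row's source row."""
        rng = np.random.default_rng(4)
        sigma = 10.0
        m = 2000
        t = pd.DataFrame(
            {"a": rng.normal(0, sigma, m), OUTCOME: np.arange(m, dtype=float)}
        )
        aug = NoiseAugmenter(sd_fraction=0.05).fit(t)
        n = 20_000
        synth = aug.sample(n, seed=6)
        src_a = t.set_index(OUTCOME)["a"]
        diff = synth["a"].to_numpy() - src_a.loc[synth[OUTCOME]].to_numpy()
        target = 0.05 * t["a"].std(ddof=1)
        se = target / np.sqrt(2 * n)
        assert abs(diff.std(ddof=1) - target) < max(3 * se, 0.01 * target)

    def test_outcome_copied_unperturbed_by_default(self, small_table):
        synth = noise_augment(small_table, NoiseConfig(n_synthetic=200, seed=7))
        src_outcomes = set(small_table[OUTCOME].round(9))
        assert all(round(v, 9) in src_outcomes for v in synth[OUTCOME])

    def test_negative_sd_fraction_rejected(self):
        with pytest.raises(ValueError, match="sd_fraction"):
            NoiseConfig(sd_fraction=-0.1)


TINY_WGAN = WganGpConfig(
    latent_dim=8, generator_widths=(16, 16), critic_widths=(16, 16),
    learning_rate=2e-4, epochs=60, batch_size=32, seed=0,
)


class TestWganGp:
    def test_seed_determinism_of_loss_traces(self, small_table):
        a = WganGpAugmenter(TINY_WGAN).fit(small_table)
        b = WganGpAugmenter(TINY_WGAN).fit(small_table)
        assert a.loss_trace_["critic"] == b.loss_trace_["critic"]
        assert a.loss_trace_["generator"] == b.loss_trace_["generator"]
        pd.testing.assert_frame_equal(a.sample(20, seed=3), b.sample(20, seed=3))

    def test_sample_schema_and_bounds(self, small_table):
        aug = WganGpAugmenter(TINY_WGAN).fit(small_table)
        synth = aug.sample(10_000, seed=1)
        assert list(synth.columns) == list(small_table.columns)
        assert len(synth) == 10_000
        assert (synth["CHO"] >= 0).all()
        for c in synth.columns:
            assert (synth[c] >= aug.bounds_.low[c] - 1e-12).all()
            assert (synth[c] <= aug.bounds_.high[c] + 1e-12).all()

    def test_scaler_fitted_on_training_subset_only(self, small_table):
        """Leakage contract: fitting on a marked subset leaves the scaler
        statistics equal to that subset's moments."""
        subset = small_table.iloc[:15]
        aug = WganGpAugmenter(TINY_WGAN).fit(subset)
        np.testing.assert_allclose(aug.scaler_mean_, subset.to_numpy().mean(axis=0))
        assert set(aug.fit_index_) == set(subset.index)

    def test_nan_input_rejected(self, small_table):
        bad = small_table.copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            WganGpAugmenter(TINY_WGAN).fit(bad)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="beta"):
            WganGpConfig(beta1=1.5)
        with pytest.raises(ValueError, match="positive"):
            WganGpConfig(epochs=0)


def test_all_augmenters_share_output_contract(small_table):
    """Row count, schema, bounds and determinism for the three methods."""
    for make in (
        lambda: MixupAugmenter(),
        lambda: NoiseAugmenter(),
        lambda: WganGpAugmenter(TINY_WGAN),
    ):
        aug = make().fit(small_table)
        s1 = aug.sample(37, seed=11)
        s2 = make().fit(small_table).sample(37, seed=11)
        assert len(s1) == 37
        assert list(s1.columns) == list(small_table.columns)
        pd.testing.assert_frame_equal(s1, s2)
        assert s1.attrs["provenance"].startswith("synthetic:")
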