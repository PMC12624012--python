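"""Tabular data augmentation: Mixup, Gaussian noise injection, and WGAN-GP.

All three augmenters share the same contract: they are fitted on a source
table (features + outcome, original scale), and produce synthetic tables
with the same columns, on the original scale, clipped to each column's
observed range extended by 1% of that range, with a hard zero floor on
designated non-negative columns (nutrient doses and counts).

* **Mixup** draws pairs of source rows (i != j, uniform, with replacement
  across synthetic rows) and interpolates features and outcome jointly with
  lambda ~ Beta(alpha, alpha), alpha = 0.20 by default.
* **Noise injection** copies a uniformly chosen source row and perturbs each
  feature with N(0, (sd_fraction * column SD)^2); sd_fraction = 0.05 by
  default.  The outcome is copied unperturbed unless ``perturb_outcome``.
* **WGAN-GP** trains a generator/critic pair on the z-scored table (features
  and outcome standardized together, scaler fitted on the source table
  only), minimizing the Wasserstein objective with a gradient penalty
  ``lambda_gp * (||grad_xhat C(xhat)||_2 - 1)^2`` at uniform real/fake
  interpolates; five critic updates per generator update; samples are
  mapped back through the stored scaler before clipping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cpsrec._nn import MLP, Adam
from cpsrec.cohort import NONNEG_COLUMNS

RANGE_EXTENSION = 0.01  # clip range extension as a fraction of the range


# ---------------------------------------------------------------------------
# clipping


@dataclass(frozen=True)
class ClipBounds:
    low: pd.Series
    high: pd.Series

    def __post_init__(self):
        if (self.low > self.high).any():
            bad = list(self.low.index[self.low > self.high])
            raise ValueError(f"low > high for columns {bad}")

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        extension: float = RANGE_EXTENSION,
        nonneg: tuple = NONNEG_COLUMNS,
    ) -> "ClipBounds":
        lo, hi = table.min(), table.max()
        pad = extension * (hi - lo)
        low, high = lo - pad, hi + pad
        floor = [c for c in table.columns if c in nonneg]
        low[floor] = low[floor].clip(lower=0.0)
        high[floor] = high[floor].clip(lower=0.0)
        return cls(low=low, high=high)


def clip_to_bounds(table: pd.DataFrame, bounds: ClipBounds) -> pd.DataFrame:
    """Clip every value into [low, high] per column; idempotent."""
    missing = set(table.columns) ^ set(bounds.low.index)
    if missing:
        raise ValueError(f"column set mismatch with bounds: {sorted(missing)}")
    return table.clip(lower=bounds.low, upper=bounds.high, axis=1)


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class MixupConfig:
    alpha: float = 0.20
    n_synthetic: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")


@dataclass(frozen=True)
class NoiseConfig:
    sd_fraction: float = 0.05
    n_synthetic: int = 2000
    seed: int = 0
    perturb_outcome: bool = False

    def __post_init__(self):
        if self.sd_fraction < 0:
            raise ValueError(f"sd_fraction must be >= 0, got {self.sd_fraction}")


@dataclass(frozen=True)
class WganGpConfig:
    """WGAN-GP training configuration.

    ``critic_lr`` (None -> same as ``learning_rate``) allows a two-timescale
    schedule in which the critic tracks faster than the generator; the
    published profile uses a single rate.  ``output_init_scale`` shrinks the
    generator's final-layer init so early samples start near the
    standardized data mean.
    """

    latent_dim: int = 100
    generator_widths: tuple = (128, 128)
    critic_widths: tuple = (128, 128)
    learning_rate: float = 0.00005
    critic_lr: float | None = None
    beta1: float = 0.50
    beta2: float = 0.90
    lambda_gp: float = 10.00
    critic_steps: int = 5
    epochs: int = 10_000
    batch_size: int = 32
    leaky_slope: float = 0.2
    output_init_scale: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("beta1 and beta2 must lie in [0, 1)")
        for name in ("latent_dim", "lambda_gp", "critic_steps", "epochs",
                     "batch_size", "learning_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: Full-scale training profile (the published recipe: latent 100, widths 128,
#: 10,000 generator cycles at a single 5e-5 learning rate).
WGAN_FULL_PRESET = WganGpConfig()

#: Reduced profile for desk-scale runs and the test suite: smaller nets and
#: latent space, fewer epochs, and a faster critic so the reduced budget
#: still reaches a settled generator.
WGAN_TEST_PRESET = WganGpConfig(
    latent_dim=16,
    generator_widths=(32, 32),
    critic_widths=(32, 32),
    learning_rate=0.00005,
    critic_lr=0.0003,
    epochs=1500,
    batch_size=64,
)


# ---------------------------------------------------------------------------
# simple augmenters


class _FittedAugmenter:
    """Shared fitted state: source table, clip bounds, provenance index."""

    method: str = "base"

    def fit(self, table: pd.DataFrame) -> "_FittedAugmenter":
        if table.isna().any().any():
            raise ValueError("augmenter input contains NaN")
        self.source_ = table.reset_index(drop=True)
        self.fit_index_ = np.asarray(table.index)
        self.bounds_ = ClipBounds.from_table(table)
        return self

    def _finish(self, values: np.ndarray) -> pd.DataFrame:
        out = pd.DataFrame(values, columns=self.source_.columns)
        out = clip_to_bounds(out, self.bounds_)
        out.attrs["provenance"] = f"synthetic:{self.method}"
        return out


def mixup_combine(row_i: np.ndarray, row_j: np.ndarray, lam: float) -> np.ndarray:
    """Convex combination ``lam * row_i + (1 - lam) * row_j`` of two full
    rows (features and outcome interpolated jointly)."""
    return lam * np.asarray(row_i, dtype=float) + (1 - lam) * np.asarray(
        row_j, dtype=float
    )


class MixupAugmenter(_FittedAugmenter):
    method = "mixup"

    def __init__(self, alpha: float = 0.20):
        self.config = MixupConfig(alpha=alpha)

    def sample(self, n: int, seed: int = 0) -> pd.DataFrame:
        src = self.source_.to_numpy(dtype=float)
        m = len(src)
        if m < 2:
            raise ValueError("Mixup needs at least 2 source rows")
        rng = np.random.default_rng(seed)
        i = rng.integers(0, m, size=n)
        j = rng.integers(0, m - 1, size=n)
        j = np.where(j >= i, j + 1, j)  # uniform over ordered pairs with i != j
        lam = rng.beta(self.config.alpha, self.config.alpha, size=(n, 1))
        values = mixup_combine(src[i], src[j], lam)
        return self._finish(values)


class NoiseAugmenter(_FittedAugmenter):
    method = "noise"

    def __init__(self, sd_fraction: float = 0.05, perturb_outcome: bool = False):
        self.config = NoiseConfig(sd_fraction=sd_fraction, perturb_outcome=perturb_outcome)

    def fit(self, table: pd.DataFrame) -> "NoiseAugmenter":
        super().fit(table)
        self.col_sd_ = self.source_.std(ddof=1).fillna(0.0)
        return self

    def sample(self, n: int, seed: int = 0) -> pd.DataFrame:
        src = self.source_.to_numpy(dtype=float)
        rng = np.random.default_rng(seed)
        rows = src[rng.integers(0, len(src), size=n)]
        sd = self.col_sd_.to_numpy(dtype=float).copy()
        if not self.config.perturb_outcome:
            sd[-1] = 0.0  # outcome is the final column; copied unperturbed
        values = rows + rng.normal(0.0, 1.0, size=rows.shape) * (
            self.config.sd_fraction * sd
        )
        return self._finish(values)


# ---------------------------------------------------------------------------
# WGAN-GP


class WganGpAugmenter(_FittedAugmenter):
    """Wasserstein GAN with gradient penalty on the z-scored table.

    The generator (ReLU hidden activations) maps a ``latent_dim`` standard
    normal vector to the standardized feature+outcome space; the critic
    (LeakyReLU) scores samples.  Training is deterministic under the config
    seed: two fits with identical config and data give identical loss
    traces.
    """

    method = "wgan-gp"

    def __init__(self, config: WganGpConfig | None = None):
        self.config = config or WGAN_TEST_PRESET

    def fit(self, table: pd.DataFrame) -> "WganGpAugmenter":
        super().fit(table)
        cfg = self.config
        X = self.source_.to_numpy(dtype=float)
        self.scaler_mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.scaler_sd_ = np.where(sd > 0, sd, 1.0)
        Z = (X - self.scaler_mean_) / self.scaler_sd_
        d = Z.shape[1]

        rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, 0x36A4])
        )
        self.generator_ = MLP(
            [cfg.latent_dim, *cfg.generator_widths, d], slope=0.0, rng=rng
        )
        self.generator_.Ws[-1] *= cfg.output_init_scale
        self.critic_ = MLP([d, *cfg.critic_widths, 1], slope=cfg.leaky_slope, rng=rng)
        opt_g = Adam(self.generator_.params, cfg.learning_rate, cfg.beta1, cfg.beta2)
        opt_c = Adam(
            self.critic_.params,
            cfg.critic_lr if cfg.critic_lr is not None else cfg.learning_rate,
            cfg.beta1, cfg.beta2,
        )

        n, B = len(Z), cfg.batch_size
        self.loss_trace_ = {"critic": [], "generator": []}
        for epoch in range(cfg.epochs):
            for _ in range(cfg.critic_steps):
                real = Z[rng.integers(0, n, size=B)]
                z = rng.standard_normal((B, cfg.latent_dim))
                fake, _ = self.generator_.forward(z)

                out_f, cache_f = self.critic_.forward(fake)
                grads_f, _ = self.critic_.backward(cache_f, np.full((B, 1), 1.0 / B))
                out_r, cache_r = self.critic_.forward(real)
                grads_r, _ = self.critic_.backward(cache_r, np.full((B, 1), -1.0 / B))

                eps = rng.random((B, 1))
                xhat = eps * real + (1 - eps) * fake
                g, pcache = self.critic_.input_gradient(xhat)
                norms = np.sqrt((g * g).sum(axis=1, keepdims=True)) + 1e-12
                gp = float(np.mean((norms - 1.0) ** 2))
                u = (2.0 * cfg.lambda_gp / B) * (norms - 1.0) / norms * g
                grads_p = self.critic_.penalty_param_grads(pcache, u)

                grads = [gf + gr + gp_ for gf, gr, gp_ in zip(grads_f, grads_r, grads_p)]
                opt_c.step(grads)
                c_loss = float(out_f.mean() - out_r.mean() + cfg.lambda_gp * gp)

            z = rng.standard_normal((B, cfg.latent_dim))
            fake, gcache = self.generator_.forward(z)
            gx, _ = self.critic_.input_gradient(fake)
            g_grads, _ = self.generator_.backward(gcache, -gx / B)
            opt_g.step(g_grads)
            out_f, _ = self.critic_.forward(fake)
            g_loss = float(-out_f.mean())

            if not (np.isfinite(c_loss) and np.isfinite(g_loss)):
                raise RuntimeError(f"non-finite WGAN-GP loss at epoch {epoch}")
            self.loss_trace_["critic"].append(c_loss)
            self.loss_trace_["generator"].append(g_loss)
        return self

    def sample_scaled(self, n: int, seed: int = 0) -> np.ndarray:
        """Draw ``n`` generator outputs in the standardized space."""
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5A17])
        )
        z = rng.standard_normal((n, self.config.latent_dim))
        out, _ = self.generator_.forward(z)
        return out

    def sample(self, n: int, seed: int = 0) -> pd.DataFrame:
        if n < 1:
            raise ValueError(f"n must be >= 1, got {n}")
        out = self.sample_scaled(n, seed)
        values = out * self.scaler_sd_ + self.scaler_mean_
        return self._finish(values)


# ---------------------------------------------------------------------------
# functional surface

AUGMENTERS = {
    "mixup": MixupAugmenter,
    "noise": NoiseAugmenter,
    "wgan-gp": WganGpAugmenter,
}


def make_augmenter(method: str, wgan_config: WganGpConfig | None = None):
    if method == "wgan-gp":
        return WganGpAugmenter(wgan_config)
    if method not in AUGMENTERS:
        raise ValueError(f"unknown augmentation method {method!r}")
    return AUGMENTERS[method]()


def mixup_augment(table: pd.DataFrame, config: MixupConfig) -> pd.DataFrame:
    aug = MixupAugmenter(alpha=config.alpha).fit(table)
    return aug.sample(config.n_synthetic, seed=config.seed)


def noise_augment(table: pd.DataFrame, config: NoiseConfig) -> pd.DataFrame:
    aug = NoiseAugmenter(
        sd_fraction=config.sd_fraction, perturb_outcome=config.perturb_outcome
    ).fit(table)
    return aug.sample(config.n_synthetic, seed=config.seed)


def wgan_gp_fit(table: pd.DataFrame, config: WganGpConfig) -> WganGpAugmenter:
    return WganGpAugmenter(config).fit(table)


def wgan_gp_sample(
    gen: WganGpAugmenter, n: int, bounds: ClipBounds | None = None, seed: int = 0
) -> pd.DataFrame:
    out = gen.sample(n, seed=seed)
    if bounds is not None:
        out = clip_to_bounds(out, bounds)
    return out
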