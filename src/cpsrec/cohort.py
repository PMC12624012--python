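"""Synthetic cohort generation.

The real dataset behind this pipeline — 231 rowing-ergometer trials with 46
numeric baseline/nutrition indicators and a "Rowing distance" outcome — is
private.  This module generates seeded synthetic cohorts that reproduce the
statistical *structure* the pipeline assumes, so every downstream stage
(partitioning, feature selection, augmentation, modeling, recommendation) is
testable end to end:

* 46 non-negative-where-appropriate numeric features, named after the study's
  indicator battery (anthropometry, sleep, HRV, blood markers, beverage
  composition, ...);
* supplement dose columns ``CHO`` and ``PRO`` in g/kg/h sampled from the
  trial conditions of the source studies (eight 4:1 CPS dose levels plus five
  crossover conditions, so both PRO = CHO/4 and PRO = 0 regimes appear);
* planted high-correlation pairs mirroring the published collinearity table
  (e.g. Magnesium-Calcium at r = 1.00, beverage minerals tracking CHO);
* an outcome built from a baseline-fitness term plus an individual-specific
  quadratic dose-response with an interior optimum, plus Gaussian noise.

Marginals are produced by pushing a Gaussian copula through exact marginal
quantile functions (truncated normal, lognormal, or scaled Poisson counts),
so planted rank structure survives the marginal transforms and analytic
moments are available for recovery tests.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

OUTCOME = "Rowing distance"

#: CHO levels (g/kg/h) of the eight randomized CPS conditions; PRO = CHO/4.
CPS_CHO_LEVELS = np.round(np.arange(0.50, 1.21, 0.10), 2)

#: Crossover conditions as (CHO, PRO) in g/kg/h; the personalized-CPS
#: analogue draws CHO uniformly on [0.50, 1.20] at 4:1, encoded as None.
CROSSOVER_CONDITIONS = [(0.0, 0.0), (0.80, 0.0), (1.00, 0.0), (0.80, 0.20), None]

#: Share of records from the randomized dose-response phase (171 of 231).
RCT_SHARE = 171 / 231

#: Dose domain in g/kg/h.
CHO_MIN, CHO_MAX = 0.50, 1.20

#: Nutrient and count columns carrying a hard non-negativity floor.
NONNEG_COLUMNS = (
    "CHO",
    "PRO",
    "fat",
    "Sodium",
    "Magnesium",
    "Calcium",
    "Total cigarettes in last 30 days",
    "Total alcohol units in last 30 days",
    "PSQI",
)


@dataclass(frozen=True)
class FeatureSpec:
    """Marginal distribution and optional collinearity link for one feature.

    ``collinear_with`` is ``(partner_name, rho)``: this feature's copula
    latent is ``rho * z_partner + sqrt(1 - rho^2) * eps``.  A partner may be
    a dose column (``CHO``/``PRO``), in which case the standardized sampled
    dose plays the role of the partner latent.
    """

    name: str
    family: str  # {"truncated-normal", "lognormal", "scaled-count"}
    location: float
    scale: float
    lower_bound: float = 0.0
    upper_bound: float = math.inf
    collinear_with: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("truncated-normal", "lognormal", "scaled-count"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.collinear_with is not None and abs(self.collinear_with[1]) > 1:
            raise ValueError(
                f"{self.name}: |target correlation| must be <= 1, "
                f"got {self.collinear_with[1]}"
            )

    # -- marginal machinery ------------------------------------------------

    def transform(self, z: np.ndarray) -> np.ndarray:
        """Map latent (approximately standard normal) values to the margin."""
        u = np.clip(stats.norm.cdf(z), 1e-12, 1 - 1e-12)
        if self.family == "truncated-normal":
            a = (self.lower_bound - self.location) / self.scale
            b = (self.upper_bound - self.location) / self.scale
            return stats.truncnorm.ppf(u, a, b, loc=self.location, scale=self.scale)
        if self.family == "lognormal":
            return self.lower_bound + stats.lognorm.ppf(
                u, s=self.scale, scale=math.exp(self.location)
            )
        # scaled-count: scale * Poisson(location) via inverse CDF
        return self.scale * stats.poisson.ppf(u, mu=self.location)

    def moments(self) -> tuple[float, float]:
        """Analytic (mean, sd) of the marginal distribution."""
        if self.family == "truncated-normal":
            a = (self.lower_bound - self.location) / self.scale
            b = (self.upper_bound - self.location) / self.scale
            m, v = stats.truncnorm.stats(
                a, b, loc=self.location, scale=self.scale, moments="mv"
            )
            return float(m), float(math.sqrt(v))
        if self.family == "lognormal":
            m, v = stats.lognorm.stats(
                s=self.scale, scale=math.exp(self.location), moments="mv"
            )
            return self.lower_bound + float(m), float(math.sqrt(v))
        return self.scale * self.location, self.scale * math.sqrt(self.location)


@dataclass(frozen=True)
class DoseResponseModel:
    """Planted ground-truth mapping from features and doses to the outcome.

    outcome = intercept
              + sum_f baseline_weights[f] * z_f          (baseline fitness)
              - curvature * (CHO - cho_opt_i)^2          (dose response)
              + pro_effect_i * PRO                       (protein response)
              + N(0, noise_sd^2)

    where ``z_f`` is the feature standardized by its analytic moments,
    ``cho_opt_i = clip(cho_opt_center + sum_f cho_opt_coeffs[f] * z_f,
    0.50, 1.20)`` is the individual's optimal CHO rate, and ``pro_effect_i``
    is ``+pro_benefit`` for responders and ``-pro_benefit`` otherwise.
    Responder status is deterministic in the record: an individual responds
    to protein iff the normal CDF of its standardized "Body water percentage"
    is at most ``responder_fraction`` (so the population responder share
    equals ``responder_fraction`` while remaining a pure function of the
    features — required for the analytic-optimum oracle).
    """

    baseline_weights: Mapping[str, float] = field(default_factory=dict)
    cho_opt_coeffs: Mapping[str, float] = field(default_factory=dict)
    curvature: float = 3000.0
    pro_benefit: float = 400.0
    responder_fraction: float = 0.7
    noise_sd: float = 300.0
    intercept: float = 14000.0
    cho_opt_center: float = 0.85
    responder_feature: str = "Body water percentage"

    def __post_init__(self) -> None:
        if self.curvature <= 0:
            raise ValueError(f"curvature must be > 0, got {self.curvature}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0 <= self.responder_fraction <= 1:
            raise ValueError(
                f"responder_fraction must be in [0, 1], got {self.responder_fraction}"
            )


def default_schema() -> list[FeatureSpec]:
    """The packaged 46-feature schema emulating the study's indicator battery.

    Locations and scales are plausible values for trained male endurance
    rowers; the collinear links plant the strongest published feature pairs
    (Magnesium-Calcium 1.00, fat-PRO 0.97, beverage minerals tracking CHO,
    the HRV block, skinfold and thigh-circumference pairs).
    """
    tn = "truncated-normal"
    ln = "lognormal"
    sc = "scaled-count"
    specs = [
        FeatureSpec("Total cigarettes in last 30 days", sc, 6.0, 1.0),
        FeatureSpec("Total alcohol units in last 30 days", sc, 5.0, 1.0),
        FeatureSpec("IES-2", tn, 3.4, 0.5, 1.0, 5.0),
        FeatureSpec("Deep sleep", tn, 1.5, 0.4, 0.0),
        FeatureSpec("light sleep", tn, 4.5, 0.8, 0.0),
        FeatureSpec("Rapid eye movement", tn, 1.8, 0.5, 0.0),
        FeatureSpec("PSQI", sc, 5.0, 1.0),
        FeatureSpec("Age", tn, 22.0, 3.0, 18.0),
        FeatureSpec("Height", tn, 180.0, 6.0, 150.0),
        FeatureSpec("weight", tn, 76.0, 8.0, 45.0),
        FeatureSpec("Triceps skinfold", ln, math.log(9.0), 0.35),
        FeatureSpec("Subscapular skinfold", ln, math.log(10.0), 0.30),
        FeatureSpec("suprailiac skinfold", ln, math.log(9.0), 0.40),
        FeatureSpec(
            "Abdominal skinfold", ln, math.log(12.0), 0.40,
            collinear_with=("suprailiac skinfold", 0.86),
        ),
        FeatureSpec("Upper arm circumference", tn, 30.0, 2.5, 15.0),
        FeatureSpec("waist circumference", tn, 80.0, 6.0, 50.0),
        FeatureSpec("hip circumference", tn, 96.0, 5.0, 60.0),
        FeatureSpec("subgluteal thigh circumference", tn, 56.0, 4.0, 30.0),
        FeatureSpec(
            "Mid-thigh circumference", tn, 52.0, 4.0, 30.0,
            collinear_with=("subgluteal thigh circumference", 0.88),
        ),
        FeatureSpec("Calf circumference", tn, 37.0, 2.5, 20.0),
        FeatureSpec("Body water percentage", tn, 60.0, 4.0, 40.0, 75.0),
        FeatureSpec("Body fat percentage", tn, 14.0, 4.0, 3.0, 40.0),
        FeatureSpec("PARS-3", tn, 55.0, 20.0, 0.0, 100.0),
        FeatureSpec("Left-hand grip strength", tn, 46.0, 7.0, 20.0),
        FeatureSpec(
            "Right-hand grip strength", tn, 48.0, 7.0, 20.0,
            collinear_with=("Left-hand grip strength", 0.75),
        ),
        FeatureSpec("average vertical jump height before exercise", tn, 48.0, 7.0, 20.0),
        FeatureSpec("Blood glucose", tn, 5.1, 0.5, 2.0),
        FeatureSpec("blood lactate", ln, math.log(1.8), 0.30),
        FeatureSpec("hemoglobin", tn, 152.0, 10.0, 100.0),
        FeatureSpec("DC Potential", tn, -15.0, 8.0, -60.0, 30.0),
        FeatureSpec("Resting heart rate", tn, 58.0, 7.0, 30.0),
        FeatureSpec("systolic blood pressure", tn, 118.0, 9.0, 80.0),
        FeatureSpec("Diastolic blood pressure", tn, 72.0, 7.0, 40.0),
        FeatureSpec("RMSSD", ln, math.log(55.0), 0.40),
        FeatureSpec("SDNN", ln, math.log(62.0), 0.35, collinear_with=("RMSSD", 0.86)),
        FeatureSpec("SDSD", ln, math.log(55.0), 0.40, collinear_with=("RMSSD", 0.86)),
        FeatureSpec("HF", ln, math.log(1000.0), 0.60, collinear_with=("RMSSD", 0.85)),
        FeatureSpec("Total power", ln, math.log(2500.0), 0.50, collinear_with=("SDNN", 0.82)),
        FeatureSpec("LF", ln, math.log(900.0), 0.55, collinear_with=("Total power", 0.85)),
        FeatureSpec("Previous meal time", tn, 2.5, 0.8, 0.5),
        FeatureSpec("CHO", tn, 0.8, 0.25, 0.0),  # dose column; margin unused
        FeatureSpec("PRO", tn, 0.2, 0.08, 0.0),  # dose column; margin unused
        FeatureSpec("fat", tn, 10.0, 6.0, 0.0, collinear_with=("PRO", 0.97)),
        FeatureSpec("Sodium", tn, 300.0, 120.0, 0.0, collinear_with=("CHO", 0.90)),
        FeatureSpec("Magnesium", tn, 48.0, 18.0, 0.0, collinear_with=("CHO", 0.95)),
        FeatureSpec("Calcium", tn, 40.0, 15.0, 0.0, collinear_with=("Magnesium", 1.00)),
    ]
    return specs


def default_dose_model() -> DoseResponseModel:
    """Default planted dose-response.

    Baseline weights (meters per SD of the feature) load on the indicators
    the study found most predictive: body weight, explosive power, meal
    timing, training load, blood markers.  The induced outcome distribution
    is centred near 14,000 m with individual spread on the order of 1,000 m,
    so a mean-predictor baseline has MAE in the high hundreds of meters.
    """
    baseline_weights = {
        "weight": 350.0,
        "average vertical jump height before exercise": 300.0,
        "PARS-3": 150.0,
        "hemoglobin": 150.0,
        "Body water percentage": 120.0,
        "Body fat percentage": -180.0,
        "Previous meal time": -150.0,
        "waist circumference": -120.0,
        "Triceps skinfold": -100.0,
        "Left-hand grip strength": 90.0,
        "Total cigarettes in last 30 days": -80.0,
        "blood lactate": -80.0,
        "Age": -60.0,
        "Total alcohol units in last 30 days": -60.0,
        "light sleep": 60.0,
        "RMSSD": 50.0,
        "systolic blood pressure": -50.0,
        "Blood glucose": 40.0,
        "hip circumference": -40.0,
        "subgluteal thigh circumference": 40.0,
    }
    cho_opt_coeffs = {
        "weight": 0.06,
        "average vertical jump height before exercise": 0.05,
        "Body water percentage": 0.04,
        "Previous meal time": -0.03,
        "hemoglobin": 0.03,
    }
    return DoseResponseModel(
        baseline_weights=baseline_weights, cho_opt_coeffs=cho_opt_coeffs
    )


# ---------------------------------------------------------------------------
# generation


def _validate_schema(schema: Sequence[FeatureSpec]) -> None:
    names = [s.name for s in schema]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate feature names in schema: {sorted(dupes)}")
    for s in schema:
        if s.collinear_with is not None and s.collinear_with[0] not in names:
            raise ValueError(
                f"{s.name}: collinear partner {s.collinear_with[0]!r} not in schema"
            )


def _generation_order(schema: Sequence[FeatureSpec]) -> list[FeatureSpec]:
    """Topological order so that each copula partner is generated first."""
    by_name = {s.name: s for s in schema}
    order: list[FeatureSpec] = []
    done: set[str] = {"CHO", "PRO"}  # doses are sampled before the copula pass
    pending = [s for s in schema if s.name not in ("CHO", "PRO")]
    while pending:
        progressed = False
        remaining = []
        for s in pending:
            partner = s.collinear_with[0] if s.collinear_with else None
            if partner is None or partner in done:
                order.append(s)
                done.add(s.name)
                progressed = True
            else:
                remaining.append(s)
        if not progressed:
            cyc = [s.name for s in remaining]
            raise ValueError(f"collinear_with links form a cycle among {cyc}")
        pending = remaining
    return order


def _sample_doses(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample (CHO, PRO) from the mixture of trial conditions."""
    cho = np.empty(n)
    pro = np.empty(n)
    is_rct = rng.random(n) < RCT_SHARE
    k_rct = int(is_rct.sum())
    levels = rng.choice(CPS_CHO_LEVELS, size=k_rct)
    cho[is_rct] = levels
    pro[is_rct] = levels / 4.0
    idx_cross = np.flatnonzero(~is_rct)
    which = rng.integers(0, len(CROSSOVER_CONDITIONS), size=idx_cross.size)
    for i, w in zip(idx_cross, which):
        cond = CROSSOVER_CONDITIONS[w]
        if cond is None:  # personalized-CPS analogue
            c = round(float(rng.uniform(CHO_MIN, CHO_MAX)), 2)
            cho[i], pro[i] = c, c / 4.0
        else:
            cho[i], pro[i] = cond
    return cho, pro


def _standardize(values: np.ndarray, spec: FeatureSpec) -> np.ndarray:
    mean, sd = spec.moments()
    return (values - mean) / sd


def _standardized_features(
    table: pd.DataFrame, schema: Sequence[FeatureSpec]
) -> dict[str, np.ndarray]:
    by_name = {s.name: s for s in schema}
    out = {}
    for name, spec in by_name.items():
        if name in ("CHO", "PRO"):
            continue
        out[name] = _standardize(table[name].to_numpy(dtype=float), spec)
    return out


def _individual_optima(
    model: DoseResponseModel, z: Mapping[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual (cho_opt, pro_effect) from standardized features."""
    n = len(next(iter(z.values())))
    opt = np.full(n, model.cho_opt_center)
    for name, coef in model.cho_opt_coeffs.items():
        opt = opt + coef * z[name]
    opt = np.clip(opt, CHO_MIN, CHO_MAX)
    u = stats.norm.cdf(z[model.responder_feature])
    responder = u <= model.responder_fraction
    pro_effect = np.where(responder, model.pro_benefit, -model.pro_benefit)
    return opt, pro_effect


def _noise_free_outcome(
    model: DoseResponseModel,
    z: Mapping[str, np.ndarray],
    cho: np.ndarray,
    pro: np.ndarray,
) -> np.ndarray:
    n = len(cho)
    y = np.full(n, model.intercept, dtype=float)
    for name, w in model.baseline_weights.items():
        y = y + w * z[name]
    opt, pro_effect = _individual_optima(model, z)
    y = y - model.curvature * (cho - opt) ** 2 + pro_effect * pro
    return y


def _schema_hash(schema: Sequence[FeatureSpec], model: DoseResponseModel) -> str:
    text = repr([(s.name, s.family, s.location, s.scale, s.lower_bound,
                  s.upper_bound, s.collinear_with) for s in schema])
    text += repr(sorted(model.baseline_weights.items()))
    text += repr(sorted(model.cho_opt_coeffs.items()))
    text += repr((model.curvature, model.pro_benefit, model.responder_fraction,
                  model.noise_sd, model.intercept, model.cho_opt_center))
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def generate_cohort(
    schema: Sequence[FeatureSpec] | None = None,
    dose_model: DoseResponseModel | None = None,
    n: int = 231,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a seeded synthetic cohort of ``n`` records.

    Returns a DataFrame with the 46 feature columns in schema order and the
    final "Rowing distance" outcome column (meters).  Identical
    ``(schema, dose_model, n, seed)`` give bit-identical output.  One global
    seed drives a splittable per-column stream, so adding or removing a
    column does not perturb the others.
    """
    schema = list(default_schema() if schema is None else schema)
    model = default_dose_model() if dose_model is None else dose_model
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    _validate_schema(schema)

    names = [s.name for s in schema]
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xC0F3])
    children = ss.spawn(len(schema) + 2)
    streams = {name: np.random.default_rng(c) for name, c in zip(names, children)}
    rng_dose = np.random.default_rng(children[-2])
    rng_noise = np.random.default_rng(children[-1])

    cho, pro = _sample_doses(n, rng_dose)
    columns: dict[str, np.ndarray] = {"CHO": cho, "PRO": pro}
    latents: dict[str, np.ndarray] = {
        "CHO": (cho - cho.mean()) / (cho.std() or 1.0),
        "PRO": (pro - pro.mean()) / (pro.std() or 1.0),
    }

    for spec in _generation_order(schema):
        eps = streams[spec.name].standard_normal(n)
        if spec.collinear_with is None:
            z = eps
        else:
            partner, rho = spec.collinear_with
            z = rho * latents[partner] + math.sqrt(max(0.0, 1 - rho**2)) * eps
        latents[spec.name] = z
        columns[spec.name] = spec.transform(z)

    table = pd.DataFrame({name: columns[name] for name in names})
    z = _standardized_features(table, schema)
    y = _noise_free_outcome(model, z, cho, pro)
    if model.noise_sd > 0:
        y = y + rng_noise.normal(0.0, model.noise_sd, size=n)
    table[OUTCOME] = y
    table.attrs["provenance"] = (
        f"synthetic seed={seed} n={n} schema={_schema_hash(schema, model)}"
    )
    return table


# ---------------------------------------------------------------------------
# ground-truth oracle


def true_optimal_dose(
    dose_model: DoseResponseModel,
    individual: pd.Series | Mapping[str, float],
    schema: Sequence[FeatureSpec] | None = None,
) -> tuple[float, float, str]:
    """Analytic argmax of the noise-free dose-response for one individual.

    The continuous domain is CHO in [0.50, 1.20] crossed with the two
    strategies PRO = CHO/4 (CPS) and PRO = 0 (CHO-only).  Under CPS the
    response is ``-k (c - opt)^2 + b c/4`` with interior maximum at
    ``opt + b / (8 k)``; under CHO-only it is maximized at ``opt``.  Ties
    (P1 == P2) go to CPS, mirroring the recommendation rule.

    Returns ``(cho_star, pro_star, strategy)`` with strategy in
    ``{"CPS", "CHO-only"}``.
    """
    schema = list(default_schema() if schema is None else schema)
    by_name = {s.name: s for s in schema}
    row = pd.Series(dict(individual))
    z = {
        name: np.atleast_1d(_standardize(np.asarray([float(row[name])]), spec))
        for name, spec in by_name.items()
        if name not in ("CHO", "PRO")
    }
    opt, pro_effect = _individual_optima(dose_model, z)
    opt_i, b = float(opt[0]), float(pro_effect[0])
    k = dose_model.curvature

    c_cps = float(np.clip(opt_i + b / (8.0 * k), CHO_MIN, CHO_MAX))
    p1 = -k * (c_cps - opt_i) ** 2 + b * c_cps / 4.0
    c_only = opt_i  # already clipped into the domain
    p2 = -k * (c_only - opt_i) ** 2

    if p1 >= p2:
        return c_cps, c_cps / 4.0, "CPS"
    return c_only, 0.0, "CHO-only"


def oracle_predictor(
    dose_model: DoseResponseModel, schema: Sequence[FeatureSpec] | None = None
) -> Callable[[pd.DataFrame], np.ndarray]:
    """Noise-free true-response predictor for recommender recovery tests.

    The returned callable maps a DataFrame of full records (feature columns
    including CHO and PRO) to the planted noise-free outcome in meters.
    """
    schema = list(default_schema() if schema is None else schema)

    def predict(records: pd.DataFrame) -> np.ndarray:
        z = _standardized_features(records, schema)
        return _noise_free_outcome(
            dose_model,
            z,
            records["CHO"].to_numpy(dtype=float),
            records["PRO"].to_numpy(dtype=float),
        )

    return predict


# ---------------------------------------------------------------------------
# CSV round trip


def write_cohort(table: pd.DataFrame, path, record_ids: bool = False) -> None:
    """Write a cohort CSV; ``record_ids=True`` adds a ``record`` id column
    so row provenance survives round trips of partitioned files."""
    if record_ids:
        table.to_csv(path, index=True, index_label="record")
    else:
        table.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "record" in table.columns:
        table = table.set_index("record")
        table.index.name = None
    if OUTCOME not in table.columns:
        raise ValueError(f"cohort file lacks the {OUTCOME!r} outcome column")
    if table.isna().any().any():
        raise ValueError("cohort contains missing values")
    table.attrs["provenance"] = f"external file {path}"
    return table
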