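"""Two-stage dose-enumeration recommender.

Given any fitted predictor of rowing distance, the recommender sweeps CHO
intake over an inclusive grid from 0.50 to 1.20 g/kg/h in 0.01 steps (71
levels), holding the individual's baseline indicators constant.  Stage one
evaluates the 4:1 carbohydrate-protein regimen (PRO = CHO/4); stage two the
CHO-only regimen (PRO = 0).  With P1 and P2 the maximum predicted
performances of the two sweeps, the CPS regimen is recommended iff
P1 >= P2 (ties go to CPS); within a stage, ties between dose levels go to
the lowest CHO, minimizing gastrointestinal load at equal predicted
performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PRO_RULES = ("quarter-of-cho", "zero")


@dataclass(frozen=True)
class DoseGrid:
    cho_min: float = 0.50
    cho_max: float = 1.20
    step: float = 0.01
    levels: tuple = ()

    def __len__(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class RecommendationResult:
    strategy: str  # "CPS-4:1" | "CHO-only"
    cho: float
    pro: float
    p1: float  # best CPS-stage prediction (meters)
    p2: float  # best CHO-only-stage prediction (meters)
    trace_cps: pd.DataFrame  # columns: cho, pro, prediction
    trace_cho_only: pd.DataFrame


def build_grid(cho_min: float = 0.50, cho_max: float = 1.20, step: float = 0.01) -> DoseGrid:
    """Inclusive arithmetic dose grid, rounded to the step's precision."""
    if not cho_min < cho_max:
        raise ValueError(f"need cho_min < cho_max, got {cho_min} >= {cho_max}")
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    k = (cho_max - cho_min) / step
    if abs(k - round(k)) > 1e-9:
        raise ValueError(f"step {step} does not evenly divide [{cho_min}, {cho_max}]")
    decimals = max(0, int(np.ceil(-np.log10(step))))
    levels = tuple(
        round(cho_min + i * step, decimals) for i in range(int(round(k)) + 1)
    )
    return DoseGrid(cho_min=cho_min, cho_max=cho_max, step=step, levels=levels)


def _predict_fn(predictor):
    return predictor.predict if hasattr(predictor, "predict") else predictor


def stage_predictions(
    predictor, baseline: pd.Series, grid: DoseGrid, pro_rule: str
) -> pd.DataFrame:
    """Predictions over all grid levels under one PRO rule.

    ``baseline`` holds the individual's indicators; CHO and PRO are
    overwritten per level (PRO = CHO/4 under "quarter-of-cho", 0 under
    "zero").  Returns a DataFrame with columns cho, pro, prediction.
    """
    if pro_rule not in PRO_RULES:
        raise ValueError(f"pro_rule must be one of {PRO_RULES}, got {pro_rule!r}")
    rows = pd.DataFrame([dict(baseline)] * len(grid))
    cho = np.asarray(grid.levels, dtype=float)
    rows["CHO"] = cho
    rows["PRO"] = cho / 4.0 if pro_rule == "quarter-of-cho" else 0.0
    pred = np.asarray(_predict_fn(predictor)(rows), dtype=float).ravel()
    if not np.isfinite(pred).all():
        bad = cho[~np.isfinite(pred)][0]
        raise ValueError(f"non-finite prediction at CHO level {bad}")
    return pd.DataFrame(
        {"cho": cho, "pro": rows["PRO"].to_numpy(), "prediction": pred}
    )


def recommend(predictor, baseline: pd.Series, grid: DoseGrid | None = None) -> RecommendationResult:
    """Two-stage enumeration over 2 x 71 candidate regimens.

    P1 = max CPS-stage prediction, P2 = max CHO-only prediction; CPS wins
    ties.  The argmax within the winning stage takes the lowest CHO among
    maximizers.  Deterministic.
    """
    grid = build_grid() if grid is None else grid
    t1 = stage_predictions(predictor, baseline, grid, "quarter-of-cho")
    t2 = stage_predictions(predictor, baseline, grid, "zero")
    i1 = int(np.argmax(t1["prediction"].to_numpy()))  # first max = lowest CHO
    i2 = int(np.argmax(t2["prediction"].to_numpy()))
    p1 = float(t1["prediction"].iloc[i1])
    p2 = float(t2["prediction"].iloc[i2])
    if p1 >= p2:
        return RecommendationResult(
            strategy="CPS-4:1",
            cho=float(t1["cho"].iloc[i1]),
            pro=float(t1["pro"].iloc[i1]),
            p1=p1, p2=p2, trace_cps=t1, trace_cho_only=t2,
        )
    return RecommendationResult(
        strategy="CHO-only",
        cho=float(t2["cho"].iloc[i2]),
        pro=0.0,
        p1=p1, p2=p2, trace_cps=t1, trace_cho_only=t2,
    )
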