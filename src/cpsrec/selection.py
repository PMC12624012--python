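"""Hybrid feature selection.

Three stages, mirroring the study's integrated assessment: a Pearson
collinearity screen (|r| > 0.80 flags a pair), boosted-tree importance
scores from a tuned model refit on the development set, and explicit
domain keep/drop rules.  For every flagged pair the lower-importance
member is removed (keep-listed names are immune), then features below an
importance floor are removed, then drop-listed features are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, ParameterSampler
from xgboost import XGBRegressor

from cpsrec.cohort import OUTCOME
from cpsrec.spaces import XGB_SPACE

#: Default collinearity threshold on |Pearson r|.
CORRELATION_THRESHOLD = 0.80

#: Default floor on normalized total-gain importance.
IMPORTANCE_FLOOR = 0.005

#: The published 21-feature working subset of the study's hybrid selection.
SELECTED_FEATURES = (
    "PARS-3",
    "average vertical jump height before exercise",
    "Total alcohol units in last 30 days",
    "weight",
    "CHO",
    "Total cigarettes in last 30 days",
    "Triceps skinfold",
    "Left-hand grip strength",
    "subgluteal thigh circumference",
    "hip circumference",
    "Age",
    "Previous meal time",
    "light sleep",
    "RMSSD",
    "systolic blood pressure",
    "waist circumference",
    "hemoglobin",
    "Body water percentage",
    "blood lactate",
    "PRO",
    "Blood glucose",
)


@dataclass(frozen=True)
class CorrelationReport:
    matrix: pd.DataFrame  # symmetric Pearson r over input features
    flagged_pairs: list  # (feature A, feature B, r), sorted by |r| descending
    threshold: float


@dataclass(frozen=True)
class SelectionDecision:
    selected: list
    dropped: list  # (feature, reason)
    importance_scores: dict
    domain_rules: dict = field(default_factory=lambda: {"keep": [], "drop": []})


def correlation_report(
    table: pd.DataFrame, threshold: float = CORRELATION_THRESHOLD
) -> CorrelationReport:
    """Pairwise Pearson correlation over input features (outcome excluded).

    Zero-variance features yield undefined correlations; their pairs are
    reported as NaN and excluded from flagging, with a warning.
    """
    if len(table) < 3:
        raise ValueError(f"need at least 3 records, got {len(table)}")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    features = table.drop(columns=[OUTCOME], errors="ignore")
    constant = [c for c in features.columns if features[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"zero-variance features excluded from collinearity flagging: {constant}",
            stacklevel=2,
        )
    matrix = features.corr(method="pearson")
    np.fill_diagonal(matrix.values, 1.0)
    flagged = []
    cols = list(matrix.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = matrix.loc[a, b]
            if np.isfinite(r) and abs(r) > threshold:
                flagged.append((a, b, float(r)))
    flagged.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))
    return CorrelationReport(matrix=matrix, flagged_pairs=flagged, threshold=threshold)


def importance_ranking(
    table: pd.DataFrame,
    hpo_config: dict | None = None,
    seed: int = 42,
) -> dict:
    """Normalized total-gain importances from a tuned boosted-tree model.

    A randomized search over the boosted-tree grid (5-fold CV, scored by
    negative MAE) picks hyperparameters; the model is then refit on the full
    input table and per-feature total-gain importances are extracted and
    normalized to sum to 1.  ``hpo_config`` may override ``n_iter`` (default
    50), ``cv`` (default 5) and ``space``.
    """
    cfg = {"n_iter": 50, "cv": 5, "space": XGB_SPACE}
    cfg.update(hpo_config or {})
    y = table[OUTCOME].to_numpy(dtype=float)
    if np.var(y) == 0:
        raise ValueError("outcome has zero variance; importances are undefined")
    X = table.drop(columns=[OUTCOME])

    sampler = list(
        ParameterSampler(cfg["space"], n_iter=cfg["n_iter"], random_state=seed)
    )
    splitter = KFold(n_splits=cfg["cv"], shuffle=True, random_state=seed)
    best_params, best_score = None, -np.inf
    for params in sampler:
        maes = []
        for tr, va in splitter.split(X):
            model = XGBRegressor(
                **params, random_state=seed, n_jobs=1, verbosity=0
            )
            model.fit(X.iloc[tr], y[tr])
            pred = model.predict(X.iloc[va])
            maes.append(np.mean(np.abs(pred - y[va])))
        score = -float(np.mean(maes))
        if score > best_score:
            best_score, best_params = score, params

    final = XGBRegressor(**best_params, random_state=seed, n_jobs=1, verbosity=0)
    final.fit(X, y)
    gains = final.get_booster().get_score(importance_type="total_gain")
    raw = np.array([gains.get(c, 0.0) for c in X.columns], dtype=float)
    total = raw.sum()
    if total == 0:
        raw = np.full(len(raw), 1.0)
        total = raw.sum()
    return {c: float(v / total) for c, v in zip(X.columns, raw)}


def integrate_selection(
    report: CorrelationReport,
    importances: dict,
    keep: tuple | list = (),
    drop: tuple | list = (),
    importance_floor: float = IMPORTANCE_FLOOR,
) -> SelectionDecision:
    """Deterministic integration of the screen, the importances and the rules.

    Order of application: domain drop-list; collinear-pair resolution
    (lower-importance member removed, lexicographic tie-break, keep-list
    immune); importance floor (keep-list immune).
    """
    names = list(report.matrix.columns)
    keep, drop = list(keep), list(drop)
    both = set(keep) & set(drop)
    if both:
        raise ValueError(f"features on both keep and drop lists: {sorted(both)}")
    for nm in keep + drop:
        if nm not in names:
            raise ValueError(f"rule names unknown feature {nm!r}")

    dropped: dict[str, str] = {}
    for nm in drop:
        dropped[nm] = "domain-exclude"

    for a, b, _r in report.flagged_pairs:
        if a in dropped or b in dropped:
            continue
        ka, kb = a in keep, b in keep
        if ka and kb:
            continue
        if ka:
            dropped[b] = f"collinear-with:{a}"
            continue
        if kb:
            dropped[a] = f"collinear-with:{b}"
            continue
        ia, ib = importances.get(a, 0.0), importances.get(b, 0.0)
        if ia > ib:
            dropped[b] = f"collinear-with:{a}"
        elif ib > ia:
            dropped[a] = f"collinear-with:{b}"
        else:  # tie: drop the lexicographically later name
            loser, winner = max(a, b), min(a, b)
            dropped[loser] = f"collinear-with:{winner}"

    for nm in names:
        if nm in dropped or nm in keep:
            continue
        if importances.get(nm, 0.0) < importance_floor:
            dropped[nm] = "low-importance"

    selected = [nm for nm in names if nm not in dropped]
    return SelectionDecision(
        selected=selected,
        dropped=sorted(dropped.items()),
        importance_scores=dict(importances),
        domain_rules={"keep": keep, "drop": drop},
    )
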