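"""Quartile-stratified development/hold-out split and CV fold assignment.

The pipeline isolates a 20% hold-out set before any model development, with
stratification on quartile bins of the outcome so both partitions span the
performance range.  Cross-validation folds reuse the same bins so each fold
is a miniature of the development set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cpsrec.cohort import OUTCOME


@dataclass(frozen=True)
class SplitResult:
    development_indices: np.ndarray
    holdout_indices: np.ndarray
    bin_labels: pd.Series  # per-record quartile bin in {1..4}
    seed: int

    def manifest(self, folds: list[np.ndarray] | None = None) -> pd.DataFrame:
        """Tabular record/partition/bin(/fold) manifest, CSV-friendly."""
        rows = []
        fold_of = {}
        if folds is not None:
            for f, idx in enumerate(folds):
                for i in idx:
                    fold_of[i] = f
        for i in self.bin_labels.index:
            part = "holdout" if i in set(self.holdout_indices) else "development"
            rows.append(
                {
                    "record": i,
                    "partition": part,
                    "bin": int(self.bin_labels.loc[i]),
                    "fold": fold_of.get(i, -1),
                }
            )
        return pd.DataFrame(rows)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def quartile_bins(outcome) -> pd.Series:
    """Assign each record a quartile bin in {1, 2, 3, 4}.

    Cuts sit at the 25th/50th/75th empirical percentiles (linear
    interpolation convention); a record exactly at a cut goes to the lower
    bin.  Degenerate outcomes (all ties) collapse into bin 1 with a warning.
    """
    y = pd.Series(outcome, dtype=float)
    if len(y) < 4:
        raise ValueError(f"need at least 4 records for quartile bins, got {len(y)}")
    if not np.isfinite(y.to_numpy()).all():
        raise ValueError("outcome contains non-finite values")
    q25, q50, q75 = np.percentile(y.to_numpy(), [25, 50, 75], method="linear")
    labels = 1 + (y > q25).astype(int) + (y > q50).astype(int) + (y > q75).astype(int)
    if labels.nunique() == 1:
        warnings.warn(
            "degenerate outcome (all quartile cuts tie): stratified split "
            "degrades to a simple random split",
            stacklevel=2,
        )
    return labels


def stratified_split(
    table: pd.DataFrame, test_fraction: float = 0.20, seed: int = 42
) -> SplitResult:
    """Quartile-stratified development/hold-out split.

    Hold-out counts are allocated per bin as round-half-up of
    ``|bin| * test_fraction`` and sampled without replacement; with the
    default 20% fraction a 231-record cohort yields a 184/47 split.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    bins = quartile_bins(table[OUTCOME])
    rng = np.random.default_rng(seed)
    holdout: list = []
    for b in sorted(bins.unique()):
        members = bins.index[bins == b].to_numpy()
        if len(members) < 2:
            warnings.warn(
                f"quartile bin {b} has fewer than 2 records; best-effort "
                "allocation keeps it in the development set",
                stacklevel=2,
            )
            continue
        k = min(_round_half_up(len(members) * test_fraction), len(members) - 1)
        take = rng.permutation(len(members))[:k]
        holdout.extend(members[take])
    holdout_idx = np.array(sorted(holdout))
    dev_idx = np.array(sorted(set(bins.index) - set(holdout)))
    return SplitResult(dev_idx, holdout_idx, bins, seed)


def make_folds(
    development: np.ndarray,
    k: int = 5,
    seed: int = 42,
    bin_labels: pd.Series | None = None,
) -> list[np.ndarray]:
    """Split development indices into ``k`` disjoint validation folds.

    Folds are disjoint, their union is the development set, and sizes differ
    by at most one.  When ``bin_labels`` is given, records are grouped by
    quartile bin (shuffled within bin) and dealt round-robin so every fold
    samples each bin evenly.
    """
    development = np.asarray(development)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(development):
        raise ValueError(f"k={k} exceeds development size {len(development)}")
    rng = np.random.default_rng(seed)
    if bin_labels is not None:
        ordered: list = []
        labels = bin_labels.loc[development]
        for b in sorted(labels.unique()):
            members = development[(labels == b).to_numpy()]
            ordered.extend(members[rng.permutation(len(members))])
        ordered = np.asarray(ordered)
    else:
        ordered = development[rng.permutation(len(development))]
    folds = [ordered[f::k] for f in range(k)]
    return [np.sort(f) for f in folds]
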