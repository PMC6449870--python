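"""Per-plate Z-score normalization, replicate averaging and feature filtering.

The screen's batch structure is removed by Z-scoring every feature within
each physical plate (all wells, controls included), replicate wells are then
averaged per target, and redundant features (pairwise Pearson |r| above a
threshold, default 0.8) are greedily eliminated in descending-variance order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io import feature_columns

__all__ = ["ProfileSet", "zscore_by_plate", "zscore_screen",
           "average_replicates", "select_features"]


@dataclass
class ProfileSet:
    """Replicate-averaged feature Z-score profiles.

    ``profiles`` is targets x features; ``n_replicates`` records how many
    replicate wells were averaged per target; ``roles`` carries the well role
    (library / nt / positive) per target.
    """

    profiles: pd.DataFrame
    n_replicates: pd.Series
    roles: pd.Series

    def subset_features(self, features: list[str]) -> "ProfileSet":
        return ProfileSet(self.profiles[features], self.n_replicates, self.roles)


def zscore_by_plate(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score every feature within its plate: z = (x − mean) / SD (ddof 1).

    Statistics are computed over all wells of the plate, controls included.
    A feature that is constant on a plate is degenerate (it carries no
    within-plate signal); it is set to zero with a warning.
    """
    feats = feature_columns(table)
    if table.groupby("plate").size().min() < 3:
        raise ValueError("need at least 3 wells per plate to Z-score")
    out = table.copy()
    for plate, idx in table.groupby("plate").groups.items():
        block = table.loc[idx, feats]
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        degenerate = sd <= 0
        if degenerate.any():
            bad = list(sd.index[degenerate])
            warnings.warn(
                f"constant feature(s) on plate {plate}: {bad}; set to 0",
                RuntimeWarning, stacklevel=2)
            # centered constant features are exactly zero; a unit divisor
            # keeps them there without dividing by zero
            sd = sd.where(~degenerate, 1.0)
        out.loc[idx, feats] = ((block - mean) / sd).values
    return out


def zscore_screen(tables: Mapping[tuple[int, int], pd.DataFrame]
                  ) -> dict[tuple[int, int], pd.DataFrame]:
    """Apply :func:`zscore_by_plate` to every (plate, replicate) table."""
    return {key: zscore_by_plate(df) for key, df in sorted(tables.items())}


def average_replicates(tables: Iterable[pd.DataFrame] | Mapping,
                       expected_targets: Iterable[str] | None = None
                       ) -> ProfileSet:
    """Average per-target feature vectors across replicate wells.

    Missing values propagate as missing into the mean (never imputed); the
    number of wells averaged is recorded per target. Targets expected but
    absent from every replicate are dropped with a warning.
    """
    if isinstance(tables, Mapping):
        tables = list(tables.values())
    tidy = pd.concat(tables, ignore_index=True)
    feats = feature_columns(tidy)
    grouped = tidy.groupby("target", sort=True)
    profiles = grouped[feats].mean()
    n_rep = grouped.size().rename("n_replicates")
    roles = grouped["role"].first()
    if expected_targets is not None:
        missing = sorted(set(expected_targets) - set(profiles.index))
        if missing:
            warnings.warn(f"targets absent from all replicates: {missing}",
                          RuntimeWarning, stacklevel=2)
    return ProfileSet(profiles, n_rep, roles)


def select_features(profiles: pd.DataFrame, threshold: float = 0.8
                    ) -> tuple[list[str], pd.DataFrame]:
    """Greedy redundancy elimination by pairwise Pearson correlation.

    Features are scanned in descending-variance order (ties broken by name);
    a feature is retained only if its absolute correlation with every
    already-retained feature is <= ``threshold``. Zero-variance features are
    dropped up front with a warning. The retained set therefore has maximal
    pairwise |r| <= threshold, and the operation is idempotent.
    """
    if profiles.shape[1] < 1:
        raise ValueError("need at least 1 feature")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    var = profiles.var(axis=0, ddof=1)
    dead = var.index[(var <= 0) | var.isna()]
    if len(dead):
        warnings.warn(f"dropping zero-variance feature(s): {list(dead)}",
                      RuntimeWarning, stacklevel=2)
    live = var.drop(dead)
    order = sorted(live.index, key=lambda f: (-live[f], f))
    corr = profiles[order].corr()  # pairwise-complete Pearson
    kept: list[str] = []
    for f in order:
        if all(abs(corr.loc[f, g]) <= threshold for g in kept):
            kept.append(f)
    return kept, profiles[kept]
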