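"""Transcriptome correlation analysis for the secondary screen.

Counts are normalized to log2(CPM + 1), the most variable genes selected on
the log scale, replicate samples averaged per condition, and condition-to-
condition Pearson correlation matrices computed. A cross-modal table pairs
the expression correlations with the high-content feature correlations of
the same knockdowns to find conditions that agree in both modalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

__all__ = ["CorrelationMatrix", "normalize_counts", "top_variable_genes",
           "average_by_condition", "condition_correlation",
           "crossmodal_concordance"]


@dataclass
class CorrelationMatrix:
    values: pd.DataFrame   # condition x condition, symmetric, unit diagonal
    modality: str          # "expression" | "high-content"
    order: list[str]       # hierarchical display order


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million then log2(CPM + 1), per sample column."""
    sums = counts.sum(axis=0)
    zero = sums.index[sums <= 0]
    if len(zero):
        raise ValueError(f"zero-sum sample column(s): {list(zero)}")
    cpm = counts * 1e6 / sums
    return np.log2(cpm + 1.0)


def top_variable_genes(lognorm: pd.DataFrame, n: int) -> list[str]:
    """The n genes with the highest log-scale variance across all samples.

    Deterministic tie-break by gene id.
    """
    if n > len(lognorm):
        raise ValueError("n exceeds the number of genes")
    var = lognorm.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda g: (-var[g], g))
    return order[:n]


def average_by_condition(lognorm: pd.DataFrame,
                         samples: pd.DataFrame) -> pd.DataFrame:
    """Average replicate sample columns per condition (genes x conditions)."""
    cond = samples.set_index("sample")["condition"]
    missing = [s for s in lognorm.columns if s not in cond.index]
    if missing:
        raise ValueError(f"samples missing from sample sheet: {missing}")
    return lognorm.T.groupby(cond.reindex(lognorm.columns)).mean().T


def condition_correlation(lognorm: pd.DataFrame, samples: pd.DataFrame,
                          genes: list[str] | None = None,
                          modality: str = "expression",
                          average: bool = True) -> CorrelationMatrix:
    """Pairwise Pearson correlation between conditions.

    Replicates are averaged per condition first (as in the figure legends);
    constant condition vectors are dropped with a warning. Rows/columns come
    back with a hierarchical ordering for heatmap display.
    """
    mat = lognorm.loc[genes] if genes is not None else lognorm
    cond = average_by_condition(mat, samples) if average else mat
    if cond.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    sd = cond.std(axis=0, ddof=1)
    dead = sd.index[sd <= 0]
    if len(dead):
        warnings.warn(f"constant condition(s) dropped: {list(dead)}",
                      RuntimeWarning, stacklevel=2)
        cond = cond.drop(columns=dead)
    r = np.corrcoef(cond.values.T)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    values = pd.DataFrame(r, index=cond.columns, columns=cond.columns)
    if len(values) > 2:
        from scipy.spatial.distance import squareform
        dist = 1.0 - values.values
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        order = [values.index[i] for i in leaves_list(Z)]
    else:
        order = list(values.index)
    return CorrelationMatrix(values, modality, order)


def crossmodal_concordance(expr_corr: CorrelationMatrix,
                           feature_corr: CorrelationMatrix,
                           expr_threshold: float = 0.7,
                           feature_threshold: float = 0.7) -> pd.DataFrame:
    """Pair up expression and high-content correlations per condition pair.

    One row per unordered pair of shared conditions, with both correlations,
    their product (a both-axes concordance score) and a flag for pairs
    exceeding both thresholds.
    """
    shared = [c for c in expr_corr.values.index
              if c in feature_corr.values.index]
    if not shared:
        raise ValueError("expression and feature matrices share no conditions")
    rows = []
    for a, b in combinations(shared, 2):
        er = float(expr_corr.values.loc[a, b])
        fr = float(feature_corr.values.loc[a, b])
        rows.append({
            "condition_a": a, "condition_b": b,
            "expression_r": er, "feature_r": fr,
            "concordance": er * fr,
            "flagged": (er >= expr_threshold) and (fr >= feature_threshold),
        })
    return pd.DataFrame(rows)
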