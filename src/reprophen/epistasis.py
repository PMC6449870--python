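"""Multiplicative genetic-interaction (epistasis) test for colony counts.

Colony ratios divide each condition's replicate counts by the mean of the
control replicates. Under independent (non-interacting) knockdown effects
the expected double-knockdown ratio is the product of the two single-
knockdown mean ratios; a deviation of the observed double-knockdown ratios
from that product indicates a functional interaction (a positive deviation,
more colonies than expected, is an alleviating interaction).

The default test is a two-tailed t test of the observed-minus-expected mean
difference in which the expected product's sampling uncertainty — it is
estimated from the two single-knockdown means and the shared control mean —
is propagated by the delta method (Welch–Satterthwaite degrees of freedom).
Treating the expected product as a known constant (``propagate=False``) is
also available but anti-conservative: the estimated product carries roughly
as much sampling variance as the observed mean it is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EpistasisResult", "colony_ratio", "expected_double_ratio",
           "test_interaction", "analyze_pair", "epistasis_analysis",
           "simulate_rejection_rate"]


@dataclass
class EpistasisResult:
    pair: tuple[str, str]
    observed_ratios: np.ndarray
    expected_ratio: float
    mean_difference: float     # observed mean - expected
    t: float
    df: float
    p: float
    significant: bool
    alpha: float
    method: str                # "propagated" | "fixed" | "degenerate"


def colony_ratio(condition_counts: np.ndarray,
                 control_counts: np.ndarray) -> np.ndarray:
    """Per-replicate ratios: condition counts over the control mean."""
    control_counts = np.asarray(control_counts, dtype=float)
    cbar = control_counts.mean()
    if not cbar > 0:
        raise ValueError("control mean must be > 0")
    return np.asarray(condition_counts, dtype=float) / cbar


def expected_double_ratio(mean_ratio_a: float, mean_ratio_b: float) -> float:
    """Expected double-knockdown ratio under the multiplicative model."""
    return float(mean_ratio_a) * float(mean_ratio_b)


def test_interaction(observed_ratios: np.ndarray, expected: float,
                     alpha: float = 0.05,
                     pair: tuple[str, str] = ("A", "B")) -> EpistasisResult:
    """One-sample two-tailed t test of observed ratios against a fixed value.

    This is the simple fixed-expected variant; it assumes ``expected`` is
    known without error. Zero-variance observations fall back to an exact
    comparison, flagged degenerate.
    """
    obs = np.asarray(observed_ratios, dtype=float)
    if len(obs) < 2:
        raise ValueError("need >= 2 observed replicates")
    diff = float(obs.mean() - expected)
    sd = obs.std(ddof=1)
    if sd == 0:
        significant = diff != 0
        return EpistasisResult(pair, obs, float(expected), diff,
                               np.inf if diff else 0.0, np.inf,
                               0.0 if diff else 1.0, significant, alpha,
                               "degenerate")
    t = diff / (sd / np.sqrt(len(obs)))
    df = len(obs) - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return EpistasisResult(pair, obs, float(expected), diff, float(t),
                           float(df), float(p), p < alpha, alpha, "fixed")


def _propagated_stat(dbar, d_var, n_d, abar, a_var, n_a,
                     bbar, b_var, n_b, cbar, c_var, n_c):
    """Delta-method t statistic for g = Dbar/cbar - Abar*Bbar/cbar^2.

    All four sample means (double, single A, single B, control) contribute
    sampling variance; the shared control enters both the observed ratio and
    the expected product, and its gradient term captures that covariance.
    Broadcasts over leading axes. Returns (g, se, df).
    """
    dbar, abar, bbar, cbar = (np.asarray(v, dtype=float)
                              for v in (dbar, abar, bbar, cbar))
    g = dbar / cbar - abar * bbar / cbar ** 2
    grads = (1.0 / cbar,
             -bbar / cbar ** 2,
             -abar / cbar ** 2,
             -dbar / cbar ** 2 + 2.0 * abar * bbar / cbar ** 3)
    comps = [grad ** 2 * v / n for grad, v, n in
             zip(grads, (d_var, a_var, b_var, c_var), (n_d, n_a, n_b, n_c))]
    var = sum(comps)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = sum(c ** 2 / (n - 1) for c, n in
                    zip(comps, (n_d, n_a, n_b, n_c)))
        df = np.where(denom > 0, var ** 2 / np.where(denom > 0, denom, 1.0),
                      np.inf)
    return g, np.sqrt(var), df


def analyze_pair(double_counts: np.ndarray, single_a_counts: np.ndarray,
                 single_b_counts: np.ndarray, control_counts: np.ndarray,
                 alpha: float = 0.05, propagate: bool = True,
                 pair: tuple[str, str] = ("A", "B")) -> EpistasisResult:
    """Full interaction test for one gene pair from raw colony counts."""
    ctrl = np.asarray(control_counts, dtype=float)
    obs = colony_ratio(double_counts, ctrl)
    ra = colony_ratio(single_a_counts, ctrl)
    rb = colony_ratio(single_b_counts, ctrl)
    expected = expected_double_ratio(ra.mean(), rb.mean())
    if not propagate:
        return test_interaction(obs, expected, alpha=alpha, pair=pair)

    d = np.asarray(double_counts, dtype=float)
    a = np.asarray(single_a_counts, dtype=float)
    b = np.asarray(single_b_counts, dtype=float)
    if min(len(d), len(a), len(b), len(ctrl)) < 2:
        raise ValueError("need >= 2 replicates in every condition")
    g, se, df = _propagated_stat(
        d.mean(), d.var(ddof=1), len(d),
        a.mean(), a.var(ddof=1), len(a),
        b.mean(), b.var(ddof=1), len(b),
        ctrl.mean(), ctrl.var(ddof=1), len(ctrl))
    if se == 0:
        significant = g != 0
        return EpistasisResult(pair, obs, expected, float(g),
                               np.inf if g else 0.0, np.inf,
                               0.0 if g else 1.0, significant, alpha,
                               "degenerate")
    t = float(g / se)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return EpistasisResult(pair, obs, expected, float(g), t, float(df), p,
                           p < alpha, alpha, "propagated")


def epistasis_analysis(table: pd.DataFrame, alpha: float = 0.05,
                       propagate: bool = True) -> pd.DataFrame:
    """Run the interaction test for every double-knockdown condition.

    ``table`` has columns condition/replicate/count with a ``control``
    condition, singles named by target and doubles named ``"A+B"``.
    """
    groups = {c: sub["count"].values
              for c, sub in table.groupby("condition")}
    if "control" not in groups:
        raise ValueError("no control condition in the colony table")
    rows = []
    for cond, counts in groups.items():
        if "+" not in cond:
            continue
        a, b = cond.split("+", maxsplit=1)
        for single in (a, b):
            if single not in groups:
                raise ValueError(f"double {cond!r} lacks single {single!r}")
        res = analyze_pair(counts, groups[a], groups[b], groups["control"],
                           alpha=alpha, propagate=propagate, pair=(a, b))
        rows.append({"pair": cond, "observed_mean": res.observed_ratios.mean(),
                     "expected": res.expected_ratio,
                     "mean_difference": res.mean_difference,
                     "t": res.t, "df": res.df, "p": res.p,
                     "significant": res.significant, "method": res.method})
    return pd.DataFrame(rows)


def simulate_rejection_rate(n_pairs: int = 10_000, gamma: float = 1.0,
                            cv: float = 0.1, n_replicates: int = 6,
                            alpha: float = 0.05, control_mean: float = 100.0,
                            effect_a: float = 0.5, effect_b: float = 0.6,
                            seed: int = 0, propagate: bool = True) -> float:
    """Monte-Carlo rejection rate of the interaction test.

    Simulates ``n_pairs`` independent experiments under the multiplicative
    model (``gamma = 1`` gives the null; larger |log gamma| gives power) with
    lognormal replicate noise, and applies the same statistic as
    :func:`analyze_pair`, vectorized across pairs.
    """
    rng = np.random.default_rng(seed)
    shape = (n_pairs, n_replicates)
    sigma2 = np.log1p(cv ** 2)

    def draw(mean):
        if cv == 0:
            return np.full(shape, mean)
        return mean * np.exp(rng.normal(-sigma2 / 2, np.sqrt(sigma2), shape))

    c = draw(control_mean)
    a = draw(control_mean * effect_a)
    b = draw(control_mean * effect_b)
    d = draw(control_mean * effect_a * effect_b * gamma)

    if propagate:
        g, se, df = _propagated_stat(
            d.mean(1), d.var(1, ddof=1), n_replicates,
            a.mean(1), a.var(1, ddof=1), n_replicates,
            b.mean(1), b.var(1, ddof=1), n_replicates,
            c.mean(1), c.var(1, ddof=1), n_replicates)
    else:
        cbar = c.mean(1)
        obs = d / cbar[:, None]
        g = obs.mean(1) - (a.mean(1) / cbar) * (b.mean(1) / cbar)
        se = obs.std(1, ddof=1) / np.sqrt(n_replicates)
        df = np.full(n_pairs, n_replicates - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = g / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return float(np.mean(p < alpha))
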