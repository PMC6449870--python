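"""Hit ranking: control-correlation scores and facilitator predictions.

Two orthogonal rankings are combined in a 2-D hit-selection space:

* every knockdown's feature profile is Pearson-correlated with each positive
  control's averaged profile; the per-control correlations are combined into
  one control-similarity score (arithmetic mean by default);
* an ensemble of two classifier families (a regularized logistic model and a
  random forest) is trained on known reprogramming facilitators and assigns
  every knockdown a facilitator probability.

Hits are the union of the top correlation-ranked knockdowns, knockdowns
above an ML-score quantile, and any user-supplied low-score ("roadblock")
inclusion list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict

__all__ = ["correlate_to_controls", "combine_control_scores",
           "FacilitatorPredictor", "train_facilitator_predictor",
           "permutation_null_auc", "select_hits", "build_ranking_table"]


def correlate_to_controls(profiles: pd.DataFrame,
                          control_profiles: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each profile with each control profile.

    Constant (zero-variance) vectors have undefined correlation and are
    recorded as missing with a warning.
    """
    if control_profiles.empty:
        raise ValueError("no control profiles given")
    shared = [f for f in profiles.columns if f in control_profiles.columns]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared features")
    X = profiles[shared].values.astype(float)
    C = control_profiles[shared].values.astype(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    Cc = C - C.mean(axis=1, keepdims=True)
    xs = np.sqrt((Xc ** 2).sum(axis=1))
    cs = np.sqrt((Cc ** 2).sum(axis=1))
    if np.any(xs == 0) or np.any(cs == 0):
        warnings.warn("constant profile(s): correlation undefined, set to NaN",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ Cc.T) / np.outer(xs, cs)
    r[~np.isfinite(r)] = np.nan
    return pd.DataFrame(r, index=profiles.index,
                        columns=[f"r_{c}" for c in control_profiles.index])


def combine_control_scores(correlations: pd.DataFrame,
                           method: str = "mean") -> pd.Series:
    """Combine per-control correlations into one ranking score per target."""
    if method == "mean":
        score = correlations.mean(axis=1, skipna=True)
    elif method == "max":
        score = correlations.max(axis=1, skipna=True)
    else:
        raise ValueError(f"unknown combination method {method!r}")
    return score.rename("combined_score")


@dataclass
class FacilitatorPredictor:
    scores: pd.Series          # target -> ensemble facilitator probability
    cv_auc: float              # cross-validated AUC of the ensemble
    model_aucs: dict[str, float]
    models: dict


def _make_models(seed: int, n_estimators: int):
    return {
        "logistic": LogisticRegression(max_iter=1000, random_state=seed),
        "forest": RandomForestClassifier(n_estimators=n_estimators,
                                         random_state=seed, n_jobs=1),
    }


def train_facilitator_predictor(profiles: pd.DataFrame,
                                facilitators: list[str] | pd.Index,
                                seed: int = 0, cv: int = 5,
                                n_estimators: int = 200
                                ) -> FacilitatorPredictor:
    """Train the two-model facilitator ensemble and score all knockdowns.

    Positives are the given known facilitators, negatives all remaining
    knockdowns. The reported AUC is computed from stratified cross-validated
    probabilities of the ensemble (mean of the two model probabilities).
    """
    y = profiles.index.isin(set(facilitators)).astype(int)
    if y.sum() < 3:
        raise ValueError("need at least 3 facilitator-labelled profiles")
    if y.sum() == len(y):
        raise ValueError("training set has a single class")
    X = profiles.values
    models = _make_models(seed, n_estimators)
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    probs, aucs = {}, {}
    for name, model in models.items():
        p = cross_val_predict(model, X, y, cv=skf,
                              method="predict_proba")[:, 1]
        probs[name] = p
        aucs[name] = float(roc_auc_score(y, p))
    ensemble_cv = np.mean(list(probs.values()), axis=0)
    cv_auc = float(roc_auc_score(y, ensemble_cv))
    final = []
    for model in models.values():
        model.fit(X, y)
        final.append(model.predict_proba(X)[:, 1])
    scores = pd.Series(np.mean(final, axis=0), index=profiles.index,
                       name="facilitator_score")
    return FacilitatorPredictor(scores, cv_auc, aucs, models)


def permutation_null_auc(profiles: pd.DataFrame,
                         facilitators: list[str] | pd.Index,
                         n_permutations: int = 100, seed: int = 0,
                         cv: int = 3, n_estimators: int = 50) -> np.ndarray:
    """Ensemble CV-AUC under random label permutation (the chance baseline).

    Lighter model settings than the main predictor keep the null affordable;
    the chance level does not depend on them.
    """
    rng = np.random.default_rng(seed)
    y0 = profiles.index.isin(set(facilitators)).astype(int)
    X = profiles.values
    aucs = np.empty(n_permutations)
    for i in range(n_permutations):
        y = rng.permutation(y0)
        models = _make_models(seed, n_estimators)
        skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        ps = [cross_val_predict(m, X, y, cv=skf, method="predict_proba")[:, 1]
              for m in models.values()]
        aucs[i] = roc_auc_score(y, np.mean(ps, axis=0))
    return aucs


def select_hits(ranking: pd.DataFrame, n_corr_top: int = 20,
                ml_quantile: float = 0.9,
                include: tuple[str, ...] = ()) -> pd.DataFrame:
    """Flag hits in the 2-D score space.

    Union of: the ``n_corr_top`` highest combined control scores, targets
    with facilitator score above the ``ml_quantile`` quantile, and an
    explicit inclusion list (low-ranking "roadblock" candidates).
    """
    if n_corr_top > len(ranking):
        raise ValueError("n_corr_top exceeds the number of targets")
    out = ranking.copy()
    corr_rank = out["combined_score"].rank(ascending=False, method="first")
    out["selected_corr"] = corr_rank <= n_corr_top
    cutoff = out["facilitator_score"].quantile(ml_quantile)
    out["selected_ml"] = out["facilitator_score"] >= cutoff
    out["selected_manual"] = out.index.isin(set(include))
    out["selected"] = (out["selected_corr"] | out["selected_ml"]
                       | out["selected_manual"])
    return out


def build_ranking_table(profiles: pd.DataFrame,
                        control_profiles: pd.DataFrame,
                        facilitators: list[str] | pd.Index,
                        seed: int = 0, combine: str = "mean",
                        n_estimators: int = 200
                        ) -> tuple[pd.DataFrame, FacilitatorPredictor]:
    """Assemble the full ranking table (correlations + ML scores)."""
    corr = correlate_to_controls(profiles, control_profiles)
    combined = combine_control_scores(corr, method=combine)
    predictor = train_facilitator_predictor(profiles, facilitators,
                                            seed=seed,
                                            n_estimators=n_estimators)
    table = corr.copy()
    table["combined_score"] = combined
    table["facilitator_score"] = predictor.scores
    return table, predictor
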