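"""End-to-end orchestration of the screen and transcriptome stages.

``run_screen_stage`` chains normalize -> select_features -> cluster -> rank
on plate tables; ``run_txome_stage`` chains CPM/log normalization ->
variable-gene selection -> condition correlation -> time projection ->
cross-modal concordance; ``run_demo`` generates all synthetic inputs, runs
both stages plus the epistasis analysis, and reports recovery metrics
against the planted truth. Every output file carries the run's config hash
and seed in its header.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from . import cluster as pc
from . import epistasis as ep
from . import io
from . import normalize as nz
from . import rank as rk
from . import simulate as sim
from . import timecurve as tc
from . import txome as tx

log = logging.getLogger("reprophen")

__all__ = ["PipelineConfig", "run_screen_stage", "run_txome_stage", "run_demo"]


@dataclass
class PipelineConfig:
    """Stage parameters with their screen-analysis defaults."""

    seed: int = 0
    zscore_threshold: float = 0.8     # feature-redundancy |r| cutoff
    k: int = 5                        # phenotype clusters
    n_top_genes: int = 200            # most-variable transcripts
    angle: float = 15.0               # embedding rotation, degrees CCW
    degree: int = 2                   # time-curve polynomial degree (fixed)
    alpha: float = 0.05               # epistasis significance level
    n_corr_top: int = 20              # correlation-ranked hits
    ml_quantile: float = 0.9          # ML-score hit quantile
    fit_days: tuple[float, float] = (2.0, 7.0)
    delay_threshold: float = 1.0      # days behind nt to flag "delayed"
    controls: tuple[str, ...] = ("Trp53", "Myc", "Oct4")
    reference: str = "nt"
    outdir: str = "reprophen_out"

    def validate(self) -> None:
        if not (0 < self.zscore_threshold <= 1):
            raise ValueError("zscore_threshold must be in (0, 1]")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.degree != 2:
            raise ValueError("the time curve is quadratic (degree 2)")

    def meta(self) -> dict:
        params = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return {"config": io.config_hash(params), "seed": self.seed}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fit_days", "controls"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class ScreenStageResult:
    profiles: nz.ProfileSet
    retained_features: list[str]
    assignment: pc.ClusterAssignment
    cluster_report: pd.DataFrame
    reference_cluster: int | None
    ranking: pd.DataFrame
    predictor: rk.FacilitatorPredictor
    feature_corr: tx.CorrelationMatrix | None = None


def run_screen_stage(tables, config: PipelineConfig,
                     facilitators: list[str] | None = None,
                     outdir: str | Path | None = None) -> ScreenStageResult:
    """Normalize plate tables, cluster phenotypes, rank hits.

    ``facilitators`` are the known-facilitator training labels for the ML
    score; without them the ranking carries only the correlation score.
    """
    config.validate()
    for key, df in tables.items():
        try:
            io.validate_plate_table(df)
        except ValueError as err:
            raise ValueError(f"plate table {key}: {err}") from err

    ztables = nz.zscore_screen(tables)
    profile_set = nz.average_replicates(ztables)
    kept, reduced = nz.select_features(profile_set.profiles,
                                       config.zscore_threshold)
    log.info("retained %d/%d features", len(kept),
             profile_set.profiles.shape[1])
    profile_set = nz.ProfileSet(reduced, profile_set.n_replicates,
                                profile_set.roles)

    assignment = pc.cluster_knockdowns(reduced, k=config.k, seed=config.seed)
    _, feature_order = pc.cluster_features(reduced)
    assignment.feature_order = feature_order
    report, reference = pc.summarize_clusters(assignment, profile_set.roles)
    log.info("cluster sizes: %s (reference=%s)",
             report["size"].to_dict(), reference)

    roles = profile_set.roles
    library = reduced.loc[roles == "library"]
    control_profiles = reduced.loc[[c for c in config.controls
                                    if c in reduced.index]]
    if control_profiles.empty:
        raise ValueError(f"no control profiles among {config.controls}")
    corr = rk.correlate_to_controls(library, control_profiles)
    ranking = corr.copy()
    ranking["combined_score"] = rk.combine_control_scores(corr)
    predictor = None
    if facilitators:
        predictor = rk.train_facilitator_predictor(
            library, facilitators, seed=config.seed)
        ranking["facilitator_score"] = predictor.scores
        ranking = rk.select_hits(ranking, n_corr_top=config.n_corr_top,
                                 ml_quantile=config.ml_quantile)
        log.info("facilitator ensemble CV AUC %.3f", predictor.cv_auc)

    feature_corr = None
    if len(library) >= 2:
        corr_vals = np.corrcoef(library.values)
        corr_vals = (corr_vals + corr_vals.T) / 2
        np.fill_diagonal(corr_vals, 1.0)
        feature_corr = tx.CorrelationMatrix(
            pd.DataFrame(corr_vals, index=library.index,
                         columns=library.index),
            "high-content", list(library.index))

    result = ScreenStageResult(profile_set, kept, assignment, report,
                               reference, ranking, predictor, feature_corr)
    if outdir is not None:
        outdir = Path(outdir)
        meta = config.meta()
        io.write_table(profile_set.profiles.rename_axis("target"),
                       outdir / "profiles.tsv", meta, index=True)
        io.write_table(assignment.labels.rename_axis("target").reset_index(),
                       outdir / "clusters.tsv", meta)
        io.write_table(report.reset_index(), outdir / "cluster_report.tsv",
                       meta)
        io.write_table(ranking.rename_axis("target").reset_index(),
                       outdir / "ranking.tsv", meta)
        (outdir / "run_meta.json").write_text(json.dumps(
            {**meta, "retained_features": kept,
             "reference_cluster": reference}, indent=2))
    return result


def run_txome_stage(counts: pd.DataFrame, samples: pd.DataFrame,
                    config: PipelineConfig,
                    feature_corr: tx.CorrelationMatrix | None = None,
                    outdir: str | Path | None = None) -> dict:
    """Transcriptome stage: correlations, progression report, concordance."""
    config.validate()
    day = samples["day"]
    lo, hi = config.fit_days
    if not day.between(lo, hi).any():
        raise ValueError(
            f"no time-course samples with day labels in {config.fit_days}")
    proj = tc.run_time_projection(
        counts, samples, n_top=config.n_top_genes, angle=config.angle,
        fit_days=config.fit_days, reference=config.reference,
        delay_threshold=config.delay_threshold)
    genes = tx.top_variable_genes(proj["lognorm"], config.n_top_genes)
    kd_samples = samples[samples["day"].isna()]
    expr_corr = tx.condition_correlation(
        proj["lognorm"].loc[:, kd_samples["sample"]], kd_samples, genes=genes)
    concordance = None
    if feature_corr is not None:
        concordance = tx.crossmodal_concordance(expr_corr, feature_corr)
    out = {"projection": proj, "expr_corr": expr_corr,
           "concordance": concordance, "top_genes": genes}
    if outdir is not None:
        outdir = Path(outdir)
        meta = config.meta()
        io.write_table(proj["report"], outdir / "progression.tsv", meta)
        io.write_table(expr_corr.values.rename_axis("condition"),
                       outdir / "expression_correlation.tsv", meta,
                       index=True)
        if concordance is not None:
            io.write_table(concordance, outdir / "concordance.tsv", meta)
    return out


def _demo_trajectory_config(truth: pd.DataFrame, seed: int,
                            n_knockdowns: int = 30) -> sim.TrajectorySimConfig:
    """Knockdowns for the demo time course, drawn from the screen targets.

    Progression points are assigned by planted role: blockers are delayed
    (days ~3.2-4.6), neutrals land near the nt control (~5.1-6.0) and
    facilitators slightly ahead (~6.1-6.8), mirroring the expectation that
    control-like blocker phenotypes lag the time course.
    """
    lib = truth[truth["role"].isin(["facilitator", "blocker", "neutral"])]
    picks = []
    for role, lo, hi, n in (("blocker", 3.2, 4.6, 9),
                            ("neutral", 5.1, 6.0, 10),
                            ("facilitator", 6.1, 6.8, 10)):
        names = list(lib.index[lib["role"] == role])[:n]
        spots = np.linspace(lo, hi, len(names))
        picks += [(t, s) for t, s in zip(names, spots)]
    picks = picks[:n_knockdowns - 1]
    names = ["nt"] + [t for t, _ in picks]
    prog = [5.7] + [s for _, s in picks]
    # offsets: the generator's default fixed interleave (nt stays at 0)
    return sim.TrajectorySimConfig(
        knockdown_names=tuple(names), n_knockdowns=len(names),
        planted_progression=tuple(prog), seed=seed + 1)


def run_demo(seed: int = 0, outdir: str | Path = "reprophen_demo",
             screen_config: sim.ScreenSimConfig | None = None,
             trajectory_config: sim.TrajectorySimConfig | None = None,
             colony_config: sim.ColonySimConfig | None = None,
             n_null_pairs: int = 2000) -> dict:
    """Generate synthetic inputs, run all stages, report recovery metrics.

    The summary compares every pipeline output with the generators' planted
    truth: clustering ARI, blocker recall in the top decile of the combined
    control score, facilitator CV AUC, Spearman correlation of pseudotime
    with planted progression, Pearson correlation of residual distance with
    planted orthogonal offsets, and the Monte-Carlo type-I rate of the
    epistasis test under the multiplicative null.
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig(seed=seed, outdir=str(outdir))
    meta = config.meta()

    scr_cfg = screen_config or sim.ScreenSimConfig(seed=seed)
    tables, truth = sim.generate_screen(scr_cfg)
    io.write_screen(tables, outdir / "screen", meta)
    io.write_table(truth.reset_index(), outdir / "screen_truth.tsv", meta)

    facilitators = list(truth.index[truth["role"] == "facilitator"])
    screen_res = run_screen_stage(tables, config, facilitators=facilitators,
                                  outdir=outdir / "screen_stage")

    shared = screen_res.assignment.labels.index.intersection(truth.index)
    ari = float(adjusted_rand_score(
        truth.loc[shared, "class_label"],
        screen_res.assignment.labels.loc[shared]))

    ranking = screen_res.ranking
    n_top = max(1, len(ranking) // 10)
    top = ranking["combined_score"].nlargest(n_top).index
    blockers = truth.index[truth["role"] == "blocker"]
    blockers = [b for b in blockers if b in ranking.index]
    recall = float(np.mean([b in top for b in blockers])) if blockers else np.nan

    trj_cfg = trajectory_config or _demo_trajectory_config(truth, seed)
    counts, samples, kd_truth = sim.generate_timecourse(trj_cfg)
    io.write_counts(counts, samples, outdir / "timecourse", meta)
    feature_corr = screen_res.feature_corr
    if feature_corr is not None and \
            kd_truth.index.intersection(feature_corr.values.index).empty:
        feature_corr = None  # knockdowns not drawn from the screen targets
    txome_res = run_txome_stage(counts, samples, config,
                                feature_corr=feature_corr,
                                outdir=outdir / "txome_stage")

    report = txome_res["projection"]["report"].set_index("condition")
    kd = kd_truth.index.intersection(report.index)
    rho = float(sps.spearmanr(kd_truth.loc[kd, "progression"],
                              report.loc[kd, "x"]).statistic)
    if kd_truth.loc[kd, "offset"].std() > 0:
        r_off = float(sps.pearsonr(kd_truth.loc[kd, "offset"],
                                   report.loc[kd, "distance"]).statistic)
    else:
        r_off = np.nan

    col_cfg = colony_config or sim.ColonySimConfig(seed=seed + 2)
    colony = sim.generate_colony_counts(col_cfg)
    io.write_colony_counts(colony, outdir / "colony_counts.tsv", meta)
    interactions = ep.epistasis_analysis(colony, alpha=config.alpha)
    io.write_table(interactions, outdir / "epistasis.tsv", meta)
    null_rate = ep.simulate_rejection_rate(
        n_pairs=n_null_pairs, gamma=1.0, cv=col_cfg.cv,
        n_replicates=col_cfg.n_replicates, alpha=config.alpha,
        seed=seed + 3)

    summary = {
        "seed": seed,
        "config_hash": meta["config"],
        "cluster_ari": ari,
        "blocker_top_decile_recall": recall,
        "facilitator_cv_auc": screen_res.predictor.cv_auc,
        "pseudotime_spearman": rho,
        "offset_distance_pearson": r_off,
        "epistasis_null_rejection_rate": null_rate,
        "n_retained_features": len(screen_res.retained_features),
        "reference_cluster": screen_res.reference_cluster,
        "n_significant_interactions": int(interactions["significant"].sum()),
        "runtime_seconds": round(time.time() - t0, 2),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    log.info("demo summary: %s", summary)
    return summary
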