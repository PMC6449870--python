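"""Synthetic data generators with planted ground truth.

Three generators emulate the three data types the analysis consumes:

* :func:`generate_screen` — per-well colony-feature tables for a multi-plate
  siRNA screen (class archetypes + plate batch offsets + Gaussian noise),
  with non-targeting (nt) and positive controls placed on every plate.
* :func:`generate_timecourse` — a gene-by-sample UMI count matrix for a
  day 0–7 reprogramming time course plus knockdown samples placed at planted
  progression points, with optional offsets orthogonal to the trajectory.
* :func:`generate_colony_counts` — colony counts for single and double
  knockdowns under a multiplicative interaction model with lognormal noise.

Every generator is deterministic given its config (including ``seed``) and
returns the planted truth alongside the data, so downstream modules can be
tested for parameter recovery.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreenSimConfig", "TrajectorySimConfig", "ColonySimConfig",
    "generate_screen", "generate_timecourse", "generate_colony_counts",
]

# ---------------------------------------------------------------------------
# High-content screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenSimConfig:
    """Configuration for the synthetic high-content screen.

    Defaults mirror the screen layout: six 96-well plates, 300 library
    targets, seven nt negative controls and three positive controls
    (Trp53, Myc, Oct4) on every plate, four replicate transfections.
    Effect sizes are in feature-SD units: each phenotype class has a fixed
    archetype vector of scale ``class_effect_size``; each physical plate
    adds a batch offset of scale ``plate_effect_sd`` (removed by per-plate
    Z-scoring); wells add i.i.d. Gaussian noise of scale ``noise_sd``.
    """

    n_plates: int = 6
    wells_per_plate: int = 96
    n_replicates: int = 4
    n_targets: int = 300
    n_nt_controls_per_plate: int = 7
    positive_controls: tuple[str, ...] = ("Trp53", "Myc", "Oct4")
    n_features: int = 40
    n_classes: int = 5
    class_effect_size: float = 3.0
    plate_effect_sd: float = 1.0
    noise_sd: float = 1.0
    # fraction of library targets per phenotype class; class 1 is the
    # facilitator-like archetype, the last class the blocker (control-like
    # severe-impairment) archetype shared with the Myc/Oct4 controls
    class_proportions: tuple[float, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.class_effect_size <= 0:
            raise ValueError("class_effect_size must be > 0")
        if self.noise_sd < 0 or self.plate_effect_sd < 0:
            raise ValueError("noise/plate effect SDs must be >= 0")
        props = self.proportions()
        if len(props) != self.n_classes or abs(sum(props) - 1) > 1e-9:
            raise ValueError("class_proportions must sum to 1 over n_classes")
        per_plate = -(-self.n_targets // self.n_plates)  # ceil
        used = per_plate + self.n_nt_controls_per_plate + len(self.positive_controls)
        if used > self.wells_per_plate:
            raise ValueError(
                f"layout infeasible: {used} wells needed per plate "
                f"but only {self.wells_per_plate} available")

    def proportions(self) -> tuple[float, ...]:
        if self.class_proportions is not None:
            return self.class_proportions
        if self.n_classes == 5:
            return (0.10, 0.35, 0.25, 0.22, 0.08)
        p = 1.0 / self.n_classes
        return tuple([p] * self.n_classes)


def _well_labels(n: int) -> list[str]:
    rows = string.ascii_uppercase
    return [f"{rows[i // 12]}{i % 12 + 1:02d}" for i in range(n)]


def _class_counts(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Deterministic largest-remainder apportionment of n targets to classes."""
    raw = np.asarray(proportions, dtype=float) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def generate_screen(config: ScreenSimConfig
                    ) -> tuple[dict[tuple[int, int], pd.DataFrame], pd.DataFrame]:
    """Simulate per-well feature tables for every plate and replicate.

    Returns ``(tables, truth)``: ``tables`` maps ``(plate, replicate)`` to a
    plate table (columns plate, well, target, role, f01..fNN) and ``truth``
    is indexed by target label with the planted ``class_label`` and ``role``
    (facilitator / blocker / neutral / nt / positive).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    k, nf = config.n_classes, config.n_features
    feature_names = [f"f{i + 1:02d}" for i in range(nf)]

    archetypes = rng.normal(0.0, 1.0, size=(k, nf)) * config.class_effect_size

    # planted class labels (1-based) for library targets; exact class sizes
    counts = _class_counts(config.n_targets, config.proportions())
    classes = rng.permutation(np.repeat(np.arange(1, k + 1), counts))
    targets = [f"t{i + 1:03d}" for i in range(config.n_targets)]

    role_of_class = {1: "facilitator", k: "blocker"}
    truth_rows = [
        {"target": t, "class_label": int(c),
         "role": role_of_class.get(int(c), "neutral")}
        for t, c in zip(targets, classes)
    ]

    # controls: nt wells carry the "normal reprogramming" archetype, Myc and
    # Oct4 the severe-impairment archetype, Trp53 a normal-like one
    nt_class = min(2, k)
    trp53_class = min(4, k)
    control_class = {"Myc": k, "Oct4": k}
    pos_classes = {name: control_class.get(name, trp53_class)
                   for name in config.positive_controls}
    for name, c in pos_classes.items():
        truth_rows.append({"target": name, "class_label": c, "role": "positive"})

    chunks = np.array_split(np.arange(config.n_targets), config.n_plates)
    labels = _well_labels(config.wells_per_plate)

    class_by_target: dict[str, int] = {t: int(c) for t, c in zip(targets, classes)}

    tables: dict[tuple[int, int], pd.DataFrame] = {}
    nt_labels_all: list[str] = []
    for p, chunk in enumerate(chunks, start=1):
        plate_rows: list[tuple[str, str, int]] = []  # (target, role, class)
        for i in chunk:
            plate_rows.append((targets[i], "library", class_by_target[targets[i]]))
        for j in range(config.n_nt_controls_per_plate):
            nt_name = f"nt_p{p}_{j + 1}"
            plate_rows.append((nt_name, "nt", nt_class))
            nt_labels_all.append(nt_name)
        for name in config.positive_controls:
            plate_rows.append((name, "positive", pos_classes[name]))
        # shuffle physical well positions within the plate
        pos = rng.permutation(config.wells_per_plate)[:len(plate_rows)]
        wells = [labels[q] for q in np.sort(pos)]
        order = rng.permutation(len(plate_rows))
        plate_rows = [plate_rows[q] for q in order]

        base = np.array([archetypes[c - 1] for _, _, c in plate_rows])
        for rep in range(1, config.n_replicates + 1):
            plate_offset = rng.normal(0.0, config.plate_effect_sd, size=nf) \
                if config.plate_effect_sd > 0 else np.zeros(nf)
            noise = rng.normal(0.0, config.noise_sd, size=base.shape) \
                if config.noise_sd > 0 else 0.0
            values = base + plate_offset + noise
            df = pd.DataFrame(values, columns=feature_names)
            df.insert(0, "role", [r for _, r, _ in plate_rows])
            df.insert(0, "target", [t for t, _, _ in plate_rows])
            df.insert(0, "well", wells)
            df.insert(0, "plate", p)
            tables[(p, rep)] = df

    for name in nt_labels_all:
        truth_rows.append({"target": name, "class_label": nt_class, "role": "nt"})
    truth = pd.DataFrame(truth_rows).set_index("target")
    return tables, truth


# ---------------------------------------------------------------------------
# Transcriptome time course
# ---------------------------------------------------------------------------


@dataclass
class TrajectorySimConfig:
    """Configuration for the synthetic reprogramming time course.

    Expression follows a smooth one-dimensional trajectory in a 2-D latent
    gene-loading space. The latent position at day ``t`` (centered at the
    midpoint of the day range) is ``(a·(t−t̄), b·((t−t̄)² − m₂) + c·(t−t̄))``
    with ``a = traj_linear`` (latent units per day), ``b = traj_quad`` and
    ``c = traj_tilt``. The quadratic (arc) axis carries the larger amplitude
    so that, as in the real data, the second principal component tracks
    time; the linear tilt ``c`` is by default calibrated per design so that
    the principal frame of the full sample cloud sits exactly
    ``frame_angle`` degrees from the trajectory's symmetry frame — i.e. the
    standard analysis (axis swap, rotation by that angle, quadratic fit) is
    exactly the right model for the planted data. Knockdown samples sit at
    ``planted_progression`` (day units) displaced by ``orthogonal_offset``
    along the local outward normal of the trajectory (away from the concave
    side, keeping the orthogonal distance identifiable). Latent positions
    are lifted to per-gene log-rates through a Gaussian loading matrix;
    counts are negative-binomial with the stated dispersion, scaled so each
    sample's expected total is ``library_size``.
    """

    n_genes: int = 2000
    days: tuple[float, ...] = tuple(float(d) for d in range(8))
    replicates_per_day: int = 3
    n_knockdowns: int = 30
    knockdown_names: tuple[str, ...] | None = None
    planted_progression: tuple[float, ...] | None = None
    orthogonal_offset: tuple[float, ...] | None = None
    replicates_per_knockdown: int = 3
    dispersion: float = 0.1
    library_size: int = 500_000
    loading_sd: float = 0.15
    base_log_sd: float = 0.7
    traj_linear: float = 1.0
    traj_quad: float = 0.95
    traj_tilt: float | None = None   # None: calibrated (see _calibrate_tilt)
    frame_angle: float = 15.0        # planted tilt of the principal frame
    seed: int = 0

    def resolve_knockdowns(self, rng: np.random.Generator
                           ) -> tuple[list[str], np.ndarray, np.ndarray]:
        n = self.n_knockdowns
        names = list(self.knockdown_names) if self.knockdown_names is not None \
            else ["nt"] + [f"kd{i:02d}" for i in range(1, n)]
        if len(names) != n:
            raise ValueError("knockdown_names length must equal n_knockdowns")
        if self.planted_progression is not None:
            prog = np.asarray(self.planted_progression, dtype=float)
        else:
            prog = np.empty(n)
            body = np.linspace(2.5, 6.8, n - 1) if n > 1 else []
            j = 0
            for i, name in enumerate(names):
                if name == "nt":
                    prog[i] = 5.7
                else:
                    prog[i] = body[j]
                    j += 1
        if self.orthogonal_offset is not None:
            off = np.asarray(self.orthogonal_offset, dtype=float)
        else:
            # fixed interleave (not seed-dependent): offset magnitudes span
            # 0-5 latent units and are balanced across progression, so the
            # planted design is the same study layout in every realization
            pattern = np.random.default_rng(2026).permutation(
                np.linspace(0.0, 5.0, max(n - 1, 1)))
            off = np.empty(n)
            j = 0
            for i, name in enumerate(names):
                if name == "nt":
                    off[i] = 0.0
                else:
                    off[i] = pattern[j]
                    j += 1
        if len(prog) != n or len(off) != n:
            raise ValueError("progression/offset lengths must equal n_knockdowns")
        lo, hi = min(self.days), max(self.days)
        if np.any(prog < lo) or np.any(prog > hi):
            raise ValueError("planted_progression must lie within the day range")
        if np.any(off < 0):
            raise ValueError("orthogonal_offset must be >= 0")
        return names, prog, off

    def validate(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if len(self.days) < 3:
            raise ValueError("need at least 3 time-course days")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")


def _latent_position(t: np.ndarray, cfg: TrajectorySimConfig,
                     tilt: float) -> np.ndarray:
    days = np.asarray(cfg.days, dtype=float)
    t0 = days.mean()
    m2 = ((days - t0) ** 2).mean()
    u = cfg.traj_linear * (t - t0)
    v = cfg.traj_quad * ((t - t0) ** 2 - m2) + tilt * (t - t0)
    return np.column_stack([u, v])


def _latent_outward_normal(t: np.ndarray, cfg: TrajectorySimConfig,
                           tilt: float) -> np.ndarray:
    """Unit normal pointing away from the arc's concave side."""
    days = np.asarray(cfg.days, dtype=float)
    t0 = days.mean()
    tangent = np.column_stack([
        np.full_like(t, cfg.traj_linear, dtype=float),
        2.0 * cfg.traj_quad * (t - t0) + tilt,
    ])
    # curve opens toward +v; outward is the -v side
    normal = np.column_stack([tangent[:, 1], -tangent[:, 0]])
    return normal / np.linalg.norm(normal, axis=1, keepdims=True)


def _latent_cloud(cfg: TrajectorySimConfig, tilt: float, prog: np.ndarray,
                  off: np.ndarray, with_offsets: bool = True
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample latent points and day labels (NaN for knockdowns)."""
    pts, days = [], []
    for d in cfg.days:
        z = _latent_position(np.array([float(d)]), cfg, tilt)[0]
        pts += [z] * cfg.replicates_per_day
        days += [float(d)] * cfg.replicates_per_day
    base = _latent_position(prog, cfg, tilt)
    normal = _latent_outward_normal(prog, cfg, tilt)
    for i in range(len(prog)):
        z = base[i] + (off[i] * normal[i] if with_offsets else 0.0)
        pts += [z] * cfg.replicates_per_knockdown
        days += [np.nan] * cfg.replicates_per_knockdown
    return np.array(pts), np.array(days)


def _frame_misfit(cfg: TrajectorySimConfig, tilt: float, prog: np.ndarray,
                  off: np.ndarray) -> float:
    """Structural residual of the standard analysis on the noise-free design.

    Replays the embedding geometry in latent space: PCA of the full design
    (offsets included), axis swap and sign conventions, rotation by
    ``frame_angle``, quadratic fit to the day means, then the residual
    distance of the offset-free knockdown positions — which the analysis
    should ideally see as exactly on the curve.
    """
    from .timecurve import TimeCurveModel, project_onto_curve

    Z, days = _latent_cloud(cfg, tilt, prog, off, with_offsets=True)
    center = Z.mean(axis=0)
    Zc = Z - center
    _, vecs = np.linalg.eigh(np.cov(Zc.T))
    pc1, pc2 = vecs[:, 1], vecs[:, 0]       # eigh: ascending eigenvalues
    x, y = Zc @ pc2, Zc @ pc1               # swap: x = PC2, y = PC1
    tc = ~np.isnan(days)
    sx = -1.0 if np.corrcoef(days[tc], x[tc])[0, 1] < 0 else 1.0
    d2 = (days[tc] - days[tc].mean()) ** 2
    sy = 1.0
    if d2.std() > 0 and np.corrcoef(d2, y[tc])[0, 1] > 0:
        sy = -1.0
    theta = np.deg2rad(cfg.frame_angle)
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    def frame(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        px = sx * ((points - center) @ pc2)
        py = sy * ((points - center) @ pc1)
        return px * cos_t - py * sin_t, px * sin_t + py * cos_t

    xr, yr = frame(Z)
    sel = tc & (days >= 2.0) & (days <= 7.0)
    if sel.sum() < 3:
        sel = tc
    day_means = pd.DataFrame({"d": days[sel], "x": xr[sel], "y": yr[sel]}) \
        .groupby("d").mean()
    if len(day_means) < 3:
        return np.inf
    c2, c1, c0 = np.polyfit(day_means["x"], day_means["y"], 2)
    model = TimeCurveModel((float(c0), float(c1), float(c2)),
                           (float(day_means["x"].min()),
                            float(day_means["x"].max())),
                           pd.DataFrame(columns=["day", "x"]))
    Zb, daysb = _latent_cloud(cfg, tilt, prog, off, with_offsets=False)
    xb, yb = frame(Zb)
    kd = np.nonzero(np.isnan(daysb))[0]
    dist = [project_onto_curve((xb[i], yb[i]), model).distance for i in kd]
    return float(np.mean(dist))


def _calibrate_tilt(cfg: TrajectorySimConfig, prog: np.ndarray,
                    off: np.ndarray) -> float:
    """Linear-tilt coefficient that aligns the design's principal frame.

    Chooses the trajectory's linear tilt so that the principal axes of the
    full design sit exactly ``frame_angle`` degrees from the trajectory's
    symmetry frame: the standard analysis (axis swap, rotation by
    ``frame_angle``, quadratic fit) then recovers the planted curve with no
    structural misfit.
    """
    # the search stays on the branch contiguous with the untilted design:
    # large positive tilts also align the frame but leave PC2 with so little
    # variance that the embedding axis drowns in measurement noise
    grid = np.linspace(-1.2, 0.2, 15)
    scores = [_frame_misfit(cfg, float(c), prog, off) for c in grid]
    best = grid[int(np.argmin(scores))]
    fine = np.linspace(best - 0.12, best + 0.12, 25)
    scores = [_frame_misfit(cfg, float(c), prog, off) for c in fine]
    return float(fine[int(np.argmin(scores))])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def generate_timecourse(config: TrajectorySimConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the time-course + knockdown count matrix.

    Returns ``(counts, samples, truth)``: ``counts`` is genes x samples
    (integer), ``samples`` has columns sample/condition/day/replicate
    (day is NaN for knockdown samples), and ``truth`` is indexed by knockdown
    condition with the planted ``progression`` (days) and ``offset``
    (latent units orthogonal to the trajectory).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names, prog, off = config.resolve_knockdowns(rng)

    genes = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    base = rng.normal(0.0, config.base_log_sd, size=config.n_genes)
    loadings = rng.normal(0.0, config.loading_sd, size=(config.n_genes, 2))
    # balance the loadings against baseline abundance so that movement along
    # the trajectory preserves total expression to first order; otherwise the
    # per-sample CPM normalizer varies nonlinearly along the trajectory and
    # bends the latent geometry the projection is meant to recover
    w = np.exp(base)
    loadings -= np.outer(w, w @ loadings) / (w @ w)

    tilt = config.traj_tilt
    if tilt is None:
        tilt = _calibrate_tilt(config, prog, off) if len(prog) else 0.0

    sample_rows = []
    latent_points = []
    for d in config.days:
        z = _latent_position(np.array([d]), config, tilt)[0]
        for r in range(1, config.replicates_per_day + 1):
            sample_rows.append({"sample": f"day{d:g}_r{r}",
                                "condition": f"day{d:g}",
                                "day": float(d), "replicate": r})
            latent_points.append(z)
    normals = _latent_outward_normal(prog, config, tilt)
    base_pts = _latent_position(prog, config, tilt)
    for i, name in enumerate(names):
        z = base_pts[i] + off[i] * normals[i]
        for r in range(1, config.replicates_per_knockdown + 1):
            sample_rows.append({"sample": f"{name}_r{r}", "condition": name,
                                "day": np.nan, "replicate": r})
            latent_points.append(z)

    Z = np.array(latent_points)  # samples x 2
    log_rate = base[:, None] + loadings @ Z.T  # genes x samples
    if np.any(np.abs(log_rate) > 30):
        warnings.warn("extreme latent offsets: clipping gene log-rates",
                      RuntimeWarning, stacklevel=2)
        log_rate = np.clip(log_rate, -30, 30)
    rate = np.exp(log_rate)
    mean = rate / rate.sum(axis=0, keepdims=True) * config.library_size
    mean = np.maximum(mean, 1e-12)
    counts = _nb_draw(rng, mean, config.dispersion)

    samples = pd.DataFrame(sample_rows)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples["sample"])
    counts_df.columns.name = None
    truth = pd.DataFrame({"condition": names, "progression": prog,
                          "offset": off}).set_index("condition")
    return counts_df, samples, truth


# ---------------------------------------------------------------------------
# Colony counts (epistasis)
# ---------------------------------------------------------------------------


@dataclass
class ColonySimConfig:
    """Configuration for single/double-knockdown colony-count simulation.

    Expected counts follow the multiplicative model: control wells have mean
    ``control_mean``; a single knockdown of A has mean ``control_mean·e_A``;
    a double knockdown of (A, B) has mean ``control_mean·e_A·e_B·γ_AB`` where
    ``γ = 1`` means no interaction and ``γ > 1`` an alleviating one. Noise is
    multiplicative lognormal with coefficient of variation ``cv`` (mean
    preserved exactly; ``cv = 0`` gives deterministic counts).
    """

    control_mean: float = 100.0
    single_effects: Mapping[str, float] = field(
        default_factory=lambda: {"Brca1": 0.35, "Bard1": 0.40, "Wdr5": 0.30})
    interaction_gamma: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {("Brca1", "Bard1"): 2.0,
                                 ("Wdr5", "Brca1"): 1.8,
                                 ("Wdr5", "Bard1"): 1.4})
    cv: float = 0.1
    n_replicates: int = 6
    seed: int = 0

    def validate(self) -> None:
        if self.control_mean <= 0:
            raise ValueError("control_mean must be > 0")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if any(e <= 0 for e in self.single_effects.values()):
            raise ValueError("single_effects must be positive ratios")
        for (a, b) in self.interaction_gamma:
            if a not in self.single_effects or b not in self.single_effects:
                raise ValueError(
                    f"pair ({a}, {b}) lacks a single-knockdown effect")


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv ** 2)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=size))


def generate_colony_counts(config: ColonySimConfig) -> pd.DataFrame:
    """Simulate a colony-count table (condition, replicate, count).

    Conditions are ``control``, each single knockdown by name, and each
    double knockdown as ``"A+B"``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []

    def emit(condition: str, mean: float) -> None:
        vals = mean * _lognormal_factor(rng, config.cv, config.n_replicates)
        for r, v in enumerate(vals, start=1):
            rows.append({"condition": condition, "replicate": r,
                         "count": float(v)})

    emit("control", config.control_mean)
    for name, e in config.single_effects.items():
        emit(name, config.control_mean * e)
    for (a, b), gamma in config.interaction_gamma.items():
        mean = (config.control_mean * config.single_effects[a]
                * config.single_effects[b] * gamma)
        emit(f"{a}+{b}", mean)
    return pd.DataFrame(rows)


def screen_config_dict(config) -> dict:
    """JSON-serializable view of any simulation config (for metadata)."""
    return asdict(config)
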