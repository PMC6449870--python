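"""Embedding, rotation, quadratic time-curve fit and orthogonal projection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from reprophen.timecurve import (Embedding2D, TimeCurveModel, embed,
                                 fit_time_curve, progression_report,
                                 project_onto_curve, project_points, rotate,
                                 run_time_projection)
from reprophen.txome import normalize_counts


def make_model(coeffs, domain, calibration=None):
    cal = calibration if calibration is not None else \
        pd.DataFrame(columns=["day", "x"])
    return TimeCurveModel(coeffs, domain, cal)


def grid_oracle(point, model, n=2_000_001):
    xs = np.linspace(*model.domain, n)
    d2 = (xs - point[0]) ** 2 + (model.curve(xs) - point[1]) ** 2
    return float(np.sqrt(d2.min()))


class TestRotation:
    def test_fifteen_degrees(self):
        emb = Embedding2D(pd.DataFrame({"x": [1.0], "y": [0.0]}, index=["s"]))
        out = rotate(emb, 15.0).coords
        assert out.loc["s", "x"] == pytest.approx(0.9659258, abs=1e-6)
        assert out.loc["s", "y"] == pytest.approx(0.2588190, abs=1e-6)

    def test_origin_fixed(self):
        emb = Embedding2D(pd.DataFrame({"x": [0.0], "y": [0.0]}, index=["o"]))
        out = rotate(emb, 123.0).coords
        assert out.loc["o"].tolist() == pytest.approx([0.0, 0.0], abs=1e-15)

    @given(st.integers(0, 2 ** 31 - 1),
           st.floats(-360, 360, allow_nan=False))
    def test_isometry(self, seed, angle):
        rng = np.random.default_rng(seed)
        pts = pd.DataFrame(rng.normal(0, 10, size=(6, 2)),
                           columns=["x", "y"])
        out = rotate(Embedding2D(pts), angle).coords
        from scipy.spatial.distance import pdist
        assert np.allclose(pdist(pts.values), pdist(out.values), atol=1e-9)

    def test_rotation_accumulates_in_provenance(self):
        emb = Embedding2D(pd.DataFrame({"x": [1.0], "y": [2.0]}),
                          {"rotation_deg": 0.0})
        assert rotate(rotate(emb, 15), 5).provenance["rotation_deg"] == 20


class TestFit:
    def test_exact_interpolation(self):
        x = np.linspace(-2, 4, 7)
        pts = pd.DataFrame({"x": x, "y": 1 + 2 * x + 0.5 * x ** 2,
                            "day": np.arange(7, dtype=float)})
        model = fit_time_curve(pts)
        assert model.coeffs == pytest.approx((1.0, 2.0, 0.5), abs=1e-9)
        assert model.domain == (x.min(), x.max())

    def test_collinear_points_give_zero_curvature(self):
        x = np.linspace(0, 5, 6)
        pts = pd.DataFrame({"x": x, "y": 3 - 2 * x,
                            "day": np.arange(6, dtype=float)})
        model = fit_time_curve(pts)
        assert model.coeffs[2] == pytest.approx(0.0, abs=1e-9)

    def test_rank_deficient_raises(self):
        pts = pd.DataFrame({"x": [1.0, 1.0, 2.0], "y": [0.0, 1.0, 2.0],
                            "day": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="distinct x"):
            fit_time_curve(pts)

    def test_ols_beats_grid_of_coefficients(self):
        """The least-squares fit has RSS no worse than any coefficient
        triple on a 50^3 grid around the truth."""
        rng = np.random.default_rng(0)
        x = np.linspace(-3, 3, 24)
        y = 1.5 - 0.8 * x + 0.6 * x ** 2 + rng.normal(0, 0.5, x.size)
        pts = pd.DataFrame({"x": x, "y": y,
                            "day": np.arange(x.size, dtype=float)})
        model = fit_time_curve(pts)
        rss_fit = np.sum((model.curve(x) - y) ** 2)
        c0s = np.linspace(0.5, 2.5, 50)
        c1s = np.linspace(-1.8, 0.2, 50)
        c2s = np.linspace(-0.4, 1.6, 50)
        C0, C1, C2 = np.meshgrid(c0s, c1s, c2s, indexing="ij")
        pred = (C0[..., None] + C1[..., None] * x
                + C2[..., None] * x ** 2)
        rss_grid = ((pred - y) ** 2).sum(axis=-1).min()
        assert rss_fit <= rss_grid + 1e-9

    def test_calibration_covers_every_day(self):
        x = np.linspace(-2, 4, 6)
        pts = pd.DataFrame({"x": x, "y": x ** 2, "day": np.arange(6.0)})
        model = fit_time_curve(pts)
        assert model.calibration["day"].tolist() == list(np.arange(6.0))


class TestProjection:
    def test_flat_curve(self):
        model = make_model((0.0, 0.0, 0.0), (-5.0, 5.0))
        res = project_onto_curve((2.0, 3.0), model)
        assert res.x == pytest.approx(2.0)
        assert res.distance == pytest.approx(3.0)

    def test_point_on_curve(self):
        model = make_model((1.0, -2.0, 0.5), (-5.0, 5.0))
        x0 = 1.7
        res = project_onto_curve((x0, model.curve(x0)), model)
        assert res.distance == pytest.approx(0.0, abs=1e-9)
        assert res.x == pytest.approx(x0, abs=1e-6)

    def test_symmetric_tie_breaks_low(self):
        """y = x^2 from (0, 1): minima at +-1/sqrt(2), tie resolved toward
        smaller x; distance sqrt(3)/2."""
        model = make_model((0.0, 0.0, 1.0), (-2.0, 2.0))
        res = project_onto_curve((0.0, 1.0), model)
        assert res.x == pytest.approx(-1.0 / np.sqrt(2.0), abs=1e-9)
        assert res.distance == pytest.approx(np.sqrt(3.0) / 2.0, abs=1e-9)

    def test_domain_clamping(self):
        model = make_model((0.0, 0.0, 0.0), (-1.0, 1.0))
        res = project_onto_curve((5.0, 0.0), model)
        assert res.x == pytest.approx(1.0)
        assert res.distance == pytest.approx(4.0)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_dense_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        coeffs = tuple(rng.uniform(-2, 2, 3))
        lo, hi = np.sort(rng.uniform(-5, 5, 2))
        model = make_model(coeffs, (float(lo), float(hi + 0.5)))
        point = tuple(rng.uniform(-6, 6, 2))
        res = project_onto_curve(point, model)
        assert res.distance <= grid_oracle(point, model, 200_001) + 1e-6

    def test_day_interpolation_clamped(self):
        cal = pd.DataFrame({"day": [2.0, 3.0, 4.0], "x": [0.0, 1.0, 3.0]})
        model = make_model((0.0, 0.0, 0.0), (-5.0, 5.0), cal)
        assert project_onto_curve((0.5, 0.0), model).day == pytest.approx(2.5)
        assert project_onto_curve((-9.0, 0.0), model).day == 2.0
        assert project_onto_curve((9.0, 0.0), model).day == 4.0


class TestEmbed:
    def test_duplicated_samples_identical_coords(self, small_timecourse):
        counts, samples, _ = small_timecourse
        dup = counts.copy()
        dup["extra"] = dup[dup.columns[0]]
        samples2 = pd.concat([samples, pd.DataFrame([{
            "sample": "extra",
            "condition": samples.iloc[0]["condition"],
            "day": samples.iloc[0]["day"], "replicate": 9}])],
            ignore_index=True)
        emb = embed(normalize_counts(dup), samples2, n_top=100)
        a = emb.coords.loc[dup.columns[0]]
        b = emb.coords.loc["extra"]
        assert np.allclose(a, b, atol=1e-9)

    def test_x_oriented_with_day(self, small_timecourse):
        counts, samples, _ = small_timecourse
        emb = embed(normalize_counts(counts), samples, n_top=100)
        day = samples.set_index("sample")["day"]
        tc = day.dropna().index
        r = np.corrcoef(day[tc], emb.coords.loc[tc, "x"])[0, 1]
        assert r > 0

    def test_projected_x_tracks_day(self, small_timecourse):
        counts, samples, _ = small_timecourse
        res = run_time_projection(counts, samples, n_top=100)
        rep = res["report"]
        tc = rep[rep["is_timecourse"]].copy()
        tc["day"] = tc["condition"].str.removeprefix("day").astype(float)
        tc = tc[(tc["day"] >= 2) & (tc["day"] <= 7)]  # fitted range
        r2 = np.corrcoef(tc["day"], tc["x"])[0, 1] ** 2
        assert r2 >= 0.8


class TestProgressionReport:
    def test_delayed_flag(self, small_timecourse):
        counts, samples, truth = small_timecourse
        res = run_time_projection(counts, samples, n_top=100)
        rep = res["report"].set_index("condition")
        nt_day = rep.loc["nt", "day_estimate"]
        early = truth.index[truth["progression"] < 4.0]
        for kd in early:
            if rep.loc[kd, "day_estimate"] < nt_day - 1.0:
                assert rep.loc[kd, "delayed"]
        assert not rep.loc["nt", "delayed"]

    def test_missing_reference_warns(self, small_timecourse):
        counts, samples, _ = small_timecourse
        with pytest.warns(RuntimeWarning, match="reference"):
            res = run_time_projection(counts, samples, n_top=100,
                                      reference="absent")
        assert not res["report"]["delayed"].any()

    def test_timecourse_day_estimates_monotone(self):
        """With vanishing dispersion the time-course conditions' day
        estimates are non-decreasing in true day (within the fitted
        range)."""
        import reprophen as rp
        cfg = rp.TrajectorySimConfig(
            n_genes=400, replicates_per_day=2, n_knockdowns=2,
            knockdown_names=("nt", "kd"), planted_progression=(5.7, 4.0),
            orthogonal_offset=(0.0, 1.0), replicates_per_knockdown=2,
            dispersion=1e-13, library_size=1_000_000, seed=9)
        counts, samples, _ = rp.generate_timecourse(cfg)
        res = run_time_projection(counts, samples, n_top=100)
        rep = res["report"]
        tc = rep[rep["is_timecourse"]].copy()
        tc["day"] = tc["condition"].str.removeprefix("day").astype(float)
        tc = tc[(tc["day"] >= 2) & (tc["day"] <= 7)].sort_values("day")
        assert (np.diff(tc["day_estimate"]) > -1e-9).all()

    def test_rotation_invariance_of_residuals(self, small_timecourse):
        """Rotating the embedding and refitting yields the same residual
        distances (the procedure is covariant with rotation angle) to a
        tolerance set by the curve-model mismatch."""
        counts, samples, truth = small_timecourse
        r15 = run_time_projection(counts, samples, n_top=100, angle=15.0)
        r20 = run_time_projection(counts, samples, n_top=100, angle=20.0)
        d15 = r15["report"].set_index("condition")["distance"]
        d20 = r20["report"].set_index("condition")["distance"]
        kd = truth.index
        r = np.corrcoef(d15[kd], d20[kd])[0, 1]
        assert r > 0.95
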