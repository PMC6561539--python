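"""Synthetic-study generator: geometry, determinism and distributional checks."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from camsecr.secr import pdot
from camsecr.simulate import (SimConfig, generate_landscape,
                              generate_trap_arrays, generate_trap_positions,
                              generate_usage, simulate_capture_histories,
                              simulate_population, simulate_prey_detections,
                              simulate_study)
from camsecr.types import StateSpace


def small_config(**kw):
    kw.setdefault("n_arrays", 2)
    kw.setdefault("stations_per_array", (9, 9))
    kw.setdefault("buffer", 3000.0)
    kw.setdefault("pixel_size", 1000.0)
    return SimConfig(**kw)


class TestConfigValidation:
    def test_rejects_nonpositive_pixel(self):
        with pytest.raises(ValueError, match="pixel_size"):
            SimConfig(pixel_size=0.0)

    def test_rejects_inverted_occasion_range(self):
        with pytest.raises(ValueError, match="min > max"):
            SimConfig(n_occasions=(30, 12))

    def test_rejects_negative_hyper_sd(self):
        with pytest.raises(ValueError):
            SimConfig(occupancy_sd=-0.5)


class TestLandscape:
    def test_pixels_cover_traps_plus_buffer(self):
        cfg = SimConfig(rng_seed=1, buffer=6000.0, pixel_size=500.0)
        rng = np.random.default_rng(1)
        xy = generate_trap_positions(cfg, rng, n_stations=25)
        space, _ = generate_landscape(cfg, "A", xy, rng)
        lo, hi = xy.min(axis=0), xy.max(axis=0)
        # every pixel centre is within the buffer of the trap bounding box
        gap = np.maximum(lo - space.xy, space.xy - hi).max(axis=1)
        assert gap.max() <= 6000.0 + 1e-9
        # and the mask reaches (nearly) the full buffer on every side
        assert gap.max() > 6000.0 - cfg.pixel_size

    def test_neighbouring_centres_spacing(self):
        cfg = SimConfig(rng_seed=1, pixel_size=500.0)
        rng = np.random.default_rng(1)
        xy = generate_trap_positions(cfg, rng, n_stations=25)
        space, _ = generate_landscape(cfg, "A", xy, rng)
        xs = np.unique(space.xy[:, 0])
        assert np.allclose(np.diff(xs), 500.0)

    def test_d2river_matches_bruteforce_segment_distance(self):
        cfg = small_config(rng_seed=7)
        rng = np.random.default_rng(7)
        xy = generate_trap_positions(cfg, rng, n_stations=9)
        space, geom = generate_landscape(cfg, "A", xy, rng)

        def seg_dist(p, a, b):
            ab = b - a
            t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
            return np.linalg.norm(p - (a + t * ab))

        segs = []
        for line in geom.rivers.geoms:
            v = np.asarray(line.coords)
            segs.extend((v[i], v[i + 1]) for i in range(len(v) - 1))
        expected = np.array([min(seg_dist(p, a, b) for a, b in segs)
                             for p in space.xy])
        np.testing.assert_allclose(
            space.covariates["d2river"].to_numpy(), expected, atol=1e-8)


class TestTrapArrays:
    def test_station_counts_in_default_range(self):
        traps, _, _ = generate_trap_arrays(SimConfig(rng_seed=2))
        for layout in traps.values():
            assert 25 <= layout.n_traps <= 34

    def test_full_usage_trap_days(self):
        cfg = small_config(rng_seed=2, n_occasions=(31, 31))
        usage = generate_usage(cfg, 9, np.random.default_rng(0))
        assert usage.shape == (9, 31)
        assert usage.sum() == 31 * 9

    def test_seed_determinism(self):
        a = generate_trap_arrays(SimConfig(rng_seed=9))
        b = generate_trap_arrays(SimConfig(rng_seed=9))
        for name in a[0]:
            np.testing.assert_array_equal(a[0][name].xy, b[0][name].xy)
            np.testing.assert_array_equal(a[0][name].usage, b[0][name].usage)


def flat_space(total_area_km2: float, pixel_km: float = 1.0) -> StateSpace:
    n = int(total_area_km2 / pixel_km ** 2)
    ncol = int(math.sqrt(n))
    nrow = n // ncol
    xs, ys = np.meshgrid(np.arange(ncol), np.arange(nrow))
    xy = np.column_stack([xs.ravel(), ys.ravel()]) * pixel_km * 1000.0
    return StateSpace(array="F", xy=xy, pixel_size=pixel_km * 1000.0,
                      covariates=pd.DataFrame(index=range(len(xy))))


class TestPopulation:
    def test_poisson_mean_monte_carlo(self):
        # 2500 km² (the whole-survey scale) at 4.22/100 km² → E[N] = 105.5
        space = flat_space(2500.0, pixel_km=2.0)
        expected = 4.22e-4 * space.total_area_ha
        assert expected == pytest.approx(105.5, abs=0.6)
        rng = np.random.default_rng(42)
        counts = [len(simulate_population(space, math.log(4.22e-4), {}, {},
                                          rng)) for _ in range(200)]
        se = math.sqrt(expected / 200)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_zero_intensity_yields_empty_population(self):
        space = flat_space(25.0)
        rng = np.random.default_rng(0)
        df = simulate_population(space, -45.0, {}, {}, rng)
        assert len(df) == 0

    def test_extreme_log_intensity_rejected(self):
        space = flat_space(25.0)
        with pytest.raises(ValueError, match="log intensity"):
            simulate_population(space, 60.0, {}, {},
                                np.random.default_rng(0))

    def test_positive_beta_concentrates_in_high_covariate_pixels(self):
        space = flat_space(100.0)
        grad = space.xy[:, 0].copy()
        space.covariates["d2boundary"] = grad
        std = {"d2boundary": (float(grad.mean()), float(grad.std()))}
        rng = np.random.default_rng(1)
        q1, q3 = np.quantile(grad, [0.25, 0.75])
        top = np.zeros(1)
        bottom = np.zeros(1)
        for _ in range(50):
            df = simulate_population(space, math.log(2e-3),
                                     {"d2boundary": 1.0}, std, rng)
            top += (df["x"] >= q3).sum()
            bottom += (df["x"] <= q1).sum()
        assert top.sum() > bottom.sum()

    def test_centres_lie_inside_state_space(self):
        cfg = small_config(rng_seed=4)
        data, truth, _ = simulate_study(cfg)
        for a in data.arrays:
            space = data.state_spaces[a]
            pts = truth.activity_centres.query("array == @a")[["x", "y"]]
            lo = space.xy.min(axis=0) - space.pixel_size / 2
            hi = space.xy.max(axis=0) + space.pixel_size / 2
            assert ((pts.to_numpy() >= lo) & (pts.to_numpy() <= hi)).all()


class TestCaptureHistories:
    def _one_animal(self, p0, sigma, d, occasions, seed=0):
        from camsecr.types import TrapLayout
        layout = TrapLayout(
            array="A", ids=["A-t1"], xy=np.array([[0.0, 0.0]]),
            usage=np.ones((1, occasions), dtype=int),
            covariates=pd.DataFrame({"d2river": [0.0], "d2boundary": [0.0],
                                     "camera_type": [0]}))
        centres = pd.DataFrame({"x": [d], "y": [0.0], "sex": ["F"]})
        return simulate_capture_histories(
            centres, layout, np.array([p0]), np.array([sigma]),
            np.random.default_rng(seed))

    def test_zero_baseline_gives_empty_history(self):
        session, detected = self._one_animal(0.0, 1000.0, 0.0, 50)
        assert len(session.detections) == 0
        assert not detected.any()

    def test_certain_detection_at_zero_distance(self):
        session, detected = self._one_animal(1.0, 1000.0, 0.0, 1)
        assert len(session.detections) == 1
        assert detected.all()

    def test_binomial_frequency_at_one_sigma(self):
        n = 100_000
        session, _ = self._one_animal(0.03, 1840.0, 1840.0, n, seed=3)
        p = 0.03 * math.exp(-0.5)
        freq = len(session.detections) / n
        assert abs(freq - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError, match="sigma"):
            self._one_animal(0.5, 0.0, 100.0, 5)

    def test_no_detection_outside_usage(self):
        data, _, _ = simulate_study(small_config(rng_seed=6))
        for s in data.sessions:
            layout = data.traps[s.array]
            jidx = {d: j for j, d in enumerate(layout.ids)}
            for r in s.detections.itertuples():
                assert layout.usage[jidx[r.detector], r.occasion] == 1

    def test_thinning_consistency(self):
        """E[# detected] = Σ_g λ_g·p·(s_g); Monte-Carlo mean over 200
        population+detection replicates within 3 SE."""
        cfg = small_config(rng_seed=0)
        rng = np.random.default_rng(123)
        traps, spaces, _ = generate_trap_arrays(cfg, rng)
        a = sorted(traps)[0]
        layout, space = traps[a], spaces[a]
        p0, sigma = 0.05, 1500.0
        diff = space.xy[:, None, :] - layout.xy[None, :, :]
        dists = np.sqrt((diff ** 2).sum(axis=2))
        pd_g = pdot(dists, np.full(layout.n_traps, p0),
                    np.full(layout.n_traps, sigma), layout.usage)
        intercept = math.log(3e-3)
        lam = math.exp(intercept) * space.pixel_area_ha
        expected = float((lam * pd_g).sum())
        counts = []
        for _ in range(200):
            centres = simulate_population(space, intercept, {}, {}, rng)
            _, detected = simulate_capture_histories(
                centres, layout, np.array([p0]), np.array([sigma]), rng)
            counts.append(detected.sum())
        se = np.std(counts) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se


class TestPreyGeneration:
    def _tables(self, **kw):
        cfg = small_config(rng_seed=8, **kw)
        rng = np.random.default_rng(8)
        traps, _, _ = generate_trap_arrays(cfg, rng)
        return simulate_prey_detections(cfg, traps, rng)

    def test_degenerate_hyperpriors_share_parameters(self):
        table, truth = self._tables(occupancy_sd=0.0, detection_sd=0.0)
        assert np.allclose(truth.prey_psi, truth.prey_psi[0, :][None, :])
        assert np.allclose(truth.prey_p, truth.prey_p[0])

    def test_structural_zero_counts(self):
        table, truth = self._tables()
        assert (table.y[truth.occupancy_states == 0] == 0).all()

    def test_hypermean_zero_gives_half_occupancy(self):
        cfg = small_config(rng_seed=8, occupancy_hypermeans=(0.0, 0.0),
                           occupancy_sd=0.0, n_prey_species=40)
        occs = []
        rng = np.random.default_rng(9)
        traps, _, _ = generate_trap_arrays(cfg, rng)
        for _ in range(30):
            _, truth = simulate_prey_detections(cfg, traps, rng)
            occs.append(truth.occupancy_states.mean())
        assert abs(np.mean(occs) - 0.5) < 0.02

    def test_binomial_marginal_mean(self):
        """Marginal E[y_ij] = ψ_ij·p_i·k_j under the mixture."""
        table, truth = self._tables(n_prey_species=30)
        expected = (truth.prey_psi.mean() * truth.prey_p.mean()
                    * table.k.mean())
        # crude first-moment check with generous Monte-Carlo slack
        assert table.y.mean() == pytest.approx(expected, rel=0.2)


class TestStudyDeterminism:
    def test_identical_seed_reproduces_everything(self):
        cfg = small_config(rng_seed=31)
        d1, t1, p1 = simulate_study(cfg)
        d2, t2, p2 = simulate_study(cfg)
        pd.testing.assert_frame_equal(t1.activity_centres,
                                      t2.activity_centres)
        np.testing.assert_array_equal(p1.y, p2.y)
        for s1, s2 in zip(d1.sessions, d2.sessions):
            pd.testing.assert_frame_equal(s1.detections, s2.detections)
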