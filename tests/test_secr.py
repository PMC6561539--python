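"""Encounter model, design matrices and the stratified Poisson likelihood."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camsecr import (ModelSpec, SECRLikelihood, fit_ml, halfnormal_p, pdot,
                     predict_density)
from camsecr.design import build_design
from camsecr.simulate import SimConfig, simulate_study
from camsecr.types import CaptureSession, SECRData

from conftest import make_micro_data


class TestHalfNormal:
    @pytest.mark.parametrize("p0,sigma,d,expected", [
        (0.5, 1000.0, 0.0, 0.5),
        (0.5, 1000.0, 1000.0 * math.sqrt(2 * math.log(2)), 0.25),
        (0.030, 1840.0, 1840.0, 0.030 * math.exp(-0.5)),
    ])
    def test_values(self, p0, sigma, d, expected):
        assert halfnormal_p(p0, sigma, d) == pytest.approx(expected,
                                                           abs=1e-12)

    def test_rejects_bad_domain(self):
        with pytest.raises(ValueError):
            halfnormal_p(0.5, 0.0, 10.0)
        with pytest.raises(ValueError):
            halfnormal_p(1.5, 100.0, 10.0)

    @settings(derandomize=True, max_examples=50)
    @given(p0=st.floats(0.0, 1.0),
           sigma=st.floats(1.0, 1e4),
           d1=st.floats(0.0, 1e4), d2=st.floats(0.0, 1e4))
    def test_monotone_nonincreasing_in_distance(self, p0, sigma, d1, d2):
        lo, hi = sorted((d1, d2))
        assert halfnormal_p(p0, sigma, hi) <= halfnormal_p(p0, sigma, lo)


class TestPdot:
    def test_single_trap_single_occasion_equals_halfnormal(self):
        d = np.array([[700.0]])
        got = pdot(d, [0.3], [1000.0], np.ones((1, 1)))
        assert got[0] == pytest.approx(halfnormal_p(0.3, 1000.0, 700.0),
                                       abs=1e-12)

    def test_no_effort_means_no_detection(self):
        d = np.array([[700.0, 200.0]])
        assert pdot(d, [0.3, 0.3], [1000.0, 1000.0],
                    np.zeros((2, 3)))[0] == 0.0

    def test_complement_product(self):
        # two traps × two occasions, each per-occasion p = 0.1
        sigma = 1000.0
        dist = 500.0
        p0 = 0.1 / math.exp(-dist ** 2 / (2 * sigma ** 2))
        d = np.array([[dist, dist]])
        got = pdot(d, [p0, p0], [sigma, sigma], np.ones((2, 2)))
        assert got[0] == pytest.approx(1 - 0.9 ** 4, abs=1e-12)


class TestDesign:
    def _sim(self, **kw):
        cfg = SimConfig(rng_seed=3, n_arrays=kw.pop("n_arrays", 6),
                        pixel_size=1000.0, **kw)
        data, _, _ = simulate_study(cfg)
        return data

    def test_standardized_columns_have_mean0_sd1(self):
        data = self._sim()
        spec = ModelSpec(density=("elevation", "d2boundary"))
        ds = build_design(spec, data)
        col = np.concatenate([s.X_density[:, 1] for s in ds.strata])
        assert abs(col.mean()) < 1e-10
        assert abs(col.std() - 1.0) < 1e-10

    def test_six_level_array_factor_gives_five_dummies(self):
        data = self._sim()
        ds = build_design(ModelSpec(sigma=("array",)), data)
        assert len(ds.names["sigma"]) == 6  # intercept + 5 dummies
        dummy_cols = [n for n in ds.names["sigma"] if n.startswith("array[")]
        assert len(dummy_cols) == 5

    def test_zero_variance_covariate_rejected(self):
        data = self._sim(n_arrays=2)
        for a in data.arrays:
            data.state_spaces[a].covariates["elevation"] = 5.0
        with pytest.raises(ValueError, match="elevation"):
            build_design(ModelSpec(density=("elevation",)), data)


def _loglik(data, density_log, p0_logit, sigma_log,
            spec=ModelSpec()) -> float:
    lik = SECRLikelihood(spec, data)
    return -lik.neg_loglik(np.array([density_log, p0_logit, sigma_log]))


class TestNegLoglik:
    def test_closed_form_one_pixel_one_trap_one_occasion(self):
        # L = exp(−λp)·λp for a single detected animal
        D, p0, sigma = 3e-4, 0.4, 800.0
        data = make_micro_data(detections=[("i1", 0, 0)])
        area_ha = 100.0  # 1 km² pixel
        lam = D * area_ha
        expected = -lam * p0 + math.log(lam * p0)
        got = _loglik(data, math.log(D), math.log(p0 / (1 - p0)),
                      math.log(sigma))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_stratified_total_is_sum_of_regions(self):
        kwargs = dict(pixels_xy=[(0.0, 0.0), (1000.0, 0.0)],
                      traps_xy=[(0.0, 0.0), (800.0, 0.0)],
                      usage=np.ones((2, 3)),
                      detections=[("i1", 0, 0), ("i1", 1, 2), ("i2", 0, 1)])
        d1 = make_micro_data(array="A", **kwargs)
        d2 = make_micro_data(array="B", **kwargs)
        both = SECRData(sessions=d1.sessions + d2.sessions,
                        traps={**d1.traps, **d2.traps},
                        state_spaces={**d1.state_spaces, **d2.state_spaces})
        params = (math.log(2e-4), -2.0, math.log(900.0))
        assert _loglik(both, *params) == pytest.approx(
            2 * _loglik(d1, *params), abs=1e-10)

    def test_invariant_to_relabelling_and_detector_order(self):
        data = make_micro_data(
            pixels_xy=[(0.0, 0.0), (1500.0, 0.0)],
            traps_xy=[(0.0, 0.0), (1000.0, 500.0), (200.0, -800.0)],
            usage=np.ones((3, 4)),
            detections=[("i1", 0, 0), ("i1", 2, 3), ("i2", 1, 1),
                        ("i2", 1, 2)])
        params = (math.log(2e-4), -2.0, math.log(900.0))
        base = _loglik(data, *params)

        # relabel individuals and permute detector order
        perm = [2, 0, 1]
        layout = data.traps["A"]
        ids = [layout.ids[j] for j in perm]
        import pandas as pd

        from camsecr.types import StateSpace, TrapLayout
        layout2 = TrapLayout(array="A", ids=ids, xy=layout.xy[perm],
                             usage=layout.usage[perm],
                             covariates=layout.covariates.iloc[perm]
                             .reset_index(drop=True))
        det = data.sessions[0].detections.copy()
        det["individual"] = det["individual"].map({"i1": "zz", "i2": "aa"})
        session2 = CaptureSession(array="A", detections=det)
        data2 = SECRData(sessions=[session2], traps={"A": layout2},
                         state_spaces=data.state_spaces)
        assert _loglik(data2, *params) == pytest.approx(base, abs=1e-10)

    def test_enumeration_total_probability(self):
        """Over every possible outcome (all multisets of detected
        histories, any population size) the model's probabilities sum
        to 1; checked via the exp(−Σλp·)·exp(Σμ(ω)) identity with μ(ω)
        enumerated history by history."""
        for traps_xy, usage in [
            ([(0.0, 0.0)], np.ones((1, 2))),
            ([(0.0, 0.0), (900.0, 0.0)], np.array([[1, 1], [1, 0]])),
        ]:
            data0 = make_micro_data(
                pixels_xy=[(0.0, 0.0), (1200.0, 300.0)],
                traps_xy=traps_xy, usage=usage, detections=[])
            params = (math.log(8e-4), -0.5, math.log(700.0))
            log_l0 = _loglik(data0, *params)  # = −Σ_g λ_g p·(s_g)
            total_mu = 0.0
            J, K = np.asarray(usage).shape
            live = [(j, k) for j in range(J) for k in range(K)
                    if usage[j][k] == 1]
            for mask in range(1, 2 ** len(live)):
                dets = [("i1", j, k) for b, (j, k) in enumerate(live)
                        if mask >> b & 1]
                data1 = make_micro_data(
                    pixels_xy=[(0.0, 0.0), (1200.0, 300.0)],
                    traps_xy=traps_xy, usage=usage, detections=dets)
                total_mu += math.exp(_loglik(data1, *params) - log_l0)
            assert log_l0 + total_mu == pytest.approx(0.0, abs=1e-10)


class TestFit:
    def test_duplicating_histories_roughly_doubles_density(self):
        cfg = SimConfig(rng_seed=11, pixel_size=1000.0, density_betas={})
        data, _, _ = simulate_study(cfg)
        spec = ModelSpec(p0=(), sigma=())
        fit1 = fit_ml(spec, data, compute_se=False)

        doubled = []
        for s in data.sessions:
            det = s.detections.copy()
            det2 = det.copy()
            det2["individual"] = det2["individual"] + "_dup"
            doubled.append(CaptureSession(
                array=s.array, detections=pd.concat([det, det2],
                                                    ignore_index=True)))
        data2 = SECRData(sessions=doubled, traps=data.traps,
                         state_spaces=data.state_spaces)
        fit2 = fit_ml(spec, data2, compute_se=False)
        ratio = math.exp(fit2.coef("density.(Intercept)")
                         - fit1.coef("density.(Intercept)"))
        assert 1.8 < ratio < 2.2
        assert fit2.loglik != pytest.approx(fit1.loglik)

    def test_zero_variance_covariate_fails_before_optimization(self):
        cfg = SimConfig(rng_seed=3, n_arrays=2, pixel_size=1000.0)
        data, _, _ = simulate_study(cfg)
        for a in data.arrays:
            data.state_spaces[a].covariates["elevation"] = 1.0
        with pytest.raises(ValueError, match="elevation"):
            fit_ml(ModelSpec(density=("elevation",)), data)

    def test_buffer_stability_of_density_mle(self):
        """With σ = 1.5 km, trimming the mask from a 9 km to a 6 km
        buffer moves the homogeneous density MLE by < 2%."""
        cfg = SimConfig(rng_seed=21, n_arrays=3, pixel_size=1000.0,
                        buffer=9000.0, density_betas={},
                        sigma_intercept=math.log(1500.0), sigma_deltas={})
        data, _, _ = simulate_study(cfg)
        spec = ModelSpec()
        fit9 = fit_ml(spec, data, compute_se=False)

        trimmed = {}
        for a, space in data.state_spaces.items():
            xy = data.traps[a].xy
            lo, hi = xy.min(axis=0) - 6000.0, xy.max(axis=0) + 6000.0
            keep = np.all((space.xy >= lo) & (space.xy <= hi), axis=1)
            from camsecr.types import StateSpace
            trimmed[a] = StateSpace(
                array=a, xy=space.xy[keep], pixel_size=space.pixel_size,
                covariates=space.covariates.loc[keep].reset_index(drop=True),
                region_covariates=space.region_covariates)
        data6 = SECRData(sessions=data.sessions, traps=data.traps,
                         state_spaces=trimmed)
        fit6 = fit_ml(spec, data6, compute_se=False)
        d9 = math.exp(fit9.coef("density.(Intercept)"))
        d6 = math.exp(fit6.coef("density.(Intercept)"))
        assert abs(d6 - d9) / d9 < 0.02


class TestPredict:
    def test_intercept_only_surface_is_constant_and_sums_to_lambda(self):
        cfg = SimConfig(rng_seed=5, n_arrays=2, pixel_size=1000.0,
                        density_betas={})
        data, _, _ = simulate_study(cfg)
        fit = fit_ml(ModelSpec(), data, compute_se=False)
        a = data.arrays[0]
        surface, lam = predict_density(fit, data.state_spaces[a])
        assert surface.min() == pytest.approx(surface.max())
        assert surface.max() == pytest.approx(
            math.exp(fit.coef("density.(Intercept)")))
        assert lam == pytest.approx(
            surface.sum() * data.state_spaces[a].pixel_area_ha)

    def test_positive_boundary_effect_raises_density_inland(self, table3_fit):
        cfg = SimConfig(rng_seed=5, n_arrays=2, pixel_size=1000.0)
        data, _, _ = simulate_study(cfg)
        spec = ModelSpec(density=("d2boundary",), p0=("d2river",),
                         sigma=("array",))
        fit = fit_ml(spec, data, compute_se=False)
        beta = fit.coef("density.d2boundary")
        a = data.arrays[0]
        space = data.state_spaces[a]
        surface, _ = predict_density(fit, space)
        d2b = space.covariates["d2boundary"].to_numpy()
        order = np.argsort(d2b)
        # monotone in the covariate when it is the only spatial term
        diffs = np.diff(surface[order])
        assert (diffs >= -1e-15).all() if beta > 0 else (diffs <= 1e-15).all()
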