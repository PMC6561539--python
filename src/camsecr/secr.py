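"""Stratified maximum-likelihood spatial capture-recapture.

The encounter model is half-normal: an individual with activity centre s is
detected at trap j on one occasion with probability

    p = p0 · exp(−d(s, j)² / (2σ²)),

with logit(p0) and log(σ) linear in trap-level covariates.  Activity
centres follow an inhomogeneous Poisson point process over a discrete
habitat mask with log-linear intensity in pixel- and region-level
covariates, and the number of activity centres in each region is
Poisson(Λ_r).  Regions (trap arrays) are independent strata; the full
(Poisson) likelihood for region r with n_r detected individuals is

    L_r = exp(−Σ_g λ_g·p·(s_g)) · Π_i Σ_g λ_g·Pr(ω_i | s_g) / n_r!

where λ_g = D(s_g)·a_g, p·(s) is the probability of at least one
detection anywhere, and Pr(ω_i | s_g) multiplies Bernoulli terms over
every live trap-occasion.  Because occasion-constant covariates make p
identical across occasions, the per-occasion product collapses to
binomial form in the per-trap effort and detection-day counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp

from .design import Stratum, build_design
from .types import (CaptureSession, FittedModel, ModelSpec, SECRData,
                    StateSpace, TrapLayout)

logger = logging.getLogger(__name__)

_PENALTY = 1.0e10        # optimizer-safe stand-in for non-finite likelihoods
_P_CLIP = 1.0 - 1e-12


def halfnormal_p(p0: float, sigma: float, d) -> np.ndarray | float:
    """Per-occasion detection probability at distance d from the centre.

    p0 is the baseline encounter probability (at d = 0) and sigma the
    spatial scale in the same units as d.
    """
    p0 = np.asarray(p0, dtype=float)
    if np.any(p0 < 0) or np.any(p0 > 1):
        raise ValueError("p0 must lie in [0, 1]")
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = p0 * np.exp(-(d ** 2) / (2.0 * np.asarray(sigma, float) ** 2))
    return out if out.shape else float(out)


def pdot(distances: np.ndarray, p0: np.ndarray, sigma: np.ndarray,
         usage: np.ndarray) -> np.ndarray:
    """Probability of ≥1 detection anywhere, per activity-centre location.

    ``distances`` is (G, J); p0 and sigma are per-trap vectors on the
    natural scale; ``usage`` is the (J, K) binary effort matrix.  Returns a
    length-G vector 1 − Π_{j,k} (1 − usage(j,k)·p(s,j)).
    """
    p0 = np.atleast_1d(np.asarray(p0, float))
    sigma = np.atleast_1d(np.asarray(sigma, float))
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    effort = np.asarray(usage).sum(axis=1).astype(float)
    p = np.minimum(p0[None, :] * np.exp(
        -distances ** 2 / (2.0 * sigma[None, :] ** 2)), _P_CLIP)
    log_surv = np.log1p(-p) @ effort
    return -np.expm1(log_surv)


@dataclass
class _StratumData:
    """Precomputed per-stratum quantities reused across likelihood calls."""

    stratum: Stratum
    distances: np.ndarray     # (G, J)
    effort: np.ndarray        # (J,)
    counts: np.ndarray        # (n, J) detection-day counts
    pixel_area_ha: float
    log_nfact: float


class SECRLikelihood:
    """Negative log-likelihood machinery for one model spec on one dataset."""

    def __init__(self, spec: ModelSpec, data: SECRData,
                 standardization: Optional[dict] = None):
        self.spec = spec
        self.data = data
        self.design = build_design(spec, data, standardization)
        self._strata: list[_StratumData] = []
        dist_cache: dict[str, np.ndarray] = {}
        for st in self.design.strata:
            traps = data.traps[st.array]
            space = data.state_spaces[st.array]
            if st.array not in dist_cache:
                diff = space.xy[:, None, :] - traps.xy[None, :, :]
                dist_cache[st.array] = np.sqrt((diff ** 2).sum(axis=2))
            session = data.session_for(st.array)
            counts = self._stratum_counts(session, traps, st.sex)
            if counts.shape[0] == 0:
                logger.warning(
                    "stratum (%s, %s) has no detections; it contributes "
                    "only the no-detection term", st.array, st.sex)
            self._strata.append(_StratumData(
                stratum=st,
                distances=dist_cache[st.array],
                effort=traps.effort,
                counts=counts,
                pixel_area_ha=space.pixel_area_ha,
                log_nfact=float(gammaln(counts.shape[0] + 1)),
            ))

    def _stratum_counts(self, session: Optional[CaptureSession],
                        traps: TrapLayout, sex: Optional[str]) -> np.ndarray:
        if session is None:
            return np.zeros((0, traps.n_traps))
        inds = session.individuals
        if sex is not None:
            unknown = [i for i in inds if session.sex_of(i) == "U"]
            if unknown:
                logger.warning(
                    "excluding %d individual(s) of unknown sex from "
                    "sex-stratified fit in array %s", len(unknown),
                    session.array)
            inds = [i for i in inds if session.sex_of(i) == sex]
        return session.count_matrix(traps, inds)

    @property
    def n_params(self) -> int:
        return self.design.n_params

    def split(self, params: np.ndarray) -> dict[str, np.ndarray]:
        s = self.design.slices
        return {p: params[s[p]] for p in ("density", "p0", "sigma")}

    def neg_loglik(self, params: np.ndarray) -> float:
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_params,):
            raise ValueError(f"expected {self.n_params} parameters")
        blocks = self.split(params)
        total = 0.0
        for sd in self._strata:
            st = sd.stratum
            eta_d = st.X_density @ blocks["density"] + st.density_offset
            if np.any(np.abs(eta_d) > 50.0):
                return _PENALTY
            lam = np.exp(eta_d) * sd.pixel_area_ha          # (G,)
            p0 = expit(st.X_p0 @ blocks["p0"])              # (J,)
            log_sig = st.X_sigma @ blocks["sigma"]
            if np.any(np.abs(log_sig) > 30.0):
                return _PENALTY
            sigma = np.exp(log_sig)
            p = np.clip(
                p0[None, :] * np.exp(-sd.distances ** 2
                                     / (2.0 * sigma[None, :] ** 2)),
                1e-300, _P_CLIP)                            # (G, J)
            log_q = np.log1p(-p)
            log_surv = log_q @ sd.effort                    # (G,)
            pd = -np.expm1(log_surv)
            ll = -float(lam @ pd)
            n = sd.counts.shape[0]
            if n:
                # log Pr(ω_i|s_g) = Σ_j e_j log(1−p) + Σ_j y_ij (log p − log(1−p))
                contrib = sd.counts @ (np.log(p) - log_q).T  # (n, G)
                log_pr = contrib + log_surv[None, :]
                with np.errstate(divide="ignore"):
                    log_lam = np.log(lam)
                marg = logsumexp(log_lam[None, :] + log_pr, axis=1)
                if not np.all(np.isfinite(marg)):
                    return _PENALTY
                ll += float(marg.sum()) - sd.log_nfact
            if not np.isfinite(ll):
                logger.debug("non-finite likelihood in stratum (%s, %s)",
                             st.array, st.sex)
                return _PENALTY
            total -= ll
        return total

    # ---- fitting -----------------------------------------------------

    def start_values(self) -> np.ndarray:
        """Documented default start: naive density, logit p0 = −3, σ from
        half the mean recapture distance (fallback 1500 m)."""
        area_ha = sum(s.total_area_ha for s in self.data.state_spaces.values())
        n = max(self.data.n_individuals, 1)
        x0 = np.zeros(self.n_params)
        sl = self.design.slices
        x0[sl["density"].start] = np.log(n / area_ha)
        x0[sl["p0"].start] = -3.0
        x0[sl["sigma"].start] = np.log(self._recapture_scale())
        return x0

    def _recapture_scale(self) -> float:
        dists = []
        for session in self.data.sessions:
            traps = self.data.traps[session.array]
            jidx = {d: j for j, d in enumerate(traps.ids)}
            for _, grp in session.detections.groupby("individual"):
                js = sorted({jidx[d] for d in grp["detector"]})
                for a in range(len(js)):
                    for b in range(a + 1, len(js)):
                        dists.append(np.linalg.norm(
                            traps.xy[js[a]] - traps.xy[js[b]]))
        if dists:
            half_mean = 0.5 * float(np.mean(dists))
            if half_mean > 0:
                return half_mean
        return 1500.0

    def _num_grad(self, params: np.ndarray, step: float = 1e-5
                  ) -> np.ndarray:
        g = np.empty(self.n_params)
        for i in range(self.n_params):
            e = np.zeros(self.n_params); e[i] = step
            g[i] = (self.neg_loglik(params + e)
                    - self.neg_loglik(params - e)) / (2 * step)
        return g

    def hessian(self, params: np.ndarray, step: float = 1e-4) -> np.ndarray:
        """Central finite-difference Hessian of the negative log-likelihood."""
        k = self.n_params
        H = np.empty((k, k))
        f = self.neg_loglik
        for i in range(k):
            ei = np.zeros(k); ei[i] = step
            for j in range(i, k):
                ej = np.zeros(k); ej[j] = step
                H[i, j] = H[j, i] = (
                    f(params + ei + ej) - f(params + ei - ej)
                    - f(params - ei + ej) + f(params - ei - ej)
                ) / (4.0 * step * step)
        return H

    def fit(self, start: Optional[np.ndarray] = None,
            compute_se: bool = True, options: Optional[dict] = None
            ) -> FittedModel:
        x0 = self.start_values() if start is None else np.asarray(start, float)
        opts = {"maxiter": 2000, "gtol": 1e-6}
        if options:
            opts.update(options)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(self.neg_loglik, x0, method="BFGS",
                           tol=1e-8, options=opts)
            # BFGS with a finite-difference gradient can stall with a
            # "precision loss" flag near the optimum; alternate with a
            # derivative-free polish until the gradient is flat.
            for _ in range(3):
                grad = self._num_grad(res.x)
                if res.fun < _PENALTY / 2 and np.max(np.abs(grad)) < 5e-2:
                    break
                polish = minimize(self.neg_loglik, res.x,
                                  method="Nelder-Mead",
                                  options={"xatol": 1e-7, "fatol": 1e-9,
                                           "maxiter": 5000, "maxfev": 8000})
                if polish.fun <= res.fun:
                    res = polish
                res = minimize(self.neg_loglik, res.x, method="BFGS",
                               tol=1e-8, options=opts)
            grad = self._num_grad(res.x)
        converged = bool(res.fun < _PENALTY / 2
                         and np.max(np.abs(grad)) < 5e-2)
        if not converged:
            logger.warning("SECR optimizer did not converge: %s", res.message)
        se = vcov = None
        if compute_se and converged:
            H = self.hessian(res.x)
            try:
                vcov = np.linalg.inv(H)
                diag = np.diag(vcov)
                if np.any(diag <= 0):
                    raise np.linalg.LinAlgError("non-positive variance")
                se = np.sqrt(diag)
                vcov = 0.5 * (vcov + vcov.T)
            except np.linalg.LinAlgError:
                logger.warning("singular Hessian; SEs not reported")
                se = vcov = None
        return FittedModel(
            spec=self.spec,
            estimates=res.x,
            names=self.design.all_names,
            se=se, vcov=vcov,
            loglik=-float(res.fun),
            n_params=self.n_params,
            convergence=converged,
            standardization=self.design.standardization,
            slices=self.design.slices,
            array_levels=self.design.array_levels,
        )


def neg_loglik(params: np.ndarray, spec: ModelSpec, data: SECRData) -> float:
    """Functional wrapper around :class:`SECRLikelihood`."""
    return SECRLikelihood(spec, data).neg_loglik(params)


def fit_ml(spec: ModelSpec, data: SECRData,
           options: Optional[dict] = None, compute_se: bool = True
           ) -> FittedModel:
    """Fit one model specification by numerical maximum likelihood."""
    return SECRLikelihood(spec, data).fit(options=options,
                                          compute_se=compute_se)


def predict_density(fit: FittedModel, space: StateSpace
                    ) -> tuple[np.ndarray, float]:
    """Per-pixel density surface (individuals/ha) and the region total Λ_r.

    Covariates are standardized with the record stored at fit time.  When
    the model stratifies by sex the surface is the sum of the two sex
    groups' intensities.
    """
    if not fit.convergence:
        raise ValueError("cannot predict from a non-converged fit")
    beta = fit.block("density")
    names = [n.split(".", 1)[1] for n in fit.names[fit.slices["density"]]]
    sexes = ["F", "M"] if fit.spec.uses_sex else [None]
    dens = np.zeros(space.n_pixels)
    for sex in sexes:
        cols = []
        for name in names:
            if name == "(Intercept)":
                cols.append(np.ones(space.n_pixels))
            elif name.startswith("array["):
                lvl = name[len("array["):-1]
                cols.append(np.full(space.n_pixels,
                                    1.0 if space.array == lvl else 0.0))
            elif name == "sex[M]":
                cols.append(np.full(space.n_pixels, 1.0 if sex == "M" else 0.0))
            else:
                key = f"density.{name}"
                if key not in fit.standardization:
                    raise ValueError(f"no standardization record for {name!r}")
                mu, sd = fit.standardization[key]
                if name == "prey_index":
                    if name not in space.region_covariates:
                        raise ValueError(
                            f"state space lacks region covariate {name!r}")
                    raw = np.full(space.n_pixels,
                                  space.region_covariates[name])
                else:
                    if name not in space.covariates.columns:
                        raise ValueError(
                            f"state space lacks covariate {name!r}")
                    raw = space.covariates[name].to_numpy(dtype=float)
                cols.append((raw - mu) / sd)
        X = np.column_stack(cols)
        offset = np.log(0.5) if sex is not None else 0.0
        dens = dens + np.exp(X @ beta + offset)
    lam_total = float(dens.sum() * space.pixel_area_ha)
    return dens, lam_total
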