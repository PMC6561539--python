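"""Shared fixtures: hand-built micro datasets and a published-scale fit stub."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from camsecr.types import (CaptureSession, FittedModel, ModelSpec, SECRData,
                           StateSpace, TrapLayout)

ARRAYS6 = ["Idete", "Lumemo", "Mbatwa", "Mwanihana", "Ndundulu", "Ruipa"]


def make_micro_data(array: str = "A",
                    pixels_xy=((0.0, 0.0),),
                    pixel_size: float = 1000.0,
                    traps_xy=((0.0, 0.0),),
                    usage=((1,),),
                    detections=(),
                    covariates: dict | None = None) -> SECRData:
    """Minimal single-array dataset for closed-form likelihood checks.

    ``detections`` is an iterable of (individual, trap_index, occasion).
    """
    traps_xy = np.asarray(traps_xy, float)
    usage = np.asarray(usage)
    J = traps_xy.shape[0]
    ids = [f"{array}-t{j + 1}" for j in range(J)]
    trap_cov = pd.DataFrame({
        "d2river": np.zeros(J), "d2boundary": np.zeros(J),
        "camera_type": np.zeros(J, dtype=int)})
    layout = TrapLayout(array=array, ids=ids, xy=traps_xy, usage=usage,
                        covariates=trap_cov)
    pixels_xy = np.asarray(pixels_xy, float)
    cov = pd.DataFrame(covariates if covariates
                       else {}, index=range(pixels_xy.shape[0]))
    space = StateSpace(array=array, xy=pixels_xy, pixel_size=pixel_size,
                       covariates=cov)
    det = pd.DataFrame(
        [(ind, ids[j], k) for ind, j, k in detections],
        columns=["individual", "detector", "occasion"])
    session = CaptureSession(array=array, detections=det)
    return SECRData(sessions=[session], traps={array: layout},
                    state_spaces={array: space})


@pytest.fixture
def table3_fit() -> FittedModel:
    """A fitted-model object populated with published-scale ML estimates:
    density ~ distance-to-boundary, p0 ~ distance-to-river, σ ~ array."""
    names = ["density.(Intercept)", "density.d2boundary",
             "p0.(Intercept)", "p0.d2river",
             "sigma.(Intercept)"] + [f"sigma.array[{a}]" for a in ARRAYS6[1:]]
    estimates = np.array([-7.770, 0.439, -3.392, -0.211,
                          7.517, 0.283, 0.033, -0.471, -0.348, 0.206])
    se = np.array([0.164, 0.203, 0.135, 0.106,
                   0.144, 0.180, 0.167, 0.198, 0.171, 0.177])
    return FittedModel(
        spec=ModelSpec(density=("d2boundary",), p0=("d2river",),
                       sigma=("array",), name="Md7"),
        estimates=estimates, names=names, se=se,
        vcov=np.diag(se ** 2), loglik=-1025.334, n_params=10,
        convergence=True,
        standardization={"density.d2boundary": (0.0, 1.0),
                         "p0.d2river": (0.0, 1.0)},
        slices={"density": slice(0, 2), "p0": slice(2, 4),
                "sigma": slice(4, 10)},
        array_levels=list(ARRAYS6))


def make_stub_fit(name: str, loglik: float, k: int,
                  extra_coef: tuple[str, float, float] | None = None
                  ) -> FittedModel:
    """Skeleton fit for ranking tests; optionally one named extra
    coefficient with its SE appended after k−1 shared ones."""
    base_names = [f"density.b{i}" for i in range(k)]
    est = np.zeros(k)
    se = np.ones(k)
    if extra_coef is not None:
        cname, cval, cse = extra_coef
        base_names[-1] = cname
        est[-1] = cval
        se[-1] = cse
    return FittedModel(
        spec=ModelSpec(name=name), estimates=est, names=base_names,
        se=se, vcov=np.diag(se ** 2), loglik=loglik, n_params=k,
        convergence=True, standardization={},
        slices={"density": slice(0, k), "p0": slice(k, k),
                "sigma": slice(k, k)},
        array_levels=["A"])
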