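"""Design-matrix construction for the stratified SECR likelihood.

Continuous covariates are standardized to mean 0 and unit variance using
means and SDs pooled across every region (each region contributes once, so
a single coefficient is interpretable landscape-wide); the (mean, sd) pair
is stored for prediction-time reuse.  Factors are dummy-coded against the
first level (sorted order).  When sex enters any predictor the likelihood
stratifies each region into known female/male groups; the density linear
predictor then carries a log(1/2) offset so the intercept keeps its
total-density meaning, and a male dummy column where 'sex' is in the
density formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .types import ModelSpec, SECRData, StateSpace, TrapLayout

LOG_HALF = float(np.log(0.5))


@dataclass
class Stratum:
    """One likelihood stratum: an array, optionally restricted to one sex."""

    array: str
    sex: Optional[str]            # None when the model ignores sex
    X_density: np.ndarray         # (G, p_d)
    X_p0: np.ndarray              # (J, p_p)
    X_sigma: np.ndarray           # (J, p_s)
    density_offset: float         # log share of the sex group (0 or log 1/2)


@dataclass
class DesignSet:
    """All strata plus coefficient names and the standardization record."""

    strata: list[Stratum]
    names: dict[str, list[str]]               # per part: coefficient names
    standardization: dict[str, tuple[float, float]]
    array_levels: list[str]

    @property
    def slices(self) -> dict[str, slice]:
        sizes = [len(self.names[p]) for p in ("density", "p0", "sigma")]
        edges = np.cumsum([0] + sizes)
        return {p: slice(int(edges[i]), int(edges[i + 1]))
                for i, p in enumerate(("density", "p0", "sigma"))}

    @property
    def n_params(self) -> int:
        return sum(len(v) for v in self.names.values())

    @property
    def all_names(self) -> list[str]:
        return ([f"density.{n}" for n in self.names["density"]]
                + [f"p0.{n}" for n in self.names["p0"]]
                + [f"sigma.{n}" for n in self.names["sigma"]])


def _standardize(col: np.ndarray, name: str,
                 record: dict[str, tuple[float, float]],
                 key: str) -> np.ndarray:
    if key in record:
        mu, sd = record[key]
    else:
        mu, sd = float(np.mean(col)), float(np.std(col))
        if sd < 1e-12:
            raise ValueError(f"covariate {name!r} has zero variance")
        record[key] = (mu, sd)
    return (col - mu) / sd


def _raw_column(term: str, part: str, array: str,
                traps: TrapLayout, space: StateSpace) -> np.ndarray:
    """Fetch the unstandardized values of a continuous term for one region."""
    if part == "density":
        if term == "prey_index":
            if term not in space.region_covariates:
                raise ValueError(f"region covariate {term!r} missing on "
                                 f"state space {array!r}")
            return np.full(space.n_pixels, space.region_covariates[term])
        if term not in space.covariates.columns:
            raise ValueError(f"state space {array!r} lacks covariate {term!r}")
        return space.covariates[term].to_numpy(dtype=float)
    # encounter parts use trap-level rows
    if term == "prey_index":
        if term not in space.region_covariates:
            raise ValueError(f"region covariate {term!r} missing on "
                             f"state space {array!r}")
        return np.full(traps.n_traps, space.region_covariates[term])
    if term not in traps.covariates.columns:
        raise ValueError(f"trap layout {array!r} lacks covariate {term!r}")
    return traps.covariates[term].to_numpy(dtype=float)


def build_design(spec: ModelSpec, data: SECRData,
                 standardization: Optional[dict] = None) -> DesignSet:
    """Assemble per-stratum design matrices for a model specification.

    Passing an existing ``standardization`` record (from a previous fit)
    reuses its means/SDs instead of recomputing them — required when
    predicting onto new state spaces.
    """
    arrays = data.arrays
    record: dict[str, tuple[float, float]] = dict(standardization or {})
    sexes: list[Optional[str]] = ["F", "M"] if spec.uses_sex else [None]

    camera_levels = sorted({
        v for a in arrays
        for v in data.traps[a].covariates.get(
            "camera_type", pd.Series(dtype=object)).unique()
    }) if any("camera_type" in getattr(s, part)
              for s in [spec] for part in ("density", "p0", "sigma")) else []

    # pooled standardization: each region contributes its rows once
    pooled: dict[str, list[np.ndarray]] = {}
    for part in ("density", "p0", "sigma"):
        for term in getattr(spec, part):
            if term in ("array", "sex", "camera_type"):
                continue
            key = f"{part}.{term}"
            if key in record:
                continue
            cols = [_raw_column(term, part, a, data.traps[a],
                                data.state_spaces[a]) for a in arrays]
            pooled[key] = cols
    for key, cols in pooled.items():
        col = np.concatenate(cols)
        mu, sd = float(np.mean(col)), float(np.std(col))
        if sd < 1e-12:
            raise ValueError(
                f"covariate {key.split('.', 1)[1]!r} has zero variance")
        record[key] = (mu, sd)

    def part_columns(part: str, array: str, sex: Optional[str],
                     traps: TrapLayout, space: StateSpace
                     ) -> tuple[np.ndarray, list[str]]:
        n_rows = space.n_pixels if part == "density" else traps.n_traps
        cols = [np.ones(n_rows)]
        names = ["(Intercept)"]
        for term in getattr(spec, part):
            if term == "array":
                for lvl in arrays[1:]:
                    cols.append(np.full(n_rows, 1.0 if array == lvl else 0.0))
                    names.append(f"array[{lvl}]")
            elif term == "sex":
                cols.append(np.full(n_rows, 1.0 if sex == "M" else 0.0))
                names.append("sex[M]")
            elif term == "camera_type":
                vals = traps.covariates["camera_type"].to_numpy()
                for lvl in camera_levels[1:]:
                    cols.append((vals == lvl).astype(float))
                    names.append(f"camera_type[{lvl}]")
            else:
                raw = _raw_column(term, part, array, traps, space)
                key = f"{part}.{term}"
                mu, sd = record[key]
                cols.append((raw - mu) / sd)
                names.append(term)
        return np.column_stack(cols), names

    strata: list[Stratum] = []
    names: dict[str, list[str]] = {}
    for array in arrays:
        traps, space = data.traps[array], data.state_spaces[array]
        for sex in sexes:
            Xd, nd = part_columns("density", array, sex, traps, space)
            Xp, np_ = part_columns("p0", array, sex, traps, space)
            Xs, ns = part_columns("sigma", array, sex, traps, space)
            names = {"density": nd, "p0": np_, "sigma": ns}
            strata.append(Stratum(
                array=array, sex=sex,
                X_density=Xd, X_p0=Xp, X_sigma=Xs,
                density_offset=LOG_HALF if sex is not None else 0.0,
            ))
    return DesignSet(strata=strata, names=names,
                     standardization=record, array_levels=arrays)
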