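"""Core data containers shared across the simulation, fitting and reporting layers.

Coordinates are planar metres throughout (projected, Euclidean distance; no
geodesy).  Density is parameterised on the log(individuals per hectare)
scale internally; the reporting layer converts to individuals / 100 km².
Occasions are daily and 0-based internally (1-based in files).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

SEX_LEVELS = ("F", "M", "U")

#: pixel-level continuous covariates usable in the density predictor
PIXEL_COVARIATES = ("elevation", "d2river", "d2boundary")
#: trap-level continuous covariates usable in the encounter predictors
TRAP_COVARIATES = ("d2river", "d2boundary")


@dataclass
class TrapLayout:
    """One array of camera-trap stations with per-occasion usage.

    A station is a pair of facing cameras modelled as a single proximity
    detector: at most one binary detection per individual per day.
    """

    array: str
    ids: list[str]
    xy: np.ndarray            # (J, 2) metres
    usage: np.ndarray         # (J, K) binary effort matrix
    covariates: pd.DataFrame  # per-station: d2river, d2boundary, camera_type

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.usage = np.asarray(self.usage)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("trap coordinates must be a (J, 2) array")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("trap coordinates must be finite")
        if self.usage.shape[0] != self.xy.shape[0]:
            raise ValueError("usage matrix rows must match number of stations")
        if not np.isin(self.usage, (0, 1)).all():
            raise ValueError("usage entries must be 0 or 1")

    @property
    def n_traps(self) -> int:
        return self.xy.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.usage.shape[1]

    @property
    def effort(self) -> np.ndarray:
        """Per-station number of active trap-days, Σ_k usage(j, k)."""
        return self.usage.sum(axis=1).astype(float)


@dataclass
class StateSpace:
    """Discrete habitat mask for one array: pixel centres plus covariates.

    ``region_covariates`` carries array-level scalars (e.g. the prey
    encounter index) that enter predictors as region-constant columns.
    """

    array: str
    xy: np.ndarray            # (G, 2) pixel centres, metres
    pixel_size: float         # metres; pixel area is pixel_size² (constant)
    covariates: pd.DataFrame  # per-pixel: elevation, d2river, d2boundary
    region_covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.covariates.isna().any().any():
            raise ValueError("state-space covariates must have no missing values")
        if len(self.covariates) != self.xy.shape[0]:
            raise ValueError("covariate rows must match number of pixels")

    @property
    def n_pixels(self) -> int:
        return self.xy.shape[0]

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size ** 2 / 1.0e4

    @property
    def total_area_ha(self) -> float:
        return self.n_pixels * self.pixel_area_ha


@dataclass
class CaptureSession:
    """Detections of identified individuals in one array (session).

    ``detections`` has columns (individual, detector, occasion) with one row
    per detection event; occasions are 0-based.  Individuals never recur
    across sessions (arrays are modelled as independent strata).
    """

    array: str
    detections: pd.DataFrame
    sex: dict[str, str] = field(default_factory=dict)  # individual -> F/M/U

    REQUIRED = ("individual", "detector", "occasion")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.detections.columns]
        if missing:
            raise ValueError(f"detections missing columns: {missing}")
        self.detections = self.detections.reset_index(drop=True)

    @property
    def individuals(self) -> list[str]:
        return sorted(self.detections["individual"].unique())

    @property
    def n_individuals(self) -> int:
        return self.detections["individual"].nunique()

    def sex_of(self, individual: str) -> str:
        return self.sex.get(individual, "U")

    def validate_against(self, traps: TrapLayout) -> None:
        """Check every detection maps to a live detector-occasion."""
        idx = {d: i for i, d in enumerate(traps.ids)}
        for row in self.detections.itertuples():
            j = idx.get(row.detector)
            if j is None:
                raise ValueError(
                    f"detection of {row.individual} at unknown detector "
                    f"{row.detector!r} in array {self.array}"
                )
            if not 0 <= row.occasion < traps.n_occasions:
                raise ValueError(
                    f"occasion {row.occasion} out of range for array {self.array}"
                )
            if traps.usage[j, row.occasion] == 0:
                raise ValueError(
                    f"detection of {row.individual} at {row.detector} on occasion "
                    f"{row.occasion} but usage is 0 (array {self.array})"
                )

    def count_matrix(self, traps: TrapLayout,
                     individuals: Optional[Sequence[str]] = None) -> np.ndarray:
        """Per-individual detection-day counts, shape (n, J).

        Duplicate (individual, detector, occasion) rows collapse to a single
        binary detection first (proximity-detector rule).
        """
        if individuals is None:
            individuals = self.individuals
        iidx = {v: i for i, v in enumerate(individuals)}
        jidx = {d: j for j, d in enumerate(traps.ids)}
        dedup = self.detections.drop_duplicates(
            subset=["individual", "detector", "occasion"])
        out = np.zeros((len(individuals), traps.n_traps))
        for row in dedup.itertuples():
            if row.individual in iidx:
                out[iidx[row.individual], jidx[row.detector]] += 1.0
        return out


@dataclass
class SECRData:
    """A full multi-array dataset: sessions, trap layouts and habitat masks."""

    sessions: list[CaptureSession]
    traps: dict[str, TrapLayout]
    state_spaces: dict[str, StateSpace]

    def __post_init__(self) -> None:
        for s in self.sessions:
            if s.array not in self.traps:
                raise ValueError(f"no trap layout for session array {s.array!r}")
            if s.array not in self.state_spaces:
                raise ValueError(f"no state space for session array {s.array!r}")
            s.validate_against(self.traps[s.array])

    @property
    def arrays(self) -> list[str]:
        return sorted(self.traps)

    @property
    def n_individuals(self) -> int:
        return sum(s.n_individuals for s in self.sessions)

    def session_for(self, array: str) -> Optional[CaptureSession]:
        for s in self.sessions:
            if s.array == array:
                return s
        return None


@dataclass(frozen=True)
class ModelSpec:
    """Declarative covariate structure for (density, p0, sigma).

    Each entry is a tuple of covariate names; the intercept is always
    present and never listed.  Factors ('array', 'camera_type', 'sex')
    expand to levels−1 dummy columns against the first level.
    """

    density: tuple[str, ...] = ()
    p0: tuple[str, ...] = ()
    sigma: tuple[str, ...] = ()
    name: str = ""

    _ALLOWED = {
        "density": {"elevation", "d2river", "d2boundary", "prey_index",
                    "array", "sex"},
        "p0": {"d2river", "d2boundary", "camera_type", "array", "sex"},
        "sigma": {"d2river", "d2boundary", "prey_index", "array", "sex"},
    }

    def __post_init__(self) -> None:
        for part in ("density", "p0", "sigma"):
            terms = getattr(self, part)
            object.__setattr__(self, part, tuple(terms))
            bad = set(terms) - self._ALLOWED[part]
            if bad:
                raise ValueError(f"covariates {sorted(bad)} not allowed on {part}")

    @property
    def uses_sex(self) -> bool:
        return "sex" in self.density + self.p0 + self.sigma

    def describe(self) -> str:
        def fmt(terms: tuple[str, ...]) -> str:
            return "+".join(terms) if terms else "1"
        return (f"D~{fmt(self.density)} p0~{fmt(self.p0)} "
                f"sigma~{fmt(self.sigma)}")


@dataclass
class FittedModel:
    """Maximum-likelihood fit: link-scale estimates, SEs and covariance."""

    spec: ModelSpec
    estimates: np.ndarray
    names: list[str]
    se: Optional[np.ndarray]
    vcov: Optional[np.ndarray]
    loglik: float
    n_params: int
    convergence: bool
    standardization: dict[str, tuple[float, float]]
    slices: dict[str, slice]          # coefficient blocks: density/p0/sigma
    array_levels: list[str] = field(default_factory=list)

    def coef(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def se_of(self, name: str) -> Optional[float]:
        if self.se is None:
            return None
        return float(self.se[self.names.index(name)])

    def block(self, part: str) -> np.ndarray:
        return self.estimates[self.slices[part]]

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame({"estimate": self.estimates}, index=self.names)
        df["se"] = np.nan if self.se is None else self.se
        return df


@dataclass
class PreyDetectionTable:
    """Species × station daily-detection counts with effort and array labels.

    ``y[i, j]`` is the number of days species i was detected at station j;
    ``k[j]`` the number of sampling days at station j.
    """

    y: np.ndarray                      # (S, J) counts
    k: np.ndarray                      # (J,) occasions per station
    array: np.ndarray                  # (J,) array label per station
    species: list[str]
    stations: list[str]
    d2boundary: Optional[np.ndarray] = None   # (J,) metres, optional

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.k = np.asarray(self.k)
        self.array = np.asarray(self.array)
        if self.y.shape != (len(self.species), len(self.stations)):
            raise ValueError("y must be species × stations")
        if (self.k < 1).any():
            raise ValueError("every station needs at least one occasion")
        if (self.y > self.k[None, :]).any() or (self.y < 0).any():
            raise ValueError("counts must satisfy 0 <= y_ij <= k_j")

    @property
    def n_species(self) -> int:
        return self.y.shape[0]

    @property
    def n_stations(self) -> int:
        return self.y.shape[1]

    @property
    def array_levels(self) -> list[str]:
        return sorted(set(self.array.tolist()))
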