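"""Post-fit derived quantities in reporting units.

Density is fitted on log(individuals/hectare); reporting converts to
individuals per 100 km² (×10⁴).  The 95% home range of the bivariate-
normal space-use model is π(σ√5.99)² with σ in km: squared trap–centre
distances are chi-square with 2 df, whose 0.95 quantile is 5.99.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .selection import wald_ci
from .types import FittedModel, StateSpace

PER_HA_TO_PER_100KM2 = 1.0e4
CHI2_95_2DF = 5.99


def mean_density(fit: FittedModel, level: float = 0.85
                 ) -> tuple[float, Optional[tuple[float, float]]]:
    """Mean density (individuals / 100 km²) with a Wald CI on the log scale.

    The point estimate is exp(β₀)·10⁴ — density at the mean of the
    standardized covariates.  Returns (point, (lo, hi)) or (point, None)
    when no SE is available.
    """
    name = "density.(Intercept)"
    b0 = fit.coef(name)
    point = math.exp(b0) * PER_HA_TO_PER_100KM2
    se = fit.se_of(name)
    if se is None:
        return point, None
    lo, hi = wald_ci(b0, se, level)
    return point, (math.exp(lo) * PER_HA_TO_PER_100KM2,
                   math.exp(hi) * PER_HA_TO_PER_100KM2)


def array_sigma(fit: FittedModel) -> dict[str, float]:
    """Per-array spatial scale σ in metres from an array-factor σ model."""
    if "array" not in fit.spec.sigma:
        raise ValueError("sigma formula has no array factor")
    d0 = fit.coef("sigma.(Intercept)")
    out = {}
    for a in fit.array_levels:
        key = f"sigma.array[{a}]"
        delta = fit.coef(key) if key in fit.names else 0.0
        out[a] = math.exp(d0 + delta)
    return out


def home_range_area(sigma_km: float) -> float:
    """95% home-range area (km²) of the bivariate-normal use model."""
    if sigma_km < 0:
        raise ValueError("sigma must be non-negative")
    return math.pi * (sigma_km * math.sqrt(CHI2_95_2DF)) ** 2


@dataclass
class DerivedReport:
    """Reporting-unit summary of a fitted density model."""

    mean_density: float                       # individuals / 100 km²
    mean_density_ci: Optional[tuple[float, float]]
    sigma_m: dict[str, float]                 # per-array σ, metres
    home_range_km2: dict[str, float]          # per-array 95% home range
    mean_home_range_km2: float
    density_surface: Optional[str] = None     # path reference, if exported
    ci_level: float = 0.85

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.home_range_km2.values()):
            raise ValueError("home-range areas must be non-negative")
        if self.mean_density_ci is not None:
            lo, hi = self.mean_density_ci
            if not lo <= self.mean_density <= hi:
                raise ValueError("CI must bracket the point estimate")

    def to_json(self) -> str:
        d = {
            "mean_density": self.mean_density,
            "mean_density_ci": list(self.mean_density_ci)
            if self.mean_density_ci else None,
            "sigma_m": self.sigma_m,
            "home_range_km2": self.home_range_km2,
            "mean_home_range_km2": self.mean_home_range_km2,
            "density_surface": self.density_surface,
            "ci_level": self.ci_level,
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DerivedReport":
        d = json.loads(text)
        ci = d["mean_density_ci"]
        return cls(mean_density=d["mean_density"],
                   mean_density_ci=tuple(ci) if ci else None,
                   sigma_m=d["sigma_m"],
                   home_range_km2=d["home_range_km2"],
                   mean_home_range_km2=d["mean_home_range_km2"],
                   density_surface=d.get("density_surface"),
                   ci_level=d.get("ci_level", 0.85))

    def render(self) -> str:
        lines = [
            "Derived quantities",
            "------------------",
            f"Mean density: {self.mean_density:.2f} / 100 km^2"
            + (f"  ({int(self.ci_level * 100)}% CI "
               f"{self.mean_density_ci[0]:.2f}-{self.mean_density_ci[1]:.2f})"
               if self.mean_density_ci else ""),
            "",
            f"{'Array':<12}{'sigma (m)':>12}{'95% HR (km^2)':>16}",
        ]
        for a in sorted(self.sigma_m):
            lines.append(f"{a:<12}{self.sigma_m[a]:>12.1f}"
                         f"{self.home_range_km2[a]:>16.1f}")
        lines.append(f"{'mean':<12}{'':>12}"
                     f"{self.mean_home_range_km2:>16.1f}")
        return "\n".join(lines)


def build_report(fit: FittedModel,
                 state_spaces: Optional[dict[str, StateSpace]] = None,
                 density_surface: Optional[str] = None,
                 level: float = 0.85) -> DerivedReport:
    """Assemble mean density, per-array σ and 95% home ranges.

    The mean home range averages the per-array areas (not the area of a
    mean σ).
    """
    if not fit.convergence:
        raise ValueError("cannot derive quantities from a non-converged fit")
    dens, ci = mean_density(fit, level)
    if "array" in fit.spec.sigma:
        sig = array_sigma(fit)
    else:
        s0 = math.exp(fit.coef("sigma.(Intercept)"))
        sig = {a: s0 for a in fit.array_levels}
    hr = {a: home_range_area(s / 1000.0) for a, s in sig.items()}
    return DerivedReport(
        mean_density=dens, mean_density_ci=ci, sigma_m=sig,
        home_range_km2=hr,
        mean_home_range_km2=float(np.mean(list(hr.values()))),
        density_surface=density_surface, ci_level=level)
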