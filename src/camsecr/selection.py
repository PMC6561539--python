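"""AIC model selection and Wald intervals.

AIC = −2·logL + 2k; models are ranked by ΔAIC from the minimum and given
Akaike weights exp(−ΔAIC/2) normalized over the supplied set.  Wald
intervals are estimate ± z·SE on the link scale; the 85% level
(z ≈ 1.4395) is the interval compatible with AIC-based selection when
screening for uninformative parameters: a near-best model whose single
extra coefficient's 85% CI covers zero, with essentially unchanged
log-likelihood, adds nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .types import FittedModel

logger = logging.getLogger(__name__)


def aic(loglik: float, k: int) -> float:
    """Akaike Information Criterion, −2·loglik + 2k."""
    if k < 1:
        raise ValueError("k must be at least 1")
    return -2.0 * loglik + 2.0 * k


def wald_ci(estimate: float, se: float, level: float = 0.85
            ) -> tuple[float, float]:
    """Two-sided normal-theory interval on the scale of the estimate."""
    if se < 0:
        raise ValueError("se must be non-negative")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    z = norm.ppf(0.5 + level / 2.0)
    return estimate - z * se, estimate + z * se


@dataclass
class ModelComparison:
    """AIC ranking table plus references back to the fits."""

    table: pd.DataFrame                  # sorted by AIC ascending
    fits: dict[str, FittedModel]

    def best(self) -> FittedModel:
        return self.fits[self.table.iloc[0]["model"]]


def rank_models(fits: Sequence[FittedModel]) -> ModelComparison:
    """Rank converged fits by AIC with ΔAIC and Akaike weights."""
    usable = []
    for i, f in enumerate(fits):
        if not f.convergence:
            logger.warning("excluding non-converged model %s from ranking",
                           f.spec.name or f.spec.describe())
            continue
        usable.append(f)
    if not usable:
        raise ValueError("no converged models to rank")
    names = [f.spec.name or f"m{i + 1}" for i, f in enumerate(usable)]
    rows = pd.DataFrame({
        "model": names,
        "spec": [f.spec.describe() for f in usable],
        "k": [f.n_params for f in usable],
        "loglik": [f.loglik for f in usable],
        "AIC": [aic(f.loglik, f.n_params) for f in usable],
    })
    # tie-break on the model id so ranking is input-order invariant
    rows = rows.sort_values(["AIC", "model"],
                            kind="mergesort").reset_index(drop=True)
    rows["dAIC"] = rows["AIC"] - rows["AIC"].iloc[0]
    w = np.exp(-rows["dAIC"] / 2.0)
    rows["weight"] = w / w.sum()
    return ModelComparison(table=rows,
                           fits=dict(zip(names, usable)))


def flag_uninformative(comparison: ModelComparison,
                       level: float = 0.85) -> pd.DataFrame:
    """Screen near-best models for a single uninformative extra parameter.

    A model within 2 ΔAIC of the best is flagged when it has exactly one
    more parameter than the best, its extra coefficient's 85% Wald CI
    covers zero, and |Δloglik| < 1.
    """
    tab = comparison.table
    best_name = tab.iloc[0]["model"]
    best = comparison.fits[best_name]
    out = []
    for _, row in tab.iterrows():
        flagged = False
        extra = None
        if (row["model"] != best_name and row["dAIC"] <= 2.0
                and row["k"] == best.n_params + 1
                and abs(row["loglik"] - best.loglik) < 1.0):
            cand = comparison.fits[row["model"]]
            extra_names = [n for n in cand.names if n not in best.names]
            if len(extra_names) == 1 and cand.se is not None:
                extra = extra_names[0]
                lo, hi = wald_ci(cand.coef(extra), cand.se_of(extra), level)
                flagged = lo <= 0.0 <= hi
        out.append({"model": row["model"], "flagged": flagged,
                    "extra_parameter": extra})
    return pd.DataFrame(out)
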