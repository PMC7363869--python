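"""Predictor-tier assembly and stepwise collinearity removal by VIF.

The two model tiers see different candidate predictors: the global tier only
climate layers (climate limits distributions at the global scale), the
regional tier climate plus habitat descriptors.  Within each tier, variables
whose variance inflation factor exceeds a threshold (default 4) are removed
one at a time, worst first, until all survivors are below it — the usual
stepwise-VIF procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grids import RasterStack

__all__ = ["PredictorSelection", "vif", "vif_step", "build_tier_stack"]

GLOBAL_CLIMATIC = "global_climatic"
REGIONAL_FULL = "regional_full"

#: Marker for R^2 numerically equal to 1 (exact collinearity).
VIF_INF = np.inf


@dataclass
class PredictorSelection:
    """Outcome of a stepwise-VIF pass for one tier."""

    tier: str
    retained: list[str]
    dropped: list[tuple[str, float]] = field(default_factory=list)
    threshold: float = 4.0

    def report(self) -> pd.DataFrame:
        rows = [
            {"tier": self.tier, "variable": n, "status": "retained", "vif_at_removal": np.nan}
            for n in self.retained
        ] + [
            {"tier": self.tier, "variable": n, "status": "dropped", "vif_at_removal": v}
            for n, v in self.dropped
        ]
        return pd.DataFrame(rows)


def vif(values: pd.DataFrame, target_name: str) -> float:
    """Variance inflation factor 1/(1-R^2) of one variable against the rest.

    R^2 comes from an ordinary least-squares regression (with intercept) of
    the target column on all other columns.  Exact collinearity
    (R^2 >= 1 - 1e-12) returns ``inf``.
    """
    if values.shape[1] < 2:
        raise ValueError("need at least 2 variables to compute a VIF")
    if values.shape[0] < values.shape[1] + 2:
        raise ValueError(
            f"need at least n_vars+2={values.shape[1] + 2} rows, got {values.shape[0]}"
        )
    y = values[target_name].to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError(f"variable {target_name!r} is constant")
    X = values.drop(columns=[target_name]).to_numpy(float)
    r2 = sm.OLS(y, sm.add_constant(X)).fit().rsquared
    if r2 >= 1 - 1e-12:
        return VIF_INF
    return 1.0 / (1.0 - r2)


def vif_step(
    values: pd.DataFrame, threshold: float = 4.0, tier: str = REGIONAL_FULL
) -> PredictorSelection:
    """Stepwise VIF removal: drop the worst variable until all pass.

    While any variable's VIF exceeds the threshold, the variable with the
    largest VIF is removed (ties broken by earliest column order) and all
    VIFs are recomputed.  A single survivor trivially passes.
    """
    if values.shape[1] == 0:
        raise ValueError("empty predictor table")
    current = list(values.columns)
    dropped: list[tuple[str, float]] = []
    while len(current) >= 2:
        vifs = np.array([vif(values[current], name) for name in current])
        worst = int(np.argmax(vifs))  # argmax takes the first of ties
        if vifs[worst] <= threshold:
            break
        dropped.append((current[worst], float(vifs[worst])))
        current.pop(worst)
    return PredictorSelection(tier=tier, retained=current, dropped=dropped, threshold=threshold)


def _tier_candidates(stack: RasterStack, tier: str) -> list[str]:
    if tier == GLOBAL_CLIMATIC:
        names = [n for n in stack.names if n.startswith("climate")]
        if not names:
            raise ValueError("no climate-tagged layers for the global tier")
        return names
    if tier == REGIONAL_FULL:
        return list(stack.names)
    raise ValueError(f"unknown tier {tier!r}")


def build_tier_stack(
    stack: RasterStack, tier: str, threshold: float = 4.0
) -> tuple[RasterStack, PredictorSelection]:
    """Select a tier's candidate layers and apply stepwise VIF over valid cells."""
    candidates = _tier_candidates(stack, tier)
    sub = stack.select(candidates)
    valid = sub.valid_mask()
    rows, cols = np.nonzero(valid)
    table = pd.DataFrame(sub.table(rows, cols), columns=candidates)
    selection = vif_step(table, threshold=threshold, tier=tier)
    return stack.select(selection.retained), selection
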