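"""Monte-Carlo operating-space mapping.

A design space is the set of factor settings whose predicted responses
meet specification deterministically.  The operating space is the robust
subset: at each candidate setpoint, factor settings are perturbed
(Normal around the setpoint, truncated to the factor ranges), response
residual noise is optionally added, and the setpoint is retained only if
the simulated probability of violating any specification stays below a
cutoff (1% by default, from 10,000 draws).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .rsm import FactorDef, RsmResults, SpecLimits, _grid_points

__all__ = ["PerturbationModel", "failure_probability", "operating_space_map"]


@dataclass
class PerturbationModel:
    """Setpoint perturbation for robustness analysis.

    ``sd`` maps factor name to the setpoint standard deviation in natural
    units (unlisted factors default to 5% of the factor half-range).
    ``residual_noise`` adds Normal response noise with SD equal to each
    fit's residual SD.  ``draws`` is the Monte-Carlo sample size per
    setpoint.
    """

    sd: Mapping[str, float] = field(default_factory=dict)
    residual_noise: bool = True
    draws: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.draws < 1:
            raise ValueError("draws must be >= 1")
        for name, s in self.sd.items():
            if s < 0:
                raise ValueError(f"negative SD for factor {name!r}")

    def sd_for(self, factor: FactorDef) -> float:
        return float(self.sd.get(factor.name, 0.05 * factor.half_width))


def _simulate_failures(
    fits: Mapping[str, RsmResults],
    specs: Sequence[SpecLimits],
    setpoints: np.ndarray,
    factors: Sequence[FactorDef],
    perturbation: PerturbationModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Failure counts for each setpoint row; vectorised over draws."""
    n_set = len(setpoints)
    draws = perturbation.draws
    sds = np.array([perturbation.sd_for(f) for f in factors])
    lows = np.array([f.low for f in factors])
    highs = np.array([f.high for f in factors])

    failures = np.zeros(n_set, dtype=int)
    for i, sp in enumerate(setpoints):
        settings = rng.normal(sp, sds, size=(draws, len(factors)))
        np.clip(settings, lows, highs, out=settings)
        fail = np.zeros(draws, dtype=bool)
        for spec in specs:
            fit = fits[spec.response]
            pred = np.atleast_1d(fit.predict(settings))
            if perturbation.residual_noise:
                pred = pred + rng.normal(0.0, fit.resid_sd, size=draws)
            fail |= ~spec.satisfied(pred)
        failures[i] = int(fail.sum())
    return failures


def failure_probability(
    fits: Mapping[str, RsmResults],
    specs: Sequence[SpecLimits],
    setpoint: Sequence[float],
    factors: Sequence[FactorDef],
    perturbation: PerturbationModel,
) -> tuple[float, float]:
    """Probability that a perturbed setpoint violates any spec.

    Returns ``(p_hat, se)`` where ``se`` is the binomial standard error
    sqrt(p(1-p)/draws).  Reproducible through the perturbation seed.
    """
    rng = np.random.default_rng(perturbation.seed)
    sp = np.atleast_2d(np.asarray(setpoint, dtype=float))
    k = _simulate_failures(fits, specs, sp, factors, perturbation, rng)[0]
    p = k / perturbation.draws
    se = float(np.sqrt(p * (1.0 - p) / perturbation.draws))
    return float(p), se


def operating_space_map(
    fits: Mapping[str, RsmResults],
    specs: Sequence[SpecLimits],
    grid: Mapping[str, np.ndarray],
    factors: Sequence[FactorDef],
    perturbation: PerturbationModel,
    fixed: Mapping[str, float] | None = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-cell failure probability and the boolean operating region.

    A cell belongs to the operating region when its Monte-Carlo failure
    probability is strictly below ``alpha``.  With zero perturbation SDs
    and residual noise off the map degenerates to the deterministic
    design space.
    """
    pts, _ = _grid_points(grid, factors, fixed)
    rng = np.random.default_rng(perturbation.seed)
    failures = _simulate_failures(fits, specs, pts, factors, perturbation, rng)
    p = failures / perturbation.draws
    df = pd.DataFrame(pts, columns=[f.name for f in factors])
    df["failure_probability"] = p
    df["se"] = np.sqrt(p * (1.0 - p) / perturbation.draws)
    df["operating"] = p < alpha
    df.attrs["alpha"] = alpha
    df.attrs["draws"] = perturbation.draws
    return df
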