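"""Proton-motive-force effect statistics on transport lags.

The PMF effect quantifies how much the proton-motive force speeds up
transport of a (variable) protein region:

    PMF effect (%) = 100 * (lag(-PMF) / lag(+PMF) - 1)

where 0% means no difference and 100% a halving of the lag when PMF is
present.  Lags entering the statistic are variable-region transport times,
i.e. construct lags with the shared baseline (short-topology construct)
subtracted.  Error bounds come from worst-case combinations of the lags'
standard errors of the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .errors import DataError

__all__ = [
    "LagMeasurement",
    "PmfEffect",
    "TransportRateFit",
    "variable_region_lag",
    "pmf_effect",
    "transport_rate_from_positions",
]


@dataclass(frozen=True)
class LagMeasurement:
    """A fitted lag (minutes) with its SEM and replicate count."""

    lag: float
    sem: float = 0.0
    n_replicates: int = 1
    condition: str = ""

    def __post_init__(self):
        if self.sem < 0:
            raise DataError("sem must be >= 0")


@dataclass(frozen=True)
class PmfEffect:
    """PMF effect in percent with SEM-derived lower/upper bounds."""

    effect_pct: float
    lower_pct: float
    upper_pct: float


@dataclass(frozen=True)
class TransportRateFit:
    """Line fit of lag against tag position; slope is min per domain."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float

    @property
    def rate(self) -> float:
        """Transport rate in domains per minute (1 / slope)."""
        return 1.0 / self.slope

    @property
    def rate_se(self) -> float:
        return self.slope_se / self.slope**2


def variable_region_lag(lag_xlx: LagMeasurement, lag_lxx: LagMeasurement) -> LagMeasurement:
    """Transport time of the variable region: construct lag minus baseline.

    SEMs combine in quadrature (independent replicates).  A negative
    difference is physically suspect and is flagged with a warning, not
    clamped.
    """
    diff = lag_xlx.lag - lag_lxx.lag
    if diff < 0:
        warnings.warn(
            f"variable-region lag is negative ({diff:.3g} min): "
            "baseline exceeds construct lag", stacklevel=2,
        )
    sem = float(np.hypot(lag_xlx.sem, lag_lxx.sem))
    return LagMeasurement(lag=diff, sem=sem,
                          n_replicates=min(lag_xlx.n_replicates, lag_lxx.n_replicates),
                          condition=lag_xlx.condition)


def pmf_effect(lag_minus: LagMeasurement, lag_plus: LagMeasurement) -> PmfEffect:
    """PMF effect (%) = 100 (lag_-PMF / lag_+PMF - 1) with SEM bounds.

    Bounds are the worst-case SEM combinations:
    upper from (lag_- + sem_-)/(lag_+ - sem_+), lower symmetrically.
    """
    if lag_minus.lag <= 0 or lag_plus.lag <= 0:
        raise DataError("lags must be > 0 (baseline-subtracted transport times)")
    if lag_plus.lag - lag_plus.sem <= 0:
        raise DataError("lag_plus - sem_plus <= 0: bounds undefined")
    effect = 100.0 * (lag_minus.lag / lag_plus.lag - 1.0)
    upper = 100.0 * ((lag_minus.lag + lag_minus.sem) / (lag_plus.lag - lag_plus.sem) - 1.0)
    lower = 100.0 * ((lag_minus.lag - lag_minus.sem) / (lag_plus.lag + lag_plus.sem) - 1.0)
    return PmfEffect(effect_pct=float(effect), lower_pct=float(lower), upper_pct=float(upper))


def transport_rate_from_positions(
    lags: Sequence[Tuple[float, LagMeasurement]],
    weighted: bool = False,
) -> TransportRateFit:
    """Least-squares line of lag against active tag position.

    The slope is the time per domain (min), its reciprocal the transport
    rate (domains per minute).  With ``weighted=True`` points are weighted
    by 1/sem^2 (measurements with sem 0 are not allowed in that mode).
    """
    pos = np.asarray([p for p, _ in lags], dtype=float)
    lag = np.asarray([m.lag for _, m in lags], dtype=float)
    if len(np.unique(pos)) < 2:
        raise DataError("need at least 2 distinct positions")
    if weighted:
        sems = np.asarray([m.sem for _, m in lags], dtype=float)
        if np.any(sems <= 0):
            raise DataError("weighted fit requires every sem > 0")
        w = 1.0 / sems**2
    else:
        w = np.ones_like(pos)
    # closed-form weighted least squares with standard errors
    W = np.diag(w)
    X = np.column_stack([np.ones_like(pos), pos])
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ lag)
    resid = lag - X @ beta
    dof = len(pos) - 2
    if dof > 0:
        s2 = float(resid @ (w * resid)) / dof
        cov = s2 * np.linalg.inv(xtwx)
        se = np.sqrt(np.diag(cov))
    else:
        se = np.array([np.nan, np.nan])
    return TransportRateFit(slope=float(beta[1]), slope_se=float(se[1]),
                            intercept=float(beta[0]), intercept_se=float(se[0]))
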