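"""Model evaluation statistics and the one-at-a-time sensitivity index.

Evaluation follows the standard soil-model trio: RMSE (absolute and as % of
the observed mean), BIAS (mean of simulated minus observed, so negative
means underestimation) and Nash-Sutcliffe model efficiency EF (1 is a
perfect fit; below 0 the model is worse than the observed mean).  The
sensitivity index for a swept input is ``(max(P_i) - min(P_i)) / max(P_i)``
over the final SOC outputs of the sweep, reported as a percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EvaluationReport",
    "SensitivityResult",
    "evaluate",
    "sensitivity_index",
    "sweep",
]

SWEEP_DOMAINS = {
    "ndf": (30.0, 70.0),
    "lignin": (9.0, 28.0),
    "moisture_factor": (0.2, 1.0),
}


@dataclass(frozen=True)
class EvaluationReport:
    rmse_abs: float  # Mg C ha-1
    rmse_pct: float  # % of observed mean
    bias: float  # Mg C ha-1, simulated - observed
    ef: float  # dimensionless <= 1 (nan if < 2 observations)
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": ["rmse_abs", "rmse_pct", "bias", "ef", "n"],
                "value": [self.rmse_abs, self.rmse_pct, self.bias, self.ef, self.n],
            }
        )

    def __str__(self) -> str:
        return (
            f"n={self.n}  RMSE={self.rmse_abs:.2f} Mg C/ha ({self.rmse_pct:.1f} % of mean)  "
            f"BIAS={self.bias:+.2f} Mg C/ha  EF={self.ef:.3f}"
        )


def _to_year_series(data) -> pd.Series:
    """Accept a Series indexed by year or a (year, soc) two-column frame."""
    if isinstance(data, pd.Series):
        return data.astype(float)
    frame = pd.DataFrame(data)
    cols = [c for c in frame.columns if str(c).lower().startswith("year")]
    vals = [c for c in frame.columns if c not in cols]
    if len(cols) != 1 or not vals:
        raise ValueError("expected a Series indexed by year or a (year, value) table")
    return frame.set_index(cols[0])[vals[0]].astype(float)


def evaluate(observed, simulated) -> EvaluationReport:
    """Compare simulated against observed annual SOC stocks on matched years."""
    obs = _to_year_series(observed)
    sim = _to_year_series(simulated)
    joined = pd.concat({"obs": obs, "sim": sim}, axis=1, join="inner").dropna()
    n = len(joined)
    if n < 1:
        raise ValueError("no overlapping years between observations and simulation")

    err = joined["sim"].to_numpy() - joined["obs"].to_numpy()
    obs_vals = joined["obs"].to_numpy()
    bias = float(err.mean())
    rmse_abs = float(np.sqrt(np.mean(err**2)))
    rmse_pct = 100.0 * rmse_abs / float(obs_vals.mean())
    if n >= 2 and np.ptp(obs_vals) > 0:
        ss_tot = float(((obs_vals - obs_vals.mean()) ** 2).sum())
        ef = 1.0 - float((err**2).sum()) / ss_tot
    else:
        ef = math.nan
    return EvaluationReport(rmse_abs=rmse_abs, rmse_pct=rmse_pct, bias=bias, ef=ef, n=n)


@dataclass(frozen=True)
class SensitivityResult:
    """Final SOC stocks over the swept grid and the resulting index."""

    parameter: str
    grid: tuple[float, ...]
    outputs: tuple[float, ...]  # final SOC, Mg C ha-1, one per grid point
    index: float  # dimensionless, in [0, 1)

    @property
    def index_pct(self) -> float:
        return 100.0 * self.index


def sensitivity_index(outputs) -> float:
    """``(max - min) / max`` over a set of model outputs; scale-invariant."""
    arr = np.asarray(list(outputs), dtype=float)
    if arr.size == 0:
        raise ValueError("sensitivity index needs at least one output")
    if (arr <= 0).any():
        raise ValueError("sensitivity index is defined for positive outputs only")
    return float((arr.max() - arr.min()) / arr.max())


def sweep(
    config,
    weather: pd.DataFrame,
    parameter: str,
    interval: tuple[float, float],
    n_points: int = 5,
) -> SensitivityResult:
    """One-at-a-time sweep of a modification input over its plausible interval.

    ``parameter`` is one of ``ndf`` (above-ground fibre share, %), ``lignin``
    (EOM lignin, % VS) or ``moisture_factor`` (the moisture rate modifier
    pinned to a constant).  The full simulation is run at each grid point
    with everything else held fixed; final SOC stocks feed
    :func:`sensitivity_index`.
    """
    from .simulate import run_scenario  # deferred: avoids a circular import

    if parameter not in SWEEP_DOMAINS:
        raise ValueError(
            f"unknown sweep parameter {parameter!r}; choose from {sorted(SWEEP_DOMAINS)}"
        )
    lo, hi = float(interval[0]), float(interval[1])
    dlo, dhi = SWEEP_DOMAINS[parameter]
    if not (dlo <= lo <= hi <= dhi):
        raise ValueError(
            f"interval [{lo}, {hi}] outside the admissible domain "
            f"[{dlo}, {dhi}] for {parameter!r}"
        )
    if n_points < 1:
        raise ValueError("n_points must be >= 1")

    grid = np.linspace(lo, hi, n_points) if n_points > 1 else np.array([lo])
    outputs = []
    for value in grid:
        cfg = config.with_swept_value(parameter, float(value))
        result = run_scenario(cfg, weather)
        outputs.append(result.final_soc)
    return SensitivityResult(
        parameter=parameter,
        grid=tuple(float(v) for v in grid),
        outputs=tuple(outputs),
        index=sensitivity_index(outputs),
    )
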