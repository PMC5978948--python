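"""Forward projection of domestic membership after stocking cessation.

Once stocking stops, only time advances: the years-since-mean-stocking
variable grows while every stocking-quantity and environmental covariate is
held at its observed value. The fitted beta-regression then gives the mean
domestic membership trajectory

    mu(t) = inv-logit( x_std(t) . beta ),

where x_std(t) re-standardizes the shifted time value with the scaler
frozen at fitting time. By default trajectories are anchored so that t = 0
reproduces the lake's *observed* mean domestic membership (an intercept
offset on the logit scale); the pure model-prediction start is available
with ``anchored=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .betareg import BetaRegFit, apply_scaler

TIME_VARIABLE = "SinceMeanYear"


@dataclass
class Trajectory:
    lake_id: str
    times: np.ndarray
    q_pred: np.ndarray
    anchored: bool
    threshold: float | None = None
    years_to_threshold: float | None = None
    # retained so continuous threshold-crossings can be solved on mu(t)
    _mu_of_t: object = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lake": self.lake_id, "time_years": self.times, "q_pred": self.q_pred}
        )


def _eta_at(fit: BetaRegFit, lake: pd.DataFrame, t: float) -> float:
    shifted = lake.copy()
    shifted[TIME_VARIABLE] = shifted[TIME_VARIABLE].astype(float) + t
    terms = [name for name in fit.term_names if name != "(Intercept)"]
    design = apply_scaler(shifted, terms, fit.scaler)
    return float((design.X @ fit.beta)[0])


def project_cessation(
    fit: BetaRegFit,
    lake: pd.Series | pd.DataFrame,
    horizon: float = 100.0,
    step: float = 10.0,
    anchored: bool = True,
    observed_column: str = "qDomestic",
) -> Trajectory:
    """Project one lake's mean domestic membership over `horizon` years.

    ``lake`` is a single covariate record on the raw scale (the nine
    predictors, plus the observed mean domestic membership when anchoring).
    Interaction columns are recomputed at every time point, so models whose
    interactions involve the time variable are handled correctly.
    """
    if TIME_VARIABLE not in fit.scaler:
        raise ValueError(f"fitted model does not include {TIME_VARIABLE}")
    row = lake.to_frame().T if isinstance(lake, pd.Series) else lake.copy()
    if len(row) != 1:
        raise ValueError("project_cessation expects a single lake record")
    needed = {v for name in fit.term_names if name != "(Intercept)" for v in name.split(":")}
    missing = sorted(needed - set(row.columns))
    if missing:
        raise ValueError(f"lake record lacks covariates: {missing}")

    lake_id = str(row["lake"].iloc[0]) if "lake" in row.columns else "lake"
    eta0 = _eta_at(fit, row, 0.0)
    if anchored:
        if observed_column not in row.columns:
            raise ValueError(f"anchored projection needs the {observed_column!r} column")
        q_obs = float(row[observed_column].iloc[0])
        offset = logit(q_obs) - eta0
    else:
        offset = 0.0

    def mu_of_t(t: float) -> float:
        return float(expit(offset + _eta_at(fit, row, t)))

    times = np.arange(0.0, horizon + 0.5 * step, step)
    q_pred = np.array([mu_of_t(t) for t in times])
    return Trajectory(
        lake_id=lake_id, times=times, q_pred=q_pred, anchored=anchored, _mu_of_t=mu_of_t
    )


def years_to_threshold(
    traj: Trajectory, threshold: float = 0.10, continuous: bool = False
) -> float | None:
    """First time the trajectory reaches the threshold, or None.

    On the reporting grid by default (the smallest grid time with
    q_pred <= threshold); with ``continuous=True`` the exact crossing time
    is solved by root-finding on mu(t) between the bracketing grid points.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be inside (0, 1)")
    below = np.flatnonzero(traj.q_pred <= threshold)
    if below.size == 0:
        return None
    i = int(below[0])
    if not continuous or i == 0:
        return float(traj.times[i])
    f = lambda t: traj._mu_of_t(t) - threshold
    lo, hi = float(traj.times[i - 1]), float(traj.times[i])
    if f(lo) <= 0:  # already at threshold on the earlier grid point
        return lo
    return float(optimize.brentq(f, lo, hi, xtol=1e-8))


def project_all(
    fit: BetaRegFit,
    lakes: pd.DataFrame,
    horizon: float = 100.0,
    step: float = 10.0,
    threshold: float = 0.10,
    anchored: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trajectories and years-to-threshold for every lake in a table.

    Returns a long-format trajectory frame (lake, time_years, q_pred) and a
    per-lake summary with the grid years-to-threshold.
    """
    long_rows, summary = [], []
    for _, lake in lakes.iterrows():
        traj = project_cessation(fit, lake, horizon=horizon, step=step, anchored=anchored)
        years = years_to_threshold(traj, threshold)
        long_rows.append(traj.to_frame())
        summary.append({"lake": traj.lake_id, "years_to_threshold": years})
    return pd.concat(long_rows, ignore_index=True), pd.DataFrame(summary)
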