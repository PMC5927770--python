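"""Readily-releasable-pool estimation by cumulative-EPSC back-extrapolation.

During a 60 Hz train the evoked amplitude collapses to a steady state set by
vesicle replenishment; the cumulative amplitude then grows linearly.  A line
fit by ordinary least squares to the linear phase (stimuli 18-30, 1-based
inclusive, configurable) of cumulative amplitude versus time, extrapolated
back to the time of the first stimulus (t = 0), intercepts the axis at the
response attributable to the initially primed pool.  Dividing that intercept
by the mean miniature amplitude converts it to quanta — the RRP estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .containers import TrainResponse

DEFAULT_WINDOW = (18, 30)


@dataclass
class RRPEstimate:
    cell_id: str | None
    cumulative: np.ndarray
    fit_window: tuple          # 1-based inclusive stimulus indices
    slope: float               # amplitude units / s
    intercept_at_t0: float     # amplitude units
    r_squared: float
    mean_mepsc: float
    rrp_quanta: float
    negative_intercept: bool   # quality flag; value is NOT clamped


def cumulative_series(train: TrainResponse) -> np.ndarray:
    """Running sum of per-stimulus amplitudes (nondecreasing when all >= 0)."""
    if train.amplitudes.size == 0:
        raise ValueError("empty train")
    return np.cumsum(train.amplitudes)


class RRPBackExtrapolator(BaseEstimator):
    """Linear back-extrapolation of the cumulative train response.

    Parameters
    ----------
    window : (int, int)
        1-based inclusive stimulus indices of the linear phase; default
        (18, 30).  Trains of 30 or 60 stimuli are both accepted — only
        stimuli up to the window end are used.

    Attributes
    ----------
    slope_, intercept_, r_squared_ : float
        OLS fit of cumulative amplitude against t_k = (k - 1)/freq; the
        intercept is the line's value at t = 0, the first stimulus.
    cumulative_ : ndarray
    rrp_quanta_ : float
        Set by :meth:`estimate` once a mean mini amplitude is supplied.
    """

    def __init__(self, window: tuple = DEFAULT_WINDOW):
        self.window = window

    def fit(self, train: TrainResponse, y=None):
        lo, hi = self.window
        n = train.n_stimuli
        if n < hi:
            raise ValueError(f"train has {n} stimuli; window requires {hi}")
        if hi - lo + 1 < 3:
            raise ValueError("fit window needs at least 3 stimuli")
        cum = cumulative_series(train)
        t = train.stimulus_times
        sel = slice(lo - 1, hi)  # 1-based inclusive -> python slice
        res = sps.linregress(t[sel], cum[sel])
        self.cumulative_ = cum
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue ** 2)
        self.train_ = train
        return self

    def estimate(self, mean_mepsc: float) -> RRPEstimate:
        """Convert the extrapolated intercept to quanta."""
        if mean_mepsc <= 0:
            raise ValueError("mean_mepsc must be positive")
        intercept = self.intercept_
        return RRPEstimate(
            cell_id=self.train_.cell_id,
            cumulative=self.cumulative_,
            fit_window=tuple(self.window),
            slope=self.slope_,
            intercept_at_t0=intercept,
            r_squared=self.r_squared_,
            mean_mepsc=float(mean_mepsc),
            rrp_quanta=intercept / mean_mepsc,
            negative_intercept=bool(intercept < 0),
        )

    def fit_estimate(self, train: TrainResponse, mean_mepsc: float) -> RRPEstimate:
        return self.fit(train).estimate(mean_mepsc)


def backextrapolate(train: TrainResponse, window: tuple = DEFAULT_WINDOW):
    """Return (slope, intercept_at_t0, r_squared) of the linear-phase fit."""
    est = RRPBackExtrapolator(window=window).fit(train)
    return est.slope_, est.intercept_, est.r_squared_


def estimate_rrp(train: TrainResponse, mean_mepsc: float,
                 window: tuple = DEFAULT_WINDOW) -> RRPEstimate:
    """Full pipeline: cumulative series, linear fit, quantal conversion."""
    return RRPBackExtrapolator(window=window).fit_estimate(train, mean_mepsc)
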