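"""Variance-mean (multiple-probability fluctuation) analysis.

Across Ca2+ conditions the trial-to-trial variance of the evoked amplitude
traces a parabola in its mean: under simple binomial release with N
identical sites of quantal size Q,

    variance = Q * I - I**2 / N,

where I is the mean evoked amplitude.  The curve passes through the origin
(a theoretical Ca-free point is appended), rises with slope Q at low release
probability, and bends down as sites saturate; its curvature gives N and the
initial slope gives Q.  Per-condition release probability follows as
p = I / (N * Q).

The model is linear in (Q, 1/N), so the unweighted least-squares fit is
solved exactly: unconstrained normal equations when the optimum is interior,
non-negative least squares when a constraint binds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .containers import VarianceMeanPoint


class UnidentifiableNError(ValueError):
    """Raised on zero-curvature data where only Q is identifiable."""


@dataclass
class ParabolaFit:
    quantal_size_Q: float
    n_sites_N: float            # np.inf when unidentifiable
    rss: float
    n_points: int
    identifiable: bool
    release_probs: dict = field(default_factory=dict)   # ca -> p
    flags: list = field(default_factory=list)
    cell_id: str | None = None


def summarize_condition(amplitudes, ca_mM: float,
                        cell_id: str | None = None) -> VarianceMeanPoint:
    """Mean and unbiased (n-1) variance of the evoked amplitudes at one Ca."""
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size < 2:
        raise ValueError("need at least 2 sweeps per condition")
    return VarianceMeanPoint(ca_mM=float(ca_mM), mean_amp=float(amps.mean()),
                             variance=float(amps.var(ddof=1)),
                             n_sweeps=int(amps.size), cell_id=cell_id)


def with_origin(points) -> list:
    """Append the theoretical Ca-free point (mean 0, variance 0)."""
    points = list(points)
    if any(p.mean_amp == 0 for p in points):
        raise ValueError("a point at mean 0 already exists")
    points.append(VarianceMeanPoint(ca_mM=0.0, mean_amp=0.0, variance=0.0,
                                    n_sweeps=0, theoretical=True))
    return points


class VarianceMeanEstimator(BaseEstimator):
    """Fit variance = Q*I - I**2/N by unweighted least squares, Q > 0, N > 0.

    Parameters
    ----------
    weighted : bool
        If True, weight each point by 1/Var(sample variance) under
        normality, 2 * variance**2 / (n - 1); the default (False) is the
        plain unweighted fit.

    Attributes
    ----------
    Q_ : float
        Quantal size (initial slope), in amplitude units.
    N_ : float
        Functional release-site number; ``inf`` when the data have no
        curvature (then ``identifiable_`` is False).
    rss_ : float
        Residual sum of squares of the accepted fit.
    """

    def __init__(self, weighted: bool = False):
        self.weighted = weighted

    def fit(self, X, y=None):
        means, variances, weights = self._coerce(X, y)
        if np.unique(means).size < 3:
            raise ValueError("need >= 3 points with distinct means "
                             "(the origin counts)")
        sw = np.sqrt(weights)
        A = np.column_stack([means, -(means ** 2)]) * sw[:, None]
        b = variances * sw

        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
        if not (coef > 0).all():
            coef, _ = nnls(A, b)        # constrained global optimum
        Q, curv = float(coef[0]), float(coef[1])
        resid = b - A @ coef
        rss = float(resid @ resid)

        if Q <= 0:
            raise ValueError(
                "fit pinned at Q = 0 (variance does not rise with the mean); "
                f"means={means!r}, variances={variances!r}")
        # identifiability floor: if the implied release probability at the
        # largest mean is numerically zero, the data carry no curvature
        p_top = curv * means.max() / Q
        if curv <= 0 or p_top <= 1e-8:
            self.Q_, self.N_ = Q, np.inf
            self.identifiable_ = False
        else:
            self.Q_, self.N_ = Q, 1.0 / curv
            self.identifiable_ = True
        self.rss_ = rss
        self.means_ = means
        self.variances_ = variances
        return self

    def predict(self, means) -> np.ndarray:
        """Parabola value at the given mean amplitudes."""
        m = np.asarray(means, dtype=float)
        curv = 0.0 if np.isinf(self.N_) else 1.0 / self.N_
        return self.Q_ * m - curv * m ** 2

    @staticmethod
    def _coerce(X, y):
        if y is not None:
            means = np.asarray(X, dtype=float).ravel()
            variances = np.asarray(y, dtype=float).ravel()
            ns = np.full(means.size, 2)
        else:
            pts = list(X)
            means = np.array([p.mean_amp for p in pts])
            variances = np.array([p.variance for p in pts])
            ns = np.array([max(p.n_sweeps, 2) for p in pts])
        if np.any(variances < 0):
            raise ValueError("negative variance")
        weights = np.ones_like(means)
        return means, variances, weights

    def _weights(self, variances, ns):
        v = np.where(variances > 0, variances, np.nan)
        w = (ns - 1) / (2 * v ** 2)
        return np.where(np.isfinite(w), w, np.nanmax(w) if np.isfinite(
            np.nanmax(w)) else 1.0)


def fit_parabola(points, weighted: bool = False,
                 cell_id: str | None = None) -> ParabolaFit:
    """Fit the standard parabola to (mean, variance) points incl. the origin.

    Raises :class:`UnidentifiableNError` on zero-curvature (purely linear)
    data, where N is infinite and only Q can be reported.
    """
    points = list(points)
    est = VarianceMeanEstimator(weighted=weighted)
    if weighted:
        means, variances, _ = est._coerce(points, None)
        ns = np.array([max(p.n_sweeps, 2) for p in points])
        w = est._weights(variances, ns)
        sw = np.sqrt(w)
        # re-run the linear solve with weights applied
        A = np.column_stack([means, -(means ** 2)]) * sw[:, None]
        b = variances * sw
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
        if not (coef > 0).all():
            coef, _ = nnls(A, b)
        est.Q_ = float(coef[0])
        est.N_ = np.inf if coef[1] <= 0 else 1.0 / float(coef[1])
        est.identifiable_ = np.isfinite(est.N_)
        r = b - A @ coef
        est.rss_ = float(r @ r)
        est.means_, est.variances_ = means, variances
    else:
        est.fit(points)

    if not est.identifiable_:
        raise UnidentifiableNError(
            "variance is proportional to mean (no curvature): N is "
            f"unidentifiable (infinite); Q = {est.Q_:.6g}")

    fit = ParabolaFit(quantal_size_Q=est.Q_, n_sites_N=est.N_, rss=est.rss_,
                      n_points=len(points), identifiable=True,
                      cell_id=cell_id)
    fit.release_probs = release_probabilities(fit, points)
    _flag(fit, points)
    return fit


def release_probabilities(fit: ParabolaFit, points) -> dict:
    """p(ca) = mean / (N * Q) for each measured (non-theoretical) point."""
    out = {}
    for p in points:
        if p.theoretical:
            continue
        out[p.ca_mM] = p.mean_amp / (fit.n_sites_N * fit.quantal_size_Q)
    return out


def _flag(fit: ParabolaFit, points) -> None:
    ps = fit.release_probs
    if any(p > 1 for p in ps.values()):
        fit.flags.append("release probability > 1")
    cas = sorted(ps)
    if any(ps[a] > ps[b] for a, b in zip(cas, cas[1:])):
        fit.flags.append("release probability not monotone in Ca")
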