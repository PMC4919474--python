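"""Four-parameter logistic (Hill) dose-response fitting.

The model is the standard 4PL on log concentration,

    a(c) = top + (bottom - top) / (1 + (EC50 / c)^s),

where ``top`` is the low-concentration asymptote, ``bottom`` the
high-concentration asymptote, ``EC50`` the midpoint concentration and
``s > 0`` the Hill slope.  Fits are deterministic: the starting point is a
grid search over the tested concentrations (no random restarts) and the
optimizer works in (top, bottom, log10 EC50, log slope) space so the slope
constraint is structural.  The same machinery fits enzyme-inhibition
titrations, where the midpoint is reported as an IC50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .screen_model import TitrationSeries

__all__ = [
    "HillFit",
    "hill_response",
    "fit_hill",
    "mask_and_refit",
    "f_test_vs_flat",
    "InsufficientDataError",
]

# Hill slopes outside ~[0.1, 10] are not distinguishable from artifacts on a
# 1:5 dilution grid; the bounds also stop the 4PL degenerating into a step.
_LOG_SLOPE_LIM = math.log(10.0)
_ASYMPTOTE_LIM = 200.0  # percent-activity; generous vs. the -100..0 anchor scale
_N_PARAMS = 4


class InsufficientDataError(ValueError):
    """Fewer than 4 unmasked points: the 4PL is not identifiable."""


@dataclass(frozen=True)
class HillFit:
    """A fitted 4PL curve plus diagnostics.

    ``r2`` compares the fit to the mean-only model (can be -inf for flat
    data with zero total variance).  ``extrapolated`` flags an EC50 outside
    the tested concentration range; such potencies are reported as-is, not
    clipped.
    """

    bottom: float
    top: float
    log10_ec50: float
    slope: float
    r2: float
    rss: float
    converged: bool
    n_used: int
    conc_min: float = float("nan")
    conc_max: float = float("nan")

    @property
    def ec50(self) -> float:
        return 10.0 ** self.log10_ec50

    @property
    def ec50_nm(self) -> float:
        return self.ec50 * 1e9

    @property
    def extrapolated(self) -> bool:
        return bool(self.ec50 < self.conc_min or self.ec50 > self.conc_max)

    @property
    def span(self) -> float:
        return self.bottom - self.top


def hill_response(c, fit: HillFit):
    """Evaluate the fitted 4PL at concentration(s) ``c`` (molar, > 0)."""
    return _response(np.log10(np.asarray(c, dtype=float)), fit.top, fit.bottom,
                     fit.log10_ec50, fit.slope)


def _response(logc, top, bottom, log10_ec50, slope):
    # (ec50/c)^s == 10^(s * (log10 ec50 - log10 c)); clip the exponent so
    # extreme slopes cannot overflow.
    expo = np.clip(slope * (log10_ec50 - logc), -300.0, 300.0)
    return top + (bottom - top) / (1.0 + 10.0 ** expo)


def _start_values(logc, y):
    order = np.argsort(logc)
    y_sorted = y[order]
    top0 = float(np.mean(y_sorted[:2]))
    bottom0 = float(np.mean(y_sorted[-2:]))
    # deterministic grid search for the midpoint over the tested points
    best, best_rss = float(logc[0]), np.inf
    for g in logc:
        r = y - _response(logc, top0, bottom0, g, 1.0)
        rss = float(r @ r)
        if rss < best_rss:
            best, best_rss = float(g), rss
    return top0, bottom0, best


def fit_hill(series: TitrationSeries, bounds=None, start=None) -> HillFit:
    """Deterministic least-squares 4PL fit on the unmasked points.

    Parameters
    ----------
    series : TitrationSeries
        Percent-activity titration; masked points are excluded.
    bounds : optional
        ``(lo, hi)`` arrays over (top, bottom, log10_ec50, log_slope)
        overriding the defaults.
    start : optional
        Starting point in the same parameter order.

    Optimizer failure is recorded as ``converged=False``, never raised.
    """
    c, y = series.unmasked()
    if len(c) < _N_PARAMS:
        raise InsufficientDataError(
            f"need >= {_N_PARAMS} unmasked points, have {len(c)}"
        )
    logc = np.log10(c)
    if bounds is None:
        lo = np.array([-_ASYMPTOTE_LIM, -_ASYMPTOTE_LIM, logc.min() - 2.0, -_LOG_SLOPE_LIM])
        hi = np.array([_ASYMPTOTE_LIM, _ASYMPTOTE_LIM, logc.max() + 2.0, _LOG_SLOPE_LIM])
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    if start is None:
        top0, bottom0, g0 = _start_values(logc, y)
        start = np.array([top0, bottom0, g0, 0.0])
    p0 = np.clip(np.asarray(start, dtype=float), lo, hi)

    def residuals(p):
        return _response(logc, p[0], p[1], p[2], math.exp(p[3])) - y

    _LN10 = math.log(10.0)

    def jac(p):
        top, bottom, g, q = p
        s = math.exp(q)
        expo = np.clip(s * (g - logc), -300.0, 300.0)
        u = 1.0 / (1.0 + 10.0 ** expo)  # occupancy fraction
        du = -_LN10 * u * (1.0 - u)
        J = np.empty((len(logc), 4))
        J[:, 0] = 1.0 - u
        J[:, 1] = u
        J[:, 2] = (bottom - top) * du * s
        J[:, 3] = (bottom - top) * du * s * (g - logc)
        return J

    try:
        res = optimize.least_squares(
            residuals, p0, jac=jac, bounds=(lo, hi), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=500,
        )
        ok = bool(res.success)
        p = res.x
        rss = float(2.0 * res.cost)
    except Exception:
        ok, p, rss = False, p0, float(np.sum(residuals(p0) ** 2))

    tss = float(np.sum((y - y.mean()) ** 2))
    if tss > 0:
        r2 = 1.0 - rss / tss
    else:
        # flat data carries no variance to explain
        r2 = 1.0 if rss == 0 and abs(p[1] - p[0]) > 1e-9 else -math.inf
    # a fit that collapsed to zero span has not identified a dose response
    if abs(p[1] - p[0]) < 1e-9:
        ok = False
    return HillFit(
        bottom=float(p[1]),
        top=float(p[0]),
        log10_ec50=float(p[2]),
        slope=float(math.exp(p[3])),
        r2=r2,
        rss=rss,
        converged=ok,
        n_used=len(c),
        conc_min=float(c.min()),
        conc_max=float(c.max()),
    )


def mask_and_refit(
    series: TitrationSeries, fit: HillFit, z_max: float = 3.0
) -> tuple[TitrationSeries, HillFit]:
    """Mask at most one outlier point and refit.

    The candidate is the point with the largest absolute residual.  Because
    a least-squares 4PL will distort itself to chase a gross outlier
    (spreading the damage over every residual), the candidate is judged by
    its *deletion* residual: the series is refit without it, and the point
    is masked when it deviates from that fit by more than ``z_max`` times
    the deletion fit's residual scale.  Points deviating by less than 1
    percent-activity unit are never masked; a series already carrying a
    masked point is returned unchanged (single-mask cap).
    """
    if series.mask.any():
        return series, fit
    c, y = series.unmasked()
    r = y - hill_response(c, fit)
    n = len(r)
    if n - 1 < _N_PARAMS:
        return series, fit
    worst = int(np.argmax(np.abs(r)))
    if abs(r[worst]) < 1.0:
        return series, fit
    candidate_mask = series.mask.copy()
    candidate_mask[np.flatnonzero(~series.mask)[worst]] = True
    loo_series = series.with_mask(candidate_mask)
    loo_fit = fit_hill(loo_series)
    c_loo, y_loo = loo_series.unmasked()
    rss_loo = float(np.sum((y_loo - hill_response(c_loo, loo_fit)) ** 2))
    dof = len(y_loo) - _N_PARAMS
    sigma = math.sqrt(rss_loo / dof) if dof > 0 else 0.0
    deletion_resid = abs(y[worst] - float(hill_response(c[worst], loo_fit)))
    if deletion_resid < 1.0:
        return series, fit
    if sigma > 0.0 and deletion_resid / sigma <= z_max:
        return series, fit
    if sigma == 0.0 and deletion_resid <= 1.0:
        return series, fit
    return loo_series, loo_fit


def f_test_vs_flat(series: TitrationSeries, fit: HillFit) -> float:
    """Extra-sum-of-squares F test of the 4PL against a flat (mean-only) model.

    Small p-values indicate genuine concentration dependence.  When both
    models fit perfectly (constant data) p = 1 by convention.
    """
    c, y = series.unmasked()
    n = len(y)
    rss1 = float(np.sum((y - hill_response(c, fit)) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    df1 = n - _N_PARAMS
    df0 = n - 1
    if df1 <= 0:
        return 1.0
    if rss1 <= 0.0:
        return 1.0 if rss0 <= 0.0 else 0.0
    f = max(0.0, (rss0 - rss1) / (df0 - df1)) / (rss1 / df1)
    return float(stats.f.sf(f, df0 - df1, df1))
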