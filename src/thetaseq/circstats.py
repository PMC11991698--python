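"""Circular statistics for spike-phase analyses.

Conventions
-----------
Angles are degrees in ``[0, 360)`` at every public boundary; radians appear
only inside numeric kernels.  Wrapped angular differences live in
``(-180, 180]``.  All tests are invariant to a global rotation of the sample.

The module provides the resultant-length descriptive statistics, the
Rayleigh test of uniformity, the Watson-Williams multi-sample test (circular
one-way ANOVA), the Mardia-Watson-Wheeler uniform-scores test, the
circular-linear regression used for phase precession, and the corrected
empirical p-value ``(r + 1) / (n + 1)`` used with shuffle nulls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats


def wrap_deg(x):
    """Wrap angles or angle differences into ``(-180, 180]`` degrees."""
    w = np.asarray(x, dtype=float) % 360.0
    w = np.where(w > 180.0, w - 360.0, w)
    if np.ndim(x) == 0:
        return float(w)
    return w


def _to_rad(angles_deg):
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("empty circular sample")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite angles in circular sample")
    return np.deg2rad(a)


def circular_mean_deg(angles_deg, weights=None):
    """Circular mean direction in degrees ``[0, 360)``."""
    a = _to_rad(angles_deg)
    if weights is None:
        z = np.exp(1j * a).mean()
    else:
        w = np.asarray(weights, dtype=float)
        z = (w * np.exp(1j * a)).sum() / w.sum()
    return float(np.rad2deg(np.angle(z)) % 360.0)


def mean_vector_length(angles_deg, weights=None):
    """Resultant length R-bar of a circular sample, in ``[0, 1]``.

    0 corresponds to a balanced (e.g. uniform) sample, 1 to all angles
    identical.
    """
    a = _to_rad(angles_deg)
    if weights is None:
        z = np.exp(1j * a).mean()
    else:
        w = np.asarray(weights, dtype=float)
        z = (w * np.exp(1j * a)).sum() / w.sum()
    return float(np.abs(z))


@dataclass(frozen=True)
class TestResult:
    """Outcome of a circular hypothesis test."""

    statistic: float
    df: tuple
    pvalue: float
    n: int
    note: str = ""


def rayleigh_test(angles_deg) -> TestResult:
    """Rayleigh test of circular uniformity.

    Uses ``Z = n * Rbar**2`` with the standard finite-n corrected
    approximation for the p-value (Zar; the same form reference circular
    toolboxes use), not the bare ``exp(-Z)``.
    """
    a = _to_rad(angles_deg)
    n = a.size
    if n < 2:
        raise ValueError("Rayleigh test needs at least 2 angles")
    rbar = np.abs(np.exp(1j * a).mean())
    big_r = n * rbar
    z = big_r**2 / n
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - big_r**2)) - (1.0 + 2.0 * n))
    return TestResult(statistic=float(z), df=(), pvalue=float(min(p, 1.0)), n=n)


def _a1inv(rbar):
    # Inverse of A1(kappa) = I1(kappa)/I0(kappa); piecewise approximation.
    if rbar >= 1.0:
        return np.inf
    if rbar < 0.53:
        return 2.0 * rbar + rbar**3 + 5.0 * rbar**5 / 6.0
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1.0 - rbar)
    return 1.0 / (rbar**3 - 4.0 * rbar**2 + 3.0 * rbar)


def watson_williams(groups) -> TestResult:
    """Watson-Williams multi-sample test for equal mean directions.

    Parameters
    ----------
    groups : sequence of angle arrays (degrees)

    Notes
    -----
    Valid for concentrated samples.  When the pooled weighted resultant
    length falls below the usual concentration guideline (0.45) the result
    carries a warning note rather than raising, since field usage applies
    the test to head-direction samples without checking.
    """
    gs = [_to_rad(g) for g in groups]
    k = len(gs)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.size for g in gs])
    if np.any(ns < 2):
        raise ValueError("every group needs at least 2 angles")
    n_tot = int(ns.sum())
    big_rs = np.array([np.abs(np.exp(1j * g).sum()) for g in gs])
    pooled = np.concatenate(gs)
    big_r = np.abs(np.exp(1j * pooled).sum())
    rw = big_rs.sum() / n_tot
    kappa = _a1inv(rw)
    beta = 1.0 + 3.0 / (8.0 * kappa) if np.isfinite(kappa) and kappa > 0 else 1.0
    num = (big_rs.sum() - big_r) / (k - 1)
    den = (n_tot - big_rs.sum()) / (n_tot - k)
    if den <= 0:
        f = np.inf if num > 0 else 0.0
        p = 0.0 if num > 0 else 1.0
    else:
        f = beta * num / den
        p = float(stats.f.sf(f, k - 1, n_tot - k))
    note = "" if rw >= 0.45 else (
        "low concentration (weighted Rbar=%.3f < 0.45): F approximation unreliable" % rw
    )
    return TestResult(statistic=float(f), df=(k - 1, n_tot - k), pvalue=max(p, np.finfo(float).tiny),
                      n=n_tot, note=note)


def mardia_watson_wheeler(groups) -> TestResult:
    """Mardia-Watson-Wheeler (uniform scores) k-sample test.

    Angles from all groups are replaced by circular ranks (uniform scores);
    ties get average ranks.  The statistic ``W = 2 * sum_k (C_k^2 + S_k^2) /
    n_k`` is referred to a chi-square distribution with ``2(k-1)`` degrees
    of freedom.  Total n below 10 flags the asymptotic p as unreliable.
    """
    gs = [np.asarray(g, dtype=float) % 360.0 for g in groups]
    k = len(gs)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.size for g in gs])
    if np.any(ns < 1):
        raise ValueError("empty group")
    pooled = np.concatenate(gs)
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)  # average ranks on ties
    beta = 2.0 * np.pi * ranks / n_tot
    w = 0.0
    start = 0
    for n_g in ns:
        b = beta[start:start + n_g]
        w += (np.cos(b).sum() ** 2 + np.sin(b).sum() ** 2) / n_g
        start += n_g
    w *= 2.0
    df = 2 * (k - 1)
    p = float(stats.chi2.sf(w, df))
    note = "" if n_tot >= 10 else "total n < 10: chi-square approximation unreliable"
    return TestResult(statistic=float(w), df=(df,), pvalue=max(p, np.finfo(float).tiny),
                      n=n_tot, note=note)


@dataclass(frozen=True)
class CircLinFit:
    """Circular-linear regression fit (phase-precession style)."""

    slope: float          # degrees of phase per unit of x
    offset_deg: float     # phase at x = 0, degrees [0, 360)
    resultant: float      # resultant length at the fitted slope
    rho: float            # circular-linear correlation coefficient
    pvalue: float
    n: int


def circular_linear_regression(x, angles_deg, slope_bounds_deg=(-1080.0, 1080.0),
                               n_grid=4097) -> CircLinFit:
    """Fit ``phase ~ slope * x + offset`` by maximizing the resultant length.

    The slope maximizes ``R(a) = | mean exp(i * (phi - a x)) |`` over a
    bounded window (coarse grid then golden-section refinement), following
    the standard phase-precession estimator; significance comes from the
    circular-linear correlation between the measured phases and the fitted
    linear predictor.

    Parameters
    ----------
    x : array
        Linear covariate (e.g. distance through the place field).  Must
        have nonzero spread.
    angles_deg : array
        Phases in degrees.
    slope_bounds_deg : (low, high)
        Search window for the slope in degrees per unit of ``x``.
    """
    phi = _to_rad(angles_deg)
    xv = np.asarray(x, dtype=float)
    if xv.shape != phi.shape:
        raise ValueError("x and angles must have the same shape")
    n = xv.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(xv) <= 0:
        raise ValueError("x has zero spread")

    lo, hi = (np.deg2rad(b) for b in slope_bounds_deg)
    grid = np.linspace(lo, hi, n_grid)

    def neg_resultant(a):
        return -np.abs(np.exp(1j * (phi - a * xv)).mean())

    # vectorized coarse scan
    r_grid = np.abs(np.exp(1j * (phi[None, :] - grid[:, None] * xv[None, :])).mean(axis=1))
    i_best = int(np.argmax(r_grid))
    a_lo = grid[max(i_best - 1, 0)]
    a_hi = grid[min(i_best + 1, n_grid - 1)]
    from scipy.optimize import minimize_scalar
    res = minimize_scalar(neg_resultant, bounds=(a_lo, a_hi), method="bounded",
                          options={"xatol": 1e-10})
    a_hat = float(res.x)
    r_hat = -float(res.fun)
    offset = np.angle(np.exp(1j * (phi - a_hat * xv)).mean())

    # circular-circular correlation between phi and the fitted predictor
    theta = (a_hat * xv) % (2.0 * np.pi)
    phi_bar = np.angle(np.exp(1j * phi).mean())
    theta_bar = np.angle(np.exp(1j * theta).mean())
    sp = np.sin(phi - phi_bar)
    st = np.sin(theta - theta_bar)
    denom = np.sqrt((sp**2).sum() * (st**2).sum())
    if denom == 0:
        rho, p = 0.0, 1.0
    else:
        rho = float((sp * st).sum() / denom)
        lam = lambda i, j: np.mean(sp**i * st**j)  # noqa: E731
        l20, l02, l22 = lam(2, 0), lam(0, 2), lam(2, 2)
        if l22 <= 0:
            p = 1.0
        else:
            z = rho * np.sqrt(n * l20 * l02 / l22)
            p = float(special.erfc(np.abs(z) / np.sqrt(2.0)))
    return CircLinFit(slope=float(np.rad2deg(a_hat)),
                      offset_deg=float(np.rad2deg(offset) % 360.0),
                      resultant=r_hat, rho=rho, pvalue=p, n=n)


def empirical_p(observed, null_samples, side="left"):
    """Corrected one-sided empirical p-value ``(r + 1) / (n + 1)``.

    ``r`` counts null values at least as extreme as ``observed`` on the
    chosen side: ``null <= observed`` for ``side='left'`` (small values
    extreme) and ``null >= observed`` for ``side='right'``.  Always lies in
    ``[1/(n+1), 1]``.
    """
    null = np.asarray(null_samples, dtype=float)
    n = null.size
    if n < 1:
        raise ValueError("need at least one null sample")
    if side == "left":
        r = int(np.sum(null <= observed))
    elif side == "right":
        r = int(np.sum(null >= observed))
    else:
        raise ValueError("side must be 'left' or 'right'")
    return (r + 1) / (n + 1)
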