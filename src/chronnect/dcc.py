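"""Dynamic conditional correlation (DCC) estimation for parcel pairs.

The DCC model of Engle (2002) estimates a time-varying correlation
``r_t`` between two series in two stages: first a univariate GARCH(1,1)
fit per series yields conditional standard deviations, then the
standardized residuals drive a correlation recursion

    Q_t = (1 - a - b) * Qbar + a * eps_{t-1} eps_{t-1}' + b * Q_{t-1},
    r_t = Q_t[0,1] / sqrt(Q_t[0,0] * Q_t[1,1]),

with news parameter ``a`` and decay parameter ``b`` estimated by
Gaussian quasi-maximum likelihood.  Estimation is pairwise-bivariate:
for a parcel set of size p, all p(p-1)/2 pairs are fit independently,
which is tractable at hundreds of parcels and matches the common
neuroimaging usage of the model.

Both the GARCH and DCC recursions are linear IIR filters in their
driving terms, so likelihood evaluations run through
``scipy.signal.lfilter`` at C speed rather than a Python loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.signal import lfilter

__all__ = [
    "Garch11Fit",
    "DccPairFit",
    "DynamicCorrelationTensor",
    "GroupConnectivityMatrix",
    "fit_garch11",
    "fit_dcc_pair",
    "dcc_all_pairs",
    "epoch_and_group_average",
    "fisher_z",
    "inverse_fisher_z",
]

logger = logging.getLogger(__name__)

MIN_SAMPLES = 30
_STATIONARITY_CAP = 0.999
# coarse initialization grids for the (news, decay) surface; the best cell
# seeds a single bounded local polish -- cheaper and more robust than
# multistart on the often-flat quasi-likelihood
_GRID_NEWS = (0.0, 0.02, 0.05, 0.10, 0.20, 0.40)
_GRID_DECAY = (0.0, 0.30, 0.60, 0.80, 0.90, 0.97)


@dataclass(frozen=True)
class Garch11Fit:
    """Quasi-ML estimate of a GARCH(1,1) conditional-variance model.

    sigma2_t = omega + alpha * x_{t-1}^2 + beta * sigma2_{t-1}
    """

    omega: float
    alpha: float
    beta: float
    conditional_sd: np.ndarray
    loglik: float
    converged: bool = True

    def __post_init__(self):
        if self.alpha + self.beta >= 1.0:
            raise ValueError("GARCH stationarity violated: alpha + beta >= 1")
        if np.any(self.conditional_sd <= 0):
            raise ValueError("conditional_sd must be positive everywhere")


@dataclass(frozen=True)
class DccPairFit:
    """Second-stage DCC(1,1) fit for one pair of standardized series."""

    a: float
    b: float
    r_t: np.ndarray
    unconditional_r: float
    loglik: float
    converged: bool = True

    def __post_init__(self):
        if self.a + self.b >= 1.0:
            raise ValueError("DCC stationarity violated: a + b >= 1")
        if np.any(np.abs(self.r_t) > 1.0 + 1e-12):
            raise ValueError("dynamic correlations must lie in [-1, 1]")


@dataclass
class DynamicCorrelationTensor:
    """Per-pair dynamic correlations, indexed (parcel_i, parcel_j, sample).

    Symmetric in (i, j) with unit diagonal; assembled from pairwise fits.
    """

    values: np.ndarray
    labels: list[str]
    n_fallback_pairs: int = 0

    def __post_init__(self):
        p, q, _ = self.values.shape
        if p != q:
            raise ValueError("tensor must be square in its parcel axes")


@dataclass
class GroupConnectivityMatrix:
    """Group-averaged connectivity at one (condition, within-trial index).

    ``z_values`` holds Fisher-z transformed correlations averaged over
    subjects and trials; the diagonal is excluded (set to zero).
    """

    condition: str
    time_index: int
    z_values: np.ndarray
    labels: list[str]
    n_averaged: int

    def r_values(self) -> np.ndarray:
        """Back-transform to the correlation scale (unit diagonal restored)."""
        r = np.tanh(self.z_values)
        np.fill_diagonal(r, 1.0)
        return r


def _grid_polish(nll):
    """Minimize a 2-parameter objective: coarse grid, then one L-BFGS-B."""
    best_fun, best_xy = np.inf, None
    for a in _GRID_NEWS:
        for b in _GRID_DECAY:
            if a + b >= _STATIONARITY_CAP:
                continue
            f = nll(np.array([a, b]))
            if f < best_fun:
                best_fun, best_xy = f, (a, b)
    if best_xy is None:
        return None
    res = minimize(nll, np.array(best_xy), method="L-BFGS-B",
                   bounds=[(0.0, _STATIONARITY_CAP)] * 2,
                   options={"maxiter": 40, "maxfun": 90, "ftol": 1e-7})
    if not np.isfinite(res.fun) or res.fun > best_fun:
        res.x = np.array(best_xy)
        res.fun = best_fun
    return res


def _garch_sigma2(x: np.ndarray, omega: float, alpha: float, beta: float,
                  s2_init: float) -> np.ndarray:
    """Conditional variance path, computed as an IIR filter."""
    n = x.shape[0]
    h = np.empty(n)
    h[0] = s2_init
    if n > 1:
        u = omega + alpha * x[:-1] ** 2
        h[1:] = lfilter([1.0], [1.0, -beta], u, zi=np.array([beta * s2_init]))[0]
    return np.maximum(h, 1e-12)


def fit_garch11(x: np.ndarray) -> Garch11Fit:
    """Fit a GARCH(1,1) model by Gaussian quasi-maximum likelihood.

    The variance intercept is profile out by variance targeting:
    omega = var(x) * (1 - alpha - beta), which keeps the optimization
    two-dimensional and the unconditional variance anchored at the
    sample variance.  On optimizer failure the constant-variance model
    (alpha = beta = 0) is returned with ``converged=False``.

    Parameters
    ----------
    x : array
        A single zero-mean series of length >= 30 with finite values.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("fit_garch11 expects a single 1-D series")
    if x.shape[0] < MIN_SAMPLES:
        raise ValueError(
            f"series of length {x.shape[0]} is too short for GARCH "
            f"estimation; at least {MIN_SAMPLES} samples are required"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    s2 = float(np.var(x))
    if s2 <= 0:
        raise ValueError("zero variance")

    xsq = x**2

    def nll(theta: np.ndarray) -> float:
        alpha, beta = theta
        if alpha + beta >= _STATIONARITY_CAP:
            return 1e10 * (1.0 + alpha + beta)
        omega = s2 * (1.0 - alpha - beta)
        h = _garch_sigma2(x, omega, alpha, beta, s2)
        return 0.5 * float(np.sum(np.log(h) + xsq / h))

    best = _grid_polish(nll)
    if best is None or best.x[0] + best.x[1] >= _STATIONARITY_CAP:
        logger.warning("GARCH optimizer failed; falling back to constant variance")
        sd = np.full_like(x, np.sqrt(s2))
        return Garch11Fit(omega=s2, alpha=0.0, beta=0.0, conditional_sd=sd,
                          loglik=-nll(np.zeros(2)), converged=False)

    alpha, beta = map(float, best.x)
    omega = s2 * (1.0 - alpha - beta)
    h = _garch_sigma2(x, omega, alpha, beta, s2)
    return Garch11Fit(omega=omega, alpha=alpha, beta=beta,
                      conditional_sd=np.sqrt(h), loglik=-float(best.fun))


def _dcc_r_path(prods: np.ndarray, sbar: np.ndarray, a: float,
                b: float) -> np.ndarray:
    """Correlation path of the DCC recursion.

    ``prods`` is the (3, n) stack of lagged-ready outer products
    (e1*e1, e1*e2, e2*e2) and ``sbar`` the matching unconditional
    moments; the three recursions share one batched IIR filter call.
    """
    n = prods.shape[1]
    q = np.empty((3, n))
    q[:, 0] = sbar
    if n > 1:
        u = (1.0 - a - b) * sbar[:, None] + a * prods[:, :-1]
        q[:, 1:] = lfilter([1.0], [1.0, -b], u, axis=1,
                           zi=b * sbar[:, None])[0]
    denom = np.sqrt(np.maximum(q[0] * q[2], 1e-24))
    return q[1] / denom


def fit_dcc_pair(e1: np.ndarray, e2: np.ndarray) -> DccPairFit:
    """Fit the DCC(1,1) correlation stage for one standardized pair.

    ``Qbar`` is set to the sample second-moment matrix of the inputs
    (correlation targeting).  The returned ``r_t`` satisfies
    ``|r_t| <= 1`` by construction: each ``Q_t`` is a convex-like
    combination of positive semidefinite terms.  On optimizer failure
    the constant-correlation model (a = b = 0) is returned flagged.
    """
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if e1.shape != e2.shape or e1.ndim != 1:
        raise ValueError("paired series must be 1-D and of equal length")
    if e1.shape[0] < MIN_SAMPLES:
        raise ValueError(
            f"series of length {e1.shape[0]} too short; need >= {MIN_SAMPLES}"
        )
    if not (np.all(np.isfinite(e1)) and np.all(np.isfinite(e2))):
        raise ValueError("non-finite values in standardized series")

    E = np.vstack([e1, e2])
    S = E @ E.T / e1.shape[0]
    if S[0, 0] <= 0 or S[1, 1] <= 0:
        raise ValueError("zero variance")
    rbar = float(S[0, 1] / np.sqrt(S[0, 0] * S[1, 1]))
    e1sq, e2sq = e1**2, e2**2
    cross = e1 * e2
    sumsq = e1sq + e2sq
    prods = np.vstack([e1sq, cross, e2sq])
    sbar = np.array([S[0, 0], S[0, 1], S[1, 1]])

    def nll(theta: np.ndarray) -> float:
        a, b = theta
        if a + b >= _STATIONARITY_CAP:
            return 1e10 * (1.0 + a + b)
        r = np.clip(_dcc_r_path(prods, sbar, a, b), -0.9999, 0.9999)
        om2 = 1.0 - r**2
        quad = (sumsq - 2.0 * r * cross) / om2
        return 0.5 * float(np.sum(np.log(om2) + quad - sumsq))

    best = _grid_polish(nll)
    if best is None or best.x[0] + best.x[1] >= _STATIONARITY_CAP:
        logger.warning("DCC optimizer failed; falling back to constant correlation")
        r = np.full_like(e1, np.clip(rbar, -1.0, 1.0))
        return DccPairFit(a=0.0, b=0.0, r_t=r, unconditional_r=rbar,
                          loglik=-nll(np.zeros(2)), converged=False)

    a, b = map(float, best.x)
    r_t = np.clip(_dcc_r_path(prods, sbar, a, b), -1.0, 1.0)
    return DccPairFit(a=a, b=b, r_t=r_t, unconditional_r=rbar,
                      loglik=-float(best.fun))


def dcc_all_pairs(values: np.ndarray, labels: list[str]) -> DynamicCorrelationTensor:
    """Estimate dynamic correlations between all parcel pairs of one run.

    Parameters
    ----------
    values : array of shape (n_parcels, n_samples)
        Band-limited series for one subject/condition, concatenated
        across trials.  Rows are demeaned before GARCH fitting.
    labels : parcel identifiers, one per row.

    Returns
    -------
    DynamicCorrelationTensor with shape (p, p, n_samples); symmetric
    slices with unit diagonal.  Pair-level failures are re-raised with
    the offending pair named; optimizer fallbacks are counted.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a (parcels, samples) array")
    p, n = values.shape
    if len(labels) != p:
        raise ValueError("label count does not match parcel count")
    x = values - values.mean(axis=1, keepdims=True)

    n_fallback = 0
    eps = np.empty_like(x)
    for i in range(p):
        try:
            g = fit_garch11(x[i])
        except ValueError as exc:
            raise ValueError(f"GARCH fit failed for parcel {labels[i]!r}: {exc}") from exc
        if not g.converged:
            n_fallback += 1
        eps[i] = x[i] / g.conditional_sd

    out = np.empty((p, p, n))
    out[np.arange(p), np.arange(p), :] = 1.0
    for i in range(p):
        for j in range(i + 1, p):
            try:
                fit = fit_dcc_pair(eps[i], eps[j])
            except ValueError as exc:
                raise ValueError(
                    f"DCC fit failed for pair ({labels[i]!r}, {labels[j]!r}): {exc}"
                ) from exc
            if not fit.converged:
                n_fallback += 1
            out[i, j, :] = fit.r_t
            out[j, i, :] = fit.r_t
    return DynamicCorrelationTensor(values=out, labels=list(labels),
                                    n_fallback_pairs=n_fallback)


def fisher_z(r):
    """Fisher z-transform, z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError(
            "|r| >= 1 cannot be Fisher z-transformed; exclude the diagonal "
            "(self-correlations) before transforming"
        )
    return np.arctanh(r)


def inverse_fisher_z(z):
    """Inverse of :func:`fisher_z` (tanh)."""
    return np.tanh(np.asarray(z, dtype=float))


def epoch_and_group_average(
    tensors: dict[tuple[int, str], DynamicCorrelationTensor],
    samples_per_trial: int,
    average_on_z: bool = False,
) -> dict[tuple[str, int], GroupConnectivityMatrix]:
    """Epoch concatenated dynamic correlations and average across the group.

    For each condition and within-trial time index k (1-based), the
    correlation slices at the k-th sample of every trial of every
    subject are averaged on the r scale, and the mean is then Fisher
    z-transformed (z applied after averaging).  With the standard
    design of 3 conditions and 9 samples per trial this yields 27
    matrices.

    Parameters
    ----------
    tensors : mapping (subject, condition) -> DynamicCorrelationTensor
        Concatenated-run tensors; the sample count of each must be an
        identical multiple of ``samples_per_trial`` within a condition.
    average_on_z : bool
        If True, z-transform each instance first and average on the z
        scale instead (off by default; the standard order averages r
        and transforms the mean).
    """
    conditions: dict[str, list[DynamicCorrelationTensor]] = {}
    for (_, cond), tensor in sorted(tensors.items(), key=lambda kv: kv[0]):
        conditions.setdefault(cond, []).append(tensor)

    out: dict[tuple[str, int], GroupConnectivityMatrix] = {}
    for cond, tlist in conditions.items():
        n_samples = {t.values.shape[2] for t in tlist}
        if len(n_samples) != 1:
            raise ValueError(f"unequal run lengths within condition {cond!r}")
        n = n_samples.pop()
        if n % samples_per_trial:
            raise ValueError(
                f"run length {n} is not a whole number of trials of "
                f"{samples_per_trial} samples (condition {cond!r})"
            )
        n_trials = n // samples_per_trial
        labels = tlist[0].labels
        p = len(labels)
        # (subjects, p, p, trials, samples_per_trial)
        stacked = np.stack([t.values for t in tlist]).reshape(
            len(tlist), p, p, n_trials, samples_per_trial
        )
        for k in range(samples_per_trial):
            off = ~np.eye(p, dtype=bool)
            if average_on_z:
                inst = np.clip(stacked[:, :, :, :, k], -1 + 1e-12, 1 - 1e-12)
                z = np.arctanh(inst).mean(axis=(0, 3))
                z[~off] = 0.0
                r_mean = np.tanh(z)
            else:
                r_mean = stacked[:, :, :, :, k].mean(axis=(0, 3))
                z = np.zeros_like(r_mean)
                z[off] = fisher_z(r_mean[off])
            out[(cond, k + 1)] = GroupConnectivityMatrix(
                condition=cond, time_index=k + 1, z_values=z,
                labels=list(labels), n_averaged=len(tlist) * n_trials,
            )
    return out
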