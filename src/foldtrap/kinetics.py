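"""Refolding-kinetics analysis: biexponential decay fitting.

Experimental chaperone-assisted refolding assays report the percent of
protein refolded versus time.  After conversion to the probability of being
non-native, ``P_NN(t)``, the decay is modelled as two parallel folding
pathways with no interconversion::

    P_NN(t) = a0 * exp(-k1 * t) + a1 * exp(-k2 * t),    a0 + a1 = 1

where ``a0``/``k1`` describe the fast-folding population and ``a1``/``k2``
the slow (misfolded) population.  Very small ``k2`` values are not
identifiable from a finite time course: when ``k2 * t`` stays near zero the
slow term is indistinguishable from the constant plateau ``a1`` (zeroth
order Taylor limit), so only a lower bound on the slow time constant can be
claimed.  The rule of thumb applied here is that decay times up to ten
times the experimental duration are measurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import norm
from statsmodels.sandbox.stats.runs import runstest_1samp

__all__ = [
    "RefoldingTimeCourse",
    "BiexponentialFit",
    "normalize",
    "fit_biexponential",
    "k2_bounds",
    "runs_test_residuals",
    "measurability_limit",
    "time_constant_order",
]

#: box bounds for log10(rate / min^-1) used by the optimizer; wide enough to
#: represent the slowest literature rates (~1e-23 min^-1) without underflow.
LOG10_RATE_BOUNDS = (-30.0, 2.0)


@dataclass
class RefoldingTimeCourse:
    """Probability of the non-native state versus time.

    Parameters
    ----------
    t : ndarray
        Time in minutes, strictly increasing.
    p_nn : ndarray
        Probability of being non-native at each time, in [0, 1].
    sigma : ndarray or None
        Optional per-point uncertainty in probability units.
    label : str
        Free-text identifier (protein/chaperone system).
    out_of_range : ndarray of bool
        Flags raw points that fell outside [0, 100] percent before clipping
        (digitization artifacts).
    """

    t: np.ndarray
    p_nn: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""
    out_of_range: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p_nn = np.asarray(self.p_nn, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.p_nn.shape:
            raise ValueError("t and p_nn must be 1-D arrays of equal length")
        if len(self.t) < 3:
            raise ValueError("a time course needs at least 3 points")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any((self.p_nn < 0) | (self.p_nn > 1)):
            raise ValueError("p_nn must lie in [0, 1]")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.t.shape:
                raise ValueError("sigma must match t in length")

    @property
    def duration(self) -> float:
        """Length of the experimental time course in minutes."""
        return float(self.t[-1] - self.t[0])


@dataclass
class BiexponentialFit:
    """Result of fitting the two-pathway decay model.

    ``k2_flag`` is one of ``"measured"`` (slow rate within the measurable
    window), ``"lower-bound-only"`` (below the ten-fold measurability
    limit; interpret as order of magnitude at best) or ``"unidentifiable"``
    (slow amplitude ~0, the data are effectively single-exponential).
    """

    a0: float
    a1: float
    k1: float
    k2: float
    residuals: np.ndarray
    converged: bool
    sse: float
    k2_flag: str = "measured"
    k2_upper: float | None = None
    k2_lower: float | None = None

    @property
    def slow_time_constant(self) -> float:
        """1/k2 in minutes (inf when k2 == 0)."""
        return math.inf if self.k2 == 0 else 1.0 / self.k2


def normalize(percent_refolded, t, error=None, label: str = "") -> RefoldingTimeCourse:
    """Convert a percent-refolded series to a non-native probability course.

    ``%non-native = 100 - %refolded``; dividing by 100 yields ``p_nn``.
    Raw values outside [0, 100] (common in digitized figures) are clipped
    and flagged in ``out_of_range``.
    """
    pct = np.asarray(percent_refolded, dtype=float)
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(pct)):
        raise ValueError("percent_refolded contains non-finite values")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t must be strictly increasing")
    p_nn_raw = (100.0 - pct) / 100.0
    out_of_range = (pct < 0) | (pct > 100)
    p_nn = np.clip(p_nn_raw, 0.0, 1.0)
    sigma = None if error is None else np.asarray(error, dtype=float) / 100.0
    return RefoldingTimeCourse(t=t, p_nn=p_nn, sigma=sigma, label=label,
                               out_of_range=out_of_range)


def biexponential(t, a0: float, k1: float, k2: float) -> np.ndarray:
    """Forward model ``a0 exp(-k1 t) + (1 - a0) exp(-k2 t)``."""
    t = np.asarray(t, dtype=float)
    return a0 * np.exp(-k1 * t) + (1.0 - a0) * np.exp(-k2 * t)


def measurability_limit(duration: float) -> float:
    """Smallest slow rate measurable from a time course of given duration.

    Decay times up to ten times the experimental window are considered
    measurable, so ``k2_min = 1 / (10 * duration)``.  A 100-minute course
    resolves characteristic decay times of 1000 minutes (1e-3 min^-1).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    return 1.0 / (10.0 * duration)


def time_constant_order(k2: float) -> float:
    """Order-of-magnitude slow folding time constant, 10^round(log10(1/k2))."""
    if k2 <= 0:
        raise ValueError("k2 must be positive")
    exponent = math.floor(math.log10(1.0 / k2) + 0.5)  # round half away from zero
    return 10.0 ** exponent


def _single_fit(t, p_nn, weights, a0_init, lk1_init, lk2_init):
    """One bounded least-squares solve; rates parameterized as log10."""

    def resid(x):
        a0, lk1, lk2 = x
        model = biexponential(t, a0, 10.0 ** lk1, 10.0 ** lk2)
        return (model - p_nn) * weights

    lo, hi = LOG10_RATE_BOUNDS
    x0 = np.array([np.clip(a0_init, 0.0, 1.0),
                   np.clip(lk1_init, lo, hi),
                   np.clip(lk2_init, lo, hi)])
    try:
        sol = least_squares(resid, x0, bounds=([0.0, lo, lo], [1.0, hi, hi]),
                            xtol=1e-15, ftol=1e-15, gtol=1e-15, method="trf")
    except Exception:  # pragma: no cover - optimizer hard failure
        return None
    return sol


def fit_biexponential(tc: RefoldingTimeCourse,
                      weight_by_sigma: bool = False) -> BiexponentialFit:
    """Fit the biexponential decay with the sum-to-one constraint exact.

    ``a1`` is substituted as ``1 - a0`` so the constraint can never be
    violated.  Rates are fitted on a log10 scale with box bounds wide
    enough for extremely slow folders.  A small multi-start grid over the
    slow-rate decade protects against the optimizer collapsing into the
    fast-rate basin.  Fitted ``k2`` values below the measurability limit
    are flagged ``"lower-bound-only"``; a vanishing slow amplitude flags
    ``k2`` as ``"unidentifiable"``.
    """
    t, p_nn = tc.t, tc.p_nn
    if len(t) < 4:
        raise ValueError("need at least 4 points to fit four parameters")
    if np.ptp(p_nn) == 0:
        raise ValueError("p_nn is constant; nothing to fit")
    weights = np.ones_like(t)
    if weight_by_sigma and tc.sigma is not None and np.all(tc.sigma > 0):
        weights = 1.0 / tc.sigma

    duration = max(tc.duration, np.finfo(float).tiny)
    plateau = float(p_nn[-1])
    amp = max(float(p_nn[0]) - plateau, 1e-3)
    # k1 initial guess: time of the first e-fold drop toward the plateau
    target = plateau + amp / math.e
    below = np.nonzero(p_nn <= target)[0]
    t_e = float(t[below[0]]) if len(below) and t[below[0]] > 0 else duration / 3.0
    lk1_init = math.log10(1.0 / t_e)
    a0_init = min(max(amp, 0.01), 0.99)

    best = None
    for m in range(7):
        lk2_init = math.log10(1.0 / duration) - m
        sol = _single_fit(t, p_nn, weights, a0_init, lk1_init, lk2_init)
        if sol is None:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("biexponential fit failed from every start")

    a0, lk1, lk2 = best.x
    k1, k2 = 10.0 ** lk1, 10.0 ** lk2
    if k2 > k1:  # enforce k1 >= k2 by relabelling the two pathways
        k1, k2 = k2, k1
        a0 = 1.0 - a0
    if k2 > 0.99 * k1:
        # equal rates: the amplitude split is arbitrary, the data are a
        # single exponential; collapse onto the fast pathway
        a0, k2 = 1.0, k1
    a1 = 1.0 - a0
    residuals = biexponential(t, a0, k1, k2) - p_nn
    sse = float(np.sum(residuals ** 2))

    if a1 < 1e-3:
        flag = "unidentifiable"
    elif k2 < measurability_limit(duration):
        flag = "lower-bound-only"
    else:
        flag = "measured"
    return BiexponentialFit(a0=float(a0), a1=float(a1), k1=float(k1),
                            k2=float(k2), residuals=residuals,
                            converged=bool(best.success), sse=sse,
                            k2_flag=flag)


def k2_bounds(tc: RefoldingTimeCourse, fit: BiexponentialFit,
              sigma_default: float = 0.01) -> tuple[float | None, float | None]:
    """Bounds on the slow rate from refitting the uncertainty envelopes.

    The model is refitted to ``p_nn + sigma`` and ``p_nn - sigma`` (reported
    per-point errors, else a flat ``sigma_default`` of 1% in probability
    units); the extreme ``k2`` values of the two envelope fits are returned
    as ``(k2_upper, k2_lower)``.  A failed envelope fit yields ``None`` for
    that bound rather than a fabricated number.  Also stores the bounds on
    ``fit``.
    """
    if not fit.converged:
        raise ValueError("k2_bounds requires a converged fit")
    sigma = tc.sigma if tc.sigma is not None else np.full_like(tc.t, sigma_default)
    if np.all(sigma == 0):
        fit.k2_upper = fit.k2_lower = fit.k2
        return fit.k2, fit.k2

    k2s = []
    for sign in (+1.0, -1.0):
        env = np.clip(tc.p_nn + sign * sigma, 0.0, 1.0)
        try:
            env_tc = RefoldingTimeCourse(t=tc.t, p_nn=env, label=tc.label)
            env_fit = fit_biexponential(env_tc)
            k2s.append(env_fit.k2)
        except Exception:
            warnings.warn("envelope fit failed; bound unavailable")
            k2s.append(None)
    available = [k for k in k2s if k is not None]
    if not available:
        return None, None
    upper = max(available + [fit.k2])
    lower = min(available + [fit.k2])
    fit.k2_upper, fit.k2_lower = upper, lower
    return upper, lower


def runs_test_residuals(residuals) -> tuple[float, float, str]:
    """Wald-Wolfowitz runs test for systematic structure in fit residuals.

    Residual signs that cluster into few runs indicate a systematic misfit
    (e.g. a single-exponential model forced onto biexponential data).  The
    test is one-sided toward *too few* runs: perfectly alternating signs
    are reported as ``"random-consistent"`` even though they are unusual
    in the other direction.  Returns ``(z_statistic, p_value, verdict)``.
    """
    r = np.asarray(residuals, dtype=float)
    r = r[r != 0]
    if len(r) < 8:
        raise ValueError("need at least 8 nonzero residuals")
    signs = r > 0
    if signs.all() or not signs.any():
        # all residuals on one side: maximally clustered
        return -math.inf, 0.0, "non-random (degenerate: one-signed residuals)"
    z, _ = runstest_1samp(signs.astype(float), cutoff=0.5, correction=False)
    p = float(norm.cdf(z))  # one-sided: few runs
    verdict = "non-random" if p < 0.05 else "random-consistent"
    return float(z), p, verdict
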