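"""Chaperone-client binding statistics from contact trajectories.

A simulation of one chaperone and one client in a finite volume yields a
per-frame count of intermolecular contacts.  Frames at or above a contact
threshold are bound; the bound occupancy converts to a dissociation
constant through

    K_D = (P_chap * P_client / P_complex) * 1/V * 1/(6.022e23 * 1e-27)

with V in Å^3, giving mol/L.  With single copies of each molecule,
P_chap = P_client = 1 - P_complex.  Odds ratios compare binding occupancy
between conformational states with the attractive chaperone interaction
switched on or off.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "ContactTrajectory",
    "BindingEstimate",
    "OddsRatioResult",
    "classify_bound",
    "kd",
    "kd_replicates",
    "odds_ratio",
    "permutation_ratio_test",
    "sphere_volume",
    "suggest_threshold",
]

#: 1/(N_A * 1e-27): converts (1/Å^3) number density to mol/L
_A3_TO_MOLAR = 1.0 / (6.022e23 * 1e-27)


def sphere_volume(radius_A: float) -> float:
    """Volume in Å^3 of the spherical simulation region (default radii in
    the source systems: 160 Å for GroEL, 200 Å for DnaK/HtpG)."""
    return 4.0 / 3.0 * math.pi * radius_A ** 3


@dataclass
class ContactTrajectory:
    """Per-frame intermolecular contact counts with a bound threshold."""

    contacts: np.ndarray
    threshold: int
    system_label: str = ""
    true_bound: np.ndarray | None = None  # generator ground truth, if any

    def __post_init__(self) -> None:
        self.contacts = np.asarray(self.contacts)
        if len(self.contacts) == 0:
            raise ValueError("empty contact series")
        if np.any(self.contacts < 0):
            raise ValueError("contact counts must be nonnegative")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    @property
    def bound(self) -> np.ndarray:
        return self.contacts >= self.threshold

    @property
    def p_complex(self) -> float:
        return float(np.mean(self.bound))


@dataclass
class BindingEstimate:
    """K_D estimate with replicate scatter."""

    p_complex: float
    volume: float
    kd: float | None
    replicate_kds: list = field(default_factory=list)
    ci95: tuple | None = None
    censored: int = 0
    log2_ratio: float | None = None

    @property
    def p_chaperone(self) -> float:
        return 1.0 - self.p_complex

    @property
    def p_client(self) -> float:
        return 1.0 - self.p_complex


@dataclass
class OddsRatioResult:
    ratio: float
    p_value: float | None
    comparison: str = ""
    interaction_mode: str = "attractive_on"


def classify_bound(contacts, threshold: int):
    """Frame-wise bound flags and the bound-state occupancy.

    ``p_complex`` is the number of frames at or above the threshold divided
    by the total number of frames.
    """
    traj = ContactTrajectory(contacts=contacts, threshold=threshold)
    return traj.bound, traj.p_complex


def suggest_threshold(contacts) -> int:
    """Midpoint threshold between the two modes of a bimodal contact
    histogram (two-means split).  The source analysis chose thresholds
    manually per system; this helper is only a default and the chosen
    value is always recorded on the trajectory."""
    x = np.asarray(contacts, dtype=float)
    lo, hi = x.min(), x.max()
    if lo == hi:
        raise ValueError("constant contact series has no two-state split")
    c1, c2 = lo, hi
    for _ in range(100):
        mid = (c1 + c2) / 2.0
        low, high = x[x <= mid], x[x > mid]
        if len(low) == 0 or len(high) == 0:
            break
        n1, n2 = low.mean(), high.mean()
        if n1 == c1 and n2 == c2:
            break
        c1, c2 = n1, n2
    return max(1, int(round((c1 + c2) / 2.0)))


def kd(p_complex: float, volume: float) -> float:
    """Dissociation constant (mol/L) from bound occupancy in volume Å^3.

    With one chaperone and one client in the box the unbound probabilities
    both equal ``1 - p_complex``.
    """
    if not 0.0 < p_complex < 1.0:
        raise ValueError("p_complex must be strictly between 0 and 1 "
                         "(fully bound/unbound trajectories are censored)")
    if volume <= 0:
        raise ValueError("volume must be positive")
    p_unbound = 1.0 - p_complex
    return (p_unbound * p_unbound / p_complex) / volume * _A3_TO_MOLAR


def kd_replicates(trajectories, volume: float,
                  reference_kd: float | None = None) -> BindingEstimate:
    """Mean K_D and t-based 95% CI over independent replicate trajectories.

    Replicates with occupancy exactly 0 or 1 carry no finite K_D and are
    excluded (counted in ``censored``) with a warning.  When
    ``reference_kd`` is given, ``log2_ratio`` of the mean to the reference
    is attached to the returned estimate.
    """
    if len(trajectories) < 2:
        raise ValueError("need at least 2 replicates")
    kds, censored = [], 0
    ps = []
    for traj in trajectories:
        p = traj.p_complex
        ps.append(p)
        if p in (0.0, 1.0):
            censored += 1
            continue
        kds.append(kd(p, volume))
    if censored:
        warnings.warn(f"{censored} replicate(s) censored (occupancy 0 or 1)")
    if not kds:
        raise ValueError("all replicates censored")
    kds = np.asarray(kds, dtype=float)
    mean = float(np.mean(kds))
    if len(kds) > 1 and np.ptp(kds) > 0:
        sem = stats.sem(kds)
        half = sem * stats.t.ppf(0.975, len(kds) - 1)
    else:
        half = 0.0
    est = BindingEstimate(p_complex=float(np.mean(ps)), volume=volume,
                          kd=mean, replicate_kds=list(kds),
                          ci95=(mean - half, mean + half), censored=censored)
    if reference_kd is not None:
        est.log2_ratio = math.log2(mean / reference_kd)
    return est


def odds_ratio(p_on: float, p_off: float, p_ref_on: float, p_ref_off: float,
               replicates: tuple | None = None,
               comparison: str = "U/F") -> OddsRatioResult:
    """Double ratio of binding probabilities (state vs folded reference,
    attraction on vs off)::

        OR = (P_X,on / P_X,off) / (P_F,on / P_F,off)

    When per-replicate probability arrays are supplied as
    ``replicates=(x_on, x_off, f_on, f_off)``, a two-tailed Student t-test
    is run on the replicate-level log odds ratios against zero (replicates
    paired by index).
    """
    for name, p in (("p_on", p_on), ("p_off", p_off),
                    ("p_ref_on", p_ref_on), ("p_ref_off", p_ref_off)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name} must be in (0, 1); ratio inestimable")
    ratio = (p_on / p_off) / (p_ref_on / p_ref_off)
    p_value = None
    if replicates is not None:
        x_on, x_off, f_on, f_off = (np.asarray(a, dtype=float)
                                    for a in replicates)
        if np.any((x_on <= 0) | (x_off <= 0) | (f_on <= 0) | (f_off <= 0)):
            raise ValueError("replicate probabilities must be positive")
        log_or = (np.log(x_on) - np.log(x_off)) - (np.log(f_on) - np.log(f_off))
        p_value = float(stats.ttest_1samp(log_or, 0.0).pvalue)
    return OddsRatioResult(ratio=float(ratio), p_value=p_value,
                           comparison=comparison)


def permutation_ratio_test(group_a, group_b, n_perm: int = 10000,
                           seed: int | None = None) -> float:
    """Two-tailed permutation p-value on the difference of group means.

    All label reassignments are enumerated exactly when their number does
    not exceed ``n_perm``; otherwise ``n_perm`` random shuffles are drawn.
    Ties count as exceedances (identical groups give p = 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 replicates")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)
    total_sum = pooled.sum()
    obs = abs(np.mean(a) - np.mean(b))

    def diffs_from_group_a_sums(sums_a):
        return np.abs(sums_a / na - (total_sum - sums_a) / (n - na))

    n_exact = math.comb(n, na)
    if n_exact <= n_perm:
        idx = np.fromiter((i for c in combinations(range(n), na)
                           for i in c), dtype=int).reshape(n_exact, na)
        d = diffs_from_group_a_sums(pooled[idx].sum(axis=1))
        return float(np.mean(d >= obs - 1e-12))
    rng = np.random.default_rng(seed)
    sums = np.empty(n_perm)
    for k in range(n_perm):
        sums[k] = pooled[rng.permutation(n)[:na]].sum()
    d = diffs_from_group_a_sums(sums)
    return float(np.mean(d >= obs - 1e-12))
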