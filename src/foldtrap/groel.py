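"""Single-ring GroEL/GroES ATP-cycle kinetic model.

The chaperonin cycle is reduced to a single-ring scheme: GroEL (G) binds a
bundle of 7 ATP, captures an unfolded client (U), is capped by GroES (ES),
hydrolyses the ATP, and releases the client partitioned into folded (F),
misfolded (M) or still-unfolded (U) states with probabilities phi_F, phi_M
and 1 - phi_F - phi_M.  A spontaneous bulk folding channel (rate k6)
partitions with its own coefficients.  A basal cycle (hydrolysis without
client, k7; ADP release, k8) consumes ATP unproductively.

Species (all concentrations in µM; the 7 ATP are booked as one bundle):

====  =================  =========================================
idx   name               meaning
====  =================  =========================================
0     G                  free single-ring GroEL
1     G_ATP              GroEL·7ATP
2     G_ATP_U            GroEL·7ATP·client
3     G_ATP_U_ES         GroEL·7ATP·client·GroES
4     G_ADP_U_ES         GroEL·7ADP·client·GroES (post-hydrolysis)
5     ES                 free GroES
6     ATP7               free ATP bundles (1 bundle = 7 ATP)
7     F                  folded client
8     M                  misfolded client
9     U                  unfolded client
10    G_ADP              GroEL·7ADP (basal cycle intermediate)
====  =================  =========================================

Rates k1..k8: ATP binding, protein binding, GroES binding, ATP hydrolysis,
protein release, spontaneous folding, basal hydrolysis, ADP release.  The
basal channel is implemented as G·7ATP --k7--> G·7ADP --k8--> G, the form
consistent with those rate definitions and with exact conservation of
total GroEL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import pearsonr

__all__ = [
    "SPECIES",
    "RateSet",
    "PartitionCoefficients",
    "GroELSystemState",
    "Trajectory",
    "rhs",
    "integrate",
    "p_nn_sim",
    "fit_phis",
    "atp_consumed",
]

SPECIES = ("G", "G_ATP", "G_ATP_U", "G_ATP_U_ES", "G_ADP_U_ES",
           "ES", "ATP7", "F", "M", "U", "G_ADP")

# conservation groups (indices into SPECIES)
_GROEL_CORE = (0, 1, 2, 3, 4, 10)
_CLIENT = (2, 3, 4, 7, 8, 9)
_GROES = (3, 4, 5)


@dataclass
class RateSet:
    """Rate constants of the cycle.  Bimolecular rates (k1, k2, k3) are in
    µM^-1 min^-1; unimolecular rates (k4, k5, k6, k7, k8) in min^-1.
    Units must be supplied consistently by the caller; nothing is guessed.
    """

    k1: float = 0.0  # ATP binding
    k2: float = 0.0  # protein binding
    k3: float = 0.0  # GroES binding
    k4: float = 0.0  # ATP hydrolysis
    k5: float = 0.0  # protein release
    k6: float = 0.0  # spontaneous (bulk) folding
    k7: float = 0.0  # basal hydrolysis
    k8: float = 0.0  # ADP release

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be nonnegative")

    def as_tuple(self):
        return (self.k1, self.k2, self.k3, self.k4,
                self.k5, self.k6, self.k7, self.k8)


@dataclass
class PartitionCoefficients:
    """Per-cycle release fractions into folded / misfolded states.

    The GroEL pair applies to clients released from the cage (k5 channel);
    the bulk pair to spontaneous folding events (k6 channel).  The
    remainder ``1 - phi_F - phi_M`` of the GroEL channel is recycled to U.
    """

    phi_f_groel: float = 0.0
    phi_m_groel: float = 0.0
    phi_f_bulk: float = 0.0
    phi_m_bulk: float = 0.0

    def __post_init__(self) -> None:
        for name in ("phi_f_groel", "phi_m_groel", "phi_f_bulk", "phi_m_bulk"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.phi_f_groel + self.phi_m_groel > 1.0 + 1e-12:
            raise ValueError("phi_f_groel + phi_m_groel must be <= 1")
        if self.phi_f_bulk + self.phi_m_bulk > 1.0 + 1e-12:
            raise ValueError("phi_f_bulk + phi_m_bulk must be <= 1")


@dataclass
class GroELSystemState:
    """Initial concentrations (µM) of the 11 species."""

    G: float = 0.0
    G_ATP: float = 0.0
    G_ATP_U: float = 0.0
    G_ATP_U_ES: float = 0.0
    G_ADP_U_ES: float = 0.0
    ES: float = 0.0
    ATP7: float = 0.0
    F: float = 0.0
    M: float = 0.0
    U: float = 0.0
    G_ADP: float = 0.0

    def __post_init__(self) -> None:
        if any(getattr(self, s) < 0 for s in SPECIES):
            raise ValueError("concentrations must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)


@dataclass
class Trajectory:
    """Integrated species trajectories on a time grid (minutes, µM)."""

    t: np.ndarray
    y: np.ndarray  # shape (11, len(t))

    def species(self, name: str) -> np.ndarray:
        return self.y[SPECIES.index(name)]

    def conservation_errors(self) -> dict[str, float]:
        """Max relative drift of the three conserved totals."""
        out = {}
        for label, idx in (("client", _CLIENT), ("groel", _GROEL_CORE),
                           ("groes", _GROES)):
            total = self.y[list(idx)].sum(axis=0)
            ref = total[0]
            out[label] = 0.0 if ref == 0 else float(
                np.max(np.abs(total - ref)) / ref)
        return out


def rhs(y, rates: RateSet, phis: PartitionCoefficients) -> np.ndarray:
    """Time derivatives of the 11 species (pure mass-action function)."""
    G, GA, GAU, GAUES, GDUES, ES, A, F, M, U, GD = y
    k1, k2, k3, k4, k5, k6, k7, k8 = rates.as_tuple()
    fF, fM = phis.phi_f_groel, phis.phi_m_groel
    bF, bM = phis.phi_f_bulk, phis.phi_m_bulk

    v_bind_atp = k1 * G * A
    v_bind_u = k2 * GA * U
    v_bind_es = k3 * GAU * ES
    v_hydro = k4 * GAUES
    v_release = k5 * GDUES
    v_bulk = k6 * U
    v_basal = k7 * GA
    v_adp = k8 * GD

    return np.array([
        -v_bind_atp + v_release + v_adp,          # G
        v_bind_atp - v_bind_u - v_basal,          # G_ATP
        v_bind_u - v_bind_es,                     # G_ATP_U
        v_bind_es - v_hydro,                      # G_ATP_U_ES
        v_hydro - v_release,                      # G_ADP_U_ES
        -v_bind_es + v_release,                   # ES
        -v_bind_atp,                              # ATP7
        fF * v_release + bF * v_bulk,             # F
        fM * v_release + bM * v_bulk,             # M
        -v_bind_u + (1.0 - fF - fM) * v_release - v_bulk,  # U
        v_basal - v_adp,                          # G_ADP
    ])


def integrate(initial: GroELSystemState, rates: RateSet,
              phis: PartitionCoefficients, t_grid,
              rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Integrate the cycle on an ascending time grid starting at 0.

    Uses a stiff-capable solver (LSODA).  Tiny negative excursions within
    integrator tolerance are clipped to zero.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be ascending and start at 0")
    y0 = initial.as_array()
    kt = rates.as_tuple()
    fF, fM = phis.phi_f_groel, phis.phi_m_groel
    bF, bM = phis.phi_f_bulk, phis.phi_m_bulk

    def f(_t, y):
        G, GA, GAU, GAUES, GDUES, ES, A, F, M, U, GD = y
        k1, k2, k3, k4, k5, k6, k7, k8 = kt
        v1 = k1 * G * A
        v2 = k2 * GA * U
        v3 = k3 * GAU * ES
        v4 = k4 * GAUES
        v5 = k5 * GDUES
        v6 = k6 * U
        v7 = k7 * GA
        v8 = k8 * GD
        return [
            -v1 + v5 + v8,
            v1 - v2 - v7,
            v2 - v3,
            v3 - v4,
            v4 - v5,
            -v3 + v5,
            -v1,
            fF * v5 + bF * v6,
            fM * v5 + bM * v6,
            -v2 + (1.0 - fF - fM) * v5 - v6,
            v7 - v8,
        ]

    sol = solve_ivp(f, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    y = sol.y
    y[(y < 0) & (y > -10 * atol)] = 0.0
    return Trajectory(t=t_grid, y=y)


def p_nn_sim(traj: Trajectory, u0: float, t_points) -> np.ndarray:
    """Simulated non-native probability ``1 - [F](t)/[U]_0``."""
    if u0 <= 0:
        raise ValueError("u0 must be positive")
    t_points = np.asarray(t_points, dtype=float)
    if np.any(t_points < traj.t[0]) or np.any(t_points > traj.t[-1]):
        raise ValueError("requested time outside the integrated range")
    F = np.interp(t_points, traj.t, traj.species("F"))
    return 1.0 - F / u0


def atp_consumed(traj: Trajectory, accounting: str = "bundle7") -> np.ndarray:
    """ATP consumed (µM) versus time.

    Free ATP is booked as 7-ATP bundles; under the default ``"bundle7"``
    accounting each consumed bundle counts as 7 ATP molecules.  The
    ``"literal"`` option reports bundle units unmultiplied (the convention
    the original experiments used is not documented, so both are exposed).
    """
    if accounting not in ("bundle7", "literal"):
        raise ValueError("accounting must be 'bundle7' or 'literal'")
    A = traj.species("ATP7")
    used = A[0] - A
    return 7.0 * used if accounting == "bundle7" else used


def fit_phis(experiment, initial: GroELSystemState, rates: RateSet,
             context: str = "groel",
             base_phis: PartitionCoefficients | None = None,
             p_nn_eq: float | None = None,
             p_nn_eq_mode: str = "final",
             rtol: float = 1e-8, atol: float = 1e-10):
    """Grid search for the partition coefficients of one folding context.

    For each candidate ``phi_F`` on the grid 0.001..1.001 (step 0.001) the
    misfolded coefficient is tied to the experimental plateau through
    ``phi_M = P_eq / (1 - P_eq) * phi_F`` where ``P_eq`` is the non-native
    probability at the final time point (``p_nn_eq_mode="last2"`` averages
    the last two points instead).  Candidates with ``phi_F + phi_M > 1``
    are discarded.  Each survivor is integrated and scored against the
    experimental ``P_NN`` curve; the best candidate maximizes the Pearson
    r^2, with ties broken by the total absolute error.

    Parameters
    ----------
    experiment : RefoldingTimeCourse
        Experimental curve; its last point(s) define the plateau.
    context : {"groel", "bulk"}
        Which coefficient pair the grid scans; the other pair is taken
        from ``base_phis`` (zeros when omitted).

    Returns
    -------
    (PartitionCoefficients, r_squared, abs_error)
    """
    if context not in ("groel", "bulk"):
        raise ValueError("context must be 'groel' or 'bulk'")
    t_exp = experiment.t
    p_exp = experiment.p_nn
    if p_nn_eq is None:
        p_nn_eq = (float(p_exp[-1]) if p_nn_eq_mode == "final"
                   else float(np.mean(p_exp[-2:])))
    if p_nn_eq >= 1.0:
        raise ValueError("P_NN^eq = 1: no folding observed, phi ratio undefined")
    ratio = p_nn_eq / (1.0 - p_nn_eq)
    base = base_phis or PartitionCoefficients()

    t_grid = np.unique(np.concatenate([[0.0], t_exp]))
    u0 = initial.U
    if u0 <= 0:
        raise ValueError("initial unfolded client concentration must be positive")

    best = None
    grid = np.round(np.arange(0.001, 1.001 + 1e-9, 0.001), 3)
    for phi_f in grid:
        phi_m = ratio * phi_f
        if phi_f + phi_m > 1.0:
            continue
        if context == "groel":
            phis = PartitionCoefficients(phi_f_groel=phi_f, phi_m_groel=phi_m,
                                         phi_f_bulk=base.phi_f_bulk,
                                         phi_m_bulk=base.phi_m_bulk)
        else:
            phis = PartitionCoefficients(phi_f_groel=base.phi_f_groel,
                                         phi_m_groel=base.phi_m_groel,
                                         phi_f_bulk=phi_f, phi_m_bulk=phi_m)
        traj = integrate(initial, rates, phis, t_grid, rtol=rtol, atol=atol)
        p_sim = p_nn_sim(traj, u0, t_exp)
        abs_err = float(np.sum(np.abs(p_sim - p_exp)))
        if np.ptp(p_sim) == 0 or np.ptp(p_exp) == 0:
            r2 = -np.inf
        else:
            r2 = float(pearsonr(p_sim, p_exp)[0] ** 2)
        key = (-r2, abs_err)
        if best is None or key < best[0]:
            best = (key, phis, r2, abs_err)
    if best is None:
        raise RuntimeError("no feasible phi candidate on the grid")
    _, phis, r2, abs_err = best
    return phis, r2, abs_err
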