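"""Static evaluator for a Cα coarse-grained potential energy function.

The potential is the sum of six terms: harmonic virtual Cα-Cα bonds, a
four-fold cosine torsion series, a double-well bond-angle term (log-sum-exp
blend of an alpha-like and a beta-like well), Debye-Hückel screened
electrostatics, a 12-10-6 native-contact potential, and the same 12-10-6
form with a tiny well depth for non-native (effectively repulsive) pairs.

This module only scores configurations -- no dynamics.  It exists so that
native and misfolded fixtures can be ranked and regression-tested.

Notes on the 12-10-6 form ``eps*(13 x^12 - 18 x^10 + 4 x^6)`` with
``x = sigma/r``: its minimum sits exactly at ``r = sigma`` with depth
``-eps`` (the coefficients are chosen for that), plus a small desolvation
barrier near ``r = 1.45 sigma``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ForceFieldParams", "energy", "pair_12_10_6"]

#: e^2/(4 pi eps0) in kcal*Å/(mol*e^2)
COULOMB_KCAL = 332.0637

#: charge per residue type: Lys/Arg +e, Glu/Asp -e, all others 0
RESIDUE_CHARGES = {"LYS": 1.0, "ARG": 1.0, "GLU": -1.0, "ASP": -1.0}

# double-well angle defaults (kcal/mol, radians); alpha well is the deeper,
# offset well, beta the wider one; gamma controls the blend sharpness
_ANGLE_DEFAULTS = dict(gamma=0.1, k_alpha=106.4, theta_alpha=1.60,
                       eps_alpha=4.3, k_beta=26.3, theta_beta=2.27)


@dataclass
class ForceFieldParams:
    """Parameters for the six-term Cα potential.

    ``native_pairs`` rows are ``(i, j, eps, sigma)`` with 0-based residue
    indices; ``sigma`` is the native Cα distance divided by 2^(1/6), the
    convention of the source parameterization.  ``torsions`` maps dihedral
    index i (residues i..i+3) to four ``(k_phi, delta)`` tuples.
    Energies kcal/mol, lengths Å, angles radians, charges in units of e.
    """

    kb: float = 50.0
    r0: float = 3.81
    torsions: dict = field(default_factory=dict)
    angle: dict = field(default_factory=lambda: dict(_ANGLE_DEFAULTS))
    charges: np.ndarray | None = None
    l_debye: float = 10.0
    eps_r: float = 78.5
    native_pairs: np.ndarray | None = None  # (n, 4): i, j, eps, sigma
    nonnative_eps: float = 0.000132
    nonnative_sigma: float = 5.0
    #: bonded neighbors closer than this sequence separation are excluded
    #: from nonbonded sums (inherited convention; configurable, not guessed)
    exclusion_separation: int = 4

    def __post_init__(self) -> None:
        if self.l_debye <= 0 or self.eps_r <= 0:
            raise ValueError("l_debye and eps_r must be positive")
        if self.native_pairs is not None:
            self.native_pairs = np.asarray(self.native_pairs, dtype=float)
            if np.any(self.native_pairs[:, 3] <= 0):
                raise ValueError("native sigma values must be positive")

    @staticmethod
    def charges_from_sequence(residue_names) -> np.ndarray:
        """Assign +e to Lys/Arg, -e to Glu/Asp, 0 otherwise."""
        return np.array([RESIDUE_CHARGES.get(str(r).upper(), 0.0)
                         for r in residue_names])


def pair_12_10_6(r, eps, sigma):
    """12-10-6 contact potential; equals ``-eps`` at ``r = sigma``."""
    x = sigma / r
    x6 = x ** 6
    return eps * (13.0 * x6 * x6 - 18.0 * x6 * x ** 4 + 4.0 * x6)


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    return math.atan2(np.dot(m1, n2), np.dot(n1, n2))


def _angle(p0, p1, p2) -> float:
    v1, v2 = p0 - p1, p2 - p1
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.acos(np.clip(c, -1.0, 1.0))


def energy(coords, params: ForceFieldParams) -> dict:
    """Score a Cα configuration; returns the six-term breakdown and total.

    Returns a dict with keys ``bond``, ``torsion``, ``angle``,
    ``electrostatic``, ``native``, ``nonnative`` and ``total`` (kcal/mol).
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or not np.all(np.isfinite(x)):
        raise ValueError("coords must be a finite (N, 3) array")
    n = len(x)

    # bonds
    bond_vec = np.diff(x, axis=0)
    bond_len = np.linalg.norm(bond_vec, axis=1)
    e_bond = float(np.sum(params.kb * (bond_len - params.r0) ** 2))

    # torsions
    e_tors = 0.0
    for i, terms in params.torsions.items():
        if i + 3 >= n:
            raise ValueError(f"torsion index {i} outside chain")
        phi = _dihedral(x[i], x[i + 1], x[i + 2], x[i + 3])
        for j, (k_phi, delta) in enumerate(terms, start=1):
            e_tors += k_phi * (1.0 + math.cos(j * phi - delta))

    # double-well angles
    a = params.angle
    e_ang = 0.0
    if n >= 3 and a.get("k_alpha") is not None:
        g = a["gamma"]
        for i in range(1, n - 1):
            th = _angle(x[i - 1], x[i], x[i + 1])
            wa = a["k_alpha"] * (th - a["theta_alpha"]) ** 2 + a["eps_alpha"]
            wb = a["k_beta"] * (th - a["theta_beta"]) ** 2
            # log-sum-exp blend, evaluated stably
            m = min(wa, wb)
            e_ang += m - (1.0 / g) * math.log(
                math.exp(-g * (wa - m)) + math.exp(-g * (wb - m)))

    # pair distances
    ii, jj = np.triu_indices(n, k=params.exclusion_separation)
    diff = x[ii] - x[jj]
    rr = np.linalg.norm(diff, axis=1)
    if np.any(rr == 0):
        raise ValueError("overlapping beads in nonbonded pair term")

    # electrostatics
    e_elec = 0.0
    if params.charges is not None:
        q = np.asarray(params.charges, dtype=float)
        qq = q[ii] * q[jj]
        sel = qq != 0
        e_elec = float(np.sum(
            COULOMB_KCAL * qq[sel] / (params.eps_r * rr[sel])
            * np.exp(-rr[sel] / params.l_debye)))

    # native / non-native split
    native_set = set()
    e_native = 0.0
    if params.native_pairs is not None and len(params.native_pairs):
        np_i = params.native_pairs[:, 0].astype(int)
        np_j = params.native_pairs[:, 1].astype(int)
        native_set = {(min(a_, b_), max(a_, b_))
                      for a_, b_ in zip(np_i, np_j)}
        d = np.linalg.norm(x[np_i] - x[np_j], axis=1)
        if np.any(d == 0):
            raise ValueError("overlapping beads in native pair term")
        e_native = float(np.sum(pair_12_10_6(
            d, params.native_pairs[:, 2], params.native_pairs[:, 3])))

    nonnative_mask = np.array([(i, j) not in native_set
                               for i, j in zip(ii, jj)], dtype=bool)
    e_nonnative = float(np.sum(pair_12_10_6(
        rr[nonnative_mask], params.nonnative_eps, params.nonnative_sigma)))

    terms = dict(bond=e_bond, torsion=e_tors, angle=e_ang,
                 electrostatic=e_elec, native=e_native,
                 nonnative=e_nonnative)
    terms["total"] = float(sum(terms.values()))
    return terms


def load_pair_params(path) -> np.ndarray:
    """Read a native-pair table ``i j eps sigma`` (whitespace separated,
    ``#`` comments, 1-based indices converted to 0-based)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if not line:
                continue
            i, j, eps, sigma = line.split()
            rows.append((int(i) - 1, int(j) - 1, float(eps), float(sigma)))
    return np.array(rows, dtype=float)
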