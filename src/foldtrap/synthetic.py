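"""Synthetic-data generators with known ground truth.

Every downstream stage of the package is testable offline through these
generators: biexponential refolding curves with additive Gaussian noise,
two-state Markov bound/unbound contact trajectories, toy Cα chains with
analytically known loop-thread linking numbers, and half-tryptic peptide
tables drawn from a stated cut-site propensity model.  All generators are
bit-reproducible under a fixed seed; seeds are explicit arguments, never
global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import ContactTrajectory
from .kinetics import RefoldingTimeCourse, biexponential
from .lipms import (CutSiteModel, LipMsPeptide, _gumbel_topk, _site_weights,
                    build_cutsite_model, enumerate_half_tryptic)
from .topology import CalphaStructure, EntanglementRecord, gauss_double_sum

__all__ = [
    "TimeCourseSpec",
    "BindingTrajSpec",
    "ToyLinkSpec",
    "LipMsSimSpec",
    "ToyLinkPair",
    "gen_timecourse",
    "gen_contact_trajectory",
    "gen_entangled_toy",
    "gen_lipms_dataset",
    "gen_consistency_scenario",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class TimeCourseSpec:
    """Forward-model parameters for a refolding curve.

    Defaults mirror typical meta-analysis conditions: 1% additive noise in
    probability units, time courses of a few hundred minutes.
    """

    a0: float
    a1: float
    k1: float
    k2: float
    duration: float = 150.0
    n_points: int = 30
    noise_sd: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if abs(self.a0 + self.a1 - 1.0) > 1e-12:
            raise ValueError("invariant violated: a0 + a1 must equal 1")
        if not (self.k1 > self.k2 >= 0):
            raise ValueError("invariant violated: require k1 > k2 >= 0")
        if self.n_points < 3:
            raise ValueError("invariant violated: n_points must be >= 3")
        if self.duration <= 0 or self.noise_sd < 0:
            raise ValueError("duration must be positive, noise_sd >= 0")


def gen_timecourse(spec: TimeCourseSpec) -> RefoldingTimeCourse:
    """Sample P_NN(t) on an even grid; noise is i.i.d. Gaussian added to
    the analytic curve, then clipped to [0, 1].  With ``noise_sd=0`` the
    values equal the analytic curve exactly."""
    t = np.linspace(0.0, spec.duration, spec.n_points)
    p = biexponential(t, spec.a0, spec.k1, spec.k2)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        p = p + rng.normal(0.0, spec.noise_sd, size=len(t))
    p = np.clip(p, 0.0, 1.0)
    sigma = np.full(len(t), spec.noise_sd) if spec.noise_sd > 0 else None
    return RefoldingTimeCourse(t=t, p_nn=p, sigma=sigma, label="synthetic")


@dataclass
class BindingTrajSpec:
    """Two-state (bound/unbound) Markov contact-count trajectory.

    Contact counts are Poisson around state-specific means; the underlying
    two-state chain has the requested stationary bound probability and
    mean bound dwell (geometric).  The Poisson choice is a stand-in: the
    source analysis only exhibits two-state behavior, not a distribution.
    """

    p_bound_target: float
    mean_dwell_bound: float
    n_frames: int
    contact_level_bound: float = 60.0
    contact_level_unbound: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_bound_target < 1.0:
            raise ValueError("p_bound_target must be in (0, 1)")
        if self.mean_dwell_bound < 1:
            raise ValueError("mean dwell must be >= 1 frame")
        if self.contact_level_bound <= self.contact_level_unbound:
            raise ValueError("bound contact mean must exceed unbound mean")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")


def gen_contact_trajectory(spec: BindingTrajSpec) -> ContactTrajectory:
    """Simulate the chain and emit counts plus ground-truth labels."""
    p_leave_bound = 1.0 / spec.mean_dwell_bound
    # stationary:  p_b = q / (p + q)  with q = P(unbound -> bound)
    q = p_leave_bound * spec.p_bound_target / (1.0 - spec.p_bound_target)
    if q > 1.0:
        raise ValueError("stationary target unreachable with this dwell: "
                         "required unbound->bound probability exceeds 1")
    rng = np.random.default_rng(spec.seed)
    u = rng.random(spec.n_frames)
    bound = np.empty(spec.n_frames, dtype=bool)
    state = rng.random() < spec.p_bound_target  # start from stationarity
    for k in range(spec.n_frames):
        if state:
            state = u[k] >= p_leave_bound
        else:
            state = u[k] < q
        bound[k] = state
    lam = np.where(bound, spec.contact_level_bound,
                   spec.contact_level_unbound)
    contacts = rng.poisson(lam)
    threshold = int(round((spec.contact_level_bound
                           + spec.contact_level_unbound) / 2.0))
    return ContactTrajectory(contacts=contacts, threshold=threshold,
                             system_label="synthetic", true_bound=bound)


@dataclass
class ToyLinkSpec:
    """Planar bead circle plus a straight thread: the simplest geometry
    with a provable |linking number| of 1."""

    loop_radius: float = 12.0
    n_loop_beads: int = 24
    thread_offset: tuple = (40.0, 0.0, 0.0)
    thread_length: float = 60.0
    handedness: int = 1
    bead_spacing: float = 3.8
    tail_spacer: int = 5

    def __post_init__(self) -> None:
        if self.n_loop_beads < 8:
            raise ValueError("need at least 8 loop beads")
        if self.handedness not in (+1, -1):
            raise ValueError("handedness must be +1 or -1")
        gap = 2.0 * self.loop_radius * math.sin(math.pi / self.n_loop_beads)
        if gap > 2.0 * self.bead_spacing:
            raise ValueError("loop is not closed within bead spacing; "
                             "increase n_loop_beads or shrink the radius")


@dataclass
class ToyLinkPair:
    """Native (unthreaded) and misfolded (threaded) toy structures.

    ``loop_slice``/``thread_slice`` select the loop and thread beads in
    either structure; the beads between them are a spacer bridge excluded
    from tail-based linking computations.
    """

    native: CalphaStructure
    misfolded: CalphaStructure
    loop_slice: slice
    thread_slice: slice
    handedness: int

    def loop(self, which: str = "misfolded") -> np.ndarray:
        return getattr(self, which).coords[self.loop_slice]

    def thread(self, which: str = "misfolded") -> np.ndarray:
        return getattr(self, which).coords[self.thread_slice]


def _toy_chain(spec: ToyLinkSpec, thread_xy: tuple) -> np.ndarray:
    """Loop beads on a circle, a spacer bridge, then a vertical thread
    rising through (thread_xy, -L/2) -> (thread_xy, +L/2)."""
    n = spec.n_loop_beads
    ang = 2.0 * math.pi * np.arange(n) / n
    loop = np.column_stack([spec.loop_radius * np.cos(ang),
                            spec.loop_radius * np.sin(ang),
                            np.zeros(n)])
    x0, y0 = thread_xy
    z_lo = -spec.thread_length / 2.0
    n_thread = max(int(round(spec.thread_length / spec.bead_spacing)) + 1, 2)
    z = np.linspace(z_lo, -z_lo, n_thread)
    thread = np.column_stack([np.full(n_thread, x0), np.full(n_thread, y0),
                              z])
    # spacer: from the last loop bead, dive below the plane and slide to
    # the thread base without ever approaching the disc from above
    start = loop[-1]
    stop = thread[0]
    frac = np.linspace(0.0, 1.0, spec.tail_spacer + 2)[1:-1]
    spacer = start[None, :] + frac[:, None] * (stop - start)[None, :]
    spacer[:, 2] = np.minimum(spacer[:, 2], z_lo / 2.0)  # stay below plane
    return np.vstack([loop, spacer, thread])


def gen_entangled_toy(spec: ToyLinkSpec) -> ToyLinkPair:
    """Toy pair for linking-number validation.

    The misfolded chain's thread passes through the loop centroid,
    producing a rounded loop-thread linking number equal to
    ``spec.handedness``; the native chain's thread is displaced by
    ``thread_offset`` and is unlinked.  The thread orientation is set so
    the discrete Gauss sum carries the requested sign.
    """
    off = np.asarray(spec.thread_offset, dtype=float)
    if np.linalg.norm(off[:2]) <= spec.loop_radius:
        raise ValueError("thread_offset must displace the native thread "
                         "outside the loop")
    mis_coords = _toy_chain(spec, (0.0, 0.0))
    nat_coords = _toy_chain(spec, (off[0], off[1]))

    n = spec.n_loop_beads
    loop_slice = slice(0, n)
    thread_slice = slice(n + spec.tail_spacer, len(mis_coords))

    # degenerate-geometry guard: thread must clear the loop beads
    loop_pts = mis_coords[loop_slice]
    thread_pts = mis_coords[thread_slice]
    dmin = np.min(np.linalg.norm(
        loop_pts[:, None, :] - thread_pts[None, :, :], axis=2))
    if dmin < spec.bead_spacing / 2.0:
        raise ValueError("degenerate geometry: thread intersects loop beads")

    closed = np.vstack([loop_pts, loop_pts[0]])
    raw = gauss_double_sum(closed, thread_pts)
    if np.sign(raw) != spec.handedness:
        # flip the thread direction to carry the requested chirality
        for coords in (mis_coords, nat_coords):
            coords[thread_slice] = coords[thread_slice][::-1]

    native = CalphaStructure(coords=nat_coords, synthetic=True,
                             label="toy-native")
    misfolded = CalphaStructure(coords=mis_coords, synthetic=True,
                                label="toy-misfolded")
    return ToyLinkPair(native=native, misfolded=misfolded,
                       loop_slice=loop_slice, thread_slice=thread_slice,
                       handedness=spec.handedness)


@dataclass
class LipMsSimSpec:
    """Half-tryptic peptide table with planted abundance-ratio effects."""

    protein_length: int = 120
    n_cutsites: int = 10
    aa_propensities: dict = field(default_factory=dict)
    effect_sites: list = field(default_factory=list)  # [(residue, sign)]
    n_timepoints: int = 3
    seed: int | None = None
    effect_window: int = 5

    def __post_init__(self) -> None:
        if self.n_cutsites > self.protein_length:
            raise ValueError("more cut sites than residues")
        if self.aa_propensities:
            w = np.array(list(self.aa_propensities.values()), dtype=float)
            if np.any(w < 0) or w.sum() == 0:
                raise ValueError("propensity weights must be nonnegative "
                                 "and not all zero")
        for res, sign in self.effect_sites:
            if not 1 <= res <= self.protein_length:
                raise ValueError("effect site outside the protein")
            if sign not in (+1, -1):
                raise ValueError("effect sign must be +1 or -1")


def _random_sequence(length: int, rng) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def gen_lipms_dataset(spec: LipMsSimSpec):
    """Peptide table plus proteome-composition table.

    Cut sites are drawn per timepoint (unique within a timepoint) with
    probability proportional to ``aa_propensities`` of the residue at the
    cut position (uniform when empty).  Peptides overlapping a planted
    effect site carry a log2 ratio of the planted sign; background
    peptides get small zero-centred ratios.  Returns
    ``(peptides_df, composition_df, sequence)``.
    """
    rng = np.random.default_rng(spec.seed)
    seq = _random_sequence(spec.protein_length, rng)
    candidates = enumerate_half_tryptic(seq)
    avail = np.sort(candidates["cut_site"].unique())
    if spec.n_cutsites > len(avail):
        raise ValueError("sequence has too few half-tryptic cut sites")
    weights = np.array([spec.aa_propensities.get(seq[s - 1], 1.0)
                        if spec.aa_propensities else 1.0 for s in avail],
                       dtype=float)
    if weights.sum() == 0:
        raise ValueError("all candidate sites have zero propensity")

    rows = []
    for tp in range(1, spec.n_timepoints + 1):
        picks = avail[_gumbel_topk(weights + 1e-300, spec.n_cutsites, rng)]
        for site in np.sort(picks):
            cand = candidates[candidates["cut_site"] == site]
            row = cand.iloc[rng.integers(len(cand))]
            planted = next((sgn for res, sgn in spec.effect_sites
                            if abs(site - res) <= spec.effect_window), None)
            if planted is not None:
                ratio = planted * abs(rng.normal(1.0, 0.25))
            else:
                ratio = rng.normal(0.0, 0.5)
            rows.append(dict(protein="synthetic", start=int(row["start"]),
                             end=int(row["end"]), cut_site=int(site),
                             log2_ratio=float(ratio), timepoint=f"T{tp}",
                             significant=True))
    peptides = pd.DataFrame(rows)
    comp_counts = {aa: seq.count(aa) for aa in AMINO_ACIDS}
    composition = pd.DataFrame(
        {"residue": list(comp_counts), "frequency": list(comp_counts.values())})
    return peptides, composition, seq


def gen_consistency_scenario(n_res: int = 120, n_entangle: int = 3,
                             n_cutsites: int = 8, n_timepoints: int = 3,
                             planted: bool = False, seed: int | None = None):
    """Complete toy setup for the LiP-MS consistency test.

    Builds an extended Cα chain, ``n_entangle`` entanglement records with
    crossing residues spread along the chain, a per-residue exposure
    -change profile (positive around crossings, mildly negative
    elsewhere), a cut-site model from the chain's own composition, and an
    observed peptide set: under the null (``planted=False``) observed cut
    sites are drawn from the same theoretical distribution the
    permutation test uses, with random ratio signs; with
    ``planted=True`` cut sites sit on the crossings with agreeing signs.

    Returns a dict with keys structure, records, delta_sasa, model,
    sequence, peptides, timepoints, longest.
    """
    rng = np.random.default_rng(seed)
    seq = _random_sequence(n_res, rng)
    coords = np.column_stack([3.8 * np.arange(n_res),
                              np.zeros(n_res), np.zeros(n_res)])
    structure = CalphaStructure(coords=coords, synthetic=True,
                                label="toy-extended")

    crossings = np.linspace(15, n_res - 15, n_entangle).astype(int)
    records = []
    for k, c in enumerate(crossings):
        records.append(EntanglementRecord(
            contact=(int(c) + 5, int(c) + 25), g_native=0, g_current=1,
            partial_n_raw=1.0, partial_c_raw=0.0, partial_n=1, partial_c=0,
            crossings_n=[int(c)], crossings_c=[], change_n="gain",
            loop_length=21))

    delta_sasa = rng.normal(-0.2, 0.05, size=n_res)
    for c in crossings:
        lo, hi = max(0, c - 6), min(n_res, c + 6)
        delta_sasa[lo:hi] = np.abs(rng.normal(1.0, 0.2, size=hi - lo))

    comp = {aa: max(seq.count(aa), 1) for aa in AMINO_ACIDS}
    model = build_cutsite_model(list(seq), comp)

    candidates = enumerate_half_tryptic(seq)
    sites_all, weights = _site_weights(candidates, model)
    timepoints = [f"T{k}" for k in range(1, n_timepoints + 1)]
    peptides = []
    for tp in timepoints:
        if planted:
            chosen = []
            for c in crossings:
                near = sites_all[np.abs(sites_all - c) <= 3]
                if len(near):
                    chosen.append(int(near[np.argmin(np.abs(near - c))]))
            extra = [int(s) for s in
                     sites_all[_gumbel_topk(weights, n_cutsites, rng)]]
            sites = list(dict.fromkeys(chosen + extra))[:n_cutsites]
        else:
            sites = [int(s) for s in
                     sites_all[_gumbel_topk(weights, n_cutsites, rng)]]
        for site in sites:
            if planted and np.min(np.abs(crossings - site)) <= 8:
                window = delta_sasa[max(0, site - 6):site + 5]
                sign = float(np.sign(np.mean(window))) or 1.0
            else:
                sign = rng.choice([-1.0, 1.0])
            cand = candidates[candidates["cut_site"] == site]
            row = cand.iloc[0]
            peptides.append(LipMsPeptide(
                protein_id="toy", start=int(row["start"]),
                end=int(row["end"]), pk_cut_site=site,
                log2_ratio=sign * abs(rng.normal(1.0, 0.3)),
                timepoint=tp, significant=True))
    return dict(structure=structure, records=records,
                delta_sasa=delta_sasa, model=model, sequence=seq,
                peptides=peptides, timepoints=timepoints,
                longest=timepoints[-1])
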