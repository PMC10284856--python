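"""Consistency between predicted entanglements and LiP-MS evidence.

Limited-proteolysis mass spectrometry (LiP-MS) exposes conformational
differences: proteinase K (PK) cleaves solvent-exposed sites, producing
half-tryptic peptides whose refolded/native abundance ratio (log2 R/N)
changes where the refolded conformation differs from native.  If a protein
misfolds into an entangled state, significant PK cut sites should (a)
overlap in primary sequence with the entanglement's crossing region and
(b) change solvent exposure in the direction the structures predict.

Two binary matrices of shape (N_e entanglements x N_l significant
peptides) encode this:

    O[e, l] = 1  iff  J(l, e) > 0
    S[e, l] = 1  iff  O[e, l] = 1 and sgn(<dSASA>_sim) = sgn(log2 R/N)

where J is the Jaccard index between the residues within ±5 of peptide
l's PK cut site and the residues within 8 Å of entanglement e's crossing
residues.  Per-timepoint averages <O>_t and <S>_t are the test
statistics.  Their significance is assessed against random PK cut-site
sets drawn from a theoretical distribution of all potential half-tryptic
peptides (intrinsic PK cutting propensity per residue type, Eq.-style
ratio of observed to proteome frequency, times a peptide length/internal
-trypsin-site probability), via a permutation rule: a random draw is "more
consistent" when it strictly exceeds both observed statistics at two or
more timepoints, one of which is the longest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LipMsPeptide",
    "ConsistencyResult",
    "CutSiteModel",
    "peptides_from_frame",
    "overlap_matrix",
    "sign_matrix",
    "consistency_stats",
    "build_cutsite_model",
    "enumerate_half_tryptic",
    "sample_random_cutsites",
    "permutation_pvalue",
    "site_lookup_tables",
]


@dataclass
class LipMsPeptide:
    """One significant half-tryptic peptide observation."""

    protein_id: str
    start: int            # 1-based inclusive
    end: int              # 1-based inclusive
    pk_cut_site: int      # 1-based residue index
    log2_ratio: float     # refolded / native abundance
    timepoint: str
    significant: bool = True

    def __post_init__(self) -> None:
        if not self.start <= self.end:
            raise ValueError("peptide start must be <= end")
        if not (self.start - 1 <= self.pk_cut_site <= self.end + 1):
            raise ValueError("PK cut site must border or lie in the span")


@dataclass
class ConsistencyResult:
    """O/S matrices, per-timepoint statistics, and the permutation p."""

    O: np.ndarray
    S: np.ndarray
    o_stat: dict
    s_stat: dict
    p_value: float | None = None
    n_perm: int = 0
    n_more_consistent: int = 0


@dataclass
class CutSiteModel:
    """Intrinsic PK cut propensity per residue type plus the peptide
    length / internal-trypsin-site probability table."""

    p_intrinsic: dict            # residue type -> observed/proteome ratio
    p_observed: dict
    p_proteome: dict
    length_trypsin_prob: dict    # (length, n_internal_trypsin) -> prob
    excluded: list = field(default_factory=list)


def peptides_from_frame(df: pd.DataFrame) -> list[LipMsPeptide]:
    """Build peptide records from a table with columns protein, start,
    end, cut_site, log2_ratio, timepoint, significant."""
    peps = []
    for row in df.itertuples(index=False):
        peps.append(LipMsPeptide(
            protein_id=str(row.protein), start=int(row.start),
            end=int(row.end), pk_cut_site=int(row.cut_site),
            log2_ratio=float(row.log2_ratio), timepoint=str(row.timepoint),
            significant=bool(row.significant)))
    return peps


def _cut_window(site: int, n_res: int, half: int) -> np.ndarray:
    lo, hi = max(1, site - half), min(n_res, site + half)
    return np.arange(lo, hi + 1)


def _entangle_region(record, coords: np.ndarray, residue_ids: np.ndarray,
                     radius: float) -> np.ndarray:
    """Residue ids within ``radius`` Å (Cα) of any crossing residue."""
    crossings = list(record.crossings_n) + list(record.crossings_c)
    if not crossings:
        raise ValueError("entanglement record has no crossing residues")
    id_to_pos = {int(r): k for k, r in enumerate(residue_ids)}
    sel = np.zeros(len(coords), dtype=bool)
    for c in crossings:
        if c not in id_to_pos:
            raise ValueError(f"crossing residue {c} absent from structure")
        d = np.linalg.norm(coords - coords[id_to_pos[c]], axis=1)
        sel |= d <= radius
    return residue_ids[sel]


def overlap_matrix(entanglements, peptides, structure,
                   cut_window: int = 5, crossing_radius: float = 8.0):
    """Binary overlap matrix O (N_e x N_l) via the Jaccard index.

    For peptide l, the residue set is the PK cut site ±``cut_window``
    residues; for entanglement e, the residues within ``crossing_radius``
    Å of any crossing residue in ``structure``.  O = 1 iff J > 0.
    Only significant peptides should be passed in.
    """
    coords, rids = structure.coords, structure.residue_ids
    n_res = len(coords)
    regions = [set(map(int, _entangle_region(e, coords, rids,
                                             crossing_radius)))
               for e in entanglements]
    O = np.zeros((len(entanglements), len(peptides)), dtype=int)
    jaccard = np.zeros_like(O, dtype=float)
    for l, pep in enumerate(peptides):
        win = set(map(int, _cut_window(pep.pk_cut_site, n_res, cut_window)))
        for e, region in enumerate(regions):
            inter = len(win & region)
            union = len(win | region)
            jaccard[e, l] = inter / union if union else 0.0
            O[e, l] = 1 if jaccard[e, l] > 0 else 0
    return O, jaccard


def sign_matrix(O: np.ndarray, delta_sasa_sim, log2_ratios) -> np.ndarray:
    """Sign-agreement matrix S, gated by O.

    ``delta_sasa_sim`` is the simulated mean change in solvent exposure of
    the cut-site region, either per peptide (shape ``(N_l,)``) or per
    (entanglement, peptide) pair (shape ``(N_e, N_l)``).  S = 1 only where
    O = 1 and the signs strictly agree; a zero on either side never
    counts as agreement.
    """
    O = np.asarray(O)
    ratios = np.asarray(log2_ratios, dtype=float)
    ds = np.asarray(delta_sasa_sim, dtype=float)
    if ds.ndim == 1:
        ds = np.broadcast_to(ds, O.shape)
    if ds.shape != O.shape:
        raise ValueError("delta_sasa_sim shape incompatible with O")
    if np.any(np.isnan(ds[O == 1])):
        raise ValueError("missing delta SASA where overlap exists")
    agree = (np.sign(ds) == np.sign(ratios)[None, :]) & (np.sign(ds) != 0)
    return (O == 1) & agree


def consistency_stats(O: np.ndarray, S: np.ndarray,
                      timepoints) -> tuple[dict, dict]:
    """Per-timepoint means of O and S over the peptides of that timepoint."""
    O = np.asarray(O)
    S = np.asarray(S)
    if O.size == 0 or S.size == 0:
        raise ValueError("empty consistency matrices")
    timepoints = np.asarray(timepoints)
    o_stat, s_stat = {}, {}
    for tp in dict.fromkeys(timepoints.tolist()):  # preserve order
        cols = timepoints == tp
        o_stat[tp] = float(np.mean(O[:, cols]))
        s_stat[tp] = float(np.mean(S[:, cols]))
    return o_stat, s_stat


def build_cutsite_model(observed_cut_types, proteome_composition,
                        length_trypsin_prob: dict | None = None
                        ) -> CutSiteModel:
    """Intrinsic PK cutting propensity per residue type.

    ``p_intrinsic(AA) = p_observed(AA) / p_proteome(AA)``; residue types
    with zero proteome frequency are excluded with a warning rather than
    producing infinities.
    """
    observed = list(observed_cut_types)
    if not observed:
        raise ValueError("no observed cut sites")
    comp = dict(proteome_composition)
    total_comp = float(sum(comp.values()))
    if total_comp <= 0:
        raise ValueError("proteome composition must have positive mass")
    p_proteome = {aa: v / total_comp for aa, v in comp.items()}
    counts: dict = {}
    for aa in observed:
        counts[aa] = counts.get(aa, 0) + 1
    p_observed = {aa: c / len(observed) for aa, c in counts.items()}
    p_intrinsic, excluded = {}, []
    for aa, po in p_observed.items():
        pp = p_proteome.get(aa, 0.0)
        if pp == 0.0:
            excluded.append(aa)
            continue
        p_intrinsic[aa] = po / pp
    if excluded:
        warnings.warn(f"residue types absent from proteome excluded: "
                      f"{sorted(excluded)}")
    return CutSiteModel(p_intrinsic=p_intrinsic, p_observed=p_observed,
                        p_proteome=p_proteome,
                        length_trypsin_prob=length_trypsin_prob or {},
                        excluded=excluded)


TRYPSIN_RESIDUES = ("K", "R")


def enumerate_half_tryptic(sequence: str) -> pd.DataFrame:
    """All potential half-tryptic peptides of a sequence.

    A PK cut after residue c pairs with the nearest downstream or upstream
    trypsin site (after K/R), yielding up to two candidate peptides per
    cut position.  Returns columns cut_site (1-based residue whose C-side
    is cut), start, end, length, n_internal_trypsin, cut_type (residue
    type at the cut site).
    """
    seq = sequence.upper()
    n = len(seq)
    tryp = [i for i, aa in enumerate(seq, start=1) if aa in TRYPSIN_RESIDUES]
    rows = []
    for c in range(1, n):  # cut between c and c+1
        downstream = next((t for t in tryp if t > c), None)
        if downstream is not None:
            start, end = c + 1, downstream
            internal = sum(1 for t in tryp if start <= t < end)
            rows.append((c, start, end, end - start + 1, internal, seq[c - 1]))
        upstream = next((t for t in reversed(tryp) if t <= c), None)
        if upstream is not None and upstream != c:
            start, end = upstream + 1, c
            internal = sum(1 for t in tryp if start <= t < end)
            rows.append((c, start, end, end - start + 1, internal, seq[c - 1]))
    return pd.DataFrame(rows, columns=["cut_site", "start", "end", "length",
                                       "n_internal_trypsin", "cut_type"])


def _candidate_probs(candidates: pd.DataFrame, model: CutSiteModel):
    """Acceptance probabilities for each candidate peptide.

    Intrinsic propensities are ratios, not probabilities; they are scaled
    by their maximum so the largest becomes acceptance probability 1.
    """
    p_int = np.array([model.p_intrinsic.get(aa, 0.0)
                      for aa in candidates["cut_type"]])
    if p_int.max() > 0:
        p_site = p_int / p_int.max()
    else:
        p_site = p_int
    if model.length_trypsin_prob:
        p_len = np.array([model.length_trypsin_prob.get((l, k), 0.0)
                          for l, k in zip(candidates["length"],
                                          candidates["n_internal_trypsin"])])
        if p_len.max() > 0:
            p_len = p_len / p_len.max()
    else:
        p_len = np.ones(len(candidates))
    return p_site, p_len


def sample_random_cutsites(model: CutSiteModel, sequence: str,
                           n_sites: int, seed=None,
                           max_draws: int = 1_000_000) -> np.ndarray:
    """Random significant cut-site set by rejection sampling.

    Candidate peptides are drawn uniformly with replacement; a draw is
    accepted when two independent uniforms fall below the candidate's
    intrinsic cut probability and its length/trypsin-count probability.
    Accepted peptides accumulate into a set of unique PK cut sites until
    ``n_sites`` are collected.  Deterministic under a fixed seed.
    """
    candidates = enumerate_half_tryptic(sequence)
    if len(candidates) == 0:
        raise ValueError("sequence yields no half-tryptic candidates")
    p_site, p_len = _candidate_probs(candidates, model)
    if np.all(p_site * p_len == 0):
        raise ValueError("all candidate acceptance probabilities are zero")
    n_avail = candidates["cut_site"].nunique()
    if n_sites > n_avail:
        raise ValueError(f"requested {n_sites} sites but only {n_avail} "
                         "candidate cut sites exist")
    rng = np.random.default_rng(seed)
    sites: list[int] = []
    seen: set[int] = set()
    cut_sites = candidates["cut_site"].to_numpy()
    for _ in range(max_draws):
        k = rng.integers(len(candidates))
        u1, u2 = rng.random(), rng.random()
        if u1 < p_site[k] and u2 < p_len[k]:
            c = int(cut_sites[k])
            if c not in seen:
                seen.add(c)
                sites.append(c)
                if len(sites) == n_sites:
                    return np.array(sites)
    raise RuntimeError("rejection sampling did not reach the requested "
                       "number of unique cut sites")


def _site_weights(candidates: pd.DataFrame, model: CutSiteModel):
    """Aggregate acceptance weight per unique cut site.

    Drawing candidates with replacement and keeping first-seen cut sites
    is distributionally identical to weighted sampling of sites without
    replacement, with each site weighted by the summed acceptance
    probability of its candidate peptides.
    """
    p_site, p_len = _candidate_probs(candidates, model)
    w = p_site * p_len
    sites = candidates["cut_site"].to_numpy()
    uniq = np.unique(sites)
    agg = np.zeros(len(uniq))
    pos = {s: i for i, s in enumerate(uniq)}
    for s, wi in zip(sites, w):
        agg[pos[s]] += wi
    keep = agg > 0
    return uniq[keep], agg[keep]


def _gumbel_topk(weights: np.ndarray, k: int, rng) -> np.ndarray:
    """Indices of a weighted sample of size k without replacement."""
    g = np.log(weights) + rng.gumbel(size=len(weights))
    return np.argpartition(-g, k - 1)[:k]


def permutation_pvalue(o_stat: dict, s_stat: dict, site_overlap: np.ndarray,
                       site_sign: np.ndarray, model: CutSiteModel,
                       sequence: str, peptides, longest_timepoint: str,
                       n_perm: int = 10000, seed=None,
                       shared_sets: bool = False) -> ConsistencyResult:
    """Permutation p-value for the observed consistency statistics.

    For each permutation, a random set of PK cut sites is drawn per
    timepoint from the theoretical half-tryptic distribution, matching
    the observed number of unique cut sites at that timepoint; random
    sites inherit the observed peptides' log2-ratio signs.  The draw
    counts as "more consistent" when its <O>'_t and <S>'_t strictly
    exceed the observed values at two or more timepoints, one of which is
    the longest.  p = (# more-consistent permutations) / n_perm, with no
    continuity correction.

    Parameters
    ----------
    site_overlap : (N_e, L) bool
        Precomputed overlap indicator for every possible cut site 1..L.
    site_sign : (N_e, L) float
        Sign of the simulated exposure change of the cut-site region.
    shared_sets : bool
        Reuse one random set across timepoints within a permutation
        (alternative reading of the sampling rule); default redraws per
        timepoint.
    """
    timepoints = list(o_stat)
    if len(timepoints) < 2:
        raise ValueError("the exceedance rule needs at least 2 timepoints")
    if longest_timepoint not in timepoints:
        raise ValueError("longest_timepoint not among the declared ones")
    if n_perm < 1000:
        raise ValueError("n_perm must be at least 1000")
    rng = np.random.default_rng(seed)
    candidates = enumerate_half_tryptic(sequence)
    sites, weights = _site_weights(candidates, model)
    site_idx = sites - 1  # 1-based residue -> column index

    tp_of = [p.timepoint for p in peptides]
    obs_signs = {tp: np.sign([p.log2_ratio for p in peptides
                              if p.timepoint == tp]) for tp in timepoints}
    n_sites_tp = {tp: len(np.unique([p.pk_cut_site for p in peptides
                                     if p.timepoint == tp]))
                  for tp in timepoints}
    n_e = site_overlap.shape[0]

    count = 0
    for _ in range(n_perm):
        shared = None
        if shared_sets:
            k = max(n_sites_tp.values())
            shared = site_idx[_gumbel_topk(weights, k, rng)]
        wins = 0
        longest_wins = False
        for tp in timepoints:
            k = n_sites_tp[tp]
            if k == 0:
                continue
            if shared is not None:
                draw = shared[:k]
            else:
                draw = site_idx[_gumbel_topk(weights, k, rng)]
            signs = obs_signs[tp]
            if len(signs) != k:  # peptides sharing a cut site: subsample
                signs = rng.choice(signs, size=k, replace=False) \
                    if len(signs) > k else np.resize(signs, k)
            O_cols = site_overlap[:, draw]
            S_cols = O_cols & (site_sign[:, draw] == signs[None, :]) \
                & (site_sign[:, draw] != 0)
            o_prime = float(np.mean(O_cols))
            s_prime = float(np.mean(S_cols))
            if o_prime > o_stat[tp] and s_prime > s_stat[tp]:
                wins += 1
                if tp == longest_timepoint:
                    longest_wins = True
        if wins >= 2 and longest_wins:
            count += 1
    p = count / n_perm
    return ConsistencyResult(O=np.empty((n_e, 0)), S=np.empty((n_e, 0)),
                             o_stat=o_stat, s_stat=s_stat, p_value=p,
                             n_perm=n_perm, n_more_consistent=count)


def site_lookup_tables(entanglements, structure, delta_sasa_per_residue,
                       cut_window: int = 5, crossing_radius: float = 8.0):
    """Precompute, for every possible cut site, the overlap indicator and
    exposure-change sign against each entanglement.

    Returns ``(site_overlap, site_sign)`` of shape (N_e, L).  The sign is
    that of the mean per-residue SASA change over the cut-site window
    (misfolded minus native), shared across entanglements when a 1-D
    ``delta_sasa_per_residue`` is given.
    """
    coords, rids = structure.coords, structure.residue_ids
    n_res = len(coords)
    ds = np.asarray(delta_sasa_per_residue, dtype=float)
    regions = [set(map(int, _entangle_region(e, coords, rids,
                                             crossing_radius)))
               for e in entanglements]
    overlap = np.zeros((len(entanglements), n_res), dtype=bool)
    sign = np.zeros((len(entanglements), n_res))
    for site in range(1, n_res + 1):
        win = _cut_window(site, n_res, cut_window)
        win_set = set(map(int, win))
        mean_ds = float(np.mean(ds[win - 1]))
        for e, region in enumerate(regions):
            overlap[e, site - 1] = bool(win_set & region)
            sign[e, site - 1] = np.sign(mean_ds)
    return overlap, sign
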