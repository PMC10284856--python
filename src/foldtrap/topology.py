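"""Native-contact and lasso-entanglement analysis of Cα structures.

A non-covalent lasso entanglement is a backbone loop, closed by a native
contact (i, j), threaded by an N- or C-terminal tail segment.  The degree
of threading is quantified by the Gauss double integral between the closed
loop and the tail, discretized over segment pairs.  For a native contact
(i, j) the total linking number g(i, j) is the sum of the N-tail and
C-tail partial linking numbers, rounded to the nearest integer (half away
from zero).  The entanglement metric

    G = (1/N) * sum_{(i,j)} Theta((i,j) in nc  and  g(i,j) != g_native(i,j))

counts, over the N native contacts, those formed in the current structure
(set nc) whose rounded linking number differs from the native structure's.
G in [0, 1]; larger G means more residues changed entanglement status.

The module also provides the fraction of native contacts Q, its windowed
mode Q_mode used to classify long-lived misfolded trajectories, crossing
-residue localization, clustering of degenerate entanglement changes, and
Shrake-Rupley solvent accessibility for Cα bead models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CalphaStructure",
    "NativeContactMap",
    "EntanglementRecord",
    "native_contacts",
    "q",
    "q_mode",
    "gauss_double_sum",
    "linking_number",
    "g_metric",
    "crossing_residues",
    "cluster_entanglements",
    "sasa",
    "delta_sasa",
    "round_half_away",
]


def round_half_away(x) -> np.ndarray | int:
    """Nearest integer, halves away from zero (so 0.5 -> 1, -0.5 -> -1)."""
    arr = np.sign(x) * np.floor(np.abs(x) + 0.5)
    if np.isscalar(x):
        return int(arr)
    return arr.astype(int)


@dataclass
class CalphaStructure:
    """One Cα bead per residue, single chain.

    ``residue_ids`` are 1-based and preserved from the source file (gaps
    are kept, never renumbered).  Physical chains must have consecutive
    Cα-Cα distances in 2.0-5.0 Å; toy geometries set ``synthetic=True``.
    """

    coords: np.ndarray
    residue_ids: np.ndarray | None = None
    ss_mask: np.ndarray | None = None
    synthetic: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.residue_ids is None:
            self.residue_ids = np.arange(1, len(self.coords) + 1)
        else:
            self.residue_ids = np.asarray(self.residue_ids, dtype=int)
            if len(self.residue_ids) != len(self.coords):
                raise ValueError("residue_ids length mismatch")
        if not self.synthetic and len(self.coords) > 1:
            d = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
            if np.any((d < 2.0) | (d > 5.0)):
                raise ValueError(
                    "consecutive Cα distances outside 2.0-5.0 Å; "
                    "pass synthetic=True for toy geometries")

    @property
    def n_res(self) -> int:
        return len(self.coords)


@dataclass
class NativeContactMap:
    """Native contact pairs as positions into the coordinate array."""

    pairs: np.ndarray        # (M, 2) int, array positions, i < j
    distances: np.ndarray    # native Cα distances
    ss_restricted: bool = False

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int)
        self.distances = np.asarray(self.distances, dtype=float)
        if len(self.pairs) == 0:
            raise ValueError("empty native contact map")
        if np.any(self.distances <= 0):
            raise ValueError("native distances must be positive")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class EntanglementRecord:
    """One native contact whose linking state differs from native."""

    contact: tuple           # residue ids (i, j)
    g_native: int
    g_current: int
    partial_n_raw: float
    partial_c_raw: float
    partial_n: int
    partial_c: int
    native_partial_n: int = 0
    native_partial_c: int = 0
    crossings_n: list = field(default_factory=list)  # residue ids
    crossings_c: list = field(default_factory=list)
    change_n: str = "none"   # {none, gain, loss, switch}
    change_c: str = "none"
    loop_length: int = 0

    def cluster_key(self) -> tuple:
        """The 6 discrete clustering parameters: crossing counts, rounded
        partial linking numbers, and change types for each tail."""
        return (len(self.crossings_n), len(self.crossings_c),
                self.partial_n, self.partial_c,
                self.change_n, self.change_c)


def native_contacts(native: CalphaStructure, cutoff: float = 8.0,
                    min_separation: int = 4,
                    ss_mask: np.ndarray | None = None) -> NativeContactMap:
    """Contacts = Cα pairs within ``cutoff`` Å and at least
    ``min_separation`` residues apart in sequence.  When a secondary
    -structure mask is supplied (boolean per residue), both partners must
    be inside it."""
    x = native.coords
    n = len(x)
    mask = ss_mask if ss_mask is not None else native.ss_mask
    ii, jj = np.triu_indices(n, k=min_separation)
    d = np.linalg.norm(x[ii] - x[jj], axis=1)
    keep = d <= cutoff
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        keep &= mask[ii] & mask[jj]
    if not np.any(keep):
        raise ValueError("no native contacts under the given criteria")
    pairs = np.column_stack([ii[keep], jj[keep]])
    return NativeContactMap(pairs=pairs, distances=d[keep],
                            ss_restricted=mask is not None)


def q(frame: CalphaStructure, cmap: NativeContactMap,
      tolerance_factor: float = 1.2) -> float:
    """Fraction of native contacts formed: a contact counts as formed when
    its current distance is within ``tolerance_factor`` times the native
    distance."""
    if frame.n_res <= int(cmap.pairs.max()):
        raise ValueError("frame shorter than the native contact map")
    d = np.linalg.norm(frame.coords[cmap.pairs[:, 0]]
                       - frame.coords[cmap.pairs[:, 1]], axis=1)
    return float(np.mean(d <= tolerance_factor * cmap.distances))


def q_mode(q_values, window: int, n_contacts: int,
           reference: float | None = None):
    """Windowed mode of Q and the long-lived-misfold verdict.

    Q is binned so that each formable-contact count is its own bin (bin
    width ``1/n_contacts``); the mode of each sliding window (stride 1
    frame) is the center of the most occupied bin, ties resolved toward
    higher Q.  With a native-ensemble reference ``<Q_mode^NS>``, a
    trajectory is "long-lived misfolded" iff no window mode ever reaches
    the reference.

    Returns ``(modes, verdict)``; ``verdict`` is None without a reference.
    """
    qv = np.asarray(q_values, dtype=float)
    if window > len(qv):
        raise ValueError("window longer than the series")
    if window < 1 or n_contacts < 1:
        raise ValueError("window and n_contacts must be positive")
    bins = np.rint(qv * n_contacts).astype(int)
    modes = np.empty(len(qv) - window + 1)
    for s in range(len(modes)):
        counts = np.bincount(bins[s:s + window], minlength=n_contacts + 1)
        best = np.flatnonzero(counts == counts.max())[-1]  # tie: higher Q
        modes[s] = best / n_contacts
    verdict = None
    if reference is not None:
        verdict = ("long-lived misfolded" if np.max(modes) < reference
                   else "folded")
    return modes, verdict


def gauss_double_sum(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Discretized Gauss linking integral between two polygonal curves.

    Uses the midpoint rule over all segment pairs::

        g = 1/(4 pi) sum_i sum_j (Ra_i - Rb_j) . (dRa_i x dRb_j) / |Ra_i - Rb_j|^3

    where ``Ra_i`` are segment midpoints and ``dRa_i`` bond vectors.
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    da = np.diff(a, axis=0)
    db = np.diff(b, axis=0)
    if np.any(np.linalg.norm(da, axis=1) == 0) or \
       np.any(np.linalg.norm(db, axis=1) == 0):
        raise ValueError("zero-length segment")
    ma = (a[:-1] + a[1:]) / 2.0
    mb = (b[:-1] + b[1:]) / 2.0
    rv = ma[:, None, :] - mb[None, :, :]
    dist3 = np.linalg.norm(rv, axis=2) ** 3
    if np.any(dist3 == 0):
        raise ValueError("coincident segment midpoints")
    cross = np.cross(da[:, None, :], db[None, :, :])
    return float(np.sum(np.einsum("ijk,ijk->ij", rv, cross) / dist3)
                 / (4.0 * math.pi))


def _per_segment_contrib(loop: np.ndarray, thread: np.ndarray) -> np.ndarray:
    """Gauss contribution of each thread segment summed over the loop."""
    da = np.diff(loop, axis=0)
    db = np.diff(thread, axis=0)
    ma = (loop[:-1] + loop[1:]) / 2.0
    mb = (thread[:-1] + thread[1:]) / 2.0
    rv = ma[:, None, :] - mb[None, :, :]
    dist3 = np.linalg.norm(rv, axis=2) ** 3
    cross = np.cross(da[:, None, :], db[None, :, :])
    contrib = np.einsum("ijk,ijk->ij", rv, cross) / dist3
    return contrib.sum(axis=0) / (4.0 * math.pi)


def linking_number(loop: np.ndarray, thread: np.ndarray,
                   close_loop: bool = True) -> tuple[float, int]:
    """Raw and rounded linking number between a contact-closed loop and a
    tail.  ``close_loop`` appends the straight virtual segment joining the
    loop's last point back to its first (the native-contact closure)."""
    loop = np.asarray(loop, dtype=float)
    thread = np.asarray(thread, dtype=float)
    if len(loop) < 3:
        raise ValueError("loop needs at least 3 points")
    if len(thread) < 2:
        raise ValueError("thread needs at least 1 segment")
    if close_loop and np.linalg.norm(loop[0] - loop[-1]) > 1e-12:
        loop = np.vstack([loop, loop[0]])
    raw = gauss_double_sum(loop, thread)
    return raw, round_half_away(raw)


def _closed_loop(coords: np.ndarray, i: int, j: int) -> np.ndarray:
    seg = coords[i:j + 1]
    return np.vstack([seg, seg[0]])


def _tails(coords: np.ndarray, i: int, j: int, tail_exclusion: int):
    """N- and C-terminal tail point sets for contact (i, j); the
    ``tail_exclusion`` residues adjacent to each loop terminus are skipped
    to suppress spurious near-loop contributions."""
    n_end = i - tail_exclusion          # first excluded position is i-5
    n_tail = coords[:n_end] if n_end >= 2 else coords[:0]
    c_start = j + tail_exclusion + 1    # last excluded position is j+5
    c_tail = coords[c_start:] if c_start <= len(coords) - 2 else coords[:0]
    return n_tail, c_tail


def contact_linking(coords: np.ndarray, i: int, j: int,
                    tail_exclusion: int = 5):
    """Partial (N-tail, C-tail) and total linking numbers of contact
    (i, j) given full-chain coordinates (array positions)."""
    loop = _closed_loop(coords, i, j)
    n_tail, c_tail = _tails(coords, i, j, tail_exclusion)
    raw_n = gauss_double_sum(loop, n_tail) if len(n_tail) >= 2 else 0.0
    raw_c = gauss_double_sum(loop, c_tail) if len(c_tail) >= 2 else 0.0
    total_raw = raw_n + raw_c
    return raw_n, raw_c, total_raw, round_half_away(total_raw)


def _change_type(native_g: int, current_g: int) -> str:
    if native_g == current_g:
        return "none"
    if native_g == 0:
        return "gain"
    if current_g == 0:
        return "loss"
    return "switch"


def g_metric(frame: CalphaStructure, native: CalphaStructure,
             cmap: NativeContactMap, tolerance_factor: float = 1.2,
             tail_exclusion: int = 5):
    """Entanglement metric G and per-discordant-contact records.

    Only native contacts *formed* in the current structure enter the sum;
    the denominator is the total number of native contacts N.  For each
    discordant contact an :class:`EntanglementRecord` is emitted with
    partial linking numbers, crossing residues (localized on whichever
    structure carries the threading: current for a gain, native for a
    loss) and per-tail change types.
    """
    if frame.n_res != native.n_res:
        raise ValueError("frame and native chain lengths differ")
    xf, xn = frame.coords, native.coords
    d = np.linalg.norm(xf[cmap.pairs[:, 0]] - xf[cmap.pairs[:, 1]], axis=1)
    formed = d <= tolerance_factor * cmap.distances
    n_total = len(cmap)
    records = []
    n_changed = 0
    for (i, j), is_formed in zip(cmap.pairs, formed):
        if not is_formed:
            continue
        fn, fc, _, g_cur = contact_linking(xf, i, j, tail_exclusion)
        nn, nc_, _, g_nat = contact_linking(xn, i, j, tail_exclusion)
        if g_cur == g_nat:
            continue
        n_changed += 1
        pn, pc = round_half_away(fn), round_half_away(fc)
        npn, npc = round_half_away(nn), round_half_away(nc_)
        rec = EntanglementRecord(
            contact=(int(native.residue_ids[i]), int(native.residue_ids[j])),
            g_native=g_nat, g_current=g_cur,
            partial_n_raw=fn, partial_c_raw=fc,
            partial_n=pn, partial_c=pc,
            native_partial_n=npn, native_partial_c=npc,
            change_n=_change_type(npn, pn), change_c=_change_type(npc, pc),
            loop_length=int(j - i + 1))
        # crossing localization: use the structure that carries the thread
        for tail, part, nat_part in (("n", pn, npn), ("c", pc, npc)):
            use = xf if abs(part) >= abs(nat_part) else xn
            g_here = part if abs(part) >= abs(nat_part) else nat_part
            if g_here == 0:
                continue
            cr = _crossings_for_contact(use, i, j, tail, g_here,
                                        tail_exclusion,
                                        native.residue_ids)
            if tail == "n":
                rec.crossings_n = cr
            else:
                rec.crossings_c = cr
        records.append(rec)
    return n_changed / n_total, records


def _crossings_for_contact(coords, i, j, tail, g_rounded, tail_exclusion,
                           residue_ids):
    loop = _closed_loop(coords, i, j)
    n_tail, c_tail = _tails(coords, i, j, tail_exclusion)
    if tail == "n":
        pts, first = n_tail, 0
    else:
        pts, first = c_tail, j + tail_exclusion + 1
    if len(pts) < 2:
        return []
    contrib = _per_segment_contrib(loop, pts)
    order = np.argsort(-np.sign(g_rounded) * contrib)
    picks = sorted(order[:abs(g_rounded)])
    return [int(residue_ids[first + p]) for p in picks]


def crossing_residues(loop: np.ndarray, thread: np.ndarray,
                      thread_residue_ids=None,
                      close_loop: bool = True) -> list[int]:
    """Thread residues piercing the loop, one per unit of linking.

    The residues returned are those whose segments carry the dominant
    per-segment Gauss contributions (an approximation to the loop-surface
    piercing test used with triangulated minimal surfaces).  Raises on an
    unlinked pair.
    """
    loop = np.asarray(loop, dtype=float)
    thread = np.asarray(thread, dtype=float)
    if close_loop and np.linalg.norm(loop[0] - loop[-1]) > 1e-12:
        loop = np.vstack([loop, loop[0]])
    raw = gauss_double_sum(loop, thread)
    g = round_half_away(raw)
    if g == 0:
        raise ValueError("crossing_residues called on an unlinked pair")
    if thread_residue_ids is None:
        thread_residue_ids = list(range(len(thread)))
    contrib = _per_segment_contrib(loop, thread)
    order = np.argsort(-np.sign(g) * contrib)
    picks = sorted(order[:abs(g)])
    return [int(thread_residue_ids[p]) for p in picks]


def cluster_entanglements(records: list[EntanglementRecord],
                          residue_window: int = 5):
    """Merge degenerate entanglement changes and pick representatives.

    Records sharing all six discrete clustering parameters *and* whose
    crossing residues all lie within ``±residue_window`` of each other are
    merged (transitively).  Each cluster's representative is the record
    with the minimal loop length, ties broken by the smaller loop start.

    Returns ``(clusters, representatives)`` where ``clusters`` is a list
    of record lists.
    """
    if not records:
        raise ValueError("no records to cluster")

    def near(a: EntanglementRecord, b: EntanglementRecord) -> bool:
        for ca, cb in ((a.crossings_n, b.crossings_n),
                       (a.crossings_c, b.crossings_c)):
            if len(ca) != len(cb):
                return False
            if any(abs(x - y) > residue_window
                   for x, y in zip(sorted(ca), sorted(cb))):
                return False
        return True

    parent = list(range(len(records)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in range(len(records)):
        for b in range(a + 1, len(records)):
            if records[a].cluster_key() == records[b].cluster_key() \
                    and near(records[a], records[b]):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra

    groups: dict[int, list[EntanglementRecord]] = {}
    for idx, rec in enumerate(records):
        groups.setdefault(find(idx), []).append(rec)
    clusters = list(groups.values())
    reps = [min(c, key=lambda r: (r.loop_length, r.contact[0]))
            for c in clusters]
    return clusters, reps


def _sphere_points(n: int) -> np.ndarray:
    """Golden-spiral quasi-uniform points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(coords, radii, probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Shrake-Rupley solvent-accessible surface area per residue (Å^2).

    Each bead's accessible sphere (radius ``r_i + probe``) is sampled with
    ``n_points`` quasi-uniform points; points falling inside any other
    bead's accessible sphere are buried.
    """
    if probe < 0:
        raise ValueError("probe radius must be nonnegative")
    x = np.asarray(coords, dtype=float)
    r = np.asarray(radii, dtype=float)
    if len(r) != len(x):
        raise ValueError("one radius per residue required")
    pts = _sphere_points(n_points)
    expanded = r + probe
    areas = np.empty(len(x))
    for i in range(len(x)):
        surface = x[i] + expanded[i] * pts
        free = np.ones(n_points, dtype=bool)
        for j in range(len(x)):
            if j == i:
                continue
            d2 = np.sum((surface - x[j]) ** 2, axis=1)
            free &= d2 > expanded[j] ** 2
        areas[i] = 4.0 * math.pi * expanded[i] ** 2 * np.mean(free)
    return areas


def delta_sasa(coords_a, coords_b, radii, probe: float = 1.4,
               n_points: int = 960) -> np.ndarray:
    """Per-residue SASA difference (structure A minus structure B)."""
    return (sasa(coords_a, radii, probe, n_points)
            - sasa(coords_b, radii, probe, n_points))


def hydrophobic_sasa(areas, hydrophobic_mask) -> float:
    """Subtotal of per-residue areas over a hydrophobic-residue mask."""
    return float(np.sum(np.asarray(areas)[np.asarray(hydrophobic_mask,
                                                     dtype=bool)]))
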