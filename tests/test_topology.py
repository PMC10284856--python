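"""Native contacts, Q/Q_mode, linking numbers, G, clustering, SASA."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from foldtrap.topology import (CalphaStructure, EntanglementRecord,
                               cluster_entanglements, crossing_residues,
                               delta_sasa, g_metric, linking_number,
                               native_contacts, q, q_mode, round_half_away,
                               sasa)

from conftest import dense_gauss_oracle


def line_structure(n, spacing=3.8):
    coords = np.column_stack([spacing * np.arange(n), np.zeros(n),
                              np.zeros(n)])
    return CalphaStructure(coords=coords, synthetic=True)


class TestNativeContacts:
    def test_cutoff_and_separation(self):
        coords = np.zeros((6, 3))
        coords[:, 0] = [0.0, 100.0, 200.0, 300.0, 400.0, 7.9]
        s = CalphaStructure(coords=coords, synthetic=True)
        cmap = native_contacts(s, cutoff=8.0, min_separation=4)
        assert cmap.pairs.tolist() == [[0, 5]]

    def test_short_separation_excluded(self):
        coords = np.zeros((6, 3))
        coords[:, 0] = [0.0, 100.0, 200.0, 7.0, 300.0, 400.0]
        s = CalphaStructure(coords=coords, synthetic=True)
        # (0, 3) is within 8 Å but |i-j| = 3 < 4
        with pytest.raises(ValueError):
            native_contacts(s, cutoff=8.0, min_separation=4)

    def test_mask_can_empty_the_map(self):
        coords = np.zeros((6, 3))
        coords[:, 0] = [0.0, 100.0, 200.0, 300.0, 400.0, 7.9]
        s = CalphaStructure(coords=coords, synthetic=True)
        mask = np.array([True, True, True, True, True, False])
        with pytest.raises(ValueError):
            native_contacts(s, cutoff=8.0, min_separation=4, ss_mask=mask)


class TestQ:
    def test_native_frame_scores_one(self, two_loop_native):
        cmap = native_contacts(two_loop_native)
        assert q(two_loop_native, cmap) == 1.0

    def test_extended_chain_scores_zero(self, two_loop_native):
        cmap = native_contacts(two_loop_native)
        frame = line_structure(two_loop_native.n_res)
        assert q(frame, cmap) == 0.0

    def test_half_displaced_contacts(self):
        # two parallel rows with four rung contacts; displace two rungs
        coords = np.zeros((8, 3))
        coords[:4, 0] = 20.0 * np.arange(4)
        coords[4:, 0] = 20.0 * np.arange(4)
        coords[4:, 1] = 7.5
        native = CalphaStructure(coords=coords, synthetic=True)
        cmap = native_contacts(native)
        assert len(cmap) == 4
        displaced = coords.copy()
        displaced[[6, 7], 2] += 50.0
        frame = CalphaStructure(coords=displaced, synthetic=True)
        assert q(frame, cmap) == 0.5

    def test_monotone_under_progressive_displacement(self, two_loop_native):
        cmap = native_contacts(two_loop_native)
        values = []
        for dz in (0.0, 30.0):
            coords = two_loop_native.coords.copy()
            if dz:
                coords[cmap.pairs[0][1]] += np.array([0.0, 0.0, dz])
            values.append(q(CalphaStructure(coords=coords, synthetic=True),
                           cmap))
        assert values[0] >= values[1]


class TestQMode:
    def test_constant_series_below_reference_is_long_lived(self):
        modes, verdict = q_mode([0.8] * 30, window=10, n_contacts=10,
                                reference=0.92)
        assert np.all(modes == 0.8)
        assert verdict == "long-lived misfolded"

    def test_reaching_reference_is_folded(self):
        series = [0.6] * 10 + [0.95] * 15
        _, verdict = q_mode(series, window=10, n_contacts=20,
                            reference=0.92)
        assert verdict == "folded"

    def test_bimodal_window_takes_majority_bin(self):
        series = [0.9] * 7 + [0.6] * 3
        modes, _ = q_mode(series, window=10, n_contacts=10)
        assert modes[0] == pytest.approx(0.9)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            q_mode([0.5] * 5, window=6, n_contacts=10)


class TestLinkingNumber:
    def test_toy_circle_matches_dense_quadrature(self, toy_pair):
        loop = toy_pair.loop("misfolded")
        thread = toy_pair.thread("misfolded")
        raw, g = linking_number(loop, thread)
        oracle = dense_gauss_oracle(np.vstack([loop, loop[0]]), thread)
        assert g == 1
        assert abs(raw - oracle) < 0.05

    def test_outside_thread_is_unlinked(self, toy_pair):
        raw, g = linking_number(toy_pair.loop("native"),
                                toy_pair.thread("native"))
        assert g == 0
        assert abs(raw) < 0.1

    def test_rigid_rotation_invariance(self, toy_pair):
        loop, thread = toy_pair.loop("misfolded"), toy_pair.thread("misfolded")
        raw0, _ = linking_number(loop, thread)
        R = Rotation.from_euler("xyz", [0.3, 1.1, -0.7]).as_matrix()
        shift = np.array([10.0, -4.0, 2.0])
        raw1, _ = linking_number(loop @ R.T + shift, thread @ R.T + shift)
        assert abs(raw1 - raw0) < 1e-9

    def test_zero_length_segment_rejected(self):
        loop = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0], [0, 1, 0]],
                        dtype=float)
        with pytest.raises(ValueError):
            linking_number(loop, np.array([[5, 5, -5], [5, 5, 5]],
                                          dtype=float))

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(0.5) == 1
        assert round_half_away(-0.5) == -1
        assert round_half_away(0.49) == 0
        assert np.array_equal(round_half_away(np.array([1.5, -1.5, 0.2])),
                              [2, -2, 0])


class TestGMetric:
    def test_native_self_comparison_is_zero(self, two_loop_native):
        cmap = native_contacts(two_loop_native)
        g, records = g_metric(two_loop_native, two_loop_native, cmap)
        assert g == 0.0 and records == []

    def test_single_changed_contact_gives_one_over_n(self, two_loop_native,
                                                     two_loop_misfolded):
        cmap = native_contacts(two_loop_native)
        n = len(cmap)
        assert n >= 2
        g, records = g_metric(two_loop_misfolded, two_loop_native, cmap)
        assert g == pytest.approx(1.0 / n)
        assert len(records) == 1
        rec = records[0]
        assert abs(rec.g_current - rec.g_native) == 1
        assert rec.change_c == "gain" or rec.change_n == "gain"
        # the crossing must sit on the thread
        crossings = rec.crossings_n + rec.crossings_c
        assert len(crossings) == 1

    def test_rigid_motion_invariance_of_g(self, two_loop_native,
                                          two_loop_misfolded):
        cmap = native_contacts(two_loop_native)
        g0, _ = g_metric(two_loop_misfolded, two_loop_native, cmap)
        R = Rotation.from_euler("zxy", [1.0, 0.2, -0.5]).as_matrix()
        moved = CalphaStructure(
            coords=two_loop_misfolded.coords @ R.T + 7.0, synthetic=True)
        g1, _ = g_metric(moved, two_loop_native, cmap)
        assert g1 == g0

    def test_no_formed_contacts_gives_zero(self, two_loop_native):
        cmap = native_contacts(two_loop_native)
        frame = line_structure(two_loop_native.n_res)
        g, records = g_metric(frame, two_loop_native, cmap)
        assert g == 0.0 and records == []


class TestCrossingResidues:
    def test_toy_crossing_is_the_central_segment(self, toy_pair):
        thread = toy_pair.thread("misfolded")
        ids = list(range(100, 100 + len(thread)))
        picks = crossing_residues(toy_pair.loop("misfolded"), thread,
                                  thread_residue_ids=ids)
        # the piercing segment is the one crossing z = 0
        z = thread[:, 2]
        central = int(np.nonzero(np.diff(np.sign(z)) != 0)[0][0])
        assert picks == [100 + central]

    def test_double_threaded_loop_yields_two_crossings(self):
        # a dense polyline threading the loop twice in the same direction:
        # up through the centre, over the rim, back under, up again at x=4
        r = 12.0
        ang = 2 * math.pi * np.arange(24) / 24
        loop = np.column_stack([r * np.cos(ang), r * np.sin(ang),
                                np.zeros(24)])
        waypoints = np.array([
            [0.0, 0.0, -30.0], [0.0, 0.0, 30.0],
            [40.0, 0.0, 30.0], [40.0, 0.0, -30.0],
            [4.0, 0.0, -30.0], [4.0, 0.0, 30.0]])
        pieces = []
        for p, qp in zip(waypoints[:-1], waypoints[1:]):
            steps = int(np.linalg.norm(qp - p) / 3.0)
            pieces.append(p + np.linspace(0, 1, steps,
                                          endpoint=False)[:, None] * (qp - p))
        thread = np.vstack(pieces + [waypoints[-1:]])
        raw, g = linking_number(loop, thread)
        assert abs(g) == 2
        picks = crossing_residues(loop, thread)
        assert len(picks) == 2
        # one pick per piercing column, each adjacent to a z = 0 crossing
        # inside the loop
        for p in picks:
            assert abs(thread[p][2]) < 5.0 and abs(thread[p][0]) < 8.0

    def test_unlinked_pair_raises(self, toy_pair):
        with pytest.raises(ValueError):
            crossing_residues(toy_pair.loop("native"),
                              toy_pair.thread("native"))


class TestClustering:
    def make(self, crossings_n, loop_length, contact=(10, 40), **kw):
        defaults = dict(contact=contact, g_native=0, g_current=1,
                        partial_n_raw=1.0, partial_c_raw=0.0, partial_n=1,
                        partial_c=0, crossings_n=crossings_n, crossings_c=[],
                        change_n="gain", change_c="none",
                        loop_length=loop_length)
        defaults.update(kw)
        return EntanglementRecord(**defaults)

    def test_identical_records_merge(self):
        recs = [self.make([20], 30), self.make([20], 30)]
        clusters, reps = cluster_entanglements(recs)
        assert len(clusters) == 1 and len(reps) == 1

    def test_distant_crossings_stay_apart(self):
        recs = [self.make([20], 30), self.make([26], 30)]
        clusters, _ = cluster_entanglements(recs)
        assert len(clusters) == 2

    def test_representative_has_minimal_loop(self):
        recs = [self.make([20], 40), self.make([21], 25),
                self.make([22], 60)]
        _, reps = cluster_entanglements(recs)
        assert len(reps) == 1
        assert reps[0].loop_length == 25

    def test_different_parameters_never_merge(self):
        recs = [self.make([20], 30),
                self.make([20], 30, change_n="loss")]
        clusters, _ = cluster_entanglements(recs)
        assert len(clusters) == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_entanglements([])


class TestSasa:
    def test_isolated_bead_closed_form(self):
        r, w = 2.0, 1.4
        area = sasa(np.zeros((1, 3)), [r], probe=w, n_points=960)
        assert area[0] == pytest.approx(4 * math.pi * (r + w) ** 2,
                                        rel=0.01)

    def test_caged_bead_is_buried(self):
        # surround the centre bead with a dense shell
        from foldtrap.topology import _sphere_points
        cage = 3.0 * _sphere_points(80)
        coords = np.vstack([[0.0, 0.0, 0.0], cage])
        radii = np.full(len(coords), 2.0)
        areas = sasa(coords, radii, probe=1.4, n_points=480)
        assert areas[0] == pytest.approx(0.0, abs=1.0)

    def test_identical_structures_have_zero_delta(self):
        rng = np.random.default_rng(3)
        coords = np.cumsum(rng.normal(scale=3.0, size=(10, 3)), axis=0)
        d = delta_sasa(coords, coords, np.full(10, 2.0))
        assert np.all(d == 0)

    def test_negative_probe_rejected(self):
        with pytest.raises(ValueError):
            sasa(np.zeros((1, 3)), [2.0], probe=-0.1)
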