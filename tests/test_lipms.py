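"""O/S consistency statistics, cut-site model, permutation machinery."""

import numpy as np
import pytest

from foldtrap.lipms import (LipMsPeptide, build_cutsite_model,
                            consistency_stats, enumerate_half_tryptic,
                            overlap_matrix, permutation_pvalue,
                            sample_random_cutsites, sign_matrix,
                            site_lookup_tables)
from foldtrap.synthetic import gen_consistency_scenario
from foldtrap.topology import CalphaStructure, EntanglementRecord


def record(crossings_n, contact=(20, 45)):
    return EntanglementRecord(contact=contact, g_native=0, g_current=1,
                              partial_n_raw=1.0, partial_c_raw=0.0,
                              partial_n=1, partial_c=0,
                              crossings_n=crossings_n, crossings_c=[],
                              change_n="gain", loop_length=26)


def extended(n=120):
    coords = np.column_stack([3.8 * np.arange(n), np.zeros(n), np.zeros(n)])
    return CalphaStructure(coords=coords, synthetic=True)


def peptide(site, ratio=1.0, tp="T1"):
    return LipMsPeptide(protein_id="p", start=max(1, site - 3),
                        end=site + 4, pk_cut_site=site, log2_ratio=ratio,
                        timepoint=tp)


class TestOverlap:
    def test_adjacent_cut_and_crossing_overlap(self):
        # crossing 99: its 8 Å neighbourhood on a 3.8 Å-spaced chain spans
        # residues 97-101; cut-site window of 100 spans 95-105
        O, J = overlap_matrix([record([99], contact=(80, 110))],
                              [peptide(100)], extended(n=130))
        assert O[0, 0] == 1 and J[0, 0] > 0

    def test_disjoint_sets_do_not_overlap(self):
        O, _ = overlap_matrix([record([20])], [peptide(100)],
                              extended(n=130))
        assert O[0, 0] == 0

    def test_identical_sets_have_unit_jaccard(self):
        # crossing neighbourhood 18-22 equals the cut window of site 20
        # when the window is narrowed to ±2
        O, J = overlap_matrix([record([20])], [peptide(20)], extended(),
                              cut_window=2)
        assert J[0, 0] == 1.0 and O[0, 0] == 1

    def test_missing_crossings_rejected(self):
        rec = record([])
        with pytest.raises(ValueError):
            overlap_matrix([rec], [peptide(50)], extended())


class TestSignMatrix:
    def test_agreeing_signs_score_where_overlap(self):
        O = np.array([[1, 1, 0]])
        S = sign_matrix(O, [2.0, 3.0, 1.0], [0.5, -0.5, 0.7])
        assert S.astype(int).tolist() == [[1, 0, 0]]

    def test_zero_signs_never_agree(self):
        O = np.array([[1, 1]])
        S = sign_matrix(O, [0.0, 1.0], [0.5, 0.0])
        assert not S.any()

    def test_gating_blocks_sign_agreement(self):
        O = np.zeros((1, 2), dtype=int)
        S = sign_matrix(O, [1.0, 1.0], [1.0, 1.0])
        assert not S.any()

    def test_missing_delta_where_overlap_rejected(self):
        with pytest.raises(ValueError):
            sign_matrix(np.array([[1]]), [np.nan], [1.0])


class TestStats:
    def test_extremes_and_means(self):
        O = np.ones((2, 4), dtype=int)
        S = np.ones((2, 4), dtype=int)
        tps = ["T1", "T1", "T2", "T2"]
        o, s = consistency_stats(O, S, tps)
        assert o == {"T1": 1.0, "T2": 1.0} and s == o
        o, s = consistency_stats(np.zeros((2, 4)), np.zeros((2, 4)), tps)
        assert set(o.values()) == {0.0}
        half = np.array([[1, 0, 1, 0], [1, 0, 1, 0]])
        o, _ = consistency_stats(half, half, tps)
        assert o["T1"] == 0.5

    def test_gating_invariant_on_scenario(self):
        sc = gen_consistency_scenario(seed=0)
        O, _ = overlap_matrix(sc["records"], sc["peptides"],
                              sc["structure"])
        per_site = np.array([np.mean(
            sc["delta_sasa"][max(0, p.pk_cut_site - 6):p.pk_cut_site + 5])
            for p in sc["peptides"]])
        S = sign_matrix(O, per_site,
                        [p.log2_ratio for p in sc["peptides"]])
        assert np.all(S <= O)

    def test_empty_matrices_rejected(self):
        with pytest.raises(ValueError):
            consistency_stats(np.empty((0, 0)), np.empty((0, 0)), [])


class TestCutSiteModel:
    def test_equal_frequencies_give_unit_propensity(self):
        comp = {"A": 10, "K": 10}
        model = build_cutsite_model(list("AK" * 5), comp)
        assert model.p_intrinsic["A"] == pytest.approx(1.0)
        assert model.p_intrinsic["K"] == pytest.approx(1.0)

    def test_enriched_type_has_double_propensity(self):
        comp = {"A": 25, "G": 75}
        model = build_cutsite_model(list("A" * 5 + "G" * 5), comp)
        assert model.p_intrinsic["A"] == pytest.approx(2.0)

    def test_type_absent_from_proteome_excluded(self):
        with pytest.warns(UserWarning, match="excluded"):
            model = build_cutsite_model(["A", "W"], {"A": 1.0, "W": 0.0})
        assert "W" not in model.p_intrinsic
        assert model.excluded == ["W"]

    def test_empty_observed_set_rejected(self):
        with pytest.raises(ValueError):
            build_cutsite_model([], {"A": 1.0})


class TestSampling:
    def test_half_tryptic_enumeration_contract(self):
        df = enumerate_half_tryptic("AAKAAA")
        # every peptide is bounded by the trypsin site at position 3
        assert set(df["cut_site"]) <= set(range(1, 6))
        down = df[(df.cut_site == 1)]
        assert (down.start == 2).any() and (down.end == 3).any()

    def test_uniform_acceptance_returns_unique_sites(self):
        seq = "AK" * 30
        model = build_cutsite_model(list(seq), {"A": 1, "K": 1})
        sites = sample_random_cutsites(model, seq, n_sites=10, seed=0)
        assert len(sites) == len(set(sites)) == 10

    def test_sampling_follows_intrinsic_propensities(self):
        from scipy.stats import chisquare
        seq = "AKGK" * 20
        # A sites cut three times as often as G relative to abundance
        model = build_cutsite_model(list("A" * 3 + "G"), {"A": 1, "G": 1})
        counts = {"A": 0, "G": 0}
        for s in range(60):
            sites = sample_random_cutsites(model, seq, n_sites=6, seed=s)
            for site in sites:
                counts[seq[site - 1]] += 1
        # availability is equal, so expect 3:1 in favour of A
        total = counts["A"] + counts["G"]
        _, p = chisquare([counts["A"], counts["G"]],
                         [0.75 * total, 0.25 * total])
        assert p > 0.01

    def test_fixed_seed_reproducible(self):
        seq = "ARNDCEQGHILKMFPSTWYV" * 4
        model = build_cutsite_model(list(seq),
                                    {aa: 1 for aa in set(seq)})
        a = sample_random_cutsites(model, seq, n_sites=8, seed=42)
        b = sample_random_cutsites(model, seq, n_sites=8, seed=42)
        assert np.array_equal(a, b)

    def test_all_zero_acceptance_rejected(self):
        seq = "AK" * 10
        model = build_cutsite_model(list("K"), {"A": 1, "K": 1})
        model.p_intrinsic = {"A": 0.0, "K": 0.0}
        with pytest.raises(ValueError):
            sample_random_cutsites(model, seq, n_sites=2, seed=0)


class TestPermutation:
    def _setup(self, seed=0):
        sc = gen_consistency_scenario(seed=seed)
        tables = site_lookup_tables(sc["records"], sc["structure"],
                                    sc["delta_sasa"])
        return sc, tables

    def test_maximal_observed_stats_give_p_zero(self):
        sc, (ov, sg) = self._setup()
        ones = {tp: 1.0 for tp in sc["timepoints"]}
        res = permutation_pvalue(ones, dict(ones), ov, sg, sc["model"],
                                 sc["sequence"], sc["peptides"],
                                 sc["longest"], n_perm=1000, seed=1)
        assert res.p_value == 0.0

    def test_zero_observed_stats_give_p_near_one(self):
        sc, (ov, sg) = self._setup()
        zeros = {tp: 0.0 for tp in sc["timepoints"]}
        res = permutation_pvalue(zeros, dict(zeros), ov, sg, sc["model"],
                                 sc["sequence"], sc["peptides"],
                                 sc["longest"], n_perm=1000, seed=1)
        # dense entanglement regions: random draws nearly always land
        # some overlap with an agreeing sign at every timepoint
        assert res.p_value > 0.8

    def test_p_monotone_in_observed_stats(self):
        sc, (ov, sg) = self._setup()
        levels = [0.0, 0.1, 0.3, 1.0]
        ps = []
        for level in levels:
            stats = {tp: level for tp in sc["timepoints"]}
            res = permutation_pvalue(stats, dict(stats), ov, sg,
                                     sc["model"], sc["sequence"],
                                     sc["peptides"], sc["longest"],
                                     n_perm=1000, seed=7)
            ps.append(res.p_value)
        assert ps == sorted(ps, reverse=True)

    def test_single_timepoint_rejected(self):
        sc, (ov, sg) = self._setup()
        with pytest.raises(ValueError):
            permutation_pvalue({"T1": 0.5}, {"T1": 0.5}, ov, sg,
                               sc["model"], sc["sequence"],
                               sc["peptides"], "T1", n_perm=1000)

    def test_planted_signal_is_detected(self):
        sc = gen_consistency_scenario(seed=3, planted=True)
        ov, sg = site_lookup_tables(sc["records"], sc["structure"],
                                    sc["delta_sasa"])
        O, _ = overlap_matrix(sc["records"], sc["peptides"],
                              sc["structure"])
        per_site = np.array([np.mean(
            sc["delta_sasa"][max(0, p.pk_cut_site - 6):p.pk_cut_site + 5])
            for p in sc["peptides"]])
        S = sign_matrix(O, per_site,
                        [p.log2_ratio for p in sc["peptides"]])
        o_stat, s_stat = consistency_stats(
            O, S, [p.timepoint for p in sc["peptides"]])
        res = permutation_pvalue(o_stat, s_stat, ov, sg, sc["model"],
                                 sc["sequence"], sc["peptides"],
                                 sc["longest"], n_perm=2000, seed=9)
        assert res.p_value < 0.05
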