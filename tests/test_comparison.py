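"""Presence partitions, family summaries, ratios, stoichiometry, positional bias."""

import numpy as np
import pandas as pd
import pytest

from antquant import (
    ProteinRecord,
    RunConfig,
    abundance_ratio,
    family_summary,
    load_table_fixture,
    positional_bias,
    presence_matrix,
    stoichiometry_report,
    venn_partition,
)
from antquant.comparison import _round_half_away
from antquant.digestion import digest
from antquant.evaluation import brute_force_venn
from antquant.io_formats import AbundanceTable


class TestPresenceMatrix:
    def test_worker_p450_count_includes_dash_rows(self):
        m = presence_matrix(load_table_fixture("table4"))
        assert int(m["worker_antenna"].sum()) == 29

    def test_zero_cell_is_not_detected(self):
        m = presence_matrix(load_table_fixture("table1"))
        assert not m.loc["ADX94400.1", "worker_antenna"]  # worker cell is 0

    def test_dash_cell_is_detected(self):
        m = presence_matrix(load_table_fixture("table4"))
        assert m.loc["XP_011172542.1", "worker_antenna"]

    def test_duplicated_accessions_merge(self):
        m = presence_matrix(load_table_fixture("table5"))
        assert m.index.is_unique
        # printed twice: once worker-antennal, once tibia-only
        assert m.loc["XP_011165649.2", "worker_antenna"]
        assert m.loc["XP_011165649.2", "worker_tibia"]


class TestVennPartition:
    def test_small_hand_example(self):
        mat = pd.DataFrame(
            {"W": [1, 1, 0], "M": [0, 1, 1], "T": [0, 1, 0]},
            index=["a", "b", "c"],
            dtype=bool,
        )
        part = venn_partition(mat)
        assert part.exactly("W", "M", "T") == 1
        assert part.only("W") == 1
        assert part.only("M") == 1
        assert part.total == 3
        assert sum(part.regions.values()) == part.total

    def test_empty_sets_are_all_zero(self):
        mat = pd.DataFrame(
            {"W": [], "M": [], "T": []}, dtype=bool
        )
        part = venn_partition(mat)
        assert part.total == 0
        assert all(v == 0 for v in part.regions.values())

    def test_two_tissues_rejected(self):
        mat = pd.DataFrame({"W": [True], "M": [False]}, index=["a"])
        with pytest.raises(ValueError):
            venn_partition(mat)

    def test_agrees_with_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 51))
            mat = pd.DataFrame(
                rng.random((n, 3)) < 0.5,
                index=[f"p{i}" for i in range(n)],
                columns=["W", "M", "T"],
            )
            part = venn_partition(mat)
            assert part.regions == brute_force_venn(mat)
            assert sum(part.regions.values()) == part.total


class TestFamilySummary:
    def test_tulip_counts_match_published_narrative(self):
        t3 = load_table_fixture("table3")
        m = presence_matrix(t3)
        fams = dict(zip(t3.values.index, t3.meta["family"]))
        tulip = family_summary(m, fams)["TULIP"]
        assert tulip.per_tissue == {
            "worker_antenna": 5,
            "male_antenna": 7,
            "worker_tibia": 2,
        }

    def test_csp_worker_count_matches_published_narrative(self):
        t2 = load_table_fixture("table2")
        m = presence_matrix(t2)
        fams = {acc: "CSP" for acc in m.index}
        assert family_summary(m, fams)["CSP"].per_tissue["worker_antenna"] == 11

    def test_obp_exclusivity_classes_sum_to_total(self):
        t1 = load_table_fixture("table1")
        m = presence_matrix(t1)
        fams = {acc: "OBP" for acc in m.index}
        obp = family_summary(m, fams)["OBP"]
        assert (
            obp.worker_only
            + obp.male_only
            + obp.both_antennae_only
            + obp.shared_with_tibia
            + obp.tibia_only
            == obp.total_detected
            == 11
        )
        # six worker and four male OBPs are exclusively antennal
        assert obp.worker_only + obp.both_antennae_only == 6
        assert obp.male_only + obp.both_antennae_only == 4

    def test_empty_family_is_all_zero(self):
        m = presence_matrix(load_table_fixture("table1"))
        fams = {acc: "OBP" for acc in m.index}
        fams[m.index[0]] = "CSP"
        summary = family_summary(m, fams)
        assert summary["CSP"].total_detected == 1

    def test_missing_family_label_rejected(self):
        m = presence_matrix(load_table_fixture("table1"))
        with pytest.raises(KeyError):
            family_summary(m, {})


class TestAbundanceRatio:
    def test_gp9_worker_male_ratio_rounds_to_eleven_fold(self):
        t1 = load_table_fixture("table1")
        r = abundance_ratio(t1, "XP_011157711.1", "worker_antenna", "male_antenna")
        assert r.raw == pytest.approx(73 / 6.5)
        assert r.rounded == pytest.approx(11.23)
        assert r.fold == 11

    def test_orco_ratio_close_to_five(self):
        t6 = load_table_fixture("table6")
        r = abundance_ratio(t6, "Orco", "worker_antenna", "male_antenna")
        assert r.raw == pytest.approx(3.1 / 0.64)
        assert r.fold == 5

    def test_absent_denominator_returns_sentinel(self):
        t1 = load_table_fixture("table1")
        r = abundance_ratio(t1, "ADX94407.1", "worker_antenna", "male_antenna")
        assert r.sentinel == "detected-only-in-numerator"

    def test_absent_in_both_rejected(self):
        t1 = load_table_fixture("table1")
        with pytest.raises(ValueError):
            abundance_ratio(t1, "ADX94400.1", "worker_antenna", "male_antenna")

    @pytest.mark.parametrize(
        "x,nd,expected", [(0.125, 2, 0.13), (1.005, 2, 1.01), (11.23, 0, 11.0)]
    )
    def test_round_half_away_from_zero(self, x, nd, expected):
        assert _round_half_away(x, nd) == pytest.approx(expected)


class TestStoichiometry:
    def test_published_snmp_orco_ratios(self):
        t6 = load_table_fixture("table6")
        s = stoichiometry_report(t6, "Orco", "SNMP1")
        assert s.snmp_orco["worker_antenna"] == pytest.approx(1.61, abs=0.01)
        assert s.snmp_orco["male_antenna"] == pytest.approx(10.0)
        assert s.orco_worker_male == pytest.approx(4.84, abs=0.01)
        assert s.snmp_worker_male == pytest.approx(0.78, abs=0.01)

    def test_missing_accession_rejected(self):
        t6 = load_table_fixture("table6")
        with pytest.raises(KeyError):
            stoichiometry_report(t6, "Orco", "NOPE")


class TestPositionalBias:
    def test_four_peptides_in_first_half_exact_p(self):
        # eight observable peptides, four per half; all 4 detections in the
        # first half -> two-sided exact binomial p = 2 * 0.5^4
        seq = (
            "AAAAAAAAAAK" "CCCCCCCCCCK" "DDDDDDDDDDK" "EEEEEEEEEEK"
            "FFFFFFFFFFK" "HHHHHHHHHHK" "IIIIIIIIIIK" "LLLLLLLLLLK"
        )
        rec = ProteinRecord("P", seq)
        peps = digest(seq, 0)
        bias = positional_bias(rec, peps[:4], RunConfig())
        assert bias.n_first_half == 4
        assert bias.n_second_half == 0
        assert bias.expected_first_fraction == pytest.approx(0.5)
        assert bias.p_value == pytest.approx(0.125)

    def test_midpoint_straddling_assigned_by_midpoint_residue(self):
        # one 22-residue peptide spanning the cut at 11: midpoint residue 10
        seq = "A" * 21 + "K" + "C" * 10 + "K"
        rec = ProteinRecord("P", seq)
        peps = digest(seq, 0)
        bias = positional_bias(rec, [peps[0]], RunConfig())
        assert bias.n_first_half == 1

    def test_no_peptides_rejected(self):
        rec = ProteinRecord("P", "AAAAAAAAAAK")
        with pytest.raises(ValueError):
            positional_bias(rec, [], RunConfig())
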