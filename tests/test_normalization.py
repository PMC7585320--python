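"""Reference normalization, trypsin volume correction, and aggregation."""

import math

import numpy as np
import pytest

from antquant import (
    aggregate_sample,
    reference_normalize,
    volume_correction,
)
from antquant.quantification import SliceQuant


def sq(acc, sample, slice_id, empai, top3=100.0, peptides=None):
    return SliceQuant(
        accession=acc,
        sample_id=sample,
        slice_id=slice_id,
        n_obsd=1,
        n_obsbl=10,
        empai=empai,
        top3=top3,
        peptides=peptides if peptides is not None else [(f"PEP{acc}K", 0, 7)],
    )


class TestReferenceNormalize:
    def test_divides_by_reference_home_slice(self):
        quants = [sq("GAPDH", "w", "S2", 2.0), sq("P1", "w", "S1", 1.0)]
        out = reference_normalize(quants, "GAPDH")
        assert {q.accession: q.empai for q in out} == {"GAPDH": 1.0, "P1": 0.5}

    def test_reference_normalized_against_itself_is_one(self):
        out = reference_normalize([sq("GAPDH", "w", "S2", 3.7)], "GAPDH")
        assert out[0].empai == pytest.approx(1.0)

    def test_missing_reference_names_the_sample(self):
        with pytest.raises(ValueError, match="male"):
            reference_normalize([sq("P1", "male", "S1", 1.0)], "GAPDH")

    def test_multi_slice_reference_uses_maximum(self, caplog):
        quants = [
            sq("GAPDH", "w", "S1", 0.5),
            sq("GAPDH", "w", "S2", 2.0),
            sq("P1", "w", "S1", 1.0),
        ]
        out = reference_normalize(quants, "GAPDH")
        p1 = next(q for q in out if q.accession == "P1")
        assert p1.empai == pytest.approx(0.5)

    def test_scale_invariance(self):
        quants = [sq("GAPDH", "w", "S2", 2.0), sq("P1", "w", "S1", 0.8)]
        scaled = [
            sq(q.accession, q.sample_id, q.slice_id, q.empai * 7.3) for q in quants
        ]
        a = reference_normalize(quants, "GAPDH")
        b = reference_normalize(scaled, "GAPDH")
        for qa, qb in zip(a, b):
            assert qa.empai == pytest.approx(qb.empai)


class TestVolumeCorrection:
    def _quants(self, tryp_empai, tryp_top3):
        quants = [sq("GAPDH", "w", "S1", 1.0)]
        for s, (e, t) in enumerate(zip(tryp_empai, tryp_top3), start=1):
            quants.append(sq("TRYPSIN", "w", f"S{s}", e, top3=t))
        quants.append(sq("P1", "w", "S2", 0.4))
        return quants

    def test_unit_factors_leave_values_unchanged(self):
        quants = self._quants([2.0, 2.0], [50.0, 50.0])
        factors, out = volume_correction(quants, "TRYPSIN", "GAPDH")
        assert all(f == pytest.approx(1.0) for f in factors.factors.values())
        mean, sd = factors.summary()
        assert (mean, sd) == (pytest.approx(1.0), pytest.approx(0.0))
        p1 = next(q for q in out if q.accession == "P1")
        assert p1.empai == pytest.approx(0.4)

    def test_factor_is_mean_of_component_ratios(self):
        # trypsin emPAI ratio 1.5 and Top3 ratio 0.5 in S2 -> f = 1.0
        quants = self._quants([2.0, 3.0], [50.0, 25.0])
        factors, _ = volume_correction(quants, "TRYPSIN", "GAPDH")
        assert factors.empai_ratios[("w", "S2")] == pytest.approx(1.5)
        assert factors.top3_ratios[("w", "S2")] == pytest.approx(0.5)
        assert factors.factors[("w", "S2")] == pytest.approx(1.0)

    def test_reference_slice_factor_is_one(self):
        quants = self._quants([2.0, 5.0], [50.0, 80.0])
        factors, _ = volume_correction(quants, "TRYPSIN", "GAPDH")
        assert factors.factors[("w", "S1")] == pytest.approx(1.0)

    def test_missing_trypsin_names_the_slice(self):
        quants = [sq("GAPDH", "w", "S1", 1.0), sq("TRYPSIN", "w", "S1", 2.0),
                  sq("P1", "w", "S2", 0.4)]
        with pytest.raises(ValueError, match="S2"):
            volume_correction(quants, "TRYPSIN", "GAPDH")

    def test_proportional_switch_divides_instead(self):
        quants = self._quants([2.0, 4.0], [50.0, 100.0])  # f(S2) = 2
        _, multiplied = volume_correction(quants, "TRYPSIN", "GAPDH")
        _, divided = volume_correction(
            quants, "TRYPSIN", "GAPDH", trypsin_proportional=True
        )
        pm = next(q for q in multiplied if q.accession == "P1")
        pd_ = next(q for q in divided if q.accession == "P1")
        assert pm.empai == pytest.approx(0.8)
        assert pd_.empai == pytest.approx(0.2)


class TestAggregateSample:
    def test_single_slice_passes_through(self):
        table = aggregate_sample([sq("P1", "w", "S1", 0.7)])
        assert table.values.loc["P1", "w"] == pytest.approx(0.7)

    def test_multi_slice_sums(self):
        table = aggregate_sample(
            [sq("P1", "w", "S1", 0.2), sq("P1", "w", "S2", 0.3)]
        )
        assert table.values.loc["P1", "w"] == pytest.approx(0.5)

    def test_all_dash_slices_propagate_dash(self):
        table = aggregate_sample([sq("P1", "w", "S1", None)])
        assert table.cell_state("P1", "w") == "detected-unquantified"

    def test_mixed_dash_and_value_keeps_value(self, caplog):
        table = aggregate_sample(
            [sq("P1", "w", "S1", None), sq("P1", "w", "S2", 0.2)]
        )
        assert table.values.loc["P1", "w"] == pytest.approx(0.2)

    def test_single_peptide_flag_pools_across_slices(self):
        one = [
            sq("P1", "w", "S1", 0.2, peptides=[("AAAK", 0, 4)]),
            sq("P1", "w", "S2", 0.3, peptides=[("AAAK", 0, 4)]),
        ]
        two = [
            sq("P2", "w", "S1", 0.2, peptides=[("AAAK", 0, 4)]),
            sq("P2", "w", "S2", 0.3, peptides=[("CCCK", 4, 8)]),
        ]
        table = aggregate_sample(one + two)
        assert table.single_peptide.loc["P1", "w"]
        assert not table.single_peptide.loc["P2", "w"]

    def test_recovered_factors_track_inverse_volume(self):
        """Seed-averaged correction factors rank-order with 1/V_s.

        A single replicate's factor is dominated by the saturated trypsin
        emPAI counting noise, so the systematic relationship is assessed on
        within-replicate-centred log factors averaged over replicates.
        """
        from antquant.evaluation import factor_recovery_spearman

        rho = factor_recovery_spearman(
            n_seeds=10, base_seed=0, n_proteins=120,
            volume_factors=(0.5, 1.0, 2.0, 1.25),
        )
        assert rho >= 0.9

    def test_excluded_accessions_absent_from_table(self):
        table = aggregate_sample(
            [sq("P1", "w", "S1", 0.7), sq("TRYPSIN", "w", "S1", 2.0)],
            exclude={"TRYPSIN"},
        )
        assert "TRYPSIN" not in table.values.index
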