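"""emPAI / Top3 indices and per-slice quantification.

``quantify_slices`` is cross-checked by a brute-force recount from the raw
accepted PSMs on randomized inputs.
"""

import math

import numpy as np
import pytest

from antquant import (
    PSM,
    ProteinRecord,
    RunConfig,
    apply_filters,
    empai,
    quantify_slices,
    top3,
)
from antquant.digestion import digest, mature_sequence, observable_count
from antquant.quantification import UnquantifiableError


class TestEmpai:
    @pytest.mark.parametrize(
        "n_obsd,n_obsbl,expected",
        [
            (0, 10, 0.0),
            (10, 10, 9.0),
            (3, 10, 0.995262315),  # 10^0.3 - 1
        ],
    )
    def test_known_values(self, n_obsd, n_obsbl, expected):
        assert empai(n_obsd, n_obsbl) == pytest.approx(expected, abs=1e-6)

    def test_zero_observable_is_unquantifiable(self):
        with pytest.raises(UnquantifiableError):
            empai(3, 0)

    def test_excess_observed_clamped(self, caplog):
        assert empai(12, 10) == pytest.approx(9.0)

    def test_strictly_increasing_in_n_obsd(self):
        values = [empai(n, 20) for n in range(21)]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestTop3:
    @pytest.mark.parametrize(
        "intensities,expected",
        [
            ([5, 5, 5], 5),
            ([10, 8, 6, 4], 8),  # (10+8+6)/3
            ([4], 4),
        ],
    )
    def test_known_values(self, intensities, expected):
        assert top3(intensities) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            top3([])

    def test_bounded_by_min_and_max(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            vals = list(rng.uniform(0, 100, size=rng.integers(1, 10)))
            assert min(vals) <= top3(vals) <= max(vals)


def _psm(peptide, accession, sample="w", slice_id="S1", intensity=100.0, charge=2):
    return PSM(peptide, accession, sample, slice_id, 50.0, 30.0, intensity, charge, False)


class TestQuantifySlices:
    def _protein_with_n_observable(self, n, accession="P1"):
        # n tryptic peptides of mass within [800, 3000]: AAAAAAAAAAK ~ 856.5 Da
        seq = "AAAAAAAAAAK" * n
        rec = ProteinRecord(accession, seq)
        assert observable_count(rec, RunConfig()) == n
        return rec

    def test_three_of_ten_peptides_gives_known_empai(self):
        # ten distinct observable tryptic peptides; three detected
        rec = ProteinRecord(
            "P1",
            "AAAAAAAAAAK" + "CCCCCCCCCCK" + "DDDDDDDDDDK" + "EEEEEEEEEEK"
            + "FFFFFFFFFFK" + "GGGGGGGGGGGGGGGGK" + "HHHHHHHHK" + "IIIIIIIK"
            + "LLLLLLLK" + "MMMMMMMK",
        )
        assert observable_count(rec, RunConfig()) == 10
        peptides = [p.sequence for p in digest(rec.sequence, 0)][:3]
        psms = [_psm(p, "P1") for p in peptides]
        (q,) = quantify_slices(apply_filters(psms, 0), [rec], RunConfig())
        assert q.n_obsd == 3
        assert q.empai == pytest.approx(0.995262315, abs=1e-6)

    def test_charge_states_collapse(self):
        rec = self._protein_with_n_observable(2)
        psms = [
            _psm("AAAAAAAAAAK", "P1", charge=2),
            _psm("AAAAAAAAAAK", "P1", charge=3),
        ]
        (q,) = quantify_slices(apply_filters(psms, 0), [rec], RunConfig())
        assert q.n_obsd == 1

    def test_unknown_accession_rejected(self):
        rec = self._protein_with_n_observable(1)
        psms = [_psm("AAAAAAAAAAK", "NOPE")]
        with pytest.raises(KeyError):
            quantify_slices(apply_filters(psms, 0), [rec], RunConfig())

    def test_protein_without_observable_peptides_is_dash(self):
        rec = ProteinRecord("P1", "AKAK")  # only dipeptides, none observable
        psms = [_psm("AK", "P1")]
        (q,) = quantify_slices(apply_filters(psms, 0), [rec], RunConfig())
        assert q.empai is None
        assert q.n_obsbl == 0

    def test_brute_force_recount_on_random_input(self, small_sim):
        """Oracle equivalence: recount n_obsd/top3 directly from accepted PSMs."""
        cfg, proteome, psms, _ = small_sim
        run_cfg = cfg.run_config()
        from antquant import filter_psms

        result = filter_psms(psms, run_cfg.fdr_target)
        quants = {
            (q.accession, q.sample_id, q.slice_id): q
            for q in quantify_slices(result, proteome, run_cfg)
        }
        by_acc = {r.accession: r for r in proteome}
        groups = {}
        for p in result.accepted:
            groups.setdefault((p.accession, p.sample_id, p.slice_id), []).append(p)
        assert set(groups) == set(quants)
        for key, members in groups.items():
            q = quants[key]
            assert q.n_obsd == len({p.peptide for p in members})
            best = sorted((p.intensity for p in members), reverse=True)[:3]
            assert q.top3 == pytest.approx(sum(best) / len(best))
            n_obsbl = observable_count(by_acc[key[0]], run_cfg)
            if n_obsbl:
                assert q.empai == pytest.approx(
                    10 ** (min(q.n_obsd, n_obsbl) / n_obsbl) - 1
                )
            else:
                assert q.empai is None

    def test_peptide_positions_on_mature_sequence(self):
        rec = ProteinRecord("P1", "MMM" + "AAAAAAAAAAK", True, 3, "OBP")
        psms = [_psm("AAAAAAAAAAK", "P1")]
        (q,) = quantify_slices(apply_filters(psms, 0), [rec], RunConfig())
        pep, start, end = q.peptides[0]
        assert (start, end) == (0, 11)
        assert mature_sequence(rec)[start:end] == pep
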