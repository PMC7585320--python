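"""End-to-end composition of the quantification stages.

``quantify_pipeline`` takes a proteome plus raw PSMs and produces the
whole-appendage abundance table exactly as the published tables are built:
FDR filtering → per-slice emPAI/Top3 → reference normalization →
trypsin-volume correction → aggregation. ``compare_report`` and
``native_gel_report`` turn tables into the JSON report blocks the CLI
writes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import pandas as pd

from . import comparison, native_gel
from .identification import FilterResult, filter_psms
from .io_formats import PSM, AbundanceTable, ProteinRecord, RunConfig
from .normalization import CorrectionFactors, aggregate_sample, reference_normalize, volume_correction
from .quantification import SliceQuant, quantify_slices


@dataclass
class PipelineResult:
    filter_result: FilterResult
    slice_quants: list[SliceQuant]
    factors: CorrectionFactors
    corrected_quants: list[SliceQuant]
    abundance: AbundanceTable


def quantify_pipeline(
    proteome: list[ProteinRecord],
    psms: list[PSM],
    config: RunConfig,
) -> PipelineResult:
    """Raw PSMs to a normalized, volume-corrected whole-appendage table.

    The trypsin reagent drives the volume correction but is excluded from
    the final table, as in the published tables.
    """
    filt = filter_psms(psms, config.fdr_target)
    quants = quantify_slices(filt, proteome, config)
    normalized = reference_normalize(quants, config.reference_accession)
    factors, corrected = volume_correction(
        normalized,
        config.trypsin_accession,
        config.reference_accession,
        trypsin_proportional=config.trypsin_proportional,
    )
    table = aggregate_sample(corrected, exclude={config.trypsin_accession})
    return PipelineResult(
        filter_result=filt,
        slice_quants=quants,
        factors=factors,
        corrected_quants=corrected,
        abundance=table,
    )


def compare_report(
    table: AbundanceTable,
    families: dict[str, str],
    config: RunConfig,
) -> dict:
    """JSON-ready comparison block: Venn partition, family summaries, stoichiometry."""
    matrix = comparison.presence_matrix(table)
    report: dict = {}
    if len(matrix.columns) == 3:
        venn = comparison.venn_partition(matrix)
        report["venn"] = {
            "total": venn.total,
            **{
                "&".join(sorted(k)): v
                for k, v in sorted(venn.regions.items(), key=lambda kv: sorted(kv[0]))
            },
        }
    fam = comparison.family_summary(matrix, families) if families else {}
    report["families"] = {
        name: dataclasses.asdict(counts) for name, counts in fam.items()
    }
    if (
        config.orco_accession in table.values.index
        and config.snmp_accession in table.values.index
    ):
        stoich = comparison.stoichiometry_report(
            table, config.orco_accession, config.snmp_accession
        )
        report["stoichiometry"] = dataclasses.asdict(stoich)
    return report


def native_gel_report(
    sections: list[native_gel.SectionQuant],
    accessions: list[str],
    mean_subunit_kda: float = 44.0,
    threshold_fold: float = 1.5,
) -> dict:
    """Hi/Lo ratios and dilution-shift classes per accession, plus oligomer masses.

    The dilution-shift classification is an extension of the published
    qualitative reasoning and is labelled as such in the output.
    """
    by_dilution: dict[str, list[native_gel.SectionQuant]] = {}
    for s in sections:
        by_dilution.setdefault(s.dilution, []).append(s)
    report: dict = {
        "oligomer_masses_kda": {
            "subunit": mean_subunit_kda,
            "tetramer": native_gel.oligomer_mass(mean_subunit_kda, 4),
            "octamer": native_gel.oligomer_mass(mean_subunit_kda, 8),
        },
        "hi_lo_ratios": {},
        "dilution_shift": {},
        "note": "dilution-shift classification is an extension beyond the "
        "published qualitative reasoning",
    }
    for acc in accessions:
        ratios = {}
        for dilution, secs in sorted(by_dilution.items()):
            try:
                ratios[dilution] = native_gel.hi_lo_ratio(secs, acc)
            except ValueError:
                continue
        report["hi_lo_ratios"][acc] = ratios
        if {"dilute", "concentrated"} <= set(ratios):
            shift = native_gel.dilution_shift_classifier(
                ratios["dilute"], ratios["concentrated"], threshold_fold
            )
            report["dilution_shift"][acc] = dataclasses.asdict(shift)
    return report
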