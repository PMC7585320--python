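"""Reference normalization, per-slice volume correction, and aggregation.

Three steps turn per-slice emPAI values into the one-number-per-protein-
per-appendage shape of the published tables:

1. every emPAI in a sample is divided by the reference protein's (GAPDH)
   emPAI in its home gel slice of that sample;
2. each slice is rescaled by a correction factor derived from trypsin
   autolysis products, whose detected signal is assumed inversely
   proportional to the relative sample volume injected from that slice;
3. corrected values are summed across slices into whole-appendage numbers.

The per-slice factor is ``f(s) = mean(emPAI_tryp(s)/emPAI_tryp(ref),
Top3_tryp(s)/Top3_tryp(ref))`` — the mean of exactly those two component
ratios, taken against the slice containing the reference protein, so
``f(ref) = 1`` by construction.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AbundanceTable, RunConfig
from .quantification import SliceQuant

logger = logging.getLogger("antquant")


@dataclass
class CorrectionFactors:
    """Per-sample per-slice volume-correction factors and their components."""

    factors: dict[tuple[str, str], float]  # (sample_id, slice_id) -> f(s)
    empai_ratios: dict[tuple[str, str], float] = field(default_factory=dict)
    top3_ratios: dict[tuple[str, str], float] = field(default_factory=dict)
    reference_slices: dict[str, str] = field(default_factory=dict)

    def summary(self) -> tuple[float, float]:
        """Mean and SD of f across all slices and samples (the 'volume error factor')."""
        vals = np.array(list(self.factors.values()), dtype=float)
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0


def _reference_home_slice(
    quants: list[SliceQuant], reference_accession: str, sample_id: str
) -> SliceQuant:
    refs = [
        q
        for q in quants
        if q.accession == reference_accession
        and q.sample_id == sample_id
        and q.empai is not None
    ]
    if not refs:
        raise ValueError(
            f"reference protein {reference_accession!r} not quantified in "
            f"sample {sample_id!r}"
        )
    if len(refs) > 1:
        logger.warning(
            "reference %s found in %d slices of sample %s; using its "
            "maximum-emPAI slice",
            reference_accession,
            len(refs),
            sample_id,
        )
        refs.sort(key=lambda q: q.empai, reverse=True)
    return refs[0]


def reference_normalize(
    quants: list[SliceQuant], reference_accession: str
) -> list[SliceQuant]:
    """Divide every emPAI by the reference's emPAI in its home slice, per sample."""
    samples = sorted({q.sample_id for q in quants})
    denominators = {
        s: _reference_home_slice(quants, reference_accession, s).empai for s in samples
    }
    out = []
    for q in quants:
        c = copy.copy(q)
        if c.empai is not None:
            c.empai = c.empai / denominators[q.sample_id]
        out.append(c)
    return out


def volume_correction(
    quants: list[SliceQuant],
    trypsin_accession: str,
    reference_accession: str,
    trypsin_proportional: bool = False,
) -> tuple[CorrectionFactors, list[SliceQuant]]:
    """Rescale each slice by its trypsin-derived volume factor.

    Under the default assumption (trypsin signal inversely proportional to
    relative sample volume) values are multiplied by ``f(s)``; with
    ``trypsin_proportional=True`` they are divided instead, for instruments
    where the autolysis signal tracks injected volume directly.
    """
    samples = sorted({q.sample_id for q in quants})
    factors: dict[tuple[str, str], float] = {}
    empai_ratios: dict[tuple[str, str], float] = {}
    top3_ratios: dict[tuple[str, str], float] = {}
    ref_slices: dict[str, str] = {}
    for sample in samples:
        ref_slice = _reference_home_slice(quants, reference_accession, sample).slice_id
        ref_slices[sample] = ref_slice
        slice_ids = sorted({q.slice_id for q in quants if q.sample_id == sample})
        tryp = {
            q.slice_id: q
            for q in quants
            if q.sample_id == sample and q.accession == trypsin_accession
        }
        missing = [s for s in slice_ids if s not in tryp]
        if missing:
            raise ValueError(
                f"trypsin {trypsin_accession!r} missing in slice(s) {missing} "
                f"of sample {sample!r}"
            )
        ref_tryp = tryp[ref_slice]
        if ref_tryp.empai in (None, 0) or ref_tryp.top3 == 0:
            raise ValueError(
                f"trypsin has zero signal in reference slice {ref_slice!r} of "
                f"sample {sample!r}"
            )
        for s in slice_ids:
            er = tryp[s].empai / ref_tryp.empai
            tr = tryp[s].top3 / ref_tryp.top3
            empai_ratios[(sample, s)] = er
            top3_ratios[(sample, s)] = tr
            factors[(sample, s)] = (er + tr) / 2.0

    corrected = []
    for q in quants:
        c = copy.copy(q)
        if c.empai is not None:
            f = factors[(q.sample_id, q.slice_id)]
            c.empai = c.empai * f if not trypsin_proportional else c.empai / f
        corrected.append(c)
    cf = CorrectionFactors(
        factors=factors,
        empai_ratios=empai_ratios,
        top3_ratios=top3_ratios,
        reference_slices=ref_slices,
    )
    mean, sd = cf.summary()
    logger.info("average sample volume error factor: %.2f ± %.2f", mean, sd)
    return cf, corrected


def aggregate_sample(
    quants: list[SliceQuant],
    exclude: set[str] = frozenset(),
) -> AbundanceTable:
    """Sum corrected normalized emPAI over slices into a protein x sample table.

    A protein whose every slice is detected-unquantified propagates the dash
    state; mixed dash/value slices keep the numeric sum with a completeness
    warning. The single-peptide flag is set when the protein's distinct
    peptides pooled across slices number exactly one.
    """
    samples = sorted({q.sample_id for q in quants})
    accs = sorted({q.accession for q in quants if q.accession not in exclude})
    values = pd.DataFrame(0.0, index=accs, columns=samples)
    dash = pd.DataFrame(False, index=accs, columns=samples)
    single = pd.DataFrame(False, index=accs, columns=samples)
    grouped: dict[tuple[str, str], list[SliceQuant]] = {}
    for q in quants:
        if q.accession in exclude:
            continue
        grouped.setdefault((q.accession, q.sample_id), []).append(q)
    for (acc, sample), qs in grouped.items():
        numeric = [q.empai for q in qs if q.empai is not None]
        n_dash = sum(1 for q in qs if q.empai is None)
        if numeric:
            values.loc[acc, sample] = float(sum(numeric))
            if n_dash:
                logger.warning(
                    "%s in %s: %d slice(s) detected-unquantified; sum over the "
                    "quantified slices only",
                    acc,
                    sample,
                    n_dash,
                )
        elif n_dash:
            values.loc[acc, sample] = math.nan
            dash.loc[acc, sample] = True
        peptides = set()
        for q in qs:
            peptides.update(pep for pep, _, _ in q.peptides)
        if len(peptides) == 1:
            single.loc[acc, sample] = True
    return AbundanceTable(values, dash, single)
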