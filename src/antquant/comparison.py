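"""Comparative analyses across appendages.

Presence/absence partitions of three tissues, per-family detection counts
with exclusivity classes, pairwise abundance ratios (e.g. the worker:male
co-receptor ratio used as a proxy for total odorant-receptor content),
SNMP:Orco stoichiometry, and the positional-bias test for tandem gene
models whose detected peptides cluster in one half of the sequence.

Detection is strict: a cell counts as detected when its value is > 0 or it
is a dash (detected-unquantified); there is no abundance floor, matching
the published tables where values as small as 0.0068 count.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import binomtest

from .digestion import Peptide, mature_sequence, observable_peptides
from .io_formats import AbundanceTable, ProteinRecord, RunConfig


def presence_matrix(table: AbundanceTable) -> pd.DataFrame:
    """Boolean accession x tissue detection matrix.

    Rows with duplicated accessions (tables occasionally print one accession
    twice) are merged with logical OR, so each accession appears once.
    """
    detected = table.detected()
    return detected.groupby(level=0).any()


@dataclass
class VennPartition:
    """Counts of the 7 exclusive regions of three presence sets."""

    tissues: tuple[str, str, str]
    regions: dict[frozenset, int]
    total: int

    def only(self, tissue: str) -> int:
        return self.regions[frozenset({tissue})]

    def exactly(self, *tissues: str) -> int:
        return self.regions[frozenset(tissues)]


def venn_partition(matrix: pd.DataFrame) -> VennPartition:
    """Exhaustive, mutually exclusive 7-region decomposition of three tissues."""
    tissues = tuple(matrix.columns)
    if len(tissues) != 3:
        raise ValueError(f"venn_partition needs exactly 3 tissues, got {len(tissues)}")
    sets = {t: set(matrix.index[matrix[t]]) for t in tissues}
    a, b, c = (sets[t] for t in tissues)
    ta, tb, tc = tissues
    regions = {
        frozenset({ta, tb, tc}): len(a & b & c),
        frozenset({ta, tb}): len((a & b) - c),
        frozenset({ta, tc}): len((a & c) - b),
        frozenset({tb, tc}): len((b & c) - a),
        frozenset({ta}): len(a - b - c),
        frozenset({tb}): len(b - a - c),
        frozenset({tc}): len(c - a - b),
    }
    return VennPartition(
        tissues=tissues, regions=regions, total=len(a | b | c)
    )


@dataclass
class FamilyClassCounts:
    per_tissue: dict[str, int]
    worker_only: int
    male_only: int
    both_antennae_only: int
    shared_with_tibia: int
    tibia_only: int
    total_detected: int

    @property
    def antenna_only(self) -> int:
        return self.worker_only + self.male_only + self.both_antennae_only


def family_summary(
    matrix: pd.DataFrame,
    families: dict[str, str],
    worker: str = "worker_antenna",
    male: str = "male_antenna",
    tibia: str = "worker_tibia",
) -> dict[str, FamilyClassCounts]:
    """Per-family detection counts and exclusivity classes.

    Antenna-only accessions split into worker-only / male-only / both;
    anything detected in the tibia is either shared (also in an antenna) or
    tibia-only. Class counts sum to the family's total detected accessions.
    """
    missing = [acc for acc in matrix.index if acc not in families]
    if missing:
        raise KeyError(f"accessions without a family label: {missing}")
    out: dict[str, FamilyClassCounts] = {}
    for family in sorted(set(families.values())):
        accs = [a for a in matrix.index if families[a] == family]
        sub = matrix.loc[accs]
        per_tissue = {t: int(sub[t].sum()) for t in matrix.columns}
        w, m, t = sub[worker], sub[male], sub[tibia]
        worker_only = int((w & ~m & ~t).sum())
        male_only = int((~w & m & ~t).sum())
        both_ant = int((w & m & ~t).sum())
        shared_tibia = int(((w | m) & t).sum())
        tibia_only = int((~w & ~m & t).sum())
        total = int((w | m | t).sum())
        out[family] = FamilyClassCounts(
            per_tissue=per_tissue,
            worker_only=worker_only,
            male_only=male_only,
            both_antennae_only=both_ant,
            shared_with_tibia=shared_tibia,
            tibia_only=tibia_only,
            total_detected=total,
        )
    return out


def _round_half_away(x: float, ndigits: int) -> float:
    # decimal-string route so printed halves (e.g. 1.005) round away from zero
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(
        decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


@dataclass
class RatioReport:
    accession: str
    numerator_tissue: str
    denominator_tissue: str
    raw: float | None
    rounded: float | None
    fold: int | None
    sentinel: str | None = None  # "detected-only-in-numerator" when denominator absent


def abundance_ratio(
    table: AbundanceTable,
    accession: str,
    numerator_tissue: str,
    denominator_tissue: str,
    precision: int = 2,
) -> RatioReport:
    """Between-tissue abundance ratio with round-half-away-from-zero reporting."""
    num_state = table.cell_state(accession, numerator_tissue)
    den_state = table.cell_state(accession, denominator_tissue)
    if num_state == "absent" and den_state == "absent":
        raise ValueError(
            f"{accession}: absent in both {numerator_tissue} and {denominator_tissue}"
        )
    if den_state != "value":
        return RatioReport(
            accession,
            numerator_tissue,
            denominator_tissue,
            raw=None,
            rounded=None,
            fold=None,
            sentinel="detected-only-in-numerator",
        )
    num = float(table.values.loc[accession, numerator_tissue])
    den = float(table.values.loc[accession, denominator_tissue])
    raw = num / den
    return RatioReport(
        accession,
        numerator_tissue,
        denominator_tissue,
        raw=raw,
        rounded=_round_half_away(raw, precision),
        fold=int(_round_half_away(raw, 0)),
    )


@dataclass
class StoichiometryReport:
    """SNMP:Orco ratios per sample and worker/male cross-caste ratios."""

    snmp_orco: dict[str, float]
    orco_worker_male: float
    snmp_worker_male: float


def stoichiometry_report(
    table: AbundanceTable,
    orco_accession: str,
    snmp_accession: str,
    worker: str = "worker_antenna",
    male: str = "male_antenna",
) -> StoichiometryReport:
    """Receptor stoichiometry via the co-receptor proxy.

    Each odor-specific receptor pairs 1:1 with the co-receptor, so the
    co-receptor's abundance proxies total receptor content (neglecting
    co-receptor homomers); SNMP:co-receptor ratios then bound the possible
    complex compositions.
    """
    for acc in (orco_accession, snmp_accession):
        if acc not in table.values.index:
            raise KeyError(f"accession {acc!r} not present in the table")
    orco = table.values.loc[orco_accession]
    snmp = table.values.loc[snmp_accession]
    snmp_orco = {
        t: float(snmp[t]) / float(orco[t])
        for t in table.tissues
        if float(orco[t]) > 0 and not math.isnan(float(orco[t]))
    }
    return StoichiometryReport(
        snmp_orco=snmp_orco,
        orco_worker_male=float(orco[worker]) / float(orco[male]),
        snmp_worker_male=float(snmp[worker]) / float(snmp[male]),
    )


@dataclass
class PositionalBias:
    n_first_half: int
    n_second_half: int
    expected_first_fraction: float
    p_value: float


def positional_bias(
    protein: ProteinRecord,
    accepted_peptides: list[Peptide],
    config: RunConfig | None = None,
) -> PositionalBias:
    """Test whether detected peptides cluster in one half of the sequence.

    The mature sequence is split at floor(L/2); each peptide is assigned to
    a half by its midpoint residue. The null expectation is the observable-
    peptide split between the halves, and the reported p-value is a
    two-sided exact binomial test. (The published analysis reports only the
    counts; the test is an extension, flagged as such in pipeline output.)
    """
    if not accepted_peptides:
        raise ValueError("positional_bias needs at least one accepted peptide")
    config = config or RunConfig()
    mature = mature_sequence(protein)
    half = len(mature) // 2

    def in_first(p: Peptide) -> bool:
        mid = (p.start + p.end - 1) // 2
        return mid < half

    n_first = sum(1 for p in accepted_peptides if in_first(p))
    n = len(accepted_peptides)
    observable = observable_peptides(protein, config)
    if observable:
        expected = sum(1 for p in observable if in_first(p)) / len(observable)
    else:
        expected = 0.5
    p_value = float(binomtest(n_first, n, expected, alternative="two-sided").pvalue)
    return PositionalBias(
        n_first_half=n_first,
        n_second_half=n - n_first,
        expected_first_fraction=expected,
        p_value=p_value,
    )
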