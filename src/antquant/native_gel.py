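"""Blue-native-gel oligomer reasoning.

Intact membrane-protein complexes separate by mass on blue native gels, so
the section a receptor migrates in constrains its oligomeric state: with an
average subunit mass near 44 kDa, a 2+2 heteromer ("tetramer") lands around
176 kDa and a 4+4 heteromer ("octamer") around 352 kDa. Comparing the
high-MW/low-MW abundance ratio of a subunit between dilute and concentrated
loadings distinguishes stable complexes (ratio unchanged) from
concentration-dependent association equilibria (ratio shifts).

Masses here are on the average (not monoisotopic) scale, appropriate for
gel-resolution molecular weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .digestion import AVERAGE_RESIDUE_MASS, AVERAGE_WATER


@dataclass(frozen=True)
class OligomerModel:
    """A candidate complex: subunit copy numbers and masses in kDa."""

    composition: dict
    subunit_masses_kda: dict

    @property
    def total_mass_kda(self) -> float:
        if any(n < 1 for n in self.composition.values()):
            raise ValueError("all copy numbers must be >= 1")
        return sum(
            n * self.subunit_masses_kda[acc] for acc, n in self.composition.items()
        )


@dataclass
class SectionQuant:
    """One native-gel section: MW range, dilution label, per-protein abundance."""

    mw_low_kda: float
    mw_high_kda: float
    dilution: str  # "dilute" | "concentrated"
    abundances: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mw_low_kda < self.mw_high_kda:
            raise ValueError("section range must satisfy low < high")

    @property
    def midpoint_kda(self) -> float:
        return (self.mw_low_kda + self.mw_high_kda) / 2.0

    def contains_mass(self, mass_kda: float) -> bool:
        """Closed-interval membership in kDa."""
        return self.mw_low_kda <= mass_kda <= self.mw_high_kda


def sections_from_frame(df: pd.DataFrame) -> list[SectionQuant]:
    """Group a (mw_low_kda, mw_high_kda, dilution, accession, abundance) frame."""
    sections = []
    for (low, high, dilution), group in df.groupby(
        ["mw_low_kda", "mw_high_kda", "dilution"]
    ):
        sections.append(
            SectionQuant(
                mw_low_kda=float(low),
                mw_high_kda=float(high),
                dilution=str(dilution),
                abundances=dict(zip(group["accession"], group["abundance"].astype(float))),
            )
        )
    return sections


def protein_average_mw(sequence: str) -> float:
    """Average-mass molecular weight of a protein sequence, in kDa."""
    if not sequence:
        raise ValueError("empty sequence")
    da = sum(AVERAGE_RESIDUE_MASS[a] for a in sequence) + AVERAGE_WATER
    return da / 1000.0


def mean_subunit_mw(records, min_mw_kda: float) -> float:
    """Mean average MW of records at or above the cutoff.

    Sequences below the cutoff are excluded as likely incomplete gene
    models (a truncated sequence under-reports the true subunit mass).
    """
    masses = [
        m
        for m in (protein_average_mw(r.sequence) for r in records)
        if m >= min_mw_kda
    ]
    if not masses:
        raise ValueError(f"no sequences at or above {min_mw_kda} kDa")
    return sum(masses) / len(masses)


def oligomer_mass(avg_subunit_kda: float, n_subunits: int) -> float:
    """Mass of an n-mer of identical-average-mass subunits."""
    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    return avg_subunit_kda * n_subunits


def hi_lo_ratio(section_quants: list[SectionQuant], accession: str) -> float:
    """Abundance ratio of one protein between the high- and low-MW sections.

    Expects the two sections of one dilution series; the section with the
    larger midpoint is 'high'.
    """
    holding = [s for s in section_quants if accession in s.abundances]
    if len(holding) != 2:
        raise ValueError(
            f"{accession!r} must be quantified in exactly two sections "
            f"(found {len(holding)})"
        )
    lo, hi = sorted(holding, key=lambda s: s.midpoint_kda)
    if lo.abundances[accession] == 0:
        raise ValueError(f"{accession!r} has zero abundance in the low-MW section")
    return hi.abundances[accession] / lo.abundances[accession]


@dataclass
class DilutionShift:
    label: str  # "stable-complex" | "concentration-dependent-shift"
    direction: str | None  # "toward-high-mw" | "toward-low-mw" | None
    fold_change: float


def dilution_shift_classifier(
    hi_lo_dilute: float,
    hi_lo_concentrated: float,
    threshold_fold: float = 1.5,
) -> DilutionShift:
    """Classify a subunit's association behaviour from its two Hi/Lo ratios.

    If the dilute and concentrated Hi/Lo ratios differ by less than
    ``threshold_fold``, the complex does not detectably re-equilibrate over a
    concentration change — a stable, high-affinity complex. Otherwise the
    equilibrium shifts with concentration, toward the high-MW form when the
    concentrated ratio is the larger one.
    """
    if hi_lo_dilute <= 0 or hi_lo_concentrated <= 0:
        raise ValueError("Hi/Lo ratios must be positive")
    fold = max(hi_lo_dilute, hi_lo_concentrated) / min(hi_lo_dilute, hi_lo_concentrated)
    if fold < threshold_fold:
        return DilutionShift("stable-complex", None, fold)
    direction = (
        "toward-high-mw" if hi_lo_concentrated > hi_lo_dilute else "toward-low-mw"
    )
    return DilutionShift("concentration-dependent-shift", direction, fold)
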