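"""In-silico tryptic digestion and observable-peptide counting.

The observable-peptide count ``N_obsbl`` is the denominator of the emPAI
index: the number of fully cleaved tryptic peptides of the mature protein
sequence that the mass spectrometer could plausibly have seen (length and
precursor-mass window). Secreted proteins are digested after removal of the
signal peptide, since the mature protein is what the instrument samples.

Cleavage rule: C-terminal to K or R, except when the next residue is P.
Coordinates are 0-based, half-open on the mature sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import ProteinRecord, RunConfig

#: Monoisotopic residue masses (Da), standard table.
MONOISOTOPIC_RESIDUE_MASS = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}
MONOISOTOPIC_WATER = 18.010565

#: Average residue masses (Da), standard Expasy/IUPAC table.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519,
    "A": 71.0788,
    "S": 87.0782,
    "P": 97.1167,
    "V": 99.1326,
    "T": 101.1051,
    "C": 103.1388,
    "L": 113.1594,
    "I": 113.1594,
    "N": 114.1038,
    "D": 115.0886,
    "Q": 128.1307,
    "K": 128.1741,
    "E": 129.1155,
    "M": 131.1926,
    "H": 137.1411,
    "F": 147.1766,
    "R": 156.1875,
    "Y": 163.1760,
    "W": 186.2132,
}
AVERAGE_WATER = 18.0153


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide located on the mature sequence."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    monoisotopic_mass_da: float


def peptide_monoisotopic_mass(sequence: str) -> float:
    """Monoisotopic peptide mass: residue sum plus one water."""
    return sum(MONOISOTOPIC_RESIDUE_MASS[a] for a in sequence) + MONOISOTOPIC_WATER


def mature_sequence(protein: ProteinRecord) -> str:
    """Sequence actually present in the sample: signal peptide removed if secreted."""
    if protein.is_secreted:
        return protein.sequence[protein.signal_peptide_length :]
    return protein.sequence


def cleavage_sites(sequence: str) -> list[int]:
    """Positions after which trypsin cuts (K/R not followed by P)."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(sequence: str, missed_cleavages: int = 0) -> list[Peptide]:
    """Tryptic peptides of ``sequence`` with up to ``missed_cleavages`` misses.

    With 0 missed cleavages the peptides tile the sequence exactly; with m,
    every join of up to m+1 adjacent fragments is additionally emitted.
    Ordered by start position, then by end.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    bounds = [0] + cleavage_sites(sequence) + [len(sequence)]
    peptides: list[Peptide] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for m in range(missed_cleavages + 1):
            j = i + m + 1
            if j > n_frag:
                break
            start, end = bounds[i], bounds[j]
            sub = sequence[start:end]
            peptides.append(
                Peptide(
                    sequence=sub,
                    start=start,
                    end=end,
                    missed_cleavages=m,
                    monoisotopic_mass_da=peptide_monoisotopic_mass(sub),
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def observable_peptides(protein: ProteinRecord, config: RunConfig) -> list[Peptide]:
    """Fully cleaved peptides of the mature sequence inside the observability window."""
    mature = mature_sequence(protein)
    return [
        p
        for p in digest(mature, missed_cleavages=0)
        if len(p.sequence) >= config.min_peptide_length
        and config.m_min_da <= p.monoisotopic_mass_da <= config.m_max_da
    ]


def observable_count(protein: ProteinRecord, config: RunConfig) -> int:
    """``N_obsbl``: how many tryptic peptides of the mature protein are observable."""
    return len(observable_peptides(protein, config))


def protein_mw_cache(proteome: list[ProteinRecord]) -> dict[str, float]:
    """Average molecular weight in Da per accession (full, unprocessed sequence)."""
    return {
        r.accession: sum(AVERAGE_RESIDUE_MASS[a] for a in r.sequence) + AVERAGE_WATER
        for r in proteome
    }
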