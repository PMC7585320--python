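"""Per-protein per-slice abundance indices: emPAI and Top3.

emPAI (exponentially modified protein abundance index) is the
spectral-counting proxy ``10^(N_obsd/N_obsbl) - 1`` where ``N_obsd`` is the
number of distinct detected tryptic peptides (charge states collapsed) and
``N_obsbl`` the number of observable peptides of the mature sequence. Top3
averages the three most intense precursor ions of a protein in a slice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .digestion import mature_sequence, observable_peptides
from .identification import FilterResult
from .io_formats import ProteinRecord, RunConfig

logger = logging.getLogger("antquant")


class UnquantifiableError(ValueError):
    """emPAI undefined: the protein has no observable peptides (N_obsbl = 0).

    Mirrors the dash cells of the published tables, where a protein with an
    incompletely known sequence is reported as detected but unquantified.
    """


@dataclass
class SliceQuant:
    accession: str
    sample_id: str
    slice_id: str
    n_obsd: int
    n_obsbl: int
    empai: float | None  # None = detected-unquantified (N_obsbl = 0)
    top3: float
    peptides: list[tuple[str, int, int]] = field(default_factory=list)


def empai(n_obsd: int, n_obsbl: int) -> float:
    """``10^(N_obsd/N_obsbl) - 1``; N_obsd above N_obsbl is clamped with a warning."""
    if n_obsd < 0:
        raise ValueError("n_obsd must be >= 0")
    if n_obsbl == 0:
        raise UnquantifiableError(
            "no observable peptides: protein is detected-unquantified"
        )
    if n_obsbl < 0:
        raise ValueError("n_obsbl must be >= 1")
    if n_obsd > n_obsbl:
        logger.warning(
            "n_obsd %d exceeds n_obsbl %d; clamping (detected peptides outside "
            "the observability window)",
            n_obsd,
            n_obsbl,
        )
        n_obsd = n_obsbl
    return 10.0 ** (n_obsd / n_obsbl) - 1.0


def top3(intensities: list[float]) -> float:
    """Mean of the three largest intensities (mean of all when fewer than three)."""
    if not intensities:
        raise ValueError("top3 of an empty intensity list")
    if any(x < 0 for x in intensities):
        raise ValueError("intensities must be non-negative")
    best = sorted(intensities, reverse=True)[:3]
    return sum(best) / len(best)


def quantify_slices(
    filter_result: FilterResult,
    proteome: list[ProteinRecord],
    config: RunConfig,
) -> list[SliceQuant]:
    """One SliceQuant per (protein, sample, slice) with >= 1 accepted peptide.

    ``N_obsd`` counts distinct peptide sequences (charges collapsed) and is
    not restricted to the observability window; ``N_obsbl`` is recomputed
    from the mature sequence. Trypsin autolysis peptides are quantified like
    any other protein — the normalization stage consumes them.
    """
    by_acc = {p.accession: p for p in proteome}
    groups: dict[tuple[str, str, str], dict] = {}
    for psm in filter_result.accepted:
        if psm.accession not in by_acc:
            raise KeyError(f"PSM references unknown accession {psm.accession!r}")
        key = (psm.accession, psm.sample_id, psm.slice_id)
        g = groups.setdefault(key, {"peptides": set(), "intensities": []})
        g["peptides"].add(psm.peptide)
        g["intensities"].append(psm.intensity)

    # cache per-protein observability
    obs_cache: dict[str, list] = {}
    quants: list[SliceQuant] = []
    for (acc, sample, slice_id), g in sorted(groups.items()):
        protein = by_acc[acc]
        if acc not in obs_cache:
            obs_cache[acc] = observable_peptides(protein, config)
        obs = obs_cache[acc]
        n_obsbl = len(obs)
        n_obsd = len(g["peptides"])
        try:
            value: float | None = empai(n_obsd, n_obsbl)
        except UnquantifiableError:
            value = None
        mature = mature_sequence(protein)
        located = []
        for pep in sorted(g["peptides"]):
            start = mature.find(pep)
            located.append((pep, start, start + len(pep)) if start >= 0 else (pep, -1, -1))
        quants.append(
            SliceQuant(
                accession=acc,
                sample_id=sample,
                slice_id=slice_id,
                n_obsd=n_obsd,
                n_obsbl=n_obsbl,
                empai=value,
                top3=top3(g["intensities"]),
                peptides=located,
            )
        )
    return quants


def write_slice_quants(quants: list[SliceQuant], path) -> None:
    import pandas as pd

    rows = []
    for q in quants:
        rows.append(
            {
                "accession": q.accession,
                "sample_id": q.sample_id,
                "slice_id": q.slice_id,
                "n_obsd": q.n_obsd,
                "n_obsbl": q.n_obsbl,
                "empai": "-" if q.empai is None else repr(q.empai),
                "top3": repr(q.top3),
                "peptides": ";".join(f"{p}|{s}|{e}" for p, s, e in q.peptides),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "accession",
            "sample_id",
            "slice_id",
            "n_obsd",
            "n_obsbl",
            "empai",
            "top3",
            "peptides",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_slice_quants(path) -> list[SliceQuant]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    quants = []
    for row in df.itertuples(index=False):
        peptides = []
        if isinstance(row.peptides, str) and row.peptides:
            for token in row.peptides.split(";"):
                pep, start, end = token.split("|")
                peptides.append((pep, int(start), int(end)))
        quants.append(
            SliceQuant(
                accession=row.accession,
                sample_id=row.sample_id,
                slice_id=row.slice_id,
                n_obsd=int(row.n_obsd),
                n_obsbl=int(row.n_obsbl),
                empai=None if row.empai == "-" else float(row.empai),
                top3=float(row.top3),
                peptides=peptides,
            )
        )
    return quants
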