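"""Score thresholding and target-decoy FDR control over PSM tables.

Two filters are applied conjunctively, mirroring search-engine practice:
each PSM must exceed its own identity threshold (the per-spectrum
significance bound), and the whole table is thresholded at the smallest
score cutoff whose decoy-estimated false discovery rate is at or below the
configured target (default 1%). The FDR estimator is the plain decoy/target
ratio D/T, which is monotone in the cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_formats import PSM

logger = logging.getLogger("antquant")

#: Returned (max score + EPSILON) when no finite cutoff reaches the target.
EPSILON = 1e-6


@dataclass
class FilterResult:
    accepted: list[PSM]
    score_cutoff: float
    achieved_fdr: float
    peptide_counts: dict[str, int] = field(default_factory=dict)
    single_peptide_flags: set[str] = field(default_factory=set)

    @property
    def detected_accessions(self) -> set[str]:
        return set(self.peptide_counts)


def fdr_cutoff(psms: list[PSM], fdr_target: float) -> tuple[float, float]:
    """Smallest score cutoff with decoy/target ratio <= ``fdr_target``.

    Returns ``(cutoff, achieved_fdr)``. If no finite cutoff reaches the
    target the maximum observed score + epsilon is returned with a warning
    (nothing will be accepted).
    """
    targets = sorted(p.score for p in psms if not p.is_decoy)
    decoys = sorted(p.score for p in psms if p.is_decoy)
    if not targets:
        raise ValueError("no target PSMs: cannot estimate an FDR cutoff")

    import bisect

    candidates = sorted(set(targets) | set(decoys))
    for c in candidates:
        n_t = len(targets) - bisect.bisect_left(targets, c)
        n_d = len(decoys) - bisect.bisect_left(decoys, c)
        if n_t == 0:
            break
        fdr = n_d / n_t
        if fdr <= fdr_target:
            return c, fdr
    logger.warning(
        "no score cutoff achieves FDR <= %g; returning max score + epsilon "
        "(empty acceptance)",
        fdr_target,
    )
    return candidates[-1] + EPSILON, 0.0


def apply_filters(psms: list[PSM], cutoff: float, achieved_fdr: float = 0.0) -> FilterResult:
    """Accept non-decoy PSMs with score >= cutoff and score > identity threshold.

    A protein with at least one accepted peptide is *detected*; proteins
    supported by exactly one distinct peptide sequence are flagged, matching
    the single-peptide footnotes of the published tables.
    """
    accepted = [
        p
        for p in psms
        if not p.is_decoy and p.score >= cutoff and p.score > p.identity_threshold
    ]
    peptides_by_protein: dict[str, set[str]] = {}
    for p in accepted:
        peptides_by_protein.setdefault(p.accession, set()).add(p.peptide)
    counts = {acc: len(peps) for acc, peps in peptides_by_protein.items()}
    flags = {acc for acc, n in counts.items() if n == 1}
    return FilterResult(
        accepted=accepted,
        score_cutoff=cutoff,
        achieved_fdr=achieved_fdr,
        peptide_counts=counts,
        single_peptide_flags=flags,
    )


def filter_psms(psms: list[PSM], fdr_target: float = 0.01) -> FilterResult:
    """Convenience composition: estimate the cutoff, then apply both filters."""
    cutoff, fdr = fdr_cutoff(psms, fdr_target)
    return apply_filters(psms, cutoff, fdr)
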