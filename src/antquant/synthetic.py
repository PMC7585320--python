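"""Synthetic proteomes and per-slice PSM tables with known ground truth.

The generator emulates the study design that the pipeline was built for:
three pooled appendage samples (worker antenna, male antenna, worker tibia),
each run in four gel slices, with a GAPDH-like reference protein, porcine
trypsin autolysis products in every slice, reversed-sequence decoys, and a
co-receptor/SNMP pair whose worker:male abundance ratios mirror the
measured 5:1 and 1:1 values.

Detection model (a stand-in — no detectability model is published for this
dataset): each observable peptide of protein p in slice s is seen with
probability ``q = 1 - (1 + C_p * V_s / kappa) ** -beta``, a saturating
curve under which emPAI grows roughly linearly with log concentration over
the simulated 100-fold range, akin to the empirical behaviour the index was
designed around. Trypsin autolysis signal is inversely proportional to the
relative slice volume, which is exactly the assumption the volume-correction
stage is built on. All randomness flows from one seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digestion import observable_peptides, protein_mw_cache
from .io_formats import PSM, GelSlice, ProteinRecord, RunConfig

_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Residue sampling weights: K+R together ~11% (tryptic site density of a
#: typical proteome); the remaining mass spread evenly.
_AA_WEIGHTS = np.array(
    [
        (0.057 if a == "K" else 0.053 if a == "R" else 0.89 / 18.0)
        for a in _AA
    ]
)
_AA_WEIGHTS /= _AA_WEIGHTS.sum()

MANDATORY_ACCESSIONS = ("GAPDH", "TRYPSIN", "ORCO", "SNMP1")

#: all generated members draw lengths uniformly from this range
_LENGTH_RANGE = (80, 600)
_SECRETED_FAMILIES = {"OBP", "CSP", "TULIP"}


@dataclass
class SimulationConfig:
    """Study conditions of a simulated experiment."""

    n_proteins: int = 200
    tissues: tuple = ("worker_antenna", "male_antenna", "worker_tibia")
    #: per-tissue true concentrations; generated log-uniformly when None
    tissue_abundances: dict | None = None
    abundance_low: float = 1.0
    abundance_high: float = 100.0
    absent_fraction: float = 0.2
    slices_per_sample: int = 4
    #: relative injected volume per slice index; rescaled so the slice
    #: containing the reference protein has factor 1
    volume_factors: tuple = (0.6, 1.0, 1.1, 0.8)
    kappa: float = 5.0
    beta: float = 1.0
    intensity_scale: float = 1.0e6
    intensity_cv: float = 0.3
    identity_threshold: float = 30.0
    true_score_mean: float = 60.0
    true_score_sd: float = 10.0
    null_score_mean: float = 15.0
    null_score_sd: float = 8.0
    decoy_fraction: float = 0.10
    duplicate_charge_prob: float = 0.2
    trypsin_level: float = 30.0
    gapdh_level: float = 50.0
    #: (worker, male, tibia) true concentrations of the special proteins;
    #: worker:male 5:1 for the co-receptor and 1:1 for SNMP, as measured,
    #: at levels where both castes are robustly detectable (as they were)
    orco_abundances: tuple = (20.0, 4.0, 0.0)
    snmp_abundances: tuple = (10.0, 10.0, 0.0)
    #: accessions forced to appear in every slice (instead of one home slice);
    #: probes for the volume-correction stage, pinned at a moderate abundance
    #: where detection responds to injected volume rather than saturating
    uniform_accessions: tuple = ()
    uniform_abundance: float = 5.0
    min_peptide_length: int = 6
    m_min_da: float = 800.0
    m_max_da: float = 3000.0
    seed: int = 0

    def run_config(self, **overrides) -> RunConfig:
        """RunConfig matching these simulation conditions."""
        kwargs = dict(
            min_peptide_length=self.min_peptide_length,
            m_min_da=self.m_min_da,
            m_max_da=self.m_max_da,
            seed=self.seed,
        )
        kwargs.update(overrides)
        return RunConfig(**kwargs)


@dataclass
class GroundTruth:
    """What the simulator knows and the pipeline must recover."""

    abundances: dict  # tissue -> accession -> C
    volume_factors: dict  # slice_id -> V_s
    slice_assignment: dict  # accession -> slice_id ("*" = all slices)
    reference_slice: str
    is_false: list = field(default_factory=list)  # aligned with the PSM list
    slices: list = field(default_factory=list)  # GelSlice metadata

    def abundance_frame(self) -> pd.DataFrame:
        rows = [
            {"tissue": t, "accession": a, "true_abundance": c}
            for t, accs in self.abundances.items()
            for a, c in accs.items()
        ]
        return pd.DataFrame(rows, columns=["tissue", "accession", "true_abundance"])


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length, p=_AA_WEIGHTS))


def generate_proteome(
    config: SimulationConfig, seed: int | None = None
) -> list[ProteinRecord]:
    """Random proteome including the four mandatory roles.

    Always contains a GAPDH-like reference, a trypsin entry, a co-receptor
    (ORCO) and an SNMP record, plus OBP/CSP/P450/TULIP family members, so
    every downstream analysis has its required inputs. Deterministic given
    the seed.
    """
    if config.n_proteins < 5:
        raise ValueError("n_proteins must be >= 5 (four mandatory roles + members)")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records = [
        ProteinRecord("GAPDH", _random_sequence(rng, 333), family="REFERENCE"),
        ProteinRecord("TRYPSIN", _random_sequence(rng, 231), family="TRYPSIN"),
        ProteinRecord("ORCO", _random_sequence(rng, 473), family="ORCO"),
        ProteinRecord("SNMP1", _random_sequence(rng, 520), family="SNMP"),
    ]
    family_cycle = ["OBP", "CSP", "P450", "TULIP", "OTHER", "OTHER", "OTHER", "OTHER"]
    for i in range(config.n_proteins - len(MANDATORY_ACCESSIONS)):
        family = family_cycle[i % len(family_cycle)]
        lo, hi = _LENGTH_RANGE
        length = int(rng.integers(lo, hi + 1))
        secreted = family in _SECRETED_FAMILIES
        signal = int(rng.integers(15, 31)) if secreted else 0
        records.append(
            ProteinRecord(
                accession=f"SINV{i:04d}",
                sequence=_random_sequence(rng, length),
                is_secreted=secreted,
                signal_peptide_length=signal,
                family=family,
            )
        )
    return records


def _default_abundances(
    proteome: list[ProteinRecord], config: SimulationConfig, rng: np.random.Generator
) -> dict:
    """Log-uniform concentrations over [low, high] with per-tissue absences."""
    specials = {
        "GAPDH": (config.gapdh_level,) * len(config.tissues),
        "ORCO": config.orco_abundances,
        "SNMP1": config.snmp_abundances,
    }
    abundances: dict = {t: {} for t in config.tissues}
    log_lo, log_hi = math.log(config.abundance_low), math.log(config.abundance_high)
    for rec in proteome:
        if rec.accession == "TRYPSIN":
            continue  # reagent, not a tissue protein
        for ti, tissue in enumerate(config.tissues):
            if rec.accession in specials:
                c = float(specials[rec.accession][ti])
            elif rec.accession in config.uniform_accessions:
                c = config.uniform_abundance
            elif rng.random() < config.absent_fraction:
                c = 0.0
            else:
                c = math.exp(rng.uniform(log_lo, log_hi))
            abundances[tissue][rec.accession] = c
    return abundances


def _slice_assignment(
    proteome: list[ProteinRecord], config: SimulationConfig
) -> dict:
    """Bin proteins into gel slices by molecular weight (gel top = heavy)."""
    weights = protein_mw_cache(proteome)
    sortable = [r.accession for r in proteome if r.accession != "TRYPSIN"]
    sortable.sort(key=lambda a: -weights[a])
    n_slices = config.slices_per_sample
    assignment = {}
    per_slice = math.ceil(len(sortable) / n_slices)
    for rank, acc in enumerate(sortable):
        assignment[acc] = f"S{min(rank // per_slice, n_slices - 1) + 1}"
    for acc in config.uniform_accessions:
        assignment[acc] = "*"
    return assignment


def simulate_psms(
    proteome: list[ProteinRecord],
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[list[PSM], GroundTruth]:
    """Simulate per-slice PSM tables plus the ground truth behind them.

    Emits true PSMs under the saturating detection model, trypsin autolysis
    PSMs in every slice with signal proportional to 1/V_s, reversed-sequence
    decoys, and an equal number of false target matches drawn from the same
    null score distribution (the working assumption of target-decoy FDR
    estimation).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    by_acc = {r.accession: r for r in proteome}
    run_cfg = config.run_config()
    abundances = config.tissue_abundances or _default_abundances(proteome, config, rng)
    for tissue, accs in abundances.items():
        unknown = set(accs) - set(by_acc)
        if unknown:
            raise KeyError(f"{tissue}: abundances for unknown accessions {sorted(unknown)}")

    observable = {r.accession: observable_peptides(r, run_cfg) for r in proteome}
    assignment = _slice_assignment(proteome, config)
    slice_ids = [f"S{i + 1}" for i in range(config.slices_per_sample)]
    ref_slice = assignment["GAPDH"]
    raw_vf = dict(zip(slice_ids, config.volume_factors))
    vf = {s: raw_vf[s] / raw_vf[ref_slice] for s in slice_ids}

    def detection_prob(c_eff: float) -> float:
        if c_eff <= 0:
            return 0.0
        if config.kappa == 0:
            return 1.0
        return 1.0 - (1.0 + c_eff / config.kappa) ** (-config.beta)

    def lognoise() -> float:
        return float(rng.lognormal(mean=0.0, sigma=config.intensity_cv))

    psms: list[PSM] = []
    is_false: list[bool] = []

    def emit(peptide, accession, sample, slice_id, amount, true_match: bool) -> None:
        if true_match:
            score = float(rng.normal(config.true_score_mean, config.true_score_sd))
        else:
            score = float(rng.normal(config.null_score_mean, config.null_score_sd))
        intensity = max(amount * config.intensity_scale * lognoise(), 0.0)
        charge = int(rng.choice([2, 3]))
        psms.append(
            PSM(
                peptide=peptide,
                accession=accession,
                sample_id=sample,
                slice_id=slice_id,
                score=score,
                identity_threshold=config.identity_threshold,
                intensity=intensity,
                charge=charge,
                is_decoy=accession.startswith("rev_"),
            )
        )
        is_false.append(not true_match)

    # --- true tissue-protein PSMs ---------------------------------------
    for tissue in config.tissues:
        for rec in proteome:
            if rec.accession == "TRYPSIN":
                continue
            c = abundances[tissue].get(rec.accession, 0.0)
            if c <= 0:
                continue
            home = assignment[rec.accession]
            slices = slice_ids if home == "*" else [home]
            for s in slices:
                amount = c * vf[s]
                q = detection_prob(amount)
                for pep in observable[rec.accession]:
                    if rng.random() < q:
                        emit(pep.sequence, rec.accession, tissue, s, amount, True)
                        if rng.random() < config.duplicate_charge_prob:
                            emit(pep.sequence, rec.accession, tissue, s, amount, True)

    # --- trypsin autolysis: every slice, signal ~ 1/V_s ------------------
    for tissue in config.tissues:
        for s in slice_ids:
            amount = config.trypsin_level / vf[s]
            q = detection_prob(amount)
            for pep in observable["TRYPSIN"]:
                if rng.random() < q:
                    emit(pep.sequence, "TRYPSIN", tissue, s, amount, True)

    # --- decoys and false target matches ---------------------------------
    n_true = len(psms)
    d = config.decoy_fraction
    rate = d / (1.0 - 2.0 * d)
    n_decoys = int(rng.poisson(rate * n_true))
    n_false = int(rng.poisson(rate * n_true))
    candidates = [r.accession for r in proteome if observable[r.accession]]
    for _ in range(n_decoys):
        acc = candidates[int(rng.integers(len(candidates)))]
        peps = observable[acc]
        pep = peps[int(rng.integers(len(peps)))].sequence[::-1]
        tissue = config.tissues[int(rng.integers(len(config.tissues)))]
        s = slice_ids[int(rng.integers(len(slice_ids)))]
        emit(pep, f"rev_{acc}", tissue, s, 0.01, False)
    for _ in range(n_false):
        acc = candidates[int(rng.integers(len(candidates)))]
        peps = observable[acc]
        pep = peps[int(rng.integers(len(peps)))].sequence
        tissue = config.tissues[int(rng.integers(len(config.tissues)))]
        s = slice_ids[int(rng.integers(len(slice_ids)))]
        emit(pep, acc, tissue, s, 0.01, False)

    slices_meta = [
        GelSlice(sample_id=t, slice_id=s, contains_reference=(s == ref_slice))
        for t in config.tissues
        for s in slice_ids
    ]
    truth = GroundTruth(
        abundances=abundances,
        volume_factors=vf,
        slice_assignment=assignment,
        reference_slice=ref_slice,
        is_false=is_false,
        slices=slices_meta,
    )
    return psms, truth


def simulate(
    config: SimulationConfig, seed: int | None = None
) -> tuple[list[ProteinRecord], list[PSM], GroundTruth]:
    """Generate a proteome and its PSM table in one call."""
    proteome = generate_proteome(config, seed)
    psms, truth = simulate_psms(proteome, config, seed)
    return proteome, psms, truth
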