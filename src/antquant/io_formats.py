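"""Readers and writers for the package's external formats.

Covers protein FASTA with annotated headers, the tab-separated PSM
(peptide-spectrum match) schema, abundance tables with the three-state cell
semantics used throughout (value / absent / detected-but-unquantifiable),
packaged transcriptions of the published appendage tables, and the TOML run
configuration.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("antquant")

#: The 20 standard amino acids; anything else in a FASTA body is rejected.
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Controlled vocabulary of protein family tags.
FAMILIES = frozenset(
    {
        "OBP",
        "CSP",
        "TULIP",
        "LIPOCALIN",
        "NPC2",
        "P450",
        "GST",
        "UDPGT",
        "ESTERASE",
        "DEHYDROGENASE",
        "ORCO",
        "SNMP",
        "REFERENCE",
        "TRYPSIN",
        "OTHER",
    }
)

PSM_COLUMNS = [
    "peptide",
    "accession",
    "sample_id",
    "slice_id",
    "score",
    "identity_threshold",
    "intensity",
    "charge",
    "is_decoy",
]

_FIXTURE_NAMES = ("table1", "table2", "table3", "table4", "table5", "table6")


class FormatError(ValueError):
    """A file is syntactically malformed (bad header, bad residue, bad cell)."""


class SchemaError(ValueError):
    """A tabular file is missing required columns."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """One database protein: the unit of quantification."""

    accession: str
    sequence: str
    is_secreted: bool = False
    signal_peptide_length: int = 0
    family: str = "OTHER"
    annotation: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise FormatError(
                f"{self.accession}: non-amino-acid characters {sorted(bad)}"
            )
        if self.signal_peptide_length < 0:
            raise ValueError(f"{self.accession}: negative signal peptide length")
        if self.signal_peptide_length >= len(self.sequence):
            raise ValueError(
                f"{self.accession}: signal peptide length "
                f"{self.signal_peptide_length} >= sequence length"
            )
        if not self.is_secreted and self.signal_peptide_length != 0:
            raise ValueError(
                f"{self.accession}: non-secreted protein with signal peptide"
            )
        if self.family not in FAMILIES:
            raise ValueError(f"{self.accession}: unknown family {self.family!r}")


@dataclass(frozen=True)
class PSM:
    """One identified peptide observation in one sample / gel slice."""

    peptide: str
    accession: str
    sample_id: str
    slice_id: str
    score: float
    identity_threshold: float
    intensity: float
    charge: int
    is_decoy: bool

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("empty peptide")
        if self.intensity < 0:
            raise ValueError(f"negative intensity {self.intensity}")
        if self.identity_threshold <= 0:
            raise ValueError("identity threshold must be positive")


@dataclass(frozen=True)
class GelSlice:
    """Metadata for one excised gel segment of one sample."""

    sample_id: str
    slice_id: str
    mw_low_kda: float | None = None
    mw_high_kda: float | None = None
    contains_reference: bool = False

    def __post_init__(self) -> None:
        if (
            self.mw_low_kda is not None
            and self.mw_high_kda is not None
            and not self.mw_low_kda < self.mw_high_kda
        ):
            raise ValueError("mw_low_kda must be < mw_high_kda")


@dataclass
class RunConfig:
    """Constants of a quantification run.

    The peptide FDR target (1%) and the reference/trypsin identities are the
    method's stated constants; the observability window and minimum peptide
    length follow common emPAI practice and are freely configurable.
    """

    reference_accession: str = "GAPDH"
    trypsin_accession: str = "TRYPSIN"
    orco_accession: str = "ORCO"
    snmp_accession: str = "SNMP1"
    fdr_target: float = 0.01
    missed_cleavages: int = 0
    m_min_da: float = 800.0
    m_max_da: float = 3000.0
    min_peptide_length: int = 6
    ratio_precision: int = 2
    trypsin_proportional: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_target < 1:
            raise ValueError("fdr_target must lie in (0, 1)")
        if not self.m_min_da < self.m_max_da:
            raise ValueError("mass window must satisfy m_min_da < m_max_da")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_KNOWN_HEADER_KEYS = {"secreted", "signal_len", "family", "annotation"}


def _parse_header(description: str, line_no: int) -> dict:
    """Parse ``accession [key=value ...]`` FASTA descriptions."""
    parts = description.split()
    if not parts:
        raise FormatError(f"line {line_no}: empty FASTA header")
    fields: dict = {"accession": parts[0]}
    for token in parts[1:]:
        if "=" not in token:
            raise FormatError(
                f"line {line_no}: malformed header token {token!r} (expected key=value)"
            )
        key, value = token.split("=", 1)
        if key not in _KNOWN_HEADER_KEYS:
            logger.warning("FASTA header line %d: ignoring unknown key %r", line_no, key)
            continue
        fields[key] = value
    return fields


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from FASTA with ``accession [key=value ...]`` headers.

    Recognised keys: ``secreted`` (0/1), ``signal_len`` (residues),
    ``family`` (controlled vocabulary, unknown values map to OTHER with a
    warning), ``annotation``. Unknown keys are ignored with a warning.
    """
    path = Path(path)
    # track header line numbers for error messages
    header_lines: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                header_lines.setdefault(line[1:].split()[0] if line[1:].split() else "", i)

    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        line_no = header_lines.get(rec.id, 0)
        fields = _parse_header(rec.description, line_no)
        family = fields.get("family", "OTHER").upper()
        if family not in FAMILIES:
            logger.warning(
                "FASTA %s: unknown family %r mapped to OTHER", fields["accession"], family
            )
            family = "OTHER"
        secreted = fields.get("secreted", "0") in {"1", "true", "True"}
        signal_len = int(fields.get("signal_len", "0")) if secreted else 0
        sequence = str(rec.seq).upper()
        bad = set(sequence) - AMINO_ACIDS
        if bad:
            raise FormatError(
                f"line {line_no}: entry {fields['accession']} contains "
                f"non-amino-acid characters {sorted(bad)}"
            )
        records.append(
            ProteinRecord(
                accession=fields["accession"],
                sequence=sequence,
                is_secreted=secreted,
                signal_peptide_length=signal_len,
                family=family,
                annotation=fields.get("annotation", ""),
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records using the same annotated-header convention read_fasta parses."""
    seq_records = []
    for rec in records:
        desc = (
            f"secreted={int(rec.is_secreted)} "
            f"signal_len={rec.signal_peptide_length} family={rec.family}"
        )
        seq_records.append(
            SeqRecord(Seq(rec.sequence), id=rec.accession, description=desc)
        )
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

_TRUTHY = {"1", "true", "True", "TRUE"}
_FALSY = {"0", "false", "False", "FALSE"}


def read_psm_table(path: str | Path) -> list[PSM]:
    """Read a tab-separated PSM table (the stand-in for a search-engine export)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    psms: list[PSM] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        flag = str(row.is_decoy)
        if flag in _TRUTHY:
            decoy = True
        elif flag in _FALSY:
            decoy = False
        else:
            raise FormatError(f"{path} row {row_no}: bad is_decoy value {flag!r}")
        intensity = float(row.intensity)
        if intensity < 0:
            raise ValueError(f"{path} row {row_no}: negative intensity {intensity}")
        psms.append(
            PSM(
                peptide=str(row.peptide),
                accession=str(row.accession),
                sample_id=str(row.sample_id),
                slice_id=str(row.slice_id),
                score=float(row.score),
                identity_threshold=float(row.identity_threshold),
                intensity=intensity,
                charge=int(row.charge),
                is_decoy=decoy,
            )
        )
    return psms


def write_psm_table(psms: Iterable[PSM], path: str | Path) -> None:
    rows = [
        {
            "peptide": p.peptide,
            "accession": p.accession,
            "sample_id": p.sample_id,
            "slice_id": p.slice_id,
            "score": repr(p.score),
            "identity_threshold": repr(p.identity_threshold),
            "intensity": repr(p.intensity),
            "charge": p.charge,
            "is_decoy": int(p.is_decoy),
        }
        for p in psms
    ]
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------


class AbundanceTable:
    """Per-protein per-appendage normalized abundances with three cell states.

    A cell is one of

    * a value (``>= 0``; 0 means not detected, matching the published tables
      where 0 cells denote absence),
    * *detected-unquantified* (printed as a dash: the protein was identified
      but its full sequence is unknown, so an observable-peptide count — and
      hence an emPAI — cannot be computed),
    * absent (value 0 and no dash flag).

    ``values`` holds floats with NaN exactly where a cell is a dash;
    ``dash`` and ``single_peptide`` are boolean masks of the same shape.
    ``meta`` carries free-text columns (name/family labels).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        dash: pd.DataFrame | None = None,
        single_peptide: pd.DataFrame | None = None,
        meta: pd.DataFrame | None = None,
    ) -> None:
        self.values = values.astype(float)
        shape_like = lambda fill: pd.DataFrame(  # noqa: E731
            fill, index=values.index, columns=values.columns
        )
        self.dash = (dash if dash is not None else shape_like(False)).astype(bool)
        self.single_peptide = (
            single_peptide if single_peptide is not None else shape_like(False)
        ).astype(bool)
        self.meta = meta
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundance values must be >= 0")
        nan_mask = self.values.isna()
        if not nan_mask.equals(self.dash):
            raise ValueError("NaN cells and dash mask must coincide")

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask: value > 0 or dash."""
        return (self.values > 0) | self.dash

    def cell_state(self, accession: str, tissue: str) -> str:
        v = self.values.loc[accession, tissue]
        d = self.dash.loc[accession, tissue]
        if np.ndim(v) > 0:  # duplicated accession rows: merged view
            if bool(np.asarray(d).any()):
                return "detected-unquantified"
            v = float(np.nansum(np.asarray(v, dtype=float)))
            return "value" if v > 0 else "absent"
        if bool(d):
            return "detected-unquantified"
        return "value" if float(v) > 0 else "absent"

    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame(index=self.values.index)
        if self.meta is not None:
            out = self.meta.copy()
        for col in self.values.columns:
            cells = []
            for acc_i in range(len(self.values)):
                if self.dash.iloc[acc_i][col]:
                    cells.append("-")
                else:
                    cells.append(repr(float(self.values.iloc[acc_i][col])))
            out[col] = cells
        flags = []
        for acc_i in range(len(self.values)):
            flagged = [c for c in self.values.columns if self.single_peptide.iloc[acc_i][c]]
            flags.append(";".join(flagged))
        out["single_peptide"] = flags
        out.index.name = "accession"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, tissues: list[str] | None = None) -> "AbundanceTable":
        raw = pd.read_csv(path, sep="\t", dtype=str).set_index("accession")
        if tissues is None:
            known_meta = {"name", "label", "family", "single_peptide"}
            tissues = [c for c in raw.columns if c not in known_meta]
        meta_cols = [c for c in raw.columns if c not in tissues and c != "single_peptide"]
        values = pd.DataFrame(index=raw.index, columns=tissues, dtype=float)
        dash = pd.DataFrame(False, index=raw.index, columns=tissues)
        single = pd.DataFrame(False, index=raw.index, columns=tissues)
        for i in range(len(raw)):
            for col in tissues:
                cell = str(raw.iloc[i][col]).strip()
                if cell in {"-", "–"}:
                    values.iloc[i, tissues.index(col)] = np.nan
                    dash.iloc[i, tissues.index(col)] = True
                else:
                    try:
                        values.iloc[i, tissues.index(col)] = float(cell)
                    except ValueError as exc:
                        raise FormatError(
                            f"{path} row {i + 2} column {col}: bad cell {cell!r}"
                        ) from exc
        if "single_peptide" in raw.columns:
            for i in range(len(raw)):
                cell = raw.iloc[i]["single_peptide"]
                if isinstance(cell, str) and cell.strip():
                    for col in cell.split(";"):
                        col = col.strip()
                        if col in tissues:
                            single.iloc[i, tissues.index(col)] = True
        meta = raw[meta_cols] if meta_cols else None
        return cls(values, dash, single, meta)


# ---------------------------------------------------------------------------
# packaged fixtures of the published tables
# ---------------------------------------------------------------------------

#: Tissue columns used by the whole-appendage fixture tables.
FIXTURE_TISSUES = ["worker_antenna", "male_antenna", "worker_tibia"]


def _fixture_path(filename: str) -> Path:
    return Path(str(resources.files("antquant.fixtures").joinpath(filename)))


def _fixture_filenames() -> list[str]:
    return sorted(
        f.name
        for f in resources.files("antquant.fixtures").iterdir()
        if f.name.endswith(".tsv")
    )


def load_table_fixture(name: str) -> AbundanceTable:
    """Load one of the packaged transcriptions of the published tables.

    ``table1`` odorant-binding proteins, ``table2`` chemosensory proteins,
    ``table3`` other binding/transport proteins, ``table4`` cytochrome P450s,
    ``table5`` other deactivation enzymes, ``table6`` whole-antenna Orco/SNMP.
    Cells are stored exactly as printed; dash cells load as
    detected-unquantified and footnoted single-peptide identifications carry a
    boolean flag.
    """
    if name not in _FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {_FIXTURE_NAMES}")
    filename = "table6_whole.tsv" if name == "table6" else f"{name}.tsv"
    tissues = (
        FIXTURE_TISSUES if name != "table6" else ["worker_antenna", "male_antenna"]
    )
    return AbundanceTable.from_tsv(_fixture_path(filename), tissues=tissues)


def load_native_gel_fixture() -> pd.DataFrame:
    """Native-gel section quantities (trypsin-normalized emPAI) as a DataFrame.

    Columns: mw_low_kda, mw_high_kda, dilution (dilute/concentrated),
    accession, abundance.
    """
    df = pd.read_csv(_fixture_path("table6_sections.tsv"), sep="\t")
    df["mw_low_kda"] = df["mw_low_kda"].astype(float)
    df["mw_high_kda"] = df["mw_high_kda"].astype(float)
    df["abundance"] = df["abundance"].astype(float)
    return df


def fixture_checksums() -> pd.DataFrame:
    """Committed row-count / numeric-column-sum checksums for every fixture TSV."""
    return pd.read_csv(_fixture_path("checksums.tsv"), sep="\t")


def compute_fixture_checksums() -> pd.DataFrame:
    """Recompute row counts and numeric cell sums of the packaged fixture TSVs."""
    rows = []
    for filename in _fixture_filenames():
        if filename == "checksums.tsv":
            continue
        df = pd.read_csv(_fixture_path(filename), sep="\t", dtype=str)
        skip = {"accession", "name", "family", "single_peptide", "dilution"}
        total = 0.0
        for col in df.columns:
            if col in skip:
                continue
            for cell in df[col]:
                try:
                    v = float(cell)
                except (TypeError, ValueError):
                    continue
                if not math.isnan(v):
                    total += v
        rows.append(
            {"file": filename, "n_rows": len(df), "numeric_sum": round(total, 4)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TOML configuration
# ---------------------------------------------------------------------------


def load_run_config(path: str | Path) -> RunConfig:
    """Read the ``[run]`` table of a TOML config into a RunConfig."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    section = data.get("run", {})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(section) - known
    if unknown:
        logger.warning("config %s: ignoring unknown run keys %s", path, sorted(unknown))
    kwargs = {k: v for k, v in section.items() if k in known}
    return RunConfig(**kwargs)


def load_toml(path: str | Path) -> Mapping:
    with open(path, "rb") as fh:
        return tomllib.load(fh)
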