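"""Readers and writers for the pipeline's external table formats.

Protein references travel as FASTA; peptide observations, protein groups,
subcellular localization labels, amino-acid analysis (AAA) data and
functional-peptide prediction scores all travel as TSV with a header row.
Decoy and contaminant records are recognized by configurable header/ID
prefixes following the common search-engine convention (``REV_``/``CON_``).

Parsers never silently drop rows: malformed or out-of-contract rows raise,
and rows retained-but-flagged (e.g. zero intensity) stay in the output.
"""

from __future__ import annotations

import dataclasses
import logging
import re
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import AA_MW, CANONICAL_AA, COMPARTMENTS, POOLED_KEYS, UNKNOWN_COMPARTMENT

logger = logging.getLogger(__name__)

_VALID_SEQ = re.compile(f"^[{CANONICAL_AA}]+$")

DECOY_PREFIX = "REV_"
CONTAMINANT_PREFIX = "CON_"

#: Digestion-specificity modes used throughout.
METHODS = ("tryptic", "semi", "unspecific")


class ParseError(ValueError):
    """Malformed input file (bad header, illegal residue, unknown code)."""


class SchemaError(ValueError):
    """A table is missing required columns."""


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """One reference protein: ID, sequence, decoy/contaminant flags and an
    optional subcellular compartment label."""

    protein_id: str
    sequence: str
    is_contaminant: bool = False
    is_decoy: bool = False
    compartment: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"protein {self.protein_id!r}: empty sequence")
        if not _VALID_SEQ.match(self.sequence):
            bad = sorted(set(self.sequence) - set(CANONICAL_AA))
            raise ParseError(
                f"protein {self.protein_id!r}: illegal residue(s) {bad} "
                "(only the 20 canonical letters are accepted)"
            )
        if self.compartment is not None and self.compartment not in COMPARTMENTS \
                and self.compartment != UNKNOWN_COMPARTMENT:
            warnings.warn(
                f"protein {self.protein_id!r}: unrecognized compartment "
                f"{self.compartment!r} mapped to {UNKNOWN_COMPARTMENT!r}",
                stacklevel=2,
            )
            object.__setattr__(self, "compartment", UNKNOWN_COMPARTMENT)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Run-level configuration housing the pipeline's tunable constants."""

    # in-silico digestion
    missed_cleavages: int = 2
    unspecific_min_len: int = 5
    unspecific_max_len: int = 65
    # iBAQ theoretical-peptide window (0 missed cleavages convention)
    ibaq_min_len: int = 7
    ibaq_max_len: int = 30
    ibaq_missed_cleavages: int = 0
    # quality filtering
    min_group_score: float = 40.0
    min_peptides: int = 2
    score_override: float = 100.0
    require_duplicate: bool = True
    abundance_threshold: float = 0.02
    suspect_min_match_count: int = 1000
    # functional-peptide thresholds
    emulsifier_z_threshold: float = 2.0
    sca_threshold: float = 0.43
    che_threshold: float = 0.3
    # misc
    pka_set: str = "default"
    seed: int = 0
    decoy_prefix: str = DECOY_PREFIX
    contaminant_prefix: str = CONTAMINANT_PREFIX

    def __post_init__(self) -> None:
        import math

        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not math.isfinite(v):
                raise ValueError(f"config field {f.name} must be finite, got {v}")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(
    path: str | Path,
    decoy_prefix: str = DECOY_PREFIX,
    contaminant_prefix: str = CONTAMINANT_PREFIX,
) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Decoys and contaminants are recognized by ID prefix. Duplicate IDs or
    illegal residues raise :class:`ParseError` naming the offending record.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id
        if pid in seen:
            raise ParseError(f"duplicate protein ID {pid!r} in {path}")
        seen.add(pid)
        records.append(
            ProteinRecord(
                protein_id=pid,
                sequence=str(entry.seq).upper(),
                is_decoy=pid.startswith(decoy_prefix),
                is_contaminant=pid.startswith(contaminant_prefix),
            )
        )
    if not records:
        raise ParseError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description="")
        for r in records
    ]
    SeqIO.write(entries, str(path), "fasta-2line")


# ---------------------------------------------------------------------------
# Peptide observation tables

#: Canonical column names of the in-memory observation table.
OBSERVATION_COLUMNS = (
    "peptide_sequence",
    "group_id",
    "sample_id",
    "replicate_id",
    "method",
    "intensity",
    "psm_score",
)

#: Column-name maps per input dialect. ``canonical`` is the package's own
#: output; ``maxquant_evidence`` covers the common evidence-table export.
DIALECTS: dict[str, dict[str, str]] = {
    "canonical": {c: c for c in OBSERVATION_COLUMNS},
    "maxquant_evidence": {
        "Sequence": "peptide_sequence",
        "Protein group IDs": "group_id",
        "Experiment": "sample_id",
        "Fraction": "replicate_id",
        "Digestion mode": "method",
        "Intensity": "intensity",
        "Score": "psm_score",
    },
}

_MOD_NOTATION = re.compile(r"[\(\[].*?[\)\]]|[^A-Z]")


def _strip_modifications(seq: str) -> tuple[str, bool]:
    """Drop modification annotations like ``M(ox)`` from a peptide string."""
    plain = _MOD_NOTATION.sub("", seq.strip("_"))
    return plain, plain != seq


def read_peptide_table(
    path: str | Path,
    dialect: str = "canonical",
    sep: str = "\t",
) -> pd.DataFrame:
    """Read a peptide-level quantification table.

    Returns a DataFrame with :data:`OBSERVATION_COLUMNS` plus a boolean
    ``flagged_zero`` column marking rows with zero/missing intensity, which
    are retained (never silently dropped).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}")
    colmap = DIALECTS[dialect]
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = set(colmap) - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {sorted(missing)}; "
            f"found {list(df.columns)}"
        )
    df = df[list(colmap)].rename(columns=colmap)
    stripped = df["peptide_sequence"].map(_strip_modifications)
    n_mod = sum(changed for _, changed in stripped)
    if n_mod:
        warnings.warn(
            f"{n_mod} peptide sequence(s) carried modification notation; "
            "stripped to plain sequences",
            stacklevel=2,
        )
    df["peptide_sequence"] = [seq for seq, _ in stripped]
    df["intensity"] = pd.to_numeric(df["intensity"], errors="coerce").fillna(0.0)
    df["psm_score"] = pd.to_numeric(df["psm_score"], errors="coerce").fillna(0.0)
    if (df["intensity"] < 0).any():
        raise ParseError(f"{path}: negative intensity values")
    bad_method = set(df["method"]) - set(METHODS)
    if bad_method:
        raise ParseError(f"{path}: unknown digestion method(s) {sorted(bad_method)}")
    df["flagged_zero"] = df["intensity"] == 0.0
    bad_len = df[
        (df["method"] == "unspecific")
        & ~df["peptide_sequence"].str.len().between(5, 65)
    ]
    if not bad_len.empty:
        raise ParseError(
            f"{path}: {len(bad_len)} unspecific peptide(s) outside the "
            "5-65 residue window"
        )
    return df.reset_index(drop=True)


def write_peptide_table(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(OBSERVATION_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Protein-group tables

GROUP_COLUMNS = (
    "group_id",
    "member_proteins",  # semicolon-separated protein IDs
    "score",
    "n_peptides",
    "is_contaminant",
    "is_decoy",
)


def read_group_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = set(GROUP_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing group column(s) {sorted(missing)}")
    df["member_proteins"] = df["member_proteins"].astype(str).str.split(";")
    df["is_contaminant"] = df["is_contaminant"].astype(bool)
    df["is_decoy"] = df["is_decoy"].astype(bool)
    return df


def write_group_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["member_proteins"] = out["member_proteins"].map(";".join)
    out.loc[:, list(GROUP_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Localization tables

def read_localization_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a per-protein compartment table (protein_id, compartment[, confidence])."""
    df = pd.read_csv(path, sep=sep)
    missing = {"protein_id", "compartment"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing localization column(s) {sorted(missing)}")
    known = set(COMPARTMENTS) | {UNKNOWN_COMPARTMENT}
    other = set(df["compartment"]) - known
    if other:
        warnings.warn(
            f"{path}: unrecognized compartment label(s) {sorted(other)} "
            f"mapped to {UNKNOWN_COMPARTMENT!r}",
            stacklevel=2,
        )
        df.loc[df["compartment"].isin(other), "compartment"] = UNKNOWN_COMPARTMENT
    return df


# ---------------------------------------------------------------------------
# Amino-acid analysis (AAA) tables

def read_aaa_table(path: str | Path, sep: str = "\t") -> dict[str, float]:
    """Read an AAA table of amino acid -> mg per g extract.

    Keys are one-letter codes or the pooled codes ``Asx``/``Glx`` (amide and
    acid forms indistinguishable after hydrolysis). Unknown codes and
    negative amounts raise :class:`ParseError`.
    """
    df = pd.read_csv(path, sep=sep, header=None, comment="#", names=["aa", "mg_per_g"])
    # tolerate a header row
    if df.iloc[0]["aa"].strip().lower() in {"aa", "amino_acid", "aminoacid"}:
        df = df.iloc[1:]
    mapping: dict[str, float] = {}
    valid = set(AA_MW) | set(POOLED_KEYS)
    for _, row in df.iterrows():
        aa = str(row["aa"]).strip()
        if aa not in valid:
            raise ParseError(f"{path}: unknown amino-acid code {aa!r}")
        if aa in mapping:
            raise ParseError(f"{path}: duplicate amino-acid code {aa!r}")
        value = float(row["mg_per_g"])
        if value < 0:
            raise ParseError(f"{path}: negative amount for {aa!r}: {value}")
        mapping[aa] = value
    if not mapping:
        raise ParseError(f"{path}: empty AAA table")
    return mapping


def write_aaa_table(mapping: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for aa, v in mapping.items():
            fh.write(f"{aa}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# Prediction tables

PREDICTION_COLUMNS = (
    "annotation",
    "peptide_class",  # alpha | beta | gamma | SCA | CHE
    "parent_id",
    "start",
    "end",
    "sequence",
    "score",
)

PEPTIDE_CLASSES = ("alpha", "beta", "gamma", "SCA", "CHE")


def read_prediction_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = set(PREDICTION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing prediction column(s) {sorted(missing)}")
    bad = set(df["peptide_class"]) - set(PEPTIDE_CLASSES)
    if bad:
        raise ParseError(f"{path}: unknown peptide class(es) {sorted(bad)}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["score"] = df["score"].astype(float)
    return df


def write_prediction_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def db_by_id(db: Sequence[ProteinRecord]) -> dict[str, ProteinRecord]:
    return {r.protein_id: r for r in db}
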