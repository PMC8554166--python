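"""Relative protein-group quantification: riBAQ and length-normalized I_L^rel.

Both estimators start from summed MS1 peptide intensity per protein group
and sample. iBAQ divides by the number of theoretically observable tryptic
peptides of the group's representative protein and riBAQ renormalizes iBAQ
to sum to one within a sample. The length-normalized alternative divides the
summed intensity by the representative protein's sequence length instead,
again normalized within the sample; under the approximation that peptide
intensity is proportional to molar amount times peptide length, it recovers
molar fractions exactly for complete digests.

The in-silico digestion used for the iBAQ denominator cleaves after K/R but
not before P (no exceptions), with configurable missed cleavages and length
bounds.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyteomics import parser as _pyt_parser

from .io import ProteinRecord, db_by_id

TRYPSIN_RULE = r"[KR](?!P)"

#: Columns of the per-sample quantification table.
QUANT_COLUMNS = (
    "group_id",
    "sample_id",
    "summed_intensity",
    "n_peptides_observed",
    "representative_id",
    "representative_length",
    "n_theoretical_peptides",
    "ribaq",
    "il_rel",
)


@dataclasses.dataclass(frozen=True)
class DigestPeptide:
    """One peptide from an in-silico digest, with 1-based inclusive
    coordinates in the parent sequence."""

    sequence: str
    start: int
    end: int


class EmptySampleError(ValueError):
    """All observations in a sample carry zero intensity."""


def digest(
    sequence: str,
    mode: str = "tryptic",
    missed_cleavages: int = 0,
    min_len: int = 1,
    max_len: int | None = None,
) -> list[DigestPeptide]:
    """In-silico digestion of one protein sequence.

    ``tryptic``: cleave after K/R except before P. ``semi``: peptides with at
    least one tryptic terminus (all truncations of tryptic peptides).
    ``unspecific``: every substring within the length bounds. Positioned
    peptides are returned; the same sequence at two loci appears twice.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    if max_len is not None and min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    n = len(sequence)
    top = n if max_len is None else min(max_len, n)
    if mode == "unspecific":
        out = [
            DigestPeptide(sequence[i : i + L], i + 1, i + L)
            for L in range(min_len, top + 1)
            for i in range(n - L + 1)
        ]
        return out
    if mode not in ("tryptic", "semi"):
        raise ValueError(f"unknown digestion mode {mode!r}")
    hits = set(
        _pyt_parser.icleave(
            sequence,
            TRYPSIN_RULE,
            missed_cleavages=missed_cleavages,
            min_length=min_len,
            max_length=max_len,
            semi=(mode == "semi"),
            regex=True,
        )
    )
    return sorted(
        (DigestPeptide(pep, start + 1, start + len(pep)) for start, pep in hits),
        key=lambda p: (p.start, p.end),
    )


def count_theoretical_peptides(
    sequence: str,
    missed_cleavages: int = 0,
    min_len: int = 7,
    max_len: int = 30,
) -> int:
    """Number of distinct tryptic peptides within the length window, the
    iBAQ denominator. Floored at 1 so short proteins stay quantifiable."""
    peptides = {
        p.sequence
        for p in digest(sequence, "tryptic", missed_cleavages, min_len, max_len)
    }
    return max(len(peptides), 1)


def _representative(
    member_ids: Sequence[str], db: Mapping[str, ProteinRecord], group_id: str
) -> ProteinRecord:
    """Longest member protein; ties broken lexicographically by ID."""
    members = []
    for pid in member_ids:
        if pid not in db:
            raise KeyError(
                f"group {group_id!r}: member protein {pid!r} not in database"
            )
        members.append(db[pid])
    if not members:
        raise KeyError(f"group {group_id!r} has no member proteins")
    return min(members, key=lambda r: (-r.length, r.protein_id))


def _prepare(
    observations: pd.DataFrame,
    db: Sequence[ProteinRecord] | Mapping[str, ProteinRecord],
    sample_id: str,
    members: Mapping[str, Sequence[str]] | None,
) -> tuple[pd.DataFrame, Mapping[str, ProteinRecord]]:
    if not isinstance(db, Mapping):
        db = db_by_id(db)
    obs = observations[observations["sample_id"] == sample_id]
    if obs.empty:
        raise EmptySampleError(f"no observations for sample {sample_id!r}")
    # sum across charge states / duplicate rows of the same peptide first
    per_group = (
        obs.groupby("group_id")
        .agg(
            summed_intensity=("intensity", "sum"),
            n_peptides_observed=("peptide_sequence", "nunique"),
        )
        .reset_index()
    )
    reps = []
    for gid in per_group["group_id"]:
        ids = members[gid] if members is not None else [gid]
        reps.append(_representative(ids, db, gid))
    per_group["representative_id"] = [r.protein_id for r in reps]
    per_group["representative_length"] = [r.length for r in reps]
    per_group["sample_id"] = sample_id
    return per_group, db


def quantify_sample(
    observations: pd.DataFrame,
    db: Sequence[ProteinRecord] | Mapping[str, ProteinRecord],
    sample_id: str,
    members: Mapping[str, Sequence[str]] | None = None,
    ibaq_missed_cleavages: int = 0,
    ibaq_min_len: int = 7,
    ibaq_max_len: int = 30,
) -> pd.DataFrame:
    """Compute riBAQ and I_L^rel for one sample.

    ``observations`` must already be free of decoy and contaminant groups.
    ``members`` maps group_id -> member protein IDs; by default each group ID
    is taken to be its single member protein's ID. Both estimators sum to one
    over the returned groups; groups observed with zero summed intensity get
    zero relative abundance.
    """
    per_group, dbmap = _prepare(observations, db, sample_id, members)
    total_intensity = per_group["summed_intensity"].sum()
    if total_intensity <= 0:
        raise EmptySampleError(f"empty sample {sample_id!r}: total intensity is zero")
    per_group["n_theoretical_peptides"] = [
        count_theoretical_peptides(
            dbmap[rid].sequence, ibaq_missed_cleavages, ibaq_min_len, ibaq_max_len
        )
        for rid in per_group["representative_id"]
    ]
    ibaq = per_group["summed_intensity"] / per_group["n_theoretical_peptides"]
    per_group["ribaq"] = ibaq / ibaq.sum()
    length_norm = per_group["summed_intensity"] / per_group["representative_length"]
    per_group["il_rel"] = length_norm / length_norm.sum()
    return per_group.loc[:, list(QUANT_COLUMNS)].sort_values("group_id").reset_index(drop=True)


def compute_ribaq(
    observations: pd.DataFrame,
    db: Sequence[ProteinRecord] | Mapping[str, ProteinRecord],
    sample_id: str,
    members: Mapping[str, Sequence[str]] | None = None,
    **ibaq_kwargs,
) -> pd.DataFrame:
    """riBAQ-only view of :func:`quantify_sample`."""
    out = quantify_sample(observations, db, sample_id, members, **ibaq_kwargs)
    return out.drop(columns=["il_rel"])


def compute_il_rel(
    observations: pd.DataFrame,
    db: Sequence[ProteinRecord] | Mapping[str, ProteinRecord],
    sample_id: str,
    members: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """I_L^rel-only view of :func:`quantify_sample`."""
    out = quantify_sample(observations, db, sample_id, members)
    return out.drop(columns=["ribaq", "n_theoretical_peptides"])


def write_quant_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
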