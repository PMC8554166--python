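"""Post-processing of functional-peptide prediction tables.

Candidate emulsifier (classes alpha/beta/gamma, by predicted interfacial
conformation) and antioxidant (SCA free-radical scavenging, CHE metal
chelation) peptides arrive as score tables from external predictors; this
module annotates physicochemical properties (length, net charge at pH 7 by
Henderson-Hasselbalch), applies score thresholds and advisory length rules,
clusters overlapping peptides within their parent proteins, picks top
non-redundant representatives, and cross-references peptides with verified
in-vitro activity.
"""

from __future__ import annotations

import dataclasses
import math
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .constants import CANONICAL_AA, DEFAULT_PKA
from .io import ProteinRecord, db_by_id
from .qc import _UnionFind

POSITIVE_GROUPS = ("K", "R", "H")
NEGATIVE_GROUPS = ("D", "E", "C", "Y")

#: Advisory length windows per class: (min, max) or None for no rule.
LENGTH_RULES: dict[str, tuple[int | None, int | None]] = {
    "alpha": (15, None),  # amphiphilic helices preferably >= 15 residues
    "beta": (9, 16),      # amphiphilic sheets suggested 9-16 residues
    "gamma": (None, None),
    "SCA": (None, None),
    "CHE": (None, None),
}

#: Default prediction score thresholds (strict >).
SCORE_THRESHOLDS: dict[str, float] = {
    "alpha": 2.0,  # z-normalized emulsifier score
    "beta": 2.0,
    "gamma": 2.0,
    "SCA": 0.43,
    "CHE": 0.3,
}


@dataclasses.dataclass(frozen=True)
class PKaSet:
    """Named pKa values for the ionizable groups of a peptide."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        required = {"n_term", "c_term", *POSITIVE_GROUPS[1:], *NEGATIVE_GROUPS, "H", "K", "R"}
        missing = required - set(self.values)
        if missing:
            raise ValueError(f"pKa set {self.name!r} missing {sorted(missing)}")
        for k, v in self.values.items():
            if not 1 < v < 14:
                raise ValueError(f"pKa {k}={v} outside (1, 14)")


DEFAULT_PKA_SET = PKaSet("default", DEFAULT_PKA)


def net_charge(
    sequence: str, pH: float = 7.0, pka: PKaSet = DEFAULT_PKA_SET
) -> float:
    """Henderson-Hasselbalch net charge of a peptide at the given pH.

    Positive groups (N-terminus, K, R, H) contribute
    ``1 / (1 + 10**(pH - pKa))``; negative groups (C-terminus, D, E, C, Y)
    contribute ``-1 / (1 + 10**(pKa - pH))``.
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - set(CANONICAL_AA)
    if bad:
        raise ValueError(f"illegal residue(s) {sorted(bad)} in {sequence!r}")
    if not 0 < pH < 14:
        raise ValueError(f"pH {pH} outside (0, 14)")
    v = pka.values
    charge = 1.0 / (1.0 + 10 ** (pH - v["n_term"]))
    charge -= 1.0 / (1.0 + 10 ** (v["c_term"] - pH))
    for aa in sequence:
        if aa in POSITIVE_GROUPS:
            charge += 1.0 / (1.0 + 10 ** (pH - v[aa]))
        elif aa in NEGATIVE_GROUPS:
            charge -= 1.0 / (1.0 + 10 ** (v[aa] - pH))
    return charge


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (display convention for charges)."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def annotate(
    records: pd.DataFrame, pka: PKaSet = DEFAULT_PKA_SET, pH: float = 7.0
) -> pd.DataFrame:
    """Fill ``length``, ``net_charge_pH7`` (raw) and ``charge_rounded``
    columns from the sequences. Empty input passes through."""
    out = records.copy()
    if out.empty:
        for col in ("length", "net_charge_pH7", "charge_rounded"):
            out[col] = pd.Series(dtype=float)
        return out
    out["length"] = out["sequence"].str.len()
    out["net_charge_pH7"] = [net_charge(s, pH, pka) for s in out["sequence"]]
    out["charge_rounded"] = [round_half_away(z, 1) for z in out["net_charge_pH7"]]
    return out


def validate_coordinates(
    records: pd.DataFrame, db: Mapping[str, ProteinRecord] | Sequence[ProteinRecord]
) -> None:
    """Check 1-based inclusive coordinates against the parent sequences."""
    if not isinstance(db, Mapping):
        db = db_by_id(db)
    for _, r in records.iterrows():
        if r["end"] - r["start"] + 1 != len(r["sequence"]):
            raise ValueError(
                f"{r['annotation']}: span [{r['start']},{r['end']}] inconsistent "
                f"with sequence length {len(r['sequence'])}"
            )
        parent = db.get(r["parent_id"])
        if parent is None:
            continue  # parent not in the supplied database: cannot verify
        window = parent.sequence[r["start"] - 1 : r["end"]]
        if window != r["sequence"]:
            raise ValueError(
                f"{r['annotation']}: sequence does not match parent "
                f"{r['parent_id']} at [{r['start']},{r['end']}]"
            )


def apply_score_thresholds(
    records: pd.DataFrame,
    thresholds: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep records scoring strictly above their class threshold.

    Returns the kept records and per-class kept counts.
    """
    thresholds = dict(SCORE_THRESHOLDS, **(thresholds or {}))
    keep = records.apply(
        lambda r: r["score"] > thresholds[r["peptide_class"]], axis=1
    ) if not records.empty else pd.Series(dtype=bool)
    kept = records.loc[keep].reset_index(drop=True)
    counts = kept["peptide_class"].value_counts().to_dict() if not kept.empty else {}
    return kept, {c: int(counts.get(c, 0)) for c in thresholds}


def apply_length_rules(records: pd.DataFrame) -> pd.DataFrame:
    """Attach advisory ``length_flag`` markers; never removes records.

    Alpha-class peptides shorter than 15 residues and beta-class peptides
    outside 9-16 residues are flagged as outside the preferred window for
    their predicted conformation.
    """
    out = records.copy()
    flags = []
    for _, r in out.iterrows():
        lo, hi = LENGTH_RULES.get(r["peptide_class"], (None, None))
        short = lo is not None and r["length"] < lo
        long = hi is not None and r["length"] > hi
        flags.append("outside_preferred_length" if short or long else "")
    out["length_flag"] = flags
    return out


def _overlaps(a: pd.Series, b: pd.Series) -> bool:
    return (
        a["parent_id"] == b["parent_id"]
        and a["start"] <= b["end"]
        and b["start"] <= a["end"]
    )


def cluster_by_overlap(records: pd.DataFrame) -> pd.DataFrame:
    """Cluster records of one class by residue overlap in parent coordinates.

    Two records link when they share a parent protein and at least one
    residue position; clusters are the transitive closure. Identical
    sequences at different loci do not overlap. Adds ``cluster_id`` (the
    representative's index) and ``is_representative``; the representative is
    the highest-scoring record, ties broken by length (longer first) then
    start position (smaller first).
    """
    out = records.reset_index(drop=True).copy()
    uf = _UnionFind()
    by_parent: dict[str, list[int]] = {}
    for i, r in out.iterrows():
        uf.find(i)
        by_parent.setdefault(r["parent_id"], []).append(i)
    for idxs in by_parent.values():
        ordered = sorted(idxs, key=lambda i: out.loc[i, "start"])
        # sweep: link any interval to the previous ones it touches
        active: list[int] = []
        for i in ordered:
            start_i = out.loc[i, "start"]
            active = [j for j in active if out.loc[j, "end"] >= start_i]
            for j in active:
                uf.union(i, j)
            active.append(i)
    roots = [uf.find(i) for i in out.index]
    out["_root"] = roots
    reps: dict[int, int] = {}
    for root, sub in out.groupby("_root"):
        best = sub.sort_values(
            by=["score", "length", "start"], ascending=[False, False, True]
        ).index[0]
        reps[root] = best
    out["cluster_id"] = [reps[r] for r in roots]
    out["is_representative"] = out.index == out["cluster_id"]
    return out.drop(columns="_root")


def select_top_nonoverlapping(records: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Greedy top-k selection of mutually non-overlapping records.

    Records are visited by descending score; one is accepted iff it overlaps
    no already-accepted record (same parent, interval intersection). Stops
    after ``k`` acceptances. Output keeps score order and gains a ``rank``
    column (1-based position in the full score ordering).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = records.sort_values(
        by=["score", "length", "start"], ascending=[False, False, True]
    ).reset_index(drop=True)
    ordered["rank"] = ordered.index + 1
    accepted: list[int] = []
    for i, row in ordered.iterrows():
        if len(accepted) >= k:
            break
        if all(not _overlaps(row, ordered.loc[j]) for j in accepted):
            accepted.append(i)
    return ordered.loc[accepted].reset_index(drop=True)


def crossref_verified(
    db: Sequence[ProteinRecord] | Mapping[str, ProteinRecord],
    verified: pd.DataFrame,
    abundances: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Locate verified functional peptides within a protein database.

    ``verified`` needs ``sequence`` and ``peptide_class`` columns (an
    ``annotation`` column is carried through); duplicates are dropped. Every
    exact substring match of a verified sequence in any database protein is
    reported with 1-based coordinates. ``abundances`` (extract -> group ->
    relative abundance) attaches the parent protein's abundance per extract.
    """
    if not isinstance(db, Mapping):
        db = db_by_id(db)
    dedup = verified.drop_duplicates(subset=["sequence", "peptide_class"])
    rows = []
    for _, v in dedup.iterrows():
        seq = v["sequence"]
        for pid, rec in db.items():
            start = rec.sequence.find(seq)
            while start != -1:
                row = {
                    "annotation": v.get("annotation", ""),
                    "peptide_class": v["peptide_class"],
                    "sequence": seq,
                    "parent_id": pid,
                    "start": start + 1,
                    "end": start + len(seq),
                }
                if abundances is not None:
                    for extract, weights in abundances.items():
                        row[f"parent_abundance_{extract}"] = weights.get(pid, 0.0)
                rows.append(row)
                start = rec.sequence.find(seq, start + 1)
    return pd.DataFrame(rows)


def load_reference_peptides() -> pd.DataFrame:
    """Load the packaged reference set of verified and predicted emulsifier
    and antioxidant peptides from enzymatic Eucheuma denticulatum extracts,
    with their published lengths, net charges at pH 7 and per-extract
    abundances."""
    with resources.files("extractprofiler.data").joinpath(
        "reference_peptides.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    df["parents"] = df["parents"].str.split(";")
    return df
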