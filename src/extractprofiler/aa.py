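"""Amino-acid composition estimation from quantitative proteomics data.

Two estimators of sample-level molar AA composition:

* peptide-level: the intensity-weighted mean of per-peptide AA frequencies,
  ``f_AA = sum_p f_AA(p) * I_rel(p)`` with ``I_rel(p)`` the relative MS1
  intensity of peptide p within the sample;
* protein-level: the abundance-weighted mean of full-length protein AA
  frequencies, weighted by length-normalized relative quantification
  (I_L^rel).

Wet-chemistry amino-acid analysis (AAA) reports mg AA per g extract; it is
converted to molar fractions by dividing each weight fraction by the free
amino acid's molecular weight and scaling by the average AA molecular
weight including water (128 g/mol). After acid hydrolysis the amide and
acid forms are indistinguishable, so AAA tables may pool Asp+Asn as Asx and
Glu+Gln as Glx; comparisons against AAA pool the sequence-based estimates
the same way.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .constants import AA_MW, AA_MW_POOLED, AVG_AA_MW, CANONICAL_AA, EAA, POOLED_KEYS
from .io import ProteinRecord, db_by_id

_SUM_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class AAConstants:
    """Molecular-weight and essentiality constants for composition math."""

    mw: Mapping[str, float] = dataclasses.field(default_factory=lambda: dict(AA_MW))
    mw_pooled: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(AA_MW_POOLED)
    )
    avg_mw: float = AVG_AA_MW
    eaa: frozenset[str] = EAA

    def __post_init__(self) -> None:
        for aa, w in self.mw.items():
            if not 75 <= w <= 250:
                raise ValueError(f"implausible MW for {aa}: {w}")
        if not self.eaa <= set(self.mw):
            raise ValueError("EAA set contains letters outside the alphabet")


@dataclasses.dataclass(frozen=True)
class AAComposition:
    """A relative molar AA frequency vector summing to one.

    ``pooled_keys`` records which entries stand for indistinguishable pairs
    (``Asx`` = D+N, ``Glx`` = E+Q). ``raw`` optionally retains the
    pre-renormalization values of a weight->molar conversion.
    """

    source: str
    frequencies: Mapping[str, float]
    pooled_keys: frozenset[str] = frozenset()
    raw: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.frequencies:
            raise ValueError("empty composition")
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"composition does not sum to 1: {total!r}")
        if any(v < 0 for v in self.frequencies.values()):
            raise ValueError("negative frequency")
        unknown = set(self.pooled_keys) - set(POOLED_KEYS)
        if unknown:
            raise ValueError(f"unknown pooled keys: {sorted(unknown)}")

    def pooled(self) -> "AAComposition":
        """Return the 18-key view with D+N pooled as Asx and E+Q as Glx."""
        if self.pooled_keys == frozenset(POOLED_KEYS):
            return self
        freqs = dict(self.frequencies)
        for pooled_key, (acid, amide) in POOLED_KEYS.items():
            freqs[pooled_key] = freqs.pop(acid, 0.0) + freqs.pop(amide, 0.0) \
                + freqs.pop(pooled_key, 0.0)
        return AAComposition(self.source, freqs, frozenset(POOLED_KEYS))

    def as_series(self) -> pd.Series:
        return pd.Series(dict(self.frequencies), name=self.source).sort_index()


def peptide_aa_frequency(peptide: str) -> dict[str, float]:
    """Relative frequency of each AA within one peptide (counts / length)."""
    if not peptide:
        raise ValueError("empty peptide")
    bad = set(peptide) - set(CANONICAL_AA)
    if bad:
        raise ValueError(f"illegal residue(s) {sorted(bad)} in {peptide!r}")
    counts = Counter(peptide)
    n = len(peptide)
    return {aa: c / n for aa, c in counts.items()}


def composition_from_peptides(observations: pd.DataFrame) -> AAComposition:
    """Intensity-weighted peptide-level AA composition of a sample.

    ``observations`` needs ``peptide_sequence`` and ``intensity`` columns and
    must already be free of decoy/contaminant peptides. Duplicate rows of
    the same peptide contribute via their summed intensity, so splitting an
    observation in two leaves the result unchanged.
    """
    if observations.empty:
        raise ValueError("no observations")
    total = observations["intensity"].sum()
    if total <= 0:
        raise ValueError("all observation intensities are zero")
    freqs: Counter = Counter()
    for peptide, intensity in zip(
        observations["peptide_sequence"], observations["intensity"]
    ):
        if intensity <= 0:
            continue
        w = intensity / total
        for aa, f in peptide_aa_frequency(peptide).items():
            freqs[aa] += f * w
    return AAComposition("peptide_level", dict(freqs))


def composition_from_proteins(
    il_rel: pd.Series | Mapping[str, float],
    db: Sequence[ProteinRecord] | Mapping[str, ProteinRecord],
    representative: Mapping[str, str] | None = None,
) -> AAComposition:
    """Protein-level AA composition: full-length protein AA frequencies
    weighted by length-normalized relative abundance.

    ``il_rel`` maps group_id -> I_L^rel (should sum to 1); ``representative``
    maps group_id -> protein ID when group IDs are not themselves protein
    IDs.
    """
    if not isinstance(db, Mapping):
        db = db_by_id(db)
    weights = dict(il_rel)
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"il_rel weights must sum to 1, got {total!r}")
    freqs: Counter = Counter()
    for gid, w in weights.items():
        pid = representative[gid] if representative is not None else gid
        if pid not in db:
            raise KeyError(f"representative protein {pid!r} for group {gid!r} not in database")
        if w == 0:
            continue
        seq = db[pid].sequence
        for aa, f in peptide_aa_frequency(seq).items():
            freqs[aa] += f * (w / total)
    return AAComposition("protein_level", dict(freqs))


def aaa_to_molar(
    aaa: Mapping[str, float],
    constants: AAConstants | None = None,
    renormalize: bool = True,
) -> AAComposition:
    """Convert an AAA table (mg AA per g extract) to relative molar fractions.

    Each amount is first reduced to a weight fraction of the summed
    quantified AAs, then divided by the free amino acid's molecular weight
    and multiplied by the average AA molecular weight including water
    (128 g/mol). The raw converted values sum to ``128 * sum(w_i / MW_i)``,
    not exactly one; with ``renormalize`` (default) they are rescaled to a
    proper composition and the raw values retained.
    """
    constants = constants or AAConstants()
    if not aaa:
        raise ValueError("empty AAA table")
    total_mg = sum(aaa.values())
    if total_mg <= 0:
        raise ValueError("AAA table has no positive amounts")
    mw_all = {**constants.mw, **constants.mw_pooled}
    raw: dict[str, float] = {}
    for aa, mg in aaa.items():
        if aa not in mw_all:
            raise KeyError(f"no molecular weight for AA code {aa!r}")
        raw[aa] = (mg / total_mg) / mw_all[aa] * constants.avg_mw
    pooled = frozenset(k for k in aaa if k in POOLED_KEYS)
    if renormalize:
        s = sum(raw.values())
        freqs = {aa: v / s for aa, v in raw.items()}
        return AAComposition("aaa", freqs, pooled, raw=raw)
    return AAComposition("aaa", raw, pooled)


def eaa_neaa_ratio(
    comp: AAComposition, eaa: Iterable[str] | None = None
) -> float:
    """Molar ratio of essential to non-essential amino acids.

    With pooled Asx/Glx entries the pools count as non-essential (both
    members are). Errors if the non-essential sum is zero.
    """
    eaa_set = set(eaa) if eaa is not None else set(EAA)
    e = sum(v for aa, v in comp.frequencies.items() if aa in eaa_set)
    ne = sum(v for aa, v in comp.frequencies.items() if aa not in eaa_set)
    if ne <= 0:
        raise ValueError("non-essential AA sum is zero; ratio undefined")
    return e / ne


def compare_compositions(
    compositions: Sequence[AAComposition],
    labels: Sequence[str] | None = None,
    reference: str | None = None,
) -> pd.DataFrame:
    """Long-format comparison table of several compositions.

    If any input carries pooled Asx/Glx keys, all are pooled first so the
    alphabets line up. Output columns: ``aa``, ``source``, ``fraction`` and,
    when ``reference`` names one of the sources, ``diff_vs_reference``.
    """
    if labels is None:
        labels = [c.source for c in compositions]
    if len(labels) != len(compositions):
        raise ValueError("labels/compositions length mismatch")
    if any(c.pooled_keys for c in compositions):
        compositions = [c.pooled() for c in compositions]
    alphabet = sorted(set().union(*(set(c.frequencies) for c in compositions)))
    rows = []
    for label, comp in zip(labels, compositions):
        for aa in alphabet:
            rows.append(
                {"aa": aa, "source": label, "fraction": comp.frequencies.get(aa, 0.0)}
            )
    table = pd.DataFrame(rows)
    if reference is not None:
        if reference not in labels:
            raise ValueError(f"reference {reference!r} not among labels {labels}")
        ref = table[table["source"] == reference].set_index("aa")["fraction"]
        table["diff_vs_reference"] = table.apply(
            lambda r: r["fraction"] - ref[r["aa"]], axis=1
        )
    return table
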