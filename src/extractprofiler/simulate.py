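"""Seeded synthetic datasets with the statistical structure the pipeline assumes.

The generator draws a toy proteome with known molar abundances and
subcellular compartments, digests it in silico, and produces MS1-style
peptide intensity tables for three digestion-specificity modes, duplicate
technical replicates and several extract conditions. The generative
convention is ``intensity = molar abundance x peptide length x detectability
penalties``: with complete tryptic coverage and no noise this makes
length-normalized quantification and intensity-weighted composition
estimation exact, so parameter-recovery tests have a clean target.

Real-data features deliberately emulated: multiplicative replicate noise,
random peptide dropout, reduced detectability of M/H/W/C-containing
peptides, contaminant and reversed-decoy entries, low-scoring spurious
single-peptide groups exclusive to one analytical method, and
extract-dependent reweighting of compartment abundances.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import (
    BACKGROUND_AA_FREQ,
    COMPARTMENTS,
    POOLED_KEYS,
    AA_MW,
    AA_MW_POOLED,
)
from .io import (
    CONTAMINANT_PREFIX,
    DECOY_PREFIX,
    ProteinRecord,
    write_aaa_table,
    write_fasta,
    write_group_table,
    write_peptide_table,
)
from .quantify import digest

#: Compartment priors loosely shaped like a eukaryotic proteome: mostly
#: cytoplasmic/nuclear, a modest secreted fraction.
DEFAULT_COMPARTMENT_PRIORS: dict[str, float] = {
    "Cytoplasm": 0.32,
    "Nucleus": 0.22,
    "Extracellular": 0.12,
    "Mitochondrion": 0.09,
    "Cell_membrane": 0.08,
    "Plastid": 0.07,
    "Endoplasmic_reticulum": 0.04,
    "Golgi_apparatus": 0.03,
    "Lysosome/Vacuole": 0.02,
    "Peroxisome": 0.01,
}

#: Extract conditions: multiplicative weight applied to the molar abundance
#: of proteins from intracellular compartments, emulating how well each
#: enzymatic treatment liberates intracellular protein.
DEFAULT_EXTRACT_PROFILES: dict[str, float] = {
    "V": 1.0,     # cell-wall degrading mix, good intracellular release
    "A": 0.35,    # protease-based, intracellular proteins suppressed
    "SC": 1.3,    # cell-wall degrading mix, best intracellular release
}


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the seed fixes every random draw."""

    n_proteins: int = 50
    length_median: float = 200.0
    length_sigma: float = 0.45
    aa_frequencies: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(BACKGROUND_AA_FREQ)
    )
    compartment_priors: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_COMPARTMENT_PRIORS)
    )
    abundance_sigma: float = 1.5
    methods: tuple[str, ...] = ("tryptic", "semi", "unspecific")
    extract_profiles: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_EXTRACT_PROFILES)
    )
    n_replicates: int = 2
    missed_cleavage_prob: float = 0.2
    detectability_penalty: float = 0.7  # per M/H/W/C residue, multiplicative
    dropout: float = 0.1
    noise_cv: float = 0.2
    length_dependent_intensity: bool = True
    complete_coverage: bool = False  # tryptic digest without length window
    contaminant_fraction: float = 0.05
    generate_decoys: bool = True
    n_spurious_groups: int = 2
    unspecific_peptides_per_protein: int = 25
    true_score_mean: float = 150.0
    spurious_score_mean: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missed_cleavage_prob", "dropout", "contaminant_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0 < self.detectability_penalty <= 1:
            raise ValueError("detectability_penalty must be in (0,1]")
        if self.n_proteins < 1:
            raise ValueError("need at least one protein")


@dataclasses.dataclass
class GroundTruth:
    """What the generator knows and the estimators try to recover."""

    molar_fractions: dict[str, float]
    compartments: dict[str, str]
    aa_composition: dict[str, float]
    base_intensity: dict[tuple, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.molar_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"molar fractions must sum to 1, got {total!r}")


def _random_sequence(rng: np.random.Generator, length: int, freqs: Mapping[str, float]) -> str:
    letters = list(freqs)
    p = np.array([freqs[a] for a in letters], dtype=float)
    p /= p.sum()
    return "".join(rng.choice(letters, size=length, p=p))


def _true_aa_composition(
    records: Sequence[ProteinRecord], fractions: Mapping[str, float]
) -> dict[str, float]:
    """Residue-molar AA composition of the sample: moles of each residue
    over total residue moles, i.e. counts weighted by protein molar
    abundance. This is what amino-acid analysis of the physical sample
    would measure."""
    comp: dict[str, float] = {}
    for r in records:
        w = fractions[r.protein_id]
        for aa in set(r.sequence):
            comp[aa] = comp.get(aa, 0.0) + r.sequence.count(aa) * w
    total = sum(comp.values())
    return {aa: v / total for aa, v in comp.items()}


def generate_proteome(
    config: SimulationConfig,
) -> tuple[list[ProteinRecord], GroundTruth]:
    """Draw the reference proteome plus ground truth.

    Target proteins get log-normal lengths and molar abundances and a
    compartment drawn from the priors. Contaminants are appended with a
    ``CON_`` ID prefix (excluded from the truth fractions, which describe
    the sample's real proteome) and decoys as reversed sequences with a
    ``REV_`` prefix.
    """
    rng = np.random.default_rng(config.seed)
    comps = list(config.compartment_priors)
    comp_p = np.array([config.compartment_priors[c] for c in comps], dtype=float)
    comp_p /= comp_p.sum()
    records: list[ProteinRecord] = []
    for i in range(config.n_proteins):
        length = max(30, int(rng.lognormal(np.log(config.length_median), config.length_sigma)))
        records.append(
            ProteinRecord(
                protein_id=f"prot{i:04d}",
                sequence=_random_sequence(rng, length, config.aa_frequencies),
                compartment=str(rng.choice(comps, p=comp_p)),
            )
        )
    abund = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=config.n_proteins)
    abund /= abund.sum()
    fractions = {r.protein_id: float(a) for r, a in zip(records, abund)}
    compartments = {r.protein_id: r.compartment for r in records}
    truth = GroundTruth(
        molar_fractions=fractions,
        compartments=compartments,
        aa_composition=_true_aa_composition(records, fractions),
    )
    n_con = int(round(config.contaminant_fraction * config.n_proteins))
    for j in range(n_con):
        length = max(30, int(rng.lognormal(np.log(config.length_median), config.length_sigma)))
        records.append(
            ProteinRecord(
                protein_id=f"{CONTAMINANT_PREFIX}prot{j:04d}",
                sequence=_random_sequence(rng, length, config.aa_frequencies),
                is_contaminant=True,
            )
        )
    # database entries hit only by spurious single-peptide matches; part of
    # the search space but not of the sample proteome (no truth abundance)
    for s in range(config.n_spurious_groups):
        records.append(
            ProteinRecord(
                protein_id=f"spurious{s:02d}",
                sequence=_random_sequence(rng, 60, config.aa_frequencies),
            )
        )
    if config.generate_decoys:
        for r in list(records):
            if r.is_contaminant:
                continue
            records.append(
                ProteinRecord(
                    protein_id=f"{DECOY_PREFIX}{r.protein_id}",
                    sequence=r.sequence[::-1],
                    is_decoy=True,
                )
            )
    return records, truth


def _penalty(sequence: str, per_residue: float) -> float:
    n = sum(sequence.count(a) for a in "MHWC")
    return per_residue ** n


def _observed_peptides(
    rng: np.random.Generator, record: ProteinRecord, method: str, config: SimulationConfig
) -> list[str]:
    """The identifiable peptide set of one protein under one search mode."""
    if method == "tryptic":
        if config.complete_coverage:
            # complete non-overlapping digest: every residue covered once
            return [p.sequence for p in digest(record.sequence, "tryptic", 0, 1, None)]
        mc = 2 if rng.random() < config.missed_cleavage_prob else 0
        return [p.sequence for p in digest(record.sequence, "tryptic", mc, 7, 30)]
    if method == "semi":
        peps = [p.sequence for p in digest(record.sequence, "semi", 0, 7, 30)]
        k = min(len(peps), 40)
        idx = rng.choice(len(peps), size=k, replace=False)
        return [peps[i] for i in sorted(idx)]
    if method == "unspecific":
        n = len(record.sequence)
        out = []
        for _ in range(config.unspecific_peptides_per_protein):
            L = int(rng.integers(5, min(65, n) + 1))
            start = int(rng.integers(0, n - L + 1))
            out.append(record.sequence[start : start + L])
        return sorted(set(out))
    raise ValueError(f"unknown method {method!r}")


def simulate_observations(
    proteome: Sequence[ProteinRecord],
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the peptide observation table and the protein-group table.

    One observation row per (extract, replicate, method, protein, peptide)
    that survives dropout. Base intensity is molar abundance (reweighted per
    extract profile) x peptide length (optional) x detectability penalties;
    replicate values multiply in log-normal noise at the configured CV.
    Contaminants get a small fixed abundance; spurious single-peptide groups
    are injected with low scores, exclusive to one method.
    """
    rng = np.random.default_rng(config.seed + 1)
    targets = [r for r in proteome if r.protein_id in truth.molar_fractions]
    contaminants = [r for r in proteome if r.is_contaminant]
    spurious = [
        r for r in proteome
        if r.protein_id.startswith("spurious") and not r.is_decoy
    ]
    sigma = np.sqrt(np.log(1.0 + config.noise_cv ** 2)) if config.noise_cv > 0 else 0.0

    rows: list[dict] = []
    extracellular_aware = {
        pid: (truth.compartments.get(pid) == "Extracellular") for pid in truth.molar_fractions
    }
    for extract, intra_weight in config.extract_profiles.items():
        reweighted = {
            pid: f * (1.0 if extracellular_aware[pid] else intra_weight)
            for pid, f in truth.molar_fractions.items()
        }
        total = sum(reweighted.values())
        reweighted = {pid: f / total for pid, f in reweighted.items()}
        for method in config.methods:
            peptide_sets = {
                r.protein_id: _observed_peptides(rng, r, method, config) for r in targets
            }
            for r in contaminants:
                peptide_sets[r.protein_id] = _observed_peptides(rng, r, method, config)
            for rep in range(1, config.n_replicates + 1):
                for r in targets + contaminants:
                    abundance = reweighted.get(r.protein_id, 0.002)
                    for pep in peptide_sets[r.protein_id]:
                        base = abundance
                        if config.length_dependent_intensity:
                            base *= len(pep)
                        base *= _penalty(pep, config.detectability_penalty)
                        truth.base_intensity[(extract, method, r.protein_id, pep)] = base
                        if config.dropout > 0 and rng.random() < config.dropout:
                            continue
                        noise = float(np.exp(rng.normal(0.0, sigma))) if sigma else 1.0
                        rows.append(
                            {
                                "peptide_sequence": pep,
                                "group_id": r.protein_id,
                                "sample_id": extract,
                                "replicate_id": f"rep{rep}",
                                "method": method,
                                "intensity": base * noise * 1e9,
                                "psm_score": float(rng.gamma(4.0, 20.0)),
                            }
                        )
    observations = pd.DataFrame(
        rows,
        columns=["peptide_sequence", "group_id", "sample_id", "replicate_id",
                 "method", "intensity", "psm_score"],
    )

    # protein-group table with scores; spurious groups injected afterwards
    group_rows = []
    for r in targets + contaminants:
        group_rows.append(
            {
                "group_id": r.protein_id,
                "member_proteins": [r.protein_id],
                "score": float(rng.gamma(4.0, config.true_score_mean / 4.0)),
                "n_peptides": int(observations[observations["group_id"] == r.protein_id][
                    "peptide_sequence"
                ].nunique()) if not observations.empty else 0,
                "is_contaminant": r.is_contaminant,
                "is_decoy": False,
            }
        )
    for s, rec in enumerate(spurious):
        gid = rec.protein_id
        method = config.methods[s % len(config.methods)]
        start = int(rng.integers(0, rec.length - 8 + 1))
        pep = rec.sequence[start : start + 8]
        for extract in config.extract_profiles:
            for rep in range(1, config.n_replicates + 1):
                observations.loc[len(observations)] = {
                    "peptide_sequence": pep,
                    "group_id": gid,
                    "sample_id": extract,
                    "replicate_id": f"rep{rep}",
                    "method": method,
                    "intensity": 1e7,
                    "psm_score": float(rng.gamma(2.0, 3.0)),
                }
        group_rows.append(
            {
                "group_id": gid,
                "member_proteins": [gid],
                "score": float(rng.gamma(2.0, config.spurious_score_mean / 2.0)),
                "n_peptides": 1,
                "is_contaminant": False,
                "is_decoy": False,
            }
        )
    groups = pd.DataFrame(group_rows)
    return observations, groups


def synthetic_aaa_table(truth: GroundTruth, total_mg_per_g: float = 30.0) -> dict[str, float]:
    """Invert the weight->molar conversion so the emitted AAA table maps back
    to the true composition: mg_i proportional to fraction_i x MW_i, with
    Asx/Glx pooled."""
    pooled: dict[str, float] = {}
    acid_of = {member: key for key, pair in POOLED_KEYS.items() for member in pair}
    for aa, f in truth.aa_composition.items():
        key = acid_of.get(aa, aa)
        pooled[key] = pooled.get(key, 0.0) + f
    mw = {**AA_MW, **AA_MW_POOLED}
    weights = {aa: f * mw[aa] for aa, f in pooled.items()}
    total = sum(weights.values())
    return {aa: w / total * total_mg_per_g for aa, w in weights.items()}


def synthetic_predictions(
    proteome: Sequence[ProteinRecord],
    truth: GroundTruth,
    config: SimulationConfig,
    n_per_class: int = 30,
) -> pd.DataFrame:
    """Random prediction-score table over abundant target proteins."""
    rng = np.random.default_rng(config.seed + 2)
    abundant = sorted(
        (r for r in proteome if r.protein_id in truth.molar_fractions),
        key=lambda r: -truth.molar_fractions[r.protein_id],
    )[: max(5, len(truth.molar_fractions) // 4)]
    rows = []
    for cls, (lo, hi) in (("alpha", (8, 30)), ("beta", (7, 20)), ("gamma", (9, 30)),
                          ("SCA", (4, 27)), ("CHE", (2, 23))):
        for i in range(n_per_class):
            r = abundant[int(rng.integers(0, len(abundant)))]
            L = int(rng.integers(lo, min(hi, r.length - 1) + 1))
            start = int(rng.integers(1, r.length - L + 2))
            score = float(rng.normal(2.5, 1.0)) if cls in ("alpha", "beta", "gamma") \
                else float(rng.uniform(0.2, 0.8))
            rows.append(
                {
                    "annotation": f"p{cls}-{i}",
                    "peptide_class": cls,
                    "parent_id": r.protein_id,
                    "start": start,
                    "end": start + L - 1,
                    "sequence": r.sequence[start - 1 : start + L - 1],
                    "score": score,
                }
            )
    return pd.DataFrame(rows)


def emit_dataset(out_dir: str | Path, config: SimulationConfig) -> dict[str, Path]:
    """Run the full generator and write every artifact type to ``out_dir``.

    Writes the FASTA reference (targets + contaminants + decoys), peptide
    observation TSVs per method, the protein-group TSV, the localization
    TSV, a synthetic AAA table, a synthetic prediction-score TSV and the
    ground truth as JSON. Deterministic for a fixed config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteome, truth = generate_proteome(config)
    observations, groups = simulate_observations(proteome, truth, config)
    paths: dict[str, Path] = {}

    paths["fasta"] = out / "proteome.fasta"
    write_fasta(proteome, paths["fasta"])
    for method in config.methods:
        p = out / f"peptides_{method}.tsv"
        write_peptide_table(observations[observations["method"] == method], p)
        paths[f"peptides_{method}"] = p
    paths["groups"] = out / "protein_groups.tsv"
    write_group_table(groups, paths["groups"])
    paths["localization"] = out / "localization.tsv"
    loc = pd.DataFrame(
        [{"protein_id": pid, "compartment": c} for pid, c in truth.compartments.items()]
    )
    loc.to_csv(paths["localization"], sep="\t", index=False)
    paths["aaa"] = out / "aaa.tsv"
    write_aaa_table(synthetic_aaa_table(truth), paths["aaa"])
    paths["predictions"] = out / "predictions.tsv"
    synthetic_predictions(proteome, truth, config).to_csv(
        paths["predictions"], sep="\t", index=False
    )
    paths["truth"] = out / "ground_truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "molar_fractions": truth.molar_fractions,
                "compartments": truth.compartments,
                "aa_composition": truth.aa_composition,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return paths
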