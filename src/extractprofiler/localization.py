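"""Subcellular-distribution summaries from quantification + compartment labels.

Per-protein compartment predictions (a 10-category vocabulary) are combined
with relative abundances to give the fraction of extract protein mass per
compartment. All non-extracellular compartments are pooled as
"intracellular" to score how well an extraction method liberates protein
from inside the cells. Replicate spread is summarized as mean +/- sd; the
sd of a pooled sum treats compartments as independent (root of summed
variances). Extract contrasts use one-way ANOVA with Tukey's HSD post hoc
test.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .constants import COMPARTMENTS, UNKNOWN_COMPARTMENT

EXTRACELLULAR = "Extracellular"


@dataclasses.dataclass(frozen=True)
class CompartmentDistribution:
    """Per-extract compartment fractions with replicate spread."""

    label: str
    fractions: Mapping[str, tuple[float, float]]  # compartment -> (mean, sd)
    intracellular: tuple[float, float]

    def __post_init__(self) -> None:
        total = sum(m for m, _ in self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"compartment means must sum to 1, got {total!r}")


def bin_by_compartment(
    weights: pd.Series | Mapping[str, float],
    localization: Mapping[str, str],
    representative: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Sum relative abundances per compartment.

    ``weights`` maps group_id -> relative abundance (normalized);
    ``localization`` maps protein_id -> compartment; group labels come from
    the group's representative protein. Unlabelled or unrecognized proteins
    fall into the "unknown" bin rather than erroring.
    """
    known = set(COMPARTMENTS) | {UNKNOWN_COMPARTMENT}
    out: dict[str, float] = {}
    for gid, w in dict(weights).items():
        pid = representative[gid] if representative is not None else gid
        label = localization.get(pid, UNKNOWN_COMPARTMENT)
        if label not in known:
            warnings.warn(
                f"unrecognized compartment {label!r} for {pid!r}; binned as unknown",
                stacklevel=2,
            )
            label = UNKNOWN_COMPARTMENT
        out[label] = out.get(label, 0.0) + float(w)
    return out


def intracellular_fraction(binned: Mapping[str, float]) -> float:
    """Pooled non-extracellular fraction (the 'intracellular' bin).

    Unknown-compartment mass is excluded from the pool, so
    intracellular + extracellular + unknown partitions the total.
    """
    return sum(
        v for c, v in binned.items() if c not in (EXTRACELLULAR, UNKNOWN_COMPARTMENT)
    )


def propagate_sum_sd(sds: Sequence[float]) -> float:
    """Standard deviation of a sum of independent variables:
    sqrt(sum of variances)."""
    if any(s < 0 for s in sds):
        raise ValueError("standard deviations must be non-negative")
    return math.sqrt(sum(s * s for s in sds))


def compartment_distribution(
    label: str,
    replicate_bins: Sequence[Mapping[str, float]],
) -> CompartmentDistribution:
    """Mean +/- sd compartment fractions over technical replicates.

    Each replicate's bins must be normalized (sum 1). The intracellular
    pool's sd is propagated as the root of the summed per-compartment
    variances (independence assumption).
    """
    if not replicate_bins:
        raise ValueError("no replicates")
    comps = sorted(set().union(*(set(b) for b in replicate_bins)))
    fractions: dict[str, tuple[float, float]] = {}
    for c in comps:
        vals = np.array([b.get(c, 0.0) for b in replicate_bins])
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        fractions[c] = (float(vals.mean()), sd)
    intra_mean = sum(
        m for c, (m, _) in fractions.items()
        if c not in (EXTRACELLULAR, UNKNOWN_COMPARTMENT)
    )
    intra_sd = propagate_sum_sd(
        [s for c, (_, s) in fractions.items()
         if c not in (EXTRACELLULAR, UNKNOWN_COMPARTMENT)]
    )
    return CompartmentDistribution(label, fractions, (intra_mean, intra_sd))


def _stars(p: float, alpha: float) -> str:
    if p < 0.01:
        return "**"
    if p < alpha:
        return "*"
    return "ns"


def _compact_letters(
    labels: Sequence[str],
    means: Mapping[str, float],
    distinct: set[tuple[str, str]],
) -> dict[str, str]:
    """Standard insert-and-absorb compact letter display; ties broken by
    group mean (descending)."""
    order = sorted(labels, key=lambda l: (-means[l], l))
    letter_sets: list[set[str]] = []
    for lab in order:
        placed = False
        for s in letter_sets:
            if all((lab, o) not in distinct and (o, lab) not in distinct for o in s):
                s.add(lab)
                placed = True
        if not placed:
            letter_sets.append({lab})
    # absorb subsets
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {lab: "" for lab in labels}
    for letter, s in zip(alphabet, letter_sets):
        for lab in s:
            out[lab] += letter
    return {lab: "".join(sorted(v)) for lab, v in out.items()}


def anova_tukey(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    ``groups`` maps condition label -> replicate values (>=2 each). Returns
    one row per pair with the adjusted p-value, mean difference, a
    significance annotation (``*`` p<alpha, ``**`` p<0.01, ``ns``) and
    compact-letter-display letters shared by statistically indistinct
    conditions. With zero variance everywhere the comparisons are reported
    as ``ns`` with a note instead of erroring.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for lab, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 replicates")
    labels = list(groups)
    values = [np.asarray(groups[l], dtype=float) for l in labels]
    means = {l: float(v.mean()) for l, v in zip(labels, values)}
    pooled = np.concatenate(values)
    degenerate = np.allclose(pooled.var(), 0.0)
    pairs = list(itertools.combinations(labels, 2))
    if degenerate:
        rows = [
            {"group_a": a, "group_b": b, "mean_diff": means[b] - means[a],
             "p_adj": 1.0, "significance": "ns", "note": "zero variance in all groups"}
            for a, b in pairs
        ]
        f_stat, f_p = 0.0, 1.0
        distinct: set[tuple[str, str]] = set()
    else:
        f_stat, f_p = stats.f_oneway(*values)
        flat = np.concatenate(values)
        cond = np.concatenate([[l] * len(v) for l, v in zip(labels, values)])
        tukey = pairwise_tukeyhsd(flat, cond, alpha=alpha)
        frame = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        rows = []
        distinct = set()
        for _, r in frame.iterrows():
            a, b = str(r["group1"]), str(r["group2"])
            p = float(r["p-adj"])
            if bool(r["reject"]):
                distinct.add((a, b))
            rows.append(
                {"group_a": a, "group_b": b, "mean_diff": float(r["meandiff"]),
                 "p_adj": p, "significance": _stars(p, alpha), "note": ""}
            )
    letters = _compact_letters(labels, means, distinct)
    out = pd.DataFrame(rows)
    out["letters_a"] = out["group_a"].map(letters)
    out["letters_b"] = out["group_b"].map(letters)
    out.attrs["f_statistic"] = float(f_stat)
    out.attrs["f_pvalue"] = float(f_p)
    out.attrs["letters"] = letters
    return out


def distribution_long_table(
    distributions: Sequence[CompartmentDistribution],
) -> pd.DataFrame:
    """Stacked-bar-ready long table: (extract, compartment, mean, sd)."""
    rows = []
    for d in distributions:
        for comp, (m, s) in sorted(d.fractions.items()):
            rows.append({"extract": d.label, "compartment": comp, "mean": m, "sd": s})
        rows.append(
            {"extract": d.label, "compartment": "intracellular (pooled)",
             "mean": d.intracellular[0], "sd": d.intracellular[1]}
        )
    return pd.DataFrame(rows)
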