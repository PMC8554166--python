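"""Quality-based filtering, quantitative-loss accounting and correlation QC.

Every filtering step reports a :class:`FilterLedger`: how many groups went
in, how many survived, which were removed, and the *quantitative loss* — the
share of pre-filter relative abundance held by the removed groups. Losses
measured on the running (renormalized) weights compose multiplicatively:
``1 - prod(1 - loss_i)`` over a chain equals the loss measured directly
between the initial and final sets.

Replicate/method agreement is diagnosed with Pearson correlation on
in-sample normalized relative abundances.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: identity columns a long quant table may carry besides group_id
_ID_COLS = ("sample_id", "replicate_id", "method")


@dataclasses.dataclass
class FilterLedger:
    """Accounting record for one filtering step."""

    step: str
    groups_before: int
    groups_after: int
    quantitative_loss: dict[tuple, float]
    removed_ids: list[str]

    def __post_init__(self) -> None:
        if self.groups_after > self.groups_before:
            raise ValueError("groups_after exceeds groups_before")
        for key, loss in self.quantitative_loss.items():
            if not -1e-12 <= loss <= 1 + 1e-12:
                raise ValueError(f"loss out of [0,1] for {key}: {loss}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"step": self.step, "unit": "/".join(map(str, key)), "loss": loss,
             "groups_before": self.groups_before, "groups_after": self.groups_after}
            for key, loss in self.quantitative_loss.items()
        ]
        return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation between two relative-abundance vectors."""

    axis: str
    label_x: str
    label_y: str
    pcc: float | None
    n_common: int
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.pcc is not None and not -1 - 1e-12 <= self.pcc <= 1 + 1e-12:
            raise ValueError(f"PCC out of [-1,1]: {self.pcc}")


def _unit_keys(df: pd.DataFrame) -> list[str]:
    return [c for c in _ID_COLS if c in df.columns]


def _loss_per_unit(df: pd.DataFrame, removed: pd.Series, weight_col: str) -> dict[tuple, float]:
    """Loss = removed weight / total weight, per identity-column combination."""
    keys = _unit_keys(df)
    out: dict[tuple, float] = {}
    grouped = df.groupby(keys, dropna=False) if keys else [((), df)]
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        total = sub[weight_col].sum()
        lost = sub.loc[removed.reindex(sub.index, fill_value=False), weight_col].sum()
        out[key] = float(lost / total) if total > 0 else 0.0
    return out


def filter_decoys_contaminants(
    quant: pd.DataFrame, weight_col: str = "il_rel"
) -> tuple[pd.DataFrame, FilterLedger]:
    """Remove decoy and contaminant groups, recording the abundance they held.

    ``quant`` must carry boolean ``is_decoy``/``is_contaminant`` columns
    (attach via :func:`attach_group_info`). Idempotent.
    """
    for col in ("is_decoy", "is_contaminant"):
        if col not in quant.columns:
            raise KeyError(f"quant table lacks required flag column {col!r}")
    removed = quant["is_decoy"] | quant["is_contaminant"]
    ledger = FilterLedger(
        step="decoy_contaminant",
        groups_before=quant["group_id"].nunique(),
        groups_after=quant.loc[~removed, "group_id"].nunique(),
        quantitative_loss=_loss_per_unit(quant, removed, weight_col),
        removed_ids=sorted(quant.loc[removed, "group_id"].unique()),
    )
    return quant.loc[~removed].reset_index(drop=True), ledger


def quality_filter(
    quant: pd.DataFrame,
    min_score: float = 40.0,
    min_peptides: int = 2,
    require_duplicate: bool = True,
    score_override: float = 100.0,
    weight_col: str = "il_rel",
) -> tuple[pd.DataFrame, FilterLedger]:
    """Score / peptide-count / replicate-consistency filtering.

    A group is kept when ``score >= min_score`` and it either has at least
    ``min_peptides`` observed peptides or clears the high-confidence score
    override. With ``require_duplicate``, a group must additionally be
    identified (summed intensity > 0) in both technical replicates of its
    sample x method combination.
    """
    if "score" not in quant.columns:
        raise KeyError("quant table lacks a 'score' column (attach_group_info)")
    keep = (quant["score"] >= min_score) & (
        (quant["n_peptides_observed"] >= min_peptides)
        | (quant["score"] >= score_override)
    )
    if require_duplicate:
        if "replicate_id" not in quant.columns:
            raise ValueError("require_duplicate needs a replicate_id column")
        ctx = [c for c in ("sample_id", "method") if c in quant.columns]
        n_reps = quant.groupby(ctx)["replicate_id"].nunique() if ctx else \
            pd.Series({(): quant["replicate_id"].nunique()})
        if (n_reps < 2).any():
            raise ValueError("require_duplicate needs >=2 technical replicates")
        identified = quant[quant["summed_intensity"] > 0]
        dup_ok = (
            identified.groupby(ctx + ["group_id"])["replicate_id"].nunique() >= 2
        )
        idx = quant.set_index(ctx + ["group_id"]).index
        keep &= pd.Series(dup_ok.reindex(idx, fill_value=False).values, index=quant.index)
    removed = ~keep
    ledger = FilterLedger(
        step="quality",
        groups_before=quant["group_id"].nunique(),
        groups_after=quant.loc[keep, "group_id"].nunique(),
        quantitative_loss=_loss_per_unit(quant, removed, weight_col),
        removed_ids=sorted(set(quant.loc[removed, "group_id"]) - set(quant.loc[keep, "group_id"])),
    )
    return quant.loc[keep].reset_index(drop=True), ledger


def quantitative_loss(before: pd.Series, after: Iterable[str] | pd.Series) -> float:
    """Share of pre-filter relative abundance held by removed groups.

    ``before`` is a normalized weight vector indexed by group_id; ``after``
    the surviving IDs (or a weight vector whose index is used).
    """
    after_ids = set(after.index) if isinstance(after, pd.Series) else set(after)
    extra = after_ids - set(before.index)
    if extra:
        raise ValueError(f"kept groups absent from pre-filter set: {sorted(extra)}")
    total = before.sum()
    if total <= 0:
        raise ValueError("pre-filter weights sum to zero")
    kept = before.loc[before.index.isin(after_ids)].sum()
    return float(1.0 - kept / total)


def requantify(
    quant: pd.DataFrame, weight_cols: Sequence[str] = ("ribaq", "il_rel")
) -> pd.DataFrame:
    """Renormalize relative abundances to sum to one over the kept groups,
    within each sample/replicate/method combination. Idempotent."""
    if quant.empty:
        raise ValueError("cannot requantify an empty group set")
    out = quant.copy()
    keys = _unit_keys(out)
    cols = [c for c in weight_cols if c in out.columns]
    if not cols:
        raise KeyError(f"no weight column among {weight_cols} present")
    grouped = out.groupby(keys, dropna=False) if keys else [((), out)]
    for _, sub in grouped:
        for col in cols:
            total = sub[col].sum()
            if total <= 0:
                raise ValueError("group set with zero total abundance")
            out.loc[sub.index, col] = sub[col] / total
    return out


def duplicate_consensus(rep_a: pd.Series, rep_b: pd.Series) -> pd.Series:
    """Average two technical replicates, requiring identification in both.

    Input vectors are normalized relative abundances indexed by group_id.
    Groups with zero/absent abundance in either replicate are dropped; the
    mean is renormalized to one.
    """
    common = rep_a[rep_a > 0].index.intersection(rep_b[rep_b > 0].index)
    if len(common) == 0:
        raise ValueError("no groups identified in both replicates")
    mean = (rep_a.loc[common] + rep_b.loc[common]) / 2.0
    return mean / mean.sum()


def pairwise_pcc(
    x: pd.Series,
    y: pd.Series,
    axis: str = "replicate",
    label_x: str = "x",
    label_y: str = "y",
    mode: str = "intersection",
) -> CorrelationReport:
    """Pearson correlation between two relative-abundance vectors.

    ``intersection`` correlates over groups quantified (> 0) in both
    vectors; ``union`` aligns on the union with zeros filled in.
    """
    if mode == "intersection":
        idx = x[x > 0].index.intersection(y[y > 0].index)
        xv, yv = x.loc[idx], y.loc[idx]
    elif mode == "union":
        idx = x.index.union(y.index)
        xv = x.reindex(idx, fill_value=0.0)
        yv = y.reindex(idx, fill_value=0.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n = len(idx)
    if n < 3:
        return CorrelationReport(axis, label_x, label_y, None, n,
                                 reason=f"only {n} common groups (need >=3)")
    if np.isclose(np.std(xv), 0) or np.isclose(np.std(yv), 0):
        return CorrelationReport(axis, label_x, label_y, None, n,
                                 reason="zero variance")
    r, _ = stats.pearsonr(xv.to_numpy(), yv.to_numpy())
    return CorrelationReport(axis, label_x, label_y, float(r), n)


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def merge_groups_across_methods(
    groups_by_method: Mapping[str, Mapping[str, Iterable[str]]],
) -> pd.DataFrame:
    """Merge protein groups that share a member protein across analytical
    methods (transitive closure).

    ``groups_by_method`` maps method -> {group_id -> member protein IDs}.
    Returns one row per merged group with its union of members, the methods
    it appears in, and the source group IDs.
    """
    uf = _UnionFind()
    protein_owner: dict[str, tuple] = {}
    nodes: dict[tuple, set[str]] = {}
    for method, groups in groups_by_method.items():
        for gid, members in groups.items():
            node = (method, gid)
            nodes[node] = set(members)
            uf.find(node)
            for pid in nodes[node]:
                if pid in protein_owner:
                    uf.union(protein_owner[pid], node)
                else:
                    protein_owner[pid] = node
    clusters: dict[tuple, list[tuple]] = {}
    for node in nodes:
        clusters.setdefault(uf.find(node), []).append(node)
    rows = []
    for members_nodes in clusters.values():
        member_proteins = sorted(set().union(*(nodes[n] for n in members_nodes)))
        source_ids = sorted({gid for _, gid in members_nodes})
        methods = sorted({m for m, _ in members_nodes})
        rows.append(
            {
                "merged_id": source_ids[0],
                "member_proteins": member_proteins,
                "methods": methods,
                "n_methods": len(methods),
                "source_group_ids": source_ids,
            }
        )
    return pd.DataFrame(rows).sort_values("merged_id").reset_index(drop=True)


def flag_suspect_outliers(
    observations: pd.DataFrame,
    promiscuity: Mapping[str, int],
    min_match_count: int = 1000,
) -> pd.DataFrame:
    """Flag potential false-positive groups for manual review.

    A group is suspect when it is identified by a single distinct peptide,
    exclusively through one analytical method, and that peptide matches at
    least ``min_match_count`` external database entries (promiscuity counts
    from e.g. a BLAST search are supplied, not computed). Flagging never
    removes anything; removal is an explicit, separately-logged action.
    """
    summary = observations.groupby("group_id").agg(
        n_distinct_peptides=("peptide_sequence", "nunique"),
        n_methods=("method", "nunique"),
        peptides=("peptide_sequence", lambda s: sorted(set(s))),
    )
    flags = []
    for gid, row in summary.iterrows():
        single = row["n_distinct_peptides"] == 1
        exclusive = row["n_methods"] == 1
        promiscuous = single and promiscuity.get(row["peptides"][0], 0) >= min_match_count
        flags.append(
            {
                "group_id": gid,
                "suspect": bool(single and exclusive and promiscuous),
                "n_distinct_peptides": int(row["n_distinct_peptides"]),
                "n_methods": int(row["n_methods"]),
                "peptide": row["peptides"][0] if single else None,
                "match_count": promiscuity.get(row["peptides"][0], 0) if single else None,
            }
        )
    return pd.DataFrame(flags).sort_values("group_id").reset_index(drop=True)


def attach_group_info(quant: pd.DataFrame, group_table: pd.DataFrame) -> pd.DataFrame:
    """Join score and decoy/contaminant flags from a protein-group table
    onto a quantification table."""
    info = group_table.set_index("group_id")[["score", "is_contaminant", "is_decoy"]]
    out = quant.merge(info, left_on="group_id", right_index=True, how="left")
    if out["score"].isna().any():
        missing = sorted(out.loc[out["score"].isna(), "group_id"].unique())
        raise KeyError(f"groups missing from group table: {missing}")
    return out
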