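import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from extractprofiler.qc import (
    duplicate_consensus,
    filter_decoys_contaminants,
    flag_suspect_outliers,
    merge_groups_across_methods,
    pairwise_pcc,
    quality_filter,
    quantitative_loss,
    requantify,
)


def quant_frame(rows, cols=("group_id", "sample_id", "replicate_id", "il_rel",
                            "summed_intensity", "n_peptides_observed", "score",
                            "is_decoy", "is_contaminant")):
    return pd.DataFrame(rows, columns=list(cols))


def simple_quant(weights, **extra):
    """One-sample one-replicate quant table from {group: il_rel}."""
    defaults = dict(score=100.0, n=5, decoy=False, contam=False)
    defaults.update(extra)
    return quant_frame(
        [
            (g, "V", "rep1", w, w * 100, defaults["n"], defaults["score"],
             defaults["decoy"], defaults["contam"])
            for g, w in weights.items()
        ]
    )


class TestDecoyContaminantFilter:
    def test_no_flags_no_loss(self):
        q = simple_quant({"g1": 0.6, "g2": 0.4})
        kept, ledger = filter_decoys_contaminants(q)
        assert len(kept) == 2
        assert all(v == 0.0 for v in ledger.quantitative_loss.values())

    def test_contaminant_loss_is_its_weight(self):
        q = simple_quant({"g1": 0.7, "gC": 0.3})
        q.loc[q["group_id"] == "gC", "is_contaminant"] = True
        kept, ledger = filter_decoys_contaminants(q)
        assert list(kept["group_id"]) == ["g1"]
        (loss,) = ledger.quantitative_loss.values()
        assert loss == pytest.approx(0.30, abs=1e-12)
        assert ledger.removed_ids == ["gC"]

    def test_idempotent(self):
        q = simple_quant({"g1": 0.7, "gC": 0.3})
        q.loc[q["group_id"] == "gC", "is_decoy"] = True
        once, _ = filter_decoys_contaminants(q)
        twice, ledger = filter_decoys_contaminants(once)
        pd.testing.assert_frame_equal(once, twice)
        assert all(v == 0.0 for v in ledger.quantitative_loss.values())


class TestQualityFilter:
    def test_score_threshold_toy(self):
        # scores spanning the reported range: very low 6.5, mid 45, maximum 323
        q = simple_quant({"g1": 0.2, "g2": 0.3, "g3": 0.5})
        q["score"] = [6.5, 45.0, 323.0]
        kept, _ = quality_filter(q, min_score=40, min_peptides=1,
                                 require_duplicate=False)
        assert sorted(kept["group_id"]) == ["g2", "g3"]

    def test_require_duplicate_removes_singletons(self):
        rows = [
            ("g1", "V", "rep1", 0.5, 50.0, 5, 200.0, False, False),
            ("g1", "V", "rep2", 0.5, 50.0, 5, 200.0, False, False),
            ("g2", "V", "rep1", 0.5, 50.0, 5, 200.0, False, False),
            ("g2", "V", "rep2", 0.5, 0.0, 5, 200.0, False, False),  # absent in rep2
        ]
        kept, _ = quality_filter(quant_frame(rows), min_score=0, min_peptides=1,
                                 require_duplicate=True)
        assert set(kept["group_id"]) == {"g1"}

    def test_identity_settings_keep_everything(self):
        q = simple_quant({"g1": 0.5, "g2": 0.5}, score=1.0, n=1)
        kept, ledger = quality_filter(q, min_score=0, min_peptides=1,
                                      require_duplicate=False)
        assert len(kept) == len(q)
        assert all(v == 0.0 for v in ledger.quantitative_loss.values())

    def test_score_override_rescues_single_peptide_group(self):
        q = simple_quant({"g1": 0.5, "g2": 0.5}, n=1)
        q["score"] = [150.0, 50.0]
        kept, _ = quality_filter(q, min_score=40, min_peptides=2,
                                 require_duplicate=False, score_override=100.0)
        assert list(kept["group_id"]) == ["g1"]

    def test_require_duplicate_needs_two_replicates(self):
        q = simple_quant({"g1": 1.0})
        with pytest.raises(ValueError, match="replicate"):
            quality_filter(q, require_duplicate=True)


class TestQuantitativeLoss:
    def test_identical_sets(self):
        before = pd.Series({"g1": 0.5, "g2": 0.5})
        assert quantitative_loss(before, before) == pytest.approx(0.0, abs=1e-12)

    def test_all_removed(self):
        before = pd.Series({"g1": 0.5, "g2": 0.5})
        assert quantitative_loss(before, []) == pytest.approx(1.0)

    def test_partial_removal(self):
        before = pd.Series({"g1": 0.05, "g2": 0.25, "g3": 0.7})
        assert quantitative_loss(before, ["g3"]) == pytest.approx(0.30, abs=1e-12)

    def test_superset_errors(self):
        before = pd.Series({"g1": 1.0})
        with pytest.raises(ValueError, match="absent"):
            quantitative_loss(before, ["g1", "gX"])

    def test_chain_rule_matches_direct_loss(self):
        # sequential losses on renormalized weights compose multiplicatively
        rng = np.random.default_rng(4)
        w = rng.dirichlet(np.ones(100))
        ids = [f"g{i}" for i in range(100)]
        before = pd.Series(w, index=ids)
        keep1 = ids[:70]
        keep2 = ids[:40]
        loss1 = quantitative_loss(before, keep1)
        renorm = before.loc[keep1] / before.loc[keep1].sum()
        loss2 = quantitative_loss(renorm, keep2)
        direct = quantitative_loss(before, keep2)
        assert 1 - (1 - loss1) * (1 - loss2) == pytest.approx(direct, abs=1e-9)

    def test_loss_monotone_in_score_threshold(self):
        rng = np.random.default_rng(5)
        w = rng.dirichlet(np.ones(30))
        q = simple_quant({f"g{i}": w[i] for i in range(30)})
        q["score"] = rng.uniform(0, 300, size=30)
        losses = []
        for thr in (0, 50, 100, 200, 400):
            _, ledger = quality_filter(q, min_score=thr, min_peptides=1,
                                       require_duplicate=False, score_override=1e9)
            (loss,) = ledger.quantitative_loss.values()
            losses.append(loss)
        assert losses == sorted(losses)


class TestRequantify:
    def test_half_half(self):
        q = simple_quant({"g1": 0.3, "g2": 0.3})
        out = requantify(q, ["il_rel"])
        assert out["il_rel"].tolist() == pytest.approx([0.5, 0.5])

    def test_single_survivor(self):
        q = simple_quant({"g1": 0.2})
        assert requantify(q, ["il_rel"])["il_rel"].tolist() == [1.0]

    def test_idempotent_and_rank_preserving(self):
        rng = np.random.default_rng(6)
        w = rng.uniform(0, 1, 10)
        q = simple_quant({f"g{i}": w[i] for i in range(10)})
        once = requantify(q, ["il_rel"])
        twice = requantify(once, ["il_rel"])
        pd.testing.assert_frame_equal(once, twice)
        assert list(once["il_rel"].rank()) == list(q["il_rel"].rank())

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            requantify(simple_quant({}), ["il_rel"])


class TestDuplicateConsensus:
    def test_identical_replicates_unchanged(self):
        a = pd.Series({"g1": 0.6, "g2": 0.4})
        out = duplicate_consensus(a, a.copy())
        assert out.to_dict() == pytest.approx({"g1": 0.6, "g2": 0.4})

    def test_group_in_one_replicate_dropped(self):
        a = pd.Series({"g1": 0.6, "g2": 0.4})
        b = pd.Series({"g1": 1.0, "g2": 0.0})
        assert "g2" not in duplicate_consensus(a, b).index

    def test_mean_of_replicates(self):
        a = pd.Series({"g1": 0.6, "g2": 0.4})
        b = pd.Series({"g1": 0.8, "g2": 0.2})
        out = duplicate_consensus(a, b)
        assert out.to_dict() == pytest.approx({"g1": 0.7, "g2": 0.3})

    def test_no_common_groups_errors(self):
        with pytest.raises(ValueError, match="both replicates"):
            duplicate_consensus(pd.Series({"g1": 1.0}), pd.Series({"g2": 1.0}))


class TestPairwisePcc:
    def test_self_correlation(self):
        x = pd.Series({"a": 0.1, "b": 0.5, "c": 0.4})
        assert pairwise_pcc(x, x).pcc == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        y = -x + 5
        assert pairwise_pcc(x, y).pcc == pytest.approx(-1.0)

    def test_textbook_formula(self):
        x = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        y = pd.Series({"a": 2.0, "b": 4.0, "c": 7.0})
        report = pairwise_pcc(x, y)
        # independent oracle: raw covariance formula
        xv, yv = x.to_numpy(), y.to_numpy()
        expected = ((xv - xv.mean()) * (yv - yv.mean())).sum() / np.sqrt(
            ((xv - xv.mean()) ** 2).sum() * ((yv - yv.mean()) ** 2).sum()
        )
        assert report.pcc == pytest.approx(expected, abs=1e-12)
        assert report.n_common == 3

    def test_agrees_with_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = pd.Series(rng.uniform(0.01, 1, 50), index=[f"g{i}" for i in range(50)])
            y = pd.Series(rng.uniform(0.01, 1, 50), index=x.index)
            got = pairwise_pcc(x, y).pcc
            xv, yv = x.to_numpy(), y.to_numpy()
            brute = ((xv - xv.mean()) * (yv - yv.mean())).sum() / np.sqrt(
                ((xv - xv.mean()) ** 2).sum() * ((yv - yv.mean()) ** 2).sum()
            )
            assert got == pytest.approx(brute, abs=1e-12)

    def test_zero_variance_reported_missing(self):
        x = pd.Series({"a": 0.5, "b": 0.5, "c": 0.5})
        y = pd.Series({"a": 0.1, "b": 0.2, "c": 0.7})
        report = pairwise_pcc(x, y)
        assert report.pcc is None and "variance" in report.reason

    def test_union_mode_fills_zeros(self):
        x = pd.Series({"a": 0.5, "b": 0.5})
        y = pd.Series({"a": 0.5, "c": 0.5})
        assert pairwise_pcc(x, y, mode="union").n_common == 3


class TestMergeGroups:
    def test_disjoint_groups_unmerged(self):
        merged = merge_groups_across_methods(
            {"tryptic": {"g1": ["pA"]}, "semi": {"g2": ["pB"]}}
        )
        assert len(merged) == 2

    def test_shared_member_merges(self):
        merged = merge_groups_across_methods(
            {"tryptic": {"g1": ["pA", "pB"]}, "semi": {"g2": ["pB"]}}
        )
        assert len(merged) == 1
        assert merged.loc[0, "n_methods"] == 2
        assert merged.loc[0, "member_proteins"] == ["pA", "pB"]

    def test_transitive_chain(self):
        merged = merge_groups_across_methods(
            {
                "tryptic": {"g1": ["pA", "pB"]},
                "semi": {"g2": ["pB", "pC"]},
                "unspecific": {"g3": ["pC", "pD"]},
            }
        )
        assert len(merged) == 1
        assert merged.loc[0, "member_proteins"] == ["pA", "pB", "pC", "pD"]

    def test_matches_brute_force_closure(self):
        rng = np.random.default_rng(8)
        proteins = [f"p{i}" for i in range(20)]
        groups_by_method = {
            m: {
                f"{m}_g{j}": list(rng.choice(proteins, size=rng.integers(1, 4),
                                             replace=False))
                for j in range(8)
            }
            for m in ("tryptic", "semi", "unspecific")
        }
        merged = merge_groups_across_methods(groups_by_method)
        # brute force: repeatedly merge any two sets sharing a protein
        sets = [set(v) for groups in groups_by_method.values() for v in groups.values()]
        changed = True
        while changed:
            changed = False
            for i, j in itertools.combinations(range(len(sets)), 2):
                if sets[i] and sets[j] and sets[i] & sets[j]:
                    sets[i] |= sets[j]
                    sets[j] = set()
                    changed = True
        brute = sorted(tuple(sorted(s)) for s in sets if s)
        got = sorted(tuple(m) for m in merged["member_proteins"])
        assert got == brute


class TestSuspectOutliers:
    def _obs(self, rows):
        return pd.DataFrame(
            rows, columns=["group_id", "peptide_sequence", "method"]
        )

    def test_promiscuous_single_peptide_single_method_flagged(self):
        obs = self._obs([("gX", "SLFSLLR", "semi"), ("gX", "SLFSLLR", "semi")])
        out = flag_suspect_outliers(obs, {"SLFSLLR": 5000})
        assert out.loc[out["group_id"] == "gX", "suspect"].item()

    def test_two_peptide_group_not_flagged(self):
        obs = self._obs([("gY", "AAAK", "semi"), ("gY", "CCCK", "semi")])
        out = flag_suspect_outliers(obs, {"AAAK": 9999, "CCCK": 9999})
        assert not out["suspect"].any()

    def test_multi_method_group_not_flagged(self):
        obs = self._obs(
            [("gZ", "AAAK", m) for m in ("tryptic", "semi", "unspecific")]
        )
        out = flag_suspect_outliers(obs, {"AAAK": 9999})
        assert not out["suspect"].any()

    def test_low_promiscuity_not_flagged(self):
        obs = self._obs([("gW", "AAAK", "semi")])
        out = flag_suspect_outliers(obs, {"AAAK": 10})
        assert not out["suspect"].any()


@given(st.lists(st.floats(min_value=1e-3, max_value=1.0), min_size=4, max_size=30))
@settings(max_examples=50, deadline=None)
def test_pcc_symmetry(values):
    ids = [f"g{i}" for i in range(len(values))]
    x = pd.Series(values, index=ids)
    y = pd.Series(values[::-1], index=ids)
    a, b = pairwise_pcc(x, y), pairwise_pcc(y, x)
    if a.pcc is not None:
        assert a.pcc == pytest.approx(b.pcc, abs=1e-12)
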