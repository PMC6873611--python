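"""Expressed filter, DEG calling, pattern clusters and hierarchical check."""

import math

import numpy as np
import pandas as pd
import pytest

from e3fam.expression import (
    CLUSTER_PROTOTYPES,
    CLUSTERS,
    assign_pattern_cluster,
    call_degs,
    deg_genes,
    expressed_set,
    fold_change_matrix,
    hierarchical_cluster,
    log2_fold_change,
    stage_summary,
)
from e3fam.io_formats import SAMPLES, STAGES, ExpressionMatrix
from e3fam.simulate import SimulationConfig, simulate_expression


def _matrix(rows: dict) -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=list(SAMPLES))
    )


def _row(mf, sh):
    return list(mf) + list(sh)


class TestExpressedSet:
    def test_below_threshold_everywhere_excluded(self):
        m = _matrix({"g1": [0.5] * 8})
        assert expressed_set(m) == set()

    def test_single_sample_above_threshold_included(self):
        m = _matrix({"g1": [1.01] + [0.0] * 7})
        assert expressed_set(m) == {"g1"}

    def test_matches_planted_silencing(self, default_dataset):
        ds = default_dataset
        truth_expressed = set(
            ds.truth.index[ds.truth["is_expressed"].astype(bool)]
        )
        assert expressed_set(ds.matrix) == truth_expressed


class TestLog2FoldChange:
    def test_equal_values_give_zero(self):
        m = _matrix({"g1": _row([5, 5, 5, 5], [5, 5, 5, 5])})
        assert log2_fold_change(m, "g1", "S3") == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_without_pseudocount(self):
        m = _matrix({"g1": _row([8, 0, 0, 0], [2, 0, 0, 0])})
        assert log2_fold_change(m, "g1", "S3", pseudocount=0.0) == 2.0

    def test_equals_direct_formula_on_random_matrices(self, rng):
        for _ in range(20):
            vals = rng.uniform(0, 50, 8)
            m = _matrix({"g1": vals})
            for i, s in enumerate(STAGES):
                expected = math.log2((vals[i] + 0.01) / (vals[4 + i] + 0.01))
                assert log2_fold_change(m, "g1", s) == pytest.approx(expected)


class TestCallDegs:
    def test_single_stage_down_call(self):
        m = _matrix({"g1": _row([8, 8, 8, 8 * 2 ** -2.5], [8, 8, 8, 8])})
        recs = {r.stage: r.direction for r in call_degs(m)}
        assert recs == {"S3": "ns", "S4I": "ns", "S4II": "ns", "S4III": "down"}
        assert deg_genes(call_degs(m)) == {"g1"}

    def test_all_ns_gene_is_not_deg(self):
        m = _matrix({"g1": _row([4, 4, 4, 4], [8, 8, 8, 8])})
        assert deg_genes(call_degs(m)) == set()

    def test_non_expressed_genes_produce_no_records(self):
        m = _matrix({"g1": [0.2] * 8})
        assert call_degs(m) == []

    def test_nonpositive_threshold_rejected(self):
        m = _matrix({"g1": [2.0] * 8})
        with pytest.raises(ValueError):
            call_degs(m, theta=0.0)

    def test_equals_brute_force_oracle_on_random_matrices(self, rng):
        """DEG calls match an independent per-cell recomputation on 50
        random matrices."""
        for _ in range(50):
            n = int(rng.integers(3, 12))
            ids = [f"g{i}" for i in range(n)]
            vals = rng.uniform(0, 40, (n, 8))
            m = ExpressionMatrix(
                pd.DataFrame(vals, index=ids, columns=list(SAMPLES))
            )
            recs = {(r.gene_id, r.stage): r.direction for r in call_degs(m)}
            expected = {}
            for i, g in enumerate(ids):
                if not (vals[i] > 1.0).any():
                    continue
                for j, s in enumerate(STAGES):
                    fc = math.log2((vals[i, j] + 0.01) / (vals[i, 4 + j] + 0.01))
                    expected[(g, s)] = (
                        "up" if fc >= 2.0 else "down" if fc <= -2.0 else "ns"
                    )
            assert recs == expected

    def test_noise_free_planted_degs_recovered_exactly(self):
        cfg = SimulationConfig(seed=11, fpkm_log2_sd=0.0)
        ids = [f"g{i:04d}" for i in range(1, 201)]
        m, truth = simulate_expression(cfg, ids)
        planted = set(truth.index[truth["cluster"] != ""])
        assert deg_genes(call_degs(m)) == planted


class TestPatternCluster:
    def test_all_down_is_cluster_vii(self):
        assert assign_pattern_cluster([-2.5, -2.1, -2.2, -3.0]) == "VII"

    def test_up_at_s4i_only_is_cluster_v(self):
        assert assign_pattern_cluster([-2.0, 2.5, -2.0, -2.0]) == "V"

    def test_tie_breaks_in_cluster_order(self):
        # (0,0,0,0) signs are distance 1 from both I and VIII; I wins
        assert assign_pattern_cluster([0.1, 0.0, 0.0, 2.0], delta=3.0) == "I"

    def test_non_deg_rejected(self):
        with pytest.raises(ValueError, match="not a DEG"):
            assign_pattern_cluster([0.5, 0.5, 0.0, 1.0])

    def test_noise_free_labels_fully_recovered(self):
        cfg = SimulationConfig(seed=13, fpkm_log2_sd=0.0)
        ids = [f"g{i:04d}" for i in range(1, 301)]
        m, truth = simulate_expression(cfg, ids)
        deg = sorted(deg_genes(call_degs(m)))
        fc = fold_change_matrix(m, deg)
        for g in deg:
            assert assign_pattern_cluster(fc.loc[g].to_numpy()) == truth.at[
                g, "cluster"
            ]

    def test_stochastic_recovery_at_default_noise(self):
        """With log2 noise sd 0.2 and effect 2.0 (400 planted DEGs, seed 7),
        >= 95% of the planted labels of called DEGs are recovered."""
        cfg = SimulationConfig(seed=7, n_genes=1000, silenced_fraction=0.2,
                               deg_fraction=0.5)
        ids = [f"g{i:04d}" for i in range(1, 1001)]
        m, truth = simulate_expression(cfg, ids)
        planted = set(truth.index[truth["cluster"] != ""])
        assert len(planted) == 400
        called = sorted(deg_genes(call_degs(m)) & planted)
        fc = fold_change_matrix(m, called)
        hits = sum(
            assign_pattern_cluster(fc.loc[g].to_numpy())
            == truth.at[g, "cluster"]
            for g in called
        )
        assert hits / len(called) >= 0.95


class TestHierarchicalCluster:
    def test_two_groups_of_identical_vectors_split_perfectly(self):
        fc = pd.DataFrame(
            [[2, 2, 2, 2]] * 5 + [[-2, -2, 2, -2]] * 5,
            index=[f"g{i}" for i in range(10)],
            dtype=float,
        )
        ids = hierarchical_cluster(fc, k=2)
        assert len(set(ids[:5])) == 1 and len(set(ids[5:])) == 1
        assert ids.iloc[0] != ids.iloc[-1]

    def test_duplicate_vector_joins_its_twin(self):
        fc = pd.DataFrame(
            [[2, 0, 0, 0], [0, 2, 0, 0], [0, 0, 2, 0], [2, 0, 0, 0]],
            index=list("abcd"),
            dtype=float,
        )
        ids = hierarchical_cluster(fc, k=3)
        assert ids["a"] == ids["d"]

    def test_agrees_with_prototype_labels_on_separable_data(self):
        """On noise-free prototype-planted profiles, cutting at k=8 matches
        the prototype assignment up to label permutation."""
        rows, labels = [], []
        for name in CLUSTERS:
            proto = np.array(CLUSTER_PROTOTYPES[name], dtype=float) * 2.0
            for _ in range(6):
                rows.append(proto)
                labels.append(name)
        fc = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
        ids = hierarchical_cluster(fc, k=8)
        mapping = {}
        for gid, lab in zip(ids, labels):
            mapping.setdefault(gid, set()).add(lab)
        assert all(len(v) == 1 for v in mapping.values())
        assert len(mapping) == 8

    def test_invalid_inputs_rejected(self):
        fc = pd.DataFrame([[1.0, 0, 0, 0]] * 3)
        with pytest.raises(ValueError):
            hierarchical_cluster(fc, k=1)
        with pytest.raises(ValueError):
            hierarchical_cluster(fc, k=8)
        zero = pd.DataFrame([[0.0, 0, 0, 0]] * 8)
        with pytest.raises(ValueError, match="all-zero"):
            hierarchical_cluster(zero, k=2)


class TestStageSummary:
    def test_counts_and_percentages_equal_brute_force(self, default_dataset):
        ds = default_dataset
        labels = dict(ds.truth["subfamily"])
        summary = stage_summary(ds.matrix, labels)
        e3_genes = [g for g in ds.matrix.gene_ids if labels[g] != "NONE"]
        sub = ExpressionMatrix(ds.matrix.values.loc[e3_genes])
        recs = call_degs(sub)
        for sf in summary.index.drop("Total"):
            members = [g for g in e3_genes if labels[g] == sf]
            assert summary.at[sf, "size"] == len(members)
            for s in STAGES:
                eg = sum(
                    ds.matrix.fpkm(g, "MF", s) > 1.0
                    or ds.matrix.fpkm(g, "SH", s) > 1.0
                    for g in members
                )
                assert summary.at[sf, f"EG_{s}"] == eg
                dg = {
                    r.gene_id for r in recs
                    if r.stage == s and r.direction != "ns"
                }
                assert summary.at[sf, f"DEG_{s}"] == sum(
                    g in dg for g in members
                )

    def test_column_sums_equal_total_row(self, default_dataset):
        ds = default_dataset
        summary = stage_summary(ds.matrix, dict(ds.truth["subfamily"]))
        body = summary.drop(index="Total")
        for col in summary.columns:
            if col.endswith("_pct"):
                continue
            assert body[col].sum() == summary.at["Total", col], col

    def test_published_scale_percentage_convention(self):
        """242 expressed of 338 prints as 71.60 under two-decimal half-up."""
        from e3fam.report import percentage

        assert percentage(242, 338, 2) == 71.60
        assert percentage(231, 765, 2) == 30.20

    def test_deg_subset_of_expressed_invariant(self, default_dataset):
        m = default_dataset.matrix
        recs = call_degs(m)
        assert deg_genes(recs) <= expressed_set(m)
        assert {r.gene_id for r in recs} <= expressed_set(m)
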