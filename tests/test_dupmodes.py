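"""Gene ranking, collinearity chaining and duplication-mode calls."""

import itertools

import pytest

from e3fam.dupmodes import (
    CollinearBlock,
    HomologPair,
    classify_duplication,
    detect_collinear_blocks,
    rank_genes,
    summarize_modes,
)
from e3fam.io_formats import GeneModel


def _gene(gid, chrom, start, length=100):
    return GeneModel(gid, chrom, start, start + length - 1, "+", 1, 0)


def _layout(ranks_by_chrom):
    """Genes at 1000-bp spacing realizing the requested rank layout."""
    genes = []
    for chrom, gids in ranks_by_chrom.items():
        for i, gid in enumerate(gids):
            genes.append(_gene(gid, chrom, 1000 * (i + 1)))
    return rank_genes(genes)


class TestRankGenes:
    def test_ranks_follow_start_order(self):
        genes = [_gene("a", "chr1", 500), _gene("b", "chr1", 100),
                 _gene("c", "chr1", 300)]
        ranks = {g.gene_id: g.rank for g in rank_genes(genes)}
        assert ranks == {"b": 1, "c": 2, "a": 3}

    def test_ranks_restart_per_chromosome(self):
        genes = [_gene("a", "chr1", 100), _gene("b", "chr2", 50)]
        assert {g.gene_id: g.rank for g in rank_genes(genes)} == {"a": 1, "b": 1}

    def test_order_invariance(self, desk_layout_dataset):
        genes = desk_layout_dataset.genes
        fwd = {g.gene_id: g.rank for g in rank_genes(genes)}
        rev = {g.gene_id: g.rank for g in rank_genes(genes[::-1])}
        assert fwd == rev

    def test_duplicate_coordinates_rejected(self):
        genes = [_gene("a", "chr1", 100), _gene("b", "chr1", 100)]
        with pytest.raises(ValueError, match="duplicate coordinates"):
            rank_genes(genes)


def _chain_layout(n, offset=0):
    a = [f"a{i}" for i in range(n)]
    b = [f"b{i}" for i in range(n)]
    genes = _layout({"chr1": a, "chr2": b})
    pairs = [HomologPair(x, y) for x, y in zip(a, b)]
    return genes, pairs


class TestCollinearBlocks:
    def test_six_order_preserving_pairs_form_one_block(self):
        genes, pairs = _chain_layout(6)
        blocks = detect_collinear_blocks(pairs, genes, min_pairs=5)
        assert len(blocks) == 1 and len(blocks[0]) == 6
        assert blocks[0].orientation == "same"

    def test_four_pairs_below_threshold_give_no_block(self):
        genes, pairs = _chain_layout(4)
        assert detect_collinear_blocks(pairs, genes, min_pairs=5) == []

    def test_inverted_orientation_detected(self):
        a = [f"a{i}" for i in range(6)]
        b = [f"b{i}" for i in range(6)]
        genes = _layout({"chr1": a, "chr2": b})
        pairs = [HomologPair(x, y) for x, y in zip(a, b[::-1])]
        (block,) = detect_collinear_blocks(pairs, genes, min_pairs=5)
        assert block.orientation == "inverted" and len(block) == 6

    def test_rank_gap_limit_splits_chains(self):
        a = [f"a{i}" for i in range(6)]
        b = [f"b{i}" for i in range(6)]
        fillers = [f"f{i}" for i in range(30)]
        genes = _layout({"chr1": a[:3] + fillers + a[3:], "chr2": b})
        pairs = [HomologPair(x, y) for x, y in zip(a, b)]
        assert detect_collinear_blocks(pairs, genes, min_pairs=5, max_gap=25) == []

    def test_close_intra_chromosome_pairs_do_not_chain(self):
        # runs of tandem pairs are not self-collinearity
        ids = [f"t{i}" for i in range(12)]
        genes = _layout({"chr1": ids})
        pairs = [HomologPair(ids[i], ids[i + 1]) for i in range(11)]
        assert detect_collinear_blocks(pairs, genes, min_pairs=5) == []

    def test_matches_exhaustive_search_on_small_instances(self, rng):
        """The DP chain equals the exhaustive optimum (length, then leftmost
        anchor) on random instances of <= 15 pairs."""
        for trial in range(30):
            n = int(rng.integers(5, 16))
            ra = rng.permutation(40)[:n] + 1
            rb = rng.permutation(40)[:n] + 1
            a_ids = [f"a{r}" for r in ra]
            b_ids = [f"b{r}" for r in rb]
            genes = _layout(
                {
                    "chr1": [f"a{r}" for r in sorted(ra)],
                    "chr2": [f"b{r}" for r in sorted(rb)],
                }
            )
            pairs = [HomologPair(x, y) for x, y in zip(a_ids, b_ids)]
            min_pairs, max_gap = 3, 10
            blocks = detect_collinear_blocks(pairs, genes, min_pairs, max_gap)

            loc = {g.gene_id: (g.chrom, g.rank) for g in genes}
            entries = []
            for p in pairs:
                (c1, r1), (c2, r2) = loc[p.gene_a], loc[p.gene_b]
                if (c2, r2) < (c1, r1):
                    r1, r2 = r2, r1
                entries.append((r1, r2))

            def valid_chain(sel, sign):
                sel = sorted(sel, key=lambda i: entries[i][0])
                for i, j in zip(sel, sel[1:]):
                    da = entries[j][0] - entries[i][0]
                    db = sign * (entries[j][1] - entries[i][1])
                    if da <= 0 or da > max_gap or db <= 0 or db > max_gap:
                        return False
                return True

            best = (0, None)
            for size in range(len(pairs), 0, -1):
                found = []
                for sel in itertools.combinations(range(len(pairs)), size):
                    for sign in (1, -1):
                        if valid_chain(sel, sign):
                            anchor = min(entries[i] for i in sel)
                            found.append((anchor, sel))
                            break
                if found:
                    best = (size, min(found)[1])
                    break
            if best[0] < min_pairs:
                assert blocks == []
            else:
                assert blocks, f"trial {trial}: missed a chain of {best[0]}"
                assert len(blocks[0]) == best[0]


class TestClassifyDuplication:
    def test_adjacent_homologs_are_tandem(self):
        genes = _layout({"chr1": ["a", "b", "c"]})
        pairs = [HomologPair("a", "b")]
        calls = {c.gene_id: c.mode for c in classify_duplication(genes, pairs, [])}
        assert calls == {"a": "TD", "b": "TD", "c": "SINGLETON"}

    def test_proximal_window(self):
        ids = ["a"] + [f"f{i}" for i in range(9)] + ["b", "c"]
        genes = _layout({"chr1": ids})
        pairs = [HomologPair("a", "b")]  # rank difference 10
        calls = {c.gene_id: c.mode for c in classify_duplication(genes, pairs, [])}
        assert calls["a"] == calls["b"] == "PD"
        pairs = [HomologPair("a", "c")]  # rank difference 11
        calls = {c.gene_id: c.mode for c in classify_duplication(genes, pairs, [])}
        assert calls["a"] == calls["c"] == "DSD"

    def test_cross_chromosome_pair_outside_blocks_is_dispersed(self):
        genes = _layout({"chr1": ["a"], "chr2": ["b"]})
        pairs = [HomologPair("a", "b")]
        calls = {c.gene_id: c.mode for c in classify_duplication(genes, pairs, [])}
        assert calls == {"a": "DSD", "b": "DSD"}

    def test_block_membership_wins_priority(self):
        genes, pairs = _chain_layout(6)
        blocks = detect_collinear_blocks(pairs, genes, min_pairs=5)
        calls = classify_duplication(genes, pairs, blocks)
        assert all(c.mode == "WGD" for c in calls)

    def test_unknown_gene_in_pair_rejected(self):
        genes = _layout({"chr1": ["a"]})
        with pytest.raises(ValueError, match="unknown gene"):
            classify_duplication(genes, [HomologPair("a", "zzz")], [])

    def test_adding_a_block_only_moves_genes_toward_wgd(self):
        genes, pairs = _chain_layout(6)
        without = {c.gene_id: c.mode
                   for c in classify_duplication(genes, pairs, [])}
        blocks = detect_collinear_blocks(pairs, genes, min_pairs=5)
        with_blocks = {c.gene_id: c.mode
                       for c in classify_duplication(genes, pairs, blocks)}
        priority = {"SINGLETON": 0, "DSD": 1, "PD": 2, "TD": 3, "WGD": 4}
        for g in without:
            assert priority[with_blocks[g]] >= priority[without[g]]


@pytest.mark.parametrize("seed", range(1, 21))
def test_planted_modes_recovered_exactly(seed):
    """Across 20 seeded 200-gene layouts every planted duplication mode is
    recovered (the noise-free parameter-recovery property)."""
    from e3fam.simulate import SimulationConfig, simulate_all

    ds = simulate_all(SimulationConfig(seed=seed, n_genes=200))
    ranked = rank_genes(ds.genes)
    pairs = [HomologPair(a, b, s) for a, b, s in ds.pairs]
    blocks = detect_collinear_blocks(pairs, ranked)
    calls = classify_duplication(ranked, pairs, blocks)
    assert len(calls) == len(ds.genes)
    for c in calls:
        assert c.mode == ds.truth.at[c.gene_id, "duplication_mode"], c


class TestSummarizeModes:
    def test_published_scale_percentages(self):
        """Half-up integer percentages match the printed convention
        (365/765 -> 48, 34/67 -> 51)."""
        calls = []
        labels = {}
        counts = {"BTB": {"DSD": 34, "TD": 11, "WGD": 14, "PD": 3,
                          "SINGLETON": 5}}
        k = 0
        for sf, modes in counts.items():
            for mode, n in modes.items():
                for _ in range(n):
                    gid = f"g{k}"
                    k += 1
                    from e3fam.dupmodes import DuplicationCall

                    calls.append(DuplicationCall(gid, mode))
                    labels[gid] = sf
        s = summarize_modes(calls, labels)
        assert s.counts.at["BTB", "Total"] == 67
        assert s.pct_of_subfamily.at["BTB", "DSD"] == 51
        assert s.pct_of_subfamily.at["BTB", "WGD"] == 21
        assert s.pct_of_subfamily.at["BTB", "TD"] == 16

    def test_mode_counts_conserve_subfamily_totals(self, desk_layout_dataset):
        ds = desk_layout_dataset
        ranked = rank_genes(ds.genes)
        pairs = [HomologPair(a, b, s) for a, b, s in ds.pairs]
        blocks = detect_collinear_blocks(pairs, ranked)
        calls = classify_duplication(ranked, pairs, blocks)
        labels = dict(ds.truth["subfamily"])
        s = summarize_modes(calls, labels)
        body = s.counts.drop(index="Total")
        assert (body[list(("DSD", "TD", "WGD", "PD", "SINGLETON"))].sum(axis=1)
                == body["Total"]).all()
        assert body["Total"].sum() == s.counts.at["Total", "Total"] == len(calls)
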