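"""Window construction, anchor detection and candidate enumeration,
checked against brute-force oracles on small genomes."""

import itertools

import numpy as np
import pytest

from ohnoscan import (
    Genome,
    HomologyMap,
    WindowSpec,
    canonical_pair,
    candidates_from_outgroup,
    candidates_from_self,
    find_anchors,
    make_window,
    window_span,
)


def _chain(genome_id, chrom, n, prefix):
    return Genome.from_chromosomes(
        genome_id, {chrom: [f"{prefix}{i}" for i in range(1, n + 1)]}
    )


class TestMakeWindow:
    def test_window_of_eight_plus_one_covers_nine_gene_chromosome(self):
        g = _chain("v", "c1", 9, "v")
        assert make_window(g, "v5", WindowSpec(8)) == frozenset(
            f"v{i}" for i in range(1, 10)
        )

    def test_truncated_at_chromosome_start(self):
        g = _chain("v", "c1", 9, "v")
        assert make_window(g, "v1", WindowSpec(8)) == frozenset(
            ["v1", "v2", "v3", "v4", "v5"]
        )

    def test_unknown_gene_raises(self):
        g = _chain("v", "c1", 9, "v")
        with pytest.raises(KeyError):
            make_window(g, "nope", WindowSpec(4))

    @pytest.mark.parametrize("W", [2, 4, 7, 10])
    def test_matches_brute_force_slicing(self, W):
        rng = np.random.default_rng(0)
        g = _chain("v", "c1", 25, "v")
        genes = g.chromosomes["c1"]
        for _ in range(20):
            pos = int(rng.integers(1, 26))
            half = W // 2
            expected = frozenset(genes[max(0, pos - 1 - half) : pos + half])
            assert make_window(g, f"v{pos}", WindowSpec(W)) == expected


def _brute_force_anchors(vertebrate, outgroup, pairs, W, min_support):
    """Independent oracle: double loop over window gene pairs."""
    spec = WindowSpec(W)
    out = {}
    for o, v in pairs:
        wo = make_window(outgroup, o, spec)
        wv = make_window(vertebrate, v, spec)
        support = sum(
            1
            for o2, v2 in pairs
            if (o2, v2) != (o, v) and o2 in wo and v2 in wv
        )
        if support >= min_support:
            out[(o, v)] = support
    return out


class TestFindAnchors:
    def _identity_setup(self, n=12):
        vert = _chain("vert", "c1", n, "g")
        outg = Genome.from_chromosomes("outg", {"c1": [f"o{i}" for i in range(1, n + 1)]})
        omap = HomologyMap(kind="ortholog", genome_a="outg", genome_b="vert")
        for i in range(1, n + 1):
            omap.add(f"o{i}", f"g{i}")
        return vert, outg, omap

    def test_identity_orthology_anchors_every_gene(self):
        vert, outg, omap = self._identity_setup()
        anchors = find_anchors(vert, outg, omap, WindowSpec(4), min_support=1)
        by_pair = {(a.outgroup_gene, a.vertebrate_gene): a.support_count for a in anchors}
        assert len(by_pair) == 12
        # interior genes see the full window of four neighbours
        assert by_pair[("o6", "g6")] == 4

    def test_windows_sharing_only_the_anchor_are_rejected(self):
        vert = _chain("vert", "c1", 10, "g")
        outg = Genome.from_chromosomes("outg", {"c1": [f"o{i}" for i in range(1, 11)]})
        omap = HomologyMap(kind="ortholog", genome_a="outg", genome_b="vert")
        omap.add("o5", "g5")  # a single ortholog pair: no additional support
        assert find_anchors(vert, outg, omap, WindowSpec(4), min_support=1) == []

    @pytest.mark.parametrize("seed,W", [(0, 4), (1, 6), (2, 10)])
    def test_support_counts_match_brute_force(self, seed, W):
        rng = np.random.default_rng(seed)
        vert = Genome.from_chromosomes(
            "vert",
            {
                "cA": [f"g{i}" for i in rng.permutation(30)],
                "cB": [f"g{i}" for i in range(30, 50)],
            },
        )
        outg = Genome.from_chromosomes(
            "outg", {"cO": [f"o{i}" for i in rng.permutation(40)]}
        )
        omap = HomologyMap(kind="ortholog", genome_a="outg", genome_b="vert")
        for _ in range(60):
            omap.add(f"o{rng.integers(40)}", f"g{rng.integers(50)}")
        expected = _brute_force_anchors(vert, outg, sorted(omap.pairs), W, 1)
        anchors = find_anchors(vert, outg, omap, WindowSpec(W), min_support=1)
        got = {(a.outgroup_gene, a.vertebrate_gene): a.support_count for a in anchors}
        assert got == expected

    def test_anchor_windows_materialise_from_spans(self):
        vert, outg, omap = self._identity_setup()
        anchor = next(
            a for a in find_anchors(vert, outg, omap, WindowSpec(4), 1)
            if a.vertebrate_gene == "g6"
        )
        assert anchor.vertebrate_window(vert) == make_window(vert, "g6", WindowSpec(4))
        assert anchor.outgroup_window(outg) == make_window(outg, "o6", WindowSpec(4))


class TestCandidatesFromOutgroup:
    def _anchors_for(self, vert_genes):
        vert = Genome.from_chromosomes(
            "vert", {f"c{i}": [f"{g}{j}" for j in range(1, 8)]
                     for i, g in enumerate(vert_genes)}
        )
        outg = _chain("outg", "c1", 7, "o")
        omap = HomologyMap(kind="ortholog", genome_a="outg", genome_b="vert")
        for g in vert_genes:
            omap.add("o4", f"{g}4")
            for j in (3, 5):  # shared support on every window
                omap.add(f"o{j}", f"{g}{j}")
        return find_anchors(vert, outg, omap, WindowSpec(4), 1)

    def test_two_anchors_sharing_an_outgroup_gene_give_one_pair(self):
        anchors = [a for a in self._anchors_for(["x", "y"]) if a.outgroup_gene == "o4"]
        cands = candidates_from_outgroup(anchors, "outg", 4)
        assert {(c.gene_1, c.gene_2) for c in cands} == {("x4", "y4")}
        (cand,) = cands
        assert {b.anchor_target_gene for b in cand.blocks} == {"x4", "y4"}
        assert all(b.anchor_source_gene == "o4" for b in cand.blocks)

    def test_single_anchor_yields_no_candidate(self):
        anchors = [a for a in self._anchors_for(["x"]) if a.outgroup_gene == "o4"]
        assert candidates_from_outgroup(anchors, "outg", 4) == []

    def test_three_anchors_yield_all_three_pairs(self):
        anchors = [a for a in self._anchors_for(["x", "y", "z"]) if a.outgroup_gene == "o4"]
        cands = candidates_from_outgroup(anchors, "outg", 4)
        expected = {
            canonical_pair(a + "4", b + "4")
            for a, b in itertools.combinations(["x", "y", "z"], 2)
        }
        assert {(c.gene_1, c.gene_2) for c in cands} == expected


def _brute_force_self(genome, paralogs, W, min_support):
    spec = WindowSpec(W)
    out = set()
    for a, b in paralogs.pairs:
        if window_span(genome, a, spec).overlaps(window_span(genome, b, spec)):
            continue
        wa, wb = make_window(genome, a, spec), make_window(genome, b, spec)
        support = sum(
            1
            for c, d in paralogs.pairs
            if (c, d) != (a, b)
            and ((c in wa and d in wb) or (c in wb and d in wa))
        )
        if support >= min_support:
            out.add((a, b))
    return out


class TestCandidatesFromSelf:
    def _paralog_setup(self):
        rng = np.random.default_rng(3)
        genome = Genome.from_chromosomes(
            "vert",
            {
                "cA": [f"g{i}" for i in rng.permutation(30)],
                "cB": [f"g{i}" for i in range(30, 50)],
            },
        )
        pmap = HomologyMap(kind="paralog", genome_a="vert", genome_b="vert")
        for _ in range(40):
            a, b = rng.choice(50, size=2, replace=False)
            pmap.add(f"g{a}", f"g{b}", "WGD")
        return genome, pmap

    def test_supported_pair_is_emitted(self):
        genome = Genome.from_chromosomes(
            "v", {"cA": [f"a{i}" for i in range(1, 8)],
                  "cB": [f"b{i}" for i in range(1, 8)]}
        )
        pmap = HomologyMap(kind="paralog", genome_a="v", genome_b="v")
        for i in (2, 3, 4, 5, 6):
            pmap.add(f"a{i}", f"b{i}", "WGD")
        cands = candidates_from_self(genome, pmap, WindowSpec(4), min_support=1)
        pairs = {(c.gene_1, c.gene_2) for c in cands}
        assert ("a4", "b4") in pairs
        cand = next(c for c in cands if (c.gene_1, c.gene_2) == ("a4", "b4"))
        assert cand.blocks[0].support == 4

    def test_tandem_paralogs_with_overlapping_windows_skipped(self):
        genome = _chain("v", "c1", 20, "g")
        pmap = HomologyMap(kind="paralog", genome_a="v", genome_b="v")
        pmap.add("g5", "g7", "WGD")
        pmap.add("g4", "g8", "WGD")
        assert candidates_from_self(genome, pmap, WindowSpec(6), 1) == []

    @pytest.mark.parametrize("W", [4, 8])
    def test_matches_brute_force_on_50_gene_genome(self, W):
        genome, pmap = self._paralog_setup()
        expected = _brute_force_self(genome, pmap, W, 1)
        got = {
            (c.gene_1, c.gene_2)
            for c in candidates_from_self(genome, pmap, WindowSpec(W), 1)
        }
        assert got == expected


class TestMonotonicity:
    def test_outgroup_candidate_sets_grow_with_W(self):
        rng = np.random.default_rng(8)
        vert = Genome.from_chromosomes(
            "vert", {"cA": [f"g{i}" for i in rng.permutation(40)],
                     "cB": [f"g{i}" for i in range(40, 80)]}
        )
        outg = Genome.from_chromosomes(
            "outg", {"cO": [f"o{i}" for i in rng.permutation(50)]}
        )
        omap = HomologyMap(kind="ortholog", genome_a="outg", genome_b="vert")
        for _ in range(90):
            omap.add(f"o{rng.integers(50)}", f"g{rng.integers(80)}")
        previous: set = set()
        for W in (4, 8, 12, 16):
            anchors = find_anchors(vert, outg, omap, WindowSpec(W), 1)
            pairs = {
                (c.gene_1, c.gene_2)
                for c in candidates_from_outgroup(anchors, "outg", W)
            }
            assert previous <= pairs
            previous = pairs

    def test_self_candidates_grow_with_W_for_non_overlapping_pairs(self):
        # the overlap-skip rule exempts same-chromosome pairs whose windows
        # meet at large W, so monotonicity is asserted on distinct chromosomes
        rng = np.random.default_rng(9)
        genome = Genome.from_chromosomes(
            "v", {"cA": [f"a{i}" for i in rng.permutation(40)],
                  "cB": [f"b{i}" for i in rng.permutation(40)]}
        )
        pmap = HomologyMap(kind="paralog", genome_a="v", genome_b="v")
        for _ in range(50):
            pmap.add(f"a{rng.integers(40)}", f"b{rng.integers(40)}", "WGD")
        previous: set = set()
        for W in (4, 8, 12):
            pairs = {
                (c.gene_1, c.gene_2)
                for c in candidates_from_self(genome, pmap, WindowSpec(W), 1)
            }
            assert previous <= pairs
            previous = pairs
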