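"""Placement P-values, block tail probabilities and q-score aggregation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ohnoscan import (
    Genome,
    PlacementModel,
    block_pvalue,
    combine_outgroups,
    count_valid_placements,
    gene_pvalue,
    geometric_mean_over_W,
    pair_q_at_W,
    poisson_binomial_sf,
)
from ohnoscan.scan import Span
from ohnoscan.stats import Q_FLOOR, count_tail_pvalue


def _enumerate_valid(chrom_sizes, positions, W):
    """Brute-force oracle: enumerate every placement explicitly."""
    count = 0
    for chrom, n in chrom_sizes.items():
        occupied = {p for c, p in positions if c == chrom}
        for start in range(1, n - W + 1):
            if not occupied & set(range(start, start + W)):
                count += 1
    return count


class TestPlacements:
    def test_schematic_genome_has_31_placements_and_12_valid(self):
        model = PlacementModel({"chr1": 36})
        homologs = [("chr1", p) for p in (1, 8, 19, 23, 32)]
        assert model.n_placements(5) == 31
        assert count_valid_placements(model, homologs, 5) == 12
        assert gene_pvalue(model, homologs, 5) == pytest.approx(1 - 12 / 31)

    def test_no_homologs_leaves_every_placement_valid(self):
        model = PlacementModel({"c1": 20, "c2": 15})
        assert count_valid_placements(model, [], 5) == model.n_placements(5)
        assert gene_pvalue(model, [], 5) == 0.0

    def test_homolog_at_every_position_blocks_everything(self):
        model = PlacementModel({"c1": 12})
        homologs = [("c1", p) for p in range(1, 13)]
        assert gene_pvalue(model, homologs, 4) == 1.0

    def test_window_larger_than_every_chromosome(self):
        model = PlacementModel({"c1": 5})
        assert count_valid_placements(model, [("c1", 2)], 8) == 0
        with pytest.raises(ValueError, match="fragmented"):
            gene_pvalue(model, [], 8)

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_random_small_genomes_match_exhaustive_enumeration(self, data):
        n_chrom = data.draw(st.integers(1, 3))
        sizes = {
            f"c{i}": data.draw(st.integers(3, 25)) for i in range(n_chrom)
        }
        W = data.draw(st.integers(1, 10))
        positions = [
            (c, p)
            for c, n in sizes.items()
            for p in data.draw(
                st.lists(st.integers(1, n), max_size=6, unique=True)
            )
        ]
        model = PlacementModel(sizes)
        if model.n_placements(W) == 0:
            return
        assert count_valid_placements(model, positions, W) == _enumerate_valid(
            sizes, positions, W
        )


def _enumerate_tail(probs, k):
    """Exact P(X >= k) by summing over all Bernoulli outcomes."""
    total = 0.0
    for outcome in itertools.product([0, 1], repeat=len(probs)):
        if sum(outcome) >= k:
            prob = 1.0
            for hit, p in zip(outcome, probs):
                prob *= p if hit else 1 - p
            total += prob
    return total


class TestCountTail:
    @pytest.mark.parametrize("seed", range(5))
    def test_poisson_binomial_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.uniform(0, 1, size=rng.integers(1, 9)).tolist()
        for k in range(len(probs) + 2):
            assert poisson_binomial_sf(k, probs) == pytest.approx(
                _enumerate_tail(probs, k), abs=1e-12
            )

    def test_poisson_approximation_tracks_exact_tail_at_small_p(self):
        rng = np.random.default_rng(1)
        probs = rng.uniform(0, 0.05, size=60).tolist()
        for k in (1, 2, 4):
            exact = count_tail_pvalue(probs, k, method="exact-tail")
            approx = count_tail_pvalue(probs, k, method="count-tail")
            assert approx == pytest.approx(exact, rel=0.1)

    def test_conditioning_erases_threshold_level_evidence(self):
        probs = [0.1] * 20
        assert count_tail_pvalue(probs, 1, condition_min=1) == 1.0
        cond = count_tail_pvalue(probs, 3, condition_min=1)
        raw = count_tail_pvalue(probs, 3)
        assert raw < cond <= 1.0

    def test_tail_is_monotone_in_k(self):
        probs = [0.3, 0.1, 0.2, 0.05]
        values = [count_tail_pvalue(probs, k, method="exact-tail") for k in range(6)]
        assert values == sorted(values, reverse=True)


class TestBlockPvalue:
    def _model(self):
        genome = Genome.from_chromosomes(
            "v", {"c1": [f"g{i}" for i in range(1, 31)]}
        )
        return genome, PlacementModel.from_genome(genome)

    def test_zero_supporting_genes_give_one(self):
        _, model = self._model()
        target = Span("c1", 10, 14)
        assert block_pvalue(model, ["s1", "s2"], target, {}, 5) == 1.0

    def test_single_supporting_gene_reduces_to_its_placement_pvalue(self):
        _, model = self._model()
        target = Span("c1", 10, 14)
        positions = {"s1": [("c1", 12)]}
        p_i = gene_pvalue(model, positions["s1"], 5)
        for method in ("product", "exact-tail", "count-tail"):
            got = block_pvalue(
                model, ["s1", "s2"], target, positions, 5,
                method=method, scope="genome",
            )
            # the Poisson tail is an approximation: 1 - exp(-p) vs p
            tolerance = 0.1 if method == "count-tail" else 1e-12
            assert got == pytest.approx(p_i, rel=tolerance)

    def test_product_method_multiplies_cooccurring_pvalues(self):
        _, model = self._model()
        target = Span("c1", 10, 14)
        positions = {"s1": [("c1", 12)], "s2": [("c1", 11), ("c1", 25)]}
        expected = gene_pvalue(model, positions["s1"], 5) * gene_pvalue(
            model, positions["s2"], 5
        )
        got = block_pvalue(
            model, ["s1", "s2"], target, positions, 5,
            method="product", scope="genome",
        )
        assert got == pytest.approx(expected)

    def test_adding_a_supporting_pair_never_raises_the_pvalue(self):
        _, model = self._model()
        target = Span("c1", 10, 16)
        positions = {"s1": [("c1", 12)], "s2": [("c1", 14)], "s3": [("c1", 25)]}
        for method in ("count-tail", "exact-tail", "product"):
            one = block_pvalue(model, ["s1", "s3"], target, positions, 7,
                               method=method, scope="genome")
            two = block_pvalue(model, ["s1", "s2", "s3"], target, positions, 7,
                               method=method, scope="genome")
            assert two <= one

    def test_chromosome_scope_conditions_on_the_target_chromosome(self):
        genome = Genome.from_chromosomes(
            "v",
            {"c1": [f"a{i}" for i in range(1, 21)],
             "c2": [f"b{i}" for i in range(1, 101)]},
        )
        model = PlacementModel.from_genome(genome)
        target = Span("c1", 8, 12)
        positions = {"s1": [("c1", 10)]}
        conditional = block_pvalue(model, ["s1"], target, positions, 5,
                                   method="exact-tail", scope="target_chromosome")
        unconditional = block_pvalue(model, ["s1"], target, positions, 5,
                                     method="exact-tail", scope="genome")
        # on the small chromosome a hit is much less surprising
        assert conditional > unconditional
        sub = PlacementModel({"c1": 20})
        assert conditional == pytest.approx(gene_pvalue(sub, positions["s1"], 5))


class TestBlockCalibration:
    def test_block_pvalue_is_conservative_under_random_placement(self):
        """Monte-Carlo calibration oracle: when the target window really is
        placed uniformly at random, P(P_block < alpha) <= alpha."""
        rng = np.random.default_rng(2024)
        n, W, n_source, n_iter = 60, 10, 8, 10_000
        model = PlacementModel({"c1": n})
        starts = n - W  # placements start at 1 .. n - W
        pvals = np.empty(n_iter)
        source = [f"s{i}" for i in range(n_source)]
        for it in range(n_iter):
            positions = {
                g: [("c1", int(p) + 1) for p in rng.choice(n, size=2, replace=False)]
                for g in source
            }
            s = int(rng.integers(1, starts + 1))
            target = Span("c1", s, s + W - 1)
            pvals[it] = block_pvalue(
                model, source, target, positions, W,
                method="exact-tail", scope="genome",
            )
        for alpha in (0.05, 0.1, 0.3):
            frac = float(np.mean(pvals < alpha))
            mc_err = 3 * np.sqrt(alpha * (1 - alpha) / n_iter)
            assert frac <= alpha + mc_err, (alpha, frac)


class TestAggregation:
    def test_pair_q_is_the_product_of_the_two_block_pvalues(self):
        assert pair_q_at_W([1.0], [1.0]) == 1.0
        assert pair_q_at_W([0.1], [0.2]) == pytest.approx(0.02)
        assert pair_q_at_W([0.3]) == pytest.approx(0.3)  # self comparison

    def test_best_block_is_used_when_several_anchors_support_a_side(self):
        assert pair_q_at_W([0.5, 0.1, 0.9], [0.4, 0.2]) == pytest.approx(0.02)

    def test_geometric_mean_is_idempotent_on_constant_scores(self):
        W_set = (100, 200, 300, 400, 500)
        assert geometric_mean_over_W({W: 0.01 for W in W_set}, W_set) == (
            pytest.approx(0.01)
        )

    def test_geometric_mean_of_two_scores(self):
        assert geometric_mean_over_W({1: 0.1, 2: 0.001}, (1, 2)) == (
            pytest.approx(0.01)
        )

    def test_missing_window_sizes_imputed_as_one(self):
        q = geometric_mean_over_W({100: 0.01}, (100, 200))
        assert q == pytest.approx(0.1)

    def test_zero_scores_clamped_to_floor_before_averaging(self):
        q = geometric_mean_over_W({1: 0.0}, (1,))
        assert q == pytest.approx(Q_FLOOR)

    @given(
        st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=6),
    )
    @settings(max_examples=100, deadline=None)
    def test_geometric_mean_matches_log_mean_oracle_and_stays_bracketed(self, qs):
        W_set = tuple(range(len(qs)))
        q_by_W = dict(zip(W_set, qs))
        got = geometric_mean_over_W(q_by_W, W_set)
        expected = math.exp(sum(math.log(q) for q in qs) / len(qs))
        assert got == pytest.approx(expected)
        assert min(qs) - 1e-12 <= got <= max(qs) + 1e-12

    def test_combine_outgroups_multiplies(self):
        assert combine_outgroups({"a": 0.05}) == pytest.approx(0.05)
        assert combine_outgroups({"a": 0.1, "b": 0.1}) == pytest.approx(0.01)
        assert combine_outgroups({}) == 1.0

    @given(
        st.dictionaries(
            st.sampled_from(["og1", "og2", "og3", "og4"]),
            st.floats(1e-6, 1.0 - 1e-9),
            min_size=1,
        ),
        st.floats(1e-6, 1.0 - 1e-9),
    )
    @settings(max_examples=100, deadline=None)
    def test_adding_an_informative_outgroup_strictly_decreases_Q(self, qs, extra):
        base = combine_outgroups(qs)
        augmented = combine_outgroups({**qs, "new": extra})
        assert augmented < base
        assert 0.0 <= augmented <= 1.0
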