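"""Placement P-values and layered q-scores for synteny block candidates.

The null model asks: if a window of ``W`` genes were dropped uniformly at
random onto the vertebrate genome, how likely is the homology content we
actually observed?  Three layers build on each other:

1. **per-gene placement P-value** ``P_i`` — the chance that a random
   window placement contains at least one homolog of source gene *i*.
   With ``N - W`` possible placements (summed over chromosomes) of which
   ``n_free`` contain no homolog of *i*, ``P_i = 1 - n_free / (N - W)``.
2. **block P-value** — the chance of the observed number of co-occurring
   source genes.  The default ``count-tail`` method treats the number of
   source-window genes with a homolog inside the target window as a sum of
   independent Bernoulli(P_i) draws and reports the upper tail
   ``P(X >= k_obs)`` of that count (a Poisson tail on ``lambda = sum P_i``;
   an exact Poisson-binomial convolution and the naive product of the
   co-occurring genes' ``P_i`` are available as alternative methods).
3. **q-score** — per window size, the product of the supporting block
   P-values (two blocks for outgroup candidates, one for self candidates);
   then a geometric mean over window sizes; then a product over outgroups,
   assuming independent rearrangement histories in lineages that diverged
   more than 500 MY ago.  Missing evidence always contributes a factor of
   1: absence of evidence is neutral, never favourable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .scan import Span

logger = logging.getLogger(__name__)

#: numeric floor applied before any log-space aggregation
Q_FLOOR = 1e-300

#: default block P-value method (see module docstring)
DEFAULT_BLOCK_METHOD = "count-tail"


@dataclass
class PlacementModel:
    """Window-placement null model of one vertebrate genome.

    A window of ``W`` genes can start at positions ``1 .. n_c - W`` on a
    chromosome of ``n_c`` genes, giving ``N - W`` placements genome-wide
    (summed per chromosome; chromosomes shorter than ``W`` contribute
    none).
    """

    chrom_sizes: dict[str, int]

    @classmethod
    def from_genome(cls, genome) -> "PlacementModel":
        return cls({c: len(g) for c, g in genome.chromosomes.items()})

    def n_placements(self, W: int) -> int:
        return sum(max(n - W, 0) for n in self.chrom_sizes.values())


def count_valid_placements(
    model: PlacementModel, positions: Iterable[tuple[str, int]], W: int
) -> int:
    """Number of W-gene window placements containing none of ``positions``.

    A placement starting at ``s`` covers positions ``s .. s+W-1``; a
    homolog at position ``p`` forbids starts in ``[p-W+1, p]``. Valid
    starts are counted per chromosome after merging forbidden intervals.
    """
    if W < 1:
        raise ValueError("W must be >= 1")
    total = model.n_placements(W)
    if total == 0:
        logger.warning("window size %d exceeds every chromosome", W)
        return 0

    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in positions:
        by_chrom.setdefault(chrom, []).append(pos)

    forbidden = 0
    for chrom, plist in by_chrom.items():
        n = model.chrom_sizes.get(chrom)
        if n is None or n <= W:
            continue
        last_start = n - W
        intervals = sorted((max(1, p - W + 1), min(last_start, p)) for p in plist)
        cur_lo, cur_hi = None, None
        for lo, hi in intervals:
            if hi < lo:
                continue
            if cur_lo is None:
                cur_lo, cur_hi = lo, hi
            elif lo <= cur_hi + 1:
                cur_hi = max(cur_hi, hi)
            else:
                forbidden += cur_hi - cur_lo + 1
                cur_lo, cur_hi = lo, hi
        if cur_lo is not None:
            forbidden += cur_hi - cur_lo + 1
    return total - forbidden


def gene_pvalue(
    model: PlacementModel, positions: Iterable[tuple[str, int]], W: int
) -> float:
    """Chance that a random W-window contains >= 1 of the given homologs.

    ``P_i = 1 - n_free / (N - W)``: 0 for a gene with no homologs in the
    vertebrate genome, 1 when every placement hits one.
    """
    total = model.n_placements(W)
    if total == 0:
        raise ValueError(f"no possible window placements for W={W}; genome too fragmented")
    return 1.0 - count_valid_placements(model, positions, W) / total


# ----------------------------------------------------------------------
def poisson_binomial_sf(k: int, probs: Sequence[float]) -> float:
    """Exact ``P(X >= k)`` for X a sum of independent Bernoulli(p_i).

    Computed by iterated convolution of the count distribution; intended
    for windows of at most a few hundred genes.
    """
    if k <= 0:
        return 1.0
    probs = [p for p in probs if p > 0.0]
    if k > len(probs):
        return 0.0
    dist = np.ones(1)
    for p in probs:
        dist = np.convolve(dist, [1.0 - p, p])
    return float(dist[k:].sum())


def count_tail_pvalue(
    probs: Sequence[float],
    k: int,
    method: str = DEFAULT_BLOCK_METHOD,
    *,
    condition_min: int = 0,
) -> float:
    """Tail probability of observing >= k co-occurrences.

    ``count-tail`` uses a Poisson tail on ``lambda = sum(probs)`` (the
    per-gene hit probabilities are small, so the Poisson law of small
    numbers applies and only the mean of the count matters);
    ``exact-tail`` evaluates the Poisson-binomial sum exactly.

    ``condition_min`` > 0 returns the selection-corrected conditional
    tail ``P(X >= k | X >= condition_min)``: a block that was *selected*
    for having at least ``condition_min`` co-occurrences must not be
    credited for that observation again, so a block at the detection
    threshold carries no evidence (P-value 1).
    """
    if k <= max(condition_min, 0):
        return 1.0
    if method == "count-tail":
        lam = float(sum(probs))
        if lam == 0.0:
            return 0.0 if k > 0 else 1.0
        p = float(sps.poisson.sf(k - 1, lam))
        if condition_min > 0:
            denom = float(sps.poisson.sf(condition_min - 1, lam))
            p = p / denom if denom > 0 else 1.0
        return float(min(1.0, p))
    if method == "exact-tail":
        p = poisson_binomial_sf(k, probs)
        if condition_min > 0:
            denom = poisson_binomial_sf(condition_min, probs)
            p = p / denom if denom > 0 else 1.0
        return float(min(1.0, p))
    raise ValueError(f"unknown count-tail method {method!r}")


def block_pvalue(
    model: PlacementModel,
    source_genes: Iterable[str],
    target_span: Span,
    homolog_positions: Mapping[str, Sequence[tuple[str, int]]],
    W: int,
    *,
    method: str = DEFAULT_BLOCK_METHOD,
    scope: str = "target_chromosome",
    condition_min: int = 0,
    pvalue_cache: dict[tuple[str, str], float] | None = None,
) -> float:
    """P-value of one synteny block under the random-placement null.

    ``source_genes`` are the genes of the source window with the anchor
    already excluded; ``homolog_positions`` maps each source gene to the
    positions of its homologs in the vertebrate (target) genome.

    ``scope`` picks the placement universe.  The default,
    ``"target_chromosome"``, restricts placements (and homolog positions)
    to the chromosome the target window sits on: conditioning on the
    observed chromosome makes the statistic reward *sub-chromosomal*
    window-scale co-occurrence rather than mere same-chromosome
    co-residence, and it is what keeps the block P-value calibrated on
    within-chromosome shuffled genomes — conserved segments tie the
    homologs of neighbouring source genes to one target chromosome, so a
    genome-wide denominator systematically understates their null hit
    rates.  ``"genome"`` uses all placements genome-wide.  Chromosomes
    shorter than ``W`` fall back to the genome-wide universe.

    ``method`` is one of ``"count-tail"`` (default), ``"exact-tail"`` or
    ``"product"`` — the latter multiplies the placement P-values of the
    co-occurring genes only and is anti-conservative when windows contain
    many genes with homologs; it is kept for comparison.
    """
    eff_model = model
    chrom_filter: str | None = None
    if scope == "target_chromosome":
        n_c = model.chrom_sizes.get(target_span.chrom, 0)
        if n_c > W:
            eff_model = PlacementModel({target_span.chrom: n_c})
            chrom_filter = target_span.chrom
    elif scope != "genome":
        raise ValueError(f"unknown placement scope {scope!r}")

    cache_key_chrom = chrom_filter or ""
    probs: list[float] = []
    hit_probs: list[float] = []
    k = 0
    for gene in source_genes:
        positions = homolog_positions.get(gene)
        if not positions:
            continue
        key = (gene, cache_key_chrom)
        if pvalue_cache is not None and key in pvalue_cache:
            p = pvalue_cache[key]
        else:
            if chrom_filter is not None:
                eff_positions = [pos for pos in positions if pos[0] == chrom_filter]
            else:
                eff_positions = list(positions)
            p = gene_pvalue(eff_model, eff_positions, W) if eff_positions else 0.0
            if pvalue_cache is not None:
                pvalue_cache[key] = p
        if p <= 0.0:
            continue
        probs.append(p)
        if any(pos in target_span for pos in positions):
            k += 1
            hit_probs.append(p)
    if method == "product":
        out = 1.0
        for p in hit_probs:
            out *= p
        return min(1.0, max(0.0, out))
    return min(
        1.0,
        max(0.0, count_tail_pvalue(probs, k, method=method,
                                   condition_min=condition_min)),
    )


# ----------------------------------------------------------------------
def pair_q_at_W(
    block_pvalues_1: Sequence[float],
    block_pvalues_2: Sequence[float] | None = None,
) -> float:
    """q-score of an ohnolog pair at one window size.

    Outgroup candidates have two supporting blocks (the outgroup window
    against each of the two vertebrate windows): q is the product of the
    two block P-values, both co-occurrence patterns having to arise by
    chance together.  Self candidates have a single block.  When several
    anchors support the same side, the best (minimum) block P-value is
    used.
    """
    q = min(block_pvalues_1)
    if block_pvalues_2:
        q *= min(block_pvalues_2)
    return min(1.0, max(0.0, q))


def geometric_mean_over_W(
    q_by_W: Mapping[int, float],
    W_set: Iterable[int],
    *,
    floor: float = Q_FLOOR,
) -> float:
    """Geometric mean of per-window-size q-scores over the full W set.

    Window sizes at which the pair was not recovered are imputed as q = 1
    (the pair simply was not seen at that scale); values at or below zero
    are clamped to ``floor`` before log-space averaging.
    """
    W_set = list(W_set)
    if not W_set:
        raise ValueError("W_set must be non-empty")
    logs = []
    for W in W_set:
        q = q_by_W.get(W, 1.0)
        q = max(min(q, 1.0), floor)
        logs.append(math.log(q))
    return math.exp(sum(logs) / len(logs))


def combine_outgroups(q_by_outgroup: Mapping[str, float]) -> float:
    """Product of per-outgroup q-scores.

    Outgroup lineages diverged independently, so the chance of spurious
    synteny in each is independent and the probabilities multiply.
    Outgroups that did not identify the pair contribute a neutral factor
    of 1 (i.e. are simply absent from the mapping).
    """
    q = 1.0
    for value in q_by_outgroup.values():
        q *= max(min(value, 1.0), 0.0)
    return min(1.0, max(0.0, q))


@dataclass
class QScoreRecord:
    """All q-score layers for one ohnolog pair in one species."""

    gene_1: str
    gene_2: str
    q_by_outgroup_and_W: dict[tuple[str, int], float] = field(default_factory=dict)
    q_self_by_W: dict[int, float] = field(default_factory=dict)
    Q_outgr: float = 1.0
    Q_self: float = 1.0

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_1, self.gene_2)

    def finalize(self, W_set: Iterable[int]) -> "QScoreRecord":
        """Aggregate per-(outgroup, W) and per-W scores into Q_outgr / Q_self."""
        W_set = list(W_set)
        per_outgroup: dict[str, dict[int, float]] = {}
        for (og, W), q in self.q_by_outgroup_and_W.items():
            per_outgroup.setdefault(og, {})[W] = q
        q_by_og = {og: geometric_mean_over_W(qs, W_set) for og, qs in per_outgroup.items()}
        self.Q_outgr = combine_outgroups(q_by_og)
        self.Q_self = (
            geometric_mean_over_W(self.q_self_by_W, W_set) if self.q_self_by_W else 1.0
        )
        return self
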