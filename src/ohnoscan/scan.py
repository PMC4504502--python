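"""Window-based detection of synteny anchors and ohnolog pair candidates.

Two detection routes feed the pipeline:

* **outgroup comparison** — for every ortholog pair between an outgroup
  (diverged before the 2R-WGD) and a vertebrate, windows are placed around
  both genes and the pair becomes an *anchor* when the windows share enough
  additional ortholog pairs.  An outgroup gene anchored to two distinct
  vertebrate genes exhibits the 1-to-2 synteny pattern that is the
  signature of a duplication on the vertebrate branch, and every such pair
  of vertebrate genes becomes an ohnolog candidate.
* **self comparison** — for every within-vertebrate paralog pair, windows
  are placed around both genes and the pair becomes a candidate when the
  windows share enough additional paralog pairs (degenerate sister regions
  left by the WGD inside the same genome).

Detection is deliberately permissive (``min_support`` defaults to 1);
pruning is the job of the statistics module downstream.  Windows are pure
gene-content sets: order within a window never matters.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .genome import Genome, HomologyMap, WindowSpec, canonical_pair

#: chunk size for the pairwise support-count matrices (bounds memory)
_CHUNK = 512


@dataclass(frozen=True)
class Span:
    """A contiguous, 1-based closed run of positions on one chromosome."""

    chrom: str
    lo: int
    hi: int

    def __contains__(self, item: tuple[str, int]) -> bool:
        chrom, pos = item
        return chrom == self.chrom and self.lo <= pos <= self.hi

    def overlaps(self, other: "Span") -> bool:
        return self.chrom == other.chrom and self.lo <= other.hi and other.lo <= self.hi


def window_span(genome: Genome, gene: str, spec: WindowSpec) -> Span:
    """Span of the window centred on ``gene``: ±``W//2``, truncated at ends."""
    chrom, pos = genome.position_of(gene)
    n = genome.chromosome_length(chrom)
    return Span(chrom, max(1, pos - spec.half), min(n, pos + spec.half))


def make_window(genome: Genome, gene: str, spec: WindowSpec) -> frozenset[str]:
    """Gene-id set of the window centred on ``gene``.

    The window holds the anchor plus up to ``W`` neighbours (``W//2`` per
    side) and shrinks near chromosome ends rather than wrapping around.
    """
    span = window_span(genome, gene, spec)
    return frozenset(genome.genes_in_span(span.chrom, span.lo, span.hi))


@dataclass(frozen=True)
class Anchor:
    """An ortholog pair whose surrounding windows share gene content.

    ``support_count`` is the number of *additional* homologous gene pairs
    between the two windows, the anchor pair itself excluded.  Window gene
    sets can be materialised from the spans via ``Genome.genes_in_span``.
    """

    outgroup_gene: str
    vertebrate_gene: str
    outgroup_span: Span
    vertebrate_span: Span
    support_count: int

    def outgroup_window(self, outgroup: Genome) -> frozenset[str]:
        s = self.outgroup_span
        return frozenset(outgroup.genes_in_span(s.chrom, s.lo, s.hi))

    def vertebrate_window(self, vertebrate: Genome) -> frozenset[str]:
        s = self.vertebrate_span
        return frozenset(vertebrate.genes_in_span(s.chrom, s.lo, s.hi))


@dataclass(frozen=True)
class SupportBlock:
    """One window pair supporting a candidate.

    ``source_span`` lives in the source genome (the outgroup for outgroup
    candidates, the vertebrate itself for self candidates); ``target_span``
    always lives in the vertebrate genome being scanned.
    """

    source_span: Span
    target_span: Span
    anchor_source_gene: str
    anchor_target_gene: str
    support: int = 0


@dataclass(frozen=True)
class OhnologCandidate:
    """A putative ohnolog pair with the window evidence that produced it."""

    gene_1: str
    gene_2: str
    source: str  # "self" or "outgroup:<genome_id>"
    window_size: int
    blocks: tuple[SupportBlock, ...]

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_1, self.gene_2)


# ----------------------------------------------------------------------
def _oriented_pairs(
    orthologs: HomologyMap, outgroup: Genome, vertebrate: Genome
) -> list[tuple[str, str]]:
    """Ortholog pairs as (outgroup_gene, vertebrate_gene), skipping genes
    absent from either genome (e.g. dropped scaffolds)."""
    if orthologs.genome_a == outgroup.genome_id:
        pairs = orthologs.pairs
    elif orthologs.genome_b == outgroup.genome_id:
        pairs = {(b, a) for a, b in orthologs.pairs}
    else:
        raise ValueError(
            f"ortholog map {orthologs.genome_a}->{orthologs.genome_b} does not "
            f"involve outgroup {outgroup.genome_id}"
        )
    return [
        (o, v)
        for o, v in pairs
        if o in outgroup.gene_index and v in vertebrate.gene_index
    ]


def _pairwise_support(
    apos: np.ndarray, bpos: np.ndarray, half: int
) -> np.ndarray:
    """For each pair i, count pairs j with both coordinates within ``half``.

    The count includes i itself; callers subtract the anchor. Chunked so the
    boolean matrices stay small.
    """
    n = len(apos)
    out = np.empty(n, dtype=np.int64)
    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        near_a = np.abs(apos[start:stop, None] - apos[None, :]) <= half
        near_b = np.abs(bpos[start:stop, None] - bpos[None, :]) <= half
        out[start:stop] = (near_a & near_b).sum(axis=1)
    return out


def find_anchors(
    vertebrate: Genome,
    outgroup: Genome,
    orthologs: HomologyMap,
    spec: WindowSpec,
    min_support: int = 1,
) -> list[Anchor]:
    """Identify synteny anchors between an outgroup and a vertebrate genome.

    One anchor is emitted per ortholog pair whose windows share at least
    ``min_support`` additional ortholog pairs. Because windows are
    contiguous position intervals, a pair (o', v') supports the anchor
    (o, v) exactly when both genes fall within ``W//2`` positions of the
    respective anchor genes on the same chromosomes, which is what the
    vectorised count below evaluates; end-of-chromosome truncation is
    automatic since out-of-range positions do not exist.
    """
    pairs = _oriented_pairs(orthologs, outgroup, vertebrate)
    groups: dict[tuple[str, str], list[tuple[int, int, str, str]]] = defaultdict(list)
    for o, v in pairs:
        ochrom, opos = outgroup.gene_index[o]
        vchrom, vpos = vertebrate.gene_index[v]
        groups[(ochrom, vchrom)].append((opos, vpos, o, v))

    anchors: list[Anchor] = []
    for (ochrom, vchrom), rows in groups.items():
        rows.sort()
        opos = np.array([r[0] for r in rows], dtype=np.int64)
        vpos = np.array([r[1] for r in rows], dtype=np.int64)
        support = _pairwise_support(opos, vpos, spec.half) - 1
        on = outgroup.chromosome_length(ochrom)
        vn = vertebrate.chromosome_length(vchrom)
        for (op, vp, o, v), s in zip(rows, support):
            if s >= min_support:
                anchors.append(
                    Anchor(
                        outgroup_gene=o,
                        vertebrate_gene=v,
                        outgroup_span=Span(ochrom, max(1, op - spec.half), min(on, op + spec.half)),
                        vertebrate_span=Span(vchrom, max(1, vp - spec.half), min(vn, vp + spec.half)),
                        support_count=int(s),
                    )
                )
    anchors.sort(key=lambda a: (a.outgroup_gene, a.vertebrate_gene))
    return anchors


def candidates_from_outgroup(
    anchors: list[Anchor], outgroup_id: str, window_size: int
) -> list[OhnologCandidate]:
    """Turn anchors sharing an outgroup gene into ohnolog pair candidates.

    Every outgroup gene anchored to two or more distinct vertebrate genes
    yields all unordered vertebrate pairs among them (1-to-2 — or 1-to-k —
    synteny pattern); each candidate carries the two supporting anchors.
    """
    by_outgroup: dict[str, list[Anchor]] = defaultdict(list)
    for anchor in anchors:
        by_outgroup[anchor.outgroup_gene].append(anchor)

    candidates: list[OhnologCandidate] = []
    for og_gene in sorted(by_outgroup):
        group = sorted(by_outgroup[og_gene], key=lambda a: a.vertebrate_gene)
        if len(group) < 2:
            continue
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a_i, a_j = group[i], group[j]
                if a_i.vertebrate_gene == a_j.vertebrate_gene:
                    continue
                g1, g2 = canonical_pair(a_i.vertebrate_gene, a_j.vertebrate_gene)
                first, second = (a_i, a_j) if a_i.vertebrate_gene == g1 else (a_j, a_i)
                candidates.append(
                    OhnologCandidate(
                        gene_1=g1,
                        gene_2=g2,
                        source=f"outgroup:{outgroup_id}",
                        window_size=window_size,
                        blocks=(
                            SupportBlock(first.outgroup_span, first.vertebrate_span,
                                         og_gene, first.vertebrate_gene,
                                         first.support_count),
                            SupportBlock(second.outgroup_span, second.vertebrate_span,
                                         og_gene, second.vertebrate_gene,
                                         second.support_count),
                        ),
                    )
                )
    return candidates


def candidates_from_self(
    vertebrate: Genome,
    paralogs: HomologyMap,
    spec: WindowSpec,
    min_support: int = 1,
) -> list[OhnologCandidate]:
    """Detect ohnolog candidates by comparing a vertebrate genome to itself.

    For each paralog pair, windows are placed around both genes; the pair
    is emitted when the windows share at least ``min_support`` additional
    paralog pairs.  Window pairs whose spans overlap on the same
    chromosome (e.g. tandem duplicates) are skipped — overlapping windows
    trivially share content and say nothing about duplicated regions.
    """
    # directed copies of every pair, grouped by (chrom_first, chrom_second)
    groups: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    directed: list[tuple[str, str]] = []
    for a, b in paralogs.pairs:
        if a not in vertebrate.gene_index or b not in vertebrate.gene_index:
            continue
        for x, y in ((a, b), (b, a)):
            cx, px = vertebrate.gene_index[x]
            cy, py = vertebrate.gene_index[y]
            groups[(cx, cy)].append((px, py))
            directed.append((x, y))

    pos_arrays = {
        key: (
            np.array([p for p, _ in rows], dtype=np.int64),
            np.array([q for _, q in rows], dtype=np.int64),
        )
        for key, rows in groups.items()
    }

    candidates: list[OhnologCandidate] = []
    for a, b in sorted(paralogs.pairs):
        if a not in vertebrate.gene_index or b not in vertebrate.gene_index:
            continue
        span_a = window_span(vertebrate, a, spec)
        span_b = window_span(vertebrate, b, spec)
        if span_a.overlaps(span_b):
            continue
        ca, pa = vertebrate.gene_index[a]
        cb, pb = vertebrate.gene_index[b]
        xs, ys = pos_arrays[(ca, cb)]
        in_win = (np.abs(xs - pa) <= spec.half) & (np.abs(ys - pb) <= spec.half)
        support = int(in_win.sum()) - 1  # the anchor pair itself always matches
        if support >= min_support:
            candidates.append(
                OhnologCandidate(
                    gene_1=a,
                    gene_2=b,
                    source="self",
                    window_size=spec.W,
                    blocks=(SupportBlock(span_a, span_b, a, b, support),),
                )
            )
    return candidates


def write_candidates_tsv(candidates: list[OhnologCandidate], path) -> None:
    """Dump candidates as ``gene_1 gene_2 source window_size support_1 support_2``."""
    with open(path, "w") as fh:
        fh.write("gene_1\tgene_2\tsource\twindow_size\tsupport_1\tsupport_2\n")
        for c in candidates:
            s2 = c.blocks[1].support if len(c.blocks) > 1 else ""
            fh.write(
                f"{c.gene_1}\t{c.gene_2}\t{c.source}\t{c.window_size}"
                f"\t{c.blocks[0].support}\t{s2}\n"
            )
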