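"""Gene-order and homology tables, and the domain types shared by all modules.

A :class:`Genome` is nothing more than an ordered list of gene identifiers
per chromosome: the method is content-based, so strand and physical
coordinates are irrelevant and only the ordinal rank of each gene matters.
A :class:`HomologyMap` is a many-to-many set of gene-id pairs, either
orthologs between two genomes or paralogs within one genome; paralog pairs
carry the taxonomic node at which the duplication occurred (Ensembl-Compara
style), which downstream modules use to restrict candidates to the
2R-WGD epoch.

File formats are deliberately plain:

* gene order TSV: ``gene_id  chromosome  position`` (a GFF3 import path
  ordering ``gene`` features by start is also provided);
* homology TSV: ``gene_a  gene_b  [duplication_node]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Window sizes (in genes) used by default on real, full-size genomes.
DEFAULT_WINDOW_SIZES: tuple[int, ...] = (100, 200, 300, 400, 500)

#: Chromosomes/scaffolds with fewer genes than this are dropped on import.
DEFAULT_MIN_GENES_PER_CHROMOSOME = 10


@dataclass(frozen=True)
class WindowSpec:
    """A window size for content-based synteny comparison.

    A window around an anchor gene contains the anchor plus up to ``W``
    neighbours, ``W // 2`` on each side, truncated at chromosome ends.
    """

    W: int

    def __post_init__(self) -> None:
        if self.W < 2:
            raise ValueError(f"window size must be >= 2, got {self.W}")

    @property
    def half(self) -> int:
        return self.W // 2


@dataclass
class Genome:
    """Ordered protein-coding genes on chromosomes.

    ``chromosomes`` maps chromosome id to the ordered list of gene ids;
    ``gene_index`` maps every gene id to its ``(chromosome, position)``
    with 1-based, dense positions.
    """

    genome_id: str
    chromosomes: dict[str, list[str]]
    gene_index: dict[str, tuple[str, int]] = field(repr=False)

    # ------------------------------------------------------------------
    @classmethod
    def from_chromosomes(
        cls, genome_id: str, chromosomes: Mapping[str, Iterable[str]]
    ) -> "Genome":
        """Build a genome, validating genome-wide gene-id uniqueness."""
        chroms = {str(c): [str(g) for g in genes] for c, genes in chromosomes.items()}
        index: dict[str, tuple[str, int]] = {}
        for chrom, genes in chroms.items():
            for pos, gene in enumerate(genes, start=1):
                if gene in index:
                    raise ValueError(f"duplicate gene id {gene!r} in genome {genome_id!r}")
                index[gene] = (chrom, pos)
        return cls(genome_id=genome_id, chromosomes=chroms, gene_index=index)

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_index)

    def chromosome_length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    def position_of(self, gene: str) -> tuple[str, int]:
        try:
            return self.gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in genome {self.genome_id!r}") from None

    def genes_in_span(self, chrom: str, lo: int, hi: int) -> list[str]:
        """Genes at positions ``lo..hi`` (1-based, closed) on ``chrom``."""
        return self.chromosomes[chrom][max(lo, 1) - 1 : hi]

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            (gene, chrom, pos)
            for chrom, genes in self.chromosomes.items()
            for pos, gene in enumerate(genes, start=1)
        ]
        return pd.DataFrame(rows, columns=["gene_id", "chromosome", "position"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self.genome_id == other.genome_id and self.chromosomes == other.chromosomes


def read_gene_order(
    path: str | Path,
    genome_id: str,
    *,
    min_genes: int = DEFAULT_MIN_GENES_PER_CHROMOSOME,
) -> Genome:
    """Read a gene-order TSV into a :class:`Genome`.

    Positions are renumbered to dense 1..n per chromosome following the
    input position order. Chromosomes with fewer than ``min_genes`` genes
    are dropped with a logged warning (fragmented scaffolds carry too
    little synteny signal to place windows on).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"gene_id", "chromosome", "position"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")

    positions = pd.to_numeric(df["position"], errors="coerce")
    bad = positions.isna() | ((positions % 1) != 0)
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: non-integer position on line {line}")
    df = df.assign(position=positions.astype(int))

    dup = df["gene_id"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate gene id {df.loc[dup.idxmax(), 'gene_id']!r}")

    chroms: dict[str, list[str]] = {}
    for chrom, sub in df.groupby("chromosome", sort=True):
        genes = list(sub.sort_values("position", kind="stable")["gene_id"])
        if len(genes) < min_genes:
            logger.warning(
                "%s: dropping chromosome %s with %d < %d genes",
                genome_id, chrom, len(genes), min_genes,
            )
            continue
        chroms[str(chrom)] = genes
    return Genome.from_chromosomes(genome_id, chroms)


def read_gene_order_gff3(
    path: str | Path,
    genome_id: str,
    *,
    min_genes: int = DEFAULT_MIN_GENES_PER_CHROMOSOME,
    feature_type: str = "gene",
) -> Genome:
    """Import gene order from a GFF3 file, ordering ``gene`` features by start."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    chroms: dict[str, list[tuple[int, str]]] = {}
    for feat in db.features_of_type(feature_type):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        chroms.setdefault(feat.seqid, []).append((feat.start, gene_id))
    ordered: dict[str, list[str]] = {}
    for chrom in sorted(chroms):
        genes = [g for _, g in sorted(chroms[chrom])]
        if len(genes) < min_genes:
            logger.warning(
                "%s: dropping scaffold %s with %d < %d genes",
                genome_id, chrom, len(genes), min_genes,
            )
            continue
        ordered[chrom] = genes
    return Genome.from_chromosomes(genome_id, ordered)


# ----------------------------------------------------------------------
def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Lexicographically ordered gene pair, so (a, b) == (b, a)."""
    return (a, b) if a <= b else (b, a)


@dataclass
class HomologyMap:
    """Many-to-many homology relations between (or within) genomes.

    Ortholog maps are directed ``genome_a -> genome_b``; paralog maps have
    ``genome_a == genome_b`` and store pairs in canonical (lexicographic)
    order so that (a, b) and (b, a) denote the same pair. Every paralog
    pair carries the duplication node at which the pair arose.
    """

    kind: str  # "ortholog" | "paralog"
    genome_a: str
    genome_b: str
    pairs: set[tuple[str, str]] = field(default_factory=set)
    duplication_node: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("ortholog", "paralog"):
            raise ValueError(f"kind must be 'ortholog' or 'paralog', got {self.kind!r}")
        if self.kind == "paralog":
            if self.genome_a != self.genome_b:
                raise ValueError("paralog map must stay within one genome")
            self.pairs = {canonical_pair(*p) for p in self.pairs}
            self.duplication_node = {
                canonical_pair(*p): n for p, n in self.duplication_node.items()
            }
            missing = self.pairs - set(self.duplication_node)
            if missing:
                raise ValueError(
                    f"paralog map missing duplication node for {len(missing)} pair(s)"
                )

    # ------------------------------------------------------------------
    def add(self, a: str, b: str, node: str | None = None) -> None:
        if self.kind == "paralog":
            pair = canonical_pair(a, b)
            if node is None:
                raise ValueError("paralog pairs require a duplication node")
            self.duplication_node[pair] = node
        else:
            pair = (a, b)
        self.pairs.add(pair)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        if self.kind == "paralog":
            return canonical_pair(*pair) in self.pairs
        return pair in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def partners_of_a(self) -> dict[str, set[str]]:
        """Adjacency from genome_a genes (paralogs: both directions)."""
        adj: dict[str, set[str]] = {}
        for a, b in self.pairs:
            adj.setdefault(a, set()).add(b)
            if self.kind == "paralog":
                adj.setdefault(b, set()).add(a)
        return adj

    def partners_of_b(self) -> dict[str, set[str]]:
        if self.kind == "paralog":
            return self.partners_of_a()
        adj: dict[str, set[str]] = {}
        for a, b in self.pairs:
            adj.setdefault(b, set()).add(a)
        return adj

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.pairs)
        if self.kind == "paralog":
            return pd.DataFrame(
                [(a, b, self.duplication_node[(a, b)]) for a, b in rows],
                columns=["gene_a", "gene_b", "duplication_node"],
            )
        return pd.DataFrame(rows, columns=["gene_a", "gene_b"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_homology(
    path: str | Path,
    kind: str,
    *,
    genome_a: str = "",
    genome_b: str = "",
    genomes: Iterable[Genome] | None = None,
    on_unknown_gene: str = "drop",
) -> HomologyMap:
    """Read a homology TSV into a :class:`HomologyMap`.

    When ``genomes`` is provided, pairs mentioning genes absent from those
    genomes are handled per ``on_unknown_gene``: ``"drop"`` (default,
    counted in the log) or ``"error"``.
    """
    if kind == "paralog" and not genome_b:
        genome_b = genome_a
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return HomologyMap(kind=kind, genome_a=genome_a, genome_b=genome_b)
    for col in ("gene_a", "gene_b"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if kind == "paralog" and "duplication_node" not in df.columns:
        raise ValueError(f"{path}: paralog table requires a duplication_node column")

    known: set[str] | None = None
    if genomes is not None:
        known = set()
        for g in genomes:
            known |= set(g.gene_index)

    hmap = HomologyMap(kind=kind, genome_a=genome_a, genome_b=genome_b)
    dropped = 0
    for row in df.itertuples(index=False):
        a, b = str(row.gene_a), str(row.gene_b)
        if known is not None and (a not in known or b not in known):
            if on_unknown_gene == "error":
                raise ValueError(f"{path}: unknown gene in pair ({a}, {b})")
            dropped += 1
            continue
        hmap.add(a, b, getattr(row, "duplication_node", None))
    if dropped:
        logger.info("%s: dropped %d pair(s) with genes absent from genomes", path, dropped)
    return hmap
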