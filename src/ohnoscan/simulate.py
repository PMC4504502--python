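"""Synthetic paleopolyploid and outgroup genomes with known ground truth.

The generator embodies the standard evolutionary scenario behind 2R
ohnolog detection: an ancestral genome duplicates wholesale (twice by
default) on the stem lineage of the vertebrates, most duplicates are
subsequently lost (non-functionalization), and every descendant lineage —
vertebrate and outgroup alike — independently scrambles its gene order
through inversions and translocations.  Outgroup lineages diverge before
the WGD and additionally lose genes outright.  Small-scale duplications
insert adjacent gene copies with a timing label relative to the WGD.

Because the WGD happens once, on the shared stem, the simulated
vertebrates carry identical ohnolog content (1-to-1 orthology between
their copies) and differ only by lineage-specific rearrangements and
small-scale duplicates — which is exactly what the multi-species
consensus machinery is meant to exploit.

All four homology table kinds plus truth tables are emitted in the
package's TSV formats, fully reproducibly per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .genome import Genome, HomologyMap, canonical_pair

#: duplication-node labels written by the simulator
NODE_WGD = "WGD"
NODE_PRE = "preWGD"
NODE_POST = "postWGD"

#: window sizes used when running the pipeline on desk-scale simulations —
#: the real-data 100..500 range scaled to the ~5,000-gene simulated genomes
#: so that the expected number of chance homolog pairs per window pair
#: stays below ~1 over most of the set, as it must for the q-score
#: aggregation to retain discriminative power
DESK_SCALE_W_SET: tuple[int, ...] = (20, 40, 60, 80, 100)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulation.

    Defaults are desk-scale: a 3,000-gene ancestor on 5 chromosomes,
    two rounds of WGD with 30% duplicate retention per round, two
    invertebrate-like outgroups and three vertebrate lineages; rates are
    expected event counts per lineage, segment lengths are geometric.
    """

    n_genes: int = 3000
    n_chromosomes: int = 5
    wgd_rounds: int = 2
    retention: float = 0.3
    inversion_rate: float = 40.0
    translocation_rate: float = 40.0
    segment_mean: float = 8.0
    #: outgroup branches are several-fold longer than the time separating
    #: the vertebrate lineages from each other, and extant invertebrate
    #: outgroups are mutually scrambled — their rates are set separately
    outgroup_inversion_rate: float = 200.0
    outgroup_translocation_rate: float = 200.0
    loss_rate_outgroup: float = 0.5
    ssd_rate: float = 0.05
    ssd_recent_fraction: float = 0.7
    ancient_paralog_rate: float = 0.02
    n_outgroups: int = 2
    n_vertebrates: int = 3
    seed: int = 0
    outgroup_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("retention", "loss_rate_outgroup", "ssd_rate",
                     "ssd_recent_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_genes < self.n_chromosomes or self.n_chromosomes < 1:
            raise ValueError("need n_genes >= n_chromosomes >= 1")

    @property
    def expected_copies(self) -> float:
        """Branching-process expectation of copies per ancestral gene."""
        return (1.0 + self.retention) ** self.wgd_rounds


# A stem/lineage gene is a token (ancestral index, copy index, ssd index);
# ssd == 0 marks the original of its copy.
Token = tuple[int, int, int]


def _gene_name(prefix: str, token: Token) -> str:
    anc, copy, ssd = token
    name = f"{prefix}_g{anc:05d}c{copy}"
    return f"{name}s{ssd}" if ssd else name


@dataclass
class TruthTables:
    """Ground truth emitted alongside the simulated tables.

    ``true_pairs`` holds, per vertebrate, every ohnolog pair (genes of the
    same ancestral family in different WGD copies — small-scale duplicates
    inherit their template's copy); ``true_families`` holds the family
    partition as tuples of ohnolog groups.  No family can exceed
    ``2 ** wgd_rounds`` groups by construction.
    """

    true_pairs: dict[str, frozenset[tuple[str, str]]] = field(default_factory=dict)
    true_families: dict[str, tuple[tuple[tuple[str, ...], ...], ...]] = field(
        default_factory=dict
    )


@dataclass
class SimResult:
    config: SimConfig
    vertebrates: dict[str, Genome]
    outgroups: dict[str, Genome]
    paralogs: dict[str, HomologyMap]
    orthologs: dict[tuple[str, str], HomologyMap]  # (vertebrate, outgroup)
    cross_orthologs: dict[tuple[str, str], HomologyMap]  # (vert, vert)
    truth: TruthTables

    def write_tables(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, genome in {**self.vertebrates, **self.outgroups}.items():
            genome.write_tsv(outdir / f"genome_{name}.tsv")
        for sp, pmap in self.paralogs.items():
            pmap.write_tsv(outdir / f"paralogs_{sp}.tsv")
        for (sp, og), omap in self.orthologs.items():
            omap.write_tsv(outdir / f"orthologs_{sp}_{og}.tsv")
        for (s1, s2), omap in self.cross_orthologs.items():
            omap.write_tsv(outdir / f"orthologs_{s1}_{s2}.tsv")
        with open(outdir / "truth_pairs.tsv", "w") as fh:
            fh.write("species\tgene_1\tgene_2\n")
            for sp in sorted(self.truth.true_pairs):
                for a, b in sorted(self.truth.true_pairs[sp]):
                    fh.write(f"{sp}\t{a}\t{b}\n")
        with open(outdir / "truth_families.tsv", "w") as fh:
            fh.write("species\tfamily\tgroups\n")
            for sp in sorted(self.truth.true_families):
                for i, fam in enumerate(self.truth.true_families[sp], start=1):
                    groups = ";".join(",".join(g) for g in fam)
                    fh.write(f"{sp}\tF{i:05d}\t{groups}\n")


# ----------------------------------------------------------------------
def _segment_length(rng: np.random.Generator, mean: float, cap: int) -> int:
    return int(min(rng.geometric(1.0 / max(mean, 1.0)), cap))


def _rearrange(
    chroms: dict[str, list[Token]],
    rng: np.random.Generator,
    inversion_rate: float,
    translocation_rate: float,
    segment_mean: float,
) -> None:
    """Apply Poisson numbers of inversions and translocations in place."""
    ids = sorted(chroms)

    def pick_chrom() -> str:
        weights = np.array([len(chroms[c]) for c in ids], dtype=float)
        return ids[rng.choice(len(ids), p=weights / weights.sum())]

    for _ in range(rng.poisson(inversion_rate)):
        c = pick_chrom()
        genes = chroms[c]
        if len(genes) < 2:
            continue
        start = int(rng.integers(0, len(genes)))
        length = _segment_length(rng, segment_mean, len(genes) - start)
        genes[start : start + length] = reversed(genes[start : start + length])

    for _ in range(rng.poisson(translocation_rate)):
        src = pick_chrom()
        genes = chroms[src]
        if len(genes) < 2:
            continue
        start = int(rng.integers(0, len(genes)))
        length = _segment_length(rng, segment_mean, min(len(genes) - start, len(genes) - 1))
        segment = genes[start : start + length]
        del genes[start : start + length]
        dst = pick_chrom()
        at = int(rng.integers(0, len(chroms[dst]) + 1))
        chroms[dst][at:at] = segment


def _stem_after_wgd(config: SimConfig, rng: np.random.Generator) -> dict[str, list[Token]]:
    """Ancestor -> post-WGD stem genome (duplication + retention + SSDs)."""
    per_chrom = np.array_split(np.arange(config.n_genes), config.n_chromosomes)
    chroms: dict[str, list[Token]] = {
        f"chr{i + 1}": [(int(g), 0, 0) for g in idx] for i, idx in enumerate(per_chrom)
    }
    next_copy = config.n_genes * [1]

    for rnd in range(1, config.wgd_rounds + 1):
        new_chroms: dict[str, list[Token]] = {}
        for chrom, genes in chroms.items():
            kept: list[Token] = []
            for anc, copy, ssd in genes:
                if rng.random() < config.retention:
                    kept.append((anc, next_copy[anc], ssd))
                    next_copy[anc] += 1
            if kept:
                new_chroms[f"{chrom}_w{rnd}"] = kept
        chroms.update(new_chroms)
    return chroms


def _apply_ssd(
    chroms: dict[str, list[Token]], config: SimConfig, rng: np.random.Generator
) -> dict[Token, str]:
    """Insert adjacent small-scale duplicates; returns copy -> timing node."""
    ssd_nodes: dict[Token, str] = {}
    for chrom in sorted(chroms):
        genes = chroms[chrom]
        out: list[Token] = []
        ssd_count: dict[tuple[int, int], int] = {}
        for token in genes:
            out.append(token)
            if rng.random() < config.ssd_rate:
                anc, copy, _ = token
                idx = ssd_count.get((anc, copy), 0) + 1
                ssd_count[(anc, copy)] = idx
                dup = (anc, copy, idx)
                out.append(dup)
                recent = rng.random() < config.ssd_recent_fraction
                ssd_nodes[dup] = NODE_POST if recent else NODE_PRE
        chroms[chrom] = out
    return ssd_nodes


def simulate(config: SimConfig) -> SimResult:
    """Run one simulation; deterministic for a fixed config.

    The vertebrate side (WGD outcome, retention, SSDs, per-lineage
    rearrangements, truth tables) depends only on ``config.seed``; the
    outgroup lineages draw from ``config.outgroup_seed`` when given, so
    outgroup history can be resampled without touching vertebrate truth.
    """
    master = np.random.SeedSequence(config.seed)
    stem_ss, vert_ss, og_default_ss, misc_ss = master.spawn(4)
    og_master = (
        np.random.SeedSequence(config.outgroup_seed)
        if config.outgroup_seed is not None
        else og_default_ss
    )

    stem_rng = np.random.default_rng(stem_ss)
    stem = _stem_after_wgd(config, stem_rng)
    ssd_nodes = _apply_ssd(stem, config, stem_rng)

    # --- vertebrate lineages ------------------------------------------------
    vertebrates: dict[str, Genome] = {}
    sp_names = [f"vert{i + 1}" for i in range(config.n_vertebrates)]
    for sp, child in zip(sp_names, vert_ss.spawn(config.n_vertebrates)):
        rng = np.random.default_rng(child)
        chroms = {c: list(genes) for c, genes in stem.items()}
        _rearrange(chroms, rng, config.inversion_rate,
                   config.translocation_rate, config.segment_mean)
        vertebrates[sp] = Genome.from_chromosomes(
            sp, {c: [_gene_name(sp, t) for t in g] for c, g in sorted(chroms.items())}
        )

    # --- outgroup lineages --------------------------------------------------
    outgroups: dict[str, Genome] = {}
    og_names = [f"outg{i + 1}" for i in range(config.n_outgroups)]
    og_survivors: dict[str, list[int]] = {}
    per_chrom = np.array_split(np.arange(config.n_genes), config.n_chromosomes)
    for og, child in zip(og_names, og_master.spawn(max(config.n_outgroups, 1))):
        rng = np.random.default_rng(child)
        chroms = {
            f"chr{i + 1}": [
                (int(g), 0, 0) for g in idx if rng.random() >= config.loss_rate_outgroup
            ]
            for i, idx in enumerate(per_chrom)
        }
        _rearrange(chroms, rng, config.outgroup_inversion_rate,
                   config.outgroup_translocation_rate, config.segment_mean)
        og_survivors[og] = sorted(t[0] for g in chroms.values() for t in g)
        outgroups[og] = Genome.from_chromosomes(
            og, {c: [f"{og}_g{t[0]:05d}" for t in g] for c, g in sorted(chroms.items())}
        )

    # --- homology tables and truth ------------------------------------------
    by_anc: dict[int, list[Token]] = {}
    for genes in stem.values():
        for token in genes:
            by_anc.setdefault(token[0], []).append(token)
    for tokens in by_anc.values():
        tokens.sort()

    misc_rng = np.random.default_rng(misc_ss)
    n_ancient = misc_rng.poisson(config.ancient_paralog_rate * config.n_genes)
    ancient_pairs: list[tuple[Token, Token]] = []
    anc_ids = sorted(by_anc)
    for _ in range(n_ancient):
        a, b = misc_rng.choice(len(anc_ids), size=2, replace=False)
        ta = by_anc[anc_ids[a]][int(misc_rng.integers(len(by_anc[anc_ids[a]])))]
        tb = by_anc[anc_ids[b]][int(misc_rng.integers(len(by_anc[anc_ids[b]])))]
        ancient_pairs.append((ta, tb))

    paralogs: dict[str, HomologyMap] = {}
    truth = TruthTables()
    for sp in sp_names:
        pmap = HomologyMap(kind="paralog", genome_a=sp, genome_b=sp)
        true_pairs: set[tuple[str, str]] = set()
        families: list[tuple[tuple[str, ...], ...]] = []
        for anc in anc_ids:
            tokens = by_anc[anc]
            groups: dict[int, list[str]] = {}
            for token in tokens:
                groups.setdefault(token[1], []).append(_gene_name(sp, token))
            for t1, t2 in combinations(tokens, 2):
                g1, g2 = _gene_name(sp, t1), _gene_name(sp, t2)
                if t1[1] != t2[1]:
                    pmap.add(g1, g2, NODE_WGD)
                    true_pairs.add(canonical_pair(g1, g2))
                else:
                    node = ssd_nodes.get(t2 if t2[2] else t1, NODE_POST)
                    pmap.add(g1, g2, node)
            if len(groups) >= 2:
                families.append(
                    tuple(tuple(sorted(g)) for _, g in sorted(groups.items()))
                )
        for ta, tb in ancient_pairs:
            pmap.add(_gene_name(sp, ta), _gene_name(sp, tb), NODE_PRE)
        paralogs[sp] = pmap
        truth.true_pairs[sp] = frozenset(true_pairs)
        truth.true_families[sp] = tuple(families)

    orthologs: dict[tuple[str, str], HomologyMap] = {}
    for sp in sp_names:
        for og in og_names:
            omap = HomologyMap(kind="ortholog", genome_a=sp, genome_b=og)
            survivors = set(og_survivors[og])
            for anc in anc_ids:
                if anc not in survivors:
                    continue
                og_gene = f"{og}_g{anc:05d}"
                for token in by_anc[anc]:
                    omap.add(_gene_name(sp, token), og_gene)
            orthologs[(sp, og)] = omap

    cross: dict[tuple[str, str], HomologyMap] = {}
    for s1, s2 in combinations(sp_names, 2):
        omap = HomologyMap(kind="ortholog", genome_a=s1, genome_b=s2)
        for anc in anc_ids:
            for token in by_anc[anc]:
                omap.add(_gene_name(s1, token), _gene_name(s2, token))
        cross[(s1, s2)] = omap

    return SimResult(
        config=config,
        vertebrates=vertebrates,
        outgroups=outgroups,
        paralogs=paralogs,
        orthologs=orthologs,
        cross_orthologs=cross,
        truth=truth,
    )


# ----------------------------------------------------------------------
def evaluate_recovery(
    true_pairs: frozenset[tuple[str, str]] | set[tuple[str, str]],
    predicted_by_tier: dict[str, set[tuple[str, str]]],
) -> dict[str, dict[str, float | int | None]]:
    """Precision and recall of predicted pair sets against ground truth."""
    out: dict[str, dict[str, float | int | None]] = {}
    truth = {canonical_pair(*p) for p in true_pairs}
    for tier, predicted in predicted_by_tier.items():
        pred = {canonical_pair(*p) for p in predicted}
        tp = len(pred & truth)
        out[tier] = {
            "n_predicted": len(pred),
            "n_true": len(truth),
            "precision": (tp / len(pred)) if pred else None,
            "recall": (tp / len(truth)) if truth else None,
        }
    return out
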