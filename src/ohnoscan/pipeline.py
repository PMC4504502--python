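"""End-to-end orchestration: detect, filter, score, integrate, classify.

The flow for each vertebrate genome, per window size, is: outgroup-window
anchor detection and self-comparison; restriction of candidate pairs to
WGD-epoch paralogs; block P-values and per-pair q-scores; geometric
averaging over window sizes and multiplication over outgroups.  Species
are then linked by orthology, their q-scores averaged, pairs classified
into the strict / intermediate / relaxed tiers, ohnolog status
transferred to species lacking their own synteny evidence, and families
built per tier.

Everything here is a thin layer over the per-module operations; the unit
of reuse is :func:`score_species`, which the shuffled-genome null also
runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .consensus import (
    TIERS,
    TierCriteria,
    link_pairs_across_species,
    transfer_by_orthology,
)
from .families import OhnologFamily, annotate_ssd, build_families, write_families_tsv
from .genome import Genome, HomologyMap, WindowSpec, canonical_pair
from .scan import candidates_from_outgroup, candidates_from_self, find_anchors
from .stats import (
    DEFAULT_BLOCK_METHOD,
    PlacementModel,
    QScoreRecord,
    block_pvalue,
    pair_q_at_W,
)
from .timing import NodePolicy, filter_by_duplication_node

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Scalar knobs of a pipeline run."""

    W_set: tuple[int, ...] = (100, 200, 300, 400, 500)
    min_support: int = 1
    node_policy: NodePolicy = field(default_factory=NodePolicy)
    tier_criteria: TierCriteria = field(default_factory=TierCriteria)
    block_method: str = DEFAULT_BLOCK_METHOD
    placement_scope: str = "target_chromosome"
    #: condition block P-values on the detection event (support >= 1);
    #: a block at the detection threshold then carries no evidence
    detection_conditioning: bool = True
    averaging: str = "arithmetic"
    require_one_to_one: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, frozenset):
                return sorted(o)
            return str(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SpeciesData:
    genome: Genome
    paralogs: HomologyMap


@dataclass
class Dataset:
    """In-memory inputs of a run (the CLI builds one from files)."""

    species: dict[str, SpeciesData]
    outgroups: dict[str, Genome]
    orthologs: dict[tuple[str, str], HomologyMap]
    cross_orthologs: dict[tuple[str, str], HomologyMap] = field(default_factory=dict)

    @classmethod
    def from_simulation(cls, sim) -> "Dataset":
        return cls(
            species={
                sp: SpeciesData(genome=g, paralogs=sim.paralogs[sp])
                for sp, g in sim.vertebrates.items()
            },
            outgroups=dict(sim.outgroups),
            orthologs=dict(sim.orthologs),
            cross_orthologs=dict(sim.cross_orthologs),
        )


# ----------------------------------------------------------------------
def _wgd_paralogs(paralogs: HomologyMap, policy: NodePolicy) -> HomologyMap:
    pairs = {p for p in paralogs.pairs if policy.is_wgd(paralogs.duplication_node[p])}
    return HomologyMap(
        kind="paralog",
        genome_a=paralogs.genome_a,
        genome_b=paralogs.genome_b,
        pairs=pairs,
        duplication_node={p: paralogs.duplication_node[p] for p in pairs},
    )


def score_species(
    genome: Genome,
    paralogs: HomologyMap,
    outgroups: dict[str, Genome],
    orthologs: dict[str, HomologyMap],
    cfg: PipelineConfig = PipelineConfig(),
) -> dict[tuple[str, str], QScoreRecord]:
    """Detect and score ohnolog candidates for one vertebrate genome.

    Returns one :class:`QScoreRecord` per candidate pair surviving the
    duplication-time filter, with aggregated ``Q_outgr`` and ``Q_self``.
    """
    policy = cfg.node_policy
    wgd_paralogs = _wgd_paralogs(paralogs, policy)
    model = PlacementModel.from_genome(genome)
    records: dict[tuple[str, str], QScoreRecord] = {}

    def record_for(pair: tuple[str, str]) -> QScoreRecord:
        if pair not in records:
            records[pair] = QScoreRecord(gene_1=pair[0], gene_2=pair[1])
        return records[pair]

    # homolog positions in the vertebrate genome, per source gene
    par_positions = {
        g: tuple(
            genome.gene_index[p] for p in partners if p in genome.gene_index
        )
        for g, partners in wgd_paralogs.partners_of_a().items()
    }
    og_positions: dict[str, dict[str, tuple]] = {}
    for og_id in outgroups:
        omap = orthologs[og_id]
        # adjacency keyed by outgroup gene -> vertebrate partners
        if omap.genome_a == genome.genome_id:
            adj = omap.partners_of_b()
        else:
            adj = omap.partners_of_a()
        og_positions[og_id] = {
            o: tuple(genome.gene_index[v] for v in vs if v in genome.gene_index)
            for o, vs in adj.items()
        }

    for W in cfg.W_set:
        spec = WindowSpec(W)

        # --- self comparison ------------------------------------------------
        cache_self: dict[tuple[str, str], float] = {}
        for cand in candidates_from_self(genome, wgd_paralogs, spec, cfg.min_support):
            block = cand.blocks[0]
            source = [
                g
                for g in genome.genes_in_span(
                    block.source_span.chrom, block.source_span.lo, block.source_span.hi
                )
                if g != block.anchor_source_gene
            ]
            p_block = block_pvalue(
                model, source, block.target_span, par_positions, W,
                method=cfg.block_method, scope=cfg.placement_scope,
                condition_min=1 if cfg.detection_conditioning else 0,
                pvalue_cache=cache_self,
            )
            rec = record_for(cand.pair)
            rec.q_self_by_W[W] = min(
                rec.q_self_by_W.get(W, 1.0), pair_q_at_W([p_block])
            )

        # --- outgroup comparison ---------------------------------------------
        for og_id, og_genome in sorted(outgroups.items()):
            anchors = find_anchors(genome, og_genome, orthologs[og_id], spec,
                                   cfg.min_support)
            cands = candidates_from_outgroup(anchors, og_id, W)
            cands = filter_by_duplication_node(cands, paralogs, policy)
            positions = og_positions[og_id]
            cache: dict[tuple[str, str], float] = {}
            block_P: dict[tuple[str, str], float] = {}
            best: dict[tuple[str, str], list[float]] = {}
            for cand in cands:
                sides = []
                for block in cand.blocks:
                    key = (block.anchor_source_gene, block.anchor_target_gene)
                    if key not in block_P:
                        source = [
                            g
                            for g in og_genome.genes_in_span(
                                block.source_span.chrom,
                                block.source_span.lo,
                                block.source_span.hi,
                            )
                            if g != block.anchor_source_gene
                        ]
                        block_P[key] = block_pvalue(
                            model, source, block.target_span, positions, W,
                            method=cfg.block_method, scope=cfg.placement_scope,
                            condition_min=1 if cfg.detection_conditioning else 0,
                            pvalue_cache=cache,
                        )
                    sides.append(block_P[key])
                entry = best.setdefault(cand.pair, [1.0, 1.0])
                entry[0] = min(entry[0], sides[0])
                entry[1] = min(entry[1], sides[1])
            for pair, (p1, p2) in best.items():
                rec = record_for(pair)
                rec.q_by_outgroup_and_W[(og_id, W)] = pair_q_at_W([p1], [p2])

    for rec in records.values():
        rec.finalize(cfg.W_set)
    return records


# ----------------------------------------------------------------------
@dataclass
class RunResult:
    config: PipelineConfig
    records_by_species: dict[str, dict[tuple[str, str], QScoreRecord]]
    consensus: list
    accepted: dict[str, dict[str, set[tuple[str, str]]]]
    families: dict[str, dict[str, list[OhnologFamily]]]
    report: dict

    def accepted_pairs(self, species: str, tier: str) -> set[tuple[str, str]]:
        return self.accepted.get(species, {}).get(tier, set())


def run_pipeline(
    dataset: Dataset,
    cfg: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> RunResult:
    """Run detection through family construction for every species."""
    records_by_species = {}
    for sp in sorted(dataset.species):
        data = dataset.species[sp]
        outgroups = {
            og: dataset.outgroups[og]
            for (s, og) in dataset.orthologs
            if s == sp and og in dataset.outgroups
        }
        orthologs = {og: dataset.orthologs[(sp, og)] for og in outgroups}
        records_by_species[sp] = score_species(
            data.genome, data.paralogs, outgroups, orthologs, cfg
        )
        logger.info("%s: %d scored candidate pairs", sp, len(records_by_species[sp]))

    presence = {
        sp: {
            p
            for p in _wgd_paralogs(data.paralogs, cfg.node_policy).pairs
            if p[0] in data.genome.gene_index and p[1] in data.genome.gene_index
        }
        for sp, data in dataset.species.items()
    }
    consensus = link_pairs_across_species(
        records_by_species,
        list(dataset.cross_orthologs.values()),
        presence,
        averaging=cfg.averaging,
        require_one_to_one=cfg.require_one_to_one,
    )
    accepted = transfer_by_orthology(consensus, cfg.tier_criteria)

    families: dict[str, dict[str, list[OhnologFamily]]] = {}
    for sp in sorted(dataset.species):
        families[sp] = {}
        for tier in TIERS:
            fams = build_families(accepted.get(sp, {}).get(tier, set()))
            families[sp][tier] = [
                annotate_ssd(f, dataset.species[sp].paralogs, cfg.node_policy)
                for f in fams
            ]

    report = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "species": {
            sp: {
                "scored_pairs": len(records_by_species[sp]),
                **{
                    tier: {
                        "pairs": len(accepted.get(sp, {}).get(tier, set())),
                        "families": len(families[sp][tier]),
                    }
                    for tier in TIERS
                },
            }
            for sp in sorted(dataset.species)
        },
    }
    result = RunResult(
        config=cfg,
        records_by_species=records_by_species,
        consensus=consensus,
        accepted=accepted,
        families=families,
        report=report,
    )
    if out_dir is not None:
        write_outputs(result, Path(out_dir))
    return result


# ----------------------------------------------------------------------
def _header(cfg: PipelineConfig) -> str:
    return f"ohnoscan {__version__}\nconfig_hash={cfg.config_hash()}\nseed={cfg.seed}"


def write_outputs(result: RunResult, out_dir: Path) -> None:
    """Write per-species q-score TSVs, the consensus TSV, family TSVs
    and a JSON run report.  Reruns with identical config and seed are
    byte-identical (all rows sorted, headers carry the config hash)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    header = _header(cfg)

    for sp, records in sorted(result.records_by_species.items()):
        rows = []
        for pair in sorted(records):
            rec = records[pair]
            row = {
                "gene_1": rec.gene_1,
                "gene_2": rec.gene_2,
                "Q_outgr": rec.Q_outgr,
                "Q_self": rec.Q_self,
            }
            for (og, W), q in sorted(rec.q_by_outgroup_and_W.items()):
                row[f"q_{og}_{W}"] = q
            for W, q in sorted(rec.q_self_by_W.items()):
                row[f"q_self_{W}"] = q
            rows.append(row)
        path = out_dir / f"qscores_{sp}.tsv"
        with open(path, "w") as fh:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
            pd.DataFrame(rows).to_csv(fh, sep="\t", index=False, float_format="%.6g")

    tier_rank = {t: i for i, t in enumerate(TIERS)}
    rows = []
    for sp in sorted(result.accepted):
        scored = set(result.records_by_species.get(sp, {}))
        for tier in TIERS:
            for pair in sorted(result.accepted[sp][tier]):
                rows.append(
                    {
                        "species": sp,
                        "gene_1": pair[0],
                        "gene_2": pair[1],
                        "tier": tier,
                        "transferred": pair not in scored,
                    }
                )
    # keep only the most stringent tier per pair in the flat consensus table
    df = pd.DataFrame(rows)
    if not df.empty:
        df["rank"] = df["tier"].map(tier_rank)
        df = (
            df.sort_values(["species", "gene_1", "gene_2", "rank"])
            .drop_duplicates(["species", "gene_1", "gene_2"], keep="first")
            .drop(columns="rank")
        )
    with open(out_dir / "consensus_pairs.tsv", "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)

    for sp, by_tier in sorted(result.families.items()):
        for tier, fams in by_tier.items():
            write_families_tsv(fams, out_dir / f"families_{sp}_{tier}.tsv", header)

    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ----------------------------------------------------------------------
def report_outgroup_overlap(
    per_outgroup_pairs: dict[str, set[tuple[str, str]]],
) -> dict[frozenset[str], int]:
    """Venn-style membership table over outgroups.

    For every pair found by at least one outgroup, record the exact subset
    of outgroups identifying it; counts over subsets partition the union.
    """
    membership: dict[tuple[str, str], set[str]] = {}
    for og, pairs in per_outgroup_pairs.items():
        for pair in pairs:
            membership.setdefault(canonical_pair(*pair), set()).add(og)
    table: dict[frozenset[str], int] = {}
    for subset in membership.values():
        key = frozenset(subset)
        table[key] = table.get(key, 0) + 1
    return table


def restrict_to_outgroups(
    records: dict[tuple[str, str], QScoreRecord],
    outgroups: set[str] | frozenset[str],
    W_set: tuple[int, ...],
) -> dict[tuple[str, str], QScoreRecord]:
    """Records as they would be with only a subset of outgroups.

    Detection and scoring are independent per outgroup, so dropping the
    evidence of the excluded outgroups and re-aggregating reproduces
    exactly the result of a run that never saw them.
    """
    out: dict[tuple[str, str], QScoreRecord] = {}
    for pair, rec in records.items():
        sub = QScoreRecord(
            gene_1=rec.gene_1,
            gene_2=rec.gene_2,
            q_by_outgroup_and_W={
                key: q for key, q in rec.q_by_outgroup_and_W.items()
                if key[0] in outgroups
            },
            q_self_by_W=dict(rec.q_self_by_W),
        )
        if sub.q_by_outgroup_and_W or sub.q_self_by_W:
            out[pair] = sub.finalize(W_set)
    return out


def pairs_by_outgroup(
    records: dict[tuple[str, str], QScoreRecord],
) -> dict[str, set[tuple[str, str]]]:
    """Which pairs each outgroup identified (any window size)."""
    out: dict[str, set[tuple[str, str]]] = {}
    for pair, rec in records.items():
        for (og, _W) in rec.q_by_outgroup_and_W:
            out.setdefault(og, set()).add(pair)
    return out
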