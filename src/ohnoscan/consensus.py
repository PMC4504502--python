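"""Cross-species integration: averaged q-scores, tiers, orthology transfer.

Amniote genomes share most of their post-WGD history, so an ohnolog pair
is usually mirrored by ortholog pairs in the other vertebrates analysed.
Averaging the q-scores of a pair over the species where it is observed
smooths over recent lineage-specific rearrangements in any single genome,
and a species can inherit a pair it has no synteny evidence for at all,
as long as both genes' orthology to a confidently identified pair
elsewhere is unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import fmean

import networkx as nx

from .genome import HomologyMap, canonical_pair
from .stats import QScoreRecord, Q_FLOOR

logger = logging.getLogger(__name__)

TIERS = ("strict", "intermediate", "relaxed")


@dataclass(frozen=True)
class TierCriteria:
    """Thresholds of the three statistical confidence tiers.

    All comparisons are strict inequalities on the averaged q-scores:

    * strict:        Q̄_outgr < 0.01  and  Q̄_self < 0.01
    * intermediate:  Q̄_outgr < 0.05  and  Q̄_self < 0.3
    * relaxed:       Q̄_outgr < 0.05  or  (Q̄_outgr < 0.5 and Q̄_self < 0.01)
    """

    strict_outgr: float = 0.01
    strict_self: float = 0.01
    intermediate_outgr: float = 0.05
    intermediate_self: float = 0.3
    relaxed_outgr: float = 0.05
    relaxed_outgr_alt: float = 0.5
    relaxed_self_alt: float = 0.01


def classify_pair(
    qbar_outgr: float, qbar_self: float, criteria: TierCriteria = TierCriteria()
) -> str:
    """Most stringent tier satisfied by the averaged q-scores (or 'none')."""
    if qbar_outgr < criteria.strict_outgr and qbar_self < criteria.strict_self:
        return "strict"
    if qbar_outgr < criteria.intermediate_outgr and qbar_self < criteria.intermediate_self:
        return "intermediate"
    if qbar_outgr < criteria.relaxed_outgr or (
        qbar_outgr < criteria.relaxed_outgr_alt and qbar_self < criteria.relaxed_self_alt
    ):
        return "relaxed"
    return "none"


@dataclass
class ConsensusRecord:
    """A group of equivalent ohnolog pairs linked across species.

    ``scored`` maps species to the pairs carrying their own synteny
    q-scores; ``present`` maps species to ortholog pairs that exist there
    without scores (transfer targets).  ``Qbar`` values are means over the
    scored members.
    """

    scored: dict[str, list[QScoreRecord]] = field(default_factory=dict)
    present: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    Qbar_outgr: float = 1.0
    Qbar_self: float = 1.0

    @property
    def species_support(self) -> list[str]:
        return sorted(self.scored)


def _mean(values: list[float], how: str) -> float:
    if how == "arithmetic":
        return fmean(values)
    if how == "geometric":
        import math

        return math.exp(fmean(math.log(max(v, Q_FLOOR)) for v in values))
    raise ValueError(f"unknown averaging {how!r}")


def link_pairs_across_species(
    records_by_species: dict[str, dict[tuple[str, str], QScoreRecord]],
    cross_orthologs: list[HomologyMap],
    presence_by_species: dict[str, set[tuple[str, str]]] | None = None,
    *,
    averaging: str = "arithmetic",
    require_one_to_one: bool = True,
) -> list[ConsensusRecord]:
    """Group equivalent pairs across species and average their q-scores.

    Two pairs in different species are equivalent when both genes of one
    are orthologous to the genes of the other; linkage groups are the
    connected components of the resulting pair-orthology graph.
    ``presence_by_species`` optionally lists, per species, the pairs that
    exist (e.g. WGD-epoch paralog pairs) without having been scored:
    components are extended through them so they become transfer targets.

    Many-to-many orthology links all consistent combinations (counted in
    the log); when ``require_one_to_one`` is set, only unambiguous
    1-to-1 links feed the transfer machinery, though scored pairs still
    link through any consistent combination.
    """
    presence_by_species = presence_by_species or {}

    # adjacency per ordered species pair: gene -> set of ortholog genes
    adjacency: dict[tuple[str, str], dict[str, set[str]]] = {}
    for omap in cross_orthologs:
        adjacency[(omap.genome_a, omap.genome_b)] = omap.partners_of_a()
        adjacency[(omap.genome_b, omap.genome_a)] = omap.partners_of_b()

    graph = nx.Graph()
    nodes_scored = {
        (sp, pair) for sp, recs in records_by_species.items() for pair in recs
    }
    nodes_present = {
        (sp, pair)
        for sp, pairs in presence_by_species.items()
        for pair in pairs
        if (sp, pair) not in nodes_scored
    }
    graph.add_nodes_from(nodes_scored | nodes_present)

    ambiguous = 0
    species = sorted(set(records_by_species) | set(presence_by_species))
    all_nodes = nodes_scored | nodes_present
    node_set = set(all_nodes)
    for sp, pair in all_nodes:
        a, b = pair
        for other in species:
            if other == sp:
                continue
            adj = adjacency.get((sp, other))
            if adj is None:
                continue
            orth_a = adj.get(a, set())
            orth_b = adj.get(b, set())
            if not orth_a or not orth_b:
                continue
            one_to_one = len(orth_a) == 1 and len(orth_b) == 1
            if len(orth_a) > 1 or len(orth_b) > 1:
                ambiguous += 1
            for a2 in orth_a:
                for b2 in orth_b:
                    if a2 == b2:
                        continue
                    target = (other, canonical_pair(a2, b2))
                    if target in node_set:
                        source = (sp, pair)
                        if graph.has_edge(source, target):
                            # a link is unambiguous only if both directions are
                            graph.edges[source, target]["one_to_one"] &= one_to_one
                        else:
                            graph.add_edge(source, target, one_to_one=one_to_one)
    if ambiguous:
        logger.info("cross-species linkage: %d many-to-many link(s) expanded", ambiguous)

    records: list[ConsensusRecord] = []
    for component in nx.connected_components(graph):
        rec = ConsensusRecord()
        scored_in_component = {n for n in component if n in nodes_scored}
        for sp, pair in component:
            qrec = records_by_species.get(sp, {}).get(pair)
            if qrec is not None:
                rec.scored.setdefault(sp, []).append(qrec)
            else:
                if require_one_to_one and not _reachable_one_to_one(
                    graph, (sp, pair), scored_in_component
                ):
                    continue
                rec.present.setdefault(sp, set()).add(pair)
        if not rec.scored:
            continue
        qo = [r.Q_outgr for recs in rec.scored.values() for r in recs]
        qs = [r.Q_self for recs in rec.scored.values() for r in recs]
        rec.Qbar_outgr = _mean(qo, averaging)
        rec.Qbar_self = _mean(qs, averaging)
        records.append(rec)
    records.sort(key=lambda r: sorted(r.scored.items())[0][0] if r.scored else "")
    return records


def _reachable_one_to_one(graph: nx.Graph, node, scored_nodes: set) -> bool:
    """True when ``node`` connects to a scored pair via 1-to-1 edges only."""
    seen = {node}
    stack = [node]
    while stack:
        cur = stack.pop()
        for nxt in graph.neighbors(cur):
            if not graph.edges[cur, nxt].get("one_to_one", False):
                continue
            if nxt in seen:
                continue
            if nxt in scored_nodes:
                return True
            seen.add(nxt)
            stack.append(nxt)
    return False


def transfer_by_orthology(
    records: list[ConsensusRecord],
    criteria: TierCriteria = TierCriteria(),
) -> dict[str, dict[str, set[tuple[str, str]]]]:
    """Per-species accepted pair sets per tier, including inherited pairs.

    Each consensus record is classified once on its averaged q-scores;
    every species holding a member pair — scored or merely present via
    orthology — receives the pair at that tier.  Tier sets are returned
    nested (strict ⊆ intermediate ⊆ relaxed), and transfer can only add
    pairs, never remove a species' own accepted ones.
    """
    accepted: dict[str, dict[str, set[tuple[str, str]]]] = {}
    order = {tier: i for i, tier in enumerate(TIERS)}
    for rec in records:
        tier = classify_pair(rec.Qbar_outgr, rec.Qbar_self, criteria)
        if tier == "none":
            continue
        members: list[tuple[str, tuple[str, str]]] = [
            (sp, r.pair) for sp, recs in rec.scored.items() for r in recs
        ] + [(sp, pair) for sp, pairs in rec.present.items() for pair in pairs]
        for sp, pair in members:
            tiers = accepted.setdefault(sp, {t: set() for t in TIERS})
            for t in TIERS[order[tier]:]:
                tiers[t].add(pair)
    return accepted
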