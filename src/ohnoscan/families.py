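"""Ohnolog family construction and small-scale-duplicate annotation.

Families are the connected components of the accepted ohnolog pair graph.
Two rounds of whole-genome duplication can leave at most four ohnologs of
an ancestral gene, so families are expected to contain at most four
*ohnolog groups*; members that never form an accepted ohnolog pair with
each other but both pair with a third member are small-scale duplicates
(SSDs) of one another and are collapsed into a single group.  SSD links
are labelled ``recent`` when the duplication node post-dates the WGD and
``ancient`` otherwise; the TSV output joins group members with ``,`` for
recent and ``|`` for ancient links.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

from .genome import HomologyMap, canonical_pair
from .timing import NodePolicy

logger = logging.getLogger(__name__)


@dataclass
class OhnologFamily:
    """One connected component of the accepted ohnolog pair graph."""

    members: tuple[str, ...]
    pairs: frozenset[tuple[str, str]]
    ohnolog_groups: tuple[tuple[str, ...], ...] = ()
    ssd_links: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ohnolog_groups:
            self.ohnolog_groups = tuple((m,) for m in self.members)

    @property
    def size(self) -> int:
        """Number of ohnolog groups (the family size reported throughout)."""
        return len(self.ohnolog_groups)


def build_families(pairs: Iterable[tuple[str, str]]) -> list[OhnologFamily]:
    """Connected components of the undirected accepted-pair graph.

    Output ordering is deterministic: members sorted lexicographically
    within each family, families sorted by their first member.
    """
    graph = nx.Graph()
    canon = {canonical_pair(a, b) for a, b in pairs}
    graph.add_edges_from(canon)
    families = []
    for component in nx.connected_components(graph):
        members = tuple(sorted(component))
        fam_pairs = frozenset(p for p in canon if p[0] in component)
        families.append(OhnologFamily(members=members, pairs=fam_pairs))
    families.sort(key=lambda f: f.members[0])
    return families


def annotate_ssd(
    family: OhnologFamily,
    paralogs: HomologyMap,
    policy: NodePolicy,
) -> OhnologFamily:
    """Collapse small-scale duplicates into shared ohnolog groups.

    Member pairs that are not accepted ohnolog pairs but are annotated
    paralogs of each other are SSD-linked; groups are the connected
    components of those links.  Unannotated non-ohnolog member pairs stay
    in separate groups (logged).  Each SSD link is labelled by the age of
    its duplication node relative to the WGD epoch.
    """
    ssd_graph = nx.Graph()
    ssd_graph.add_nodes_from(family.members)
    links: dict[tuple[str, str], str] = {}
    unannotated = 0
    members = family.members
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            pair = canonical_pair(members[i], members[j])
            if pair in family.pairs:
                continue
            node = paralogs.duplication_node.get(pair)
            if node is None:
                unannotated += 1
                continue
            links[pair] = policy.ssd_age(node)
            ssd_graph.add_edge(*pair)
    if unannotated:
        logger.debug(
            "family %s: %d non-ohnolog member pair(s) without paralogy annotation",
            members[0], unannotated,
        )
    groups = tuple(
        sorted(tuple(sorted(c)) for c in nx.connected_components(ssd_graph))
    )
    return OhnologFamily(
        members=family.members,
        pairs=family.pairs,
        ohnolog_groups=groups,
        ssd_links=links,
    )


def family_size_histogram(
    families: Iterable[OhnologFamily],
) -> tuple[dict[int, int], float]:
    """Histogram of family sizes (ohnolog-group counts) and fraction <= 4."""
    counts = Counter(f.size for f in families)
    total = sum(counts.values())
    if total == 0:
        return {}, float("nan")
    small = sum(c for size, c in counts.items() if size <= 4)
    return dict(sorted(counts.items())), small / total


def _format_group(group: tuple[str, ...], links: dict[tuple[str, str], str]) -> str:
    """Join group members with ',' (recent SSD) or '|' (ancient SSD).

    Members are ordered lexicographically; the separator between two
    consecutive members is taken from their direct SSD link when present,
    falling back to the group's dominant label.
    """
    if len(group) == 1:
        return group[0]
    labels = [links[p] for p in (canonical_pair(a, b) for a in group for b in group if a < b) if p in links]
    dominant = "|" if labels.count("ancient") > labels.count("recent") else ","
    parts = [group[0]]
    for prev, cur in zip(group, group[1:]):
        label = links.get(canonical_pair(prev, cur))
        sep = {"recent": ",", "ancient": "|"}.get(label, dominant)
        parts.append(f" {sep} " if sep == "|" else f"{sep} ")
        parts.append(cur)
    return "".join(parts)


def write_families_tsv(
    families: Iterable[OhnologFamily], path: str | Path, header: str | None = None
) -> None:
    """Write families with one ohnolog group per column."""
    families = list(families)
    width = max((f.size for f in families), default=0)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        cols = [f"group_{i + 1}" for i in range(width)]
        fh.write("\t".join(["family_id", "size", *cols]) + "\n")
        for idx, fam in enumerate(families, start=1):
            groups = [_format_group(g, fam.ssd_links) for g in fam.ohnolog_groups]
            groups += [""] * (width - len(groups))
            fh.write("\t".join([f"F{idx:05d}", str(fam.size), *groups]) + "\n")
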