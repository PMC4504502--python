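"""Duplication-time filter: keep candidates duplicated at the 2R-WGD epoch.

Candidate pairs from both detection routes must be annotated paralogs
whose duplication node falls at the base of the vertebrates.  Node labels
follow a Compara-style taxonomy annotation and drift across database
releases, so the accepted set is configuration, not code.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .genome import HomologyMap, canonical_pair
from .scan import OhnologCandidate

logger = logging.getLogger(__name__)

#: node labels treated as the 2R-WGD epoch on real Compara exports
DEFAULT_WGD_NODES = frozenset({"Vertebrata", "Euteleostomi", "Chordata"})

#: node labels strictly inside the vertebrate crown (younger than the WGD);
#: used to tell recent from ancient small-scale duplicates
DEFAULT_RECENT_NODES = frozenset(
    {
        "Tetrapoda", "Amniota", "Mammalia", "Theria", "Eutheria",
        "Euarchontoglires", "Primates", "Rodentia", "Sauria", "Aves",
    }
)


@dataclass(frozen=True)
class NodePolicy:
    """Which duplication-node labels count as the 2R-WGD epoch.

    ``allowed_nodes`` gates candidate pairs; ``recent_nodes`` marks nodes
    younger than the WGD (post-WGD small-scale duplicates).  Labels in
    neither set are treated as older than — or contemporaneous with — the
    WGD.
    """

    allowed_nodes: frozenset[str] = DEFAULT_WGD_NODES
    recent_nodes: frozenset[str] = DEFAULT_RECENT_NODES

    def __post_init__(self) -> None:
        if not self.allowed_nodes:
            raise ValueError("allowed_nodes must be non-empty")

    def is_wgd(self, node: str) -> bool:
        return node in self.allowed_nodes

    def ssd_age(self, node: str) -> str:
        """'recent' for post-WGD duplications, 'ancient' otherwise."""
        return "recent" if node in self.recent_nodes else "ancient"


#: policy matching the simulator's {preWGD, WGD, postWGD} node labels
SIMULATOR_NODE_POLICY = NodePolicy(
    allowed_nodes=frozenset({"WGD"}), recent_nodes=frozenset({"postWGD"})
)


def filter_by_duplication_node(
    candidates: list[OhnologCandidate],
    paralogs: HomologyMap,
    policy: NodePolicy = NodePolicy(),
) -> list[OhnologCandidate]:
    """Keep candidates whose pair was duplicated at the WGD epoch.

    Pairs absent from the paralog map are dropped and counted; per-node
    rejection tallies go to the run log.  Idempotent, and the output is
    always a subset of the input.
    """
    kept: list[OhnologCandidate] = []
    rejected: Counter[str] = Counter()
    missing = 0
    for cand in candidates:
        pair = canonical_pair(cand.gene_1, cand.gene_2)
        node = paralogs.duplication_node.get(pair)
        if node is None:
            missing += 1
            continue
        if policy.is_wgd(node):
            kept.append(cand)
        else:
            rejected[node] += 1
    if missing or rejected:
        logger.info(
            "duplication-time filter: kept %d, dropped %d unannotated, rejected by node %s",
            len(kept), missing, dict(rejected),
        )
    return kept
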