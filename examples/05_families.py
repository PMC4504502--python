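"""Ohnolog families: connected components with small-scale duplicates.

Accepted pairs are joined into families; members that never pair with
each other but are annotated paralogs are small-scale duplicates and
collapse into one ohnolog group, labelled recent (',') or ancient ('|')
relative to the WGD.  Two rounds of WGD cap families at four groups.
"""

from ohnoscan import (
    HomologyMap,
    NodePolicy,
    annotate_ssd,
    build_families,
    family_size_histogram,
)
from ohnoscan.families import _format_group

pairs = [
    ("RGL1", "RGL2"), ("RGL1", "RGL3"), ("RGL2", "RGL3"),
    ("RGL1", "RALGDS"), ("RGL2", "RALGDS"), ("RGL3", "RALGDS"),
    ("RGL1", "RGL4"), ("RGL2", "RGL4"), ("RGL3", "RGL4"),
    ("SOX11", "SOX12"),
]
paralogs = HomologyMap(kind="paralog", genome_a="human", genome_b="human")
paralogs.add("RALGDS", "RGL4", "Mammalia")  # duplicated after the 2R-WGD

policy = NodePolicy()
families = [annotate_ssd(f, paralogs, policy) for f in build_families(pairs)]
for fam in families:
    groups = " / ".join(_format_group(g, fam.ssd_links) for g in fam.ohnolog_groups)
    print(f"family of size {fam.size}: {groups}")

hist, frac = family_size_histogram(families)
print(f"\nsize histogram: {hist}; fraction of families <= 4 groups: {frac:.0%}")
print()
print("RGL4 never forms an accepted pair with RALGDS yet pairs with the")
print("other members, so the two genes share one ohnolog group as recent")
print("small-scale duplicates - the family size stays at the 2R maximum, 4.")
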