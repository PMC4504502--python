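"""Simulate a small 2R-WGD dataset and detect raw synteny candidates.

The simulator duplicates a 400-gene ancestor twice on the vertebrate
stem, thins the duplicates, rearranges every lineage and emits genomes
plus homology tables with ground truth.  We then run anchor detection
against one outgroup and self-comparison at a single window size.
"""

from ohnoscan import (
    SimConfig,
    WindowSpec,
    candidates_from_outgroup,
    candidates_from_self,
    find_anchors,
    simulate,
)

sim = simulate(SimConfig(n_genes=400, n_chromosomes=3, seed=42,
                         n_vertebrates=1, n_outgroups=1))
vert = sim.vertebrates["vert1"]
outg = sim.outgroups["outg1"]
print(f"vertebrate genome : {vert.n_genes} genes on {len(vert.chromosomes)} chromosomes")
print(f"outgroup genome   : {outg.n_genes} genes")
print(f"true ohnolog pairs: {len(sim.truth.true_pairs['vert1'])}")

spec = WindowSpec(20)
anchors = find_anchors(vert, outg, sim.orthologs[("vert1", "outg1")], spec)
outgroup_cands = candidates_from_outgroup(anchors, "outg1", spec.W)
self_cands = candidates_from_self(vert, sim.paralogs["vert1"], spec)

print(f"\nwindow size W = {spec.W} genes")
print(f"synteny anchors (ortholog pairs with supported windows): {len(anchors)}")
print(f"candidate pairs from the 1-to-2 outgroup pattern       : {len(outgroup_cands)}")
print(f"candidate pairs from self-comparison                    : {len(self_cands)}")
print()
print("Candidates are permissive by design; the statistics stage assigns")
print("each one a q-score and the tier thresholds do the pruning.")
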