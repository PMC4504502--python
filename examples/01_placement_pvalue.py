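"""The per-gene placement P-value on a schematic linear genome.

A 36-gene chromosome admits 31 placements of a 5-gene window.  One
outgroup gene has orthologs at vertebrate positions 1, 8, 19, 23 and 32;
we count the placements that avoid all of them and turn the count into
the chance probability that a random window contains at least one.
"""

from ohnoscan import Genome, PlacementModel, count_valid_placements, gene_pvalue

genome = Genome.from_chromosomes("toy", {"chr1": [f"v{i}" for i in range(1, 37)]})
model = PlacementModel.from_genome(genome)
homologs = [("chr1", p) for p in (1, 8, 19, 23, 32)]

W = 5
total = model.n_placements(W)
valid = count_valid_placements(model, homologs, W)
p_i = gene_pvalue(model, homologs, W)

print(f"possible {W}-gene window placements : {total}")
print(f"placements free of all orthologs   : {valid}")
print(f"placement P-value P_i = 1 - {valid}/{total} = {p_i:.4f} (~{p_i:.1f})")
print()
print("P_i is the probability that a randomly placed window would contain")
print("an ortholog of this gene by chance alone - the building block of")
print("every synteny-block P-value downstream.")
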