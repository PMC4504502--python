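# Methods

`ohnoscan` identifies **ohnologs** — paralogs retained from the two
rounds of whole-genome duplication (2R-WGD) at the base of the
vertebrates, ~500 MY ago — from gene order and homology annotations
alone. This note records the model, the statistical machinery, the
parameter choices and their rationale, what the simulator does and does
not emulate, and the known limitations.

## The detection model

After a WGD, sister regions decay: most duplicates are lost and
chromosomal rearrangements disperse the survivors. What remains of a
duplicated region is *content-based synteny*: two genomic windows that
share several homologous genes, regardless of gene order. Two
complementary comparisons expose it:

* **Outgroup comparison (1-to-2 pattern).** An outgroup genome that
  diverged before the WGD carries one unduplicated copy of each
  ancestral region. For every ortholog pair (O, V) between outgroup and
  vertebrate, windows of `W` genes (anchor ± `W//2`, truncated at
  chromosome ends) are placed around both genes; the pair is an *anchor*
  when the windows share at least `min_support` additional ortholog
  pairs. An outgroup gene anchored to two distinct vertebrate genes
  marks those genes as an ohnolog candidate pair.
* **Self comparison.** For every within-genome paralog pair duplicated
  at the WGD epoch, windows around the two genes are compared the same
  way. Window pairs with overlapping spans (tandem arrays) are skipped.

Detection is deliberately permissive (`min_support = 1`); all pruning is
statistical. Candidates from both routes are then restricted to pairs
whose Compara-style duplication node falls in the configured WGD-epoch
set (`NodePolicy.allowed_nodes`; node labels drift across annotation
releases, so this is configuration, not code).

## Placement P-values and block P-values

The elementary quantity is the **placement P-value** `P_i` of a source
gene *i*: the probability that a window of `W` genes dropped uniformly
at random on the vertebrate genome contains at least one homolog of
*i*. With `N − W` possible placements (summed per chromosome; windows
start at positions `1 .. n_c − W`) of which `n_free` avoid every
homolog, `P_i = 1 − n_free/(N − W)`. A 36-gene toy chromosome with
homologs at positions 1, 8, 19, 23 and 32 has 31 placements of a 5-gene
window, 12 of them empty, giving `P_i = 1 − 12/31 ≈ 0.61`.

A candidate's supporting **block** (source window vs target window) is
scored by the number `k` of source-window genes with a homolog inside
the target window. Under independent placement this count is a sum of
Bernoulli(`P_i`) draws, and the block P-value is its upper tail
`P(X ≥ k)`. Three implementation choices matter here; all three are this
package's own design decisions:

1. **Count tail, not product.** Multiplying the `P_i` of co-occurring
   genes alone (available as `method="product"`) is not a P-value: with
   many source genes its chance of being small grows with the window
   content and the score becomes anti-conservative. The default
   `count-tail` evaluates the tail of the count via a Poisson
   approximation on `λ = Σ P_i` (the `P_i` are small, so only the mean
   matters; `exact-tail` runs the exact Poisson-binomial convolution and
   agrees to within ~10% at the default scales).
2. **Chromosome conditioning.** Pipeline scoring restricts the
   placement universe to the chromosome the target window sits on
   (`placement_scope="target_chromosome"`, genome-wide fallback for
   chromosomes shorter than `W`). Conserved segments tie the homologs of
   neighbouring source genes to one target chromosome in any genome that
   has synteny at all, so the genome-wide denominator systematically
   understates null hit rates; conditioning makes the statistic reward
   *sub-chromosomal* co-occurrence and keeps it calibrated under
   within-chromosome shuffling. The raw operations (`gene_pvalue`,
   `count_valid_placements`) keep the genome-wide `N − W` convention.
3. **Detection conditioning.** A block enters scoring only because
   support ≥ `min_support` was observed; crediting that observation
   again double-counts the discovery. The pipeline therefore uses the
   conditional tail `P(X ≥ k | X ≥ 1)`, so a block at the detection
   threshold carries no evidence (P-value 1). The raw `block_pvalue`
   operation defaults to the unconditional tail.

## q-scores and their aggregation

Every layer maps to [0, 1], lower = less likely by chance:

* per window size: `q_W = P_block(window around gene 1) ×
  P_block(window around gene 2)` for outgroup candidates (both
  co-occurrence patterns must arise together), the single block P-value
  for self candidates. When several anchors support a side, the best
  (minimum) block P-value is used.
* over window sizes (default real-data set `{100, 200, 300, 400, 500}`
  genes): geometric mean over the **full** W set, window sizes at which
  the pair was not recovered imputed as `q = 1`. Absence of evidence is
  neutral, never favourable — and this imputation is what makes the
  aggregate super-uniform on shuffled genomes (a chance candidate is
  typically recovered at only the largest windows).
* over outgroups: plain product, justified by the independent
  rearrangement histories of lineages that diverged > 500 MY ago. The
  product requires genuinely independent outgroup genomes; closely
  related (or insufficiently diverged) outgroups violate it, which the
  shuffled-genome control makes visible.
* over species: ohnolog pairs are linked across vertebrates when both
  genes map through cross-species orthology; `Q̄_outgr` and `Q̄_self`
  are arithmetic means over the linked, scored species (geometric
  averaging available via `averaging="geometric"`; arithmetic is the
  default because a single well-assembled genome should be able to
  rescue a pair blurred by one poor assembly).

Numerical details: all averaging happens in log space with values
clamped to a floor of 1e-300 first; empty products are 1; scores are
clamped to [0, 1] at every step.

## Tiers, transfer, families

Pairs are classified on the averaged scores with strict inequalities:

* strict: `Q̄_outgr < 0.01` and `Q̄_self < 0.01`
* intermediate: `Q̄_outgr < 0.05` and `Q̄_self < 0.3`
* relaxed: `Q̄_outgr < 0.05` or (`Q̄_outgr < 0.5` and `Q̄_self < 0.01`)

The defaults nest (strict ⊆ intermediate ⊆ relaxed) and all thresholds
are user-overridable. A species inherits a pair it has no synteny
evidence for when both genes' orthology to a classified pair elsewhere
is unambiguous (1-to-1 in both directions by default;
`require_one_to_one=False` transfers through many-to-many links).
Transferred pairs keep the consensus tier rather than being re-tiered
per species.

Families are connected components of the accepted-pair graph, built per
tier independently, with deterministic lexicographic ordering. Members
that never form an accepted pair with each other but are annotated
paralogs are small-scale duplicates (SSDs) and collapse into one
*ohnolog group*; the family size is the group count, which two rounds of
WGD cap at four. SSD links are labelled `recent` when the duplication
node lies strictly inside the vertebrate crown (`NodePolicy.
recent_nodes`) and `ancient` otherwise; the family TSV joins group
members with `", "` (recent) or `" | "` (ancient). Non-paired members
without paralogy annotation stay in separate groups and are logged.

## The simulator

`simulate(SimConfig())` emulates the canonical scenario: an ancestral
genome; `wgd_rounds` (default 2) whole-genome duplications applied once
on the shared vertebrate stem, each new duplicate surviving with
probability `retention` (default 0.3, matching the ~20–35% ohnolog
retention observed in vertebrates); small-scale duplications inserted
adjacently on the stem with rate `ssd_rate` (0.05 per gene) and a
recent/ancient timing label; then independent lineages — vertebrates
rearranged mildly, outgroups heavily — via Poisson numbers of segment
inversions and translocations with geometric segment lengths.

Default study conditions and why:

| parameter | default | rationale |
|---|---|---|
| `n_genes`, `n_chromosomes` | 3000, 5 | desk scale: minutes per seed on one CPU |
| `retention` | 0.3 / round | realistic ohnolog survival |
| `inversion_rate`, `translocation_rate` | 40, 40 per vertebrate lineage | amniote-scale divergence; segments (mean 8 genes) preserve local content |
| `outgroup_*_rate` | 200, 200 | invertebrate outgroups are mutually scrambled; near-identical outgroups would break the independence behind the outgroup product |
| `loss_rate_outgroup` | 0.5 | ortholog callability to > 500-MY-diverged invertebrates is roughly half the gene set |
| `ssd_recent_fraction` | 0.7 | most annotated SSDs post-date the WGD |
| `ancient_paralog_rate` | 0.02 | cross-family pre-WGD pairs that exercise the duplication-time filter |
| `n_outgroups`, `n_vertebrates` | 2, 3 | smallest counts that exercise multi-outgroup and consensus machinery |

Pipeline runs on simulated data use `DESK_SCALE_W_SET = (20, 40, 60,
80, 100)`: the real-data 100–500 range scaled to the ~5,000-gene
simulated genomes so that the expected chance pair count per window
pair stays below ~1 over most of the set — the regime in which the
imputation-diluted geometric mean retains its discriminative power.

What the simulator does **not** emulate: sequence evolution and
homology-inference errors (homology tables are exact, so measured
precision/recall are upper bounds for real annotations); per-lineage
vertebrate gene loss after the WGD (all simulated vertebrates share the
full post-WGD gene complement, making cross-species orthology exactly
1-to-1 — real transfer has to survive annotation gaps); genuinely
pre-WGD small-scale duplications (ancient SSDs are placed post-WGD and
only *labelled* ancient); teleost-specific third-round duplications;
and realistic chromosome-number evolution (fissions/fusions are
approximated by segmental translocations). Passing tests therefore
demonstrate the machinery's correctness and calibration under the
stated model, not end-to-end accuracy on real annotation pipelines.

## The shuffled-genome control

`shuffle_genome` permutes gene order (default: within each chromosome,
preserving the chromosome sizes that enter `N − W`; `genome_wide`
available), leaving homology untouched, and
`null_qscore_distribution` reruns detection and scoring per replicate.
On the default conditions the fraction of shuffled-genome candidates
reaching `Q_outgr < 0.01` is ~0.1–0.3%, versus a heavy sub-0.01 tail on
the unshuffled data. Per-gene `P_i` values are unchanged in expectation
by the shuffle; only co-occurrence collapses.

## Problem sizes in the test suite

The heavier properties run on ten seeds of the default conditions
(shared across tests via a session fixture), twenty shuffle replicates
for the calibration check, and 10⁴ Monte-Carlo draws for the block
P-value calibration oracle; oracle-equivalence checks run on ≤ 100-gene
instances against brute-force enumerations. The whole suite completes
in a few minutes on one CPU.

## Known limitations

* The Poisson tail overestimates single-gene block P-values by up to
  `p/ (1 − e^{−p})` (~10% at `p = 0.2`); `exact-tail` is available where
  that matters.
* The outgroup product assumes independent outgroups; correlated
  outgroups (e.g. two closely related species) inflate significance.
  Choose phylogenetically dispersed outgroups and check the shuffled
  control.
* Candidate sets grow monotonically with `W` for the outgroup route;
  for the self route the tandem-overlap rule can drop same-chromosome
  pairs at large `W`, so monotonicity holds only for pairs whose windows
  stay disjoint.
* Self-comparison block orientation is the canonical gene order
  (gene 1's window is the source); the asymmetry is deterministic and
  second-order, but it exists.
* Window sizes must be re-scaled when genome size or homolog density
  departs strongly from the vertebrate defaults; `DESK_SCALE_W_SET`
  documents the scaling used for simulations.
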