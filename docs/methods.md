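# Methods

This note documents the models, estimators, defaults and numerical choices
behind popkit, and what its synthetic-data tests do and do not demonstrate.

## Coalescent generator

The nuclear and mitochondrial simulators share a discrete-event structured
Kingman coalescent.  Time is scaled so a within-deme pair of lineages
coalesces at rate 1; under the n-island model each lineage migrates at rate
M/2 (M = 4Nm) to a uniformly chosen other deme.  Mutations fall on branches
at rate θ/2 per lineage per unit time under infinite sites, so the expected
pairwise diversity of a panmictic sample is θ per block (θ = 4NμL nuclear
diploid, 2NμL haploid mitochondrial).  Lineages are leaf-set bitmasks; a
mutation is the bitmask of its derived carriers, which makes genotype-column
construction and haplotype identity exact.  Each block is one independent
tree with no intra-block recombination — the same granularity as the 1-Mb
jackknife blocks downstream — and diploids are formed by pairing consecutive
haploids within a deme.  Infinite sites on a finite sequence is implemented
by sampling distinct positions; exhaustion raises with advice to enlarge the
sequence.  Isolated multi-deme models (M = 0) are rejected because lineages
in different demes would never coalesce.

All generators derive their randomness from a single root seed through
`numpy.random.SeedSequence` spawning (`spawn_seeds`), so a whole pipeline
run is reproducible and child streams are independent.

What the generator does *not* emulate: sequencing error, genotype-likelihood
uncertainty (the pipeline operates on called genotypes with explicit
missingness), recombination within blocks, selection, or realistic
chromosome structure.  Passing tests therefore demonstrate correctness of
the estimators and decision rules under the stated models, not robustness to
low-coverage genotyping error.

## Mitochondrial statistics

Nucleotide diversity is the average over sequence pairs of the proportion of
differing sites, excluding positions where either sequence has a gap or N
("pairwise deletion"); pairs sharing no usable site are excluded with a
warning.  Haplotype diversity uses h = n/(n−1)(1 − Σp_k²).  Haplotype
identity treats N and "-" as wildcards: sequences differing only at uncalled
positions are merged (visit order is by name, followed by re-merging to a
fixpoint), because counting low-coverage sites as distinct haplotypes would
inflate both the haplotype count and h.

The haplotype network is an ε-relaxed minimum spanning network: all MST
edges plus any edge no longer than (1+ε) times the largest edge on the MST
path between its endpoints (the weight at which the endpoints' components
merged during Kruskal).  ε = 0 with distinct weights yields exactly the MST;
ε = ∞ the complete graph.  This preserves the qualitative content of a
reticulated haplotype figure — nodes, mutation-step edges, loops — with a
single tolerance parameter and is fully testable against a brute-force MST.

Consensus calling emits the most frequent base per pileup column, and N when
coverage is below `min_consensus_depth` (default 5) or the top count is tied
— ties emit N rather than a random base so consensus is deterministic.

Model comparison takes natural-log marginal likelihoods with their standard
deviations and favours the larger only when |ΔlogML| > 2√(SD₁² + SD₂²);
otherwise the models are indistinguishable.  `scale_effective_size` divides
a coalescent size in N·τ (years) units by the generation time (default
23.4 years, a beaked-whale average).  The mitochondrial clock rate
(0.0038 substitutions/site/Myr) is stored in the config for documentation;
no tree dating is performed here.

## Nuclear structure

**Genotype convention.** Readers re-orient every site so allele 1 is the
whole-sample minor allele (ties broken by the lexicographically smaller
base); the simulator instead emits the derived allele as allele 1 with an
ancestral (outgroup) track, which D-statistics use for polarisation.
Missing genotypes are stored explicitly and never imputed at I/O time.

**Filters.** Sites are kept when minor-allele frequency (on non-missing
genotypes) ≥ 0.05 and at least ⌈0.5·n⌉ individuals are genotyped (defaults).
There is no analogue of a genotype-likelihood SNP p-value filter on called
genotypes; the simulator's segregating-site guarantee (minor allele count
≥ 1) stands in for it.  LD pruning computes pairwise-complete genotype r²
between sites within 20 kb on a chromosome and greedily removes the site
with the most edges at r² ≥ 0.5 until none remain, breaking ties by removing
the later position.

**PCA.** Sites are centred by 2p̂ and scaled by √(2p̂(1−p̂)); missing values
are imputed to the centred mean (zero); the individual×individual covariance
is eigendecomposed, with a deterministic sign convention (largest-magnitude
loading positive) and truncation to matrix rank with a warning.

**IBS and NJ.** IBS distance is the proportion of jointly called sites whose
single-allele calls differ; consensus mode maps genotypes ≥1 to the minor
allele (the deterministic heterozygote rule), random mode samples one allele
per individual per site from a seeded stream.  Neighbour joining is
Saitou–Nei with lowest-index tie-breaks; a negative branch is clamped to
zero and its excess moved to the sister branch so the joined distance is
preserved.

**F_ST.** The Hudson (1992) estimator per site, aggregated per window as a
ratio of sums (the aggregation recommended for two-population comparisons).
Windows are half-open [k·w, (k+1)·w) with w = 100 kb default and at least
500 usable sites; negative window values are retained so the signed-rank
test against zero is unbiased.

**Wilcoxon signed-rank.** Exact enumeration of all 2ⁿ sign patterns for
n ≤ 12 (tied ranks included; the distribution of W⁺ is symmetric because
flipping all signs maps W⁺ to total−W⁺); otherwise a normal approximation
with tie correction, continuity correction and an Edgeworth fourth-cumulant
term (κ₄ of r·Bernoulli(½) is −r⁴/8), which keeps the approximation within
~0.001 of the exact tail at n = 12.

**D-statistics.** One allele per individual per site is sampled from a
single seeded stream (so every quartet in a run sees the same calls), site
patterns are polarised by the per-site outgroup allele, and
D = (nABBA − nBABA)/(nABBA + nBABA) with a delete-one jackknife over 1-Mb
blocks for the SE and Z = D/SE.  Blocks without informative sites are
skipped.  The plain delete-one jackknife was validated against the replicate
standard deviation of D on simulated blocks in both sparse and
tree-dominated regimes (and agrees with the ratio-estimator linearisation);
a count-weighted variant was tried and rejected because it underestimated
the SE under strong per-block tree effects.  When nABBA + nBABA = 0, D is
undefined and flagged — note this necessarily includes genotypically
identical H1/H2 pairs whose sampled alleles coincide, since both patterns
require H1 ≠ H2; for such pairs D is zero in expectation, not identically.

**Topology test.** Every unordered individual triple is expanded into its
three (H1 < H2 | H3) arrangements; when H1 and H3 share a locality the pair
is re-labelled so the shared-locality pair sits on (H2, H3).  Classes:
*correct* (H1, H2 share a locality), *incorrect* (H2, H3 share one),
*within-locality* (all three share one).  Per class and locality grouping
the package reports the D and Z lists, signed-rank p-values of D and Z
against zero, the proportion of quartets with |Z| > 3, and the class-level
structure call: a one-sided signed-rank test of whether the class's |Z|
values exceed 3.  The D-against-zero p-values are reported for completeness
but are anticonservative as structure detectors, because quartets within a
class share individuals, genealogy and allele draws and are therefore
strongly positively correlated; simulation shows any-class rejection rates
of 60–75% under panmixia at nominal α = 0.05.  The |Z|-against-3 call is
properly conservative (null |Z| sits near 0.7) while retaining full power
under structure, and is the decision the pipeline draws conclusions from.

## Sexing and relatedness

Sex calls use the ratio of mean depth on X-linked scaffolds to mean depth on
autosomal scaffolds, length-weighted when scaffold lengths are known and
with ambiguous (X/Y-homologous) scaffolds excluded.  Bands are deliberately
wide with an abstention zone — female [0.8, 1.2], male [0.35, 0.65],
otherwise undetermined — rather than a single hard threshold, so noisy
profiles abstain instead of guessing.  The call is scale-invariant in
overall coverage.

Relatedness is the moment estimator
r̂ = mean over sites of (g_i − 2p̂)(g_j − 2p̂)/(2p̂(1−p̂)) with p̂ the
whole-sample allele frequency, skipping sites missing in either individual
or monomorphic in the sample, and requiring ≥ 100 usable sites.  The
estimator assumes allele frequencies are essentially known: with p̂ from a
small panel it is biased low (about −0.08 on a parent–offspring pair at 30
individuals).  The pedigree generator therefore defaults to 200 founders, a
reference-panel scale at which the bias is negligible; interpretation
anchors are 1 for duplicates/monozygotic twins, 0.5 for parent–offspring or
full siblings, 0 for unrelated pairs.

## Scaffolding

Mate-pair libraries default to 1, 2, 5, 8, 10, 15 and 20 kb inserts with
150 bp reads and 30× coverage per library; inserts are
Normal(insert, 0.1·insert) truncated to [read length, sequence length] (the
10% relative SD is this package's choice).  Pairs are emitted in outward
mate-pair orientation and normalised to genome-forward during placement,
which is exact 150-mer matching over both strands; reads matching zero or
several locations are discarded and counted.  Cross-contig pairs accumulate
links between the implied contig ends with gap estimate
insert − d₁ − d₂ (each read's distance to its linking end).

Greedy scaffolding accepts links by decreasing support when support ≥ 5, the
link is the strongest at both of its ends with the runner-up at most 0.7 of
it, neither end is already used, and no cycle forms; joined contigs are
concatenated with max(mean gap, 1) Ns, and output scaffolds shorter than
1 kb are dropped.  Because long-insert libraries also produce strong links
between *non-adjacent* contigs, the pipeline scaffolds hierarchically:
smallest insert first, each round re-placing that library's reads on the
current scaffolds — once neighbours are merged, a longer library's skip
links become intra-scaffold and are ignored.  This mirrors how multi-library
scaffolders are run in practice and is what achieves zero false joins on the
toy genome.

The genome fragmenter cuts at uniform positions subject to a minimum contig
length (default 800 bp).  Real assemblies are size-filtered, and the bound
is a resolvability limit: a contig shorter than the smallest insert minus
two read lengths (700 bp for a 1 kb library of 150 bp reads) can be skipped
entirely by every library, so no link-based scaffolder can place it
unambiguously.

## Test and calibration scales

The scientific checks run at desk scale, chosen once as realistic for a
small panel: mitochondrial calibration at n = 22, θ = 40, 16 kb over 200
replicates (E[π] = θ/L within 3 SE); topology-test null with 8 individuals
under panmixia labelled as four localities of two (50 replicates) and power
with two demes of two diploids at 4Nm = 0.1 (50 replicates); jackknife null
calibration with three demes of three diploids at 4Nm = 1 over 200 blocks
(100 replicates, |Z| > 3 in ≤ 1% of sister-pair quartets); scaffolding on a
100 kb genome in 20 contigs over 20 seeds.  Estimator identities (π, h,
Hudson components, IBS, ABBA/BABA counts) are checked exactly against
independent double-loop implementations on ~1000 random inputs, and the
coalescent engine is cross-checked against an independent simulator
(msprime) at matched scaling.

## Known limitations

- Genotype-level only: no genotype likelihoods, BAM/CRAM or beagle/glf
  input; equivalence with likelihood-based pipelines on low-coverage data is
  not claimed.
- The topology test's D-against-zero p-values should not be used as
  structure calls (see above); they are reported because both conventions
  exist in the field.
- The scaffolder has no gap closing, no read-error model, and exact-match
  placement only; it is a faithful toy of the link-evidence logic, not an
  assembler.
- The haplotype-network wildcard merge can, in principle, join two
  haplotypes that differ only where a third sequence is uncalled; merge
  order is deterministic (by name) so results are reproducible.
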