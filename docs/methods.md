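# Methods

`mlstpop` analyses six-locus MLST data for *Bifidobacterium longum* — allele
and sequence-type (ST) assignment, goeBURST clustering, minimum spanning
trees, diversity/selection statistics, recombination detection, and
distance-based phylogeny — and ships a synthetic population generator so the
whole pipeline can be exercised and scored without any external data. This
note records the models, the defaults and why they were chosen, the
numerical conventions, and the known limitations.

## The typing scheme

The scheme is the six-locus *B. longum* set (*clpC*, *fusA*, *ileS*,
*purF*, *rplB*, *rpoB*) with trimmed fragment lengths 600, 664, 487, 574,
355 and 497 bp (3,177 bp concatenated). Canonical locus order is
alphabetical, and all concatenated coordinates are 0-based half-open in that
order.

Raw sequences longer than the scheme length are trimmed by an anchor-free
window search: the window of scheme length with the smallest Hamming
distance to the locus reference allele is kept (leftmost wins ties), and a
best window below a configurable identity floor (default 0.80) is rejected
as a locus mismatch. This replaces manual alignment-based trimming with a
deterministic rule that is adequate for high-identity housekeeping
fragments.

Allele numbers and ST numbers are assigned in first-seen input order,
contiguously from 1. The labels are arbitrary; every downstream statistic
is invariant under relabeling (tested by randomized relabeling). A catalog
may be preloaded from an existing allele database and extended with novel
alleles, so both de-novo and database-seeded typing are supported.
Ambiguous bases abort an allele call rather than minting a spurious allele.

`LocusScheme.default()` carries synthetic reference alleles (fixed-seed
random sequences at 62.5% GC); they anchor trimming for simulated data.
For real data, supply true reference alleles via
`LocusScheme.from_references` or the CLI's `--ref-fasta`.

## The synthetic population

The generator emulates a bacterial species structured into a few deeply
diverged lineages (the three *B. longum* subspecies), with neutral point
mutation within lineages and rare imports of donor DNA from other lineages:

1. A latent root sequence is drawn i.i.d. per site with
   P(G or C) = `gc_target`.
2. Each lineage ancestor flips each root site independently with
   probability δ/2 (`lineage_divergence`/2) to a uniformly chosen different
   base. Any two ancestors therefore differ at ≈δ of sites (to first
   order), and the true lineage topology is a star — every lineage is
   monophyletic, as the subspecies are in practice. (Deriving the other
   ancestors from the first lineage's ancestor instead would make that
   lineage paraphyletic by construction and no tree method could recover
   three monophyletic groups.)
3. Each isolate copies its ancestor and substitutes each site independently
   with probability θ (`per_site_mutation_rate`), uniformly over the three
   other bases (Jukes–Cantor-like, no selection — deliberately untuned to
   the K2P/NG86 machinery downstream).
4. With probability `recombination_prob` an isolate receives one
   `fragment_length`-bp fragment copied from a uniformly chosen *other*
   lineage's ancestor at a uniform position (at most one event per isolate,
   which keeps the ground truth unambiguous).

Defaults: 3 lineages × 20 isolates, θ = 0.002/site, δ = 0.02/site,
p_rec = 0.02, fragment 213 bp, GC 0.625, the published locus lengths.
These give per-locus π of the order 10⁻² and a dataset in which almost
every isolate is its own ST — the diversity regime reported for the
organism — at a size a laptop processes in seconds. Everything is
reproducible from the single `seed`; the returned `SimulationTruth` holds
lineage labels, ancestors, implanted segments and realized mutation counts.

What the generator does *not* emulate: coalescent genealogy within
lineages (isolates radiate independently from their ancestor), indels,
codon-aware or selective mutation, within-host dynamics, and
recombination between isolates of the same lineage. Tests passing on this
generator therefore show correctness of the algorithms under a clean,
known-truth population model — not performance on any particular real
dataset.

## Population structure

Profile distance is the number of loci (0–6) at which two STs carry
different alleles. Groups are connected components of the graph linking ST
pairs at distance ≤ level: level 1 (single-locus variants) gives clonal
complexes, level 2 (double-locus variants) gives BURST groups; both levels
are always available because both conventions are in use. The founder of a
group maximizes the goeBURST tie-break chain — SLV count, then DLV count,
then isolate frequency, then smallest ST number — with all variant counts
taken against the whole dataset.

The minimum spanning tree is built with Kruskal's algorithm over all ST
pairs, ordered by weight and then by the same goeBURST chain (higher
maximum endpoint SLV count, DLV count, isolate frequency, then smallest ST
pair). Because the edge ordering is total and deterministic, the traversal
(Prim vs Kruskal) cannot change the total weight, which the test suite
pins to the exhaustive-enumeration minimum on all datasets with ≤7 STs.

## Diversity and selection statistics

Per locus and for the concatenation the package reports allele counts,
segregating sites S, pooled GC content, nucleotide diversity π (mean
pairwise Hamming distance per site, computed by default over isolates, with
an allele-weighted option since either convention appears in published
tables), Tajima's D, and dN/dS.

Tajima's D follows the 1989 constants exactly
(a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ are all exposed in the result object for
auditing); D is an `NA` sentinel when S = 0 and an error below four
sequences. No significance stars are attached: the beta-distribution
approximation used by common software is out of scope, and an honest
p-value would need coalescent simulation.

dN/dS uses Nei–Gojobori (1986) pathway counting: per-codon synonymous site
fractions, equal-weight enumeration of minimal substitution pathways
between differing codons, averaging of site and difference counts over all
sequence pairs, and Jukes–Cantor correction of the proportions. This is a
deliberate substitution for codon-model maximum likelihood: it is
closed-form, exactly testable against an independent brute-force oracle,
and agrees closely with ML at the low divergences (π ≤ 0.02) typical of
housekeeping fragments. Conventions: the standard genetic code (code 11
agrees with code 1 for these fragments); reading frames default to offset 0
with trailing partial codons truncated (the published fragment lengths are
not codon multiples and no frame is stated — offsets are
scheme-configurable); codon columns containing a stop in any sequence are
excluded with a warning (keeping pairwise site counts comparable);
substitutions *to* stop codons count as nonsynonymous; dN/dS is `NA` when
dS = 0, and 0 when there is synonymous but no nonsynonymous divergence.

## Recombination

**PHI-style test.** The statistic is the mean 0/1 incompatibility over
pairs of parsimony-informative sites whose alignment positions are within
`w` bp (default 100). Two sites are incompatible when no single genealogy
explains both without homoplasy, decided by acyclicity of the bipartite
graph joining the observed states of the two columns — exactly the
four-gamete test for biallelic sites, and the correct generalization for
multi-allelic ones (verified against exhaustive small-parsimony search over
all trees). Significance permutes the assignment of informative columns to
their positions (1,000 permutations by default, add-one p-value estimator,
seeded). Two variants from the originally published test are deliberate:
the 0/1 score replaces the refined multistate score (brute-force testable),
and the one-sided rejection direction is *elevated* nearby incompatibility,
which is the direction in which donor-fragment imports concentrate signal.
The window is measured in alignment positions; measuring it in
informative-site ranks would make the statistic permutation-invariant
whenever fewer than `w` informative sites exist, leaving the test without a
null distribution. Calibration under clonal simulation (single lineage,
n = 20, θ = 0.012 → ≈27 informative sites) holds the 5% level to within
[0.01, 0.10]; power is demonstrated at p_rec = 0.5 with δ = 0.10 donors.

**Segment scanner.** A transparent clustered-SNP method, not a
reimplementation of model-based recombination inference. Within each
labeled subgroup (typically one isolate or ST, scanned one lineage or
population at a time so the complement consensus approximates the clonal
background), SNPs are positions where the subgroup consensus differs from
the complement consensus (column majority, ties broken alphabetically).
Every window of `window_bp` (default 200, step 1) is scored by the binomial
tail probability of its SNP count under the subgroup's alignment-wide SNP
rate; windows below `score_cutoff` (default 10⁻⁶) are merged, and each
merged region is trimmed to its densest SNP cluster (maximum gap
`window_bp`/2), which strips isolated background SNPs from the flanks. In
the recovery experiments (δ = 0.10, θ = 0.002, one 213-bp implant) a true
fragment carries ≈20 diagnostic SNPs and is recovered with Jaccard ≥ 0.5
in ≥90% of replicates with ≤5% false-positive replicates; at δ ≲ 0.05 a
fragment carries too few SNPs to clear a 10⁻⁶ cutoff reliably, which is the
method's detection floor, not a bug.

**r/m.** `r_over_m_simple` partitions segregating sites by membership in
any reported segment and takes the inside/outside ratio (0 with no
segments, infinite sentinel when nothing falls outside). It is a
descriptive SNP-partition summary, intentionally labeled to avoid
conflation with model-based r/m estimators, and is validated only for
monotonicity in the simulated recombination rate.

## Phylogeny

Kimura two-parameter distances count transition (A↔G, C↔T) and
transversion difference fractions P and Q, with
d = −½ ln((1−2P−Q)√(1−2Q)); saturation (non-positive log argument)
returns a sentinel rather than a number. Gaps and ambiguity codes are
rejected upstream rather than silently deleted pairwise.

Neighbor joining is the Saitou–Nei Q-criterion agglomeration with a
deterministic tie-break (smallest active-index pair; exact float ties
resolve row-major). Negative branch lengths are clamped to zero with the
deficit moved to the sister branch (configurable to keep raw values).
Consistency on additive matrices — exact topology and patristic distances
to 10⁻⁹ on random trees up to 12 leaves — is part of the test suite, as is
agreement with an independent NJ implementation.

Trees are computed on one representative sequence per ST by default
(per-isolate trees are available). Bootstrap support resamples columns
with replacement, reruns NJ per replicate, and reports the percentage of
replicates containing each internal bipartition of the point tree;
degenerate replicates (identical sequences or saturated distances) are
skipped, logged, and kept in the denominator. The conventional 1,000
replicates is the default; tests use ≤100 for speed. A group is
monophyletic when some edge of the unrooted tree bipartitions exactly its
leaves from the rest.

## Problem sizes used in tests and the acceptance script

Oracle checks run at the sizes where exhaustive enumeration is exact
(≤7 STs for the MST, ≤12 leaves for NJ, ≤6 distinct rows for two-site
compatibility); simulation-based rates use 20–200 replicates at 20–60
isolates on the full 3,177-bp scheme. These sizes were chosen so the whole
suite re-runs in well under a minute of CPU per experiment while keeping
Monte-Carlo error far from each decision boundary.

## Known limitations

- No maximum-likelihood or Bayesian phylogenetics, split networks, or
  model-based recombination inference; those are different tools.
- The PHI variant's p-values are not numerically comparable to the
  published software's refined-score p-values.
- The scanner detects only imports that are diverged enough to produce a
  local SNP cluster above the binomial cutoff.
- Tajima's D and dN/dS sentinels (`NA`) propagate into output tables;
  downstream consumers must expect them.
- Typing real data requires true reference alleles for trimming; the
  default scheme's synthetic references are anchors for simulated data
  only.
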