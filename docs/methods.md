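# Methods

This note documents the models and procedures implemented in `fairylit`,
the parameter defaults and why they were chosen, the design decisions made
where the design was genuinely open, and the limits of what the synthetic
benchmarks demonstrate.

## Distances

Pairwise divergence is the uncorrected *p*-distance: mismatches divided by
compared sites. Sites holding a gap or any non-ACGT symbol (IUPAC
ambiguity codes, N) in *either* sequence are excluded pair by pair
(**pairwise deletion**). Ambiguity codes are treated as non-comparable
rather than as partial matches; this keeps the distance deterministic and
matches the behaviour of the distance tools commonly used for
intra-/inter-specific divergence tables. Complete deletion (drop a column
for every pair if any row is ambiguous there) is available as a switch.
A pair with no comparable site is assigned distance 0 with a warning.

The Jukes–Cantor correction d = −¾·ln(1 − 4p/3) is defined for
p < 0.75 and raises a saturation error beyond. Delimitation defaults to JC
distances; congruence statistics and reports use *p*-distances, both
selectable. Reported percentages are rounded half-up to two decimals,
matching the print precision of a species table.

## Barcode-gap (ASAP-style) partitioning

Single-linkage agglomeration over the pairwise distances yields a nested
chain of candidate partitions, one per distinct merge height, from
all-singletons to a single cluster. Each candidate (the one-cluster root
excluded — it exhibits no gap) is scored by two ranked statistics:

**Relative gap width.** For a partition with maximum intra-group distance
d_low and minimum inter-group distance d_high, the width is
(d_high − d_low)/max(d_low, ε) with ε = 10⁻⁶ guarding the division when
the partition has no intra pairs (the ε-capped value acts as a sentinel
for gap-from-zero partitions). The gap location reported is d_low.

**Panmixia probability.** The evidence *for* a candidate partition is that
merging its groups any further would be inconsistent with a single
randomly mating population. For each merge in the dendrogram, the merged
group's deepest split is tested: θ is estimated as the mean pairwise
distance within the two subgroups being joined, and the observed maximum
pairwise distance of the merged group is compared with the maxima of
`reps` (default 1000) simulated samples from a Kingman coalescent, where
the maximum pairwise distance of a sample of size *n* is θ·T_MRCA(n),
T_MRCA(n) = Σ_{k=2..n} Exp(k(k−1)/2) in units where the expected pairwise
coalescence time is 1. The probability is the fraction of simulated
maxima at least as large as the observed one. Two corner cases: a group
whose distances are all zero has probability 1 (no split signal), and
when the subgroups carry no internal pairs θ falls back to the mean
within-cluster distance of the partition being evaluated — without any
within-group diversity the test has no power and the probability is
defined as 1. A candidate partition's probability is the product of the
per-merge probabilities at the next distinct merge height (the merges
that would destroy it), floored at machine epsilon.

Candidates are ranked by probability ascending (an improbable next merge
supports the partition) and by width descending; the final score is the
mean of the two competition ranks, lower better, with ties broken by
larger width and then fewer clusters. The top `asap_top_k` (default 3)
candidates are returned. This scoring reproduces planted partitions on
gap-mode benchmarks (see below) but is not a byte-for-byte
re-implementation of any particular released tool; on real data the exact
candidate ranking may differ from other barcode-gap programs.

Delimitation runs on the haplotype-collapsed matrix — duplicate sequences
carry no delimitation signal — and partitions are expanded back to
specimens afterwards, which also makes within-haplotype distances exactly
zero by construction.

## Refined single linkage (RESL-style)

Single-linkage pre-clustering connects every pair at distance ≤ 2.2%
(`resl_threshold`). Each pre-cluster of size ≥ 3 is then refined by Markov
clustering (MCL) of its similarity graph: nodes are sequences, edges join
pairs at distance ≤ the threshold (the same links that chained the
pre-cluster) with weight 1 − p (an exponential kernel e^(−d/0.01) is
available for sharper contrast). MCL adds self-loops equal to the maximum
incident edge weight, normalises columns, and alternates expansion
(matrix squaring) with inflation (entry-wise power 2.0 and renormalising),
pruning entries < 10⁻⁵, until the maximum entry change is below 10⁻⁶ or
100 iterations (non-convergence returns the current interpretation with a
warning). Clusters are the connected components of the limit matrix's
support. Inflation 2.0, expansion 2, and the pruning/tolerance values are
the standard MCL defaults; the reference BIN-clustering service does not
publish its internal parameters, so cluster counts on real data should be
treated as calibration-dependent. Because MCL runs within pre-clusters
only, the result is always a refinement of the 2.2% single linkage.

## LIT congruence engine

The baseline is the candidate partition with the fewest clusters (ties:
lowest score). A baseline cluster is **stable** if exactly the same
specimen set appears as a cluster in every other candidate partition —
both finer and coarser. A cluster is **potentially incongruent (PI)** if
it is unstable and/or its *maximum* intra-cluster p-distance exceeds
`pi_pdist_threshold` (default 1.5%). The maximum (not the mean) is used
because a single divergent lineage inside a cluster is precisely the
signal the flag should catch, and reported tables pair the mean with the
maximum for exactly this reason.

Specimen selection per cluster: (1) the haplotype pair with the largest
p-distance (ties broken by the lexicographically smallest specimen-id
pair; monomorphic and singleton clusters contribute their single
haplotype); (2) PI clusters additionally cover every haplotype carried by
more than `dominant_haplotype_fraction` (default 20%) of the cluster's
specimens; (3) up to two females per chosen haplotype, males only when the
haplotype has none; (4) a males-only haplotype triggers a supplement of up
to two females from the nearest haplotype that has any, since
identification keys mostly address females. PI clusters therefore never
receive fewer specimens than they would as non-PI.

Reconciliation walks the baseline clusters: if all validated specimens
agree on one morphospecies the cluster is **congruent**; if they disagree,
the ranked candidates are searched in order for the first partition whose
restriction to the cluster separates the labels into homogeneous
sub-clusters (**split**; unvalidated specimens inherit their sub-cluster's
label — the natural reading of validating only a subset); if none does,
the cluster is kept whole and **unresolved** with an empty label —
deliberate conservatism, since over-lumping is easier to repair later than
over-splitting. Labels with "near" confidence count as distinct
morphospecies strings from the species they approach; "unidentified"
labels are uninformative and excluded from homogeneity tests. Finally,
clusters sharing an identical *confirmed* label are merged (**lumped**),
within genus-hint groups when hints exist, so a shared species name never
merges across genera.

## Haplotype networks

Identical (uppercased) aligned sequences collapse to one haplotype; gap
characters are significant. Haplotype ids are assigned by descending
abundance with sequence-string tie-breaks, so they are independent of
input order. Network edges weigh the integer number of base differences
(pairwise deletion), matching the hash-mark convention of haplotype
figures. The strict minimum spanning tree uses Kruskal with edges sorted
by (weight, haplotype-id pair) — reproducible under any input
permutation. The `msn_with_ties` variant also keeps every non-tree edge
whose weight equals the maximum weight on the tree path between its
endpoints, showing the alternative equally short connections that pure
MSTs hide. Nodes carry specimen counts and a cluster colour key from any
supplied partition.

## Barcode caller

The read construct is spacer (1–4 bases) + 5-bp tag + degenerate primer
(BF1 forward, C_LepFolR reverse) + insert. Demultiplexing requires an
exact tag match at one of the spacer offsets (no mismatches; a rough
primer match downstream guards against chance 5-mers). Primer trimming
allows five mismatches with at least five bases of overlap; 3′ ends are
quality-trimmed with a sliding-minimum window of 4 at Q20 (window width is
unstated in typical protocols; 4 is common practice), and reads under 250
bases are dropped. Pairs are merged at the overlap maximising matches with
a mismatch rate ≤ 10%, disagreements resolving to the higher-quality
base. Merged reads are clustered by greedy, abundance-sorted centroid
clustering at 98% identity with ≥ 250 bases of overlap — a deterministic
desk-scale stand-in for interactive de-novo assembly — and each cluster's
majority-rule consensus is extracted. The largest on-target cluster is the
bin's call; additional clusters are flagged `ambiguous_multi`
(heteroplasmy or cross-contamination candidates); calls under 10 reads
are `low_coverage`. The pseudogene screen translates the consensus under
the invertebrate mitochondrial code in the frame (of three) minimising
internal stops — the amplicon does not encode its frame — and flags any
internal stop, or any length deviating from the 316-bp target by a
non-multiple of three, as a NUMT. An optional reference profile marks
clusters below 80% identity to it as `off_target`; taxonomic BLAST
identification is out of scope.

## Synthetic data

`simulate_community` plants a known truth: species founders are mutated
copies of a stop-free random coding root, rejection-sampled (≤ 10,000
proposals) so every founder pair lies inside `inter_divergence_range`
(default 4.5%–27%); haplotypes mutate each founder within
`intra_divergence_max` (default 1.5%), with per-subclade haplotype
richness scaling as ~2.6·√n so large clusters carry many more haplotypes
than small ones; mutations are substitution-only (indel-free minibarcodes
keep the alignment trivial) and never create in-frame stops, so clean
barcodes always pass the pseudogene screen. Abundances follow a geometric
(default) or lognormal rank-abundance model with every species at ≥ 1
specimen. Cryptic complexes give a species a second subclade at a stated
depth (≤ 11%). Sexes are Bernoulli with `sex_ratio`. The same seed gives
byte-identical output.

The `paper_like_spec` preset emulates a survey of 2098 specimens across
45 species with a heavily skewed abundance distribution (largest species
~900 specimens), a ~10.7% cryptic complex inside the dominant species and
a second mid-depth complex — producing ~350 unique haplotypes and
intra-cluster divergences up to ~11–12%.

`simulate_reads` emits one plate (≤ 96 tag combinations) of paired tagged
reads with configurable depth, per-base error rate, and planted artefacts:
NUMT amplicons (one-base deletion plus an in-frame stop, so the length
gate fires deterministically), shuffled-codon off-target reads, and a
second ~4%-divergent variant for heteroplasmy. `morpho_oracle` returns
the true species label with probability 1 − error_rate and can mark males
unidentifiable.

**What the benchmarks do and do not show.** The generator produces clean
barcode gaps by construction in gap mode, substitution-only variation and
a perfectly calibrated oracle; recovery of the planted partition under
these conditions demonstrates the internal consistency of the pipeline —
that the scoring, refinement and reconciliation logic find structure that
is genuinely there — not that the methods resolve real communities where
gaps overlap, NUMTs escape the stop-codon screen, or morphology is
ambiguous. Cryptic-complex presets probe the flagging machinery (deep
substructure must be caught by the PI criteria) but real cryptic diversity
may lack any barcode signature.

## Numerical and procedural choices

* Seeds are explicit everywhere; one `rng_seed` in the config drives the
  panmixia simulations, and generator seeds live in the community spec.
* Competition ("1224") ranking for the partition scores; deterministic
  tie-breaks everywhere a sort could be ambiguous (documented per module).
* The coalescent test uses `reps = 1000` by default; below 100 replicates
  a warning is emitted.
* Distance matrices are dense float64; a 2098-specimen survey needs
  ~35 MB and computes in a few seconds. Benchmarks in the test suite use
  200-specimen communities (40 seeds) and a 96-bin plate, sized so the
  whole suite runs in well under a minute on one CPU.

## Known limitations

* The barcode-gap scoring is a faithful implementation of the
  gap-width-plus-panmixia idea, not a clone of any released tool; exact
  candidate rankings on real datasets may differ.
* The BIN-service's refinement parameters are unpublished; the MCL
  defaults here are the community-standard ones and real-data cluster
  counts should be treated as calibration exercises.
* Multiple sequence alignment is consumed, never produced; inputs are
  assumed aligned (equal-length minibarcodes make this near-trivial).
* Stability is assessed against the ranked gap candidates only; the
  refined-single-linkage partition can be included by passing it
  explicitly to `assess_pi`.
* The morphology side is an input (labels), not a model: the package
  never infers morphospecies.
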