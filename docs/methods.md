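# Methods

## The pooled-sample ("metagenome") view

All barcode sequences of one regional catch are analyzed together, without
separating species. The sample is assumed to be a pre-aligned, equal-length
set of COI fragments with species labels; alignment and primer trimming
happen upstream. Under this view, haplotype and nucleotide diversity are
community-level quantities: they mix within- and between-species variation
deliberately, with the between-species component dominated by the most
divergent species pairs and the sample weights set by the catch-proportional
sampling design.

## Estimators

**Haplotype collapsing.** Exact string identity over {A,C,G,T}. A sequence
containing N or `-` merges into an existing haplotype only when it is
identical at all mutually unambiguous sites to exactly one of them;
otherwise it stays distinct. Unambiguous sequences are processed first so
an ambiguous read never absorbs a cleanly determined state. This is a
convention: merging into "any compatible" haplotype would undercount k,
counting every ambiguous read as new would overcount it.

**Haplotype (gene) diversity.** Hd = n/(n−1) · (1 − Σ pᵢ²) with Nei's
(1987) sampling variance

    V(Hd) = 2/(n(n−1)) · [ 2(n−2)(Σpᵢ³ − (Σpᵢ²)²) + Σpᵢ² − (Σpᵢ²)² ].

**Nucleotide diversity.** π is the mean over all C(n,2) sequence pairs of
(differences / compared sites), compared sites being those where both
sequences are unambiguous (pairwise deletion). Its standard deviation uses
Nei's (1987) total variance

    V(π) = (n+1)/(3(n−1)L) · π + 2(n²+n+3)/(9n(n−1)) · π²,

the convention of DnaSP. Identical sequences are grouped before the pair
loop, so cost scales with the number of distinct sequences rather than n²;
a pooled sample of thousands of reads with tens of haplotypes is cheap.
A pair with zero comparable sites is an error rather than a silent skip.

**Translation.** Vertebrate mitochondrial code (NCBI table 2; TGA = Trp,
AGA/AGG = stop, ATA = Met). Barcode amplicons do not start in frame
universally, so the default reading frame is auto-detected as the unique
frame with no internal stop over *all* haplotypes of the alignment;
ambiguity (none or several stop-free frames) is an error and the frame
must then be forced. Codons containing N or a gap translate to X; a
trailing partial codon is dropped. k/P ≥ 1 always, since translation is a
function of the DNA sequence.

## Catch composition

Dominant species are the minimal descending-tonnage prefix whose
cumulative share of the **total** catch reaches the threshold (default
0.65). The total may be passed explicitly so that an aggregated "Others"
tonnage stays in the denominator without competing as a species. The
comparison is ≥, ties in tonnage keep input order.

Sample allocation uses largest-remainder (Hamilton) apportionment over the
within-dominant-set renormalized fractions; remainder ties go to the
larger fraction, then input order; every dominant species receives at
least one sample, any deficit taken from the largest count. The published
sampling designs this mirrors were only approximately proportional, so the
generator also accepts explicit per-species counts.

The Shannon index uses the natural logarithm and is computed on the
realized sample composition (per-species sequence counts), not on raw
tonnage: the sample is what was actually sequenced, and reconstructed
sample compositions — not tonnage fractions — reproduce published H values
of this study design. The mean trophic level is unweighted across the
dominant species with (n−1) sample variance (0 for a single species);
catch-weighted versions are available behind a flag since published
trophic means rarely state their weighting.

## Taxonomic distinctness

Both indices live on a fixed six-rank tree (root → phylum → class → order
→ family → genus → species) with every edge weighted 100/6, so the longest
species-to-species path (different phyla) scores exactly 100:

* ω(i,j) = (ranks ascended to the lowest common taxon) × 100/6;
* TTD = Σᵢ [Σ_{j≠i} ω_ij/(S−1)];
* sΦ⁺ = (100/6) × (number of distinct taxa across the six ranks among the
  selected lineages) — Faith-style total path length with the root edge
  above each distinct phylum included.

Two deliberate choices: the step weight is *fixed* rather than
re-standardized per dataset (keeping values comparable across
communities), and sΦ⁺ is implemented as total path length. The latter is
sometimes verbally described as a variance of pairwise path lengths in the
literature around these indices; the reference values this package
reproduces are path lengths (7 edges × 100/6 = 116.7 for two congeners,
16 × 100/6 = 266.7 for the four-species marine set), so the path-length
reading is the one implemented.

ω is ultrametric by construction; TTD strictly grows when a species from a
new phylum is added; adding a congener adds exactly 100/6 to sΦ⁺. These
invariants are property-tested.

## Median-joining network

The network starts from the ε-relaxed minimum spanning network over the
haplotype states (ε = 0 by default: the union of all minimum spanning
trees; an edge of weight w enters iff its endpoints are not connected by
edges of weight < w − ε). For every triple whose three pairs are all
linked, the site-wise majority consensus is proposed as a median state;
new medians are added and the network rebuilt until stable. Median nodes
of degree ≤ 1, and degree-2 medians that lengthen the connection between
their neighbours, are pruned. Ties at a site (all three states distinct)
generate no median — a conservative choice. Characters are the aligned
nucleotide columns, equally weighted; columns with any ambiguity in any
haplotype are excluded and reported on the graph. Determinism comes from
lexicographic processing order, so the output is invariant to input
relabelling.

## Protein distances, NJ, bootstrap

The p-distance is the proportion of differing sites with pairwise deletion
of non-standard residues. The JTT distance maximizes the likelihood
Σ N_ab log(π_a P_ab(t)) in t, with P(t) = exp(Qt) from the Jones–Taylor–
Thornton empirical rate matrix (eigendecomposition, normalized to one
expected substitution per site per unit time), optionally averaged over
four equal-probability discrete-gamma rate categories (category rates are
bin means, mean 1) at a user-supplied shape. The optimizer is bounded
(t ∈ [1e-8, 30], |Δt| ≈ 1e-5); the implementation agrees with an
independent R implementation of the same estimator to ~2e-4 on frozen
fixtures. Model-shape estimation (which gamma shape to use) is a user
input, not performed here.

Neighbor joining follows Saitou–Nei with the Studier–Keppler Q criterion;
Q ties break on the lexicographically smallest label pair, making the tree
deterministic. Negative branch-length estimates are clamped to zero with a
warning (the MEGA convention). The tree is unrooted (trifurcating root).
Bootstrap resamples alignment columns with replacement; support is the
percentage of replicates whose NJ tree contains each internal split of the
point tree; replicates that lose all comparable sites for some pair are
skipped and counted. NJ on an exactly additive matrix reproduces the
generating tree's path lengths — this is the oracle test.

## Synthetic communities

The generator emulates: (i) a shared ancestral coding sequence mutated
along the taxonomy, each branch drawing fresh codon positions so pairwise
species distances are exact branch-sum Hamming distances and strictly
rank-consistent (species branches carry ⌈divergence/2⌉ mutations, every
higher rank adds one more per branch); (ii) per-species haplotype sets in
which each haplotype draws its own codons — synonymous-only by default,
with a configurable number of haplotypes carrying one amino-acid-changing
substitution each, so the designed polypeptide count is exact;
(iii) catch-proportional sampling via the allocator (or explicit counts)
with a geometric (default ratio 0.5) or uniform haplotype frequency
profile, the geometric default mirroring the skewed frequency spectra of
real barcode surveys. All sequences are stop-free in frame 1 by
construction. One PRNG stream drives a dataset; identical seeds give
byte-identical files.

Defaults (barcode length 300, minimum inter-species divergence 20 sites,
n = 40 sequences per community, 3 haplotypes per species) are chosen to
resemble a partial COI barcode survey of a small dominant-species set.

What the generator does **not** emulate: coalescent genealogies within
species, indels and alignment error, sequencing error, recombination
(irrelevant for mtDNA), base-composition and codon-usage bias, and
saturation at deep divergences. Passing parameter-recovery tests therefore
shows the estimators are correct on cleanly structured data, not that real
samples of n = 40 estimate community diversity precisely — the sampling
variance visible in the Hd/π standard deviations is the honest statement
of that uncertainty.

## Test and verification sizes

Oracle equivalence for π uses ≤ 8 sequences of length ≤ 20 against a
brute-force double loop; network bounds use ≤ 5 binary-state haplotypes of
length 6 against brute-force Steiner enumeration; TTD uses ≤ 6 species
against the double-loop definition; parameter recovery draws n = 2000
sequences from a three-species design and requires Hd and π within 2% of
their closed-form expectations under the designed sampling distribution.
The whole suite runs in a few seconds on one CPU.

## Known limitations

* The ambiguity-merge rule and the conservative median rule are
  conventions; other published tools make different choices, so k and
  median-node counts can differ on ambiguous or tie-rich data.
* sΦ⁺ and TTD assume a complete, internally consistent six-rank taxonomy;
  missing ranks are not interpolated.
* The pairwise JTT ML distance ignores among-pair correlation; it is a
  distance, not a joint model fit.
* Pooled Hd/π on a 40-sequence sample carry large sampling variance; the
  profile reports standard deviations but no confidence intervals.
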