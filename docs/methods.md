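# Methods

## Composition-vector distance

A DNA sequence of length *L* is summarized at word size *K* by the counts
*n*(s) of every K-string s among its *L* − *K* + 1 sliding windows;
frequencies are *p*(s) = *n*(s)/(*L* − *K* + 1). The distance between two
sequences is *D* = (1 − *C*)/2 where *C* is the cosine between the two
frequency vectors. With raw frequencies every entry is nonnegative, so
*C* ∈ [0, 1] and *D* ∈ [0, 0.5]; *D* = 0.5 means the two sequences share
no K-string at all.

Two modes are provided:

* **raw** (default) — the cosine of the raw frequency vectors. This is the
  variant the rest of the pipeline is calibrated against.
* **background** — the classic Markov-normalized CV: each entry becomes
  (*p*(s) − *p*₀(s))/*p*₀(s) with
  *p*₀(α₁…α_K) = *p*(α₁…α_{K−1}) · *p*(α₂…α_K) / *p*(α₂…α_{K−1}),
  the (K−2)-order Markov expectation estimated from the same sequence.
  Entries with *p*₀ = 0 are dropped (treated as 0); an observed count of 0
  with *p*₀ > 0 yields −1. Requires K ≥ 3. On a homopolymer the normalized
  vector is identically zero and the correlation is undefined; the
  pipeline raises rather than guessing.

Degenerate and messy inputs: windows containing any non-ACGT symbol
(N, IUPAC ambiguity codes) are skipped, but the frequency denominator
remains *L* − *K* + 1 — the frequencies of a sequence with ambiguities sum
to slightly less than 1 rather than being renormalized. Gap characters in
pre-aligned FASTA exports are stripped on ingestion (the method is
alignment-free). Sequences are not reverse-complement-canonicalized:
barcoding amplicons arrive in a fixed orientation, and folding strands
would discard signal.

Vectors are stored sparsely, keyed by 2-bit-packed integers, so K up to 31
fits in int64 and no 4^K array is ever allocated. All-pairs distances for
one locus are computed as a single sparse row-normalized matrix product
(CSR, cosine = A·Aᵀ); the pairwise entry point accumulates the dot product
over the sorted key intersection, which makes C(a, b) == C(b, a)
bit-for-bit. Identical vectors short-circuit to C = 1 exactly so that
D(a, a) == 0 without square-root round-off.

## Length-weighted combination across loci

Per-locus matrices, each at its own K, are combined per pair of taxa
(i, j) with weights

  w_g(i, j) = (L_g^i + L_g^j) / Σ_h (L_h^i + L_h^j),

i.e. each locus is weighted by its share of the pair's summed sequence
length. The weights sum to 1 per pair, are independent of K, and make the
combined entry a convex combination of the per-locus entries (so it stays
within their min/max and within [0, 1]). The formula lives in one function
(`pair_weights`) so an alternative weighting is a one-line change; the
vectorized all-pairs form (`weight_matrices`) is tested to agree with it
exactly. The defining equations of the published weighting are available
only as figure images in the source we reconstructed them from; the form
above is the reading consistent with every stated property (pairwise,
length-ratio based, sums to one, K-independent) — callers who need a
different algebra can swap `pair_weights`.

Missing loci (non-strict datasets): a locus absent from either taxon of a
pair gets weight 0 and the remaining weights renormalize; a pair sharing
no locus is an error. Strict mode (default) requires a complete
taxon × locus table up front.

## Neighbor joining

Textbook Saitou–Nei NJ, O(n³): join the pair minimizing
Q(i, j) = (n − 2)d(i, j) − r_i − r_j, attach limbs
l_i = d(i, j)/2 + (r_i − r_j)/(2(n − 2)), reduce with
d(u, k) = (d(i, k) + d(j, k) − d(i, j))/2, and finish with a trifurcating
root whose three limbs come from the closed-form three-taxon solution. At
n = 2,000 this is minutes of work; no heuristic variants are needed at
barcoding scale. Ties in Q break to the smallest (row, column) pair, so
runs are bit-reproducible; input asymmetry beyond 1e-9 is rejected.
Negative branch lengths (possible on non-additive input) are kept as
produced; `clamp_negative` zeroes a negative limb and moves the deficit to
its sister, which preserves each cherry's summed length. On additive
matrices NJ provably recovers the generating tree; the test suite checks
RF = 0 and branch lengths to 1e-6 on random trees up to n = 32, and the
topology against scikit-bio's independent NJ.

Newick output uses 10 significant digits and quotes labels containing
metacharacters; on reading, unquoted underscores are kept literal
(sequence ids are underscore-delimited) rather than converted to spaces.

## Grouping effectiveness

"Grouped" is formalized as an exact bipartition of the unrooted tree — a
leaf set separated from everything else by removing one edge, equivalently
a clade under some rooting. NJ output is unrooted and no rooting procedure
is assumed, so both metrics are rerooting-invariant by construction
(bitset-per-node implementation; an edge-removal enumeration serves as the
test oracle).

* Sequence-level: N₁ counts sequences whose genus has ≥ 2 species or whose
  species has ≥ 2 sequences. A sequence succeeds when every applicable
  condition holds — genus exclusive if the genus condition applies AND
  species exclusive if the species condition applies. The defining
  sentence conjoins both requirements but is genuinely ambiguous; the
  lenient either/or reading is one flag away (`--or-semantics`).
* Species-level: N₂ counts species with ≥ 2 sequences; a species succeeds
  iff its leaf set is exclusive.

Singletons (only sequence of its species and genus-with-one-species) are
excluded from the denominators but remain in the tree, where they can
still break other groups — large reference sets with many single-taxon
sequences therefore score low, which is a property of the data, not a bug.

## Best-K scan

For each K in [6, 20] (inclusive; default range) the single-locus pipeline
runs end to end and is scored with the sequence-level metric; the best K
is the argmax, ties to the smallest K. K values exceeding the locus's
shortest sequence length minus one are skipped with a warning. The scan is
the honest but slow protocol; the shipped presets (matK = 14, rbcL = 14,
trnH-psbA = 8) shortcut it for the three canonical plant loci and are
advisory defaults, not claims about new data.

## Synthetic data generator

The generator emulates the hierarchical structure of a curated barcode
library, not its evolutionary realism: per locus, a uniform-random root
sequence; genus ancestors by per-site substitution at `genus_divergence`;
species ancestors from genus ancestors at `species_divergence`;
individuals at `individual_divergence`. Substitutions are Jukes–Cantor
style (uniform over the three alternatives) with no rate heterogeneity, no
codon structure, and a star genealogy at every level (no coalescent).
Loci with `indel_rate` > 0 additionally gain Poisson(rate · L) indel
events per branch, each a 1–5 bp geometric(0.5) run, half insertions half
deletions — enough to give the spacer locus genuine length variation.

Defaults (the "easy" preset): 5 genera × 3 species × 3 individuals;
loci 800 ± 10, 550 ± 8 and 450 ± 15 bp with indels only in the 450 bp
spacer (rate 0.002/site/branch, a realistic order for a fast-evolving
plastid spacer); divergences 0.10 / 0.02 / 0.002 per site per level —
roughly 10× separation between levels, comparable to congeneric plastid
divergences. The "degraded" preset sets species divergence equal to
individual divergence (0.002), collapsing the species level: conspecific
individuals still share their species ancestor's private mutations, so
some signal survives, but species monophyly measurably drops.

What passing on these fixtures shows: that every pipeline stage (counting,
distances, weighting, NJ, monophyly scoring) is wired correctly and that
the method recovers a clean hierarchy. What it does not show: performance
on real libraries with uneven sampling, misidentified vouchers,
contamination, heterotachy or deep coalescence — real-data grouping rates
will be lower.

## Numerical choices

* Floating comparisons in tests use absolute 1e-9 unless a tighter oracle
  bound (1e-12) is stated; cosines are clipped into [−1, 1] before D.
* PHYLIP matrices are written with 6 decimals, strict 10-character names
  by default (collisions after truncation are an error advising the
  relaxed dialect, which writes full names).
* Determinism: one `numpy.random.Generator` seeded from the config drives
  the whole simulation; identical seeds give bit-identical FASTA. NJ and
  the scan have no randomness.

## Problem sizes

Routine validation uses 45-taxon, 3-locus datasets (20 replicate seeds)
and a 500-taxon, 2-locus run at K = 14 as the scale check — sizes chosen
so the entire suite exercises every stage, including the full K = 6…20
scan, in well under a minute each.

## Known limitations

* The length-share weight formula is a reconstruction (see above); other
  readings that satisfy the same stated properties would change combined
  distances slightly.
* Substitution-rate differences between loci are not modelled in the
  weights — length is the only factor, so a slow-evolving long locus can
  dominate a fast-evolving short one.
* Background-normalized mode is provided for completeness but the
  grouping calibration and presets were established in raw mode.
* The grouping metrics are tree-based: one misplaced sequence fails its
  whole group, so they are not comparable to pairwise "barcode gap"
  discrimination rates.
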