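# Methods

## Model

Each DNA sequence is summarised by an 18-dimensional positional
correlation natural vector: the four nucleotide counts, the four mean
occurrence positions κ<sub>α</sub>, the four positional variances
D²<sub>α</sub>, and the six pairwise positional covariances cov(α, β).
The moments are taken over a per-nucleotide *positional distribution*
U<sub>α</sub>: a length-N step function whose value on the block between
consecutive occurrences p<sub>j</sub> and p<sub>j+1</sub> is
p<sub>j</sub>/(p<sub>j+1</sub> − p<sub>j</sub>), with p₀ = 0 (so sites
before the first occurrence carry 0) and a tail block
p<sub>n</sub>/(N − (p<sub>n</sub> − 1)) from the last occurrence to the
end. The construction has two properties the implementation and tests
lean on:

- **Telescoping block sums.** Each interior block contributes
  p<sub>j</sub> to Σᵢ U<sub>α</sub>(i), so the total equals
  Σⱼ p<sub>j</sub>. Hence κ<sub>α</sub> = Σᵢ U<sub>α</sub>(i)/n<sub>α</sub>
  is exactly the arithmetic mean of the occurrence positions — checked as
  an identity in the property suite.
- **Unusual covariance normalisation.** cov(α, β) divides by
  n<sub>α</sub>·n<sub>β</sub>, not by N. This is not the statistician's
  covariance; it is deliberate, keeps the covariance components
  commensurate with the count and mean components, and is pinned by the
  hand-computed worked value 319/216 ≈ 1.4769 for the A–C pair of
  `ACTGGCAAT` (denominator 3·2).

Distances between sequences are unweighted Euclidean distances in the
18-dimensional space. Components are *not* standardised: counts scale
with N while covariances do not, so on datasets of near-equal genome
length (the intended use: one virus family or one set of bacterial
genomes at a time) the count components carry real signal, whereas mixing
wildly different lengths will let the counts dominate. This is a known
property of the method, not a bug; see Limitations.

## Assumptions and input conventions

- Input sequences are DNA over {A, C, G, T}. Input is uppercased
  (soft-masked genomes) and U is mapped to T, so RNA records pass through.
- IUPAC ambiguity codes (N, R, Y, …) occur in real GenBank genomes but
  the vector is defined only for the four bases. Default policy: an
  ambiguous character *holds its position* — it joins no nucleotide's
  position list, but all downstream coordinates are unchanged. This
  preserves positional semantics instead of silently shifting every later
  occurrence. `strict` mode (CLI `--ambiguity strict`) rejects such
  records instead. The choice matters only in proportion to the ambiguity
  density of the input.
- Positions are 1-based throughout, matching the defining formulas;
  nothing user-visible is 0-based.
- An absent nucleotide (n<sub>α</sub> = 0) would make the moment formulas
  divide by zero; its κ, D², and every covariance involving it are
  defined as 0 — the natural "no signal" value consistent with its
  all-zero U. A length-1 sequence is valid: the single base gets U = 1.

## Numerical choices

- Double precision throughout. Internal identities are tested at absolute
  tolerance 1e-9; the comparison against the 4-decimal hand-computed
  covariance uses the printed precision.
- `positional_distribution` fills U by closed-form block construction
  (`np.repeat` over the occurrence gaps), O(N) time and memory. The test
  suite holds it against an independent, literal site-by-site evaluation
  of the defining cases (`tests/reference.py`) on ~1300 random sequences.
- Vector tables are written with `repr` round-trip formatting, so reading
  a written table reproduces components bit-exactly.

## Neighbor joining

Trees are built with canonical Saitou–Nei neighbor joining (the join pair
minimises Q(i,j) = (r−2)d(i,j) − Σ<sub>k</sub>d(i,k) − Σ<sub>k</sub>d(j,k));
the last three nodes are resolved by the standard closing formula and the
tree is left unrooted. Determinism: Q-ties are broken by the lowest
(i, j) index pair in current matrix order. Negative branch-length
estimates (possible on non-additive input) are clamped to 0 by default,
with the pre-clamp value kept on the node for diagnostics;
`--allow-negative` disables clamping. Correctness is tested by the
defining consistency property — exact recovery of topology and
leaf-to-leaf path lengths (within 1e-9) on random additive matrices —
plus an independent cross-check against scikit-bio's NJ and Newick
round-trips through dendropy.

## Classification protocol

Genotype assignment is leave-one-out 1-nearest-neighbor on the full
distance matrix: each record takes the class of its nearest other record,
ties broken by the smallest matrix index. Leave-one-out is the standard
protocol for 1-NN evaluated on a single labelled dataset; no train/test
split is involved. Metrics are tabulated one-vs-rest per class:
sensitivity = TP/(TP+FN), specificity = TN/(FP+TN). Per-class accuracy is
implemented as the fraction of that class's members predicted correctly,
which under one-vs-rest tabulation coincides with sensitivity; a separate
overall accuracy (total correct / total records) is reported as a clearly
labelled extension. Dataset averages are unweighted means over classes;
a class with no true members yields NA and is excluded from averages with
a warning. A singleton class is permitted but its member is necessarily
mispredicted (warned).

## Synthetic data generator

`pcnv.simulate` emulates a genotyping dataset: each cluster is an
i.i.d.-uniform random ancestor genome whose members are produced by
independent per-site substitutions (probability `sub_rate` per site, the
replacement base uniform over the other three). Defaults — 4 clusters,
10 descendants each, 5 kb genomes, substitution rate 0.01 — give
within-cluster vector distances well below between-cluster distances, so
the end-to-end pipeline classifies every record correctly; genome length
is kept at 5 kb (virus scale) so the full suite runs in seconds.
Substitution-only evolution keeps the ancestor–descendant Hamming
distance exactly Binomial(L, rate), which the tests check against 5σ
bounds. Randomness derives from a single integer seed through per-record
`SeedSequence` spawn keys (seed, cluster, member), so enlarging a
configuration never perturbs records already generated.

What the generator does **not** emulate: indels, rate heterogeneity,
GC-content skew, transition/transversion bias, recombination, or
horizontal transfer. Passing the end-to-end tests therefore demonstrates
that the pipeline is implemented correctly and separates clusters whose
divergence is substitution-driven; it does not by itself certify accuracy
on real viral or bacterial genomes, which differ in all of the above.

## Design choices where the design was open

- NJ is implemented in-package rather than shelling out to an external
  tree program: the algorithm is small, fully specified, and this keeps
  the pipeline dependency-free and its tie-breaking deterministic.
  External NJ implementations may order ties differently, so
  bit-identical topologies with other software are not claimed —
  path-length agreement on additive inputs is.
- PHYLIP distance matrices are written in the relaxed dialect (full
  labels); `--strict-phylip` pads/truncates to the classic 10 characters
  for older consumers.
- FASTA record ids are the first whitespace-delimited header token (the
  NCBI accession convention).

## Limitations

- The vector is length-sensitive (counts grow with N); compare sequences
  of comparable length, as in single-family genotyping.
- Euclidean distance on these vectors is positively associated with
  divergence but is not an evolutionary distance: no substitution model,
  no time calibration, and branch lengths are not interpretable as
  substitutions per site.
- 18 dimensions cannot distinguish all sequences; distinct sequences can
  in principle collide, although the moments make this rare in practice.
- Bootstrap support, rooting, and tree visualisation are out of scope;
  the Newick output opens in any standard tree viewer.
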