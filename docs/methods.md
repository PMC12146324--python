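# Methods

## Problem and model

A lncRNA's localization label in one cell line is the sign of its
CNRCI, the log2 ratio of cytoplasmic to nuclear FPKM.  The classifier
never sees expression data: it learns a mapping from fixed-length
sequence descriptors to that sign, one model per cell line, because the
same transcript can have opposite CNRCI signs in different cellular
contexts.  The positive class is cytoplasm throughout.

The pipeline is: label assignment → greedy redundancy reduction →
length filter (≤ 10,000 nt, inclusive) → stratified 80/20 split →
featurization → optional mRMR selection → stratified five-fold CV and
hold-out evaluation over a classifier registry → best-model selection by
validation AUC (ties by MCC, then registry order).

## Dataset construction choices

- **Boundary CNRCI.**  CNRCI = 0 carries no directional signal and a
  zero-FPKM compartment makes the ratio undefined; both cases drop the
  record, and the drop count is reported so attrition is auditable.
- **Redundancy reduction.**  Exact clustering parity with external tools
  is not a goal.  The package uses greedy longest-first clustering:
  identity between a candidate and a cluster founder is estimated as the
  fraction of the shorter sequence's 12-mers contained in the founder's
  12-mer set; a candidate joins the first cluster at ≥ 0.90, else founds
  one.  The scheme is deterministic, idempotent, and O(n·clusters).
  Note the estimate decays quickly with divergence: p point mutations
  per residue cost up to 12p of the k-mers, so 0.90 containment
  corresponds to roughly ≤ 0.9% mutations — stricter than 90%
  alignment identity.  That conservatism only keeps marginally similar
  sequences apart.
- **Split sizing.**  Validation size is ceil(0.2·N); per-class counts
  use proportional allocation with largest-remainder rounding (ties by
  class name).  This arithmetic reproduces published per-cell-line
  train/validation counts exactly (e.g. 2,552 → 511 = 307 + 204;
  703 → 141 = 118 + 23); the seed shuffles membership only, never sizes.
- **Alphabet.**  Input may be DNA or RNA; U maps to T.  The strict
  policy rejects ambiguous residues (default); `drop-ambiguous` removes
  them, configurable because upstream pipelines differ in how they emit
  Ns.

## Descriptors

All encoders operate on the given strand; there is no silent
reverse-complement canonicalization (the RCK family collapses strands
explicitly, by construction).

- **Composition (123).**  Dinucleotide composition counts overlapping
  2-mers over L−1 windows.  The repeat index is the longest homopolymer
  run of each base divided by L — a simple monotone repeat measure with
  the required dimension of 4.  The distance distribution is the mean
  gap between consecutive occurrences of a base, normalized by L (bases
  seen < 2 times score 0).  Entropy contributes the Shannon entropy of
  the base distribution and its four −p·log2 p terms.
- **Pseudo compositions.**  Type-I factors θ_j average the mean squared
  difference of the 12 standardized property values between k-mers j
  positions apart; type-II factors τ_j average the lagged product of one
  designated property (p1).  Weight w = 0.05, the conventional default.
  λ values are fixed by the published family dimensions: pseudo
  dinucleotide 19 = 16+3, pseudo trinucleotide 65 = 64+1 on the
  composition side; 17 = 16+1 and 65 = 64+1 for the parallel/serial
  correlation variants.
- **Correlation families (1,100).**  Each descriptor summarizes one
  property profile (or an ordered pair of profiles) at lag d ∈ {1, 2}:
  plain autocovariance, Moran (autocovariance over the 1/N variance),
  Geary (half mean squared lag difference over the 1/(N−1) variance),
  Moreau–Broto (mean raw lagged product), and cross-covariance for
  ordered property pairs.  With 12 properties and 2 lags the dimensions
  are forced: 24 per autocorrelation family, 264 cross, 288 auto+cross.

### Property tables

Correlation descriptors are driven by a 12-property table per k-mer size
(k = 2, 3), standardized per property to mean 0, sd 1 over all 4^k
k-mers at load time.  The bundled defaults combine helical geometry
(twist, tilt, roll, shift, slide, rise), nearest-neighbour duplex
thermodynamics (ΔH, ΔS, ΔG37) and composition fractions (GC, purine,
keto); trinucleotide physical values are the means of their two
overlapping dinucleotide steps.  Because standardization happens at
load, any affine rescaling of a raw property column leaves Moran/Geary
descriptors bit-for-bit unchanged (tested).  Users can substitute their
own tables: TSV with a `kmer` column plus 12 property columns, all 4^k
rows present; the p-index mapping is documented in
`data/property_names.tsv`.

### Numerical conventions

- Zero-variance (constant) property profiles make Moran and Geary
  0/0; both are defined as 0 so homopolymer-rich sequences featurize.
  Constancy is detected exactly (range = 0), not via the computed
  variance, which can be polluted by rounding.
- Metric ratios with zero denominators (e.g. precision with no positive
  predictions) are reported as 0, matching how degenerate all-negative
  predictors are conventionally tabulated (sens 0, spec 1, prec 0,
  mcc 0, f1 0).
- The decision threshold on predicted cytoplasm probability is 0.5.
- AUC is the rank-based Mann–Whitney statistic with ties counting ½.

## mRMR

Greedy forward selection: the first pick maximizes ANOVA-F relevance;
each later pick maximizes relevance minus the mean |Pearson r| with the
already-selected set (a quotient criterion is available).  Because the
F-statistic is unbounded while redundancy lives in [0, 1], the criterion
uses the F-statistic mapped onto the correlation scale,
r = √(F/(F+n−2)) — exactly the point-biserial correlation, and a
strictly monotone function of F, so relevance ordering is unchanged
while the difference subtracts commensurate quantities.  This makes an
exact duplicate of a selected feature (redundancy 1, criterion ≤ 0)
lose to any modestly informative independent feature.  Exact score ties
break lexicographically by descriptor name; constant columns warn and
rank last.  Greedy selection guarantees the prefix property (top-k′ is a
prefix of top-k).

## Synthetic data

The generator emulates the study conditions: per sequence a latent
compartment class is drawn (default balance 0.5), residues come from a
first-order Markov chain whose transitions are tilted by class —
cytoplasmic sequences gain C marginally and G after C (CpG steps),
nuclear sequences gain T marginally and G after T (TpG steps), tilt 0.12
each — and CNRCI = β·z(f_CG − f_TG) + N(0, σ) with defaults β = 3,
σ = 0.5, lengths 200–2,000 nt, n = 1,000, seed 42.  When β > 0, values
whose magnitude clears σ have their sign forced to agree with the class,
capping label noise at the boundary; at β = 0 no forcing is applied so
labels are genuinely independent of composition (the null case).
Additional cell lines reuse the same genes with an optional seeded
fraction of sign flips, emulating cross-cell-line relocalization.

Because the signal enters through dinucleotide *transitions*, the
correlation families — not just raw composition — carry class
information, and CpG-containing k-mer descriptors correlate positively
with CNRCI while TpG/poly-T descriptors correlate negatively, the
contrast the feature-importance analysis is designed to surface.

What the generator does **not** emulate: real lncRNA length and GC
distributions, secondary structure, splicing isoforms, repeat elements,
localization motifs beyond dinucleotide bias, or measurement noise in
compartment RNA-seq.  Passing tests therefore demonstrate that the
machinery is correct and can recover a planted compositional signal at
realistic sample sizes — not that any particular AUC is attainable on
real transcriptomes, where signal is far weaker (published AUCs on real
per-cell-line data sit around 0.6–0.8).

## Problem sizes

The default benchmark (n = 1,000, lengths 200–2,000) featurizes in a few
seconds and trains in seconds per classifier; the test suite's oracle
equivalence uses 100 sequences of lengths 50–2,000 at 1e-10 relative
tolerance, and the full suite runs in about half a minute.

## Known limitations

- The greedy clusterer is stricter than alignment-based 90% identity
  (see above); counts on real data will differ slightly from tools like
  MeshClust or CD-HIT.
- The repeat-index and distance-distribution formulas are fixed by name
  and dimension, not by a published equation; they are isolated behind
  one function each so alternative definitions are a one-line change.
- The 12 bundled properties are a reasonable default set, not a claim
  about which properties are optimal; substitute tables reproduce any
  published property choice.
- Gaussian-process and SVM classifiers scale poorly past a few thousand
  training sequences; the tree ensembles and linear models are the
  practical choices at scale.
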