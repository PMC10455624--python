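# Methods

## Distance models

For a pair of aligned sequences, a site is *comparable* iff both
characters are unambiguous bases (A, C, G, T) after input normalisation
(upper-case, U→T, ?→N, .→gap).  With n comparable sites of which s are
transitions (A↔G, C↔T) and v transversions, the models are

* raw (p-distance): d = (s + v) / n
* Kimura two-parameter: d = −½·ln((1 − 2P − Q)·√(1 − 2Q)) with
  P = s/n, Q = v/n.

Exclusion is *pairwise* (pairwise deletion): a gap or ambiguity only
removes the site from pairs containing it.  Consequences worth knowing:

* Partial IUPAC ambiguities (R, Y, S, …) are treated as fully missing
  for the pair.  Distance routines that weight partial ambiguities
  fractionally will differ in the rare sites where this matters; on
  ambiguity-free data the output agrees with the standard R routine
  (`ape::dist.dna`, pairwise.deletion=TRUE) to ≤ 1e-6, which the test
  suite checks on a fixture.
* A distance is *undefined* (NaN) when the pair shares no comparable
  sites (n < `min_comparable_sites`, default 1) or when K80 saturates
  (1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0).  Undefined pairs are excluded from
  pools but always counted (`n_undefined_excluded`), so pool sizes
  reconcile with C(N, 2) exactly.
* An optional coverage pre-filter drops sequences with < 50% non-gap,
  non-N characters in a region before analysis (on by default in the
  CLI), reflecting standard curation practice for partial sequences.
* Distances are computed in double precision and never rounded until
  report stage (4 decimals in tables, 1 decimal for percent cutoffs).

Patristic (cophenetic) distances are branch-length path sums between
tree tips, computed via dendropy on newick input.  Branch lengths are
required; `assume_unit_lengths=True` substitutes 1.0 per edge for
topology-only exploration.  Negative lengths are rejected rather than
clamped.

## Pooling and partitions

Each unordered pair of distinct sequences contributes exactly once, to
the intra pool if both members share a species label and to the inter
pool otherwise; self-pairs never count.  Alternative taxonomies are
plain relabelings: `relabel` applies an explicit label map (many-to-one
= lumping), and `merge_closest_species` lumps the k closest disjoint
species pairs by mean between-member distance, mimicking how
distance-based partitioners merge sister taxa.  Cross-dataset "overall"
statistics concatenate pools, i.e. they are pair-weighted: a genus with
many sequences dominates in proportion to its pair count.  Per-dataset
averaging is available by summarising pools individually.

## Summaries and the stress test

Quantiles are type-7 (linear interpolation of order statistics,
h = (n−1)p + 1) and variances are sample variances (n−1 denominator) —
the defaults of the R environment where this style of analysis is
conventionally run, so numbers are directly comparable.  A pool of size
one gets variance 0 with a warning rather than an error, because
singleton species are deliberately retained in curated datasets.

The stress test at level p compares the intra pool's upper p-quantile
with the inter pool's lower (1−p)-quantile; the default levels are
0.85, 0.90, 0.95.  The one-sided convention is the default; a
`two_sided=True` option instead uses central intervals (intra at
(1+p)/2, inter at (1−p)/2) for readers who interpret "quantiles around
the distribution" that way.  Both conventions make gap(p) monotone
non-increasing in p, so presence is monotone too: once a gap is lost at
some level it stays lost at all higher levels.  Gap presence is
strictly `gap_size > 0`; a tiny positive gap can display as 0.0000
after 4-decimal rounding.  The midpoint (intra_upper + inter_lower)/2
is reported regardless of presence, as the percent-divergence cutoff a
clustering workflow would adopt.

The report table carries one row per dataset and, per region × level, a
Gap? flag and size; the footer counts gap-positive datasets and
averages sizes *among those only*.

## Synthetic data generator

The generator emulates curated congeneric barcode matrices: multiple
species with ≥3 sequences each (singletons allowed via per-species
count lists), within-species divergence well below between-species
divergence, κ-biased substitution, and the characteristic region
structure of the barcode (fast ITS1, conserved 5.8S, intermediate
ITS2).

Mechanics: a uniform-random root sequence per region descends an
explicit individual-level tree.  Each species ancestor hangs off the
root by a stem of `inter_divergence / 2` and each individual off its
ancestor by `intra_divergence / 2`, so two conspecifics are separated
by an expected `intra_divergence` and two heterospecifics by
`inter_divergence + intra_divergence`, scaled per region by its rate
multiplier.  Mutations are drawn from the exact K80 transition
probabilities for each branch length (matrix-exponential endpoint
sampling), not a Bernoulli approximation, so the K80 distance estimator
is the generator's matched inverse and parameter recovery is a clean
closed-loop check.  Gap masking is applied to the concatenated matrix
before slicing, so region files are exact column slices of the full
alignment; `terminal_gaps=True` masks contiguous prefixes/suffixes
instead of scattered columns, stressing the coverage filter.  A single
`numpy` generator seeded from `config.seed` drives all draws; output is
byte-deterministic per seed.

Defaults are chosen to resemble curated macrofungal data and are fixed:
region lengths (333, 175, 312) columns; rates (1.5, 0.1, 1.0);
intra divergence 0.006 and inter divergence 0.055 substitutions/site
(giving nrITS pool means near 0.006/0.061); κ = 2; 2% scattered gaps;
10 species × 5 sequences.  The species tree is a star by default —
i.i.d. ancestors keep expected pool means analytic — with a Yule-like
option (`tree_shape="yule"`: exponential stem depths rescaled to the
same mean) when between-species distance heterogeneity matters, e.g.
for lumping experiments, where merging *closest* pairs is only
meaningful if some pairs are genuinely closer.

What the generator does **not** emulate: indel evolution (gaps are
masking, not evolutionary events), alignment error, length
heterogeneity between taxa, intragenomic ITS variation, and base
composition bias.  Passing tests therefore demonstrate correctness of
the measurement pipeline and qualitative behaviour of the gap under
controlled divergence structure — not that any particular real genus
has a gap.

## Numerical and design choices

* Distance matrices are validated on construction (zero diagonal,
  symmetry, non-negativity) and frozen read-only.
* The K80 ≥ raw inequality and the four-point (additivity) condition on
  patristic matrices are enforced as property tests.
* The pairwise-deletion guarantee tested is the sharp one: gapping a
  column in some sequences leaves all pairs of untouched sequences
  bit-identical, and lowers the touched pairs' comparable-site counts.
* Stochastic checks (parameter recovery within 3 SE over 20 seeds at
  10 species × 5 × 600 columns; region-variance ordering and
  lumping-variance effects as majorities over 20 seeds; gap detection in
  ≥95% of seeds at intra 0.01 / inter 0.10) run at problem sizes chosen
  to finish in seconds while keeping standard errors far below the
  effects tested.

## Limitations

* Exact numeric reproduction of published per-genus tables requires the
  corresponding deposited alignments and trees as input; this package
  provides the measurement machinery and verifies it on synthetic data.
* The strict ambiguity rule can shift distances slightly against
  fractional-weighting implementations on ambiguity-rich data.
* The one-sided vs two-sided quantile convention changes gap sizes at a
  given nominal level; comparisons across studies must fix the
  convention (both are implemented, one-sided is the default).
* No hypothesis testing on gap existence is offered — the stress test
  is descriptive, not inferential.
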