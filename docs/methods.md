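# Methods

This note documents the models, conventions and numerical choices behind
mirconcord, in the spirit of a statistical-methods appendix.

## Combined-evidence concordance model

For each homolog pair with per-species raw p-values (p₁, p₂) the combined
statistic is Fisher's product, χ² = −2(ln p₁ + ln p₂), referred to a
chi-square distribution with 2k = 4 degrees of freedom. For df = 4 the
survival function has the closed form S(x) = e^(−x/2)(1 + x/2), which the
test suite uses as an independent oracle.

Conventions that matter and their rationale:

- **Raw p-values enter the product; BH is applied once, to the combined
  p-values, across exactly the set of evaluated pairs.** Combining
  already-adjusted p-values is statistically incoherent (adjusted values are
  not uniform under the null), and the subsequent FDR step presumes raw
  inputs. The per-species `padj` columns are still read and validated — they
  drive the per-contrast significance calls used elsewhere.
- **Concordance is a sign condition on the two log2 fold-changes.** A pair
  is called when q ≤ α and sign(L2FC₁) = sign(L2FC₂) ≠ 0. A zero fold-change
  has no direction and is never concordant. The α comparison is inclusive
  (q ≤ α).
- **Paralog collapsing** (many zebrafish features mapping to one human
  feature) defaults to `min_p`: keep the paralog with the smallest raw p,
  ties broken lexicographically by id, carrying its L2FC. The alternative
  `within_species_fisher` policy combines the paralog p-values by the same
  product method (df = 2·#paralogs) and takes the direction of the
  smallest-p paralog; for a single paralog both policies are the identity.
  `min_p` is the default because it is the simplest defensible rule and
  biases the screen toward the best-supported paralog, matching how a
  duplicated miRNA family (e.g. miR-21-1/-2) is usually reported.
- **Underflowed p-values** (exact zeros emitted by DE software) are clamped
  to 1e-300 before the logarithm, with a warning counted in the run
  summary. This keeps χ² finite and preserves the ordering of evidence.

Under the global null with both sign agreement (probability ½) and q ≤ α
required, the expected called fraction is well below α; the suite asserts
the conservative bound (called fraction ≤ 0.05) over 50 simulated nulls.

## Significance thresholds

A feature is significantly dysregulated when |L2FC| ≥ 0.5 (inclusive at the
boundary) and padj < 0.05 (strict). Both thresholds are arguments
everywhere they are used. The combined-evidence call uses q ≤ 0.05
(inclusive), a deliberate asymmetry: the per-contrast rule and the
combined-evidence rule are stated independently and configured
independently. Features filtered before testing (e.g. low counts) are
excluded before BH adjustment, matching standard DE-software semantics of a
pre-test filter; `filter_min_count` removes rows with total count strictly
below the threshold.

## Factorial classification

The four contrasts of the 2×2 genotype × diet design are reduced to
per-gene boolean significance and direction calls; classes are pure set
logic (no interaction-term model):

| class | rule |
|---|---|
| diet_dependent | significant same-direction in A and D; not significant in B or C |
| mir21_dependent | significant same-direction in B and C |
| divergent | significant in A and C with opposite directions |
| mir21_hcd_dependent | significant in C and D; not in B; not diet_dependent |

The same-direction requirement for diet dependence can be switched off. The
`mir21_hcd_dependent` rule is the package's own explicit definition for the
"needs both transgene and diet" class, chosen as the minimal pattern that
distinguishes it from the other three; it is configurable. Genes absent
from one contrast's universe count as not significant there rather than
being excluded, matching intersection logic on exported DE workbooks.
Overlapping labels are resolved by the fixed precedence divergent >
mir21_dependent > diet_dependent > mir21_hcd_dependent; the precedence is a
package decision (a gene satisfying two patterns must land somewhere
deterministic) and is configurable.

## Exact overlap statistics

**Two-sided Fisher's exact test** uses the point-probability definition:
the p-value sums hypergeometric probabilities (margins fixed) of all tables
whose point probability does not exceed the observed one (within relative
tolerance 1e-7). The p-value is delegated to scipy, which implements this
definition; the odds ratio is reported as the sample ratio a·d/(b·c),
infinite when b·c = 0. A zero margin raises.

**Multi-set intersection test.** Model: m sets are drawn independently,
uniformly without replacement from a background of size N. The distribution
of the m-way intersection size is built by iterated convolution — given a
current intersection of size y, intersecting with a new set of size s gives
a Hypergeometric(N, y, s) count. Because the intersection law is symmetric
in the sets, sets are processed smallest-first so every intermediate state
stays within 0..min(sᵢ). The reported p is the upper tail P(X ≥ observed)
(enrichment only; depletion is out of scope), expectation N·∏(sᵢ/N), fold
enrichment observed/expected. The computation is plain double-precision
scipy hypergeometric pmfs; the suite verifies the pmf sums to 1 within
1e-9, equals the direct hypergeometric tail for m = 2, and matches
exhaustive subset enumeration for all size combinations at small N and
permutation Monte-Carlo (10⁵ draws) at N = 1000.

**Seed-site enrichment 2×2.** By default the query genes are removed from
the background margin (disjoint cells); the overlapping convention is
available via `disjoint_background=False`. "Contains a seed site" counts
the predicted-site classes {7mer-A1, 7mer-m8, 8mer}; 6mer-only matches are
excluded by default and configurable.

## Seed-site scanner

The seed is miRNA nucleotides 2–8 (1-based from the 5′ end). A UTR locus
matching the reverse complement of positions 2–7 is classified by two
independent extensions: a downstream A (7mer-A1) and a match to the reverse
complement of position 8 (7mer-m8); both together make an 8mer, neither a
6mer. Each core-hexamer match yields exactly one site of the strongest
applicable type; coordinates are 0-based half-open on the given strand.
U and T are interchangeable on input. This is a transparent exact-match
scanner: no context scoring, conservation weighting, or UTR alignment.

## Morphometry

Pixel calibration is field span divided by pixel count (e.g.
290.62 µm / 1024 px = 0.284 µm/px, displayed at 3 decimals, full precision
internally). ROI areas use the shoelace formula via shapely with validity
(self-intersection) checking; centroids exactly on the ROI boundary count
as inside (deterministic, inclusive annotation semantics). Density is
1000·n/area (nuclei per 1000 µm²).

Inter-nuclear spacing is the mean nearest-neighbour distance over
centroids, chosen over mean pairwise distance because the latter scales
with ROI extent rather than cell packing; mean pairwise distance is
available separately. **No edge correction is applied by default**: a
nucleus near the ROI boundary may have its true nearest neighbour outside
the imaged region, biasing the mean slightly upward. This mirrors how such
spacing is computed in practice from raw detection tables, and the bias is
documented rather than corrected. `nn_distances` exposes per-nucleus
values so a caller can apply minus-sampling (score an interior sub-region
while allowing neighbours in a guard zone); the acceptance checks use
exactly that construction, because the closed-form Poisson expectation
1/(2√λ) describes the unbounded process and the uncorrected window
estimator is biased away from it by a few standard errors at any window
size. Analysis is strictly 2-D, matching single optical-slice acquisition.

## Synthetic-data generators

The generators exist to exercise every stage with known truth; they model
the *statistical* structure downstream methods assume, not assay chemistry
(no read counts, probe effects, or spectra).

- **Paired DE tables**: per-feature z-scores, z = s·μ + ε with ε ~ N(0, 1)
  independently per species; p = two-sided normal tail; L2FC = z·lfc_scale;
  per-table BH. Concordant pairs share the direction s across species,
  discordant pairs flip it, null features are pure noise. This is the
  minimal generative model under which two-sided p-values, signed
  fold-changes and BH behave as the analysis assumes, with analytic nulls
  (uniform p under μ = 0) and closed-form power. Defaults: 1000 homolog
  pairs, 10% concordant, 2% discordant, μ = 5, lfc_scale = 1, 100 unpaired
  features per species, 5% paralog rate. Paralogs receive the same
  direction with independent noise, mimicking a within-species duplicate
  pair.
- **Factorial tables**: each gene draws a class; the class determines which
  of contrasts A–D carry the signed effect (templates mirror the class
  definitions above); all other cells are noise.
- **Gene sets**: each set is a planted core plus a uniform
  without-replacement sample of the remaining background — exactly the null
  model of the multi-set test when the core is empty.
- **UTRs**: uniform random nucleotides with non-overlapping planted 8mer
  motifs (reverse complement of seed 2–8 followed by A) on a block grid.
- **Point patterns**: count ~ Poisson(λ·area), locations uniform inside the
  polygon (batch rejection from the bounding box); with a minimum spacing,
  simple sequential inhibition with a bounded retry budget that raises when
  the requested density is unreachable. Nuclear areas are
  Gamma(shape 8) with mean 30 µm², a realistic hepatocyte-nucleus scale
  with mild right skew.

Everything is driven by `numpy.random.default_rng(seed)`: one config, one
output, byte-identical across runs. What passing tests on these inputs do
**not** show: robustness to correlated features, heavy-tailed effect
distributions, count-model mean–variance structure, or segmentation errors
in real detection tables.

## Problem sizes in the test and acceptance runs

Null calibration uses 5000 homolog pairs × 50 seeds; recovery uses 1000
pairs × 20 seeds (concordance) and 2000 genes × 5 seeds (factorial);
enumeration oracles sweep all m = 3 size combinations for backgrounds up to
N = 12 (tests) / N = 10 (script) plus a 10⁵-draw Monte-Carlo at N = 1000;
the Fisher sweep covers all 2×2 tables with total n ≤ 30 (tests) / ≤ 20
(script); the Poisson check uses 200 replicates of ≈2900 points. These
sizes give Monte-Carlo standard errors comfortably below the asserted
bounds while keeping a full run in well under a minute of compute for the
script and a few tens of seconds for the suite.

## Known limitations

- The concordance screen assumes independent per-species evidence; shared
  technical structure between the two experiments would inflate the
  combined statistic.
- The multi-set model assumes uniform sampling from one shared background;
  real DE gene lists are size-biased (expression-dependent power).
- The seed scanner predicts sites by exact complementarity only.
- Morphometry is 2-D and uncorrected for section thickness or edge effects
  (by design, see above).
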