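# Methods

`halobarcode` re-implements, as a tested pipeline, a barcode-evaluation and
sampling-strategy analysis for widespread plant species whose coastal
salt-marsh populations carry habitat-private genetic variants. This note
records the models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic-data tests do and do not demonstrate.

## Genetic distances

Pairwise divergence is the Kimura 2-parameter (K2P) distance

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

where P and Q are the transition (A↔G, C↔T) and transversion proportions
over the jointly valid columns of an aligned pair. Columns containing a
gap, `N`, or any IUPAC ambiguity code in either row are excluded entirely
(full masking, no fractional counting) — this matches the common MEGA
setting and keeps the computation deterministic. Two site modes exist:

* `pairwise_deletion` (default): masking per pair, MEGA's default for
  distance matrices.
* `complete_deletion`: columns with any gap/missing in **any** row are
  removed once before all comparisons (DnaSP-consistency checks).

When a log argument is ≤ 0 (observed divergence beyond the correction's
domain) or no valid columns remain, the distance is **undefined** and is
carried as an explicit NaN marker. Undefined entries are never clamped;
every downstream operation either skips them with a logged count
(intraspecific distance extraction), refuses them naming the offending
pairs (PCoA, neighbor joining, theta), or reports the query as
`uncomparable` (best close match).

## Best-close-match identification

Every sequence is classified as a query against all others: no neighbour
within the threshold → `no_id`; otherwise the species of all neighbours
tied at the minimum distance decide `correct` / `ambiguous` / `incorrect`.
Conventions:

* threshold comparison is inclusive (m ≤ t qualifies);
* tie tolerance for "equal minimum" is 1e-12 absolute — identical
  sequences collapse to one tie, biologically distinct near-ties do not;
* self-matches are always excluded; percentages are reported to 2 decimals.

The threshold is either fixed (default 0.03, the conventional 3%) or the
95th percentile of all defined intraspecific pairwise distances
("pairwise summary" convention). Percentiles use linear interpolation
between order statistics (numpy's default rule).

## Tree-based discrimination

A species with ≥ 2 tips is *discriminated* when some node's clade contains
all of and only that species' tips **and** that node's support strictly
exceeds the cutoff (default 0.95, i.e. "over 95%"). Supports are
normalized on read: if any value exceeds 1 the whole tree is treated as
percent-scaled. Singleton species are reported separately and excluded
from the rate by default (`count-as-fail` available). Outgroup tips are
pruned (after rerooting on their attachment edge) before evaluation.

Trees whose root is a multifurcation are treated as unrooted; they are
refused unless an outgroup is declared or split-based evaluation
(`unrooted=True`) is requested, under which a species is discriminated
when its tip set forms either side of a supported bipartition. This mode
exists for the neighbor-joining fixture builder, whose trees are unrooted
and carry no supports (`missing_support="full"` treats them as fully
supported topology checks). Bayesian inference itself is out of scope;
support-annotated trees arrive as newick input.

Neighbor joining follows the Saitou–Nei agglomeration with a
deterministic tie-break (lowest index pair in the current working order in
row-major scan). It exists to build fixtures and sanity trees, not to
replace model-based inference.

## Haplotypes

Collapsing mirrors DnaSP's treatment of unphased haploid marker reads:
under `exclude_sites` (default) all columns containing a gap/`N`/ambiguity
in any retained row are removed once, then identical remaining rows share
a haplotype (1-based indices in first-occurrence order). Because the
removed columns depend on the rows present, collapsing is repeated
independently within the inland group, the coastal group, and the combined
set; the combined count can therefore be smaller than the sum of group
counts. DnaSP's autosome/chloroplast switch affects phase handling, not
haplotype counts of haploid sequences, so both map to the same collapsing
here. The paper trail for the gap option of the original analysis is
absent, so `exclude_sites` is an assumption and `include` is exposed.

Proportional subsampling (used to shrink over-sampled species while
preserving haplotype composition) allocates per-haplotype quotas by
largest-remainder rounding of n_h · target/N with every haplotype's floor
clamped to 1 (feasible whenever target ≥ number of haplotypes); remaining
seats (or the excess created by the clamp) are settled deterministically —
larger remainder first, then larger haplotype, then first-occurrence
order. Members within a haplotype are drawn uniformly with the supplied
seed. Requests below the haplotype count are refused unless loss is
explicitly allowed.

## Ordination

Classical PCoA: B = -1/2 J (D∘D) J with J the centering matrix, symmetric
eigendecomposition, coordinates = eigenvectors · sqrt(positive
eigenvalues). Axes are sorted by descending eigenvalue and sign-flipped so
the largest-magnitude loading is positive (reproducible plots). Negative
eigenvalues — the signature of non-Euclidean distances — are dropped and
reported (count and magnitude sum) rather than corrected; no
Lingoes/Cailliez adjustment. Eigenvalues within 1e-12 of zero (relative to
the spectral radius) are treated as numerical zeros. Proportions explained
are percentages of the positive-eigenvalue sum.

## Group comparison

The habitat contrast compares intraspecific K2P distances of the
inland-only subset against the combined (inland + coastal) set — the two
vectors overlap by construction, and pairwise distances are not
independent observations; the procedure is reproduced as defined, not
endorsed as inference, and a disjoint inland-vs-coastal mode exists.

Mann–Whitney U: exact enumeration of the null distribution (partition
recurrence) when n1 + n2 ≤ 16 and the pooled sample is tie-free — the
two-sided p is the sum of both tails, with p = 1 when U sits exactly at
the null center. Otherwise: normal approximation with tie-corrected
variance and a 0.5 continuity correction (the SPSS-style asymptotic
two-sided p). Cross-validation in the test suite checks exact vs
approximate agreement within 0.02 at 8+8 and a simulated type-I error of
0.05 ± 0.01 at n = 30+30. Boxplot summaries use linear-interpolation
quartiles and Tukey 1.5·IQR fences.

## Sampling sufficiency (theta resampling)

θ of a subset is the arithmetic mean of its C(n,2) pairwise K2P distances.
For each subset size n from 2 to N, 20 random subsets (default) are drawn
without replacement; the per-size **trend** is the maximum of the 20
per-subset θ values (each subset's θ is itself an average, so this is the
"maximum average" trend). The reference band is a Student-t confidence
interval (default confidence 0.9999) on the mean of the full set of
pairwise distances, treated as independent observations — again a
reproduced convention, with the independence violation documented rather
than corrected. The CI is computed on the pairwise distances, not on
per-subset θ values; the alternative is a one-line change if wanted.

The **minimum sufficient sample size** is the smallest n from which the
trend stays at or below the CI's upper limit for *all* larger sizes (a
stability rule — trend lines fluctuate, and a first-crossing rule is
exposed separately for sensitivity analysis). If only the degenerate
full-sample size qualifies, the verdict is NOT_REACHED. At n = N every
"random subset" is the full set, so replicate θ values collapse exactly to
the full-sample θ; subset indices are sorted before summation and a
degenerate mean short-circuits so this identity holds bitwise.

Randomness: one generator stream per species, seeded from the master seed
plus the species index (numpy `SeedSequence([seed, index])`), so curves
are reproducible under (seed, input order) and species are independent.

## Synthetic data generator

Sequences evolve under the Kimura 1980 (K80) model — the generative dual
of the K2P estimator — with uniform base composition, exact per-site
transition probabilities at the requested distance, and
transition/transversion ratio κ (default 2, a typical plant nuclear/
plastid value). Defaults emulate realistic barcode data: 600 bp sequences,
intraspecific divergences on the 0.00–0.03 scale, interspecific ancestor
divergence 0.15 (a clean barcode gap; override `require_barcode_gap` to
construct hard cases), per-species sample sizes in the single digits to a
few tens. Each species' ancestor is a mutated copy of one shared root at
half the interspecific divergence; each haplotype is a mutated copy of the
species ancestor; samples draw haplotypes by weight, restricted to their
habitat's availability. A coastal-private haplotype is therefore only ever
carried by coastal samples.

No indels are simulated by default, which keeps the haplotype ground
truth exact (`gap_mode="include"` recovers it verbatim); a gap-injection
helper exists purely to exercise the masking code paths. Expected θ truth
values use the star-topology additivity of expected distances (a pair on
haplotypes i ≠ j sits at expected distance d_i + d_j).

What the generator does **not** emulate: indel-rich loci (trnH-psbA-like
length variation), rate heterogeneity across sites, non-uniform base
composition, coalescent genealogies, migration between habitats, or
alignment error. Passing tests therefore demonstrate algorithmic
correctness and the qualitative sampling conclusions under a clean
substitution model, not robustness to alignment or model misspecification
on real herbarium data.

## The rare-variant experiment

The package's central qualitative claim — a rare, divergent,
habitat-private haplotype inflates the sample size needed for a
representative barcode — is tested with a paired design
(`halobarcode.experiments`): a species of N = 20 (19 inland carrying two
common low-divergence haplotypes at d = 0.002 and 0.004; one coastal
sample carrying a private d = 0.03 haplotype, frequency 1/N) against a
uniform comparator of the same N and group structure with two
equal-frequency haplotypes whose divergence is set analytically so the
expected mean pairwise distance matches. The comparator is the minimal
"uniform diversity" population; success means the rare-variant species
shows both the combined-haplotype gain and a strictly larger minimum
sufficient sample size. Typical paired win rates are 98–99 out of 100,
with median minimum sizes around 12 (rare variant) vs 5 (uniform) — the
same order as the 11–15 range recommended for widespread species.

## Problem sizes

Validation runs use 500 random pairs (L = 600) for the distance oracle,
100 random 20-sample instances for identification, 100 random 6–10-taxon
additive metrics for neighbor joining, 50 random simulation specs for
haplotype truth, 10,000 null pairs (30+30) for the type-I error, 2,000
replicates for the resampling-bias check, and 100 paired simulations for
the rare-variant experiment. These sizes give Monte-Carlo standard errors
comfortably inside the asserted tolerances while keeping a full run in
well under a minute per component.

## Known limitations

* Real Bayesian trees (the original discrimination evidence) are consumed,
  never inferred; the NJ builder is a fixture tool.
* The confidence interval and the Mann–Whitney test inherit the
  independence violation of pairwise-distance inputs from the procedure
  they reproduce.
* Haplotype counts under `exclude_sites` are not monotone in sample
  addition (adding a gapped row can shrink the comparable region); the
  monotonicity property holds only for `include`.
* The identification module implements only the best-close-match variant;
  "best match" (thresholdless) and "all species barcodes" are out of
  scope.
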