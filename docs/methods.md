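# Methods

## The design this package models

`ptxmap` analyses an F1 cross between two highly heterozygous, outbred
parents — the *pseudo-testcross* design used for linkage mapping in clonally
propagated crops such as cranberry (*Vaccinium macrocarpon*). A marker
heterozygous in exactly one parent (configurations ABxAA and AAxAB)
segregates 1:1 like a backcross, so each parent yields its own map;
double-heterozygous markers (ABxAB, 1:2:1) tie the two parental maps
together, and four-allele markers (ABxCD, 1:1:1:1) are informative for both
parents at once.

## DH recoding and pairwise recombination

Uniparental markers are recoded to which of the het parent's two homologs
each progeny received (0/1), as in a doubled-haploid panel. ABxCD markers
contribute one such recoded copy to *each* parental set, because both
transmitted alleles are observable; the published protocol maps these 68
markers but does not state its handling, so the split is this package's own
choice. ABxAB markers are recoded only at homozygous progeny (a het
offspring does not reveal which parent sent which allele) and are reserved
for map integration.

For a marker pair, `r = R/N` over pairwise-complete gametes and the
two-point LOD is `(N−R)·log10 2(1−r) + R·log10 2r` (`N·log10 2` at r = 0).
Because each marker's 0/1 polarity is arbitrary before phasing, grouping
uses the phase-folded `min(r, 1−r)` and the LOD evaluated there. Groups are
the single-linkage closure of edges with LOD > 10 and r < 0.35; phases are
then fixed by a breadth-first walk that flips any marker whose raw r to an
oriented neighbour exceeds 0.5.

## Bins, ordering, error scan, distances

Markers with zero observed recombination on pairwise-complete entries
collapse into bins (single-linkage components of that relation; the
representative is the member with the least missing data, ties broken on
marker id). Bin representatives are ordered by: minimum spanning tree of the
complete r-weighted graph → longest tree path as the backbone → insertion of
off-path bins where they least increase SARF (the sum of adjacent
recombination fractions) → an exhaustive sliding ripple with window 5 until
no improvement. Orientation is canonicalised so the first bin has the
smaller original index.

A genotype that differs from *both* adjacent informative genotypes of the
same gamete is an apparent isolated double crossover; on a dense map these
are overwhelmingly genotyping errors, so they are set to missing, and a
marker with more than 5 % of its informative genotypes flagged is dropped.
Distances are Kosambi transforms of adjacent recombination fractions,
`d = 25·ln((1+2r)/(1−2r))`, accumulated from 0 per linkage group. Adjacent
distances (rather than multipoint likelihood) keep every number
oracle-checkable; the downward bias at the simulated marker densities is a
few percent (see below).

## Integration of the parental maps

Each ABxAB anchor is placed in both parental frameworks with the parental
orders held fixed (SARF-minimising slot between adjacent bin
representatives; its cM coordinate from Kosambi distances to the flanking
representatives). Linkage groups are paired by shared-anchor majority; the
paternal axis is flipped when anchor positions run in reverse; the
integrated coordinate of an anchor is the mean of its two parental
coordinates (made monotone), and uniparental markers are carried over by
piecewise-linear interpolation between anchors, with unit-slope linear
extension beyond the terminal anchors. A pair with fewer than two shared
anchors is emitted unmerged with a warning. The commercial regression-based
merging used in the original protocol is proprietary and is *not*
reproduced; this anchor-averaging rule is the package's declared, testable
substitute.

## Segregation distortion

Each classifiable marker is tested by Pearson chi-square against its
Mendelian ratio — df 1 (1:1), 2 (1:2:1) or 3 (1:1:1:1). The expected ratio
is derived mechanically as the multiset of sorted offspring genotypes over
the four gamete combinations, so no per-configuration case analysis exists
to get wrong. Markers with p < 0.001 are excluded from mapping input;
p < 0.10 is flagged as distorted; thresholds are raw p-values with no
multiple-testing correction, matching standard practice for these scans.
The "favored class" is the class with the largest signed deviation from
expectation. MAF uses allele counts over 2×(non-missing progeny calls);
the filter order is missingness/MAF first, then (optionally) imputation,
then distortion exclusion.

## Imputation

Calls are class-coded per marker (AA=0, AB=1, BB=2; four codes for ABxCD).
*Median* fills with the per-marker modal class. *PC* reconstructs the
mean-filled, marker-centered samples×markers matrix at rank k and rounds to
the nearest valid class. *LDA* computes the population's first k SVD sample
scores once from the mean-filled matrix and fits, per marker, a linear
discriminant of the observed classes on those scores (solver `lsqr`,
fixed shrinkage 0.02 on the pooled covariance — Ledoit–Wolf auto-shrinkage
collapses the linkage signal and was measurably worse). Computing scores
once instead of excluding each marker's own row is a deliberate
approximation: exact exclusion costs one eigen-update per marker, and one
row among thousands perturbs the subspace by O(1/m). Markers whose
discriminant cannot be fit fall back to median and are logged. Observed
entries are never altered; k defaults to 80 and is capped at
min(samples, markers)−1.

Masking cross-validation hides 5 % of observed entries uniformly at random
(default; 10 repetitions) and reports the misclassified fraction — the
criterion for choosing k. The original study reports neither its masking
fraction nor its repetition count; these defaults are declared, not
inferred.

## Linkage disequilibrium

Gametic LD uses `r² = D²/(π_A π_a π_B π_b)` with `D = π_AB − π_A π_B`,
computed from phased 0/1 gamete vectors over pairwise-complete entries;
this equals the squared Pearson correlation and is asserted against it.
Decay pools all intra-LG pairs genome-wide per parent into half-open 5-cM
bins over 0–50 cM; the decay distance linearly interpolates the first
downward crossing of the threshold (0.2) between bin centers. No smoothing
is applied. In a full-sib family mean r² at recombination fraction θ is
(1−2θ)² plus a finite-sample inflation of ~1/n; the two-locus harness draws
pairs at θ equal to the Kosambi inverse of their separation
(θ = 0.5·tanh(2d/100)), which is the analytic reference the curves are
checked against.

## Genome statistics

Chakravarti method 4 inflates each LG's observed length by (m+1)/(m−1);
coverage is ΣL/ΣGE. Genome size defaults to 470 Mb (the cranberry
estimate) and is a configurable constant; Kb/cM reports the float and its
integer part. "Average gap" is defined as length/(unique positions − 1);
the published tables' gap column does not match any denominator derivable
from their printed totals, so this package documents and uses its own
definition.

## Scaffold anchoring and microsynteny

A scaffold inherits the majority LG of its mapped markers (a tie excludes
it as conflicted — the original protocol states no conflict rule, so this
one is ours) and the median cM of its supporting markers. Pseudomolecules
concatenate anchored scaffolds in cM order (ties lexicographic) with 100-N
spacers, unoriented. Homology hits are filtered at e ≤ 1e-10, bit score
> 80 (strict) and alignment length ≥ 50 bp; each CDS keeps its best hit
(lowest e, ties by score; K=1 to avoid paralog blow-up, configurable). Two
CDS < 10 cM apart whose best hits share a reference chromosome < 10 Mbp
apart form a syntenic pair; pairs sharing a CDS chain into blocks
(single linkage) and a block needs ≥ 2 pairs. Macrosynteny is not
automated; the dot-plot table is exported for visual inspection.

## The synthetic-data generator

`simulate_cross` emulates the study conditions: 362 progeny, 12 chromosomes
with the published integrated-map lengths, marker configurations at the
published proportions 1977:2370:1273:68 (taken as absolute counts, 5688
markers total), ≤20 % missingness (default 10 %) and genotyping error
(default 0.5 %). Unique marker positions arise as a sequential process with
mean 2-cM gaps; several markers share each position, which is what creates
non-trivial cosegregation bins (the real map has ~3 markers per unique
position). Meiosis is interference-free: crossover counts are
Poisson(L/100) with uniform positions. Interference does not change the
*mean* event count, which is what the recombination summaries measure, but
note the consequence below. Errors replace a call with a different valid
class for the configuration; planted distortion is post-meiosis viability
selection with coefficient s against one homozygote class at a chosen
locus. Everything is deterministic given the config (seed included), and
the returned truth object carries phases, crossovers and masks, so every
genotype is reconstructible.

What the generator does *not* emulate: read depths and allele-dropout
structure of GBS, SSR markers, interference, segregation distortion of
biological origin beyond single-locus viability, and assembly errors in the
scaffold fixtures. Passing tests therefore demonstrate correctness of the
estimators under a clean generative model, not robustness to every artefact
of real GBS data.

### Known numerical consequences

* Simulated meiosis is Haldane (no interference) while map distances use
  Kosambi. At a 5-cM effective gap the Kosambi transform of a Haldane
  recombination fraction is ~4.5 % short, so recovered map lengths sit
  systematically below the nominal simulated lengths (tests compare
  against the correctly transformed expectation, not the nominal length).
* Counting sign changes on a 2-cM marker grid observes only odd-parity
  crossover counts per interval, a further ~1 % loss: the expected observed
  events per gamete are ≈0.99·L/100 at the simulated densities.
* The two-locus Kosambi-pairwise mode exists because a multilocus crossover
  process exactly consistent with the Kosambi function is not well defined;
  LD-decay references use the two-locus mode, multilocus simulations use
  the Poisson model.

## Problem sizes used in the shipped checks

Deterministic map statistics run on the packaged 12-row published summary.
Stochastic checks simulate at the design size n = 362 (decay curves with
200 pairs per 5-cM bin, averaged over 10 seed replicates; recombination
counts averaged over 3 replicates). Property tests that sweep seeds use
reduced crosses (2–3 chromosomes, 450–600 markers, 150–250 progeny), chosen
so the whole suite completes in a few minutes while keeping every
per-marker quantity at realistic within-LG densities.

## Degenerate inputs and tie-breaks

Ties everywhere break lexicographically on marker id; LGs are numbered by
descending marker count; LG orientation is canonicalised. Pairs with no
complete gametes are uninformative (excluded from grouping; adjacent
uninformative gaps map to 0 cM with a warning). Adjacent r ≥ 0.5 reports a
map break and clamps. Markers with every call missing cannot be imputed and
are dropped with a reason. A monomorphic locus in the pairwise-complete
subset has undefined r² and the pair is skipped and counted. An LG with
fewer than 2 markers has no Chakravarti expected length and is excluded
from coverage with a warning.

## Known limitations

Multipoint likelihood ordering, sex-averaged map estimation beyond the
anchor-averaging rule, QTL mapping, haplotype/HMM imputation, VCF input,
scaffold orientation and reciprocal-best-hit filtering are out of scope.
The double-recombinant scan assumes dense maps; at sparse densities real
double crossovers would be flagged at a higher rate than errors.
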