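# Methods

This note documents the models, statistics, numerical conventions and
deliberate design choices behind `radiascope`, in enough detail that every
test expectation can be reproduced by hand or by an independent
implementation.

## Trees, bipartitions, comparison

`PhyloTree` is a rooted node structure; an unrooted tree is represented
with a basal multifurcation, and all split-level operations work on
*unrooted bipartitions* in canonical form (the side not containing the
lexicographically smallest taxon). With a degree-2 root the two root edges
are one unrooted edge; contraction, NNI and internal-edge enumeration all
treat them as such. Robinson–Foulds distance is the symmetric difference of
nontrivial bipartition sets (polytomies allowed); the normalized form
divides by the sum of the two trees' internal-edge counts (2(n−3) for a
binary pair), and the "differing branches" convention is RF/2.

Support values are auto-scaled: any value above 1 switches the tree to a
percent scale, and values in (0, 1) coexisting with values above 1 are an
error. `collapse_low_support` contracts internal edges with support
*strictly below* the threshold; unannotated edges are never collapsed —
an absent value means "not tested", not "poorly supported".

Per-tree covariates: tree length, diameter (max tip-to-tip path),
stemminess (internal/total length), mean support and threshold
proportions, and clocklikeness — the coefficient of variation of
root-to-tip distances using the **population (n-denominator) standard
deviation**, so distances {1,1,1,2} give CV = sqrt(0.1875)/1.25 ≈ 0.3464.
Unrooted inputs are midpoint-rooted for this metric and flagged.

## Synthetic-data generator

The generator is first-class, tested code: it defines the study conditions
every downstream check runs under.

**Species trees.** Backward Yule construction: with k lineages the next
(older) join waits Exp(k·birth_rate), giving E[root age] = Σ_{k=2..n}
1/(k·λ). Defaults: birth rate 0.1/Ma, diploid Ne = 5×10⁵, generation time
g = 1 yr, substitution rate 10⁻³ subs/site/Ma — all overridable per
branch. With the defaults one Ma equals one coalescent unit
(d = T·10⁶/(2·Ne·g)), which makes ground-truth bookkeeping transparent;
the conversion round-trips to better than 12 significant digits because it
is a single multiplication.

**Gene trees.** One sampled lineage per species (matching one genome per
species in the motivating data). Lineages are carried up the species tree;
within a branch, k lineages coalesce pairwise at rate k(k−1)/2 per local
coalescent unit, with per-branch Ne and g setting the local unit. Each
lineage accumulates branch length simultaneously in Ma, local coalescent
units and subs/site (per-branch rate), so one simulation yields all three
length systems. The simulator is validated against the closed form
q1 = 1 − (2/3)e^(−d) at d ∈ {0.1, 0.5, 1, 2} with 10,000 loci.

**Hybridization** is a locus-level tree mixture (pulse introgression): the
recipient clade is re-attached to the donor branch at the midpoint of
their temporal overlap, and each locus follows the rerouted tree with
probability γ. This is deliberately *not* continuous migration — a mixture
is sufficient to produce the asymmetric quartet signal the tests target,
and its expectations are closed-form (the mixture of two MSC quartet
distributions). Per-locus seed streams are shared between the plain and
hybrid simulators, so γ = 0 reproduces the plain output byte-for-byte.
Note that rerouting a clade across the root split changes only the root
position, not the unrooted topology; meaningful scenarios reroute within
one side of the root.

**Estimation error.** Each internal edge is independently NNI-perturbed
with probability p_nni (a proper unrooted NNI, including across
root-adjacent edges); then the floor(collapse_fraction × n_internal)
shortest internal edges are contracted, emulating aLRT-style collapsing of
weak branches. Branch-length noise is multiplicative lognormal with median
multiplier 1 (exp(N(0, sd))), so medians are unbiased and rate-recovery
tests can separate noise from signal.

**Sequences.** GTR with the six exchangeabilities and equilibrium
frequencies, scaled to mean rate 1; discrete-gamma heterogeneity with four
equal-probability categories at median rates renormalized to mean 1.
Transition matrices come from one eigendecomposition per distinct
frequency vector (cached), so the parametric-bootstrap screens can afford
tens of thousands of simulated alignments. Nonstationarity is a
composition shift: edges whose subtree lies inside a designated clade use
equilibrium frequencies retuned to a GC target with within-class A:T and
C:G ratios preserved. No indels, recombination or selection are simulated;
alignments are gapless, so occupancy-driven behaviour is exercised through
the window-fixture generator instead.

**Window fixtures** emit alignment blocks (or, at published-tally scale,
metadata-only locus records) plus BED-like annotation intervals arranged
so the partition operation reproduces requested category counts exactly by
construction.

What passing tests on these synthetics do *not* show: robustness to
alignment error, gappy occupancy patterns inside loci, intralocus
recombination, or selection — real-data features the generator omits by
design.

## Locus windows

Within each window the contiguous 1-kb sub-span (configurable) maximizing
summed per-column occupancy over the first 2 kb is selected by exact scan
(stride 1 default; coarser strides supported for speed); ties go leftmost.
Fragment filtering computes the median ungapped length once, over all
sequences, before any removal — one pass, deterministic — and drops
sequences strictly under half the median (exactly-half survives); loci
with fewer than four surviving sequences are rejected as a value, not an
error. Classification is 0-based half-open with overlap = at least one
shared base; a locus overlapping both exon and intron annotation counts as
exon-overlap (this precedence is what makes the published class counts
additive; it is our choice, recorded, not the original authors' documented
rule). Set union demands disjoint id spaces and errors on the first
duplicate id.

## Quartet machinery

For each internal branch with a binary context, the four adjacent groups
are read off the tree (a branch meeting the root of the rooted
representation takes the sibling subtree's two children as its far-side
groups). One-per-group tuples are counted per gene tree by an aggregation
identity rather than enumeration: a tuple resolved as AB|CD is separated
by the k edges of its central path and witnessed by the k+1 vertices on
it, so

    count(AB|CD) = Σ_vertices (component patterns with the AB-pair and the
                   CD-pair in disjoint components, at least one pair
                   sharing a component)
                 − Σ_edges (patterns split AB | CD across the edge)

counts each resolved tuple exactly once; polytomy-star tuples cancel.
Implementation is bitmask popcounts vectorized over all edges/vertices of
all gene trees; an explicit `itertools` enumeration oracle ships alongside
and the two are asserted equal on hundreds of random instances with
missing taxa and polytomies.

Unresolved quartets contribute to no topology by default (matching a
collapse-then-count workflow); an optional 1/3-each mode exists for
sensitivity checks. Default weighting normalizes each gene tree's
contribution to one (its within-tree resolved-quartet proportions), so
counts are non-integer and effective n equals the number of contributing
gene trees; raw tuple counts are also reported. The exact effective-n
treatment for missing taxa in the original workflow is not documented;
ours is stated here, not asserted as identical.

Derived statistics per branch:

- **Coalescent length**: d = −ln(1.5(1−q1)); q1 ≤ 1/3 → 0; values within
  e^(−cap) of 1 return the cap (default 10) flagged saturated.
- **Local posterior**: P(resolution i | counts) under the multinomial
  quartet likelihood with an Exp(prior_rate) branch-length prior (default
  0.5) and equal 1/3 topology priors; closed form via the regularized
  incomplete beta, checked against quadrature to 1e−6; weighted counts
  supported.
- **Polytomy test**: Pearson chi-square of the (rounded) three counts
  against n/3 each, 2 df.
- **Asymmetry test**: for a pair (a, b), statistic (a−b)²/(a+b), 1 df;
  one-sided with p/2 when the observed direction matches H1, 1−p/2
  otherwise, and p = 0.5 exactly at a = b. The branch family is a
  parameter (the original pooling is ambiguous); BH runs separately within
  each comparison family. The default alternative-vs-alternative direction
  is canonical group order, which keeps the test valid (uniform null);
  an "observed" larger-vs-smaller mode exists for ranking but is
  anti-conservative and excluded from size guarantees.
- **Multilocus bootstrap**: loci resampled with replacement, species tree
  re-estimated per replicate, per-branch support = fraction of successful
  replicates containing the reference bipartition; failed replicates are
  excluded and counted.

**Species-tree estimation** maximizes the total quartet score (fraction of
resolved gene-tree quartets concordant with the candidate, via a cached
per-gene-tree labelling of all four-taxon subsets). Below eight taxa the
maximum is found by exhaustive enumeration of unrooted topologies —
measurements showed plain NNI hill-climbing strands in local optima on
8–11% of weak-signal six-taxon instances, and at that scale enumeration
(105–945 topologies) is cheaper anyway. From eight taxa up, a greedy
consensus of complete-gene-tree bipartitions (frequency order,
compatibility-checked, deterministically resolved) seeds best-improvement
NNI hill-climbing; all ties break on the lexicographically smallest
canonical newick. Statistical consistency is checked by Monte Carlo at ten
taxa (2,000 clean loci, internal branches ≥ 0.5 CU).

## Locus diagnostics

Parsimony-informative columns have at least two states each present in at
least two sequences (A/C/G/T only); GC is per taxon over unambiguous
bases. ΔGC = mean |GC difference| over (focal, background) pairs minus the
mean over cross-focal pairs; zero in expectation under stationarity,
positive when the two focal groups resemble each other more than the
background. The original supplement's exact formula is not reproduced
here; this cross-minus-within form satisfies every stated property and is
recorded as a stand-in. Note that with only four sequences every PI column
is a 2+2 pattern with entropy exactly 1 bit — the saturation statistic is
informative only with more taxa, which the tests respect by screening on
eight-taxon trees.

Both screens are parametric bootstraps: the statistic (across-taxa
composition chi-square; mean PI-column entropy in bits, gaps excluded) is
compared with n_sim simulations under the supplied stationary model and
tree, p = (1 + #{sim ≥ obs})/(n_sim + 1), n_sim ≥ 19 enforced. The
"all simulations misleading" rule is operationalized as high-risk when the
observed statistic exceeds all but at most `risk_count` (default 0)
simulated values. A shared null distribution can be supplied when many
loci share the model and tree. The quantile analysis splits loci into
rank-order groups (stable ties, sizes within one), re-estimates per group
and reports RF to a reference.

## Subsampling designs

Locus subsampling draws without replacement within a replicate
(with-replacement resampling lives only in the bootstrap), independently
across replicates, seeded from one root seed via named substreams. Clade
difficulty classes follow all-replicate recovery: `easy` (consistent from
the smallest size), `needs_N` (consistent from size N on), `unresolved`
(never consistent at the largest size); the consistency threshold defaults
to 100% and is configurable. Taxon subsampling keeps all members of a
group smaller than the requested size and rescores the restricted
reference tree against restricted gene trees with the standard
missing-taxon rules. Data-type variability is the mean pairwise RF matrix
(cross pairs off-diagonal, within pairs on the diagonal, missing for
single-tree groups).

## Rates and demography

A gene-tree branch is concordant with a species-tree branch when their
bipartitions agree after restricting the species tree to the gene tree's
taxa; restrictions that become trivial or collide across species branches
are skipped for that locus (conservative). In particular the two
root-adjacent species branches share one unrooted bipartition and are
therefore never attributable. Each concordant branch contributes
(subs/site length)/(branch duration in Ma); per-branch summaries report
median (robust to the lognormal noise model; the default headline number)
and mean, with contributing-locus counts.

ρ = T/d is the branch's Ma-per-coalescent-unit ratio (= 2·g·Ne in years);
with a supplied generation time, Ne = T·10⁶/(2·g·d), reported missing for
saturated d. Absolute Ne is not claimed — the quantity is for
branch-to-branch comparison, and outputs are labelled 2·g·Ne-scaled when g
is unknown (global default 1 yr otherwise). Binning through time uses
1-Ma bins by default, either by branch midpoint or overlap-weighted
(weights per branch sum to its duration); empty bins are missing, never
zero.

## Trait signal

V is the matrix of shared root-to-tip path lengths; Pagel's λ scales only
the off-diagonal entries (the standard transform, chosen over
tip-branch stretching). Simulation draws from N(root_state, σ²V(λ)) via
one Cholesky per parameter set. The λ likelihood profiles the ancestral
mean and σ² analytically; writing V(λ) = D^(1/2)(I + λW)D^(1/2) with
D = diag(V), one symmetric eigendecomposition of W makes each likelihood
evaluation O(n), so 100 fits on a 363-tip tree take about a second.
Optimization is bounded Brent on [0,1] (xatol 1e−6) with both endpoints
checked; zero-variance traits yield a flagged missing fit; missing taxa
are dropped and counted. PGLS estimates (X'V⁻¹X)⁻¹X'V⁻¹y under BM (λ = 1)
or with λ profiled by ML; residuals are in response units ("relative brain
size" when y is log brain volume and x log body mass).

Misplacement prunes each selected tip (round(fraction·n), sampled without
replacement) and re-attaches it at a uniformly random point on a uniformly
random branch, pendant length chosen to keep the tip at age 0 — the
reattachment distribution is our choice; the original procedure does not
specify one. Convergence forces round(fraction·n/2) cross-group pairs to
share the first member's value. Ancestral states under constant-rate BM
are the GLS conditional expectations given the tips (this constant-rate
reconstruction is a labelled stand-in for multiple-variance approaches,
which are out of scope); branch values are endpoint means, binned with the
same through-time machinery.

## Pipeline

One YAML config; the root seed fans out into fixed per-stage substreams,
so enabling or disabling a stage never shifts another stage's randomness.
Stages run in dependency order (validation errors name the missing
dependency before anything runs), every output file is sha256-checksummed
into a manifest, and identical config + seed reproduces identical
checksums.

## Problem sizes used in the tests

The automated suite runs the closed-form MSC checks at 10,000 loci per
branch length; polytomy-test calibration on 2,000 simulated branches of
250 loci; asymmetry size on 200 pure-ILS families of 500 loci and power on
five replicates of 10,000 loci at γ = 0.3; Ne recovery end-to-end at
10,000 loci on an eight-taxon tree; rate recovery on 1,002 noisy loci;
screen size on 300–400 loci with 99 parametric simulations each and power
on 100 loci; estimator consistency on eight replicates of 2,000 loci at
ten taxa; and λ recovery with the full 100-trait, 363-tip design. These
sizes were chosen so each check's Monte-Carlo error is small against its
tolerance band.

## Known limitations

- Gene trees are simulated topologically exactly, but "coalescent-unit"
  branch lengths sum locally rescaled units across branches with different
  Ne — a deliberate convention, documented, matching how summary methods
  interpret them.
- The root-adjacent attribution gap (above) means per-branch rate and Ne
  tables have no entries for the two branches flanking the root split.
- Quartet machinery assumes fewer than a few dozen taxa per analysis
  (bitmask words scale, but the all-quartets labeller is O(n⁴) memory);
  the trait machinery scales to hundreds of tips.
- The asymmetry test's power depends on the canonical direction matching
  the introgression signal; designed analyses should order the comparison
  by hypothesis, as the power tests do.
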