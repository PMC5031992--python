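# Methods

## The event model and the minimum-event distance

Profiles are vectors of non-negative integer total copy numbers over
genomic fragments, with chromosome boundaries marked.  An *event* selects
one chromosome, one contiguous run of fragments, and adds +1 or −1 to every
covered fragment.  Two variants are used:

* **Strict (directed).**  An event may never cover a fragment whose current
  copy number is 0; consequently a fragment at 0 never regains copies, and a
  target with copies where the source has none is unreachable.  For
  reachable pairs the minimum number of events has a closed form: per
  chromosome, split `D = target − source` into positive part `P` and
  negative part `N`; the minimum is
  `Σᵢ max(0, Pᵢ − Pᵢ₋₁) + Σᵢ max(0, Nᵢ − Nᵢ₋₁)` (with `P₀ = N₀ = 0`),
  i.e. one event per unit "ascent" of the difference profile.  Intuitively,
  a stack of nested interval indicators of unit height is a minimal
  decomposition of `D`; the strict no-zero-coverage rule never forces more
  events because gains and losses are applied by single-signed runs that
  can always be ordered to avoid crossing zero.  This is not assumed but
  *verified*: a breadth-first search over the exact event model (the BFS
  oracle) agrees with the closed form on the exhaustive set of profile
  pairs with ≤4 fragments and CN ≤ 4 and on 10,000 random 5-fragment pairs.
* **Relaxed (symmetric).**  The same ascent count without the reachability
  check.  It is symmetric, zero on identical profiles, and satisfies the
  triangle inequality (the ascent count is subadditive over sums of
  difference profiles), so it is usable as a dissimilarity for
  distance-based tree building, where finiteness is required.

The strict count annotates tree branches and cross-checks the simulator;
the relaxed count feeds neighbour joining.  Distances are integer event
counts; no normalisation by genome length is applied.  This total-copy-
number event metric is a deliberately simplified, fully specified and
oracle-verifiable stand-in for allele-specific evolutionary distances
used by finite-state-transducer methods (MEDICC); no attempt is made to
match those numerically.

## Breakpoint harmonisation and filtering

All coordinates are 0-based half-open internally; SEG-style TSV input is
declared 1-based inclusive and converted on read.  Sex chromosomes are
dropped on load (counted in the log).  Within each chromosome, the union of
all samples' segment boundaries defines the fragment grid; each sample's
value on a fragment is its covering segment's CN.  Regions a sample does
not cover — possible only in toy or synthetic input, since array profiles
are genome-wide — are filled with that sample's ploidy rounded to the
nearest integer (its neutral state) and logged.  Fragments are then
filtered to length strictly greater than 500 kb (configurable).

Ploidy adjustment subtracts the sample's (real-valued) average genome copy
number, so 0 always means "no change relative to this genome's baseline"
and diploid and whole-genome-doubled samples are comparable on one axis.

## Tree inference and ancestral reconstruction

A pseudo-sample with CN 2 everywhere is appended, pairwise relaxed MEDs are
computed, and neighbour joining is run with deterministic tie-breaking
(candidate pairs are compared by Q-criterion, then by the lexicographically
smallest leaf labels of the clusters), so the topology is independent of
input order.  NJ is implemented in-package rather than through a library
because the determinism contract, the clamping of negative branch lengths
to 0, and the collapsing of zero-length internal edges are all part of the
method: an internal edge of length 0 carries no event evidence, and keeping
it would manufacture arbitrary resolutions of true polytomies (and would
break the chromosome-subsampling calibration, which relies on clades
vanishing when their supporting chromosome is excluded).  The unrooted tree
is rooted at the diploid pseudo-leaf, encoding the assumption that every
tumour lineage begins from a normal diploid genome.  Internal nodes are
labelled with roman numerals in pre-order.

Ancestral integer profiles are assigned per fragment by a Sankoff dynamic
programme over states 0..(max observed CN + 1) with per-edge cost
|child − parent| and the root fixed at 2; among co-optimal states the
smallest copy number is chosen (biasing against unobserved amplification).
Per-fragment |Δ| parsimony is an approximation to whole-profile event
parsimony — it ignores that one event spans several fragments — chosen for
tractability and determinism; it is validated by exact recovery of
simulated ancestors (100 % of noiseless replicates in the acceptance run)
rather than by an optimality proof.  Branch events are the strict directed
MED from parent to child, falling back to the relaxed count if the strict
model deems the child unreachable (possible after whole-genome doubling).

## Clade confidence

Support for each clade of the source tree is its recovery frequency over 30
replicate trees, each built from a random draw (without replacement) of 15
of the 22 autosomes.  One master seed spawns per-iteration RNGs, so
iterations are independent and individually replayable, and results do not
depend on sample order.  Replicates are rebuilt with tree inference only
(no ancestral reconstruction) and re-rooted at the diploid pseudo-leaf; a
clade a replicate leaves unresolved (polytomy) counts as absent, which is
conservative.  Clades with support < 0.5 — strictly, so exactly 0.5 is
retained (majority rule) — are collapsed bottom-up into their parents.  A
clade supported by events on exactly one chromosome is recovered precisely
when that chromosome is drawn, so its support follows Binomial(30, 15/22);
this is the calibration the tests check.

## Category representatives and transition analysis

The representative ancestor of a category is the internal node maximising
the F1 score between its leaf descendants and the category's samples (ties
resolve toward the root); the diploid root represents the "diploid"
category.  A category split across clades is represented by the majority
clade; a single-sample category by that sample's parent.  Patients lacking
a category simply skip the transitions that need it.

Transition profiles subtract consecutive representatives' ploidy-adjusted
profiles: diploid→central, central→EPE, EPE→lymph, and primary→bone, where
the bone transition's parent is whichever of the patient's central/EPE
representatives is the nearest ancestor of its bone representative.  A
representative node's "ploidy" is its length-weighted mean CN rounded to
the nearest integer (sample-level ploidies exist only for leaves), which
keeps transition values at integer differences for diploid lineages.
Representative profiles are re-harmonised across patients (union of all
patients' breakpoints, then the >500 kb filter); fragments one patient's
filtered grid does not cover are filled with the neutral state, logged.

Each harmonised fragment is tested by one-way ANOVA with transition as the
group factor and one observation per patient per transition (group sizes
are therefore small and unbalanced, matching the study design).  Fragments
with zero total variance get p = 1 and a flag.  P-values are adjusted by
the Benjamini–Hochberg step-up rule; the Benjamini–Yekutieli variant is
available by flag, but BH is the default because it is the rule the
published adjusted values actually follow (all twelve rows of the
concordance table reproduce under BH to the printed precision, which the
acceptance script recomputes).  Rows with adjusted p below 0.25
(configurable; figure shading conventionally uses 0.1) are reported.

## MLPA validation

Raw MLPA intensities carry a technical trend with probe length.  The trend
is estimated by least squares on the benign control sample(s) — whose
uniform CN 2 leaves the fit uncontaminated by CNAs — and divided out of
every sample; per-sample fitting is available when no control exists but
distorts tumour/control ratios on aberrant genes, since the tumour-side fit
absorbs its own CNAs.  Gene ratios are probe-level tumour/control ratios
averaged within gene, and calls use ploidy-shifted thresholds:
`adjusted = ratio − (ploidy − 2)/2`, loss below 0.75, gain above 1.25
(defaults are the midpoints between expected ratios for CN 1/2/3 in a
diploid background; both configurable).  With integer copy numbers this
adjustment is exact: `cn/2 − (ploidy−2)/2 = 1 + (cn − ploidy)/2`, so a gene
at the sample's ploidy is always neutral.

A probe is informative for a branch when the array-derived direction
(loss/neutral/gain relative to the node's integer baseline) differs between
the branch's parent and child.  Each (informative probe × descendant sample
with MLPA data) pair is a trial; success means the MLPA call equals the
sample's own array-derived direction.  Significance is the two-sided exact
binomial test (the sum of all outcome probabilities no larger than the
observed one) with null success probability 0.33 — one of three categorical
outcomes — and p-values are FDR-adjusted across branches.  Branches with no
informative probes are reported with p = 1 and a flag.

## Category geometry

Centroids are arithmetic means of ploidy-adjusted profiles per category (or
of transition profiles per transition).  Distances are Euclidean.
Robustness uses leave-one-patient-out replicates — one matrix per patient
plus the full-data matrix — because the replicate count equals the patient
count; categories emptied by the removal are flagged and dropped from that
replicate.  Classical MDS double-centres the squared distances, takes the
top eigenvectors scaled by root eigenvalues, truncates negative eigenvalues
at zero, and fixes orientation by making each axis's largest-magnitude
coordinate positive, so embeddings are reproducible.

## The synthetic cohort

The generator emulates the study conditions: 6 patients with 5–9 sampled
clones each; per-patient clone trees whose categories respect the lineage
constraints (benign → central → EPE → lymph node; bone from central or from
EPE); at least one ±1 segmental event per edge (Poisson with mean 3,
minimum enforced), runs of at most 4 fragments within one chromosome,
floors at CN 0 with no regain; 22 autosomes of 10 fragments each with
lengths uniform on 0.6–10 Mb so everything passes the >500 kb filter;
roughly a fifth of samples whole-genome doubled ("triploid-like" in array
terms); observed segmentations merge equal-CN runs and, when noise is on,
jitter interior boundaries by up to ±10 kb to exercise harmonisation.
Sample ploidy metadata is the length-weighted mean CN of the observed
profile, as an allele-specific caller would estimate it.  One RNG stream
per patient derives from (seed, patient index), so patients are independent
and individually reproducible; the fragment grid derives from the seed
alone and is shared cohort-wide (one reference genome).

Events on one edge are placed on distinct chromosomes, and by default every
event in a patient occupies a run disjoint (with a one-fragment margin)
from all others (`private_events=True`).  This makes the strict directed
distance from parent to child exactly the number of events applied — the
oracle linking simulator and metric — and keeps pairwise distances additive
on the clone tree.  Setting `private_events=False` allows recurrent and
overlapping events (homoplasy).  MLPA intensities are
`base × (cn/2) × (1 + slope·length) × (1 + N(0, σ))` with per-probe base
signals and lengths uniform on 70–500 nt; most simulated genes sit on
fragments aberrant in at least one sample, as in a cancer CNA panel, and a
benign all-CN-2 control is always included.

What passing on these data does **not** show: robustness to recurrent CNAs
(real prostate tumours share 8p loss / 8q gain across lineages — homoplasy
that the private-event default excludes from benchmarks), to subclonal
mixtures within a sample (purity is metadata only), to allele-specific
effects (total CN only), or to array-level measurement noise beyond
breakpoint jitter.  Whole-genome-doubled samples are simulated and flow
through ploidy adjustment, MLPA calling and geometry, but topology-recovery
benchmarks use diploid cohorts: a doubled genome breaks the additivity of
total-CN event distances (and allele-specific methods equally assume no
WGD), so mixed-ploidy tree accuracy is a documented limitation, not a
tested guarantee.

## Problem sizes and numerical choices

Test and acceptance runs use the sizes above (60–100 simulation replicates
for recovery rates, 300–500 replicates for calibration, 3,000–10,000 random
pairs for oracle agreement), chosen to keep the whole suite in the
low minutes while leaving binomial 99 % calibration intervals tight.
Zero-length internal edges are collapsed at tolerance 1e-6 (distances are
integers, so NJ arithmetic on them is exact in floating point).  The BFS
oracle refuses state spaces beyond ~2·10⁵ states.  Ancestral-state ties
resolve to the smallest CN; NJ pair ties resolve lexicographically; MDS
signs are fixed per axis.  Degenerate inputs (all-identical profiles, star
trees, empty categories, zero-variance fragments, branches without
informative probes) are handled explicitly and flagged rather than
erroring, except where the result would be meaningless (no fragments left
after filtering, fewer than 3 samples, fewer autosomes than the subsample
size).
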