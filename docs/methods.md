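# Methods

## Scope and data model

`gapdelim` operates on aligned single-locus barcode fragments (mitochondrial
16S ~440 bp or COI ~650 bp; nuclear ITS-1 for congruence checks) joined to
specimen metadata (morphospecies label, locality, Britain/Ireland flag,
new/GenBank source, locus). Alignment construction is out of scope: inputs
are assumed aligned, and rows of unequal length are rejected as unaligned.
Identical sequences — exact string identity after uppercasing, with gaps and
ambiguity codes compared literally — are collapsed to haplotypes labelled
H1, H2, … in first-occurrence order, keeping the full specimen-to-haplotype
map. Collapsing is idempotent and conserves specimen counts.

## K2P distances

Distances use Kimura's two-parameter correction,
d = −½·ln[(1−2P−Q)·√(1−2Q)], with P and Q the transition and transversion
proportions over the sites compared. Sites with a gap or any IUPAC ambiguity
code in either member of a pair are excluded for that pair only (pairwise
deletion), mirroring the convention of the standard phylogenetics GUIs; each
pair therefore carries its own `sites_used`. Transitions are A↔G and C↔T;
every other difference between unambiguous bases is a transversion. Whenever
the logarithm argument is non-positive the pair is *saturated*: it is
reported as a flagged error and any matrix containing such a pair is refused
downstream. Clamping to an arbitrary large value would inject a spurious
"gap" exactly where gap detection is most sensitive.

## Barcode-gap partitioning

The gap scan works on the sorted distinct pairwise distances
d(1) ≤ … ≤ d(N) with gaps g(i) = d(i+1) − d(i). Given a prior maximum
intraspecific divergence P, the significant gap is the smallest i with
d(i) ≥ P and

    g(i) > X · w(i)    and    g(i) > d(i)

where w(i) is the mean of the preceding min(W, i−1) gaps; for the first gap,
where no preceding gaps exist, w is the mean of all *other* gaps (zero when
the first gap is the only one, so a two-valued distance set is splittable).
X defaults to 1.5 (relative gap width) and W to 10; `bins` (20) only controls
the diagnostic distance histogram.

The second condition — the gap must at least double the distance at which it
occurs — is this module's operational hardening of the windowed relative-gap
test. Ranked distances inside a single intraspecific cloud have roughly
exponential spacing, for which a spacing exceeding 1.5× a running mean is a
~20% event per gap; a first-exceedance rule alone therefore shreds dense
clouds at arbitrary ranks. Requiring a change of divergence *scale* matches
what the term barcode gap means empirically (interspecific divergences
observed at ≥ 2.5× intraspecific ones, a property the test battery asserts)
and leaves all toy constructions with genuine structure splittable. The cost
is that hierarchical levels separated by less than a doubling (e.g. 0.10 vs
0.18) are not split; for barcode-scale data this regime is far inside the
zone where no method distinguishes structure from noise.

Partitioning is single linkage: connected components (scipy) of the graph
joining haplotype pairs at or below d(i). Group ids are contiguous from 1,
ordered by smallest contained haplotype index. The procedure then recurses
within every group of ≥ 3 members and ≥ 2 distinct distances until nothing
splits; groups of ≤ 2 members are never re-split. The recursive partition
refines the initial one by construction, an invariant the property tests
exercise on random matrices.

The sweep evaluates the priors P_k = Pmin·(Pmax/Pmin)^(k/(steps−1)),
k = 0…steps−1, defaults Pmin = 0.001, Pmax = 0.2, steps = 20. Geometric
spacing spans the two orders of magnitude between plausible intra- and
interspecific scales without wasting steps at the top. Because the scan
requires d(i) ≥ P, priors above the largest intraspecific distance find no
qualifying gap and the partition collapses to one group — group counts fall
rapidly once the prior overshoots the gap, which is what the stability rule
relies on.

**Degeneracy.** A dataset with fewer than two distinct distances, or whose
mean pairwise distance is ≤ 0.005 substitutions/site (`degenerate_mean`),
has too little variation for gap-based delimitation and is flagged
degenerate: it is treated as a single species and the selection stage
records the flag instead of pretending a delimitation happened. The floor
corresponds to the "mean intraspecific distance ~0.001 or less" regime in
which real surveys declare families unanalysable, with headroom for sampling
noise at 650 bp.

## Stability selection (PSH)

At each prior the smaller of the initial and recursive group counts is used,
carrying the partition that attains it. Maximal runs of consecutive priors
with equal count are collected; among counts whose run spans ≥ `min_run`
(default 3) priors, the smallest wins, with ties going to the run starting at
the lower prior, and the reported partition taken at the run's smallest
prior. The trivial count 1 — which every dataset reaches once the prior
overshoots the gap — is excluded from candidacy unless it is the only stable
count; the selection records when this exclusion fired. The largest prior of
the chosen run is reported as the "maximum prior intraspecific divergence
over which stable". Degenerate sweeps yield a flagged single-species
selection rather than an error.

## Trees, monophyly, bootstraps

Neighbour joining, midpoint rooting and Newick I/O are delegated to
scikit-bio. Negative NJ branch lengths are clamped to zero (the library's
behaviour; additive matrices are still recovered exactly, which the
acceptance tests assert to 1e−9). Two-leaf midpoint rooting is handled
explicitly since the general rerooting degenerates there. Monophyly is an
unrooted clan test — a group is monophyletic iff it is exactly one side of
some bipartition — so results are rooting-invariant, and singleton groups are
trivially monophyletic. The test suite verifies the clan test against
exhaustive edge-removal enumeration on an independent graph representation.

Bootstrap support resamples alignment columns with replacement, recomputes
K2P distances with pairwise deletion *of the resampled columns*, rebuilds the
NJ tree, and scores each group per replicate; support is the percentage of
usable replicates. Replicates containing a saturated or incomparable pair
are dropped and counted. Support attaches to bipartitions, not nodes.
Bayesian posterior probabilities appear only as externally supplied fixture
evidence; no MCMC is implemented.

## Refinement to SSH and downstream comparisons

"Monophyletic" for rule purposes means NJ bootstrap ≥ 75 (the display
threshold used in published figures) in at least one relevant analysis
(whole-family or subset); single-haplotype PSHs are trivially monophyletic.
Morphological uniqueness is external OR internal "yes"; "uncertain" does not
count as unique for merging but does not veto acceptance under strong
monophyly. The rules: R1 accept; R2 split along subset-analysis children
whose clades are supported (a PSH whose whole-group support clears the
threshold keeps its split plan unused); R3 merge a declared
morphologically-indistinguishable set when its joint clade is supported; R4
keep the members separate otherwise (each must then be individually
monophyletic). Every decision is logged with its rule id; a PSH that is
non-monophyletic with no split plan or merge evidence is an error, not a
silent acceptance.

The fauna comparison counts SSH species matched to ≥ 1 checklist name,
lumped pairs (one SSH absorbing two names), split known species (two SSHs
sharing one name), and additional species (no name), with the percentage
increase rounded to the nearest integer. The conflict table classifies
mito/morphology discordance per species pair as one- or two-way; one-way
direction names the recipient morphospecies (individuals carrying foreign
mtDNA, i.e. hybrids descended from a donor-species mother). Nuclear
congruence tests each group for monophyly on a nuclear tree and flags a
shared pool when ≥ 2 groups are individually non-monophyletic while their
union is a clade.

### Packaged reference bundle

The package ships a transcription of the summary evidence of a DNA-barcoding
survey of the slugs of Britain and Ireland: 45 putative species with
haplotype/individual counts, mean intra/min-inter distances, four monophyly
supports each, morphology flags, a split plan (PSH 1 → 1A | 1B+1C) and three
merge-candidate sets ({7,8}, {9,10}, {33,34,35,36}); a 36-name checklist of
the previously known fauna; and the name correspondences of each refined
species. Blank morphology cells in the source table are encoded "no", "?" as
"uncertain". Joint-clade supports for the merge sets are not printed in the
source table, which reports only whether each union was monophyletic; they
are encoded as 99 (monophyletic) or 0 (not monophyletic in any analysis) —
the engine consumes only the ≥ 75 comparison. Running `refine` on the bundle
reproduces the published accounting (42 refined species, 44 with the two
degenerate monotypic families; 36 accepted unchanged; 8 additional species,
+22%). The checklist entry for the common tramp *Deroceras* is encoded under
its current name (*D. invadens*) so that true *D. panormitanum* is, as
published, one of the additional species.

## Synthetic data

The simulator uses the two-parameter Markov chain that underlies the K2P
distance, with the rate matrix normalised to one expected substitution per
site per unit time, so branch length equals expected K2P distance and
calibration is closed-form. Defaults: transition/transversion rate ratio
κ = 4 (typical of animal mtDNA), uniform base frequencies (the K2P
stationary distribution), 650 sites, five species of six individuals, mean
intraspecific divergence 0.01 and interspecific scale 0.15 — the divergence
regime of well-sampled mollusc barcode surveys. Species sit on a star tree:
each species ancestor evolves (inter − intra)/2 from the root and each
individual intra/2 from its ancestor, so expected pairwise divergence is
`intra` within and `inter` between species. Targets whose expected
substitution count is below one site for the configured length are rejected
as unrealisable. Introgression directives re-source the mtDNA of an exact
rounded fraction of a recipient species' individuals from the donor ancestor
while morphology labels and any nuclear locus stay with the true species —
the maternal-capture pattern. Determinism: one `numpy` generator per
dataset; identical config + seed gives byte-identical sequences.

The fixed battery (`simulate_reference_suite`) covers clean K ∈ {2, 5, 9}
datasets, a near-zero-variation set (intra 0.002, flagged degenerate by the
sweep), an unbalanced 1-vs-50 set, a one-way introgression set
(intra 0.005, inter 0.10, half of the recipient introgressed), and a paired
mito/nuclear set in which five of six species share a single nuclear pool.

What the simulator does **not** emulate: rate heterogeneity among sites and
lineages, base-composition bias, coalescent genealogies within species
(individuals are star-shaped around their ancestor, so realized intraspecific
variation is more homogeneous than in real populations), recombination, and
selection. Passing tests therefore demonstrate correctness of the pipeline's
logic under the model assumed by the distance correction, not robustness to
model violation on real data.

## Verification problem sizes

The test battery runs the species-count recovery check over 100 seeds for
each K ∈ {2, 5, 9} (≥ 95% required), introgression classification over 50
seeds (100% one-way with correct direction required), single-linkage oracle
equivalence on 1,000 random matrices of ≤ 8 haplotypes against an
independent graph library, exact NJ recovery on 40 random 4–8 leaf additive
trees, the ≥ 2.5 inter/intra ratio on every clean battery dataset, and the
full published refinement accounting on the packaged bundle. These sizes
keep the whole suite around ten seconds while estimating the recovery rates
to within a few percent.

## Known limitations

- The gap test requires interspecific scales to at least double the local
  intraspecific scale; shallower structure is deliberately left unsplit.
- The prior is used directly as the lower bound of the gap search; no
  coalescent transform between prior and search threshold is applied.
- Single linkage chains: one intermediate haplotype below threshold merges
  two otherwise distinct clusters (inherent to the partitioning choice).
- Bootstrap supports on very short fragments are granular (each replicate is
  a whole-column resample) and saturated replicates reduce the effective
  replicate count.
- The refinement engine trusts its evidence table; it does not re-derive
  morphology or subset-analysis structure from sequences.
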