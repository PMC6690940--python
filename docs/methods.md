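# Methods

## The model

Phylogenetic endemism (PE) asks how much of a phylogeny's branch length is
geographically concentrated in one place. Every branch *c* of a rooted,
dated tree is weighted by the inverse of its range — here the number of
islands *R_c* on which at least one descendant genus occurs — and an
island's score is the sum of weighted lengths over the branches its genera
subtend:

PE(i) = Σ_{c∈C(i)} l_c / R_c,

with C(i) the union of tip-to-root paths of the island's genera and l_c in
millions of years. A branch endemic to one island contributes its full
length; a cosmopolitan branch contributes almost nothing. With a single
island in the matrix all R_c = 1 and PE reduces to Faith's PD.

PEalt replaces every branch length with a single value l (the arithmetic
mean branch length of the tree), keeping the topology, so it measures the
concentration of *branch rarity* alone. The ratio RPE = PE/PEalt exceeds
its null expectation where rare branches are disproportionately long
(old lineages) and falls below it where they are disproportionately short
(recent divergence).

Two range-weighting variants are computed. In the *expanded* variant every
genus native to an island counts, whether or not it also occurs on
continents. In the *restricted* variant any branch supporting at least one
continent-occurring genus has its denominator replaced wholesale by N_max
(the number of islands in the matrix), because such a lineage could in
principle occupy any island; island-restricted lineages then dominate the
score. The rule is applied to terminal and internal branches alike — a
branch with one continental descendant among many insular ones is still
down-weighted — which matches the reading that continental genera should
have "very little influence" rather than none; applying N_max only to
exclusively-continental branches remains available via the annotations one
passes. PE_R(i) ≤ PE_E(i) always holds when N_max ≥ max R_c, and is
asserted in the tests.

Branch ranges, and hence all three metrics, are computed as one boolean
matrix product between the incidence matrix and the tree's branch-by-tip
descendant matrix; the null-model loop evaluates stacks of randomized
matrices as a single batched contraction (float32 matmul, float64
accumulation), which keeps 1,000 randomizations of a few hundred islands
in seconds.

## Null model and significance

PE, PEalt and RPE all grow with richness, so observed values are ranked
against randomizations that preserve both matrix marginals: each island
keeps its genus count, each genus its island count. Sampling uses the
curveball algorithm — repeated trades between random island pairs of the
genera not shared by the two — whose steps preserve the marginals exactly
and whose stationary distribution on the fiber is uniform. One long chain
is run from the observed matrix with burn-in 5× the number of presences
and thinning of one presence-count between samples (a `restart` mode
re-burns per sample for auditing). A state in which no row pair has
exclusive presences (e.g. an all-ones matrix) is its own one-point fiber
and is detected and returned unchanged rather than spun on forever.

Tail frequencies are strict: freq_higher is the fraction of simulations
the observed value strictly exceeds, ties counting in neither tail
(conservative toward non-significance; at n_sims = 1000 ties are
essentially confined to degenerate fibers). RPE under the null is the
ratio of the simulated PE and PEalt of the same randomized matrix. Total
PE is identical in every randomization — a branch is present somewhere iff
its genera have positive column sums, which are fixed — so the null
redistributes evolutionary history among islands without creating it;
this conservation is asserted to 1e-9.

Categories are assigned from four frequencies (PE high, PEalt high, RPE
high, RPE low) at alpha = 0.05 and super-alpha = 0.01, thresholds
inclusive. Precedence is paleo → neo → super → mixed, after an OR-rule
significance gate on PE/PEalt. Islands that pass the gate but match none
of the four patterns (e.g. only PEalt high with a middling ratio) are
labeled `significant_other` and excluded from four-category summaries
rather than silently dropped. No multiple-testing correction is applied
across islands. For the restricted variant, metrics and the null model
always use the full matrix, but only islands harboring at least one
island-restricted genus are tested and classified.

Percentages in category summaries are rounded to two significant figures,
the precision at which such per-category shares are conventionally
reported.

## Preprocessing

Occurrence records pass two filters: removal when the genus is flagged
non-native in the island's region (unknown status falls through), then
removal when the coordinates fall strictly outside the genus's native
bounding box (boundary-inclusive; boxes crossing the antimeridian are two
longitude segments — a naive min/max would invert Pacific ranges). Both
filters are idempotent and report per-rule counts for a bias audit trail.

Island-level under-sampling is screened with a species–area model:
ordinary least squares of log10(richness) on log10(area), optionally with
log10(1 + distance-to-continent), chosen because the species–area power
law is the standard island richness predictor and the exclusion rule needs
only a prediction. An island is excluded when observed richness falls
below predicted/factor (default factor 5). Fits on fewer than 10 islands
proceed but are flagged unreliable.

Sampling completeness per island is scored with the incidence-based
coverage estimator (ICE, Lee–Chao form with the standard infrequent-taxon
cutoff of 10 and the squared-CV term over N_inf²), as ICEr = S_obs/S_ICE ∈
(0, 1]. When all infrequent taxa are singletons the estimator's coverage
term is zero; a Chao2-style fallback is returned flagged unstable.
Sampling units are caller-defined (collection events in real data,
simulated visits in synthetic data). How ICEr should *correct* the metrics
is exposed as a mode rather than hard-wired: `off` (default),
`divide_observed` (observed scores divided by ICEr, compared with the raw
null) and `divide_both`. Because tail frequencies are rank statistics, a
positive per-island factor applied to both observed and null values
cancels — `divide_both` provably changes reported scores but never
categories, and the tests assert exactly that. The sensitivity sweep
(re-running the analysis on islands with ICEr above a rising threshold and
flagging category changes) is therefore the primary use of the score.

## Synthetic worlds

The generator emulates the statistical shape of occurrence-derived island
data: a Yule tree (pure birth, no extinction — chosen so terminal-branch
scaling gives direct control over branch-age signal), a zeta-distributed
islands-per-genus occupancy (exponent 2 by default, matching the strong
right skew of natural-history data; rarity is the lever of endemism), and
continental flags drawn Bernoulli per background genus. Signal is planted
through two pools of rare genera — long terminal branches (×m_long) and
short ones (×m_short) — steered onto designated islands with probability
κ, dealt round-robin so every planted island receives a comparable share;
pool genera occupy at most two islands (one in the strong scenario) and
are never flagged continental. Occurrence records are emitted 1–3 per
presence around island centroids, and noise is injected as *spurious*
presences (genus–island pairs absent from the clean matrix) placed outside
the genus box or flagged non-native in a region where the genus has no
clean record, so inverting the filters must recover the clean incidence
exactly — the generator's bookkeeping is the oracle.

Two canonical conditions are frozen: a *null world* (40 islands, 300
genera, uniform occupancy, no pools) for type-I calibration, and a
*strong planted world* (60 islands, 300 genera, κ = 1, m_long = 10,
m_short = 0.1, single-island pools of 20% of genera each, two planted
islands per class) for recovery. Under the OR-rule significance gate with
two correlated tests at alpha = 0.05, the expected per-island significance
rate on null worlds lies between 0.05 and 1 − 0.95² ≈ 0.0975; observed
rates sit in that band. On strong worlds planted paleo and neo islands are
recovered at ≈0.9 recall; planted *mixed* islands are frequently labeled
paleo or super rather than mixed — with both pools present the long
branches tend to dominate the ratio — a known ambiguity of
ratio-based classification, not a defect of the implementation.

What passing these tests does *not* show: the generator has no spatial
autocorrelation between neighboring islands, no collector-effort gradients,
no taxonomic misidentification, and its bounding boxes derive from the
same coordinates that generate the records; real-data filter performance
will be worse than the oracle recovery here.

## Numerical and design choices

- Tip labels are opaque case-sensitive strings after trimming; genus-to-tip
  matching is exact, unmatched names surfaced, never guessed.
- A root edge in the source Newick is ignored everywhere (it would add the
  same constant to every island's path); the PEalt mean is over all
  non-root branches, unweighted. Zero-length branches are retained: they
  add 0 to PE but l to PEalt, as the uniform-topology reading implies.
- N_max defaults to the current matrix's island count; an external value
  (e.g. a worldwide island total) can be supplied when analyzing a subset.
- Incidence rows/columns are sorted by identifier, making matrix
  construction invariant to record order and runs byte-reproducible from
  (inputs, seed); all stage seeds derive from one top-level seed via
  seed-sequence spawning.
- Problem sizes in the test suite and acceptance script (300-genus trees,
  40–60 islands, 500–1,000 randomizations, 5–20 replicate worlds) were
  chosen as the smallest at which the binomial error bands of the
  calibration checks are informative.

## Known limitations

- The analysis is genus-level presence-only; no abundance weighting, no
  species-level PE, and no range-area weighting (island counts replace
  spatial ranges).
- The null model is marginal-preserving but spatially unstructured; it
  cannot express dispersal limitation between neighboring islands.
- ICE requires meaningful sampling units; with few units per island every
  taxon is "infrequent" and ICEr becomes noisy.
- `significant_other` islands indicate patterns the four-category scheme
  does not name; they are reported, not interpreted.
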