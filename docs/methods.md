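# Methods

## Coordinate frame and input formats

All mtDNA fragments are addressed in 1-based inclusive coordinates of the
circular bovine mitochondrial reference (V00654, 16 338 sites). A region may
wrap once through the origin; the D-loop fragment (16031–178) does, giving
486 columns, and concatenated with the ND5 fragment (12911–13091, 181
columns) forms the 667 bp haplotype region. The frame assumes a gapless
reference per fragment: alignment columns map one-to-one onto reference
positions, which is adequate for short amplicons aligned to a same-length
reference. Alignments are read from pre-aligned FASTA (alignment
construction is out of scope); metadata from TSV with columns
`id, site, region, period, date_early, date_late, age_bp, sex`.

Gap (`-`) and `N` are distinct symbols: a gap is an alignment deletion and
drives column exclusion, `N` is unknown data and is ignored per site.

Sample ages are years before 1950 (the radiocarbon BP datum). Samples dated
only by archaeological context carry a calendar range; a point date is drawn
uniformly over the range — the minimal assumption for a context interval —
from a per-sample stream keyed by (sample id, seed), so results are
reproducible and independent of call order.

## Haplotypes, cohorts and grouping

Haplotype collapsing defaults to complete deletion: columns carrying `-` or
`N` in any sample are removed before comparison (the standard behaviour of
haplotype software on gapped alignments); a greedy pairwise-compatibility
mode exists for sensitivity checks only, as compatibility is not transitive.
Labels H01, H02, … are assigned canonically — descending carrier count, then
lexicographic sequence — so labels are invariant under input order.

Temporal cohorts use half-open calendar bins [700 BC, 1200), [1200, 1550),
[1550, 1800), [1800, ∞); date ranges bin by midpoint. The grouping scheme
for ancient-vs-modern comparisons marks the single most frequent haplotype
of the combined panel as `common` (ties broken by lexicographically smallest
sequence), the remaining haplotypes as `ancient_shared`, `unique_ancient` or
`not_found_in_ancient` by panel occurrence.

## Haplogroup classification

Classification is a deepest-match walk over a tree of diagnostic rules
(label, parent, required alleles at reference positions). Semantics chosen
for degraded ancient DNA:

- a rule matches only if every required site carries exactly the required
  base; the deepest exact match wins (configuration order breaks ties);
- a required site that is `N` or uncovered skips the rule and its subtree;
- an IUPAC ambiguity covering the required base does not contradict the rule
  but does not advance depth (conservative: damaged bases never push a call
  deeper);
- if no diagnostic position at all is covered the call is `unassigned`.

Consequences, verified by property tests: private mutations at
non-diagnostic sites can never change a call, and any sequence assigned a
child label satisfies every ancestor rule.

The rule set is data, not code. The shipped default fixes the T/Q split at
position 15953 (the one position hard-wired by the marker design) and
carries placeholder positions for T1, T1f, T2, T3b, T4, T5, P and R in the
published-motif style; T3 is the all-reference default profile. Any
project-specific site list can be loaded from the same TSV format, and no
quantitative result in this package depends on the placeholder positions —
synthetic panels derive their truth from whatever rule set they are given.

Y haplotypes are called from a single base: the UTY intron-19 transversion
at position 423 (reference AY936543). The allele→label mapping defaults to
G→Y2, T→Y1 but is configuration — the polarity is taken from the cited
literature, not asserted; any other symbol yields `no_amplification`.

## Diversity statistics

Per cohort: S excludes indel-bearing columns and ignores `N`; K is the mean
Hamming difference over all pairs on the same retained columns, skipping
sites where either sequence is `N`; π = K/L with L the retained length.
Hd, θ_W = S/a₁ and Tajima's D follow the standard formulations (the a₁…e₂
constants are exposed as a dataclass). D is undefined at S = 0 and returned
as NaN with a warning.

Significance of D uses the scaled-beta approximation of the null
distribution: D is assumed beta-distributed over its theoretical range
[Dmin, Dmax] with mean 0 and variance 1, and the two-sided p is
2·min(F(D), 1−F(D)). This matches the tabulated confidence limits of the
classic implementations; a coalescent-simulation p could be added but the
beta approximation is what the reference software reports.

### Heterochrony correction

For sample ages t in years BP, the expected inflation of π is
μ_year · mean pairwise |tᵢ−tⱼ|, because a pair sampled Δt apart shares
2T−tᵢ−tⱼ = 2(T−t_old) + Δt branch years instead of 2(T−t_old). Hence
π_hμ = π − μ_year·Δt̄, clamped at 0 with a warning. The rate is configurable
as per-site-per-Myr (default; 0.43 means 43%/Myr), per-site-per-year, or
per-site-per-generation with a generation length (5 or 7 years are the
conventional cattle values). The default rate of 0.43/Myr with generation
length 5 reflects the upper/lower bracketing used for Near-Eastern cattle
control-region data; both bracket values (0.34–0.53) are accepted.

The serial-coalescent experiment in `analysis/05_heterochrony_bias.py`
validates sign and scale: with ages spread over 20 kyr, mean K exceeds θ by
the predicted μ_year·Δt̄·L within Monte-Carlo error, and the correction
recovers θ/L.

## Median-joining network

Construction, at tolerance ε (default 0):

1. **Feasible links.** d(u,v) ≤ minimax(u,v) + ε, where minimax is the
   minimal over paths of the largest edge (computed on an MST). At ε = 0
   this is exactly the union of all minimum spanning trees of the node set.
2. **Median proposal.** For every triplet with at least two feasible links
   among its pairs, the per-column majority consensus; a three-state tie
   keeps the first sequence's symbol in canonical order.
3. **Addition criterion.** A proposed median is added only if it strictly
   reduces the minimum-spanning cost of the node set; candidates are tried
   in order of connection cost then sequence. One median per round, links
   recomputed, to a fixpoint. The strict-decrease rule guarantees
   termination and is the conservative reading of the ε = 0 setting.
4. **Reduction.** Median nodes of degree ≤ 2 in the final link graph are
   pruned iteratively.

Guarantees (property-tested): the final edge set contains every MST of the
final node set; an observed-haplotype MST edge absent from the network is
always bypassed by a path of strictly smaller edges (the cycle property that
justified dropping it); adding medians never increases the spanning cost;
the output is deterministic under permutation of the input because the
haplotype table is canonically ordered. Characters are unweighted.

Note the naming in the field conflates "reduced median" and "median-joining"
networks; what is implemented here is median-joining with ε plus
obsolete-node pruning — the behaviour of the standard network software on
multistate data. Export is GraphML (+ TSV edge list); nodes carry type
(observed/median), count, member ids and period composition; edges carry
weight and the differing positions. An optional static plot renders node
size ∝ carrier count with medians as black diamonds.

## Cohort frequency tests

Pearson χ² is uncorrected (no Yates continuity), df = (r−1)(c−1), p from the
χ² upper tail — this reproduces the published χ² = 355 on the 3×10 table, so
no correction was applied there either. The two-tailed Fisher exact p sums
hypergeometric probabilities ≤ the observed table's (SPSS/R convention;
verified against direct enumeration). The selection rule computes expected
counts and switches to Fisher when ≥ 20% of cells have E < 5 *and* the table
is 2×2; larger sparse tables keep χ² with a logged caveat, since the exact
test is only implemented for 2×2. Calibration on simulated independent
multinomial tables shows χ² rejecting at ≈ 5% for large counts and Fisher at
≤ 5% (conservative).

## Synthetic data

The generators are pure functions of (config, seed) and define the study
conditions used by the tests:

- **Serial coalescent.** Lineages activate backwards in time at their
  sampling ages (converted to generations via the generation length); while
  k are active, pairwise coalescence occurs at rate C(k,2)/(2Ne) per
  generation, so θ = 4·Ne·μ·L equals the expected K of an isochronous
  sample. Mutations are Poisson on branches, mapped to distinct uniform
  positions (infinite sites; collisions re-drawn), keeping distances
  additive for network tests. Desk-scale defaults used throughout the
  suite: n = 20, L = 500, θ = 5, 60–200 replicates — sizes at which the
  Monte-Carlo standard error of mean K is ≈ 0.2–0.3, small enough to
  resolve the heterochrony inflation studied (≈ 1.6 at a 20 kyr age
  spread).
- **Haplogroup panel.** Cohorts with configured sizes, haplogroup
  frequencies, Y1 frequencies and sex ratios; diagnostic alleles planted
  along the rule path, private mutations sprinkled only at non-diagnostic
  sites, UTY19 fragments emitted for males; truth labels recorded.
- **Multinomial count tables** for test calibration and power studies.

What these emulate is the *statistical* structure: heterochronous genealogy,
diagnostic-site determinism, multinomial cohort sampling. They do not
emulate post-mortem damage (deamination), contamination, alignment error,
recombination, selection or population structure; the replicate-based QC in
`pipeline` reflects an authentication protocol that is replicate-based, not
damage-model-based. Passing tests therefore demonstrate correctness of the
estimators and algorithms under the assumed models, not robustness to those
real-data artefacts.

## Replication QC and pipeline

A (sample, fragment) passes authentication when ≥ 3 amplifications yield an
identical sequence spanning ≥ 2 extractions and ≥ 2 laboratories (all three
thresholds configurable); failures are classified (insufficient replicates /
extractions / laboratories, discordant). `run_pipeline` chains
load → collapse → classify → per-cohort diversity → network → cohort tests,
logging sample counts at every filter, and its outputs are byte-identical
across reruns with the same inputs and seed. Cohorts below 4 samples are
reported without Tajima's D (undefined small-n behaviour) and skipped in the
per-cohort table.

## Numerical and design choices

- Printed per-cohort summaries and count tables of the reference dataset
  ship in `published` as *inputs*; everything derived from them (θ_W, D,
  significance flags, π = K/486, χ², Fisher p) is recomputed at run time.
  The printed pooled-cohort θ_S (7.736) is internally inconsistent with
  S = 33, n = 45 (S/a₁ = 7.547, which also matches the printed pooled D)
  and is treated as a typo: the package reports 7.547.
- Fisher ties use the standard 1+1e−7 relative slack on hypergeometric
  probabilities.
- Tajima's D significance threshold is two-sided 0.05, matching the
  starred-table convention.
- All randomness flows through explicit integer seeds; no global RNG state.

## Known limitations

- The exact test is 2×2 only; r×c exact or Monte-Carlo tests are not
  implemented (the published protocol used χ² there too).
- The heterochrony correction subtracts the *expected* inflation; it does
  not propagate age uncertainty beyond the uniform context-date draw.
- The shipped haplogroup rule set is a usable default, not an authority;
  real analyses should supply a curated site list.
- The 245 bp common-region coordinates used in ancient/modern comparisons
  are dataset-specific and must be provided as a region parameter.
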