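# Methods

## Problem setting

Direct experimental PPI coverage in cyanobacteria is sparse, while most of
the proteome lacks a functional annotation. The package infers a
genome-wide confidence-scored PPI network from seven indirect evidence
layers, then uses the network to (i) propose GO terms for unknown proteins
and (ii) extract and interpret functional modules. All components run
offline on a synthetic benchmark world that mimics the statistical
structure of the real inputs.

## Gold standard

The positive set (GSP) is the curated list of known interactions. The
negative set (GSN) is combinatorial: all pairs of proteins whose cellular
locations are disjoint, after excluding possibly mobile or secreted
proteins and any GSP pair. Locations are compared as direct GO
cellular-component terms plus their is_a ancestors with the namespace root
removed — every protein trivially reaches the root, so keeping it would
empty the set. The mobility flag is an input column, not inferred: the
judgement that a protein may relocate is curatorial, not algorithmic. The
GSN is kept in full by default (no subsampling); a seeded `max_size`
subsample is available for very large catalogs.

## Evidence features

| feature | value | missing when |
|---|---|---|
| coexpression | Fisher-z mean of per-dataset Pearson r, in [-1, 1] | gene absent or zero-variance in all retained datasets |
| ssbp | protein count of the most specific shared GO BP term (ancestors propagated) | no shared BP term |
| domain | number of cross-pair domain combinations in the DDI catalogue | either protein domainless |
| phylo_profile | Jaccard similarity of ortholog presence sets | an all-zero profile |
| neighborhood | fraction of informative genomes with orthologs ≤ K intervening genes apart on one replicon (K = 5) | orthologs co-present in < 1 genome |
| fusion | boolean: both proteins hit one target with span overlap < 20% of the shorter span | never (0 is informative) |
| cluster | boolean: same predicted operon (same strand, same replicon, intergenic gaps ≤ 300 bp) | gene not in the study genome |

An expression dataset is retained only if its GSP-pair correlations exceed
its GSN-pair correlations by a one-sided Mann–Whitney U test at α = 0.05 —
an explicit, testable form of "co-expression positively correlated with
interaction". Retained datasets are combined into one feature by Fisher-z
averaging rather than entering the integrator separately, keeping
expression a single evidence source among seven. The four genome-context
features use the canonical published definitions with all thresholds
exposed as configuration.

Missing evidence is absence, never zero: the integrator assigns a missing
feature likelihood ratio 1, so a pair is neither rewarded nor punished for
not being measurable.

## Naive Bayes integration

Continuous features are discretized into 5 quantile bins fitted on the
pooled GSP ∪ GSN values (boolean features get two categorical bins; a
feature with fewer distinct values collapses to distinct-value bins with a
warning). Per-bin likelihood ratios use Laplace smoothing,

    LR(b) = [(c_pos(b) + α) / (N_pos + αB)] / [(c_neg(b) + α) / (N_neg + αB)],

with α = 1 and B the bin count, so every ratio is finite and positive even
for empty bins. Prior odds default to |GSP| / |GSN| (overridable with a
genome-wide estimate). Posterior odds are the prior times the product of
per-feature ratios; the high-confidence cutoff is *strictly* greater than
5. Only pairs carrying at least one observed feature are scored by
default; GSP pairs are excluded from the predicted set and enter the
merged network with GSP provenance instead. Ties in the ranking break on
the canonical (lexicographic) pair so output order is deterministic.

## Simulated-annealing annotation

Known proteins keep their annotations, mapped up to the set of level-5
ancestors (minimum is_a distance 5 from the namespace root; the root is
level 0). Candidate terms are the level-5 terms occurring among the fixed
annotations of the network, falling back to all level-5 terms of the
namespace. Each unknown protein carries exactly one candidate term per
run; the energy is the number of network edges whose endpoints share no
term, and moves (reassign one random free protein to one random candidate)
are accepted by the Metropolis rule. Multi-term annotations arise from
aggregating 100 independent runs (seeds `base_seed + i`): a term is
accepted for a protein only when its cross-run frequency strictly exceeds
a background-noise threshold, computed as mean + 2 SD over a seeded random
sample of 10% of the (protein, term) frequency-table cells, zeros
included. Sampling cells (rather than runs or proteins) is one of several
defensible readings of "a random 10% of results"; the fraction, the
statistic, and the sampling unit are all configurable.

The cooling schedule is geometric: T₀ = 1.0, γ = 0.9, 5·|free| moves per
temperature, T_min = 0.01 (≈ 44 temperatures). This short schedule reaches
the enumerated optimum on every solvable test instance while keeping 100
repeats on a 300-protein network in tens of seconds; longer schedules are
a configuration change, not a code change. Energy is maintained
incrementally across moves and the bookkeeping is checked against a
from-scratch recount in the tests.

## Module detection and enrichment

Vertex weight is the MCODE core-clustering coefficient: the highest k-core
number of the node's open neighborhood graph times that k-core's density
(degree < 2 ⇒ weight 0). Complexes grow breadth-first from unvisited
seeds in descending weight order, admitting neighbors whose weight is at
least (1 − 0.2) × the seed's weight, then iteratively shedding members
with fewer than two intra-complex links (haircut) and dropping complexes
without a 2-core. Nodes join at most one complex; all tie-breaks are
lexical. A known limitation of this (published) growth rule: the weight
threshold, not connectivity, gates expansion, so equally dense regions
joined by even one qualifying edge merge into a single complex — dense
blocks of a planted-partition graph are recovered only when no
between-block edge touches a high-weight node.

Each core is extended with its first-layer neighbors; sub-networks are
tested against every pathway with the hypergeometric upper tail
P(X ≥ k), the population being proteins with ≥ 1 pathway annotation
(conservative; a whole-genome population is available). P-values are
Benjamini–Hochberg adjusted within each sub-network; significance is
adjusted p strictly below 0.05.

## Interolog evaluation

Ortholog maps come either from input tables or from reciprocal best hits
with both E-values strictly below 1e-10 (ties broken lexically with a
warning). A predicted pair is *mapped* in a foreign species when both
members have orthologs there, and *conserved* when the ortholog image is a
known foreign interaction. Conservation fractions are reported with the
mapped-pair denominator, and also over all predictions, since the two
conventions differ substantially.

## Synthetic world

The generator plants a modular interactome — 300 proteins in 8 equal
modules, within-module edge probability 0.25, background 0.002 — with 60%
of proteins function-unknown and 30% of true pairs revealed as the known
PPI set. Each evidence layer has an independent signal-strength knob:
expression datasets share per-module latent profiles (amplitude 1.0, noise
SD 0.7, plus one pure-noise dataset to exercise retention); known proteins
are annotated to (a depth-6 child of) their module's level-5 GO term with
probability 0.9; 80% of true pairs plant an interacting domain
combination; gene order, reference-genome adjacency, and presence/absence
profiles are module-correlated (signals 0.7–0.8); 30% of true pairs get a
fusion target; pathways mirror modules; two foreign species carry the
ortholog image of half of the mappable truth plus 50% noise edges.
Localization is module-correlated (flip probability 0.25), which makes the
cross-location GSN deplete true pairs as in a real cell.

These defaults were chosen once as a plausibly informative regime — signal
levels at which each layer is individually noisy but clearly
truth-associated — and define the benchmark conditions. Setting every
signal to zero yields the null world used as a false-positive guard. What
the synthetic world does *not* emulate: realistic microarray noise
structure, sequence-level homology, unequal module sizes, scale-free
degree distributions, or annotation biases of real GO corpora — so passing
tests demonstrate correctness of the machinery and recoverability of
planted structure, not performance on real data.

## Numerical and design notes

- Pairs are canonicalized (lexicographic) at construction; nothing
  downstream sees orientation. Self-pairs are rejected everywhere.
- Pearson r is clipped to ±0.999999 before the Fisher z-transform to keep
  perfectly correlated toy profiles finite.
- All stochastic stages (GSN subsampling, annealing, world generation)
  take explicit seeds; `run_all` derives every stage seed from one base
  seed and writes byte-identical outputs on rerun. Wall-clock timings go
  to the logging stream only.
- Degenerate inputs fail loudly: empty GSP or GSN, a feature with no
  gold-standard coverage, an empty pathway universe, and cyclic ontologies
  are errors, not silent defaults.
- Problem sizes in the test suite and acceptance script (300-protein
  world, 100 annealing repeats, 80-protein worlds for pipeline
  round-trips) were chosen as the smallest sizes at which every planted
  effect is statistically unambiguous.

## Known limitations

- The naive-independence assumption is wrong for correlated evidence
  (e.g. neighborhood and cluster both derive from gene order); posterior
  odds are a ranking score, not calibrated probabilities.
- MCODE-style growth merges equally dense adjacent regions (see above).
- The annealer's single-term-per-run move set cannot represent genuinely
  multifunctional proteins within one run; multi-term output exists only
  through cross-run frequencies.
- SSBP uses term size in proteins (not term depth) as the specificity
  measure; the alternative is a configuration switch away but untested
  against real corpora.
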