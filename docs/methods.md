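# Methods

## The selection model

The package treats screening-library design as a subset-selection
problem over a pool of candidate compounds (PCC). The objective couples
three things a good deck should have: predicted bioactivity, coverage of
many protein families, and a bias toward families of current research
interest.

**Target prediction** is 2D similarity transfer: a query compound is
assigned the active targets of every reference compound whose Morgan
(radius 2, 2048-bit) fingerprint has Tanimoto similarity ≥ 0.5 to the
query. All neighbors above the threshold contribute (a union, not a
k-nearest cut): the threshold itself is the retention rule, and the
number of neighbors searched is an implementation detail of the
similarity scan, so the union is the faithful reading. Predicted
"bioactivities" are unique (compound, target) pairs regardless of how
many neighbors support them. Queries with no neighbor at or above the
threshold get no prediction and are reported as dark chemical matter;
they are excluded from the PCC but remain in the property-filtered pool
from which baseline libraries are drawn.

**Family novelty.** Targets map to protein families via a mapping table
produced upstream (e.g., by HMM scans of target sequences against a
family database). Targets with no assignment share a single dummy
family, `PF_DUMMY`: they are known to differ from the classified
targets but not from each other, so pooling them is the conservative
choice; the dummy family participates in novelty scoring and fitness
like any other. Family novelty is

    novelty = n_after / (n_after + n_before)

counting dated bioactivity records published in or after 2010 (a record
dated exactly 2010 counts as recent). The counting unit is the merged
bioactivity record — one per (standardized structure, target) pair —
and each record contributes to every family of its target. Records
without a date are excluded from the counts; a family with no dated
records receives the arithmetic mean of the directly scored families.
A multi-family target's own novelty (used only for per-library median
reporting) is the mean of its family scores; the combination rule is a
package choice, as no canonical rule exists.

**Merged-pair year.** When replicate measurements of one pair are merged
(median activity; mean of the two middle values for even counts), the
merged record carries the *earliest* dated replicate's year — the first
report of the bioactivity is when the interaction entered the record.
Pairs with no dated replicate keep a null year and drop out of novelty
counting only.

**Fitness.** For a library of N compounds,

    fitness = ( Σ_f  novelty_f · (1 − r^count_f) / (1 − r) ) / N

where `count_f` is the number of *distinct* library compounds predicted
to interact with at least one target of family *f* (a compound hitting
two targets of one family counts once; a target in two families
increments both), and the common ratio r defaults to 0.99 — at that
value the per-family series plateaus slowly, so repeat coverage keeps
paying off while diversity still dominates. r is configurable for
sensitivity analysis. Because of the 1/N normalization, fitness is only
comparable between libraries of equal size; every report carries N.

## The genetic algorithm

An individual is an ordered sequence of N distinct PCC compounds; a
population holds M individuals. Per generation:

- **Elitism / selection.** The P fittest individuals survive unchanged,
  with P the largest even number ≤ M/3 (at least 2; M ≥ 6 required).
  Parents are mated in pairs, hence the even rounding. Ties in fitness
  are broken by earlier population index (stable sort).
- **Crossover.** Parents are paired uniformly at random without
  replacement; each pair yields four children from a midpoint split at
  ⌊N/2⌋: A1+B2, B1+A2, A1+B1, A2+B2 (for odd N the same-half children
  take complementary-length pieces of the second parent so every child
  has length N). Pairing rounds repeat until the M − P child slots are
  filled; surplus children are discarded in generation order. The
  four-children construction is an interpretation: a midpoint split
  passing half of a parent to each child pins down the two mixed
  children, and the two same-half children are the natural completion.
- **Repair, then mutation.** Duplicate compounds inherited from both
  parents are repaired by replacing the later occurrence with a uniform
  draw from the PCC excluding current members (rejection sampling, which
  is exactly uniform on the complement). Each child is then mutated at
  ⌊0.10·N⌋ positions chosen uniformly without replacement, replacements
  again drawn from the PCC excluding current members. Note the floor:
  at N < 10 the default rate mutates zero positions and all variation
  comes from crossover repair. Mutation draws come from the PCC only,
  even when baseline pools include dark matter.
- A single seeded NumPy generator drives initialization, pairing,
  repair and mutation, so a (config, seed) pair fully determines the
  run. Best fitness per generation is non-decreasing by elitism.

**Baseline libraries** are the fittest of max(1, ⌊0.1·N⌋) uniformly
random N-subsets of the property-filtered pool *including* dark-matter
compounds — selection ignores predictions entirely; they enter only in
scoring. This is the comparison point for optimization gains.

Fitness evaluation is vectorized: a boolean compound × family
membership matrix and a novelty vector are precomputed once per pool,
reducing each evaluation to a row-gather, a column sum and a dot
product. Tests verify exact (1e-9 relative) agreement with a literal
term-by-term geometric summation over the unvectorized definitions.

## Standardization and filters

Standardization is RDKit's normalization stack: cleanup → largest
organic fragment (salt/solvent stripping) → charge neutralization where
chemically possible → canonical tautomer → stereochemistry stripped →
canonical SMILES. Stereochemistry is discarded because supplier
stereo annotations are frequently incomplete, and identity is wanted at
the constitution level; deduplication keeps the lexicographically
smallest id so results are input-order independent. Canonical-tautomer
output strings are toolkit-version dependent, so tests assert
idempotence and duplicate merging rather than exact strings.

Ring systems group SSSR rings sharing at least one atom, which treats
spiro junctions as part of one system — the conservative superset,
since ring-membership-based descriptions do not distinguish spiro from
fused. The ring count is SSSR. "Charged carbon" means any carbon with
nonzero formal charge *after* neutralization (e.g., trityl-type
carbocations that cannot be neutralized by proton transfer). The
structural-alert lists are consumed as a user-supplied `name SMARTS`
file because no canonical machine-readable list ships with the package;
only the tosyl pattern `S(=O)(=O)O` is built in. Verdicts report every
violated rule, not just the first, for reporting value. logP is
computed and reported but not re-filtered after standardization (the
upstream pool is assumed pre-bounded on logP); QED is descriptive only.

## Synthetic data

The generators are the package's study conditions, not conveniences.

**Annotation tier** (`synth_annotation_pool`, defaults: 10,000
compounds, 300 targets, 120 families, seed-deterministic): per-compound
predicted-target counts are zero-truncated geometric with mean 3
(promiscuity is heavy-tailed in real extracts); 30% of compounds are
dark; target popularity and family sizes are Zipf-skewed; 8% of mapped
targets carry a second family and 2% are unmapped (falling to the dummy
family), echoing the small multi-family and unassignable shares of real
target sets; family recency is Beta(3.5, 1.5) (mean 0.7, the typical
center of family novelty distributions), realized as Bernoulli
pre/post-2010 splits of per-target record streams over 1995–2020, with
3% of records undated. Realized novelty scores are exactly what the
scoring module recomputes from the emitted records.

**Chemistry tier** (`synth_chemistry_pool`): a grammar of 6 verified
scaffold cores × 10 substituents (plus optional aromatic methyl
decoration), every member of which passes all property filters by
construction, mixed with a violator suite of 12 molecules each designed
to break exactly one filter rule, plus a compliant control. The
synthetic bioactivity table draws its reference compounds from the
first four cores only, so queries built on the remaining cores have no
neighbor at similarity ≥ 0.5 and surface as dark chemical matter, as a
large share of purchasable compounds do. The grammar's structural
diversity is deliberately tiny (~10² distinct constitutions), enough to
exercise standardization, deduplication, fingerprinting, prediction and
clustering — not to emulate the scaffold diversity of a real pool.

What passing tests on these fixtures shows: the operations implement
their definitions exactly, the GA optimizes what the fitness function
says, and the pipeline is deterministic and self-consistent. What they
do not show: performance on real vendor pools and curated databases,
whose promiscuity structure, family imbalance, similarity landscape and
noise are far richer than the emulation.

## Numerical and procedural choices

- Tanimoto of two all-zero fingerprints is defined as 0.
- Thresholds are inclusive (≥) for prediction (0.5), clustering (0.4)
  and the activity cutoff (≤ 10,000 nM).
- Taylor–Butina: centroid ties go to the earliest input index; members
  are assigned to the first centroid that claims them; compounds whose
  neighbors are all already assigned become singletons (classic
  false-singleton behavior).
- Medians over even counts are the mean of the two middle values
  (activities, novelty reporting alike).
- Acyclic molecules have the empty Murcko scaffold, counted as one
  scaffold class.
- µg/mL→nM conversion uses the monoisotopic (exact) molecular weight of
  the standardized structure; the eligibility window uses the average
  molecular weight.
- Demonstration problem sizes (also used by `scripts/acceptance.py`):
  annotation pool 10,000 with N = 500, M = 50, 150 generations and 50
  baseline draws; chemistry pool 1,200 structures with a 600-record
  bioactivity table. These are the package's shipped scale: large
  enough for the optimization effect and funnel statistics to be
  stable, small enough to run in minutes on one CPU.

## Known limitations

- Fitness values are not comparable across library sizes; no
  size-normalized variant is provided.
- The prediction model transfers targets by similarity only; it ignores
  activity magnitude beyond the 10 µM cutoff and cannot predict targets
  absent from the reference.
- The GA uses fixed mutation and parenting schedules; no adaptive or
  island variants. At N < 10 with the default rate, mutation is a no-op
  and exploration rests on crossover repair.
- Novelty depends on publication-year metadata; families dominated by
  undated records inherit the fallback mean, which can misrank them.
- Exclusion-pattern screening is only as good as the supplied SMARTS
  list; only the tosyl alert is built in.
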