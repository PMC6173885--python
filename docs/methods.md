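# Methods

## The analysis in brief

`regcircuit` implements a regulatory-circuit discovery pipeline for the
setting where two phenotypically divergent groups of genetically identical
embryos (here: morphologically normal vs neural-tube-defect knockouts)
show divergent transcriptomes, and the question is which transcription
factors (TFs) drive the divergence.  The pipeline has four analytic
stages plus companion statistics:

1. **Expression conditioning.** A background directed TF→target network
   (e.g. an experimental-evidence extraction from a regulatory-interaction
   database) is reduced to a *general network*: an edge survives only if
   the regulator's transcript is detected in the embryos, the target is
   called differentially expressed in the comparison of interest, and the
   magnitude of the target's per-biological-replicate log2 fold change
   reaches 0.4.  Nodes with no surviving incident edge are dropped.
2. **Seed subnetworks and shared TFs.** Around each gene of interest
   (seed) the neighbors up to two levels are collected *ignoring edge
   direction* — the regulators of a non-TF seed would otherwise be
   unreachable — then pruned in two ordered steps: (i) one pass removing
   every node with fewer than two incident edges inside the subnetwork
   (the seed included), (ii) removal of remaining non-TF nodes, sparing
   the seed.  The candidate circuit is the set of TFs present in all seed
   subnetworks, seeds themselves excluded.
3. **Quadruplet null.** How unusual is a seed set sharing k TFs?  The
   same subnetwork recipe is applied to *every* possible quadruplet of
   nodes in the general network (or to every one-TF-three-non-TF
   quadruplet, mirroring the composition of the observed seed set) and
   the histogram of shared-TF counts is the empirical null.  The tail
   probability P(K ≥ k_obs) is the exact probability of the observation
   under random seed choice.  When C(n, 4) is infeasible, a seeded
   uniform subsample without replacement is taken and recorded in the
   provenance.
4. **Master-regulator ranking.** Every TF of the general network is
   scored by the sum of its unweighted directed shortest-path lengths to
   the genes of interest; only TFs with a directed path to *every* target
   are ranked (ascending sum, ties share a rank and are listed
   alphabetically).  For circuit reporting, shortest paths between genes
   of interest and circuit TFs are traced on the undirected projection,
   returning the lexicographically smallest node sequence and the count
   of equally short alternatives.

Companion statistics: efficiency-corrected qPCR relative expression
(`ratio = E_t^ΔCt_t / E_ref^ΔCt_ref`, ΔCt = control − treated mean Ct, so
ratio > 1 means up-regulation in the treated group), a pair-wise fixed
reallocation randomisation test on that ratio, Pearson correlation
matrices with 95% CIs from the Fisher z transform (significance ⇔ CI
excludes zero), grand-mean log centering for heat maps, hypergeometric
gene-set enrichment with Benjamini–Hochberg adjustment, and Fisher /
chi-square tests for genotype proportions.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `min_abs_log2fc` | 0.4 | log2 | the fold-change threshold of the edge filter |
| `detection_threshold` | 0 (strict >) | FPKM-like | any positive abundance counts as detected — the minimal defensible reading of "detected" |
| `replicate_rule` | `all` (criteria); `any` in the recovery pipeline | — | see below |
| `pseudocount` | 0 | FPKM-like | division by zero yields ±inf log2FC, which compares correctly against the threshold |
| pruning degree cutoff | 2 incident edges | — | one pass, not iterated (`iterate=True` available for sensitivity analysis) |
| `n_perm` | 2000 | reallocations | exhaustive enumeration whenever C(n, n_ctrl) ≤ n_perm |
| correlation CI | 95%, Fisher z | — | half-width 1.96/√(n−3); needs n ≥ 4 |
| heat-map centering | base 2, pseudocount 1 | — | the usual heat-map convention; both configurable |

### The replicate rule

"Evaluated per biological replicate" leaves open how per-replicate
decisions are merged: intersection (`all`, an edge must pass in every
replicate) or union (`any`, at least one).  `FilterCriteria` defaults to
the conservative intersection.  The end-to-end synthetic recovery,
however, runs with the union rule, and this is a considered choice, not a
tuning: under the generator's stochastic activity model (per-replicate
latent activity with sd 1 around group means 1.5 apart), the probability
that a truly responsive gene clears |log2FC| ≥ 0.4 in a *single*
replicate is capped near 0.78 regardless of effect size — the reference
group's lognormal mean inflates with the square of the effect while the
signal grows only linearly — so the intersection over three replicates
passes a true-positive gene only about half the time and no effect size
can rescue it.  The union rule keeps planted edges recoverable without
admitting false edges, because the filter also requires DE significance,
which synthetic null genes never have.  Both rules remain one switch
apart for real data, where the DE caller, not the fold-change filter,
carries the false-positive control.

### Other interpretation choices

- **Target vs regulator DE.** The filter requires the *target* to be
  differentially expressed; the regulator need only be detected.
  `require_regulator_de=True` switches to the stricter reading.
- **Seed exemption.** The seed is exempt only from the non-TF pruning
  step, not from degree pruning; a degree-1 seed prunes itself away and
  the empty subnetwork is a legal, recorded outcome.
- **Seeds in intersections.** Seeds are excluded from shared-TF
  intersections even when a seed is itself a TF: the question is which
  regulators act on all seeds, and self-membership is uninformative.
  `include_seeds=True` reports the inclusive variant alongside.
- **Self-distance.** A TF that is itself a gene of interest contributes
  d = 0 for itself (the standard graph convention);
  `exclude_self_targets=True` drops such TFs from the ranking instead.
- **Parallel opposite edges** between the same pair count as two incident
  edges in degree pruning (each stored directed edge counts once per
  endpoint); a self-loop contributes two.
- **Fisher two-sided definition**: the sum of point probabilities no
  larger than the observed table's (the conventional definition used by
  scipy); alternatives exist, hence the note.

## The synthetic generator

`generate_network` draws a sparse random TF→target background (30 TFs, 90
non-TFs, Poisson out-degree with mean 3) and plants a circuit: a master
TF regulating two integrator TFs, with master and integrators together
regulating every gene of two disjoint four-gene modules.  This guarantees
each module gene is within two undirected hops of the master and each
pair of module genes shares at least two direct TF regulators.

`simulate_expression` mirrors a three-group embryo-pool design (WT, KO-N,
KO-NTD × 3 biological replicates).  Each replicate draws a latent master
activity a ~ Normal(group mean, 1) with group means (0, 0, 1.5) — the
defect group is the divergent one.  "Lipid-like" module genes scale their
lognormal baselines by 2^(+effect·a), "neural-tube-like" genes by
2^(−effect·a) (effect = 1.0 log2 units per activity unit by default,
giving a true between-knockout-group log2FC of 1.5, an apolipoprotein
"strongly divergent" scale), and every measurement receives multiplicative
lognormal noise (sd 0.1, roughly 10% CV).  The DE table carries the
*true* expected log2FCs with significance = |log2FC| ≥ 0.4: the pipeline
consumes DE calls, it does not make them.  The shared latent activity
also produces the expected correlation signature across individual
embryos: positive within modules, negative between them.

`simulate_qpcr` writes Ct values exactly consistent with the
efficiency-corrected ratio model (the treated-group Ct shifts by
−log(ratio)/log(E), the reference gene is flat), plus optional Normal Ct
noise, so the noiseless case inverts exactly.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: realistic FPKM distributions and
mean–variance coupling, correlated or hub-biased background topology,
DE-caller uncertainty (significance flags are exact by construction),
batch effects, and any gene-identifier ambiguity.  Recovery of the
planted circuit demonstrates the pipeline's correctness and statistical
behaviour, not the biological validity of any particular network
database.

## Numerical and implementation notes

- Shortest paths and neighborhoods are unweighted BFS via networkx; the
  quadruplet null memoizes one pruned subnetwork per node (built by the
  identical code path as the observed statistic) so exhaustive
  enumeration over C(n, 4) quadruplets costs four set intersections each.
  Sampled mode unranks lexicographic combination indices drawn without
  replacement, so it is reproducible and scheduling-independent.
- The randomisation test's p-value includes the observed allocation in
  numerator and denominator in sampled mode; in exhaustive mode the
  observed allocation is one of the enumerated ones.  Because every
  allocation's mirror has the same |log ratio|, the smallest attainable
  two-sided p is 2/C(n, n_ctrl): with 3v3 designs no result can reach
  p < 0.1, which is why calibration checks use 5 samples per group
  (252 reallocations, attainable rejection rate 12/252 ≈ 0.048 at
  α = 0.05).
- Benjamini–Hochberg adjustment is delegated to statsmodels and
  cross-checked in the tests against a hand-rolled step-up recipe;
  hypergeometric tails come from scipy and are cross-checked against
  direct summation.
- r = ±1 correlations get a degenerate CI at the point value (the Fisher
  transform diverges); zero-variance genes and pairs with fewer than four
  complete observations are flagged invalid rather than guessed.
- All generators take explicit integer seeds and use a dedicated
  `numpy.random.Generator`; derived streams are separated with
  `SeedSequence` tuples.  Exhaustive computations are deterministic;
  sampled ones are reproducible given the seed.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script runs use 120-node synthetic
backgrounds (≈ 130 edges), 20 generator seeds for recovery, exhaustive
quadruplet nulls on the filtered networks (a few thousand quadruplets),
1,000 datasets for the type-I calibration of the randomisation test, and
1,000 noisy simulations for qPCR bias — sizes chosen so the whole suite
runs in well under a minute per component while keeping every binomial
check inside its stated band.

## Known limitations

- The edge filter treats detection and fold change marginally per gene;
  it does not model replicate pairing across groups.
- The quadruplet null conditions on the realised general network; it does
  not propagate uncertainty from the expression filtering itself.
- Undirected path tracing reports one lexicographically chosen shortest
  path; biological path multiplicity is summarised only as a count.
- The enrichment test assumes the background set is the correct sampling
  frame; no annotation-database handling is included by design.
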