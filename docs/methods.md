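# Methods

This note documents the models, statistics and design choices behind
`phosphonet`, in the order the pipeline runs them.

## Input model

The quantification unit is a phosphopeptide with per-sample light (sample)
and heavy (pooled internal standard) MS1 intensities, phosphate positions on
the host protein, and a false-localisation-rate (FLR) score from an upstream
localization tool. Localization scoring, spectral searching and the
kinase–substrate prediction itself are consumed as inputs, not recomputed.

Phosphosites are written `PROTEIN_<residue><position>` with 1-based protein
coordinates (e.g. `AKT_S473`).

## Localization filtering

Records at or below the FLR threshold (default 1%) pass as confidently
localized. Records above it are positional isomers; all isomers sharing a
backbone sequence and phosphate count are collapsed to one record carrying
the positions and intensities of the member with the highest localization
score, flagged `localized=False`. Ambiguous groups are retained rather than
discarded because they can still indicate regulation; groups whose members
lack a localization score cannot be ranked and are dropped with a logged
diagnostic.

## Spike-in normalization

Two steps on the light/heavy ratio *r*<sub>ps</sub> = *L*<sub>ps</sub>/*H*<sub>ps</sub>:

1. per-sample median normalization: each sample's ratios are divided by the
   sample's median ratio, cancelling errors in mixing sample and standard;
2. the peptide-specific heavy intensity in the denominator cancels
   peptide-level ionization and recovery differences.

The median anchor is 1 — the natural scale for a ratio to the internal
standard — rather than a data-derived constant. This makes the output
*exactly* invariant to any per-sample multiplicative error on the light
channel: a data-derived anchor (e.g. the median of per-sample medians)
would itself shift under such an error and leak it into every sample.
Entries with zero or missing heavy intensity become missing, never zero,
and missing values are never imputed.

Replicate reproducibility is summarized as the median coefficient of
variation (sample SD/mean, %) over all site × replicate-group combinations;
groups with fewer than two values or zero mean are skipped and counted.

## Site conversion

Every phosphate position on every peptide nominates a site row; when
several peptides cover one site, the representative is the peptide with the
fewest phosphates (least ambiguous quantification), ties broken by highest
median abundance. Multi-site peptides contribute one row per site sharing
the peptide's abundances.

## Differential calling

Stimulated vs mock at each time point, two-tailed unpaired t-test with
pooled variance (the conventional choice at n = 3 per group; Welch is
available via `equal_var=False`). Sites missing in either group at a time
point are excluded from that time point's family. Degenerate zero-variance
cases are resolved, not raised: equal means give p = 1, unequal means the
smallest positive float (triplicate MS data can genuinely produce them).

Benjamini–Hochberg correction is applied within each time point (the family
is the set of sites tested at that time point). A site is a target when
q < 0.1 and |fold change| > 1.5, where fold change is the ratio of group
means; the union of targets over time points is the set the network must
explain. Scores for network inference are s = log₂(q/qThresh), zero at the
threshold, strictly increasing in q; q = 0 is clamped to the smallest
positive float.

## Kinase-activity inference

**Substrate-set enrichment.** Sites are ranked by log₂ fold change
(descending, ties broken by identifier). Each kinase's measured substrate
set is scored with a weighted Kolmogorov–Smirnov running sum: hits
increment proportionally to |metric| (normalized to 1 over hits), misses
decrement uniformly; the enrichment score (es) is the running sum at its
maximal absolute deviation, so |es| ≤ 1. Kinases with fewer than three
measured substrates are excluded. The null distribution draws random
substrate sets of equal size from the measured sites (substrate-label
permutation — sample permutation is not meaningful at n = 3), 10,000
permutations by default. The normalized enrichment value is
es / mean(|es<sub>perm</sub>| of matching sign), keeping the sign
convention positive = activation; the p-value is the add-one tail
probability among matching-sign permutations, BH-corrected across kinases
within a time point. The running-sum internals are this package's
documented choice; they are validated against an exhaustive loop oracle
and a super-uniformity check of null p-values.

**Clustering.** Target-site profiles (replicate-averaged, per-site
z-scored) are split into k = 6 fuzzy c-means clusters (fuzzifier m = 2,
alternating updates, convergence when the largest center shift falls below
1e-6, coincident points handled by assigning full membership). Hard
assignments (argmax membership) feed a one-sided Fisher exact test per
(cluster, kinase) on the 2×2 table against the full identified-site
background, BH over all pairs.

## Prior-knowledge network

Three node classes (one receptor, proteins, sites) and three edge classes:
kinase→site, site→host-protein coupling, and signed directed PPIs.
Closely related isoforms and G-protein subunits can be merged via a
grouping map; merging rewrites endpoints, unions references, and drops
loops it creates — both literal self-loops and autophosphorylation loops
(kinase → site hosted on the merged kinase) — reporting the references
lost with them.

Site→protein coupling edges (added for every site whose host has outgoing
edges) let paths traverse intermediary kinases through their activating
sites. Couplings default to activating; an override set marks inhibitory
sites with sign −1, since prior knowledge rarely annotates per-site
functional signs. Signs are carried through assembly, but the baseline ILP
propagates Boolean activation only; a signed mode is a possible extension,
and the pruning and ILP treat −1 edges like +1 edges by default.

Before inference the graph is pruned to edges (u, v) with u reachable from
the receptor and some regulated site reachable from v — exactly the edges
on a receptor→site path in an acyclic graph, and a tight superset in
cyclic ones (deciding membership on a *simple* path through a cycle is
NP-hard; the ILP's acyclicity constraints make the distinction immaterial).
Unreachable regulated sites are reported, not fatal.

## ILP network selection

Per time point, binary variables: x_e (edge selected), y_v (non-receptor
protein active), z_s (site included), plus integer depths d_v ∈ [0, |V|].
Constraints:

* receptor active at depth 0;
* x_e ≤ activity(source): y for protein sources, z for site sources;
* y_v ≤ Σ x_e over incoming edges (activation needs a selected input);
* z_s ≤ Σ x_e over incoming kinase→site edges;
* d_target ≥ d_source + 1 − |V|·(1 − x_e) (selected edges form a DAG);
* forced edges fixed at 1.

Objective: minimise Σ_s score(s)·z_s + ε·Σ_{e not forced} x_e. Regulated
sites (negative score) pay for their path; unregulated sites a path must
traverse cost their positive score; ε (default 0.01) makes every
unnecessary edge strictly costly, so the empty network is optimal when
nothing is regulated and shorter routes beat longer ones. Runs abort if ε
is not strictly below the smallest |score| among regulated sites, which
would let parsimony override data. Solves use the HiGHS MILP backend at a
relative gap of 0, so reported solutions are provably optimal; edge
reporting is sorted for determinism. Alternate optima are possible and are
precisely what the bootstrap ensemble is for.

The time course is solved in ascending order; each later time point forces
the previous solution's edges (their ε cost waived) and optimises only its
own scores, so edge sets are nested by construction and a branch that loses
significance later persists.

## Bootstrap consensus

Each of 100 runs resamples the measured site identifiers with replacement
to the original count and deduplicates — retaining on average
1 − (1 − 1/N)^N ≈ 63% unique sites — then reruns the full time-course
solve on the subset. Edge weight at time t = number of runs whose time-t
network contains the edge; entry time = first time point with weight ≥ 20
(of 100). Failed runs are skipped and counted; more than 10% failures
aborts. A randomized control re-keys the regulated sites' quantitative
profiles to identifiers drawn without replacement from the non-regulated
pool; a network built from it should recover little of the true structure.

## Synthetic generator

The generator emulates the study design the pipeline targets: a receptor
feeding `n_branches` transducer proteins, kinase chains per branch (each
kinase phosphorylates `substrates_per_kinase` leaf sites and the next
kinase via a linking site), random cross-branch PPI confounders, and a
large pool of background sites outside the graph (default 200) so that
median normalization and BH correction operate at a realistic
regulated-site fraction. Defaults: 5 time points (2, 10, 30, 60, 90 min),
biological triplicates, mock/stimulated × WT/KO, fold change 2.5 (20% of
sites down-regulated, i.e. divided), step-onset kinetics with onset time
increasing with chain depth, per-sample loading errors (log-normal,
σ = 0.35) on each channel, and multiplicative noise calibrated so the
*observed* median triplicate CV of the normalized ratio is ≈ the `cv`
parameter (0.12): the per-channel log-normal σ is
√(ln(1 + cv²)/2)/c₄(n), where c₄ corrects the small-sample bias of the
SD at n replicates.

What it does not model: transient (pulse-shaped) responses beyond an
optional flag, missing values other than absent channels,
localization-error processes, protein-abundance changes, and correlated
noise between sites. Passing recovery benchmarks on this generator
therefore shows the inference machinery is sound under the stated noise
model, not that real biological confounders are handled.

Recovery is scored as edge precision/recall/F1 of the consensus edges
(final-time weight ≥ threshold) against the true subnetwork, with the
convention that an empty inferred set has precision 1, plus the fraction of
scheduled sites with a selected incoming edge.

## Problem sizes and numerics

The test suite and benchmarks run at reduced scale chosen to exercise every
code path with comfortable statistical margins: graphs of ~33 nodes
(8 kinases, 4 branches, 2 active modules, 100 background sites), 50
bootstrap runs with consensus at 20% of runs, 10 generator seeds for
recovery (mean F1 ≥ 0.8 required), 100 random instances for
ILP-vs-enumeration equivalence (≤ 10 edges, exhaustive over all 2^|E|
subsets), and 500 iterations × 1,000 sites for the resampling statistic.
Tolerances: 1e-9 for normalization invariance, 1e-6 absolute for ILP
objective equality, exact (float) agreement for BH and Fisher against
their combinatorial oracles.

## Known limitations

* Activation-only Boolean logic: no AND gates, no inhibitory propagation in
  the baseline, no continuous dynamics.
* The ILP depth bound |V| makes big-M constraints loose on large graphs;
  for PKNs beyond ~10³ edges a longest-path-based bound would tighten them.
* Substrate-label permutation tests exchangeability of sites, not samples;
  p-values are conservative when substrate sets overlap strongly.
* The bootstrap quantifies selection stability under data perturbation, not
  posterior edge probability.
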