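# Methods

## Statistical model

For a panel of species with known nodulation status and an orthogroup ×
species gene-count matrix `C`, each comparison mode partitions the
status-assigned species into group 1 (nodulators under that mode's
definition) and group 2. Two modes are built in:

* **Fabales** — group 1 = nodulating species of the order Fabales; group 2 =
  every other status-assigned species (including non-nodulating legumes and
  any nodulating non-Fabales taxa).
* **Viridiplantae** — group 1 = all nodulators, group 2 = all
  non-nodulators.

Species with status `unknown` are retained in profiles and trees but join no
group in any mode.

**Presence/absence.** An orthogroup is *present* in a species when its count
reaches the presence threshold (default 1 gene). The 2×2 table
`(a, b; c, d)` = (group-1 present, group-1 absent; group-2 present, group-2
absent) is summarized by the unconditional sample odds ratio `ad/(bc)` with
the conventions 0 (`ad = 0 < bc`), ∞ (`bc = 0 < ad`) and NA (both products
zero), and tested with a two-sided Fisher exact test. Sidedness uses the
point-probability (minimum-likelihood) rule: the p-value is the sum of
hypergeometric point probabilities over all tables with the observed margins
whose probability does not exceed the observed table's, with a 1e-7 relative
tolerance for ties. The sum is accumulated in log space
(`scipy.stats.hypergeom.logpmf` + `logsumexp`) for stability; degenerate
margins (an empty row or column) return p = 1 with a warning. The
implementation is checked in the test suite against an exact
rational-arithmetic enumeration of the hypergeometric support and against
`scipy.stats.fisher_exact`.

**Normalized counts.** Counts are divided by each species' total annotated
gene number (`species_totals`), which defaults to the assigned-gene column
sum but should be overridden with true genome/transcriptome totals when
known (assignment rates below 100% make the column sum an underestimate).
Groups are compared with an independent-samples *t* test. The default is the
pooled-variance statistic with `df = n1 + n2 − 2`; Welch's correction is a
flag. Positive *t* means the nodulating group's mean is larger. Two
constant, equal samples return (t = 0, p = 1) rather than an indeterminate
value.

**Multiplicity.** Within each mode and track, raw p-values are Bonferroni
multiplied by m = the number of orthogroups actually tested (after filtering
families observed in fewer than `min_species_represented = 2` of the tested
species), capped at 1. `m_override` reproduces alternative conventions. A
family is significant when its adjusted p falls below α = 0.001. Bonferroni
rather than FDR is deliberate: the aim is a short, high-confidence candidate
list, and the family-wise guarantee makes the null calibration
interpretable (expected false families per run ≤ α·(modes × tracks)).

One row is reported per (orthogroup, mode); the condensed presence/absence
table additionally picks a single reporting mode per orthogroup — the mode
with the smaller adjusted presence-track p, ties resolved to Viridiplantae.

## Dollo reconstruction and pattern classification

Presence profiles are binarized at the presence threshold and reconciled
with the rooted species tree under a single-gain assumption: the family is
gained once on the edge above the MRCA of its present tips, and within that
gain clade a node is present iff at least one present tip lies below it.
Every maximal absent subtree inside the gain clade is one loss edge; this
assignment minimizes losses for a single gain (verified exhaustively in the
tests for all rooted binary shapes with ≤ 8 tips against a brute-force
enumeration of every admissible state assignment). The reconstruction
depends only on the binarized profile, so extra gene copies never change it,
and it is invariant to tip order.

Classification applies the first matching rule in a fixed order, against a
user-supplied dictionary of named focal tip sets (taxonomic clades and/or
status groups):

1. `absent_everywhere` — empty profile.
2. `clade_exclusive_gain` — the gain clade lies inside a focal clade and
   nothing is present outside it; the most specific containing clade is
   reported. Requiring the *gain clade* (not just the present tips) inside
   the focal set prevents a family lost in all nodulators from being
   mislabelled as "exclusive to non-nodulators" merely because those tips
   are the complement of the lost group.
3. `clade_loss_punctuated` — a focal clade with absent-tip fraction ≥ 0.9
   explained by 1–2 loss edges intersecting the clade.
4. `gradual_loss` — ≥ 4 loss edges intersecting a focal clade that still
   retains present tips, with absent fraction ≥ 0.5.
5. `expansion` — group-1/group-2 ratio of raw-count means ≥ 1.5 with both
   groups represented.
6. `background` — everything else.

The loss-edge thresholds (k_p = 2, k_g = 4), the 0.9 and 0.5 absent-fraction
cutoffs, and the 1.5-fold expansion cutoff are package defaults exposed in
`PatternConfig`; the patterns they operationalize are usually described
verbally, and different panels may warrant different values. Focal clades
smaller than `min_clade_size = 3` tips cannot anchor a loss call, because a
one- or two-species clade is absent by chance too easily for "its loss" to
be evidence of anything. When several focal clades match a rule the largest
one is reported (ties alphabetical).

## Synthetic data generator

The generator emulates the statistical structure of a 74-species
comparative study — not its sequences. Defaults:

* **Panel/tree** — 74 species in eight labelled clades on a fixed ladder
  backbone, with Fabaceae (44 species: Cercidoideae 3, Detarioideae 2,
  Caesalpinioideae 4 non-nodulating + 9 nodulating, Papilionoideae 26
  nodulating) nested inside non-nodulating outgroups. 35 species nodulate,
  39 do not, matching the group margins of both comparison modes in the
  study design this emulates. Topology is deterministic; all stochasticity
  flows from the mandatory seed through one `numpy` generator.
* **Family sizes** — per-species counts of background families are negative
  binomial with mean μ = 2 and NB2 dispersion α = 0.5 (variance
  μ + αμ², shape k = 1/α = 2), giving a zero mass of 0.25 — i.e. a typical
  family is observed in ~75% of species, a realistic mixed
  genome/transcriptome detection rate, while the right tail reproduces the
  heavy-tailed family-size distributions orthogroup clustering produces.
  "Dispersion" throughout is the NB2 α (the statsmodels/ecology
  convention), not the raw shape parameter.
* **Planted effects** — *punctuated losses* zero a named clade or status
  group wholesale; *gradual losses* zero each focal tip independently
  (default probability 0.6); *gains* are present only inside their clade
  (model draws floored at one copy); *expansions* multiply a target group's
  counts by a fold factor (default 3, rounded). Expansion families draw
  their baseline from NB(μ = 10, α = 0.1) rather than the background model:
  real copy-number expansions are a phenomenon of large families that are
  consistently present across a panel (baselines near ten genes per
  species), and a fold change on a mean-2, highly dispersed family is not a
  detectable — or biologically meaningful — "expansion" at these sample
  sizes.
* **Dropout** — after all effects, every cell is independently zeroed with
  probability 0.05, modelling transcriptome incompleteness (a present gene
  unexpressed in the sampled tissue). Dropout is applied last so planted
  zeros stay zero and planted presences can be falsely lost, which is the
  direction real transcriptome noise works in.
* **Totals** — species totals are assigned-gene column sums inflated by a
  12% unassigned-gene fraction, mimicking realistic orthogroup assignment
  rates.

What passing tests on these panels does **not** show: robustness to
phylogenetically autocorrelated presence noise (dropout here is i.i.d.),
to assembly-quality differences between lineages, to mis-specified
nodulation status, or to gene-tree discordance — none of which the
generator models. The statistical tracks also ignore phylogenetic
non-independence of species, exactly as the analysis they implement does;
the hits are descriptive contrasts, not phylogenetically corrected effect
estimates.

## Numerical and design notes

* Fisher p-values are exact to float precision on the panel sizes used
  (support ≤ min(group sizes)); the 1e-7 tie tolerance only matters for
  near-equal point probabilities and is shared by implementation and test
  oracle.
* Duplicate datasets of one species (e.g. two independent transcriptomes)
  are collapsed by element-wise maximum before testing — presence evidence
  from either dataset counts, without pseudo-replicating the species; the
  collapsed total is the max of dataset totals, floored by the collapsed
  column sum to keep totals consistent.
* Odds-ratio conventions (0 / ∞ / NA) are preserved through the TSV output
  (NA as literal `NA`).
* Problem sizes in the analysis scripts and tests (1000 background
  families, 20 + 10 planted effects, 20 null replicates) are chosen to make
  the recovery and calibration experiments sharp while keeping a full run
  of the suite near-interactive.
* Ordering of result rows (by smaller adjusted p, then orthogroup id and
  mode) and of simulated species (clade blocks, numbered tips) is
  deterministic, so repeated runs with one seed are byte-identical.
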