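# Methods

`paleomt` re-implements, as a tested library, the computational chain of a
PCR/cloning-era ancient mitochondrial DNA (aDNA) population study: from raw
clone sequences of HVS1 amplicons, through authenticated consensus
haplotypes and haplogroup calls, to multi-population comparison. This note
records the models, conventions and design choices; it states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinates, haplotypes and the reference

All coordinates are 1-based, inclusive positions in rCRS numbering; there
are no 0-based interfaces. A haplotype is a set of substitutions relative
to the reference within an explicitly stated covered window (the complete
HVS1 analysis window is np 16,126–16,369). The motif grammar is
`<position><base>` for substitutions, `<position>d` for deletions and the
literal `CRS` for the reference type; insertions are outside the grammar
and rejected. Haplotype equality for deduplication ignores the window, so
a partial motif identical to a complete one collapses with it — the
convention under which the packaged 15-profile study sample contains 9
distinct types (7 among complete-window profiles only).

The package ships no copy of the genuine rCRS. `synthetic_reference()`
builds a deterministic HVS1-like segment in which every position touched by
packaged motifs, decision rules or simulator founders carries the true rCRS
base, with seeded filler elsewhere; it is labelled synthetic in name and
docstring. Every computation the pipeline actually reports (motif algebra,
consensus replication, FST, sharing, PCA) depends only on variant sets, not
on reference content; analyses of real sequence reads should load the
genuine reference via `reference_from_fasta`.

The poly-cytosine tract (np 16,182–16,193) is excluded from variant
calling, consensus, and lesion counting, because length variation there is
a replication-slippage artefact. The exclusion lives on the
`ReferenceSegment` so every consumer applies the same mask.

## Clone authentication and consensus

Two overlapping amplicons cover HVS1 (fragment 1: 16,126–16,258; fragment
2: 16,258–16,369); primer-annealing stretches flank these windows and are
never scored. Each amplification yields a clone set (typically 10–15
clones).

**Origin labelling.** Against the per-amplicon majority, a clone is a
`staff_contaminant` when it reproduces a handler's motif, `carry_over` when
it reproduces another sample's motif from the same processing batch
(cross-batch matches are logged, not auto-labelled), `endogenous` when it
matches the majority or deviates only by damage-typed substitutions, and
`unclassified` otherwise. Clones combining the consensus variants with
extra damage-typed changes are damage on the endogenous template, not
chimeras; chimera detection beyond this is out of scope.

**Majority consensus.** Per position among non-contaminant clones; ties
resolve to the reference base and are flagged — conservative toward rCRS,
in the same spirit as requiring replication before accepting a variant.

**Replication rule.** A variant enters a sample's consensus only when the
consensus of at least two amplifications from independent *extractions*
carries it; when a sample has a single extract, independent PCRs are
accepted as replication units (mirroring the two single-extract exceptions
such studies allow). A fragment amplified in a single replication unit is
excluded from the validated motif, producing a partial-window profile
rather than an unreplicated call. SNP typings are `validated` when the
same base is observed in two extracts. Profile status is `validated` when
at least one fragment replicates (and, if a checker is wired in, the
haplogroup-diagnostic SNPs do not contradict the motif), `provisional`
otherwise, `discarded` when no amplicon retains endogenous signal.

**Miscoding lesions.** Each clone-vs-consensus substitution outside primer
and poly-C regions is typed: type 1 = A→G / T→C, type 2 = C→T / G→A (the
cytosine-deamination signature), anything else (including indels) =
`other`. The per-sample lesion rate is pooled:
(total lesions) / Σ_amplicons (n_clones × n_scored_bases) — the units
"per clone and nucleotide", weighted by the amount sequenced. A
mean-of-per-amplification-rates variant is available behind
`method="per_amplicon_mean"` because the normalisation is describable both
ways; the pooled form is the default on the units argument.
Contaminant-labelled clones contribute to neither numerator nor
denominator.

**Screening and recovery.** A sample is discarded at the first run of two
consecutive negative amplifications. The recovery ratio is validated
skeletons / skeletons sampled × 100 (one decimal) — skeletons, not
extracts, in the denominator; the packaged study roster gives
15/63 = 23.8%.

## Haplogroup classification

Haplogroups are assigned from the HVS1 motif plus a nine-position
coding-region SNP panel (7028, 12308, 14766, 10873, 10550, 12705, 10398,
10400, 4646) by walking a small, user-editable decision table rather than
an embedded phylogeny: the panel can only resolve a handful of clades
(L3, N\*, K, U\*, H, HV, R0), and a table makes the logic inspectable and
overridable.

Rule semantics: a typed SNP contradicting a rule rejects it; untyped SNPs
and motif positions outside the covered window are wildcards; a rule needs
at least one positively typed required SNP (or, for SNP-less rules, a fully
observed motif requirement). Among surviving rules, those whose motif
conditions are fully observed rank first, then untested motifs, then
contradicted ones; ties break by priority. SNP evidence outranks motif
evidence; a call resting solely on unreplicated SNP typings is assigned but
not **firm**. On the packaged fixture this reproduces all 15 published
labels with exactly 14 firm (the CRS-motif/unreplicated-SNP profile is
assigned HV but stays provisional). Two rules carry panel-specific motif
conditions (R0: 16293C; U\*: 16311C) that encode distinctions the typed
SNPs alone cannot make in this dataset; users with different panels should
edit the table.

A separate consistency check compares motif-implied candidate clades
(rules with fully observed motif conditions) against SNP-implied candidates
and flags disjoint sets as conflicts; an empty side makes the check
untestable (e.g. motif-only profiles).

Frequencies pool raw labels into 25 categories (H, HV, HV0, R0, K, U1–U7,
U\*, U+, R+, J, T, N\*, N1, N2, I, W, X, AF, AS) through a grouping TSV;
sub-clades fall back to their longest mapped prefix, and unmapped labels
raise rather than vanish. For the ancient sample, only firm calls enter
the denominator. Bootstrap confidence intervals resample individuals with
replacement (percentile intervals, mandatory seed). Because category
counts are discrete, a percentile bound near a CDF atom can legitimately
land on either neighbouring atom at finite replicate counts; tests compare
bounds against exact binomial quantiles with that granularity in mind.

## Population comparison

**Shared haplotypes.** A database individual carries a query haplotype
when their variant sets over the comparison window are identical and
(by default) haplogroup labels agree — a label matches its own named
sub-clades, while paragroup labels (`U*`) match only themselves. Both
directions are reported per population: distinct query haplotypes found,
and individuals carrying any of them. Complete-window query haplotypes
only by default, with a flag to admit partials (matching over their covered
window).

**FST.** The haplotype-frequency flavour: a two-group AMOVA with
inter-individual distance 0 (identical variant sets) / 1 (otherwise), so
the sums of squared differences reduce to haplotype counts;
FST = σ²_a / (σ²_a + σ²_w) with the usual average-corrected sample size n′.
Negative estimates are reported as computed (the estimator is unbiased
around zero, so identical small samples give slightly negative values);
when every individual in both samples is identical the value is defined as
0. Molecular-distance variants (Tamura–Nei etc.) are out of scope. The
implementation is checked to 1e-12 against an independent brute-force
double-loop AMOVA on random small instances.

**Significance.** Individuals are permuted between the two populations
(sample sizes preserved); p = (1 + #{FST_perm ≥ FST_obs}) / (1 + n_perm),
ties counting as exceedances, so p is never 0 and the test is exact-level
or conservative. Because the identity-distance statistic is discrete, the
p-value is exactly uniform under the null only when the statistic takes
many distinct values; with very few haplotype classes (or all-unique
haplotypes, where the statistic degenerates) it becomes conservative.
All pairwise comparisons of one query against the database form a single
Benjamini–Hochberg family (`fst_scan`); `bh_adjust` is the standard
step-up adjustment.

**PCA + Ward.** PCA of the populations × 25-category percentage table,
centred and (by default) scaled to unit variance, ddof = 1, so eigenvalues
sum to the number of retained variables; component signs follow a
deterministic convention (largest-magnitude loading positive);
zero-variance categories are dropped with a warning. Ward minimum-variance
clustering runs on the first six component scores (Euclidean distances);
the inertia decomposition (between + within = total) and the between/total
ratio are reported for any cut. Clusters are characterised by the v-test

    v = (x̄_cluster − x̄_overall) / sqrt(((N − n)/(N − 1)) · s²_overall / n)

with s² the population (1/N) variance and a two-sided normal p-value
(v = 0 by convention when the cluster is the whole data set), plus
one-sample t-test higher/lower marks at α = 0.05.

**Affinity surfaces.** Inverse-distance-weighted interpolation
(w_i = d_i^−power, default power 2) on a lon/lat grid replaces proprietary
kriging: it is documented, dependency-free, exact at data points and
bounded by the data range. Populations without a clear geographic location
are excluded upstream. IDW flattens gradients between points, so even a
linear field is reproduced only approximately (tested: max error < 2 units
on a field spanning 18, with generators on an 11 × 11 grid).

## Synthetic data

The generator emulates every pipeline input with known ground truth.
Populations draw haplogroup-category frequencies from a symmetric Dirichlet
and counts from a multinomial; each individual carries its category's
founder motif plus Poisson(μ) private substitutions (a star phylogeny),
90% transitions by default, matching control-region behaviour. Defaults
mirror the laboratory design the pipeline was built to validate: 10–15
clones per amplicon, two extracts per skeleton, two PCRs per extract.
Damage is independent per clone and scored site at rate λ (default 0.005
per clone per site, within the range such studies report), with an 85%
type-2 fraction; each lesion picks a C/G site (type 2) or A/T site
(type 1) and applies the corresponding transition, so a lesion can also
revert a true variant toward the reference. Staff-contaminant and
carry-over clones replace endogenous ones at configured fractions. Every
emission is a pure function of (config, seed).

What the generator does **not** model — and hence what passing tests do not
show about real data: coalescent genealogies (no shared sub-structure
beyond the founder), rate heterogeneity along the molecule, fragment-end
damage enrichment, sequencing error beyond miscoding lesions, and
heteroplasmy. It is sufficient to exercise haplotype sharing, FST
structure, consensus replication and lesion-rate estimation, which is what
the downstream analyses consume.

## Problem sizes used in the test-bed

Simulation-based checks use sizes chosen to make their statistical
assertions sharp while keeping the suite quick: 200 random instances for
the FST oracle; 1,000 null replicates at 199 permutations for type-I-error
calibration (12 haplotype classes, 30 + 30 individuals, so the discrete
statistic is effectively continuous); 40 simulated skeletons at λ = 0.01
with 20% contaminant clones for consensus recovery; 60 replicate samples
for lesion-rate recovery at λ = 0.005; 10,000 bootstrap replicates on the
n = 14 frequency toy.

## Known limitations

- The decision table is panel-specific by construction; it is a faithful
  encoding of what this nine-SNP panel plus HVS1 motifs can resolve, not a
  general haplogrouper.
- Identity-distance FST discards within-haplotype molecular divergence.
- The permutation p-value is conservative when the haplotype-frequency
  configuration admits few distinct FST values.
- IDW surfaces are visual summaries; no variogram modelling, no
  uncertainty quantification.
- Authentication is rule-based (replication + panels), not a probabilistic
  damage/contamination model; there are no per-base qualities.
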