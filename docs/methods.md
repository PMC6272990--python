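# Methods

## Data model

The analysis unit is the scored band: a 0/1 matrix of individuals by band
loci, each band assigned to exactly one primer and each primer to one
marker system. Missing data are rejected at load: the statistics are
frequency-based, and silent imputation would bias every downstream
frequency estimate. Cells other than 0/1 raise an error naming the sample
and band. A band is *polymorphic* when both states are observed across the
samples; a band present (or absent) in every individual is monomorphic, so
PPB = 100·NPB/TNB reaches 100% only when every band shows both states.

## Synthetic band matrices

The generator emulates a germplasm survey: populations (accessions)
diverge from a common ancestor under the Balding–Nichols model. Per band,
an ancestral dominant-allele frequency p0 is drawn uniformly from
[0.05, 0.95] — bounded away from fixation so panels stay polymorphic, as
real published panels are — and each population's frequency p comes from a
Beta with mean p0 and variance F·p0·(1−p0), i.e. shapes p0(1−F)/F and
(1−p0)(1−F)/F. F is the single divergence dial and plays the role of Fst.
Individuals are diploid and the marker dominant, so a band is present with
probability 1 − (1−p)². All draws flow from one `numpy` Generator seeded
by the config, so equal configs give bit-identical matrices.

Defaults mirror the survey design the package targets: 20 accessions of
6–10 plants (the nine-subspecies accession layout, including its
countries, is reused so subspecies- and country-level analyses have
realistic strata), 21 + 15 primer panels of 3–13 bands, F = 0.2 — a
divergence that reproduces the ~70/30 intra/inter diversity partition
reported for the real collection.

What the generator does *not* emulate: linkage between bands, comigrating
non-homologous fragments, scoring error, null-allele size homoplasy, and
polyploid dosage. Passing recovery tests therefore show the estimators are
correct under idealized dominant HWE sampling, not that they are robust to
those artefacts.

## Marker efficiency

PIC per primer defaults to **pattern mode**: every distinct multiband
fingerprint of the primer is treated as one allele and PIC = 1 − Σf² of
the fingerprint spectrum. Rationale: published per-primer PIC values for
multi-band dominant primers routinely exceed the 1 − 1/k ceiling that k
per-band "alleles" would allow, which only the fingerprint reading can
produce; the per-band biallelic mode (`mode="band"`, mean over polymorphic
bands of 1 − p² − q²) is kept as an explicit alternative and the report
records which was used. Ibav pools presence proportions over all samples
(one value per marker system, matching how surveys tabulate it), EMR is
the mean polymorphic-band count per primer, and MI = Ibav × EMR holds
exactly by construction.

## Diversity

Band-absence proportion x estimates the null-allele frequency as
q = √x under HWE (default). The Lynch–Milligan-style correction
q = √x / (1 − s/(8x)) with s = x(1−x)/n is available for small samples;
it converges to √x as n grows and is clamped to [0, 1]. Per-locus Na
counts observed band states in the group (1 or 2), Ne = 1/(p²+q²),
He = 1 − p² − q², and Shannon's I uses natural logs with 0·ln 0 = 0, so
per-locus I ≤ ln 2. Group rows average over *all* bands of the matrix
(absent bands contribute zeros), the Total row pools all samples rather
than averaging group rows — pooling is what makes total diversity exceed
the group mean when groups diverge. Is averages group Shannon values
unweighted by default (a sample-size-weighted option exists, since legacy
programs do not document their choice); S′ = (It − Is)/It, and
Is/It + S′ = 1 holds identically.

## Distances and trees

Dice similarity 2a/(2a+b+c) ignores shared absences and is undefined when
both profiles are empty — treated as an error because an all-zero profile
signals a corrupt sample rather than biology. Dissimilarity is 1 − Dice;
group-level similarity averages Dice over cross-group (off-diagonal) or
within-group (diagonal) pairs, with singleton-group diagonals reported as
missing.

Neighbor joining is the canonical Saitou–Nei algorithm: Q-criterion, limb
lengths from the row-sum formula, plain-average distance update
d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2. Ties in Q are broken by the lowest
(row, column) index pair in the current working order so results are
deterministic; negative limb estimates are clamped to zero with the
deficit moved to the sister edge, preserving the pair's mutual distance.
On additive inputs the algorithm is exact (verified against every 4- and
5-leaf topology, and cross-checked against scikit-bio's implementation).

Bootstrap support resamples **band columns** with replacement (the band is
the scored character; a primer-block option resamples whole primer panels
for users worried about intra-primer dependence), rebuilds distance and
tree per replicate, and reports each internal bipartition's replicate
frequency in percent on the original topology. Supports are written as
integer internal-node labels in Newick output.

## AMOVA

One-way, on squared Euclidean distances of the raw 0/1 profiles — for
band data this equals the mismatching-band count, the convention of the
classic AMOVA programs; Dice distances are deliberately *not* used here
(they belong to the tree analysis). Sums of squares follow the distance
formulation SS_total = (1/N)Σ_{i<j}d², SS_within = Σ_g(1/n_g)Σ_{i<j∈g}d²,
which agrees with the Euclidean ANOVA identity to 1e-9 (tested). Variance
components use n0 = (N − Σn_g²/N)/(G−1); a negative among-group component
is reported as-is with its proportion floored at zero and flagged. The
permutation test shuffles the sample-to-group assignment, uses σ²_among
as the statistic (equivalent to Φ_ST for this design), applies the +1
correction so p > 0, and defaults to 999 permutations — enough to express
the "< 0.001" convention. Only the among-group component gets a p-value:
there is no standard permutation analogue for the within row of a one-way
design, so none is reported.

## Pipeline

One config (YAML or constructed in Python) either points at input files
or embeds a simulation block — never both. A single seed drives bootstrap
and permutations, so runs are byte-identical end to end; any stage failure
removes partial outputs and names the stage. The run log echoes versions,
seed, parameters and per-analysis sample/band counts so df values are
auditable.

## Problem sizes used in the checks

The self-checks run on deliberately compact designs chosen to keep the
full suite in the seconds-to-a-few-minutes range while leaving the
statistics well-resolved: frequency-recovery at 500 diploids per
population (RMSE < 0.03), permutation-null calibration over 200
structure-free replicates at 99 permutations each, bootstrap power on a
two-population F = 0.3 design with 200 replicates, and S′ monotonicity
over 20 replicates per divergence level.

## Limitations

- Dominant scoring cannot separate heterozygotes from dominant
  homozygotes; all allele-frequency-based quantities inherit the HWE
  assumption, and depart under inbreeding or selfing.
- The Shannon partition is a descriptive decomposition, not a variance
  decomposition; it carries no significance test.
- Trees are unrooted and reported as-is; group labelling of clades is an
  annotation left to the user.
- Hierarchical (three-level) AMOVA and Bayesian admixture/cluster-number
  inference are out of scope.
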