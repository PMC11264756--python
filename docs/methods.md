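# Methods

## Scope

`saltscreen` implements a desk-scale version of a salt-tolerance screening
pipeline for forage sorghum: fast chlorophyll-a fluorescence (OJIP)
phenomics, construction of a salt performance index from stage-wise
relative values, the group statistics used to letter such panels, SSR
marker diversity with a Shannon-information partition of molecular
variance, physicochemical characterisation of candidate proteins, and
relative expression by 2^-ΔΔCt. No field or laboratory data ship with the
package; a synthetic-data module generates every input with known ground
truth, which is what the test suite and the acceptance script run on.

## OJIP transients and the JIP test

A transient is a strictly increasing time series of fluorescence values
over roughly 10 µs – 1 s. Marks default to F0 at 50 µs, F300 at 300 µs and
FJ at 2 ms, with FM the global maximum of the curve rather than the final
point, tolerating transients that peak before the end of acquisition.
Because OJIP sampling is log-spaced, interpolation at mark times is linear
in log10(time); linear-in-time interpolation overshoots badly between
decade-spaced samples. Mark times are configurable (`MarkConfig`) so
non-default conventions remain expressible; a 3-point median filter is
available for noisy curves and is off by default.

Parameters follow the standard JIP-test definitions: FvFm = (FM−F0)/FM,
M0 = 4(F300−F0)/(FM−F0), VJ = (FJ−F0)/(FM−F0), and

    PIabs = [1 − F0/FM] / (M0/VJ) · (FM−F0)/F0 · (1−VJ)/VJ.

Some published renderings of the index print the middle term as
(FM/F0)/F0, which is dimensionally anomalous; the package defaults to the
standard term and exposes the literal form as the `as_printed` variant,
recording the variant used in all outputs.

One caveat worth stating: expressed in marks, PIabs =
(FM−F0)²(FM−FJ)/(4·FM·F0·(F300−F0)). It therefore decreases with rising F0
only while F0 < F300/2; past that point the shrinking F300−F0 gap (i.e.
the induced drop in M0) dominates. The monotonicity property is tested on
the side where it holds.

## Relative values, reduction factors and the SPI

Relative values are ratios of platform means (medium 8 dS/m over low
4 dS/m) per variety × stage × parameter cell; dry-matter gain is the same
ratio for harvest dry mass. The reduction factor RF is the relative value
at leaf 3 over the relative value at flowering. Significance of a
variety's decline is assessed by a leaf3-vs-flowering contrast on
replicate-level relative values (each medium replicate divided by the
low-platform cell mean), using the two-group one-way ANOVA at p ≤ 0.01;
the exact test behind "significant reduction" was an open design choice
and this one keeps the machinery inside the package's own ANOVA. Cells
with fewer than 3 replicates are excluded from testing; means use
whatever replicates exist, with 6 the design size.

The marker parameter is the one with the largest mean RF among those
declining significantly in at least a configurable fraction of varieties
(default 100%); ties break on the fraction of significant varieties, then
lexicographically, making selection order-invariant. The SPI weight n is
the marker's mean RF rounded to the nearest integer with a floor of 1
(2.3 → 2); the rounding rule is a package choice, as only the resulting
integer is conventionally reported. The index itself is

    SPI = log10(A) + n · log10(B)

with A and B the marker's relative values at leaf 3 and flowering. Base
10 is the default (configurable), matching the drought-factor-index
lineage this construction follows.

## ANOVA, Duncan and letters

The one-way ANOVA is the classical fixed-effects decomposition. Duncan's
multiple range test uses least significant ranges
R_p = q(1−α_p, p, df_error)·√(MSE/n) with protection level
α_p = 1−(1−α)^(p−1); studentized-range quantiles come from
`scipy.stats.studentized_range` (computed numerically, no table lookup,
memoised because each quantile evaluation is expensive). Stepwise testing
declares any pair inside a non-significant span non-significant, which
guarantees a contradiction-free compact letter display; letters are
assigned by insert-and-absorb. Unbalanced groups fall back to the
harmonic-mean group size. α defaults to 0.01 for ANOVA screening and 0.05
for post-hoc comparisons of small transformation experiments.

## SSR diversity and the Shannon AMOVA

Per locus: allele frequencies over non-missing copies (pairwise deletion,
matching frequency-based estimators), observed heterozygosity as the
fraction of heterozygous calls, gene diversity He = 1−Σp², and
PIC = 1−Σp²−Σ_{i<j}2p_i²p_j².

The molecular-variance partition uses Shannon information in natural
logarithms: per locus, the pooled-frequency information I_total splits
exactly into the copy-weighted mean within-population information and the
among-population mutual information, and 2N·I (N allele copies at the
locus) is the G statistic of the alleles × populations contingency table.
G statistics are summed over loci, so G_total = G_among + G_within holds
by construction; natural logs are required for this G-test identity.
Variance components come from a standard two-level AMOVA on
allele-mismatch distances (per-locus mismatch 0/1/2 between diploid
calls), since published tables of this kind report both G statistics and
variance components; percentages are always computed from the package's
own components. Degrees of freedom follow the general convention
(df_among = k−1, df_within = N−k).

P values permute individuals across populations with sizes fixed, with
the +1/(perm+1) correction. p_among is the upper tail of G_among;
p_within is the lower tail of G_within, because population structure
depresses within-population information — under the null both are
approximately uniform, which the type-I-error suite verifies against the
exact binomial interval.

Evanno's ΔK is |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K)) with
sample sd over replicates, defined for interior K only and flagged NaN
where sd = 0.

## Protein properties

Average (not monoisotopic) residue masses with one water per chain; MW is
summed with `math.fsum` so additivity holds to well below 1e-9 Da. The pI
is found by bisection on [0, 14] to 1e-3 pH of the Henderson–Hasselbalch
net charge under the Bjellqvist/ExPASy pKa set, including the
residue-specific terminal corrections; an EMBOSS-style set is selectable.
Note that biopython's `ProteinAnalysis.isoelectric_point` brackets its
search to [4.05, 12], so for very acidic or basic peptides only the
full-range bisection here satisfies the zero-charge definition. GRAVY is
the mean Kyte–Doolittle hydropathy, the aliphatic index is Ikai's
mole-percent formula X_A + 2.9·X_V + 3.9·(X_I + X_L), and the instability
index is Guruprasad's (10/L)·Σ DIWV over consecutive dipeptides; the
hydropathy and DIWV weight tables are imported from
`Bio.SeqUtils.ProtParamData`. Sequences with non-standard residues get MW
and composition indices over known residues only and no pI or instability
value (refuse rather than guess), with a warning.

## 2^-ΔΔCt

Replicate Cts are averaged per (sample, condition, gene) before ΔCt =
Ct_target − Ct_reference, ΔΔCt = ΔCt_treated − ΔCt_control and fold =
2^-ΔΔCt. Amplification efficiency is fixed at 2; plate-wide Ct shifts
cancel exactly. A clustered row ordering (Euclidean distance, average
linkage on log2 folds) is provided for heatmap presentation.

## Synthetic data: what it does and does not emulate

* **Transients** are sums of three saturating exponentials (J/I/P phases)
  rising from F0* to FM*, with the kinetic clock starting at the 50-µs F0
  mark so the origin level is held through the O region, log-uniform
  sampling with mark times included exactly, and optional Gaussian noise.
  This exercises mark extraction and the parameter algebra; it is not a
  photochemical ODE model and carries no I-step heterogeneity,
  photoinhibition or instrument artefacts.
* **Panels** default to 18 varieties × 3 stages × 2 platforms × 6
  replicates with ~4% replicate CV. The planted medium-salinity
  depressions give the marker (PIabs) relative values of 0.85 at leaf 3
  and 0.37 at flowering — a reduction factor near 2.3, the design point of
  the field study — with mild declines for NPQ/ETR/FvFm/A, log-normal
  variety-to-variety RF spread (sd 0.08), and dry-matter gain correlated
  with the planted SPI at r = 0.8. Real panels add year effects, spatial
  structure and non-Gaussian replicate error that are not modelled, so
  passing tests demonstrate correctness of the computations, not field
  predictivity.
* **Genotypes** follow the Balding–Nichols island model (Dirichlet
  ancestral frequencies, Beta/Dirichlet population frequencies at the
  planted FST) with 30 loci of 2–5 alleles, matching the marker panel's
  reported allelic range; there is no linkage, admixture or genotyping
  error.
* **Ct tables** realise requested fold changes exactly at zero noise;
  **peptides** are uniform-composition random sequences.

All generators are pure functions of (config, seed); regeneration is
byte-identical.

## Problem sizes in the standard runs

The test suite and the acceptance script use 500 noiseless transients for
the mark round trip, 200 random 3–6-group datasets for the Duncan oracle,
300 null datasets (2 populations × 9 individuals × 30 loci, 200
permutations each) for the permutation test's type-I error with 50 seeds
per FST level for the differentiation sweep, and 100 random 50-mers for
the pI and MW checks. These sizes give stable Monte-Carlo estimates (the
type-I check uses the exact binomial 95% interval at n = 300) while
keeping a full run in the tens of seconds on one CPU.

## Known limitations

* The published molecular-variance table this pipeline's layout follows
  prints degrees of freedom (2, 14) that no standard convention
  reproduces for 18 individuals, and a percentage (71.7%) inconsistent
  with its own printed components (3.84/5.43 = 70.7%); the package always
  reports df and percentages computed from its own inputs.
* Field-scale correlations (SPI vs dry-matter gain and the like) depend
  on unreleased raw data; the package reproduces the machinery and
  verifies it on planted ground truth instead.
* No STRUCTURE-style MCMC admixture inference is included — only the ΔK
  post-processing of externally produced log-probabilities.
* Duncan's test assumes approximate normality and homoscedasticity; no
  robust or mixed-model alternative is provided.
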