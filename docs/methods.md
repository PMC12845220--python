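# Methods

`dinpop` implements the statistical pipeline used to characterise genetic
diversity and structure in a fragmented, mixed-ploidy mountain plant from
four marker systems: flow-cytometry genome sizes, codominant nuclear
microsatellites, dominant AFLP-style fingerprints, and aligned chloroplast
spacer sequences.  This note records the models, the parameters that
matter, the numerical choices, and what the synthetic generators do and do
not emulate.

## Flow cytometry (`dinpop.cytometry`)

Absolute genome size follows the linear fluorescence relationship
`2C = 2C_standard x I_sample / I_standard`, with the internal standard's 2C
defaulting to 1.99 pg (tomato).  Monoploid size is `1Cx = 2C / ploidy`;
picograms convert to Mbp with the standard factor 978.  Ploidy is assigned
as the unique p in {2, 4} for which `2C/p` falls inside the diploid 1Cx
envelope, default [0.60, 0.81] pg — the min–max range observed across
diploid populations of the target system; a value fitting neither or both
cytotypes raises an error carrying both quotients rather than guessing.

Among-population comparison of 1Cx is a one-way ANOVA with Tukey HSD
(scipy implementations).  Preprocessing is deliberately conservative:
per-population outliers beyond **3.0 x IQR** (Tukey's "far out" fence) are
removed — the common 1.5 fence trims about 1% of clean normal points at
n = 10 per group and measurably inflates the ANOVA's type-I error (0.115 vs
0.0525 at the nominal 0.05 in our calibration runs) — and a Shapiro–Wilk
screen at alpha = 0.05 triggers a log transform that is applied to **all**
groups, never only the failing ones, because mixing transformed and raw
groups in one ANOVA fabricates group differences.  Populations with fewer
than three plants after cleaning are excluded with a warning.

## Microsatellite diversity (`dinpop.ssr`)

All frequencies are over gene copies: two per diploid and four per
tetraploid individual.  Dosage-ambiguous tetraploid cells (fragment
analysis cannot distinguish AAAB from AABB) are expanded at read time to
four copies by the largest-remainder rule over the listed alleles; the
affected cells stay flagged, and `allele_counts(distinct_only=True)`
offers a sensitivity mode in which each distinct allele of an ambiguous
call contributes a single copy.

Per locus and scope the module reports A_N (detected alleles), A_E = 1 /
sum p_i^2 (effective alleles), rarefied allelic richness
`AR(g) = sum_i [1 - C(N - N_i, g) / C(N, g)]` at g gene copies (per
population we rarefy to the smallest per-population depth, so equal sample
sizes make AR coincide with A_N), observed heterozygosity H_O (fraction of
individuals carrying >= 2 distinct alleles — the simplest notion that
extends to tetraploids), Nei's unbiased expected heterozygosity
`H_E = (n_c / (n_c - 1)) (1 - sum p_i^2)`, and F = 1 - H_O/H_E.

The two skew indices are `R = A_E / A_N` and `iMAF = (1/A_N) / MAF`; both
approach 1 for equifrequent alleles and shrink as one or a few alleles
dominate.  Their significance is Monte-Carlo: the null redraws the scope's
gene copies from a uniform multinomial over the A_N observed alleles
(keeping the denominator fixed at A_N) and asks how often the null
statistic falls at or below the observed one, with the add-one correction.
Because both statistics are discrete — iMAF depends only on the largest
count — a tie-inclusive rank is conservative (measured rejection ~0.036 at
nominal 0.05), so draws exactly tied with the observation receive a
uniform random rank (seed-controlled).  With that construction the
rejection rate under the null is 0.05 within Monte-Carlo error, which the
acceptance suite verifies at 2000 simulations.

## Differentiation (`dinpop.differentiation`)

Weir–Cockerham moment estimators use per-allele variance components a
(among populations), b (among individuals within), c (within individuals);
overall and per-locus F_ST (theta), F_IS and F_IT are ratios of summed
components, never means of per-locus ratios.  The estimator is defined for
diploids; tetraploid individuals enter at the gene-copy level with the
">= 2 distinct alleles" heterozygosity notion, and any run containing them
carries an `approximate_for_tetraploids` flag.  Pairwise F_ST applies the
same machinery to each population pair; negative estimates are reported as
computed (flagged by a warning) for comparability with published tables.

AMOVA is one level (among/within populations) at the **gene-copy level**:
per locus, the units are gene copies with the allele-mismatch (0/1)
squared distance — sums of squares then reduce to allele-count algebra —
and variance components are summed across loci.  This is the formulation
whose Phi_ST is commensurable with theta (an inter-individual-distance
AMOVA estimates 2F/(1+F) instead, which we verified numerically before
settling the design).  Significance permutes whole individuals among
populations, default 9999 permutations, add-one p-value.

PCoA double-centres `-d^2/2` (Gower), keeps every eigenvalue, but computes
axis percentages over positive eigenvalues only and returns coordinates
only for them.  Evanno's delta-K pairs replicate runs by index:
`dK = mean_r |L_r(K+1) - 2 L_r(K) + L_r(K-1)| / sd_r L_r(K)`; a zero SD
yields NA with a warning rather than an infinite peak.

## Dominant markers (`dinpop.aflp`)

Scoring error comes from replicated profiles: over every within-group pair,
the mismatch rate among loci scored in both.  Under independent per-scoring
flips with probability e, a pair mismatches at rate 2e(1-e); the report
therefore carries both the raw mismatch rate (the figure conventionally
quoted as a study's "error rate") and the inverted flip rate
`e = (1 - sqrt(1 - 2m)) / 2`, which is the quantity our simulations recover
without bias.  Loci whose per-locus flip rate exceeds 0.10 (configurable)
are flagged; filtering drops them and collapses each replicate group to a
majority-consensus profile (ties and all-missing loci become missing).

Distances: Nei–Li/Dice `d = 1 - 2a/(2a + b + c)` over co-scored loci
(shared absences carry no weight by the formula itself) and the uncorrected
p-distance (mismatches / compared loci, 0/0 counting as agreement).  A pair
with no co-scored loci becomes NA with a warning, and trees refuse NA
matrices by name.

Neighbor-Joining is Saitou–Nei with the Studier–Keppler Q criterion; ties
in Q break deterministically toward the smallest pair of leaf labels, limb
lengths clamp at zero, and the final three nodes join by the three-point
formulas.  Bootstrap support resamples columns with replacement and is
mapped by bipartition identity; Newick output hides supports below 50% by
convention.

## Chloroplast haplotypes (`dinpop.cpdna`)

Only substitution sites are analysed: every column containing a gap — and,
by default, an N, since ambiguity codes are not expected in clean plastid
spacer data — is masked before anything else.  Sequences identical on kept
columns collapse into haplotypes, labelled H1... by first occurrence, with
frequencies, per-population membership and private/shared flags.

Diversity and neutrality: pi is the mean pairwise difference count,
theta_W = S/a1, Tajima's D uses the standard constants, and Fu's Fs is
`ln(S'/(1-S'))` with `S' = P(K >= k_obs | theta)` from the Ewens sampling
distribution, `P(K = k) = |s(n, k)| theta^k / (theta)_n`, taking
theta = pi as is standard for this statistic.  The primary evaluation runs
in log space on a Stirling-number recurrence (numerically exact to ~1e-12
against the secondary route); `fus_fs_exact` re-derives the same quantity
in exact rational arithmetic with big-integer Stirling numbers for
verification and extreme tails.

The statistical-parsimony connection limit asks for the largest number of
steps j whose probability of being homoplasy-free reaches 95%.  We model
substitutions as independent per-site Poisson(d) processes under
Jukes–Cantor, with d matched to the observed per-site difference p = j/m;
conditioning on j visible differences gives the closed form
`P(j) = (d e^-d / p)^j (e^-d / (1 - p))^(m-j)`, which is 1 at j = 0,
non-decreasing in sequence length, and admits one step at any realistic
length.  For the 1650-position concatenated spacer matrix the 95% limit is
12 steps (frozen as a regression value and cross-checked against a
Monte-Carlo per-site simulation).  The network then joins haplotype pairs
in order of increasing Hamming distance up to the limit — ties break
toward higher combined frequency, then lexicographic ids — inserting d-1
hypothetical nodes for a d-step join so that every edge spans exactly one
mutational step; pairs already connected are skipped (the result is a
forest), and components unreachable within the limit stay disconnected.
Hypothetical nodes are abstract steps: no intermediate sequence
reconstruction is attempted, matching how such networks draw unsampled
intermediates as featureless dots.

## Synthetic data (`dinpop.simulate`)

The default `SimConfig` *is* the emulated study design: 15 demes x 20
genotyped diploid individuals with deme index 1 ("population 2")
autotetraploid; 4 codominant loci with 9 ancestral alleles at target
F_ST = 0.12 (the study's overall differentiation scale); 818 dominant
fragments in 100–500 bp scored in 4 replicates for 4 individuals per deme
with a 5.93% per-scoring flip error; 61 chloroplast sequences of 1650
positions carrying 28 infinite-sites mutations; and per-cytotype 2C of
1.37 +- 0.05 pg (diploid) and 2.74 +- 0.11 pg (tetraploid) against a
1.99 pg standard.

Codominant and dominant differentiation use the Balding–Nichols model —
deme frequencies Dirichlet(p(1-F)/F) (Beta for the biallelic dominant
case) around Dirichlet-uniform ancestral frequencies — chosen over explicit
migration because the expected F_ST is available in closed form, which
makes estimator-recovery tests sharp.  Dominant presence follows the
diploid dominance law 1-(1-q)^2.  Chloroplast genealogies are either a
Kingman coalescent (rate k(k-1)/2, branch lengths in coalescent units) or
a star tree with unit branches emulating sudden expansion; a fixed number
of mutations is placed multinomially in proportion to branch length, each
on its own column (infinite sites, so the haplotype partition and
segregating-site count are exact bookkeeping), with optional gap columns
injected away from mutated sites to exercise masking.  Every generator is
a pure function of (config, seed) and returns a truth record sufficient to
recompute the downstream statistics by brute force at small n.

What the generators do **not** emulate: stepwise microsatellite mutation
and allele-size homoplasy, null alleles, linkage, selection, spatially
explicit migration, fragment-size co-migration artefacts in dominant data,
recurrent or multi-base substitution in the sequences, and cytometry
debris/gating noise.  Passing tests therefore demonstrate that the
estimators recover the parameters of these idealised models at the study's
sample sizes — not that real data meet the models' assumptions.

## Numerical conventions

Alignment columns are 1-based and intervals closed; missing data are
excluded pairwise or per locus, never imputed; allele labels are opaque
strings compared exactly (any fragment-size binning belongs upstream);
Monte-Carlo and permutation p-values use the add-one form with randomized
tie rank where the statistic is discrete; every stochastic routine takes a
seed or Generator and is reproducible bit-for-bit given one.  Problem
sizes in the test and acceptance runs (200 replicates for recovery, 2000
for null calibration, 60–200 for the reported summaries) were chosen so
Monte-Carlo error sits comfortably inside the asserted tolerances.

## Known limitations

Weir–Cockerham components for tetraploids are an approximation (the 1984
derivation is diploid); mixed-ploidy AMOVA treats each gene copy as an
exchangeable unit, ignoring within-individual correlation in
autotetraploids; the parsimony-probability model addresses multiple hits
but not recombination or indel homoplasy; and Fu's Fs at very large |Fs|
depends on log-tail accuracy — use `fus_fs_exact` when the tail matters.
External Bayesian clustering itself is out of scope: the toolkit only
post-processes its log-likelihood traces (delta-K) and exports NEXUS
distance blocks for external split-network drawing.
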