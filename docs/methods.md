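# Methods

This note documents the models and procedures implemented in `introscan`,
the choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Synthetic cohorts (`introscan.simgen`)

**Demography.** Cohorts are simulated with msprime under a configurable
`DemographicModel` (populations with per-epoch diploid sizes, population
splits, admixture pulses, uniform recombination and mutation rates, a
generation time). The default `papuan_model()` sketches Oceanian history: an
African-like outgroup (N=14,000), an East-Asian-like sister group (N=5,000)
and a Papuan-like focal group (N=4,000) splitting from a bottlenecked
out-of-Africa ancestor (N=3,000) 1,800 generations ago, out-of-Africa at
3,500 generations, archaic (Neanderthal/Denisovan-like) populations
diverging from modern humans 20,000 generations ago (~580 kya at g=29
years/generation) and from each other at 15,000 generations, a Neanderthal
pulse of 2% into the out-of-Africa ancestor at 2,000 generations and a
Denisovan pulse of 4% into the focal group at 1,500 generations.
r = 1e-8 and mu = 1.25e-8 per bp per generation. These are round
placeholder values on the right scale, intended to be edited per analysis;
none of the benchmarks depends on their exact values.

**Introgression ground truth.** A census is placed immediately above each
admixture pulse; a segment of a sampled haplotype is introgressed from donor
D exactly when its ancestral lineage sits in D at that census (recorded
ancestry via `tskit`'s `link_ancestors`, never re-inference). One caveat:
the simulator stops tracking a genomic segment once the entire sample set
has coalesced, so segments that fully coalesce more recently than the pulse
carry no truth. This matters only for very small samples of the focal group
alone (~20% of the genome for a single pair with N=4,000 and a pulse 1,800
generations back) and vanishes when any outgroup individual is co-sampled,
which every shipped benchmark does.

**Donor-private "tag" alleles.** Archaic-branch mutations arise naturally at
~0.4 per kbp inside tracts under the default divergence. On top of these,
explicit donor-private tag alleles are implanted at `tag_density`
(default 1 per kbp) on the census ancestors' segments — shared by descent
among all haplotypes inheriting a segment, and carried by every sampled
haplotype of the donor population, emulating variants fixed on the donor
lineage before the pulse. Tags make the private-variant observable and the
match-rate classifier strongly informative; setting `tag_density=0` leaves
only the divergence-scaled signal.

**Tract lengths.** For a single pulse t generations ago the mean tract
length is 1/(r t) (the `expected_tract_length` closed form); empirically the
length distribution is indistinguishable from exponential (KS at the 1%
level on 500+ near-independent tracts). Pooled multi-pulse scenarios are a
mixture of exponentials and are not tested against a single one.

**SVs, sweeps, satellites.** `implant_svs` places typed INS/DEL/INV events
(half-open reference coordinates; insertions carry their sequence and a 1 bp
breakpoint footprint) either uniformly or strictly inside truth tracts; SVs
overlapping the chromosome end are resampled. `apply_sweep` emulates
positive selection on an existing allele: the allele frequency is advanced
deterministically by p' = p + s p(1-p)/(1+s p) per generation and the focal
haplotype pool is then resampled to the new frequency, dragging linked
variation and compressing carrier coalescence times; recombination and drift
during the sweep are not modelled, so it represents a short, tightly linked
window around the selected site. `synthesize_satellite_array` builds an
alpha-satellite higher-order-repeat (HOR) array as tandem copies of one
random ancestral unit (default 171 bp monomers), each copy independently
substituted at a per-base rate, with unique flanks; the annotation tiles the
array exactly.

**Formats and determinism.** FASTA (one record per haplotype, `SAMPLE_hapK`),
VCF v4.2 with phased `GT` (internal coordinates are 0-based half-open;
conversion to 1-based happens only at the VCF boundary), BED for truth
tracts (column 4 = donor label) and truth SVs (column 4 = `INS:len` / `DEL`
/ `INV`). Every stochastic entry point requires an explicit seed; per-stage
generators are derived by hashing a stage label into the master seed, so
write→read→write round trips are byte-identical and identical seeds give
hash-identical cohorts.

## Tract detection (`introscan.archdetect`)

A two-state (modern/archaic) HMM runs over non-overlapping windows (default
1,000 bp) of one haplotype. The observable is the count of private derived
variants: derived alleles the focal haplotype carries at positions where the
outgroup panel carries none. Emissions are Poisson with rate lambda_state x
callable_fraction — the Poisson family is the natural choice for a count
observable and makes the callable-fraction scaling exact. Parameters are
fitted by Baum-Welch (scaled forward-backward in linear space with
per-window normalisation; no underflow at 1e6 windows; the sequential
recursion is JIT-compiled with numba when available). The log-likelihood is
non-decreasing by construction; states are relabelled after fitting so the
archaic state has the larger rate; all-equal counts return the initial
parameters with a warning. Segments are maximal runs of windows with
archaic posterior >= 0.8 (the posterior cutoff and the window size are
conventional defaults, both configurable).

**Origin classification.** For each segment, the match rate to each archaic
genome is the fraction of the segment's private derived alleles that the
archaic carries, restricted to sites the archaic genotypes cover. Segments
whose rates all fall below the low-affinity floor (default 10%) are
REJECTED; exactly one rate at or above the high cutoff (default 30%, a
conventional value — only the 10% floor is externally anchored) labels the
segment with that archaic; anything else is AMB(iguous). Zero informative
sites ⇒ REJECTED. Consensus with an external segment set (e.g. Sprime
output read from BED) intersects intervals per haplotype, drops
intersections below a minimum overlap, and recomputes the match profile on
the intersected span; Sprime's own score is never re-implemented.

On the default two-pulse benchmark (50 Mbp, 50,000 windows per haplotype)
base-level F1 against truth tracts is ~0.95 and the donor label is wrong on
<1% of truth tracts with >=20 informative sites.

## SV projection (`introscan.svmap`)

Merging: deletions/inversions link when they reciprocally overlap by >=50%
of both lengths; insertions (reciprocal overlap is ill-defined) link when
breakpoints are within 500 bp and the size ratio is >=0.5. Clusters are
single-linkage connected components over canonically sorted records, so the
result is independent of input order; the representative is the longest
member (ties: leftmost start, then source name). Projection requires the
SV's reference interval to be fully contained in a non-rejected segment on a
carrier haplotype (a conservative choice; `mode="overlap"` relaxes it);
origin is inherited from the segment. Tallies report introgressed INS/DEL
bases per genome and origin.

Genic enrichment crosses {introgressed, not} x {within 1 kbp of a gene,
not}: one-sided Fisher exact test (enrichment direction) plus a permutation
null that re-places all SVs uniformly on the same chromosome with lengths
preserved, p = (1 + #{perm >= obs})/(1 + n_perm) with the observed statistic
being the count of introgressed SVs near genes. SVs are counted, not base
pairs. Genotype concordance compares unordered diploid allele pairs on
shared (chrom, pos, ref, alt) keys, excludes missing genotypes from the
denominator, and stratifies SV classes by length bins.

## Archaic k-mer scan (`introscan.kmerscan`)

The k-mer set holds canonical (lexicographic min of self and reverse
complement) k-mers seen at least `min_archaic_occurrences` (default 2) times
across archaic inputs and never in the outgroup inputs; k = 31 by default.
Neither k nor the occurrence floor is externally fixed; 31 balances
specificity against error tolerance and the floor suppresses k-mers created
by isolated errors in archaic short reads. Counting assigns a k-mer to the
window containing its start only if it fits inside that window (so a 2 kbp
window fully covered by one member k-mer at k=31 counts 2000-31+1 = 1970).
Counting is strand-invariant up to window mirroring.

The count cutoff is calibrated as the smallest candidate (0, the observed
count values, max+1) whose flagged-window fraction does not exceed the
genome-wide introgression fraction — the conservative side of the
correspondence. Enrichment of counts in windows overlapping introgressed
segments uses a one-sided Mann-Whitney U test (exact when both groups are
<=50 and tie-free, midranks with tie-corrected normal approximation
otherwise). Window identity aligns sliding query windows (default 20 kbp,
1 kbp step) to a target with an optimal local alignment (match +1, mismatch
-1, gap -1; Biopython's PairwiseAligner) and reports
matches/(matches+mismatches+indel bases) of the single best hit.

## Selection statistics (`introscan.selscan`)

Hudson F_ST with the finite-sample numerator correction; slightly negative
values at finite n are retained. PBS = (T(fst_fs)+T(fst_fo)-T(fst_so))/2
with T(x) = -ln(1-x); any F_ST of 1 flags the statistic undefined. Segments
are consecutive non-overlapping blocks of exactly 100 SNVs (remainder
dropped); block F_ST is ratio-of-averages (mean numerator over mean
denominator) per pair before the T-transform. Per-SV PBS applies the same
machinery to the SV allele frequencies, mapping a zero Hudson denominator
(a pair monomorphic for the same allele) to F_ST = 0 so that SVs absent
from both reference groups remain scorable. f_D follows the per-site
donor-proxy definition: the denominator substitutes, at each site, the one
of {focal, archaic} with the larger derived frequency. f_D carries a mild
(~10-15%) downward bias relative to the realized admixture fraction when
the archaic panel is small — sampling noise inflates the per-site max in
the denominator — which stays within the three-standard-error acceptance
band at the benchmark's 40 replicates. r2 and D' use the standard haplotype
definitions with the sign-dependent D_max. Empirical p-values are
(1 + #{null >= obs})/(1 + n), never zero; null draws are simulated under the
same demographic model, matched SNV counts and sample sizes, and computed
through the same `segment_scan` code path (undefined replicates are redrawn
and counted).

## TMRCA and selection inference (`introscan.timeinfer`)

**Pairwise TMRCA decoding.** Hidden state of a window = TMRCA bin T_j;
emission = Poisson(2 mu L T_j) on the window's pairwise difference count;
transition = stay with probability 1-rho plus a prior-weighted switch with
total probability rho (default 0.1), a one-parameter stand-in for
sequential-coalescent switch rates. Posteriors come from scaled
forward-backward and normalise to 1 per window. On an independent
coalescent simulation the posterior-mean TMRCA tracks the true per-window
pair coalescence times with mean absolute log10 error ~0.15 (acceptance
bound 0.35). The sweep score is the posterior mass below a recent-time
threshold; sweeps compress carrier coalescence times and raise it.

**Wright-Fisher trajectory likelihood.** The population frequency lives on
a uniform grid (>=100 points; default 151). Per generation the transition
is Gaussian with mean p + s p(1-p)/(1+s p) (genic selection) and variance
p(1-p)/(2N), integrated over grid cells with absorbing boundaries at 0 and
1; multi-generation propagation uses cached matrix powers. Observations are
binomial samples at given times; the prior at the oldest observation is
uniform on (0,1) with trapezoid weights. `fit_selection` maximises over s
(a signed log-spaced grid refined by bounded scalar minimisation) for the
single-epoch model (df=1), or over (s1, s2) with one free change time for
the two-epoch model (df=3). The test statistic is the deviance
2(LL_alt - LL_null) referred to chi-squared — under neutral simulations the
5% rejection rate is ~0.035, and the MLE at s=0.02 (N=1e4, 50 replicates)
has ~3% bias. This frequency-grid HMM replaces ancestral-recombination-graph
importance sampling; it is validated by parameter recovery, not by matching
any particular published estimate.

**Satellite mutation rate.** For per-window divergence d (mismatches over
aligned columns, indel columns excluded; optional Jukes-Cantor correction
with saturation flagged at d >= 0.75), the neutral-model estimate is
mu = d / (2T/g + 4 N_anc) per bp per generation: 2T/g generations of branch
plus the expected 2 x 2N_anc generations of coalescent depth in the common
ancestor. Estimates are evaluated on a (T, N_anc) grid spanning the assumed
ranges (e.g. 400-700 kya, g=29) and summarised by mean and s.d.; a
per-allele rate is the per-bp rate times the allele length. Recovery at
mu = 3e-8 over 100 windows with known T and N_anc is within 15%.

**QV utilities.** error = 10^(-QV/10) and QV = -10 log10(error); an error
rate of zero maps to infinite QV with a warning.

## Problem sizes and what the benchmarks show

The shipped benchmarks use a 50 Mbp chromosome for tract recovery (50,000
one-kbp windows per haplotype), 0.5-2 Mbp cohorts elsewhere, 40-50
replicates for estimator recovery and 200 replicates for calibration checks
— sizes at which every property is testable on a single CPU in minutes.
The generator reproduces the features the methods rely on (exponential
tract lengths, donor-private allele density, shared descent of tags,
frequency differentiation under drift and pulses) but not others present in
real data: no genotyping or phasing error, no reference bias or callability
gaps (callable fraction defaults to 1), uniform recombination and mutation
rates, no background selection, a single chromosome, and satellite arrays
without HOR turnover or large-scale rearrangement. Passing benchmarks
therefore demonstrates correctness of the implementations and calibration
under the model's assumptions, not performance on real cohorts.
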