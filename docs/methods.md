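# Methods

`mitemap` re-implements, as a tested pipeline over synthetic data, the
computational analyses used to map maize resistance to the two-spotted
spider mite: bulked-segregant G′ scans from pooled allele depths,
sliding-window haplotype-identity detection among inbred lines, a pooled
allele-frequency meta-analysis across a shared haplotype, and the phenotype
statistics around them. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
emulate.

## The experimental design being emulated

A susceptible reference-like inbred (B73) is crossed to a resistant inbred;
F1 plants are selfed to produce F2 populations. Each cross is phenotyped in
two replicates of 200 plants with a 1–7 visual damage score (1 = least
damage = most resistant), the 50 most resistant and 50 most sensitive
plants per replicate are pooled, and each pool is sequenced to a few fold
coverage. Replicates are combined for the headline scan, with depth
thresholds doubled. Three related resistant lines share a long
identical-by-descent haplotype on chromosome 6 carrying a recessive
large-effect resistance locus.

## Synthetic data generator

**Genome.** Ten chromosomes spanning 300 Mb down to 150 Mb of physical
coordinate space, so Mb-scale windows behave realistically, but carrying
only thousands of SNP sites each (default 3,000; supported range roughly
2,000–20,000). Genetic lengths are proportional to physical length (about
2 M for the largest chromosome, in line with maize linkage maps); the
chromosome‑6 analog has its centromere at ~50 Mb.

**Parents.** Inbred lines are haploid-coded (homozygous) over biallelic
sites. Each resistant line carries the alternate allele at an independent
`divergence` fraction of sites (default 0.5 — at SNP sites that segregate
among maize inbreds, two unrelated lines differ about half the time; for a
single-cross SNP table, where every called site segregates between the two
parents, use 1.0). Inside an IBD segment all member lines copy one donor
haplotype, mismatching only at a `mutation_leak_rate` fraction of sites
(≤ 1%). Hard-filter annotations follow joint-call VCF semantics: QD, SOR,
MQ and the two rank sums are per-site INFO-style values (a configurable
fraction drawn failing each criterion; rank sums missing at 15% of sites),
while read depth is per line × site, so the depth-fold criterion is
line-specific.

**Meiosis.** No-interference (Haldane) model: crossover count per
chromosome is Poisson with mean equal to the map length in Morgans,
breakpoints uniform in bp, independent gametes. Crossover interference
would only sharpen short-range linkage and is immaterial at the 5–10 Mb
window scale analysed here.

**Phenotypes.** The damage score is the susceptible-class mean (5.2) minus
additive locus effects plus Gaussian noise (sd 0.5), clamped to [1, 7] and
kept continuous internally (scores were averages over raters; a helper
rounds to 0.5 steps for display). For each locus the effect size is set
from its target variance explained *h* among the two homozygous marker
classes: the classes are equifrequent in an F2, so the between-class
variance is Δ²/4 and Δ = 2σ√(h/(1−h)). Recessive coding makes the
heterozygote effect exactly equal to the susceptible homozygote's.

**Progeny counts** (for the damage-vs-productivity regression) are negative
binomial with a linear mean in the damage score. The slope is calibrated by
root finding so the *expected* ordinary-least-squares R² equals the target
(default 0.83): with mean μ = c₀ + b·s and size k, the expected R² is
b²·Var(s) / (b²·Var(s) + mean(μ + μ²/k)), whose supremum over b is
1/(1 + E[s²]/(Var(s)·k)). A size of 5 caps the attainable R² near 0.45 for
realistic score distributions, so when the target exceeds the supremum the
calibrator raises the size to twice the minimal feasible value before
solving for the slope; the realized size and slope are recorded in the
population's metadata.

**Bulks and pooled sequencing.** Bulks are the k lowest / highest damage
scores among non-excluded plants, ties broken by a seeded draw. At each
site informative for the cross, the true pool alternate-allele frequency is
the allele count over the 2k sampled chromosomes; per-pool depth is
Poisson, alternate read counts are binomial with a symmetric per-base
miscall probability (default 0.001), and GQ = min(99, 10·DP) — a coarse
stand-in whose only role is its interaction with the GQ ≥ 20 filter.
Because the bulks are finite samples of a finite population, pool allele
frequencies fluctuate coherently along whole chromosomes ("composition
noise"), exactly as in the real experiment.

**What is not emulated.** No read-level artifacts: mapping error,
copy-number regions, reference bias, indel misalignment and duplicate reads
do not exist here, so the hard filters reject only the simulated failing
fraction, and the G′ null is cleaner than on real data. No crossover
interference, no segregation distortion, no batch or greenhouse effects,
and exclusions (trapped-mite rule) default to probability 0. Passing tests
therefore demonstrate correctness of the analyses and recoverability of
planted signal, not robustness to alignment artifacts.

## Bulked-segregant scan

Sites are filtered on total depth within [min, max], per-pool depth,
between-pool depth difference, GQ in both pools, and a symmetric pooled
reference-allele-frequency band [0.2, 0.8] (defaults 6/36/8/3 per
replicate, doubled after merging replicates; PL is read but ignored). At
each retained site the 2×2 pool × allele table gives the likelihood-ratio
statistic G = 2 Σ nᵢ ln(nᵢ/n̂ᵢ) with expectations from the marginals; zero
cells contribute zero and a zero marginal makes the site degenerate
(skipped). G′ is the tricube-weighted mean of G over sites within
window/2 = 5 Mb of the focal site, truncated at chromosome ends. A
log-normal null is fitted to Hampel-filtered G′ (values within 5.2 MAD of
the median retained; location = ln median, scale = 1.4826 × MAD of ln G′ —
the standard normal-consistent MAD), upper-tail p-values are converted to
Benjamini–Hochberg q-values over all scanned sites, and QTL intervals are
maximal runs of consecutive scanned sites with q < 0.01, with runs closer
than one window width joined and the leftmost argmax of G′ as the peak.

Numerical notes: all coordinates are 1-based inclusive internally, BED
output is 0-based half-open; merged GQ is the minimum across replicates
covering a site; REF/ALT conflicts between replicates drop the site with a
logged count.

### Known limitation: interval-exactness at desk-scale SNP density

With ~10,000 simulated sites genome-wide, a 10 Mb window holds only ~20
retained SNPs, so the fitted null scale is dominated by per-site counting
noise rather than by pool-composition variance. Two consequences, both
measured by `mitemap.studies` and reported by the acceptance script:

1. The selection-induced G′ shoulder around a true QTL hovers near the
   significance threshold over tens of Mb and fragments into several
   intervals separated by more than one window, which the join rule cannot
   merge.
2. When the discovery set is large, the ~1% of false sites tolerated by BH
   cluster (G′ is window-correlated) into occasional separate intervals
   elsewhere; "exactly one interval" is an interval-level property that
   site-level FDR does not control.

Chromosome- and peak-level recovery is much higher than strict
interval-exactness (the strongest interval localizes the planted locus
within ±10 Mb in roughly 75–90% of runs, against ~10–50% for "exactly one
interval", varying by seed), and a no-QTL
null yields a significant-site fraction at or below the nominal FDR with
calibrated p-values. Strict interval-exactness improves only with SNP
density approaching the real data's 1–2 SNPs per kb.

## Haplotype identity

Six hard-filter criteria select high-confidence sites per line: depth
between 0.25× and 1.5× the line's genome-wide mean, QD ≥ 2, SOR ≤ 3,
MQ ≥ 50, and both rank sums ≥ −8 (missing rank sums pass, standard
hard-filter practice; missing QD/SOR/MQ fail; non-homozygous calls fail
since inbreds are compared as haploids). Windows of 5 Mb advance by
500 kb, anchored at position 1, with a final partial window kept when it
covers at least half a window. A window is valid for a pair only when at
least 20% of its SNP sites pass in both lines and more than 20 variable
sites remain (variable = at least one line carries the non-reference
allele). Similarity is matches over variable passing sites — sites where
both lines equal the reference carry no haplotype information against a
shared reference, and this denominator is insensitive to SNP density; both
counts are emitted so the all-passing-sites denominator can be recomputed.
Blocks are maximal runs of consecutive windows that are valid and ≥ 99%
similar for every pair of the line set, reported as the union of window
spans. Note the validity rule couples density to window size: below
~3,000 sites per chromosome, IBD windows (where variable-site density is
halved) cannot reach 21 variable sites and blocks fragment.

## Pooled meta-analysis

All resistant-pool tables (across crosses and replicates) are summed per
site, and likewise all sensitive-pool tables. At each haplotype-defining
SNP (resistant allele = the allele shared by the resistant lines, sensitive
allele = the reference-line allele) read counts are relabelled accordingly;
tables whose alleles match neither orientation are discarded at that site.
The module operates on per-site allele-depth counts rather than raw
alignments — equivalent information at SNP sites, which lets the generator's
tables feed it directly. Windows of 5 Mb advance by 1 Mb anchored at the
first haplotype site; per window, each pool's resistant-allele frequency is
pooled counts over total counts, and delta is their difference. The peak
interval is the maximal contiguous run of windows with delta ≥ 0.9 × max
containing the argmax (the 0.9 plateau fraction is configurable; no formal
rule exists for delimiting the published plateau). The centromere position
is attached as an annotation only. Under perfect selection at a recessive
locus the expected delta at the locus is 1 − (2/3)·0.5 = 2/3, from the
truncated F2 genotype distribution of the sensitive bulk.

## Phenotype statistics

Effective females per enclosure is max(day-1, day-6) counts; progeny per
female is per-enclosure progeny over effective females (undefined and
flagged at zero), or the two-leaf sum divided by the fixed 40 released.
Samples with more than 10 trapped mites are excluded (strictly more).
Group comparison is one-way ANOVA followed, when significant, by all
pairwise Welch t-tests (the safer default when only "t-tests" is specified)
with Hochberg step-up adjustment; the compact letter display assigns one
letter per maximal clique of the non-significance graph, ordered by group
means so relabelling groups permutes letters but preserves the partition.
ANOVA runs on raw rates by default with an optional log transform. The
single-marker analysis compares the three genotype classes, calls the mode
recessive when the heterozygote is indistinguishable from the susceptible
homozygote while the resistant homozygote differs from both (dominant in
the mirrored case, additive when all three differ), and reports variance
explained as the squared point-biserial correlation among homozygotes;
optionally the single most extreme residual in the resistant homozygous
class (a putative marker-QTL recombinant) is dropped and R² recomputed —
reported separately, never auto-applied. Missing genotype calls are dropped
listwise.

Note on the recessive-mode call rate: under a truly recessive locus the
heterozygote-vs-susceptible test is an exact null, so the mode is called
recessive in about 95% of replicates at α = 0.05 by construction — the
5% type-I error is irreducible at that α.

## Replication studies and problem sizes

`mitemap.studies` packages the end-to-end designs used for validation:
50-run single-QTL and two-QTL scan recoveries (two replicates of 200 F2,
50/50 bulks, 4× pool depth, 1,000 sites/chromosome), a 5-run no-QTL null,
500-replicate marker-R² recovery (200 F2 with 180 genotyped, emulating
failed PCRs), 200-replicate progeny-R² calibration at n = 100, haplotype
recovery at 4,000 sites/chromosome with the chromosome-6 segment spanning
7,895,601–109,684,471 bp, and a constructed meta plateau. These sizes keep
the full validation under a minute or two of CPU while preserving the
designs' statistical structure; the two-QTL simulation assigns both loci
the 0.70 homozygous-class variance target measured for the shared
chromosome-6 locus.
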