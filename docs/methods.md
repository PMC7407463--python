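# Methods

This note documents the models implemented in `crossbredsim`, the
defaults they run under, the numerical choices, and what the reduced
presets can and cannot say about the full-scale system.

## 1. Genome and historical population

Loci are biallelic and scattered uniformly at random over autosomes of
120 cM. Meiosis follows the Haldane model: the crossover count per
chromosome is Poisson with mean length/100, crossover positions are
uniform, no interference; a gamete starts on a random parental haplotype
per chromosome. Mutation is a recurrent symmetric allele flip at
2.5e-4 per locus per transmitted gamete. Haplotypes are stored
bit-packed (one bit per locus); this is purely an implementation choice
— a 2,010-generation history is memory-bandwidth bound, and packing
makes one desk replicate ~35 s — and all public accessors return 0/1/2
dosages.

The historical population starts at allele frequency 0.5 everywhere
(haplotype bits i.i.d. Bernoulli(0.5)) and runs 1,000 generations at
N = 2,500, a linear decline to 300 over 1,000 generations (a bottleneck
creating LD), and a linear re-expansion to 2,500 over 10 generations.
Each offspring draws a sire and a dam uniformly with replacement; sexes
are balanced. An exponential reading of the "gradual" decline was also
tried and produced nearly identical LD (the LD time scale 1/(2c) is slow
relative to the decline), so the simpler linear form is used.

## 2. Breed formation

Two disjoint base samples (80 males + 400 females each) found breeds P1
and P2, which undergo 20 generations of divergent truncation selection
(P1 up, P2 down) on a transient additive dummy trait: effects at the
QTL, rescaled to a target heritability, discarded afterwards. Each
generation the selected males and 400 females produce litters of 10
(equal sexes; 4,000 animals per breed), with full-sib and
parent-offspring matings excluded.

The number of selected sires per generation and the within-litter
structure of real QMSim-style breed formation are not observable from
the outside; they were reconstructed by requiring the simulated breeds
to reproduce the founder-structure statistics that the study reports as
its own validation: mean marker-pair r² of 0.15 at 0.9–1 Mbp
(1 cM = 1 Mbp), between-breed relationship 8cov(pP1, pP2) = 0.24 over
QC-passed markers, ~70% of markers passing QC, marker homozygosity
~0.62, and mean QTL frequency divergence |pP1 - pP2| = 0.21. At the
full scale the defaults are 40 sires and dummy-trait h² = 0.5.

**Desk-scale adaptation.** The desk genome carries 1,200 QTL instead of
7,200, so the same selection differential concentrates on 6x fewer loci:
per-locus selection pressure scales as i·h/sqrt(m). Running the
full-scale selection settings on the desk genome overshoots divergence
badly (8cov 0.045 instead of 0.24, |dp| 0.34 instead of 0.21). The desk
preset therefore uses 22 sires and dummy-trait h² = 0.03, calibrated
once against the five statistics above over replicate ensembles and then
frozen. With those values the desk replicate means are: QC keep 0.67,
8cov 0.23, PB homozygosity 0.626, CB homozygosity 0.558, E|dp| 0.20,
heterosis H ≈ 0.76.

**Known limitation:** the desk LD level plateaus at r² ≈ 0.13 in the
0.9–1.0 cM bin, ~10% below the full-scale 0.15, for any breed-formation
Ne that keeps the divergence statistics in range — LD and divergence
pull the effective population size in opposite directions at the reduced
genome. The replicate-to-replicate spread of this bin mean is tiny
(±0.002), so the offset is systematic, not sampling noise.

## 3. Marker QC

A marker is kept iff in *both* breeds independently MAF >= 0.05 and the
observed heterozygote frequency deviates from 2pq by at most t = 0.15.
QTL are never filtered. All evaluation, EFI and genomic-inbreeding
computations run on the QC-passed marker panel.

## 4. Trait architecture

2,500 trait QTL (417 at desk, proportional to the genome; 30 at mini)
are sampled uniformly among the simulated QTL segregating in at least
one founder cohort. Per locus the additive triple (a_P1, a_P2, a_C) is
MVN(0, Sigma_a) with diagonal sigma_u/m — base variances
(0.86, 0.54, 0.28) for P1, P2, CB — and correlation rQTL (0.5, or 0.8
in one contrast); dominance deviations d* likewise with base variances
(0.04, 0.06, 0.02). Directional dominance enters as d = mu_d + d* with
mu_d = -b/m per population and b = -10 (one unit lost per 10% increase
in homozygosity); the division by m is forced by the requirement that an
individual's heterosis (1 - fg)·m·mu_d be independent of the QTL count,
and is verified empirically by the slope-recovery test (regressing total
genotypic value on QTL homozygosity returns b).

**Calibration.** At founder frequencies (CB taken as the parental mean)
the realized components are sigma_u² = sum 2pq·alpha² with
alpha = a + d(q - p), and sigma_v² = sum (2pq·d)². d* is rescaled by a
per-population scalar so that sigma_v²/sigma_u² = hd²/h²; because alpha
itself contains d, both variances are quadratics in the scalar and the
condition is solved exactly. mu_d is never rescaled, preserving b. The
residual follows as sigma_e² = sigma_u²(1 - h² - hd²)/h². Three variance
cases are predefined: (1) h² = 0.1, hd² = 0.01; (2) 0.1, 0.1;
(3) 0.3, 0.1.

*Edge case:* for case 1 at reduced QTL numbers the target dominance
ratio can be unattainable for the CB population — the unscaled mu_d
alone carries more dominance variance than hd²/h² times the additive
variance (mu_d/sd(d*) grows as 1/sqrt(m)). The calibration then warns
and settles at the closest attainable ratio, found from the analytic
critical points of the ratio function. At m = 2,500 all cases are
feasible.

Phenotypes are y = 10 + g + e, females only (a maternal trait); for PB
animals g is the full own-breed genotypic value (additive plus dominance
including mu_d), so PB records carry the dominance signal the trivariate
model estimates; for CB animals g is the TTGV.

## 5. Genomic evaluation

Variance components and the across-population effect correlation are
treated as known (the calibrated true values), as the study does.

**GBLUP (scenarios S1/S2).** Per breed, y = 1·mu + fg·b + u + e with
u ~ N(0, G·sigma_u²), G the VanRaden matrix over records and candidates
jointly, centered at training-record frequencies; fg is the marker
homozygosity fraction (dropped with a warning if constant). The solve
uses the observation-space form u = sigma_u²·G·V^{-1}(y - X·beta), which
needs no G inverse (duplicate genotypes and other rank deficiencies are
harmless) and is algebraically identical to ridge regression on centered
markers — a property tested to 1e-6 relative.

**Trivariate SNP-BLUP (S3/S4).** Joint solve over P1, P2 and CB records
with additive covariates z - 2p_t, genotypic ("biological") dominance
covariates het(z) - 2p_t q_t, intercept and fg per population. Per SNP
the additive triples across populations are MVN(0, Sigma_a*) with
scales sigma_u_t²/sum 2p_t q_t and correlation rQTL; dominance likewise
with sigma_v_t²/sum (2p_t q_t)². Residuals are independent across
populations. A population without records (CB in the first cycle) still
receives effect estimates through the correlation. Systems up to 5,000
unknowns are assembled and solved densely; larger ones use
Jacobi-preconditioned conjugate gradients, matrix-free, relative
residual 1e-8, at most 5,000 iterations (non-convergence flags the fit
and warns). Candidates are scored from SNP effects without re-solving:
EBVC_i = sum_j (z_ij - 2p_own)(a_Cj + (q_opp - p_opp) d_Cj) with current
cohort frequencies.

## 6. Breeding scheme

Founders are 12 males + 204 females per breed drawn uniformly from the
breed-formation output. Candidates are selected at birth: a female born
in wave g delivers her record one reproductive cycle later, so the
evaluation of wave-g candidates uses PB female records of waves <= g-1
and CB records of waves <= g-2 (the commercial tier reports with an
extra lag; this reproduces the asymmetric information structure of the
study design, where the closest recorded CB relative of a P1 candidate
is an offspring of its paternal grandsire). CB cohort g is born together
with PB wave g+1 and shares its sires; its dams are the second-best 204
P2 females (founder females for the first cohort, which is mated at
random in every scenario).

Within-breed matings are always random with a balanced 17-dams-per-sire
deal; litters are 12 with a fixed 10F/2M split (the deterministic sex
ratio removes binomial noise from the selectable counts), giving 2,448
offspring per population per generation. Mate allocation applies only
to CB production: S2 minimizes mean EFI over QC markers, S4 maximizes
mean ETGV under the CB-population SNP effect estimates, S4* scores the
same LP with the true QTL effects and genotypes (an upper bound used
only in the mating step, never in selection). The LP has transportation
structure (sire quotas exactly 17, dams at most once), so the HiGHS
relaxation returns integral vertices; integrality is verified and a
deterministic greedy repair handles tied fractional vertices. All ties
elsewhere break by ascending id.

Reported metrics per generation: mean TTGV of CB and mean TBVP per breed
(relative to generation 0), rPC per breed and averaged, marker-based
genomic inbreeding per population, expected heterosis
H = sum d_c(pP1 - pP2)², mean |pP1 - pP2|, and the depression
regressions b-hat from each evaluation.

## 7. Randomness and reproducibility

All randomness flows from one master seed through named substreams
(genome, historical, breed-formation, founders, effects, phenotypes,
per-generation mating and reproduction streams, replicate index). Two
scenarios sharing a master seed therefore share genomes, architectures,
founder draws and purebred mating, and differ only where the scenario
differs — S3 and S4 have bit-identical purebred trajectories until
records of differently-mated CB cohorts feed back into training (wave 4
at the earliest), which the controlled-difference tests exploit.

## 8. Presets, problem sizes and what the tests show

* `full` — the study scale (72K markers, 2,500 trait QTL, 10
  generations, 10 replicates). Provided as a documented preset; a full
  sweep is an overnight-scale computation and is not exercised by the
  test suite.
* `desk` — 3 chromosomes / 12,000 markers with the unchanged demography
  and family structure. Used for the founder-structure statistics (5
  replicates) and the controlled-difference runs (2 generations). One
  replicate of history + breed formation takes ~35 s + ~10 s.
* `mini` — 2 chromosomes / 500 markers / 100 QTL, 4 sires x 20 dams,
  litter 6, shortened history. Used for 10-generation whole-scheme
  property tests (selection-criterion and mate-allocation orderings,
  rPC decline, homozygosity trends). At this scale the trait has only
  30 QTL, so per-locus effects are large, architecture draws are noisy
  and case-1 dominance calibration is always in the fallback regime;
  mini results are orderings, not magnitudes.

What desk-scale agreement does *not* show: LD beyond the calibrated
regime (see §2), magnitudes of 10-generation selection response (the
417-QTL trait has coarser effect granularity than 2,500 QTL), or
anything about real pig data — the simulation inherits the study's
idealizations (discrete generations, random mating within breed, known
variance components, no genotyping error, a single trait).
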