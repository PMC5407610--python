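# Methods

This note records the models, conventions and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and
the problem sizes the test suite and acceptance script run at.

## Demographic model

The simulator encodes a two-population (Han "HAN", Tibetan "TIB") model
consumed as fitted constants: diploid sizes nA1 (ancestral), nC1–nC3 (Han)
and nT1–nT3 (Tibetan); epoch bounds T1 < T3 < T2+T3 in years ago; and four
per-generation per-chromosome migration rates. The split is exactly
T2 + T3 = 54,007 years ago.

**Size-history reading.** The size parameters are interpreted as
exponential-growth epochs, the usual convention for multi-epoch diffusion
fits: each population is founded at the split at (nC1, nT1), grows
exponentially to (nC2, nT2) by T3 years ago, grows on to (nC3, nT3) by T1
years ago and is constant since. We also implemented the alternative
piecewise-constant reading (sizes switching instantaneously at T3 and T1)
and rejected it: holding nC1 = 500 and nT1 = 2445 constant for the whole
~45 ky inter-split epoch produces a simulated genome-wide Hudson F_ST of
~0.149 between the two samples, an order of magnitude above the model's
published prediction, while the growth reading gives 0.0136–0.0145 across
seeds (target 0.0147 ± Monte-Carlo error). The growth reading is therefore
the package default, and the F_ST check in the acceptance suite is the
calibration surface that pins the choice down.

**Conventions.** Generation time 25 yr, mutation rate 1.25e-8 /bp/gen,
recombination rate 1e-8 /bp/gen. None of these are part of the fitted
parameter set; all are fields of `DemographicModel`. Migration indices:
m11/m21 are Tibetan→Han and m12/m22 Han→Tibetan forward-time fractions,
active before/after T3 years ago respectively (converted to backward
lineage-movement rates for msprime). The fractions are tiny, so the
direction convention is immaterial for every statistic we compute.

## Archaic scenarios

Archaic admixture layers four populations onto the modern model: a sampled
Denisovan ("DEN"), the introgressing Denisovan-like branch ("DENI", split
from DEN 400 kya), Neanderthal ("NEA", split from the Denisovan stem 450
kya) and their common archaic stem (split from moderns 700 kya). All
archaic sizes default to 2,500 diploids. Default pulses: 2% Neanderthal at
55 kya and 0.4% Denisovan at 40 kya. Because 55 kya predates the 54-kya
Han–Tibetan split, the Neanderthal pulse necessarily enters the common
ancestor ("ANC"); pulses aimed at a not-yet-diverged population are
rejected with an explicit error (a silent no-op otherwise — msprime moves
no lineages from an inactive population). The Denisovan pulses are
post-split and enter both modern populations at equal fractions, matching
the observation that genome-wide Denisovan ancestry does not differ
between the two.

True introgressed tracts are recorded by a census just older than the
oldest pulse: every sample segment whose census-time ancestor sits in
"DENI" or "NEA" is an introgressed tract by construction. The recorded
tract fraction converges to the pulse fraction (checked at 3-SE tolerance
in the tests).

The outgroup track is the ancestral allele, which is known by construction
in simulation; no chimpanzee branch is simulated.

## Sweep simulation

msprime's sweep model cannot condition on both the selection onset time
and the end frequency, which the scenario grid requires, so sweeps are
simulated in two stages:

1. **Conditioned frequency trajectory.** A discrete-generation
   Wright–Fisher path with genic selection runs forward from onset to the
   present with the model's (time-varying) population size. The proposal
   adds a bridging drift term — the deterministic logistic remainder is
   pulled toward the requested end frequency — and paths are
   rejection-accepted when the final frequency lands within ±0.02 of the
   target. All 60 grid cells have accepting trajectories. When the end
   frequency is not logistically reachable from a single de novo copy
   within the onset time, the sweep starts from standing variation at the
   back-solved logistic frequency (the unswept population then also
   carries the variant at that pre-selection frequency); `de_novo=True`
   raises `UnattainableSweepError` instead. Onset 0 degenerates to a
   conditioned standing variant with no selection phase.

2. **Forward copying phase.** The trajectory drives a conditioned forward
   phase on an msprime neutral panel (default 1,000 haplotypes for the
   swept population; tests use 250–600). Per generation the derived class
   reproduces by multinomial resampling — preserving the genuine founder
   amplification that creates long shared haplotypes — while the ancestral
   class reproduces by a minimal-drift permutation, so panel-scale
   resampling does not inject artificial drift at unlinked sites.
   Recombinant children (probability 1−exp(−rL)) take a single crossover
   from a uniform partner, keeping the focal-site side from the class
   parent. New mutations during the ≤400-generation sweep phase are
   ignored (negligible against the coalescent timescale).

Known approximations, stated so that test outcomes are read correctly:
the within-derived-class genealogy runs at panel scale rather than
population scale (faster coalescence → somewhat stronger EHH signal); the
neutral starting panel represents the population at the present rather
than at onset (≤400 generations of double-counted neutral history); the
comparison population is frozen during the sweep phase. The composite
score is trained and evaluated on the same generator, so these choices are
self-consistent; they do mean that absolute power numbers on real data may
differ from what the tests show.

## Component statistics

EHH is the probability that two random carrier haplotypes are identical
from the core site to a flanking site (missing calls break identity). iHH
integrates EHH outward by trapezoid over genetic distance (cM; fallback
1 cM/Mb from physical positions), truncated at the first site where EHH
< 0.05 — conventions inherited from the EHH literature. iHS is
ln(iHH_ancestral / iHH_derived), so long derived haplotypes give negative
raw scores; ΔiHH is the difference; both are flagged invalid when either
allele has < 2 carriers, the derived frequency is outside [0.05, 0.95], or
an iHH is 0. XP-EHH computes each population's unconditional haplotype
homozygosity integral over the interval where the *pooled* panel's EHH
stays ≥ 0.05, and takes the log ratio. F_ST uses the Hudson estimator
(numerator (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1), denominator
p1(1−p2) + p2(1−p1)) or the two-population Weir–Cockerham θ for haploid
counts; multi-site values are always ratio-of-sums. PBS transforms the
three pairwise F_ST values by T = −ln(1−F) (negatives clamped to 0) and
takes (T_TH + T_TE − T_HE)/2. Normalization of EHH-family scores is
genome-wide z-scoring against the neutral ensemble's moments (the phrasing
"SD above the genome-wide mean" is orientation-robust after
normalization). The partition-refinement EHH kernel is compiled with numba
when available, with an identical pure-numpy fallback.

## Composite score

Per-statistic densities are 60-bin histograms with a pseudo-count of 1 per
bin, shared bin edges between null and alternative, trained from neutral
simulations and from the focal-site statistics of sweeps pooled uniformly
over the scenario grid. Values outside the trained support clip into the
terminal bins. The per-site score is the sum of log naive-Bayes posteriors
with prior π = 1e-4.

Two deliberate choices:

- **Invalid components contribute ln π** (likelihood ratio 1, the
  evidence-free posterior) rather than rescaling the valid components by
  5/(number valid). Rescaling amplifies the remaining components by 5/4 at
  exactly the sites where iHS drops out — near-fixed hitchhikers — and
  systematically ranks them above the swept site; prior-padding keeps all
  sites on the same 5-component scale without amplification.
- **The null composite ensemble is held out**: half the neutral replicates
  train the densities, the other half are scored to form the ensemble
  against which empirical p-values are computed. Scoring the training
  sites against densities they shaped is anticonservative.

Empirical p-values are (1 + #{null ≥ observed})/(1 + N); q-values are
Benjamini–Hochberg. Windows aggregate the maximum score over member sites;
top windows (by fraction or count) are merged when adjacent and report the
maximum member score.

**Localization resolution.** The swept 200-kb window reliably outranks
neutral windows (100% in our checks), and at the strongest grid corner
(s = 0.04, end frequency 0.8) the swept site sits near the top of its
window. The swept site is *not* reliably the strict per-site argmax: every
perfect-LD proxy on the core haplotype shares its five statistics up to
sampling noise, and with an end frequency of 0.8 the ancestral class holds
only ~11 haplotypes, so iHH_A noise decides the ranking among ~10–40
proxies. Observed argmax rates are 10–30% across training densities from
8 to 216 alternative replicates; we believe this is a property of the
composite itself, not of the scaled-down training.

## QC filters

Quality masking (< 30 → missing) precedes the missingness cap (> 5%
removed), then duplicate-callset discordance (> 5% of shared samples with
unequal unphased genotypes — phase-insensitive because the callsets were
phased independently). Missing genotype pairs are excluded from the
discordance denominator. The enrichment filter requires derived frequency
> 10% in the target and < 1% in *each* reference population (the
conjunction reading); the archaic-like mask requires ≥ 1 archaic copy of
the derived allele, ≥ 1 target carrier, and folded MAF < 5% in every
reference.

## D, U, D* and S*

D is oriented so positive values mean excess archaic sharing in the case
population — term_case = p_case(1−p_ctrl)p_arch(1−p_out) — which is the
interpretation the statistic is used with (the printed equation's literal
term order is the opposite; we follow the meaning, not the typography).
The 1-Mb block bootstrap (200 replicates, 2.5/97.5 percentiles) supplies
CIs. U is D's denominator summed per window. D* sorts windows by U, splits
them into 20 near-equal groups (ties by chromosome and start; remainder to
the lowest-U groups) and divides each window's D by its group's sample SD;
p-values come from the same pipeline run on neutral equal-admixture
simulations, q-values from BH.

S* chains, per target haplotype, the derived alleles absent from the
comparison panel: score(i,j) = 5000 + distance for pairs ≥ 10 bp apart,
−10,000 otherwise; S(j) = max over i of score(i,j) + max(S(i), 0); window
score is the best chain over haplotypes, with candidacy requiring both a
score threshold (default 50,000) and ≥ 30% of the chained alleles matching
the archaic genome. All constants are configuration with these defaults.
The dynamic program is verified against exhaustive subset enumeration.

## Q-style admixture estimation

With a single sampled genome per archaic, the Denisovan and Neanderthal
fractions (m_D, m_N) are estimated simultaneously by equating observed
sharing statistics with Monte-Carlo expectations under the calibration
model and intersecting the two implicit curves (bisection; explicit
diagnostic when they fail to cross in [0,1]² beyond a small noise margin).

The observed statistic per archaic X is the **archaic-specific sharing
mass per Mb**: Σ p_case·w over sites, where w selects sites with X derived,
the other archaic ancestral (otherwise the two statistics are nearly
collinear — the archaics share most derived alleles), and the outgroup
ancestral. Two further design points, both forced by failure analysis:

- A per-site *mean* is non-monotone in the admixture fraction (admixture
  adds many new low-frequency informative sites that drag a mean down);
  the per-Mb mass is monotone.
- For *post-split* sources the weight additionally requires the derived
  allele to be rare (< 1%) in the comparison population, which suppresses
  the noisy incomplete-lineage-sorting baseline while keeping
  tract-specific sharing. For *pre-split* sources (pulses into the common
  ancestor, e.g. the default Neanderthal pulse) this conditioning would
  discard the genuinely shared tracts, so it is disabled per source.

Expectations are evaluated on a linear response surface fitted by
least squares through Monte-Carlo means at three anchors — (0,0),
(0.05, 0), (0, 0.05); anchors must sit well away from 0 because the
slopes are finite differences of noisy means. CIs are bootstrap-t over
1-Mb (tests: 500-kb) blocks of the observed statistics, with the
calibration anchor replicates resampled inside the bootstrap so
calibration uncertainty propagates; percentile intervals from tens of
blocks undercover. Parameter recovery is checked over a 3×3 grid of true
fractions, counting per-parameter coverage events.

## Dating

Sweep-age ML: summaries are (core derived frequency, log1p iHH_derived);
for each grid age a reference table of simulated summaries is built (the
table is reusable across estimates) and the likelihood of the observed
summary is a Gaussian product kernel over replicates (Scott bandwidth,
floored at 0.02 to avoid degenerate kernels). The CI is the
likelihood-ratio set at the χ²₁ cutoff. At desk scale the intervals are
wide — as are the published ones (point 12 kya, CI 7–28 kya) — and
coverage of a 480-generation truth is ≥ 90%.

The introgression window runs from the sweep onset (latest) back to the
oldest introduction time at which a single neutral archaic copy survives
to the onset with probability ≥ 5% (vectorized Wright–Fisher drift under
the model's size history; threshold 1 collapses the window). Gene-tree
divergence is k/(2·μ·span) years with an exact Poisson interval on k
(μ default 0.5e-9 /bp/yr ≈ 1.25e-8 per 25-yr generation); population
divergence subtracts the expected within-population coalescent waiting
2·N_archaic·generation_time, floored at 0.

## Enrichment

Genes attach to every window they overlap by ≥ 1 bp. A term's statistic is
the count of distinct term genes among the top windows' genes; the null
redraws the same number of windows without replacement, so the test
inherits gene clustering. q-values are BH; term maps are flat sets (no
ontology propagation). Verified against exhaustive enumeration on toy
instances.

## Problem sizes in the test suite and acceptance script

Chosen for a single CPU; all are scaled-down versions of the study-scale
conditions (1000 simulations per scenario cell, whole-genome panels):

- F_ST calibration: 40 × 5 Mb replicates (200 Mb), 27 + 62 diploids.
- Composite training: 8 grid cells × 4 sweeps, 25 neutral replicates of
  250 kb (panel 500 haplotypes), ~30–40 scored interior sites per
  replicate; held-out half of the neutral replicates forms the p-value
  ensemble.
- Type-I calibration: 10 fresh neutral panels × 40 sites; count-based
  tolerance with a ~2× variance allowance for LD clustering.
- Localization: 8–15 sweeps at s = 0.04, end frequency 0.8 vs 10 neutral
  windows.
- Q recovery: 3×3 truth grid, 10 Mb observed per cell, calibration 4
  replicates × 8 Mb per anchor.
- Sweep-age recovery: 5-age grid × 15 reference replicates of 500 kb,
  10 observed meta-replicates.

What passing these tests shows — and does not show: the pipeline's
statistics, calibration and estimators are internally consistent and
recover the truths of their own generative model at the stated tolerances.
The generator does not emulate genotyping error, phasing switch error,
variable recombination/mutation maps, GC-biased gene conversion or
background selection, so thresholds transferred to real data should be
re-calibrated against real-data nulls.

## Known limitations

- Sweep haplotype structure is panel-scale within the derived class (see
  above); absolute EHH magnitudes are approximate.
- The Q estimator's desk-scale uncertainty is dominated by the Monte-Carlo
  calibration; genome-scale data and larger calibration ensembles shrink
  both.
- The per-site argmax localization of the composite is a lottery among
  perfect-LD proxies (see "Localization resolution").
- Indels are supported only through PBS-style frequency statistics; the
  haplotype statistics require phased SNVs.
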