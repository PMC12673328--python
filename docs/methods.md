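# Methods

## The model

An admixed population of haploid genomes is described by a one-pulse model:
a fraction `m` of ancestry A (EUR) entered `t` generations ago into an
ancestry-B (AFR) background, followed by random mating.  Along a chromosome,
the ancestry of a sampled haploid genome is a two-state Markov chain: over a
genetic distance `d` (Morgans) the chain stays put with probability
`e^(−t·d)` and otherwise re-enters according to the genome-wide fractions
`(m, 1−m)`.  This is the standard exponential tract-length approximation;
drift corrections through the effective size `Ne` are omitted because at the
fixed `Ne = 100,000` and `t ≤ ~150` they are negligible, and the selection
statistic is insensitive to `Ne` at these time scales.

Emissions are called haploid genotypes.  The panel allele frequency for
ancestry `k` is the plug-in estimate with a 0.5 pseudocount,
`f = (alt + 0.5)/(total + 1)`, and a symmetric per-allele error `ε` gives
`P(obs = 1 | k) = f(1−ε) + (1−f)ε`; missing calls contribute likelihood 1.
`ε` defaults to 0.01 — a conventional error rate for called genotypes from
moderate-coverage short reads; no read-level modelling is attempted since
the target data are called haploid drone genotypes.  Chromosomes are
independent chains re-initialised at `(m, 1−m)`.

**Fitting.**  Stage 1 runs the forward–backward algorithm at `(t_init = 100,
m_init = 0.5)` and replaces `m` with the mean posterior ancestry-A fraction
until the update falls below 1e-4 (it converges in a few iterations and
further runs do not move it).  Stage 2 maximises the summed log-likelihood
over `t ∈ [1, 500]` by golden-section search to 0.5 generations, after which
the `m` iteration is repeated at the fitted `t` so the reported `m` is the
mean posterior under the reported model.  Uncertainty in `t` comes from a
block bootstrap: each chromosome is cut into windows of 200 contiguous AIMs,
windows are resampled with replacement and `t` refit per resample with each
window treated as an independent chain.

**Selection alternative.**  A sweep of haploid strength `s` at a focal site
moves the favored-ancestry frequency by `p_{g+1} = p_g(1+s)/(1+p_g s)` from
`p_0` = the genome-wide fraction of the favored ancestry.  A linked marker
at per-generation recombination fraction `r` (Haldane, `r = (1−e^(−2d))/2`)
is tracked on the selected and unselected backgrounds (`q_C = 1`, `q_N = 0`
initially); each generation the marker ancestries relax toward their mixture
`q̄ = p·q_C + (1−p)·q_N` at rate `r`, and `p` takes one selection step.  The
hypothesis likelihood substitutes the resulting per-site `q̄(d)` for `m` in
the transition re-entry terms and the initial distribution, keeping the
switch rate `t`; at `s = 0` this reduces exactly to the neutral model.  The
cited selection-scan tool modifies the full transition structure; the
stationary-fraction substitution is the simplest model consistent with the
forward iteration and is validated here by its own calibration and
localization tests rather than by equivalence to that tool.  The statistic
is `Λ = 2(ℓ(ŝ) − ℓ(0))`, floored at zero, with `ŝ` from golden-section
search over `[0.001, 0.5]` (tolerance 1e-3); each chromosome is scanned
separately, so a hypothesis' likelihood covers the focal chromosome only.

**Significance.**  Peaks are strict local maxima (plateaus keep the leftmost
index) with topographic prominence computed on a zero-flanked profile so
chromosome-terminal peaks get their full height and the peak set is
invariant to zero padding.  Maxima within 20 AIMs keep only the highest.
Defaults: minimum Λ equals the χ²₁ Bonferroni critical value at
`α/n_tests` and minimum prominence half of it; the published analysis states
that height and prominence filters exist but not their values, so both are
exposed as parameters.  `n_tests` is the size of the AIM panel — a strided
scan subsamples the same test family and does not shrink the correction.

## The synthetic data

Parental panels follow the Balding–Nichols model: per site an ancestral
frequency is uniform on (0.05, 0.95) and each population's frequency is
Beta-distributed around it with differentiation `F = 0.368`, the printed
ADMIXTURE-level F_ST between the EUR and AFR lineages.  Sites are
independent given frequencies — there is no within-panel linkage
disequilibrium; linkage in admixed genomes comes entirely from ancestry
tracts.  Consequently, passing tests demonstrate correct inference under
the HMM's own emission assumptions; real panels carry background LD, allele
frequency spectra and genotyping artefacts the generator does not emulate.

The default genome is 5 chromosomes × 10 Mb at a uniform 20 cM/Mb — the
honey bee's genome-wide recombination rate is the highest known among
animals — with candidate SNPs every 3.3 kb, yielding ≈ 10,000 AIMs after
the 0.10-difference and spacing filters.  The 16-chromosome fine-scale map
of the real genome is not reproduced.

The forward simulator performs copy-level Wright–Fisher reproduction over
chromosome copies: every offspring copy recombines two uniformly chosen
parent copies with Poisson(length in Morgans) crossovers placed uniformly
in genetic distance (no interference).  A pulse replaces the stated
fraction of the current generation's copies with unadmixed donor genomes; a
resize sets the diploid size of a generation.  The bottleneck "to four
admixed individuals" is modelled as 4 diploids = 8 chromosome copies without
explicit queen/drone structure or haplodiploid sex determination — the
lineage count and drift magnitude are what matter for calibration.
Selection is haploid multiplicative viability `(1+s)` at one site.
Ancestry labels are generic integers, which also supports lineage tracing
(unique founder labels) used to assert that at most 8 lineages survive the
bottleneck at any locus.

## Calibration under the bottleneck demography

The neutral reference scenario is: AFR population of 1,000 diploids, a 0.3
EUR pulse, 100 generations of random mating, a one-generation bottleneck to
4 diploids, a 0.5 EUR pulse (the resident EUR population), then 50
generations at 1,000 diploids (G = 150, expected EUR fraction
0.5 + 0.5·0.3 = 0.65).  Twenty end-to-end replicates (simulate → emit →
fit → scan both directions at stride 20 → peaks → Bonferroni) measure the
mean number of significant peaks per genome per direction.

Two facts frame the result.  First, the likelihood-ratio statistic is well
calibrated against sampling noise: under a one-pulse history with a large
population, the genome-wide maximum Λ stays below the Bonferroni critical
value.  Second, the bottleneck demography itself generates local-ancestry
fluctuations with standard deviation ≈ 0.14 (dominated by the 8-copy
bottleneck and the 50 generations at N = 1,000; a tenfold larger
pre-bottleneck population changes nothing).  Such drift deviations are real
population-level signals that an ancestry-frequency test cannot distinguish
from selection, so on this 10-Morgan genome a handful of drift peaks per
genome can exceed the threshold.  The calibration therefore reports the
drift-induced false-discovery rate of the scaled study conditions, not a
software error bar; on the ~44-Morgan real genome with a higher critical
value (24.50 at 67,361 tests) the same arithmetic yields proportionally
fewer discoveries per Morgan.

## Numerical choices

Golden-section searches use tolerance 1e-3 on `s` and 0.5 generations on
`t` and return the best evaluated point of a unimodal objective.  The
stationary fraction under selection is clamped to `[1e-6, 1 − 1e-6]` before
entering the chain.  Forward–backward uses per-site normalisation; Viterbi
runs in log space with ties broken toward ancestry A.  Map queries outside
the anchored span clamp to the terminal anchor (zero-rate extrapolation).
Interval arithmetic is 0-based half-open internally; positions are 1-based
at I/O boundaries.  Viterbi tract boundaries fall at midpoints between
adjacent AIMs of differing state.  The decile Spearman correlation computes
its two-sided P exactly by dynamic programming over rank subsets when the
10 bin means are untied, else falls back to the asymptotic approximation.
Permutation-enrichment P-values carry the add-one correction and a
per-term Monte-Carlo standard error; the default 100,000 draws (versus the
published 10 million) keeps desk runs tractable, with `n_perm` exposed.

## Test and validation scales

Parameter recovery uses ten datasets at (t = 74, m = 0.65, 30 haploids,
~2,000 AIMs, ε = 0.01).  Sweep localization uses a positive-control
scenario chosen so the signal is strong and demographic noise small: a
completed s = 0.1 sweep at the study's t = 74 in a population of 2,000
diploids, markers at the study-like density of ~0.0125 cM per AIM.  Even
then, localization is limited by the geometry of a completed sweep: the
ancestry plateau is flat at fixation, so the focal position is informed
only by the stochastically eroded flanks, and the argmax settles near the
plateau centre with a spread of a few tenths of a cM up to ~1 cM.  This is
an intrinsic property of ancestry-frequency evidence, not of the
implementation.  Bootstrap and enrichment tests run at reduced replicate
counts with fixed seeds; all simulation-backed checks state their seeds in
the test code.

## Known limitations

Two ancestries only; one pulse in the inference model (the simulator can
generate more complex histories, which then appear as an effective `t`);
called genotypes rather than read pileups; no dominance in selection
(drones are haploid); no GO-graph ancestor propagation beyond what the
input table encodes; the permutation null resamples peak locations jointly
with the 20-AIM separation rule, which is one reading of "non-overlapping
genomic regions".
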