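# ancestry-select

Local-ancestry-aware detection of ancestry-specific selection in admixed,
haploid genomes — built around the population history of Africanized honey
bees, whose New-World populations are recent admixtures of European (EUR) and
African (AFR) lineages.  Haploid drones make local ancestry directly
observable from called genotypes, and selection favoring alleles linked to
one ancestry leaves a measurable distortion in local ancestry frequency
around the selected site.

The package implements the full analysis chain as a tested library plus a
thin `ancestry-select` CLI:

1. **I/O** — haploid multi-sample VCF (two parental panels + admixed
   samples), recombination map (bp ↔ cM), BED/GFF3 gene annotation,
   gene→GO tables, and the tab-separated Ancestry_HMM-style observation
   format.
2. **Ancestry-informative markers (AIMs)** — sites with parental
   allele-frequency difference ≥ 0.10, thinned to ≥ 2.5 kb and ≥ 0.01 cM.
3. **Local ancestry HMM** — a two-state chain along each chromosome under a
   one-pulse admixture model: `P(i→j | d) = e^(−t·d)·1[i=j] + (1−e^(−t·d))·m_j`
   with `d` in Morgans, `t` generations since admixture and `m` the
   genome-wide EUR fraction.  Exact forward–backward posteriors, Viterbi
   tract calls, a two-stage (m, t) fit and a 200-AIM block bootstrap of t.
4. **Selection scan** — for each AIM and favored ancestry, the likelihood
   ratio `Λ = 2(max_s ℓ(s) − ℓ(0))` where the alternative replaces the
   stationary fraction with the expected local ancestry `q̄(d)` produced by a
   haploid sweep of strength `s` (forward-iterated over t generations,
   recombination fraction from Haldane's map function); `ŝ` by golden-section
   search over s ∈ [0.001, 0.5].
5. **Peaks & significance** — prominence-filtered local maxima, ≥ 20-AIM
   separation, χ²₁ Bonferroni threshold, and end-to-end false-discovery
   calibration on neutral forward simulations of the two-pulse bottleneck
   demography.
6. **Forward simulator** — tract-tracking Wright–Fisher reproduction with
   Poisson crossovers, pulses, bottlenecks, and optional ancestry-specific
   viability selection; the ground truth for every recovery test.
7. **Diagnostics** — ancestry-conditioned haplotype diversity in 200 bp
   windows, π / exon density / recombination rate in 100 kb AIM windows with
   decile-binned Spearman correlations, and permutation GO enrichment of
   peak-proximal genes (nearest gene within 50 kb, peak positions resampled
   from AIMs).

## Worked example

```python
import numpy as np
from ancestry_select import (Demography, EmissionModel, PanelModel,
                             RecombinationMap, emit_observations,
                             fit_admixture, gen_panel_freqs,
                             sample_panel_genotypes, select_aims, simulate)
from ancestry_select.selection_scan import EUR, scan

# two parental panels differentiated at F_ST ~ 0.368, 5 x 10 Mb genome
lengths_bp = {f"chr{i+1}": 10_000_000 for i in range(5)}
recmap = RecombinationMap.uniform(lengths_bp, 20.0)          # 20 cM/Mb
freq_a, freq_b = gen_panel_freqs(PanelModel(n_sites=2500, F=0.368, seed=11))
geno_a = sample_panel_genotypes(freq_a, 30, seed=1)           # EUR panel
geno_b = sample_panel_genotypes(freq_b, 28, seed=2)           # AFR panel

chrom = np.repeat(list(lengths_bp), 500).astype(object)
pos = np.tile(np.arange(500) * 20_000 + 10_000, 5)
counts = lambda g: np.stack([(g == 0).sum(1), (g == 1).sum(1)], axis=1)
panel = select_aims(counts(geno_a), counts(geno_b), chrom, pos, recmap)

# admixed drones: one pulse of 65% EUR ancestry, 74 generations ago
tracts = simulate(Demography.one_pulse(0.65, 74, size=1000),
                  {c: 200.0 for c in lengths_bp}, n_sample_haploids=30,
                  seed=5)
idx = {(c, p): i for i, (c, p) in enumerate(zip(chrom, pos))}
aim = np.array([idx[(c, p)] for c, p in zip(panel.chrom, panel.pos)])
geno = emit_observations(tracts, panel.chrom, panel.cm,
                         freq_a[aim], freq_b[aim], EmissionModel(0.01),
                         seed=7)

model, post = fit_admixture(geno, panel)
print(f"t = {model.t:.1f} generations, m = {model.m:.3f} EUR")
# -> t = 76.5 generations, m = 0.651 EUR

profile = scan(geno, panel, model, EUR, stride=20)
print(f"max LLR (EUR direction) = {profile.llr.max():.1f}")
# -> max LLR (EUR direction) = 7.5
```

On this neutral dataset the fit recovers the simulated history (t = 76.5 vs
74 true; m = 0.651 vs 0.65 true) and the scan's largest likelihood ratio
(7.5) stays far below the χ²₁ Bonferroni critical value (24.50 at α = 0.05 over
67,361 tests; `bonferroni_chi2_threshold(0.05, 67_361)`).  The admixture
clock `generations_per_year(74)` prints `1.28`.

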