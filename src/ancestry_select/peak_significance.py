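"""Peak calling, Bonferroni significance and neutral false-discovery calibration.

Candidate selected loci are local maxima of the likelihood-ratio profile,
filtered on height and topographic prominence, thinned to a minimum pairwise
separation of 20 AIMs (nearby maxima likely reflect one causative allele),
and declared significant when Λ exceeds the χ²₁ critical value at the
Bonferroni-corrected level α / n_tests, with n_tests the number of AIMs
scanned.  The calibration driver replays the whole pipeline — simulate a
neutral admixture history, emit genotypes, fit the admixture model, scan both
ancestry directions, call peaks — on replicate genomes and reports the mean
number of significant (false) peaks per genome per direction.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy import signal, stats

from . import admix_simulator as sim
from . import synthetic_data as sd
from .local_ancestry_hmm import AIMPanel, fit_admixture, select_aims
from .selection_scan import AFR, EUR, LLRProfile, scan
from .io_formats import RecombinationMap


@dataclasses.dataclass
class Peak:
    """A candidate selected locus on a likelihood-ratio profile."""

    chrom: str
    pos: int
    aim_index: int           # index into the scanned profile's AIM panel
    profile_index: int       # index into the profile itself
    llr: float
    prominence: float
    s_hat: float
    favored: int
    significant: bool = False
    ancestry_fraction: float | None = None


def bonferroni_chi2_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    """χ²₁ critical value at the Bonferroni-corrected tail level α/n."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return float(stats.chi2.isf(alpha / n_tests, df=1))


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateaus take the leftmost index."""
    n = x.size
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        left_ok = i == 0 or x[i - 1] < x[i]
        right_ok = j == n - 1 or x[j + 1] < x[i]
        # an all-flat or boundary plateau is not a peak
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            out.append(i)
        i = j + 1
    return np.array(out, dtype=np.int64)


def find_llr_peaks(profile: LLRProfile, min_llr: float,
                   min_prominence: float,
                   min_sep_aims: int = 20) -> list[Peak]:
    """Call peaks on a likelihood-ratio profile.

    Local maxima (strictly above their immediate neighbours; plateaus keep
    the leftmost index) are kept when Λ >= ``min_llr`` and their topographic
    prominence >= ``min_prominence``; among maxima on the same chromosome
    closer than ``min_sep_aims`` AIMs, only the highest-Λ one survives (ties
    broken leftmost).  Separation is measured in units of the underlying AIM
    panel index (``profile.aim_index``), so a strided scan still applies the
    same physical 20-AIM proximity rule.
    """
    peaks: list[Peak] = []
    chrom_arr = np.asarray(profile.chrom, dtype=object)
    for chrom in dict.fromkeys(chrom_arr):  # preserve order
        idx = np.flatnonzero(chrom_arr == chrom)
        x = profile.llr[idx]
        aim_idx = profile.aim_index[idx]
        cand = _local_maxima(x)
        if cand.size == 0:
            continue
        # prominence on a zero-flanked copy: chromosome-terminal maxima get
        # their full height and the peak set is invariant to zero padding
        padded = np.concatenate(([0.0], x, [0.0]))
        prom = signal.peak_prominences(padded, cand + 1)[0]
        keep = (x[cand] >= min_llr) & (prom >= min_prominence)
        cand, prom = cand[keep], prom[keep]
        # greedy thinning: highest Λ first, ties leftmost
        order = np.lexsort((cand, -x[cand]))
        taken: list[int] = []
        taken_prom: list[float] = []
        for k in order:
            c = cand[k]
            if all(abs(aim_idx[c] - aim_idx[t]) >= min_sep_aims
                   for t in taken):
                taken.append(int(c))
                taken_prom.append(float(prom[k]))
        for c, p in sorted(zip(taken, taken_prom)):
            g = idx[c]
            peaks.append(Peak(str(chrom), int(profile.pos[g]),
                              int(profile.aim_index[g]), int(g),
                              float(profile.llr[g]), p,
                              float(profile.s_hat[g]), profile.favored))
    return peaks


def flag_significance(peaks: Sequence[Peak], n_tests: int,
                      alpha: float = 0.05) -> list[Peak]:
    """Set each peak's significance flag from the Bonferroni χ²₁ rule."""
    threshold = bonferroni_chi2_threshold(alpha, n_tests)
    for p in peaks:
        p.significant = p.llr >= threshold
    return list(peaks)


def peaks_to_frame(peaks: Sequence[Peak], population: str = ""):
    """Tabulate peaks in the layout of the study's selected-loci table
    (population, ancestry, chromosome, position, ancestry proportion at the
    peak, Λ, proximal gene ids — filled by the GO module when available)."""
    import pandas as pd
    from .selection_scan import _DIRECTION_NAMES

    columns = ["population", "ancestry", "chrom", "pos",
               "ancestry_proportion", "llr", "s_hat", "significant",
               "proximal_genes"]
    if not peaks:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame([{
        "population": population,
        "ancestry": _DIRECTION_NAMES[p.favored],
        "chrom": p.chrom,
        "pos": p.pos,
        "ancestry_proportion": p.ancestry_fraction,
        "llr": p.llr,
        "s_hat": p.s_hat,
        "significant": p.significant,
        "proximal_genes": "",
    } for p in peaks])


# ---------------------------------------------------------------------------
# Neutral false-discovery calibration
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CalibrationSettings:
    """Study conditions for the neutral calibration replicates.

    The synthetic genome is 5 chromosomes of 10 Mb at a uniform 20 cM/Mb
    (honey-bee-like) recombination rate with candidate SNPs every
    ``site_spacing_bp``; parental panels are Balding-Nichols at F = 0.368
    with 30 EUR and 28 AFR haploids (the study's panel sizes); the admixed
    population follows the two-pulse bottleneck demography and 30 haploid
    genomes are sampled.
    """

    n_chrom: int = 5
    chrom_mb: float = 10.0
    rate_cm_per_mb: float = 20.0
    site_spacing_bp: int = 3300
    fst: float = 0.368
    n_panel_a: int = 30
    n_panel_b: int = 28
    n_admixed: int = 30
    epsilon: float = 0.01
    stride: int = 20
    alpha: float = 0.05
    min_sep_aims: int = 20
    demography: sim.Demography = dataclasses.field(
        default_factory=sim.Demography.puerto_rico_neutral)


def build_synthetic_aims(settings: CalibrationSettings, seed: int
                         ) -> tuple[AIMPanel, np.ndarray, np.ndarray,
                                    RecombinationMap, Mapping[str, float]]:
    """Generate panels and select AIMs for one synthetic genome.

    Returns (panel, freq_a, freq_b, recmap, chrom_lengths_cm) with the
    frequency arrays aligned to the AIM panel.
    """
    rng = np.random.default_rng(seed)
    lengths_bp, lengths_cm = sd.default_genome(
        settings.n_chrom, settings.chrom_mb, settings.rate_cm_per_mb)
    recmap = RecombinationMap.uniform(lengths_bp, settings.rate_cm_per_mb)
    per_chrom = int(settings.chrom_mb * 1e6) // settings.site_spacing_bp
    n_sites = per_chrom * settings.n_chrom
    model = sd.PanelModel(n_sites=n_sites, F=settings.fst,
                          seed=int(rng.integers(2**31)))
    freq_a, freq_b = sd.gen_panel_freqs(model)
    geno_a = sd.sample_panel_genotypes(freq_a, settings.n_panel_a,
                                       int(rng.integers(2**31)))
    geno_b = sd.sample_panel_genotypes(freq_b, settings.n_panel_b,
                                       int(rng.integers(2**31)))
    chrom = np.repeat(list(lengths_bp), per_chrom).astype(object)
    offset = settings.site_spacing_bp // 2
    pos = np.tile(np.arange(per_chrom) * settings.site_spacing_bp + offset,
                  settings.n_chrom)
    counts_a = np.stack([(geno_a == 0).sum(1), (geno_a == 1).sum(1)], axis=1)
    counts_b = np.stack([(geno_b == 0).sum(1), (geno_b == 1).sum(1)], axis=1)
    panel = select_aims(counts_a, counts_b, chrom, pos, recmap)
    # align per-site frequencies to the retained AIMs
    site_index = {(c, p): i for i, (c, p) in enumerate(zip(chrom, pos))}
    idx = np.array([site_index[(c, p)]
                    for c, p in zip(panel.chrom, panel.pos)], dtype=np.int64)
    return panel, freq_a[idx], freq_b[idx], recmap, lengths_cm


def run_neutral_replicate(settings: CalibrationSettings, seed: int
                          ) -> dict[int, int]:
    """One end-to-end neutral replicate: simulate, emit, fit, scan both
    directions, call peaks against the Bonferroni rule.  Returns the number
    of significant peaks per favored-ancestry direction."""
    rng = np.random.default_rng(seed)
    panel, freq_a, freq_b, _, lengths_cm = build_synthetic_aims(
        settings, int(rng.integers(2**31)))
    tracts = sim.simulate(settings.demography, lengths_cm,
                          n_sample_haploids=settings.n_admixed,
                          seed=int(rng.integers(2**31)))
    genotypes = sd.emit_observations(
        tracts, panel.chrom, panel.cm, freq_a, freq_b,
        sd.EmissionModel(settings.epsilon), seed=int(rng.integers(2**31)))
    model, _ = fit_admixture(genotypes, panel, epsilon=settings.epsilon)
    counts = {}
    n_tests = panel.n_sites  # the Bonferroni family is the full AIM set
    for direction in (EUR, AFR):
        profile = scan(genotypes, panel, model, direction,
                       stride=settings.stride, epsilon=settings.epsilon)
        threshold = bonferroni_chi2_threshold(settings.alpha, n_tests)
        peaks = find_llr_peaks(profile, min_llr=threshold,
                               min_prominence=threshold / 2.0,
                               min_sep_aims=settings.min_sep_aims)
        peaks = flag_significance(peaks, n_tests, settings.alpha)
        counts[direction] = sum(p.significant for p in peaks)
    return counts


def calibrate_false_discoveries(n_replicates: int,
                                settings: CalibrationSettings | None = None,
                                seed: int = 0) -> dict:
    """Mean significant peaks per neutral genome per direction, with the
    Monte-Carlo standard error of each mean."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    settings = settings or CalibrationSettings()
    seeds = np.random.default_rng(seed).integers(2**31, size=n_replicates)
    per_rep = {EUR: [], AFR: []}
    for s in seeds:
        counts = run_neutral_replicate(settings, int(s))
        for d in (EUR, AFR):
            per_rep[d].append(counts[d])
    out = {"n_replicates": n_replicates, "counts": per_rep}
    for d, name in ((EUR, "EUR"), (AFR, "AFR")):
        arr = np.array(per_rep[d], dtype=float)
        out[f"mean_{name}"] = float(arr.mean())
        out[f"se_{name}"] = float(arr.std(ddof=1) / np.sqrt(len(arr))
                                  if len(arr) > 1 else 0.0)
    return out
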