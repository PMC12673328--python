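"""Synthetic parental panels and admixed-sample observations.

Real analyses of Africanized honey bees use empirical European (EUR) and
African (AFR) reference panels; here the two panels are generated under the
Balding–Nichols model so that every downstream stage (AIM selection, the local
ancestry HMM, the selection scan, calibration) is testable without any
download.  The differentiation parameter F defaults to 0.368, the ADMIXTURE
K=2 F_ST level reported between the EUR and AFR lineages.

Sites are independent given the panel frequencies (no within-panel linkage
disequilibrium); linkage in admixed samples comes entirely from the ancestry
tracts that own each site, which is exactly the signal the HMM models.
All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_formats import MISSING


@dataclasses.dataclass(frozen=True)
class PanelModel:
    """Balding–Nichols panel-pair model.

    ``F`` controls differentiation: per site an ancestral frequency p is drawn
    uniformly from ``ancestral_freq_range`` and each population's frequency
    from Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance
    F p(1-p).
    """

    n_sites: int
    F: float = 0.368
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.F < 1.0:
            raise ValueError("F must be in (0, 1)")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("ancestral_freq_range must satisfy 0 < low < high < 1")


@dataclasses.dataclass(frozen=True)
class EmissionModel:
    """Per-allele symmetric genotype error probability."""

    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")


def gen_panel_freqs(model: PanelModel) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-site allele frequencies for the two parental populations."""
    rng = np.random.default_rng(model.seed)
    lo, hi = model.ancestral_freq_range
    p = rng.uniform(lo, hi, size=model.n_sites)
    c = (1.0 - model.F) / model.F
    freq_a = rng.beta(p * c, (1.0 - p) * c)
    freq_b = rng.beta(p * c, (1.0 - p) * c)
    return freq_a, freq_b


def sample_panel_genotypes(freqs: np.ndarray, n_haploids: int,
                           seed: int = 0) -> np.ndarray:
    """Sample an (n_sites, n_haploids) haploid genotype matrix, each allele
    Bernoulli(freq) independently across sites and samples."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return (rng.random((freqs.size, n_haploids)) < freqs[:, None]).astype(np.int8)


def emit_observations(tracts, site_chrom: np.ndarray, site_cm: np.ndarray,
                      freq_a: np.ndarray, freq_b: np.ndarray,
                      emission: EmissionModel = EmissionModel(),
                      seed: int = 0,
                      missing_rate: float = 0.0) -> np.ndarray:
    """Emit haploid genotypes for admixed samples from their ancestry tracts.

    Parameters
    ----------
    tracts : sequence of HaploidTracts
        One tract set per sample (simulator truth or Viterbi output); ancestry
        labels 0 = panel A, 1 = panel B.  Tracts must cover every site.
    site_chrom, site_cm : per-site chromosome label and genetic position (cM).
    freq_a, freq_b : per-site panel allele frequencies.
    missing_rate : fraction of calls dropped to MISSING at random.

    Returns an (n_sites, n_samples) int8 matrix: each allele is drawn
    Bernoulli(freq of the ancestry owning the site's tract) then flipped with
    probability ``emission.epsilon``.
    """
    rng = np.random.default_rng(seed)
    site_cm = np.asarray(site_cm, dtype=float)
    freq_a = np.asarray(freq_a, dtype=float)
    freq_b = np.asarray(freq_b, dtype=float)
    n_sites = site_cm.size
    out = np.empty((n_sites, len(tracts)), dtype=np.int8)
    for j, tr in enumerate(tracts):
        anc = tr.ancestry_at_sites(site_chrom, site_cm)  # 0/1 per site
        f = np.where(anc == 0, freq_a, freq_b)
        allele = rng.random(n_sites) < f
        flip = rng.random(n_sites) < emission.epsilon
        out[:, j] = (allele ^ flip).astype(np.int8)
    if missing_rate > 0:
        out[rng.random(out.shape) < missing_rate] = MISSING
    return out


def hudson_fst(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Hudson's F_ST, ratio-of-averages form, over shared biallelic sites.

    Numerator per site: (pA-pB)^2 - pA(1-pA)/(nA-1) - pB(1-pB)/(nB-1);
    denominator: pA(1-pB) + pB(1-pA).  Sites are haploid genotype matrices of
    shape (n_sites, n_haploids); missing calls (-1) are excluded per site.
    """
    ga = np.asarray(geno_a)
    gb = np.asarray(geno_b)
    if ga.shape[1] < 2 or gb.shape[1] < 2:
        raise ValueError("need at least 2 haploids per panel")
    ok_a = ga != MISSING
    ok_b = gb != MISSING
    na = ok_a.sum(axis=1)
    nb = ok_b.sum(axis=1)
    usable = (na >= 2) & (nb >= 2)
    pa = np.where(ok_a, ga, 0).sum(axis=1)[usable] / na[usable]
    pb = np.where(ok_b, gb, 0).sum(axis=1)[usable] / nb[usable]
    na = na[usable]
    nb = nb[usable]
    num = ((pa - pb) ** 2
           - pa * (1 - pa) / (na - 1)
           - pb * (1 - pb) / (nb - 1))
    den = pa * (1 - pb) + pb * (1 - pa)
    mean_den = den.mean() if den.size else 0.0
    if den.size == 0 or mean_den == 0.0:
        raise ValueError("F_ST undefined: panels monomorphic at every usable site")
    return float(num.mean() / mean_den)


def default_genome(n_chrom: int = 5, chrom_mb: float = 10.0,
                   rate_cm_per_mb: float = 20.0):
    """Default synthetic genome: ``n_chrom`` chromosomes of ``chrom_mb`` Mb at
    a uniform honey-bee-like recombination rate (returns chrom-length dict in
    bp and cM lengths)."""
    lengths_bp = {f"chr{i + 1}": int(chrom_mb * 1e6) for i in range(n_chrom)}
    lengths_cm = {c: rate_cm_per_mb * L / 1e6 for c, L in lengths_bp.items()}
    return lengths_bp, lengths_cm
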