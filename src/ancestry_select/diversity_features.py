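"""Ancestry-conditioned haplotype diversity and genomic-feature correlations.

Two diagnostics guard the selection scan against demographic confounding:

* Haplotype diversity inside inferred ancestry tracts.  A founding bottleneck
  would depress the number of distinct haplotypes genome-wide; ancestry-
  specific selection would depress it only around selected loci of one
  ancestry.  Diversity is measured as the count of unique haplotype strings
  over biallelic SNPs in 200 bp windows, restricted to samples whose Viterbi
  ancestry covers the whole window with the target ancestry, with the more
  abundant population randomly down-sampled so both populations contribute
  equal sample sizes.

* Correlation of the likelihood-ratio profile with nucleotide diversity,
  exon density and recombination rate in 100 kb windows around each AIM,
  summarised by Spearman's rank correlation on decile-binned data, plus the
  Pearson correlation between two populations' profiles.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GeneAnnotation, RecombinationMap, VariantTable
from .selection_scan import LLRProfile


@dataclasses.dataclass
class HaplotypeDiversitySummary:
    """Mean and spread of unique-haplotype counts over eligible windows."""

    population: str
    ancestry: int
    mean: float
    sd: float
    n_windows: int


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def window_pi(genotypes: np.ndarray, window_length: int) -> float:
    """Nucleotide diversity per site in a window.

    ``genotypes`` is (n_sites, n_samples) haploid 0/1/-1 for the window's
    SNPs; ``window_length`` the number of surveyed sites (monomorphic sites
    contribute 0 to the numerator but count in the denominator).  Uses the
    unbiased mean pairwise difference: sum over SNPs of 2 p (1-p) n/(n-1),
    divided by the window length.
    """
    g = np.asarray(genotypes)
    if g.ndim != 2 or g.shape[1] < 2:
        raise ValueError("need at least 2 haploid samples for pi")
    called = g != MISSING
    n = called.sum(axis=1)
    ok = n >= 2
    if g.shape[0] == 0 or not ok.any():
        return 0.0
    p = np.where(called, g == 1, 0).sum(axis=1)[ok] / n[ok]
    num = 2.0 * p * (1.0 - p) * n[ok] / (n[ok] - 1.0)
    return float(num.sum() / window_length)


# ---------------------------------------------------------------------------
# Haplotype diversity in ancestry tracts
# ---------------------------------------------------------------------------

def _covered_windows(tracts: pd.DataFrame, sample: str, chrom: str,
                     ancestry: int) -> list[tuple[int, int]]:
    sel = tracts[(tracts["sample"] == sample) & (tracts["chrom"] == chrom)
                 & (tracts["ancestry"] == ancestry)]
    return list(zip(sel["start"].astype(int), sel["end"].astype(int)))


def _fully_covered(intervals: list[tuple[int, int]], lo: int, hi: int) -> bool:
    return any(a <= lo and b >= hi for a, b in intervals)


def haplotype_diversity(variants: VariantTable, tracts: pd.DataFrame,
                        populations: Mapping[str, Sequence[str]],
                        ancestry: int, window_bp: int = 200,
                        seed: int = 0) -> dict[str, HaplotypeDiversitySummary]:
    """Unique-haplotype counts per population inside shared ancestry windows.

    ``tracts`` is a tidy (sample, chrom, start, end, ancestry) frame of
    Viterbi tracts in bp (0-based half-open); ``populations`` maps the two
    population names to their sample lists.  Windows of ``window_bp`` tile
    each chromosome; a window enters the summary when it contains at least
    one SNP and both populations have >= 2 eligible samples — samples whose
    target-ancestry tracts fully cover the window and whose calls in it are
    complete.  The larger eligible set is randomly down-sampled to the
    smaller's size before counting distinct haplotype strings.
    """
    if len(populations) != 2:
        raise ValueError("expected exactly two populations")
    rng = np.random.default_rng(seed)
    (name1, pop1), (name2, pop2) = populations.items()
    col = {s: variants.samples.index(s) for p in (pop1, pop2) for s in p}
    counts: dict[str, list[int]] = {name1: [], name2: []}
    chrom_arr = np.asarray(variants.chrom, dtype=object)
    for chrom in pd.unique(chrom_arr):
        mask = chrom_arr == chrom
        pos = variants.pos[mask] - 1  # to 0-based
        geno = variants.genotypes[mask]
        cover = {s: _covered_windows(tracts, s, str(chrom), ancestry)
                 for p in (pop1, pop2) for s in p}
        for w in np.unique(pos // window_bp):
            lo, hi = int(w) * window_bp, (int(w) + 1) * window_bp
            in_win = (pos >= lo) & (pos < hi)
            if not in_win.any():
                continue
            sub = geno[in_win]
            eligible = {}
            for name, popn in ((name1, pop1), (name2, pop2)):
                eligible[name] = [
                    s for s in popn
                    if _fully_covered(cover[s], lo, hi)
                    and not np.any(sub[:, col[s]] == MISSING)]
            k = min(len(eligible[name1]), len(eligible[name2]))
            if k < 2:
                continue
            for name in (name1, name2):
                chosen = eligible[name]
                if len(chosen) > k:
                    chosen = list(rng.choice(chosen, k, replace=False))
                haps = {tuple(sub[:, col[s]]) for s in chosen}
                counts[name].append(len(haps))
    out = {}
    for name in (name1, name2):
        arr = np.array(counts[name], dtype=float)
        if arr.size == 0:
            warnings.warn("no eligible haplotype-diversity windows")
            out[name] = HaplotypeDiversitySummary(name, ancestry, float("nan"),
                                                  float("nan"), 0)
        else:
            out[name] = HaplotypeDiversitySummary(
                name, ancestry, float(arr.mean()),
                float(arr.std(ddof=1)) if arr.size > 1 else 0.0, arr.size)
    return out


# ---------------------------------------------------------------------------
# Genomic features in windows
# ---------------------------------------------------------------------------

def _union_coverage(intervals: list[tuple[int, int]], lo: int, hi: int) -> int:
    """Length of the union of intervals clipped to [lo, hi)."""
    clipped = sorted((max(a, lo), min(b, hi)) for a, b in intervals
                     if b > lo and a < hi)
    covered = 0
    cur_lo, cur_hi = None, None
    for a, b in clipped:
        if cur_hi is None or a > cur_hi:
            if cur_hi is not None:
                covered += cur_hi - cur_lo
            cur_lo, cur_hi = a, b
        else:
            cur_hi = max(cur_hi, b)
    if cur_hi is not None:
        covered += cur_hi - cur_lo
    return covered


def window_features(annotation: GeneAnnotation, recmap: RecombinationMap,
                    windows: Sequence[tuple[str, int, int]]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Exon density (union-covered fraction) and recombination rate (cM/Mb)
    for each (chrom, start, end) window, 0-based half-open bp."""
    exons_by_chrom: dict[str, list[tuple[int, int]]] = {}
    gene_ids = np.asarray(annotation.gene_id)
    chrom_ids = np.asarray(annotation.chrom, dtype=object)
    for i, gid in enumerate(gene_ids):
        exons_by_chrom.setdefault(str(chrom_ids[i]), []).extend(
            annotation.exon_intervals(str(gid)))
    density = np.empty(len(windows))
    rate = np.empty(len(windows))
    for i, (chrom, lo, hi) in enumerate(windows):
        length = hi - lo
        density[i] = (_union_coverage(exons_by_chrom.get(chrom, []), lo, hi)
                      / length if length > 0 else 0.0)
        cm_lo = recmap.genetic_position(chrom, lo)
        cm_hi = recmap.genetic_position(chrom, hi)
        rate[i] = (cm_hi - cm_lo) / (length / 1e6) if length > 0 else 0.0
    return density, rate


def profile_window_stats(profile: LLRProfile, variants: VariantTable,
                         annotation: GeneAnnotation, recmap: RecombinationMap,
                         window_bp: int = 100_000) -> pd.DataFrame:
    """Per-AIM window statistics: pi, exon density, recombination rate and Λ
    in a ``window_bp`` window centred on each scanned AIM (windows overlap)."""
    half = window_bp // 2
    windows = [(str(c), max(0, int(p) - 1 - half), int(p) - 1 + half)
               for c, p in zip(profile.chrom, profile.pos)]
    density, rate = window_features(annotation, recmap, windows)
    chrom_arr = np.asarray(variants.chrom, dtype=object)
    pis = np.empty(len(windows))
    for i, (chrom, lo, hi) in enumerate(windows):
        mask = (chrom_arr == chrom) & (variants.pos - 1 >= lo) \
            & (variants.pos - 1 < hi)
        pis[i] = window_pi(variants.genotypes[mask], hi - lo)
    return pd.DataFrame({"chrom": profile.chrom, "pos": profile.pos,
                         "llr": profile.llr, "pi": pis,
                         "exon_density": density, "recomb_rate": rate})


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def _exact_spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided exact P for Spearman's rho on n untied ranks.

    Enumerates the null distribution of D = sum of squared rank differences
    by dynamic programming over rank subsets (feasible for n <= ~12).
    """
    max_d = n * (n * n - 1) // 3
    counts = np.zeros((1 << n, max_d + 1))
    counts[0, 0] = 1.0
    for s in range(1, 1 << n):
        k = bin(s).count("1")  # position being assigned (1-based)
        row = counts[s]
        for j in range(n):
            if s & (1 << j):
                d2 = (k - (j + 1)) ** 2
                prev = counts[s ^ (1 << j)]
                row[d2:] += prev[:max_d + 1 - d2]
    dist = counts[(1 << n) - 1]
    total = dist.sum()
    scale = n * (n * n - 1) / 6.0
    d_obs_low = scale * (1.0 - abs(rho))
    d_obs_high = scale * (1.0 + abs(rho))
    d_vals = np.arange(max_d + 1)
    p = (dist[d_vals <= d_obs_low + 1e-9].sum()
         + dist[d_vals >= d_obs_high - 1e-9].sum()) / total
    return float(min(1.0, p))


def decile_spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman's rank correlation on decile-binned data.

    Observations are sorted by x and split into 10 equal-count bins (any
    remainder spread one-per-bin over the leading bins); the correlation and
    its two-sided P are computed on the 10 per-bin means — the P exactly, by
    enumerating the rank-permutation null, when the bin means are untied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 10:
        raise ValueError("need at least 10 paired observations")
    order = np.argsort(x, kind="stable")
    n = x.size
    base, extra = divmod(n, 10)
    bins_x, bins_y = [], []
    start = 0
    for b in range(10):
        size = base + (1 if b < extra else 0)
        idx = order[start:start + size]
        bins_x.append(x[idx].mean())
        bins_y.append(y[idx].mean())
        start += size
    bx = np.array(bins_x)
    by = np.array(bins_y)
    rho = float(stats.spearmanr(bx, by).statistic)
    untied = (np.unique(bx).size == 10) and (np.unique(by).size == 10)
    if untied and not math.isnan(rho):
        p = _exact_spearman_pvalue(rho, 10)
    else:
        p = float(stats.spearmanr(bx, by).pvalue)
    return rho, p


def pearson_between_scans(profile1: LLRProfile,
                          profile2: LLRProfile) -> tuple[float, float]:
    """Pearson correlation (r, two-sided P) between two profiles' per-AIM Λ.

    Profiles must be on identical AIM sets (same chromosomes and positions).
    """
    same = (profile1.pos.size == profile2.pos.size
            and np.array_equal(profile1.pos, profile2.pos)
            and np.array_equal(np.asarray(profile1.chrom, dtype=object),
                               np.asarray(profile2.chrom, dtype=object)))
    if not same:
        raise ValueError("profiles are not on identical AIM sets")
    r, p = stats.pearsonr(profile1.llr, profile2.llr)
    return float(r), float(p)
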