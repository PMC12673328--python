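"""Local ancestry inference for haploid genomes under a one-pulse admixture HMM.

Two hidden states — ancestry A (EUR) and ancestry B (AFR) — evolve along each
chromosome as a Markov chain whose switch rate reflects t generations of
recombination since a single admixture pulse of fraction m:

    P(i -> j | d) = exp(-t d) * 1[i = j] + (1 - exp(-t d)) * m_j,

with d the inter-marker distance in Morgans and (m_A, m_B) = (m, 1 - m).
Tract lengths therefore decay exponentially at rate t per Morgan and re-entry
is proportional to the genome-wide ancestry fractions; drift corrections via
the effective size Ne are omitted, which is negligible for Ne = 100,000 at
t <= ~125.  Chromosomes are independent chains re-initialised at (m, 1 - m).

Emissions are called haploid genotypes: the panel allele frequency is the
plug-in estimate with a 0.5 pseudocount, f = (alt + 0.5) / (total + 1), and a
symmetric per-allele error epsilon gives P(obs = 1 | k) = f(1-e) + (1-f)e.
Missing genotypes are uninformative (likelihood 1 under both states).

Ancestry-informative markers (AIMs) are selected greedily left-to-right with
a minimum parental frequency difference and minimum bp/cM spacing, matching
the accumulate-distance-from-last-emitted-site behaviour of vcf2ahmm.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .io_formats import MISSING, ObservationTable, RecombinationMap

DEFAULT_EPSILON = 0.01
DEFAULT_NE = 100_000.0
_Q_CLAMP = 1e-6


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AIMPanel:
    """Ancestry-informative marker set with parental allele counts.

    Arrays are per site and grouped by chromosome in genome order:
    ``counts_a``/``counts_b`` hold (ref, alt) haploid allele counts for the
    two parental panels; ``cm`` is the genetic position.
    """

    chrom: np.ndarray
    pos: np.ndarray
    cm: np.ndarray
    counts_a: np.ndarray
    counts_b: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=float)
        self.counts_a = np.asarray(self.counts_a, dtype=np.int64)
        self.counts_b = np.asarray(self.counts_b, dtype=np.int64)

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Contiguous (chromosome, slice) runs in storage order."""
        out = []
        chrom = np.asarray(self.chrom, dtype=object)
        start = 0
        for i in range(1, chrom.size + 1):
            if i == chrom.size or chrom[i] != chrom[start]:
                out.append((str(chrom[start]), slice(start, i)))
                start = i
        return out

    def frequencies(self, pseudocount: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
        """Panel alt-allele frequencies with the emission pseudocount."""
        tot_a = self.counts_a.sum(axis=1)
        tot_b = self.counts_b.sum(axis=1)
        fa = (self.counts_a[:, 1] + pseudocount) / (tot_a + 2 * pseudocount)
        fb = (self.counts_b[:, 1] + pseudocount) / (tot_b + 2 * pseudocount)
        return fa, fb

    def distances_morgans(self) -> np.ndarray:
        """Inter-site distance in Morgans, 0 at each chromosome's first site."""
        d = np.zeros(self.n_sites)
        for _, sl in self.chrom_slices():
            d[sl][1:] = np.diff(self.cm[sl]) / 100.0
        return d

    def subset(self, index: np.ndarray) -> "AIMPanel":
        return AIMPanel(np.asarray(self.chrom, dtype=object)[index],
                        self.pos[index], self.cm[index],
                        self.counts_a[index], self.counts_b[index])

    @classmethod
    def from_observations(cls, obs: ObservationTable,
                          recmap: RecombinationMap | None = None) -> "AIMPanel":
        """Build a panel from an observation table, recovering cM positions
        from the stored inter-site Morgan distances (or a map if given)."""
        if recmap is not None:
            cm = np.concatenate([
                np.asarray(recmap.genetic_position(c, obs.pos[sl]), dtype=float)
                for c, sl in cls(obs.chrom, obs.pos, np.zeros(obs.n_sites),
                                 obs.panel_a, obs.panel_b).chrom_slices()])
        else:
            cm = np.zeros(obs.n_sites)
            tmp = cls(obs.chrom, obs.pos, cm, obs.panel_a, obs.panel_b)
            for _, sl in tmp.chrom_slices():
                cm[sl] = np.cumsum(obs.distance_morgans[sl]) * 100.0
        return cls(obs.chrom, obs.pos, cm, obs.panel_a, obs.panel_b)


@dataclasses.dataclass
class AdmixtureModel:
    """One-pulse admixture parameters: t generations since the pulse,
    genome-wide fraction m of ancestry A (EUR), and a fixed effective size."""

    t: float
    m: float
    Ne: float = DEFAULT_NE

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError("t must be positive")
        if not 0.0 < self.m < 1.0:
            raise ValueError("m must be in (0, 1)")
        if self.Ne <= 0:
            raise ValueError("Ne must be positive")


@dataclasses.dataclass
class PosteriorMatrix:
    """Per-sample, per-site posterior probability of ancestry A, with the
    per-sample total log-likelihood."""

    prob_a: np.ndarray       # (n_samples, n_sites)
    loglik: np.ndarray       # (n_samples,)

    @property
    def total_loglik(self) -> float:
        return float(self.loglik.sum())

    def mean_ancestry_a(self) -> float:
        return float(self.prob_a.mean())


# ---------------------------------------------------------------------------
# AIM selection
# ---------------------------------------------------------------------------

def select_aims(counts_a: np.ndarray, counts_b: np.ndarray,
                chrom: np.ndarray, pos: np.ndarray,
                recmap: RecombinationMap,
                min_diff: float = 0.10, min_bp: int = 2500,
                min_cm: float = 0.01) -> AIMPanel:
    """Greedy left-to-right AIM selection.

    A site is kept iff the absolute parental allele-frequency difference is
    >= ``min_diff`` and it lies at least ``min_bp`` bp *and* ``min_cm`` cM
    beyond the last retained site on its chromosome.
    """
    counts_a = np.asarray(counts_a, dtype=np.int64)
    counts_b = np.asarray(counts_b, dtype=np.int64)
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    if np.any(counts_a.sum(axis=1) < 1) or np.any(counts_b.sum(axis=1) < 1):
        raise ValueError("every site needs at least one called allele per panel")
    fa = counts_a[:, 1] / counts_a.sum(axis=1)
    fb = counts_b[:, 1] / counts_b.sum(axis=1)
    informative = np.abs(fa - fb) >= min_diff

    keep = np.zeros(pos.size, dtype=bool)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        cm = np.asarray(recmap.genetic_position(str(c), pos[idx]), dtype=float)
        last_bp = -np.inf
        last_cm = -np.inf
        for k, i in enumerate(idx):
            if not informative[i]:
                continue
            if pos[i] - last_bp >= min_bp and cm[k] - last_cm >= min_cm:
                keep[i] = True
                last_bp = pos[i]
                last_cm = cm[k]
        if not keep[idx].any():
            warnings.warn(f"no AIMs retained on chromosome {c}")
    sel = np.flatnonzero(keep)
    cm_all = np.concatenate([
        np.asarray(recmap.genetic_position(str(c), pos[sel][chrom[sel] == c]),
                   dtype=float)
        for c in pd.unique(chrom[sel])]) if sel.size else np.empty(0)
    return AIMPanel(chrom[sel], pos[sel], cm_all, counts_a[sel], counts_b[sel])


# ---------------------------------------------------------------------------
# HMM components
# ---------------------------------------------------------------------------

def transition_matrix(model: AdmixtureModel, delta_d: float) -> np.ndarray:
    """2x2 transition matrix over ``delta_d`` Morgans."""
    if delta_d < 0:
        raise ValueError("genetic distance must be non-negative")
    e = np.exp(-model.t * delta_d)
    stat = np.array([model.m, 1.0 - model.m])
    return e * np.eye(2) + (1.0 - e) * stat[None, :]


def emission_loglik(observed: int, counts_k: Sequence[int],
                    epsilon: float = DEFAULT_EPSILON) -> float:
    """Log-probability of one observed allele under ancestry k's panel."""
    if not 0.0 <= epsilon < 0.5:
        raise ValueError("epsilon must be in [0, 0.5)")
    ref, alt = int(counts_k[0]), int(counts_k[1])
    if ref + alt == 0:
        raise ValueError("zero total panel count at site")
    if observed == MISSING:
        return 0.0
    f = (alt + 0.5) / (ref + alt + 1.0)
    p_alt = f * (1.0 - epsilon) + (1.0 - f) * epsilon
    return float(np.log(p_alt if observed == 1 else 1.0 - p_alt))


def emission_likelihoods(genotypes: np.ndarray, panel: AIMPanel,
                         epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Linear-space emission likelihoods, shape (n_samples, n_sites, 2).

    genotypes: (n_sites, n_samples) int8 with -1 missing.
    """
    fa, fb = panel.frequencies()
    p1 = np.stack([fa, fb], axis=1) * (1 - epsilon) \
        + (1 - np.stack([fa, fb], axis=1)) * epsilon   # (n_sites, 2)
    g = np.asarray(genotypes)
    n_sites, n_samples = g.shape
    out = np.ones((n_samples, n_sites, 2))
    gt = g.T  # (n_samples, n_sites)
    out[gt == 1] = np.broadcast_to(p1, (n_samples, n_sites, 2))[gt == 1]
    out[gt == 0] = np.broadcast_to(1 - p1, (n_samples, n_sites, 2))[gt == 0]
    return out


@njit(cache=True)
def _forward_loglik_kernel(emis, decay, q):  # pragma: no cover
    n_samples, n_sites, _ = emis.shape
    total = 0.0
    for s in range(n_samples):
        a0 = q[0] * emis[s, 0, 0]
        a1 = (1.0 - q[0]) * emis[s, 0, 1]
        c = a0 + a1
        total += np.log(c)
        a0 /= c
        a1 /= c
        for i in range(1, n_sites):
            e = decay[i]
            t0 = e * a0 + (1.0 - e) * q[i]
            t1 = e * a1 + (1.0 - e) * (1.0 - q[i])
            b0 = t0 * emis[s, i, 0]
            b1 = t1 * emis[s, i, 1]
            c = b0 + b1
            total += np.log(c)
            a0 = b0 / c
            a1 = b1 / c
    return total


@njit(cache=True)
def _forward_backward_kernel(emis, decay, q, post, loglik):  # pragma: no cover
    n_samples, n_sites, _ = emis.shape
    alpha = np.empty((n_sites, 2))
    beta = np.empty((n_sites, 2))
    for s in range(n_samples):
        ll = 0.0
        a0 = q[0] * emis[s, 0, 0]
        a1 = (1.0 - q[0]) * emis[s, 0, 1]
        c = a0 + a1
        ll += np.log(c)
        alpha[0, 0] = a0 / c
        alpha[0, 1] = a1 / c
        for i in range(1, n_sites):
            e = decay[i]
            t0 = e * alpha[i - 1, 0] + (1.0 - e) * q[i]
            t1 = e * alpha[i - 1, 1] + (1.0 - e) * (1.0 - q[i])
            b0 = t0 * emis[s, i, 0]
            b1 = t1 * emis[s, i, 1]
            c = b0 + b1
            ll += np.log(c)
            alpha[i, 0] = b0 / c
            alpha[i, 1] = b1 / c
        beta[n_sites - 1, 0] = 1.0
        beta[n_sites - 1, 1] = 1.0
        for i in range(n_sites - 2, -1, -1):
            e = decay[i + 1]
            eb0 = emis[s, i + 1, 0] * beta[i + 1, 0]
            eb1 = emis[s, i + 1, 1] * beta[i + 1, 1]
            mix = (1.0 - e) * (q[i + 1] * eb0 + (1.0 - q[i + 1]) * eb1)
            b0 = e * eb0 + mix
            b1 = e * eb1 + mix
            c = b0 + b1
            beta[i, 0] = b0 / c
            beta[i, 1] = b1 / c
        for i in range(n_sites):
            p0 = alpha[i, 0] * beta[i, 0]
            p1 = alpha[i, 1] * beta[i, 1]
            post[s, i] = p0 / (p0 + p1)
        loglik[s] = ll


@njit(cache=True)
def _viterbi_kernel(emis, decay, q, path, pathll):  # pragma: no cover
    n_samples, n_sites, _ = emis.shape
    d0 = np.empty(n_sites)
    d1 = np.empty(n_sites)
    ptr0 = np.empty(n_sites, dtype=np.int8)
    ptr1 = np.empty(n_sites, dtype=np.int8)
    for s in range(n_samples):
        d0[0] = np.log(q[0]) + np.log(emis[s, 0, 0])
        d1[0] = np.log(1.0 - q[0]) + np.log(emis[s, 0, 1])
        for i in range(1, n_sites):
            e = decay[i]
            p00 = np.log(e + (1.0 - e) * q[i])
            p01 = np.log((1.0 - e) * (1.0 - q[i]))
            p10 = np.log((1.0 - e) * q[i])
            p11 = np.log(e + (1.0 - e) * (1.0 - q[i]))
            from0 = d0[i - 1] + p00
            from1 = d1[i - 1] + p10
            if from0 >= from1:
                d0[i] = from0 + np.log(emis[s, i, 0])
                ptr0[i] = 0
            else:
                d0[i] = from1 + np.log(emis[s, i, 0])
                ptr0[i] = 1
            from0 = d0[i - 1] + p01
            from1 = d1[i - 1] + p11
            if from0 >= from1:
                d1[i] = from0 + np.log(emis[s, i, 1])
                ptr1[i] = 0
            else:
                d1[i] = from1 + np.log(emis[s, i, 1])
                ptr1[i] = 1
        if d0[n_sites - 1] >= d1[n_sites - 1]:
            state = 0
            pathll[s] = d0[n_sites - 1]
        else:
            state = 1
            pathll[s] = d1[n_sites - 1]
        path[s, n_sites - 1] = state
        for i in range(n_sites - 1, 0, -1):
            state = ptr0[i] if state == 0 else ptr1[i]
            path[s, i - 1] = state


def _stationary(panel: AIMPanel, model: AdmixtureModel) -> np.ndarray:
    return np.full(panel.n_sites, model.m)


def _decay(panel: AIMPanel, t: float) -> np.ndarray:
    return np.exp(-t * panel.distances_morgans())


def forward_backward(genotypes: np.ndarray, panel: AIMPanel,
                     model: AdmixtureModel,
                     epsilon: float = DEFAULT_EPSILON,
                     stationary: np.ndarray | None = None) -> PosteriorMatrix:
    """Exact posterior P(ancestry A) per sample and site, with per-sample
    total log-likelihood.  Chromosome boundaries reset the chain.

    ``stationary`` optionally overrides the per-site stationary ancestry-A
    fraction (used by the selection scan); default is m everywhere.
    """
    if genotypes.shape[0] != panel.n_sites:
        raise ValueError("observations not aligned to AIM panel")
    emis = emission_likelihoods(genotypes, panel, epsilon)
    q = np.clip(stationary if stationary is not None
                else _stationary(panel, model), _Q_CLAMP, 1 - _Q_CLAMP)
    decay = _decay(panel, model.t)
    n_samples = genotypes.shape[1]
    post = np.empty((n_samples, panel.n_sites))
    loglik = np.zeros(n_samples)
    for _, sl in panel.chrom_slices():
        ll = np.empty(n_samples)
        _forward_backward_kernel(np.ascontiguousarray(emis[:, sl, :]),
                                 np.ascontiguousarray(decay[sl]),
                                 np.ascontiguousarray(q[sl]),
                                 post[:, sl], ll)
        loglik += ll
    return PosteriorMatrix(post, loglik)


def total_loglik(genotypes: np.ndarray, panel: AIMPanel, model: AdmixtureModel,
                 epsilon: float = DEFAULT_EPSILON,
                 stationary: np.ndarray | None = None) -> float:
    """Summed forward log-likelihood over samples (no posterior storage)."""
    emis = emission_likelihoods(genotypes, panel, epsilon)
    q = np.clip(stationary if stationary is not None
                else _stationary(panel, model), _Q_CLAMP, 1 - _Q_CLAMP)
    decay = _decay(panel, model.t)
    out = 0.0
    for _, sl in panel.chrom_slices():
        out += _forward_loglik_kernel(np.ascontiguousarray(emis[:, sl, :]),
                                      np.ascontiguousarray(decay[sl]),
                                      np.ascontiguousarray(q[sl]))
    return float(out)


def viterbi(genotypes: np.ndarray, panel: AIMPanel, model: AdmixtureModel,
            epsilon: float = DEFAULT_EPSILON) -> tuple[np.ndarray, np.ndarray]:
    """Most probable ancestry path per sample.

    Returns (paths, path_loglik): paths is (n_samples, n_sites) of state
    indices (0 = ancestry A), path_loglik the per-sample joint log-probability
    of the best path (summed over chromosomes).
    """
    emis = emission_likelihoods(genotypes, panel, epsilon)
    q = np.clip(_stationary(panel, model), _Q_CLAMP, 1 - _Q_CLAMP)
    decay = _decay(panel, model.t)
    n_samples = genotypes.shape[1]
    paths = np.empty((n_samples, panel.n_sites), dtype=np.int8)
    pathll = np.zeros(n_samples)
    for _, sl in panel.chrom_slices():
        ll = np.empty(n_samples)
        _viterbi_kernel(np.ascontiguousarray(emis[:, sl, :]),
                        np.ascontiguousarray(decay[sl]),
                        np.ascontiguousarray(q[sl]),
                        paths[:, sl], ll)
        pathll += ll
    return paths, pathll


def viterbi_tracts(paths: np.ndarray, panel: AIMPanel,
                   samples: Sequence[str] | None = None,
                   chrom_lengths_bp: dict[str, int] | None = None) -> pd.DataFrame:
    """Convert Viterbi state paths into bp-interval ancestry tracts.

    Tract boundaries fall at the midpoint between adjacent AIMs of differing
    state; terminal tracts extend to the chromosome ends (position 0 and the
    chromosome length when provided, else the last AIM position).
    Returns a tidy frame (sample, chrom, start, end, ancestry), 0-based
    half-open.
    """
    n_samples = paths.shape[0]
    names = list(samples) if samples is not None else [
        f"sample{i}" for i in range(n_samples)]
    rows = []
    for chrom, sl in panel.chrom_slices():
        pos = panel.pos[sl]
        end_bp = (chrom_lengths_bp or {}).get(chrom, int(pos[-1]))
        for s in range(n_samples):
            p = paths[s, sl]
            switch = np.flatnonzero(p[1:] != p[:-1])
            bounds = [0] + [int((pos[i] + pos[i + 1]) // 2) for i in switch] \
                + [end_bp]
            states = np.concatenate((p[switch], p[-1:]))
            for k, st in enumerate(states):
                rows.append((names[s], chrom, bounds[k], bounds[k + 1], int(st)))
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                       "ancestry"])


# ---------------------------------------------------------------------------
# Parameter estimation
# ---------------------------------------------------------------------------

def _golden_section_max(f, lo: float, hi: float, tol: float) -> tuple[float, float]:
    """Golden-section maximization of a unimodal f on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (c, fc) if fc >= fd else (d, fd)


def fit_admixture(genotypes: np.ndarray, panel: AIMPanel,
                  t_bounds: tuple[float, float] = (1.0, 500.0),
                  m_init: float = 0.5, t_init: float = 100.0,
                  epsilon: float = DEFAULT_EPSILON,
                  m_tol: float = 1e-4, max_iter: int = 50,
                  t_tol: float = 0.5, Ne: float = DEFAULT_NE,
                  ) -> tuple[AdmixtureModel, PosteriorMatrix]:
    """Two-stage fit of the one-pulse admixture model.

    Stage 1 starts at (t_init, m_init) and repeatedly replaces m with the
    mean posterior ancestry-A fraction over all samples and sites until the
    update is below ``m_tol``; stage 2 maximizes the summed log-likelihood
    over t by golden-section search at the fixed m, after which the m
    iteration is repeated at the fitted t so that the returned m equals the
    mean posterior ancestry under the returned model (further runs do not
    move the estimate).  Returns the fitted model and that posterior matrix.
    """
    if genotypes.shape[1] < 1:
        raise ValueError("need at least one sample")

    def iterate_m(m: float, t: float) -> tuple[float, PosteriorMatrix]:
        for _ in range(max_iter):
            post = forward_backward(genotypes, panel,
                                    AdmixtureModel(t, m, Ne), epsilon)
            m_new = float(np.clip(post.mean_ancestry_a(), 1e-3, 1 - 1e-3))
            if abs(m_new - m) < m_tol:
                return m_new, post
            m = m_new
        raise RuntimeError("admixture-fraction iteration did not converge")

    m, _ = iterate_m(float(m_init), t_init)

    def objective(t: float) -> float:
        return total_loglik(genotypes, panel, AdmixtureModel(t, m, Ne), epsilon)

    t_hat, _ = _golden_section_max(objective, t_bounds[0], t_bounds[1], t_tol)
    m, post = iterate_m(m, t_hat)
    return AdmixtureModel(t_hat, m, Ne), post


def bootstrap_t(genotypes: np.ndarray, panel: AIMPanel, model: AdmixtureModel,
                window: int = 200, B: int = 1000, seed: int = 0,
                t_bounds: tuple[float, float] = (1.0, 500.0),
                t_tol: float = 0.5, epsilon: float = DEFAULT_EPSILON,
                resample: bool = True) -> dict[str, np.ndarray]:
    """Block bootstrap of the admixture-time estimate.

    Each chromosome is cut into non-overlapping windows of ``window``
    contiguous AIMs (tail sites beyond the last full window are dropped);
    each replicate resamples that many windows with replacement and refits t
    at fixed m, treating each window as an independent chain.  With
    ``resample=False`` the original window sequence is refit B times
    (identity resample), which reproduces the windowed point estimate.
    Chromosomes with fewer than ``window`` AIMs are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    emis_all = emission_likelihoods(genotypes, panel, epsilon)
    out: dict[str, np.ndarray] = {}
    for chrom, sl in panel.chrom_slices():
        n = sl.stop - sl.start
        if n < window:
            warnings.warn(f"chromosome {chrom} shorter than one bootstrap window")
            continue
        n_win = n // window
        dist = panel.distances_morgans()[sl]
        emis = emis_all[:, sl, :]
        windows = [(w * window, (w + 1) * window) for w in range(n_win)]

        def fit_once(chosen: np.ndarray) -> float:
            def objective(t: float) -> float:
                ll = 0.0
                for w in chosen:
                    lo, hi = windows[w]
                    d = dist[lo:hi].copy()
                    d[0] = 0.0  # each window is its own chain
                    ll += _forward_loglik_kernel(
                        np.ascontiguousarray(emis[:, lo:hi, :]),
                        np.exp(-t * d),
                        np.full(window, np.clip(model.m, _Q_CLAMP, 1 - _Q_CLAMP)))
                return ll
            return _golden_section_max(objective, t_bounds[0], t_bounds[1],
                                       t_tol)[0]

        ests = np.empty(B)
        for b in range(B):
            chosen = (rng.integers(0, n_win, n_win) if resample
                      else np.arange(n_win))
            ests[b] = fit_once(chosen)
        out[chrom] = ests
    return out


def generations_per_year(t: float, start_year: int = 1957,
                         end_year: int = 2015) -> float:
    """Generations per year over the admixture span, rounded to 2 decimals."""
    if end_year <= start_year:
        raise ValueError("end_year must exceed start_year")
    return round(t / (end_year - start_year), 2)
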