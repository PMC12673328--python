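"""Likelihood-ratio scan for ancestry-specific selection (AHMM-S style).

For each ancestry-informative marker and each favored ancestry, the scan
compares the neutral one-pulse HMM with a model in which viability selection
of strength s has acted at the focal site since admixture.  Selection distorts
the expected local ancestry around the focal site: the favored-ancestry
frequency at the site follows the haploid selection recursion

    p_{g+1} = p_g (1 + s) / (1 + p_g s),

and a linked marker at recombination fraction r per generation carries the
favored ancestry with expected frequency q̄(r) obtained by tracking the marker
ancestry separately on the selected background (q_C, initialised 1) and the
unselected background (q_N, initialised 0), mixing the two at rate r each
generation.  The HMM likelihood under the hypothesis replaces the stationary
ancestry fraction m — in both the transition re-entry terms and the initial
distribution — with the position-specific q̄, keeping the switch rate t; at
s = 0 this reduces exactly to the neutral model.

The reported statistic is Λ = 2 (max_s ℓ(s) − ℓ(0)), floored at 0 and
compared to χ²₁ quantiles; ŝ is found by golden-section search over
s ∈ [0.001, 0.5].  Chromosomes are scanned separately, so each hypothesis'
likelihood is over the focal chromosome's markers and all samples.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .local_ancestry_hmm import (AIMPanel, AdmixtureModel, DEFAULT_EPSILON,
                                 _Q_CLAMP, _forward_loglik_kernel,
                                 _golden_section_max, emission_likelihoods)

EUR = 0
AFR = 1
_DIRECTION_NAMES = {EUR: "EUR", AFR: "AFR"}

S_MIN = 0.001
S_MAX = 0.5


@dataclasses.dataclass(frozen=True)
class SelectionHypothesis:
    """One focal AIM, one favored ancestry, one selection coefficient."""

    focal_index: int
    favored: int           # 0 = ancestry A (EUR), 1 = ancestry B (AFR)
    s: float

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be non-negative")
        if self.favored not in (EUR, AFR):
            raise ValueError("favored ancestry must be 0 (A/EUR) or 1 (B/AFR)")


@dataclasses.dataclass
class LLRProfile:
    """Per-AIM selection likelihood-ratio statistics for one favored ancestry."""

    chrom: np.ndarray
    pos: np.ndarray
    cm: np.ndarray
    aim_index: np.ndarray      # indices into the scanned AIMPanel
    llr: np.ndarray            # Λ = 2(ℓ(ŝ) − ℓ(0)), floored at 0
    s_hat: np.ndarray
    favored: int

    @property
    def direction(self) -> str:
        return _DIRECTION_NAMES[self.favored]

    @property
    def n_sites(self) -> int:
        return int(self.llr.size)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "chrom": self.chrom, "pos": self.pos, "cm": self.cm,
            "aim_index": self.aim_index, "direction": self.direction,
            "s_hat": self.s_hat, "llr": self.llr})


# ---------------------------------------------------------------------------
# Forward iteration of the selected-site and linked-marker trajectories
# ---------------------------------------------------------------------------

def selected_trajectory(p0: float, s: float, t: int) -> np.ndarray:
    """Favored-ancestry frequency at the selected site, generations 0..t,
    under the haploid selection recursion."""
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    out = np.empty(t + 1)
    out[0] = p0
    p = p0
    for g in range(t):
        p = p * (1.0 + s) / (1.0 + p * s)
        out[g + 1] = p
    return out


def linked_expected_ancestry(p0: float, s: float, t: int, r) -> np.ndarray | float:
    """Expected favored-ancestry frequency after t generations at a marker
    linked to the selected site at recombination fraction ``r`` (scalar or
    array).  r = 0 returns the selected-site trajectory endpoint; s = 0
    returns p0 for any r."""
    r_arr = np.asarray(r, dtype=float)
    if np.any((r_arr < 0) | (r_arr > 0.5)):
        raise ValueError("recombination fraction must be in [0, 0.5]")
    q_c = np.ones_like(r_arr)
    q_n = np.zeros_like(r_arr)
    p = float(p0)
    for _ in range(int(t)):
        qbar = p * q_c + (1.0 - p) * q_n
        q_c += r_arr * (qbar - q_c)
        q_n += r_arr * (qbar - q_n)
        p = p * (1.0 + s) / (1.0 + p * s)
    out = p * q_c + (1.0 - p) * q_n
    return float(out) if np.isscalar(r) else out


def haldane_r(d_morgans) -> np.ndarray | float:
    """Map genetic distance (Morgans) to recombination fraction per meiosis."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_morgans, dtype=float)))


def golden_section_max(f, lo: float = S_MIN, hi: float = S_MAX,
                       tol: float = 1e-3) -> tuple[float, float]:
    """Golden-section maximization of a unimodal function on [lo, hi];
    returns the best evaluated point and its value."""
    if not lo < hi:
        raise ValueError("lo must be less than hi")
    return _golden_section_max(f, lo, hi, tol)


# ---------------------------------------------------------------------------
# Site likelihood under selection
# ---------------------------------------------------------------------------

def _stationary_under_selection(panel_cm: np.ndarray, focal_cm: float,
                                p0: float, s: float, t: float,
                                favored: int) -> np.ndarray:
    """Per-site stationary ancestry-A fraction under the hypothesis."""
    d = np.abs(panel_cm - focal_cm) / 100.0
    qbar = linked_expected_ancestry(p0, s, int(round(t)), haldane_r(d))
    q_a = qbar if favored == EUR else 1.0 - qbar
    return np.clip(q_a, _Q_CLAMP, 1.0 - _Q_CLAMP)


def site_loglik(genotypes: np.ndarray, panel: AIMPanel, model: AdmixtureModel,
                hypothesis: SelectionHypothesis,
                epsilon: float = DEFAULT_EPSILON) -> float:
    """HMM log-likelihood of the focal chromosome under the hypothesis.

    The focal index addresses ``panel``; only AIMs on the focal site's
    chromosome enter the likelihood (each chromosome is scanned separately),
    summed over samples.  At s = 0 the value equals the neutral forward
    likelihood of that chromosome.
    """
    if not 0 <= hypothesis.focal_index < panel.n_sites:
        raise IndexError("focal index outside the AIM panel")
    chrom = np.asarray(panel.chrom, dtype=object)
    focal_chrom = chrom[hypothesis.focal_index]
    sl = next(s for c, s in panel.chrom_slices() if c == str(focal_chrom))
    sub = panel.subset(np.arange(sl.start, sl.stop))
    emis = emission_likelihoods(genotypes[sl, :], sub, epsilon)
    decay = np.exp(-model.t * sub.distances_morgans())
    p0 = model.m if hypothesis.favored == EUR else 1.0 - model.m
    q = _stationary_under_selection(
        sub.cm, float(panel.cm[hypothesis.focal_index]),
        p0, hypothesis.s, model.t, hypothesis.favored)
    return float(_forward_loglik_kernel(np.ascontiguousarray(emis),
                                        np.ascontiguousarray(decay),
                                        np.ascontiguousarray(q)))


# ---------------------------------------------------------------------------
# Genome scan
# ---------------------------------------------------------------------------

def scan(genotypes: np.ndarray, panel: AIMPanel, model: AdmixtureModel,
         favored: int, stride: int = 1,
         s_bounds: tuple[float, float] = (S_MIN, S_MAX),
         s_tol: float = 1e-3,
         epsilon: float = DEFAULT_EPSILON) -> LLRProfile:
    """Scan every ``stride``-th AIM for selection favoring one ancestry.

    For each focal site, ŝ maximizes the selection likelihood by
    golden-section search and Λ = 2 (ℓ(ŝ) − ℓ(0)) is floored at 0.  Swapping
    ``favored`` swaps the roles of the two ancestries.
    """
    chroms: list = []
    positions: list = []
    cms: list = []
    indices: list = []
    llrs: list = []
    s_hats: list = []
    p0 = model.m if favored == EUR else 1.0 - model.m
    t_int = int(round(model.t))
    for chrom, sl in panel.chrom_slices():
        sub = panel.subset(np.arange(sl.start, sl.stop))
        emis = np.ascontiguousarray(
            emission_likelihoods(genotypes[sl, :], sub, epsilon))
        decay = np.ascontiguousarray(np.exp(-model.t * sub.distances_morgans()))
        cm = sub.cm
        neutral_q = np.full(cm.size, np.clip(model.m, _Q_CLAMP, 1 - _Q_CLAMP))
        ll0 = _forward_loglik_kernel(emis, decay, neutral_q)

        def loglik_at(focal_cm: float, s: float) -> float:
            r = haldane_r(np.abs(cm - focal_cm) / 100.0)
            qbar = linked_expected_ancestry(p0, s, t_int, r)
            q_a = qbar if favored == EUR else 1.0 - qbar
            q_a = np.clip(q_a, _Q_CLAMP, 1.0 - _Q_CLAMP)
            return _forward_loglik_kernel(emis, decay, np.ascontiguousarray(q_a))

        for j in range(0, cm.size, stride):
            focal = float(cm[j])
            s_hat, ll_s = _golden_section_max(
                lambda s: loglik_at(focal, s), s_bounds[0], s_bounds[1], s_tol)
            llr = max(0.0, 2.0 * (ll_s - ll0))
            chroms.append(chrom)
            positions.append(int(sub.pos[j]))
            cms.append(focal)
            indices.append(sl.start + j)
            llrs.append(llr)
            s_hats.append(s_hat)
    return LLRProfile(np.array(chroms, dtype=object),
                      np.array(positions, dtype=np.int64),
                      np.array(cms, dtype=float),
                      np.array(indices, dtype=np.int64),
                      np.array(llrs, dtype=float),
                      np.array(s_hats, dtype=float), favored)


def scan_both_directions(genotypes: np.ndarray, panel: AIMPanel,
                         model: AdmixtureModel, stride: int = 1,
                         **kwargs) -> dict[int, LLRProfile]:
    """Run the scan for both favored ancestries (EUR and AFR)."""
    return {d: scan(genotypes, panel, model, d, stride=stride, **kwargs)
            for d in (EUR, AFR)}
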