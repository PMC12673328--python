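"""Forward-in-time, tract-tracking admixture simulator.

Simulates a Wright-Fisher population of chromosome copies under a one- or
two-pulse admixture demography with bottlenecks and optional ancestry-specific
viability selection, recording ancestry tracts exactly (continuous genetic
coordinates, no marker grid).  It is the neutral-calibration engine for the
selection scan and the ground-truth source for HMM parameter-recovery tests.

Model
-----
* Reproduction is copy-level Wright-Fisher: each offspring chromosome copy is
  a recombinant of two uniformly (or fitness-weighted) chosen parent copies.
* Crossovers are Poisson with mean equal to the chromosome length in Morgans
  (no interference), positions uniform in genetic distance.
* A pulse at generation g replaces the stated fraction of the generation-g
  copies with unadmixed donor genomes; a resize at generation g sets the
  diploid population size of generation g.
* Selection is haploid multiplicative viability: copies carrying the favored
  ancestry at the focal position are chosen as parents with weight (1+s).

The bottleneck "to four admixed individuals, representing a single mated
queen" is modeled as 4 diploids = 8 chromosome copies; there is no explicit
queen/drone mating structure or haplodiploid sex determination — copy-level
reproduction preserves the lineage count and drift magnitude, which is what
the calibration needs.

Ancestry labels are small integers (0 = EUR/panel A, 1 = AFR/panel B by
convention).  With ``trace_lineages=True`` every founding copy and every
pulse genome receives a unique label instead, which lets tests count distinct
parental lineages surviving a bottleneck.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from numba import njit

EUR = 0
AFR = 1

_LABEL_DTYPE = np.int32


# ---------------------------------------------------------------------------
# Tract container
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HaploidTracts:
    """Ancestry tracts of one haploid genome.

    ``junctions[c]`` holds the internal ancestry-switch positions (cM,
    strictly increasing, open interval (0, L)); ``labels[c]`` the per-tract
    ancestry labels (length = junction count + 1, adjacent labels differ);
    ``lengths_cm[c]`` the chromosome length.
    """

    sample_id: str
    junctions: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]
    lengths_cm: dict[str, float]

    def validate(self) -> None:
        for c, j in self.junctions.items():
            lab = self.labels[c]
            L = self.lengths_cm[c]
            if lab.size != j.size + 1:
                raise ValueError(f"{c}: labels/junctions size mismatch")
            if j.size and (j[0] <= 0 or j[-1] >= L or np.any(np.diff(j) <= 0)):
                raise ValueError(f"{c}: junctions not strictly inside (0, L)")
            if np.any(lab[1:] == lab[:-1]):
                raise ValueError(f"{c}: adjacent tracts share ancestry")

    def tracts(self, chrom: str) -> list[tuple[float, float, int]]:
        """(start cM, end cM, label) covering [0, L]."""
        j = self.junctions[chrom]
        bounds = np.concatenate(([0.0], j, [self.lengths_cm[chrom]]))
        return [(float(bounds[i]), float(bounds[i + 1]), int(self.labels[chrom][i]))
                for i in range(self.labels[chrom].size)]

    def ancestry_at(self, chrom: str, cm) -> np.ndarray:
        """Ancestry label at genetic position(s) ``cm`` on ``chrom``."""
        idx = np.searchsorted(self.junctions[chrom], np.asarray(cm, float),
                              side="right")
        return self.labels[chrom][idx]

    def ancestry_at_sites(self, site_chrom: np.ndarray,
                          site_cm: np.ndarray) -> np.ndarray:
        out = np.empty(len(site_cm), dtype=_LABEL_DTYPE)
        site_chrom = np.asarray(site_chrom, dtype=object)
        for c in self.junctions:
            mask = site_chrom == c
            if mask.any():
                out[mask] = self.ancestry_at(c, np.asarray(site_cm, float)[mask])
        return out

    def junction_count(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self.junctions[chrom].size)
        return int(sum(j.size for j in self.junctions.values()))


def junction_count(tracts: HaploidTracts, chrom: str | None = None) -> int:
    """Number of ancestry switches; grows with generations since admixture."""
    return tracts.junction_count(chrom)


def tracts_to_frame(tract_sets: Sequence[HaploidTracts], recmap=None):
    """Flatten tract sets to a tidy table (chrom, start/end in cM — and bp if
    a RecombinationMap is given — ancestry, sample)."""
    import pandas as pd

    rows = []
    for ts in tract_sets:
        for chrom in ts.junctions:
            for start, end, lab in ts.tracts(chrom):
                rows.append((chrom, start, end, int(lab), ts.sample_id))
    df = pd.DataFrame(rows, columns=["chrom", "start_cm", "end_cm",
                                     "ancestry", "sample"])
    if recmap is not None:
        bp_cols = {"start_bp": [], "end_bp": []}
        for _, r in df.iterrows():
            bp, cm = recmap._anchors[r["chrom"]]
            bp_cols["start_bp"].append(int(round(np.interp(r["start_cm"], cm, bp))))
            bp_cols["end_bp"].append(int(round(np.interp(r["end_cm"], cm, bp))))
        df = df.assign(**bp_cols)
    return df


# ---------------------------------------------------------------------------
# Demography
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DemographicEvent:
    """A pulse (fraction of copies replaced by donor genomes) or a resize
    (new diploid population size) at a given generation."""

    generation: int
    kind: str                 # "pulse" | "resize"
    value: float              # pulse fraction in (0, 1] or new diploid size
    donor: int = EUR          # ancestry label introduced by a pulse

    def __post_init__(self) -> None:
        if self.kind not in ("pulse", "resize"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "pulse" and not 0.0 < self.value <= 1.0:
            raise ValueError("pulse fraction must be in (0, 1]")
        if self.kind == "resize" and self.value < 1:
            raise ValueError("population size must be >= 1")


@dataclasses.dataclass(frozen=True)
class Demography:
    """Event schedule for a single admixed population.

    Events are applied in list order; generations must be non-decreasing so a
    bottleneck and a pulse can share a generation (bottleneck first).
    """

    initial_size: int
    generations: int
    events: tuple[DemographicEvent, ...]
    founder_label: int = AFR

    def __post_init__(self) -> None:
        gens = [e.generation for e in self.events]
        if any(b < a for a, b in zip(gens, gens[1:])):
            raise ValueError("event generations must be non-decreasing")
        if gens and (gens[0] < 0 or gens[-1] > self.generations):
            raise ValueError("event outside [0, generations]")

    def sizes(self) -> np.ndarray:
        """Diploid size of each generation 0..G."""
        out = np.full(self.generations + 1, self.initial_size, dtype=np.int64)
        for e in self.events:
            if e.kind == "resize":
                out[e.generation:] = int(e.value)
        return out

    @classmethod
    def one_pulse(cls, m: float, t: int, size: int = 1000,
                  donor: int = EUR, founder: int = AFR) -> "Demography":
        """Single admixture pulse of fraction ``m`` donor ancestry at
        generation 0, then ``t`` generations of random mating."""
        return cls(size, t, (DemographicEvent(0, "pulse", m, donor),),
                   founder_label=founder)

    @classmethod
    def puerto_rico_neutral(cls, pre_bottleneck_size: int = 1000) -> "Demography":
        """The neutral calibration scenario: an AFR population receives a
        0.3 EUR pulse, mates randomly for 100 generations, collapses to four
        admixed diploids (a single mated queen), receives a 0.5 EUR pulse
        from the resident European population, and recovers to 1,000
        diploids for 50 generations (G = 150)."""
        return cls(pre_bottleneck_size, 150, (
            DemographicEvent(0, "pulse", 0.3, EUR),
            DemographicEvent(100, "resize", 4),
            DemographicEvent(100, "pulse", 0.5, EUR),
            DemographicEvent(101, "resize", 1000),
        ), founder_label=AFR)


@dataclasses.dataclass(frozen=True)
class SelectionSpec:
    """Haploid viability selection favoring one ancestry at one position."""

    chrom: str
    position_cm: float
    favored: int
    s: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 0.5:
            raise ValueError("selection coefficient must be in [0, 0.5]")


# ---------------------------------------------------------------------------
# Numba kernels over the flat tract representation
#
# A generation of n copies is stored as:
#   junc : float64[:]  all internal junction positions, concatenated
#   lab  : int32[:]    all per-tract labels, concatenated
#   joff : int64[n+1]  junction offsets; copy i's labels live at
#                      lab[joff[i] + i : joff[i+1] + i + 1]
# ---------------------------------------------------------------------------

@njit(cache=True)
def _reproduce_kernel(junc, lab, joff, p1, p2, xpos, xoff, L,
                      out_junc, out_lab, out_joff):  # pragma: no cover
    pos = 0
    for o in range(p1.size):
        out_joff[o] = pos
        lpos = pos + o
        k0 = xoff[o]
        k1 = xoff[o + 1]
        nseg = (k1 - k0) + 1
        cur = -1
        a = 0.0
        for seg in range(nseg):
            b = L if seg == nseg - 1 else xpos[k0 + seg]
            src = p1[o] if (seg & 1) == 0 else p2[o]
            j0 = joff[src]
            j1 = joff[src + 1]
            l0 = j0 + src
            lo = j0 + np.searchsorted(junc[j0:j1], a, side="right")
            hi = j0 + np.searchsorted(junc[j0:j1], b, side="left")
            lab0 = lab[l0 + (lo - j0)]
            if seg == 0:
                out_lab[lpos] = lab0
                lpos += 1
                cur = lab0
            elif lab0 != cur:
                out_junc[pos] = a
                pos += 1
                out_lab[lpos] = lab0
                lpos += 1
                cur = lab0
            for t in range(lo, hi):
                out_junc[pos] = junc[t]
                pos += 1
                nl = lab[l0 + (t - j0) + 1]
                out_lab[lpos] = nl
                lpos += 1
                cur = nl
            a = b
    out_joff[p1.size] = pos


@njit(cache=True)
def _labels_at_kernel(junc, lab, joff, x, out):  # pragma: no cover
    for i in range(joff.size - 1):
        j0 = joff[i]
        j1 = joff[i + 1]
        idx = np.searchsorted(junc[j0:j1], x, side="right")
        out[i] = lab[j0 + i + idx]


class _ChromState:
    """Flat tract arrays for all copies of one chromosome."""

    __slots__ = ("junc", "lab", "joff", "length_cm")

    def __init__(self, junc, lab, joff, length_cm):
        self.junc = junc
        self.lab = lab
        self.joff = joff
        self.length_cm = float(length_cm)

    @classmethod
    def founded(cls, labels: np.ndarray, length_cm: float) -> "_ChromState":
        n = labels.size
        return cls(np.empty(0, dtype=np.float64),
                   labels.astype(_LABEL_DTYPE),
                   np.zeros(n + 1, dtype=np.int64), length_cm)

    @property
    def n_copies(self) -> int:
        return self.joff.size - 1

    def labels_at(self, x: float) -> np.ndarray:
        out = np.empty(self.n_copies, dtype=_LABEL_DTYPE)
        _labels_at_kernel(self.junc, self.lab, self.joff, float(x), out)
        return out

    def copy_tracts(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        j0, j1 = self.joff[i], self.joff[i + 1]
        return (self.junc[j0:j1].copy(),
                self.lab[j0 + i:j1 + i + 1].copy())

    def replace_with_pure(self, idx: np.ndarray, labels: np.ndarray) -> "_ChromState":
        """Replace the copies at ``idx`` with single-tract genomes."""
        n = self.n_copies
        keep_junc = []
        new_joff = np.zeros(n + 1, dtype=np.int64)
        new_lab = np.empty(0, dtype=_LABEL_DTYPE)
        labs = []
        pure = np.zeros(n, dtype=bool)
        pure[idx] = True
        new_label = np.empty(n, dtype=_LABEL_DTYPE)
        new_label[idx] = labels
        pos = 0
        for i in range(n):
            if pure[i]:
                labs.append(new_label[i:i + 1].astype(_LABEL_DTYPE))
            else:
                j, l = self.copy_tracts(i)
                keep_junc.append(j)
                labs.append(l)
                pos += j.size
            new_joff[i + 1] = pos
        junc = (np.concatenate(keep_junc) if keep_junc
                else np.empty(0, dtype=np.float64))
        return _ChromState(junc, np.concatenate(labs), new_joff, self.length_cm)

    def reproduce(self, n_off: int, rng: np.random.Generator,
                  weights: np.ndarray | None = None) -> "_ChromState":
        n = self.n_copies
        if weights is None:
            p1 = rng.integers(0, n, n_off)
            p2 = rng.integers(0, n, n_off)
        else:
            p = weights / weights.sum()
            p1 = rng.choice(n, n_off, p=p)
            p2 = rng.choice(n, n_off, p=p)
        L = self.length_cm
        counts = rng.poisson(L / 100.0, n_off)
        total = int(counts.sum())
        ids = np.repeat(np.arange(n_off), counts)
        x = rng.random(total) * L
        xpos = x[np.lexsort((x, ids))]
        xoff = np.zeros(n_off + 1, dtype=np.int64)
        np.cumsum(counts, out=xoff[1:])
        njunc = np.diff(self.joff)
        bound = int((counts + njunc[p1] + njunc[p2]).sum())
        out_junc = np.empty(bound, dtype=np.float64)
        out_lab = np.empty(bound + n_off, dtype=_LABEL_DTYPE)
        out_joff = np.empty(n_off + 1, dtype=np.int64)
        _reproduce_kernel(self.junc, self.lab, self.joff,
                          p1.astype(np.int64), p2.astype(np.int64),
                          xpos, xoff, L, out_junc, out_lab, out_joff)
        used = int(out_joff[-1])
        return _ChromState(out_junc[:used].copy(),
                           out_lab[:used + n_off].copy(),
                           out_joff.copy(), L)


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

def simulate(demography: Demography,
             chrom_lengths_cm: Mapping[str, float],
             selection: SelectionSpec | None = None,
             n_sample_haploids: int = 30,
             seed: int = 0,
             trace_lineages: bool = False) -> list[HaploidTracts]:
    """Run the demography and return tracts for sampled haploid genomes.

    Chromosomes evolve as independent Wright-Fisher populations of 2N copies
    (copy-level reproduction makes inter-chromosome linkage irrelevant);
    sampled genomes take the same copy indices on every chromosome.
    """
    if trace_lineages and selection is not None:
        raise ValueError("lineage tracing is incompatible with selection")
    rng = np.random.default_rng(seed)
    sizes = demography.sizes()
    G = demography.generations
    n0 = 2 * int(sizes[0])
    next_label = 0
    if trace_lineages:
        founder = np.arange(n0, dtype=_LABEL_DTYPE)
        next_label = n0
    else:
        founder = np.full(n0, demography.founder_label, dtype=_LABEL_DTYPE)
    states = {c: _ChromState.founded(founder, L)
              for c, L in chrom_lengths_cm.items()}

    pulses: dict[int, list[DemographicEvent]] = {}
    for e in demography.events:
        if e.kind == "pulse":
            pulses.setdefault(e.generation, []).append(e)

    for g in range(G + 1):
        for e in pulses.get(g, ()):
            n = next(iter(states.values())).n_copies
            k = int(round(e.value * n))
            if k:
                idx = rng.choice(n, k, replace=False)
                if trace_lineages:
                    labels = np.arange(next_label, next_label + k,
                                       dtype=_LABEL_DTYPE)
                    next_label += k
                else:
                    labels = np.full(k, e.donor, dtype=_LABEL_DTYPE)
                for c in states:
                    states[c] = states[c].replace_with_pure(idx, labels)
        if g == G:
            break
        n_off = 2 * int(sizes[g + 1])
        for c in states:
            weights = None
            if selection is not None and selection.chrom == c and selection.s > 0:
                at = states[c].labels_at(selection.position_cm)
                weights = np.where(at == selection.favored,
                                   1.0 + selection.s, 1.0)
            states[c] = states[c].reproduce(n_off, rng, weights)

    n_final = next(iter(states.values())).n_copies
    if n_sample_haploids > n_final:
        raise ValueError(
            f"sample of {n_sample_haploids} exceeds {n_final} final copies")
    chosen = rng.choice(n_final, n_sample_haploids, replace=False)
    out = []
    for rank, i in enumerate(chosen):
        junctions = {}
        labels = {}
        for c, st in states.items():
            j, l = st.copy_tracts(int(i))
            junctions[c] = j
            labels[c] = l
        ts = HaploidTracts(f"hap{rank}", junctions, labels,
                           {c: st.length_cm for c, st in states.items()})
        out.append(ts)
    return out
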