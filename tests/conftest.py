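import numpy as np
import pytest

from ancestry_select.io_formats import RecombinationMap
from ancestry_select.local_ancestry_hmm import AIMPanel, select_aims
from ancestry_select import synthetic_data as sd


@pytest.fixture
def uniform_map():
    """5 x 10 Mb genome at a uniform honey-bee-like 20 cM/Mb."""
    lengths_bp, _ = sd.default_genome()
    return RecombinationMap.uniform(lengths_bp, 20.0)


@pytest.fixture
def random_panel():
    """Small random AIM panel on one chromosome (8 sites)."""
    rng = np.random.default_rng(7)
    n = 8
    return AIMPanel(np.array(["chr1"] * n, dtype=object),
                    np.arange(1, n + 1) * 1000,
                    np.arange(n) * 0.15,
                    rng.integers(1, 30, (n, 2)),
                    rng.integers(1, 30, (n, 2)))


def make_synthetic_dataset(seed, n_chrom=5, chrom_mb=10.0, rate=20.0,
                           spacing_bp=20_000, n_a=30, n_b=28,
                           min_diff=0.10, fst=0.368):
    """Panels + AIM selection on a synthetic genome.

    Returns (panel, freq_a, freq_b, recmap, chrom_lengths_cm) with the true
    per-site frequencies aligned to the retained AIMs.
    """
    rng = np.random.default_rng(seed)
    lengths_bp, lengths_cm = sd.default_genome(n_chrom, chrom_mb, rate)
    recmap = RecombinationMap.uniform(lengths_bp, rate)
    per = int(chrom_mb * 1e6) // spacing_bp
    model = sd.PanelModel(n_sites=per * n_chrom, F=fst,
                          seed=int(rng.integers(2**31)))
    freq_a, freq_b = sd.gen_panel_freqs(model)
    geno_a = sd.sample_panel_genotypes(freq_a, n_a, int(rng.integers(2**31)))
    geno_b = sd.sample_panel_genotypes(freq_b, n_b, int(rng.integers(2**31)))
    chrom = np.repeat(list(lengths_bp), per).astype(object)
    pos = np.tile(np.arange(per) * spacing_bp + spacing_bp // 2, n_chrom)
    counts_a = np.stack([(geno_a == 0).sum(1), (geno_a == 1).sum(1)], axis=1)
    counts_b = np.stack([(geno_b == 0).sum(1), (geno_b == 1).sum(1)], axis=1)
    panel = select_aims(counts_a, counts_b, chrom, pos, recmap,
                        min_diff=min_diff)
    index = {(c, p): i for i, (c, p) in enumerate(zip(chrom, pos))}
    idx = np.array([index[(c, p)] for c, p in zip(panel.chrom, panel.pos)])
    return panel, freq_a[idx], freq_b[idx], recmap, lengths_cm
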