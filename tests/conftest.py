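import numpy as np
import pytest

import paraloci as pl


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated genome with sequence: 3 genes + 3 pseudogenes
    (one lesion of each kind), two contigs."""
    cfg = pl.SimConfig(
        seed=11,
        contig_lengths=(600_000, 600_000),
        n_genes=3,
        n_pseudogenes=3,
        genes_per_cluster=3,
        background_te_density=0.30,
        divergence=0.02,
        focal_pad_bp=20_000,
        placement_margin_bp=60_000,
    )
    return pl.simulate_genome(cfg)


@pytest.fixture(scope="session")
def coords_dataset():
    """Coordinate-only dataset (no sequence) for enrichment statistics."""
    cfg = pl.SimConfig(
        seed=21,
        contig_lengths=(4_000_000,),
        n_genes=10,
        n_pseudogenes=0,
        genes_per_cluster=5,
        background_te_density=0.40,
        focal_enrichment_factor=1.5,
        signature_te=None,
        generate_sequence=False,
    )
    return pl.simulate_genome(cfg)


def brute_force_coverage(window, tes):
    """Per-base boolean-mask coverage oracle (independent of the index path)."""
    mask = np.zeros(window.width, dtype=bool)
    for te in tes:
        iv = te.interval
        if iv.contig_id != window.contig_id:
            continue
        lo = max(iv.start, window.start) - window.start
        hi = min(iv.end, window.end) - window.start
        if hi > lo:
            mask[lo:hi] = True
    return mask.mean()
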