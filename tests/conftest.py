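import numpy as np
import pandas as pd
import pytest

from breakscape import CoverageTrack, SimConfig, simulate_genome


@pytest.fixture
def flat_track():
    """Constant-1.0 coverage on a single 100 bp chromosome."""
    return CoverageTrack(values={"chr1": np.ones(100)}, library_size=1e6,
                         label="flat")


@pytest.fixture
def small_genome():
    """Tiny deterministic synthetic genome (fast to simulate)."""
    cfg = SimConfig(chrom_length=300_000, n_genes=10, n_sites=30, n_cut=8,
                    gene_length_range=(3000, 15000), edge_margin=10_000,
                    seed=11)
    return simulate_genome(cfg)


def make_sites(*positions, chrom="chr1", cut=True):
    """Minimal site table for signal-level tests."""
    return pd.DataFrame([
        dict(site_id=f"s{i + 1}", chrom=chrom, position=p, cut=cut,
             cleavage_efficiency=1.0 - 0.1 * i)
        for i, p in enumerate(positions)
    ])
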