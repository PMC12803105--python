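import numpy as np
import pandas as pd
import pytest

from clipfunnel.simulate import (SimulationConfig, simulate_clip_events,
                                 simulate_transcriptome)


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-signal simulation shared across tests (read-only)."""
    cfg = SimulationConfig(n_genes=60, n_ligands=10, seed=3)
    transcriptome, truth = simulate_transcriptome(cfg)
    sites1, sites2 = simulate_clip_events(cfg, transcriptome, truth)
    return cfg, transcriptome, truth, sites1, sites2


def make_sites(positions, scores, gene_id="gX", chrom="chrS", strand="+"):
    return pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(positions, dtype=int),
        "strand": strand, "score": np.asarray(scores, dtype=int),
        "gene_id": gene_id,
    })
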