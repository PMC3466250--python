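from __future__ import annotations

import numpy as np
import pytest

from oligocap import simulate
from oligocap.preprocess import preprocess_read


@pytest.fixture(scope="session")
def small_library():
    """A 200-gene synthetic library with truncation and realistic error
    rates, preprocessed once for the whole session."""
    cfg = simulate.SynthConfig(
        n_genes=200, seed=42, truncation_prob=0.2, error_rate=0.005
    )
    rng = np.random.default_rng(cfg.seed)
    genes = simulate.make_transcriptome(cfg, rng)
    clones = simulate.simulate_library(genes, cfg, rng)
    reads = [r for lc in clones for r in (lc.read5, lc.read3)]
    anns = {r.id: preprocess_read(r) for r in reads}
    inserts = [a.insert for a in anns.values() if a.insert is not None]
    hits = simulate.simulate_evidence(
        inserts,
        genes,
        {r.id: r.clone_id for r in reads},
        {lc.clone_id: lc.truth for lc in clones},
        noise=0.0,
        rng=np.random.default_rng(7),
    )
    return dict(
        cfg=cfg, genes=genes, clones=clones, reads=reads, anns=anns,
        inserts=inserts, hits=hits,
    )


@pytest.fixture(scope="session")
def clean_library():
    """Error-free, truncation-free library: every 5' read starts with the
    cap tag and every truth quantity is recoverable exactly."""
    cfg = simulate.SynthConfig(
        n_genes=120, seed=11, truncation_prob=0.0, error_rate=0.0
    )
    rng = np.random.default_rng(cfg.seed)
    genes = simulate.make_transcriptome(cfg, rng)
    clones = simulate.simulate_library(genes, cfg, rng)
    reads = [r for lc in clones for r in (lc.read5, lc.read3)]
    anns = {r.id: preprocess_read(r) for r in reads}
    inserts = [a.insert for a in anns.values() if a.insert is not None]
    hits = simulate.simulate_evidence(
        inserts,
        genes,
        {r.id: r.clone_id for r in reads},
        {lc.clone_id: lc.truth for lc in clones},
        noise=0.0,
        rng=np.random.default_rng(3),
    )
    return dict(
        cfg=cfg, genes=genes, clones=clones, reads=reads, anns=anns,
        inserts=inserts, hits=hits,
    )
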