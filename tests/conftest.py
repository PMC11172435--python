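import numpy as np
import pytest

import ribocontext as rc


@pytest.fixture
def tiny_orfs():
    """Five short hand-written ORFs (lengths are multiples of 3)."""
    return rc.OrfSet(
        {
            "g1": "AUGGCUGAAGGUUAA",
            "g2": "AUGCCUGGCACUUGA",
            "g3": "AUGUUUGAUCGAUAG",
            "g4": "AUGGGUCAUACGUAA",
            "g5": "AUGACUUCUGCCUAA",
        }
    )


@pytest.fixture(scope="session")
def effect_dataset():
    """Simulated 28-nt dataset with the documented NNU/+1 GNN dwell preset."""
    cfg = rc.preset("paper_effect", seed=101, n_genes=100,
                    min_codons=200, max_codons=400)
    orfs, truth = rc.gen_orfs(cfg)
    counts, truth = rc.gen_profiles(orfs, cfg, truth)
    return cfg, orfs, counts, truth


@pytest.fixture(scope="session")
def null_dataset():
    """Simulated 28-nt dataset with no injected effects."""
    cfg = rc.preset("null", seed=202, n_genes=60, min_codons=150, max_codons=300)
    orfs, truth = rc.gen_orfs(cfg)
    counts, truth = rc.gen_profiles(orfs, cfg, truth)
    return cfg, orfs, counts, truth
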