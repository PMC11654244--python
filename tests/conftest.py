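import numpy as np
import pandas as pd
import pytest

from degronscreen import synthetic_data as sim
from degronscreen.enrichment import AnnotationTable


@pytest.fixture
def small_annotation() -> AnnotationTable:
    """Tiny hand-built gene->term table for exact-count checks."""
    pairs = pd.DataFrame(
        [
            ("g1", "T_A"), ("g2", "T_A"), ("g3", "T_A"),
            ("g1", "T_B"), ("g4", "T_B"),
            ("g5", "T_C"),
        ],
        columns=["gene_id", "term_id"],
    )
    return AnnotationTable(pairs)


@pytest.fixture
def plate_pair():
    """Noise-free induced/uninduced plate pair with planted lethals."""
    cfg = sim.ScreenSimConfig(
        layout=(8, 12), n_strains=96, lethal_fraction=0.125, effect_size=0.0,
        noise_cv=0.0, edge_boost=1.0, seed=7,
    )
    return sim.gen_plate_pair(cfg) + (cfg,)
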