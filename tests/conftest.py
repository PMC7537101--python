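from __future__ import annotations

import pandas as pd
import pytest

from tempoclust.dge import de_all_timepoints
from tempoclust.simdata import SimulationConfig, simulate_counts


@pytest.fixture(scope="session")
def sim_bank():
    """Lazily cached (DE table, ground truth, timepoints) per default-config seed.

    Shared across tests so the expensive simulate+DE step runs once per seed.
    """
    cache: dict[int, tuple] = {}

    def get(seed: int):
        if seed not in cache:
            cm, truth = simulate_counts(SimulationConfig(seed=seed))
            cache[seed] = (de_all_timepoints(cm), truth, cm.timepoints)
        return cache[seed]

    return get


@pytest.fixture
def tiny_de_table() -> pd.DataFrame:
    """Hand-written complete DE table: 6 genes x 4 timepoints.

    Genes g1-g4 are significant somewhere; g5, g6 never are.
    """
    rows = []
    profiles = {
        "g1": [1.0, 0.5, 0.2, 0.1],
        "g2": [0.9, 0.6, 0.1, 0.0],
        "g3": [-0.1, -0.2, -0.8, -1.2],
        "g4": [0.0, -0.3, -0.9, -1.0],
        "g5": [0.05, 0.02, -0.03, 0.01],
        "g6": [0.0, 0.01, 0.02, 0.0],
    }
    sig_at = {"g1": 0, "g2": 0, "g3": 3, "g4": 3}
    for tp_i, tp in enumerate(["E14.5", "1mo", "6mo", "12mo"]):
        for gene, prof in profiles.items():
            sig = sig_at.get(gene) == tp_i
            adjp = 0.01 if sig else 0.5
            rows.append(
                {
                    "gene_id": gene,
                    "timepoint": tp,
                    "log2fc": prof[tp_i],
                    "pvalue": adjp / 2,
                    "adjp": adjp,
                    "mean_expr": 5.0,
                }
            )
    return pd.DataFrame(rows)
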