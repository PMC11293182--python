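import numpy as np
import pandas as pd
import pytest

import aknno as ak
from aknno.preprocess import embed_counts
from aknno.graph import (
    AdaptiveGraphConfig,
    build_adaptive_graph,
    build_fixed_graph,
    compute_neighbor_table,
    snn_jaccard,
)
from aknno.clustering import louvain_cluster


@pytest.fixture(scope="session")
def small_counts():
    """3-type simulated dataset (200/200/10 cells) with strong markers."""
    return ak.simulate_nb_counts(ak.SimulationDesign(seed=7))


@pytest.fixture(scope="session")
def recovery_results():
    """Parameter-recovery sweep shared by the recovery and resolution tests.

    20 simulated datasets under the default design (200/200/10 cells,
    log2_fc=3, marker_fraction=0.05); the adaptive graph and the fixed-k=20
    baseline are each clustered at r in {0.1, 0.3, 0.8}.
    """
    rows = []
    for seed in range(20):
        cm = ak.simulate_nb_counts(ak.SimulationDesign(seed=seed))
        emb = embed_counts(cm, n_hvg=100, n_pcs=20)
        truth = np.asarray(emb.provenance["labels"], dtype=object)
        table = compute_neighbor_table(emb, 20)
        cfg = AdaptiveGraphConfig()
        graphs = {
            "aknno": snn_jaccard(build_adaptive_graph(table, cfg), cfg.prune),
            "fixed_knn": snn_jaccard(build_fixed_graph(table, 20), cfg.prune),
        }
        for method, snn in graphs.items():
            for r in (0.1, 0.3, 0.8):
                res = louvain_cluster(snn, resolution=r, seed=seed)
                rows.append(
                    {
                        "seed": seed,
                        "method": method,
                        "resolution": r,
                        "rare_accuracy": ak.rare_accuracy(
                            res.labels, truth, rare_type="type_2"
                        ),
                        "ari": ak.adjusted_rand_index(res.labels, truth),
                    }
                )
    return pd.DataFrame(rows)
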