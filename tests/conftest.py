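import numpy as np
import pandas as pd
import pytest

from memtype import diffexpr, synthetic_data as synth


@pytest.fixture
def tiny_design():
    """3 genes × 8 samples, 4 conditions × 2 replicates, hand-set FPKMs."""
    sheet = pd.DataFrame(
        [(f"{c}_{r}", c, r) for c in ("C1", "D1", "R1", "D2") for r in (1, 2)],
        columns=["sample_id", "condition", "replicate"])
    matrix = pd.DataFrame(
        {
            "C1_1": [10.0, 20.0, 0.0],
            "C1_2": [10.0, 20.0, 0.0],
            "D1_1": [40.0, 20.0, 0.0],
            "D1_2": [40.0, 20.0, 0.0],
            "R1_1": [10.0, 20.0, 0.0],
            "R1_2": [10.0, 20.0, 0.0],
            "D2_1": [40.0, 5.0, 0.0],
            "D2_2": [40.0, 5.0, 0.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    return matrix, sheet


@pytest.fixture
def noiseless_sim():
    config = synth.SimulationConfig(n_per_class=12, noise_sd=0.0, seed=11)
    return synth.generate_expression(config)


@pytest.fixture
def noisy_sim():
    config = synth.SimulationConfig(n_per_class=40, noise_sd=0.25, seed=11)
    return synth.generate_expression(config)


def classify_pipeline(matrix, sheet, criteria=None, method="pooled"):
    """Run both contrasts and the 9-way classification; returns assignments."""
    from memtype import memory_classify as mc

    criteria = criteria or diffexpr.DEGCriteria()
    first = diffexpr.contrast_with_calls(matrix, sheet, "C1", "D1",
                                         criteria, method=method)
    second = diffexpr.contrast_with_calls(matrix, sheet, "D1", "D2",
                                          criteria, method=method)
    return mc.classify_genes(first, second)


def reference_bh(p: np.ndarray) -> np.ndarray:
    """Independent step-up Benjamini–Hochberg, written from the definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        q[i] = running_min
    return q
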