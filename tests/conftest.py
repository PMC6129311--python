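import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tissuesets import synthetic, weights

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

TISSUES = [f"T{i:02d}" for i in range(1, 7)]


@pytest.fixture(scope="session")
def small_bundle():
    """Small simulated HPA bundle with one planted set (deterministic)."""
    return synthetic.simulate_hpa(
        n_genes=300,
        tissues=TISSUES,
        planted=[(15, "T03", 6.0)],
        n_decoy_sets=20,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_set_weights(small_bundle):
    expr, ihc, gsc, _ = small_bundle
    gw = weights.gene_weights(expr, ihc)
    return weights.collection_weights(gw, gsc)


@pytest.fixture()
def toy_sw():
    """Hand-built set weight matrix with one undefined cell."""
    w = pd.DataFrame(
        {
            "liver": [3.7, 7.0, 2.0, 5.0],
            "pancreas": [1.1, 8.0, float("nan"), 5.0],
            "muscle": [5.0, 9.0, 1.0, 5.0],
            "adipose": [2.2, 9.5, 4.0, 5.0],
        },
        index=["SET_A", "SET_B", "SET_C", "SET_D"],
    )
    return weights.SetWeightMatrix(w=w, n_used=pd.Series([3, 3, 3, 3], index=w.index))
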