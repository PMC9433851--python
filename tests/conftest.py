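import numpy as np
import pandas as pd
import pytest

from hcdn.atlas import default_network_atlas, hippocampus_atlas
from hcdn.deconfound import ConfoundTable, VolumeMatrix
from hcdn.synthetic import CohortSpec, generate_cohort


def make_volume_matrix(values: np.ndarray, structure: str = "DN",
                       prefix: str = "col") -> VolumeMatrix:
    """Wrap a plain array as a VolumeMatrix with generic anatomy labels."""
    n, p = values.shape
    cols = [f"{prefix}_{j}" for j in range(p)]
    meta = pd.DataFrame({
        "structure": structure,
        "hemisphere": ["L" if j % 2 == 0 else "R" for j in range(p)],
        "category": "Temporal" if structure == "DN" else "CA1",
        "segment": "whole",
    }, index=pd.Index(cols, name="subregion"))
    idx = pd.Index([f"sub-{i:04d}" for i in range(n)], name="participant_id")
    return VolumeMatrix(values=pd.DataFrame(values, index=idx, columns=cols),
                        meta=meta)


def make_confounds(values: np.ndarray, names=None) -> ConfoundTable:
    n, c = values.shape
    names = names or [f"conf_{j}" for j in range(c)]
    idx = pd.Index([f"sub-{i:04d}" for i in range(n)], name="participant_id")
    return ConfoundTable(values=pd.DataFrame(values, index=idx, columns=names))


@pytest.fixture(scope="session")
def small_cohort():
    """Shared small synthetic cohort with three well-separated modes."""
    spec = CohortSpec(n_per_group=500, p_dn=20, q_hc=12, k_true=3,
                      factor_strengths=(3.0, 2.0, 1.0), loading_sparsity=0.5,
                      seed=42)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def full_atlases():
    return hippocampus_atlas(), default_network_atlas()
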