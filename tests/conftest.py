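import numpy as np
import pytest

from mvmr import CorrelationSpec, SummaryDataset, generate_dataset

FAST_FIT = dict(chains=2, iterations=600, warmup=250)


@pytest.fixture
def lipid_corr() -> CorrelationSpec:
    return CorrelationSpec.lipid_default()


@pytest.fixture
def small_ds() -> SummaryDataset:
    """Five independent variants, one risk factor; hand-checkable numbers."""
    return SummaryDataset(
        variant_ids=("v1", "v2", "v3", "v4", "v5"),
        risk_factor_names=("rf",),
        X=np.array([[0.10], [0.20], [0.15], [0.05], [0.25]]),
        SE_X=np.full((5, 1), 0.01),
        Y=np.array([0.04, 0.09, 0.05, 0.03, 0.11]),
        SE_Y=np.array([0.02, 0.03, 0.02, 0.04, 0.03]),
    )


@pytest.fixture
def synthetic_ds():
    ds, truth = generate_dataset(J=60, K=3, seed=1)
    return ds, truth


def make_dataset(rng: np.random.Generator, J: int = 4, K: int = 2,
                 with_ld: bool = False) -> SummaryDataset:
    """Random small dataset for oracle comparisons."""
    ld = None
    if with_ld:
        ld = np.eye(J)
        for j in range(J - 1):
            r = rng.uniform(-0.2, 0.2)
            ld[j, j + 1] = ld[j + 1, j] = r
        # AR-style fill keeps it PD for small r
        for j in range(J):
            for k in range(J):
                if abs(j - k) > 1:
                    ld[j, k] = np.prod(
                        [ld[i, i + 1] for i in range(min(j, k), max(j, k))]
                    )
    return SummaryDataset(
        variant_ids=tuple(f"s{j}" for j in range(J)),
        risk_factor_names=tuple(f"rf{v}" for v in range(K)),
        X=rng.normal(0, 0.1, (J, K)),
        SE_X=rng.uniform(0.01, 0.05, (J, K)),
        Y=rng.normal(0, 0.05, J),
        SE_Y=rng.uniform(0.01, 0.05, J),
        ld=ld,
    )
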