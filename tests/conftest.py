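import numpy as np
import pandas as pd
import pytest

from seasonet import syndata
from seasonet.study import ExpressionStudy, default_gene_annotation


@pytest.fixture(scope="session")
def default_study_truth():
    """Default synthetic study (seed 0): the spec's study conditions."""
    return syndata.generate_study(syndata.SynConfig(seed=0))


@pytest.fixture(scope="session")
def small_study_truth():
    """Scaled-down synthetic study for fast end-to-end checks."""
    cfg = syndata.SynConfig(
        n_genes=600, n_immune=80, n_core=20, n_interface=4,
        n_stable=30, seed=3,
    )
    return syndata.generate_study(cfg)


def make_study(matrix: np.ndarray, samples: pd.DataFrame) -> ExpressionStudy:
    """Wrap a raw matrix + metadata into a study with blank annotation."""
    genes = [f"g{i:03d}" for i in range(matrix.shape[0])]
    mdf = pd.DataFrame(matrix, index=pd.Index(genes, name="gene"),
                       columns=samples.index)
    return ExpressionStudy(mdf, samples, default_gene_annotation(genes))


def two_group_samples(n_per_group: int, site: str = "site1") -> pd.DataFrame:
    rows = []
    for season in ("winter", "summer"):
        for i in range(n_per_group):
            rows.append({
                "sample": f"{site}_{season}_{i:02d}",
                "site": site,
                "season": season,
                "sex": "M" if i % 2 == 0 else "F",
                "length_mm": 30.0 + i,
            })
    return pd.DataFrame(rows).set_index("sample")
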