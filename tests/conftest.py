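import numpy as np
import pandas as pd
import pytest

from inparkit.diffexpr import ExpressionStudy
from inparkit.synthdata import GwasConfig, PpiConfig, SyntheticConfig, simulate


@pytest.fixture(scope="session")
def default_bundle():
    """One full synthetic study at the default design."""
    return simulate(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def null_config():
    """A configuration with nothing planted: pure noise everywhere."""
    return SyntheticConfig(
        n_genes=80,
        n_samples_per_arm=12,
        pathways={"set_a": 15, "set_b": 15, "set_c": 10},
        planted_de_pathway=None,
        coexpression_blocks=[],
        dysregulated_pairs=[],
        gwas=GwasConfig(n_snps=1500, planted_pathway=None),
        ppi=PpiConfig(density=0.05, crossing_pathways=None),
        seed=5,
    )


def make_study(matrix: np.ndarray, genes=None, n_per_arm=None, log2_scale=True) -> ExpressionStudy:
    """Wrap a raw genes x samples array into a 2x2 annotated study."""
    n_genes, n_samples = matrix.shape
    assert n_samples % 4 == 0
    n = n_samples // 4 if n_per_arm is None else n_per_arm
    genes = genes or [f"g{i}" for i in range(n_genes)]
    cols, annot = [], []
    i = 0
    for group in ("case", "control"):
        for challenge in ("allergen", "diluent"):
            for k in range(n):
                sid = f"{group}_{challenge}_{k}"
                cols.append(sid)
                annot.append((sid, group, challenge, f"{group}_{k}"))
                i += 1
    mat = pd.DataFrame(matrix, index=genes, columns=cols)
    samples = pd.DataFrame(annot, columns=["sample", "group", "challenge", "pairing"]).set_index("sample")
    return ExpressionStudy(matrix=mat, samples=samples, log2_scale=log2_scale)
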