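import numpy as np
import pandas as pd
import pytest

from multifate import lineage, synthetic


@pytest.fixture(scope="session")
def small_multiome():
    """A compact three-lineage multiome shared across tests."""
    cfg = synthetic.SimConfig(
        seed=11,
        n_cells_per_lineage={"basal": 60, "L1": 120, "L2": 60},
        n_genes=300,
        n_peaks=300,
        signature_size=20,
    )
    return cfg, synthetic.gen_multiome(cfg)


@pytest.fixture(scope="session")
def small_scores(small_multiome):
    cfg, (rna, atac, seqs, truth) = small_multiome
    expr = pd.DataFrame(
        lineage.normalize_expression(rna.X), index=rna.obs_names, columns=rna.var_names
    )
    sigs = [
        lineage.GeneSignature(name=k, genes=tuple(v))
        for k, v in truth.signatures.items()
    ]
    return lineage.score_matrix(expr, sigs), truth


@pytest.fixture()
def reference_cohort_file(tmp_path):
    path = tmp_path / "cohort.tsv"
    synthetic.make_reference_cohort().to_csv(path, sep="\t", index=False)
    return path
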