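import numpy as np
import pandas as pd
import pytest

from kdsig.containers import CountMatrix
from kdsig.expression import filter_protein_coding, normalize
from kdsig.simulate import PlantedGene, SimCountConfig, simulate_counts


def make_count_matrix(counts, biotypes=None, lines=None, conditions=None):
    """Small hand-built CountMatrix; counts is genes x samples array."""
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    gene_ids = [f"G{i}" for i in range(n_genes)]
    genes = pd.DataFrame(
        {
            "symbol": [f"SYM{i}" for i in range(n_genes)],
            "biotype": biotypes or ["protein_coding"] * n_genes,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    sample_ids = [f"S{j}" for j in range(n_samples)]
    samples = pd.DataFrame(
        {
            "cell_line": lines or ["L1"] * n_samples,
            "condition": conditions or ["NT"] * n_samples,
            "shRNA": ["shNT"] * n_samples,
            "replicate": list(range(1, n_samples + 1)),
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    return CountMatrix(pd.DataFrame(counts, index=genes.index, columns=samples.index),
                       genes, samples)


@pytest.fixture(scope="session")
def planted_config():
    """Two lines, NT/KD1/KD2 x 2 reps, with a known concordant program."""
    program = (
        tuple(PlantedGene(f"UP{i}", (2.0, 2.0)) for i in range(20))
        + tuple(PlantedGene(f"DN{i}", (-2.0, -2.0)) for i in range(20))
        + tuple(PlantedGene(f"PRIV{i}", (2.0, 0.0)) for i in range(5))
        + (PlantedGene("DISC0", (2.0, -2.0)),)
    )
    return SimCountConfig(n_genes=800, program=program, noncoding_fraction=0.1, seed=42)


@pytest.fixture(scope="session")
def planted_counts(planted_config):
    return simulate_counts(planted_config)


@pytest.fixture(scope="session")
def planted_expr(planted_counts):
    return filter_protein_coding(normalize(planted_counts))
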