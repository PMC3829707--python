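import pandas as pd
import pytest

from cycleseq import coverage, synthetic


def make_expression_matrix(data: dict[str, list[float]]) -> coverage.ExpressionMatrix:
    """Build an ExpressionMatrix from {gene: 15 values} (5 tp x 3 reps)."""
    cols = pd.MultiIndex.from_product(
        [range(5), range(3)], names=["timepoint", "replicate"]
    )
    values = pd.DataFrame.from_dict(data, orient="index")
    values.index.name = "gene_id"
    values.columns = cols
    ones = pd.Series(1.0, index=values.index)
    return coverage.ExpressionMatrix(
        values=values,
        retained_fraction=ones,
        fallback_flag=ones.astype(bool) & False,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small full coverage simulation with ground truth (session-cached)."""
    spec = synthetic.GenomeSpec(genome_length=40_000, n_genes=40)
    return synthetic.simulate_experiment(spec, seed=101)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Zero-noise simulation: replicates identical to the planted programs."""
    spec = synthetic.GenomeSpec(
        genome_length=20_000, n_genes=20, duplicate_gene_pairs=1
    )
    return synthetic.simulate_experiment(
        spec,
        seed=7,
        gc_noise=synthetic.GcNoise(affected_fraction=0.0, cv_target=0.0),
        dispersion=0.0,
        nucleotide_noise=False,
    )


@pytest.fixture(scope="session")
def planted_tree():
    """236-species tree with planted broad and clade-specific modules."""
    mts = [
        {"module_id": f"b{i}", "depth_class": "broad", "size": 10}
        for i in range(3)
    ] + [
        {"module_id": f"c{i}", "depth_class": "clade", "size": 10}
        for i in range(3)
    ]
    return synthetic.simulate_tree_and_conservation(236, mts, seed=42)
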