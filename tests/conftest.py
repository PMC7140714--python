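import numpy as np
import pandas as pd
import pytest

from omicshub import ExpressionStudy, FactorialAnova, SyntheticDesign, generate_expression_study


def build_study(values_by_gene: dict[str, dict[tuple, list[float]]]) -> ExpressionStudy:
    """Construct a balanced 2x2x2 study from per-cell replicate values.

    ``values_by_gene[gene][(genotype, condition, tissue)]`` is a list of
    replicate log2 values; every gene must cover the same cells with the
    same replicate count.
    """
    genes = list(values_by_gene)
    cells = list(values_by_gene[genes[0]])
    n_rep = len(values_by_gene[genes[0]][cells[0]])
    rows, cols = [], []
    for geno, cond, tis in cells:
        for r in range(1, n_rep + 1):
            sid = f"{geno}_{cond}_{tis}_r{r}"
            cols.append(sid)
            rows.append({"sample_id": sid, "genotype": geno,
                         "condition": cond, "tissue": tis, "replicate": r})
    samples = pd.DataFrame(rows).set_index("sample_id")
    matrix = pd.DataFrame(
        [
            [v for cell in cells for v in values_by_gene[g][cell]]
            for g in genes
        ],
        index=pd.Index(genes, name="gene_id"),
        columns=cols,
    )
    conditions = list(dict.fromkeys(c for _, c, _ in cells))
    return ExpressionStudy(matrix=matrix, samples=samples,
                           condition_levels=(conditions[0], conditions[1]))


def random_small_study(n_genes: int = 4, n_rep: int = 3, seed: int = 7) -> ExpressionStudy:
    rng = np.random.default_rng(seed)
    cells = [
        (g, c, t)
        for g in ("WT", "OX")
        for c in ("nS", "-S")
        for t in ("shoot", "root")
    ]
    values = {
        f"g{i}": {cell: list(rng.normal(8, 1, n_rep)) for cell in cells}
        for i in range(n_genes)
    }
    return build_study(values)


@pytest.fixture(scope="session")
def planted_study():
    """Seeded 1000-gene study with planted DEGs (log2FC=2, sd=0.25, n=3)."""
    design = SyntheticDesign(
        n_genes=1000, planted_deg_fraction=0.1, planted_log2fc=2.0,
        noise_sd=0.25, n_replicates=3, seed=11,
    )
    return generate_expression_study(design)


@pytest.fixture(scope="session")
def planted_results(planted_study):
    study, _ = planted_study
    return FactorialAnova(study).fit()


@pytest.fixture(scope="session")
def null_study():
    """Seeded 1000-gene study with no planted effects."""
    design = SyntheticDesign(
        n_genes=1000, planted_deg_fraction=0.0, noise_sd=0.25,
        n_replicates=3, seed=13,
    )
    return generate_expression_study(design)
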