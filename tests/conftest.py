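import numpy as np
import pandas as pd
import pytest

from clockko import ExpressionStudy, SimConfig, simulate_expression


def make_study(tpm_by_gene: dict[str, dict[str, list[float]]]) -> ExpressionStudy:
    """Build a small study from {gene: {genotype: [replicate TPMs]}}."""
    genotypes = list(next(iter(tpm_by_gene.values())).keys())
    samples, design_rows = [], []
    for g in genotypes:
        n = len(next(iter(tpm_by_gene.values()))[g])
        for r in range(1, n + 1):
            samples.append(f"{g}_{r}")
            design_rows.append({"sample": f"{g}_{r}", "genotype": g, "replicate": r})
    data = {
        gene: np.concatenate([vals[g] for g in genotypes])
        for gene, vals in tpm_by_gene.items()
    }
    tpm = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    tpm.index.name = "gene"
    design = pd.DataFrame(design_rows).set_index("sample")
    return ExpressionStudy(tpm, design)


@pytest.fixture(scope="session")
def planted_study():
    """A 2000-gene simulated study with the default planted-class mixture."""
    config = SimConfig(n_genes=2000, replicate_sd=0.1, seed=20240101)
    study, truth = simulate_expression(config)
    return study, truth
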