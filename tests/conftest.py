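import numpy as np
import pytest

from transage import (
    ExpressionDataset,
    StepGeneSpec,
    SyntheticSpec,
    simulate_expression,
)


@pytest.fixture
def tiny_dataset():
    """4 subjects, 3 genes, no ties in age."""
    return ExpressionDataset(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [4.0, 3.0, 2.0, 1.0],
                [2.0, 2.0, 2.0, 2.0],
            ]
        ),
        ages=np.array([20.0, 30.0, 40.0, 50.0]),
        sex=np.array(["F", "M", "F", "M"], dtype=object),
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """Noisy planted-step cohort used by several recovery tests."""
    spec = SyntheticSpec(
        n_subjects=40,
        step_genes=[StepGeneSpec(30, 55.0, 2.0, direction="up")],
        null_genes=70,
        noise_sd=0.5,
        seed=7,
    )
    ds, truth = simulate_expression(spec)
    return ds, truth


@pytest.fixture
def noiseless_step_dataset():
    """12 subjects, one clean step gene at age 50, three null-ish genes."""
    rng = np.random.default_rng(3)
    ages = np.linspace(25, 95, 12)
    step = np.where(ages > 50, 8.0, 6.0)
    others = rng.normal(6, 1, (3, 12))
    values = np.vstack([step, others])
    return ExpressionDataset(
        gene_ids=["step", "n1", "n2", "n3"],
        sample_ids=[f"s{j}" for j in range(12)],
        values=values,
        ages=ages,
    )
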