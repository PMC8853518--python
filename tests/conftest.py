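import numpy as np
import pandas as pd
import pytest

from bloodbrain.ingest import CountMatrix
from bloodbrain.synthio import DegSpec, ModuleSpec, SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def small_counts():
    """Tiny deterministic count matrix for formula-level tests."""
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 500, size=(30, 8))
    return CountMatrix(
        pd.Index([f"g{i}" for i in range(30)]),
        pd.Index([f"s{j}" for j in range(8)]),
        counts,
    )


@pytest.fixture(scope="session")
def module_study():
    """One-tissue study with a planted module, trait link and DEGs."""
    config = SyntheticConfig(
        n_subjects_per_group=10,
        tissues=("BLD",),
        n_genes=600,
        module_specs=(ModuleSpec(1, 100, ("BLD",), 0.8, trait_r=0.7),),
        deg_specs=(DegSpec("BLD", 50, 2.0, "up"),),
        seed=42,
    )
    return generate_study(config)


@pytest.fixture(scope="session")
def null_study():
    """Study with no planted structure at all (global null)."""
    config = SyntheticConfig(
        n_subjects_per_group=8, tissues=("BLD",), n_genes=2000, seed=99
    )
    return generate_study(config)


@pytest.fixture(scope="session")
def multi_tissue_study():
    """Four-tissue study with a conserved blood-brain module and DEGs."""
    config = SyntheticConfig(
        n_subjects_per_group=10,
        tissues=("BLD", "PFC", "AMY", "HYP"),
        n_genes=500,
        module_specs=(
            ModuleSpec(1, 120, ("BLD", "PFC", "AMY"), 0.8, trait_r=0.6, group_shift=1.0),
            ModuleSpec(2, 100, ("BLD",), 0.8, group_shift=1.0),
        ),
        deg_specs=tuple(DegSpec(t, 30, 2.0, "up") for t in ("BLD", "PFC", "AMY", "HYP")),
        seed=5,
    )
    return generate_study(config)
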