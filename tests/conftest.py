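import numpy as np
import pytest

from chromqsar.dataset import Split, molecule_from_smiles
from chromqsar.fields import assemble_descriptor_matrix, compute_field_matrices
from chromqsar.pls import fit_pls, loo_cross_validate
from chromqsar.synthetic import make_benchmark


@pytest.fixture(scope="session")
def benchmark():
    """Canonical synthetic benchmark: n=60, noise SD 0.1 pMIC, seed 42."""
    molecules, activities, grid, truth = make_benchmark(n=60, noise_sd=0.1, seed=42)
    return {"molecules": molecules, "activities": activities, "grid": grid, "truth": truth}


@pytest.fixture(scope="session")
def benchmark_training(benchmark):
    """Descriptor matrix and activities for the benchmark training split."""
    by_id = {m.id: m for m in benchmark["molecules"]}
    train = [a for a in benchmark["activities"] if a.split is Split.TRAIN]
    mols = [by_id[a.compound_id] for a in train]
    fields = compute_field_matrices(mols, benchmark["grid"])
    dm = assemble_descriptor_matrix(fields, grid=benchmark["grid"])
    y = np.array([a.pmic for a in train])
    return {"dm": dm, "y": y, "activities": train, "molecules": mols}


@pytest.fixture(scope="session")
def benchmark_model(benchmark_training):
    dm, y = benchmark_training["dm"], benchmark_training["y"]
    cv = loo_cross_validate(dm, y, 10)
    model = fit_pls(dm, y, cv.selected_components)
    return {"model": model, "cv": cv, "dm": dm, "y": y}


@pytest.fixture(scope="session")
def sulfanilamide():
    """4-aminobenzenesulfonamide: donors, acceptors and an aromatic ring."""
    return molecule_from_smiles("Nc1ccc(cc1)S(N)(=O)=O", name="sulfanilamide")


@pytest.fixture(scope="session")
def benzene():
    return molecule_from_smiles("c1ccccc1", name="benzene")
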