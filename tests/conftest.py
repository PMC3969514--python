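import numpy as np
import pytest

from focelin import foce, simulate
from focelin.model import (
    EtaBlock,
    ParameterModel,
    PopulationModel,
    RandomEffectStructure,
    ResidualModel,
    StructuralModel,
)


def small_oral_model(sigma2=0.01, form="additive", omega2=(0.1, 0.1)):
    """Compact oral 1-compartment model used by fast unit tests."""
    if form == "combined":
        s2 = (sigma2, sigma2 / 4)
    else:
        s2 = (sigma2,)
    return PopulationModel(
        structural=StructuralModel("one_compartment_oral"),
        parameters=ParameterModel(theta={"CL": 10.0, "V": 50.0, "KA": 1.5}),
        random_effects=RandomEffectStructure(
            blocks=[
                EtaBlock(targets=("CL",), values=[[omega2[0]]], label="bsv_CL"),
                EtaBlock(targets=("V",), values=[[omega2[1]]], label="bsv_V"),
            ],
        ),
        residual=ResidualModel(form=form, sigma2=s2),
    )


def small_design(n_subjects=20, seed=0, **model_kw):
    """Sparse sampling design around `small_oral_model` (fast to fit)."""
    return simulate.SimulationDesign(
        n_subjects=n_subjects,
        sampling_times=[[0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0]],
        dosing=[[(0.0, 100.0, 0.0, 1)]],
        true_model=small_oral_model(**model_kw),
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_additive_dataset():
    design = small_design(n_subjects=20, seed=11)
    return design, simulate.simulate_dataset(design)


@pytest.fixture(scope="session")
def preset_datasets():
    """One simulated dataset per preset design (seeds 1-3)."""
    out = {}
    for seed, (name, maker) in enumerate(simulate.PRESETS.items(), start=1):
        design = maker(seed=seed)
        out[name] = (design, simulate.simulate_dataset(design))
    return out


@pytest.fixture(scope="session")
def preset_base_evals(preset_datasets):
    """FOCE-I evaluation of each preset's true model on its dataset
    (EBEs and OFV at the known parameters; no outer optimization)."""
    out = {}
    for name, (design, ds) in preset_datasets.items():
        out[name] = foce.ofv(design.true_model, ds)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(2025)
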