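import numpy as np
import pytest

from phyloensemble.simulate import (
    SimulationParams,
    simulate_experiment,
    simulate_yule_tree,
)


@pytest.fixture(scope="session")
def study_tree():
    """A 19-species ultrametric tree at the scale of the strain experiment."""
    return simulate_yule_tree(19, birth_rate=1.0, seed=11)


@pytest.fixture(scope="session")
def experiment(study_tree):
    """Default factorial experiment: 35 strains, 10 lakes, 280 rows."""
    return simulate_experiment(study_tree, params=SimulationParams(seed=12))


@pytest.fixture(scope="session")
def prepared_experiment(experiment):
    from phyloensemble.presets import prepare_observation_table

    return prepare_observation_table(experiment.table)


def strain_mapping(exp):
    """species -> strain -> [strain] mapping for strain-level augmentation."""
    mapping = {}
    for strain, sp in exp.truth["strain_species"].items():
        mapping.setdefault(sp, {})[strain] = [strain]
    return mapping


def true_coefficients(X, names, table, effects):
    """Project the generator's fixed-effect predictor onto a design coding.

    The generator parameterises treatments as baseline + offsets while the
    intercept-free design uses absolute first-factor levels, so the true
    coefficient vector is the exact least-squares representation of the true
    linear predictor in the design's column space.
    """
    eta = np.full(len(table), effects.get("intercept", 0.0))
    for key, val in effects.items():
        if ":" in key:
            fac, lev = key.split(":")
            eta = eta + val * (table[fac].astype(str) == lev).to_numpy(float)
    coef, *_ = np.linalg.lstsq(X, eta, rcond=None)
    resid = eta - X @ coef
    assert np.abs(resid).max() < 1e-8, "true predictor not in design span"
    return dict(zip(names, coef))
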