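import warnings

import pytest

warnings.filterwarnings("ignore", message=".*BiopythonDeprecationWarning.*")


@pytest.fixture(scope="session")
def model():
    from toxta.reference import load_reference

    return load_reference()


@pytest.fixture(scope="session")
def promoters():
    from toxta.simulate import load_promoters

    return load_promoters()


@pytest.fixture(scope="session")
def background():
    from toxta.simulate import load_background

    return load_background()


@pytest.fixture(scope="session")
def expression_experiment(tmp_path_factory, model):
    """Simulated wildtype/ΔtoxA/Δsxy mini-experiment shared across tests.

    3 replicates of wildtype and ΔtoxA at t=0 plus wildtype/Δsxy at t=0 and
    t=30 (2 replicates), 25k pairs each — enough to estimate fold changes
    to within a few percent while staying fast.
    """
    from toxta.quant import quantify_experiment
    from toxta.simulate import simulate_experiment

    outdir = tmp_path_factory.mktemp("expr")
    conditions = []
    for rep in (1, 2, 3):
        conditions.append({"genotype": "wildtype", "timepoint": 0, "replicate": rep})
        conditions.append({"genotype": "dtoxA", "timepoint": 0, "replicate": rep})
    for rep in (1, 2):
        conditions.append({"genotype": "wildtype", "timepoint": 30, "replicate": rep})
        conditions.append({"genotype": "dsxy", "timepoint": 0, "replicate": rep})
        conditions.append({"genotype": "dsxy", "timepoint": 30, "replicate": rep})
    # n_cells=10 keeps the fixture fast; the tests that consume it use
    # tolerances sized for the extra molecule-count noise
    manifest = simulate_experiment(outdir, conditions, seed=11, pairs_per_library=25_000, n_cells=10.0)
    expr = quantify_experiment(manifest, model=model)
    return manifest, expr
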