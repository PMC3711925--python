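import pytest

from kcurate import pipeline, registry, simulate


@pytest.fixture(scope="session")
def reg():
    return registry.load_registry()


@pytest.fixture(scope="session")
def missing():
    return registry.load_missing_genes()


@pytest.fixture(scope="session")
def default_bundle():
    return simulate.simulate_genomes(simulate.default_config(seed=1))


@pytest.fixture(scope="session")
def default_report(default_bundle):
    cfg = default_bundle.config
    return pipeline.run_pipeline(
        default_bundle.maps,
        default_bundle.sequences,
        default_bundle.tree_newick,
        domains=simulate.config_domain_annotations(cfg),
    )
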