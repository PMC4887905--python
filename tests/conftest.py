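import pytest

from mirspace import evaluation, io, ontology, synthetic

SMALL = dict(
    n_mirnas=60,
    n_diseases=12,
    n_targets=45,
    n_families=6,
    n_words=150,
    n_clusters=3,
    seed=11,
)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    params = synthetic.GeneratorParams(**SMALL)
    return synthetic.generate(params, tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def small_dataset(small_bundle):
    return io.load_bundle(small_bundle.directory)


@pytest.fixture(scope="session")
def small_ontology(small_bundle, small_dataset):
    associations = {rec.id: rec.diseases for rec in small_dataset.mirnas}
    return ontology.build_ontology(small_bundle.paths["tree"], associations)


@pytest.fixture(scope="session")
def small_pipeline(small_dataset, small_ontology):
    return evaluation.Pipeline(small_dataset, small_ontology)
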