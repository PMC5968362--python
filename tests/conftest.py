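import pytest

import phenolex


@pytest.fixture(scope="session")
def default_run():
    """One full discovery run on the reference synthetic corpus.

    Session-scoped because training the embedding dominates the suite's
    runtime; every end-to-end assertion shares this result.
    """
    return phenolex.run_discovery()


@pytest.fixture(scope="session")
def small_corpus():
    """A small seeded corpus for cheap generator-level checks."""
    config = phenolex.GeneratorConfig(
        n_patients=40,
        docs_per_patient_range=(2, 5),
        n_families=8,
        n_pc_families=3,
        background_vocab_size=300,
        seed=99,
    )
    corpus, truth = phenolex.generate_corpus(config)
    return config, corpus, truth
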