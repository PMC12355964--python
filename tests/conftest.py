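import pytest

from kinlit import synth
from kinlit.extraction import reference_extract


ZERO_RATES = {k: 0.0 for k in synth.CORRUPTION_KINDS}


def make_corpus(n_docs=20, seed=0, **rates):
    r = dict(ZERO_RATES)
    r.update(rates)
    return synth.generate_corpus(synth.CorpusSpec(n_docs=n_docs, seed=seed,
                                                  corruption_rates=r))


@pytest.fixture(scope="session")
def clean_corpus():
    """50 uncorrupted documents (the clean round-trip condition)."""
    return make_corpus(n_docs=50, seed=101)


@pytest.fixture(scope="session")
def clean_measurements(clean_corpus):
    return [raw.to_measurement()
            for sd in clean_corpus.docs
            for raw in reference_extract(sd.document)]


@pytest.fixture(scope="session")
def clean_truth_csv(clean_corpus, tmp_path_factory):
    path = tmp_path_factory.mktemp("truth") / "ground_truth.csv"
    synth.emit_ground_truth(clean_corpus).to_csv(path, index=False)
    return path
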