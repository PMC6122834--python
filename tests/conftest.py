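import pytest

import splicedm as sp


@pytest.fixture(scope="session")
def toy_gtf() -> str:
    return sp.make_toy_annotation(n_events_per_type=1, seed=0)


@pytest.fixture(scope="session")
def toy_clusters(toy_gtf):
    return sp.build_gene_clusters(sp.parse_gtf(toy_gtf.splitlines()))


@pytest.fixture(scope="session")
def toy_events(toy_clusters):
    return sp.enumerate_all_events(toy_clusters)


@pytest.fixture(scope="session")
def toy_transcripts(toy_clusters):
    return [t for c in toy_clusters for t in c.transcripts]
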