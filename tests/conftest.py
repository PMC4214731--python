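import dataclasses

import pytest
from hypothesis import settings

import drugnet as dn
from drugnet.entities import load_catalogs

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def chain_net():
    """Path graph A-B-C-D used by the worked scoring examples."""
    return dn.load_network([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture
def cfg():
    return dn.PathScoreConfig()


def _load_benchmark(spec, tmp_path_factory, name):
    outdir = tmp_path_factory.mktemp(name)
    paths = dn.generate_benchmark(spec, outdir)
    net = dn.read_network(paths.network)
    catalogs, assoc, report = load_catalogs(
        paths.drugs, paths.diseases, paths.associations, net
    )
    return {
        "spec": spec,
        "paths": paths,
        "net": net,
        "catalogs": catalogs,
        "assoc": assoc,
        "report": report,
    }


@pytest.fixture(scope="session")
def benchmark(tmp_path_factory):
    """The default planted-signal benchmark (500 nodes, 60 drugs, 20 diseases,
    200 positives, signal 0.8, seed 1)."""
    return _load_benchmark(dn.BenchmarkSpec(), tmp_path_factory, "bench_default")


@pytest.fixture(scope="session")
def null_benchmark(tmp_path_factory):
    """Same conditions with the proximity signal switched off (s = 0)."""
    spec = dataclasses.replace(dn.BenchmarkSpec(), signal=0.0)
    return _load_benchmark(spec, tmp_path_factory, "bench_null")


@pytest.fixture(scope="session")
def small_benchmark(tmp_path_factory):
    """A fast benchmark for CV smoke/determinism tests."""
    spec = dn.BenchmarkSpec(
        n_nodes=150, n_drugs=15, n_diseases=6, n_positive=30,
        genes_per_disease=(3, 6), seed=11,
    )
    return _load_benchmark(spec, tmp_path_factory, "bench_small")
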