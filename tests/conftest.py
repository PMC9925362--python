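import pytest

from ssrscape import benchmark_config, simulate

BENCHMARK_SEED = 42


@pytest.fixture(scope="session")
def benchmark_sim():
    """The standard ~1.1 Mb synthetic genome with >= 200 planted SSRs."""
    return simulate(benchmark_config(seed=BENCHMARK_SEED))


@pytest.fixture(scope="session")
def benchmark_paths(benchmark_sim, tmp_path_factory):
    """The benchmark genome written to FASTA + GFF3 + truth TSV."""
    d = tmp_path_factory.mktemp("benchmark")
    benchmark_sim.write_fasta(d / "genome.fa")
    benchmark_sim.write_gff3(d / "genome.gff3")
    benchmark_sim.write_truth_tsv(d / "truth.tsv")
    return {
        "fasta": d / "genome.fa",
        "gff3": d / "genome.gff3",
        "truth": d / "truth.tsv",
        "dir": d,
    }
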