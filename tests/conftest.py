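import pytest

from ribostar import fixtures as fx


@pytest.fixture(scope="session")
def spec():
    return fx.FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def transcriptome(spec):
    return fx.make_transcriptome(spec)


@pytest.fixture(scope="session")
def riboseq(spec, transcriptome):
    return fx.make_riboseq(spec, transcriptome)


@pytest.fixture(scope="session")
def clip(spec, transcriptome):
    return fx.make_clip(spec, transcriptome)


@pytest.fixture(scope="session")
def fastq_truth(spec):
    return fx.make_fastq(spec)


@pytest.fixture(scope="session")
def fixture_dir(spec, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixtures")
    return fx.write_fixture_files(spec, outdir)
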