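import pytest

from chemmix import (
    DEFAULT_CONFIG,
    generate_fixture,
)


def write(path, text):
    path.write_text(text, encoding="utf-8")
    return path


@pytest.fixture
def links_tsv(tmp_path):
    return write(
        tmp_path / "links.tsv",
        "chemical\tprotein\tcombined_score\n"
        "CID1\t9606.ENSP1\t200\n"
        "CID1\t9606.ENSP2\t450\n"
        "CID1\t9606.ENSP3\t900\n",
    )


@pytest.fixture
def alias_tsv(tmp_path):
    return write(
        tmp_path / "aliases.tsv",
        "CID1\tisoniazid\nCID1\t54-85-3\nCID2\tstavudine\nCID2\t3056-17-5\n",
    )


@pytest.fixture
def map_tsv(tmp_path):
    return write(
        tmp_path / "map.tsv",
        "9606.ENSP1\tCYP19A1\t1588\taromatase\n"
        "9606.ENSP2\tESR1\t2099\testrogen receptor 1\n"
        "9606.ENSP3\tAR\t367\tandrogen receptor\n",
    )


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The frozen default synthetic bundle (seed 42), generated once."""
    outdir = tmp_path_factory.mktemp("fixture42")
    return generate_fixture(DEFAULT_CONFIG, outdir)
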