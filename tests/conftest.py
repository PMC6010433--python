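import pytest

from ligasespace import Msa, SyntheticConfig, generate


@pytest.fixture
def tiny_msa() -> Msa:
    """Six-row toy alignment with a reference row and labels."""
    records = (
        ("REF", "MAC-DEFGHIKLMNPQ"),
        ("LIG1", "MAC-DEFGHIKLMNPQ"),
        ("LIG2", "MACIDEFGHIKLMNPQ"),
        ("PRO1", "MVCWDEFGHIKLMNPQ"),
        ("PRO2", "MVCWDEFGHIKLMNPQ"),
        ("UNK1", "MAC-DEFGHIKLMNPQ"),
    )
    labels = {"LIG1": "ligase", "LIG2": "ligase", "PRO1": "protease", "PRO2": "protease"}
    return Msa(records, labels)


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


@pytest.fixture(scope="session")
def default_synthetic():
    """One default synthetic alignment + truth, shared across tests."""
    config = SyntheticConfig(seed=11)
    msa, truth = generate(config)
    return config, msa, truth
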