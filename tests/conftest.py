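import pytest

from sodfam import synthetic_data


@pytest.fixture(scope="session")
def family_fixture():
    """40+ synthetic proteins, 10 per functional group, 5% background
    divergence away from ligand columns."""
    records, truth = synthetic_data.make_protein_family(
        n_per_group=10, background_mut_rate=0.05, seed=5
    )
    return records, truth


@pytest.fixture(scope="session")
def scanned_family(family_fixture):
    from sodfam import domain_scan

    records, truth = family_fixture
    archs, hits = domain_scan.scan_proteome(records)
    return records, truth, archs, hits
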