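import pytest

from fintegrate.synth import generate_anatomy_template
from fintegrate.taxonomy import TaxonRecord, Taxonomy


@pytest.fixture(scope="session")
def template():
    return generate_anatomy_template()


@pytest.fixture()
def tiny_taxonomy():
    """One family, two genera, four species (Alpha/Beta), plus an order root."""
    return Taxonomy(
        [
            TaxonRecord("T0", "Rootfishes", "order"),
            TaxonRecord("F1", "Alphidae", "family", "T0"),
            TaxonRecord("G1", "Alpha", "genus", "F1", ncbi_id=11),
            TaxonRecord("G2", "Beta", "genus", "F1"),
            TaxonRecord("S1", "Alpha unus", "species", "G1", ncbi_id=101),
            TaxonRecord("S2", "Alpha duo", "species", "G1", ncbi_id=102),
            TaxonRecord("S3", "Beta unus", "species", "G2"),
            TaxonRecord("S4", "Beta duo", "species", "G2", extinct=True),
        ]
    )
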