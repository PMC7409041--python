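import pytest

from viromepipe.io import OrfRecord, pad_lineage
from viromepipe.synthetic import generate_two_site_dataset


def make_orf(
    orf_id="orf1",
    contig_id="c1",
    length=300,
    lineage="",
    function_label="",
    viral_flag=False,
):
    return OrfRecord(
        orf_id=orf_id,
        contig_id=contig_id,
        start=1,
        end=length,
        strand="+",
        length_bp=length,
        lineage=lineage,
        function_label=function_label,
        viral_flag=viral_flag,
    )


LINEAGE_A = "Bacteria;Proteobacteria;c1;o1;f1;g1;s1"
LINEAGE_B = "Bacteria;Bacteroidetes;c2;o2;f2;g2;s2"
LINEAGE_DOMAIN_ONLY = pad_lineage(["Bacteria"])


@pytest.fixture(scope="session")
def small_dataset():
    """Two-site synthetic dataset at reduced size, fixed seed."""
    return generate_two_site_dataset(
        n_taxa=12,
        n_orfs=60,
        library_size=200_000,
        n_populations=10,
        contigs_per_population=3,
        contig_length=400,
        seed=42,
    )
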