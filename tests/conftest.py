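import pytest

from qsalvage.records import ProteinRecord


def make_contig(genome_id, contig_id, families_per_gene, start_index=0):
    """Build a contig's ProteinRecords from a list of family iterables."""
    return [
        ProteinRecord(
            protein_id=f"{genome_id}_{contig_id}_p{i}",
            genome_id=genome_id,
            contig_id=contig_id,
            gene_index=start_index + i,
            strand="+",
            length_aa=300,
            families=frozenset(fams),
        )
        for i, fams in enumerate(families_per_gene)
    ]


@pytest.fixture
def small_pangenome():
    """A 60-genome synthetic pangenome shared by the cheaper integration tests."""
    from qsalvage.synthetic import SyntheticConfig, generate_pangenome

    return generate_pangenome(SyntheticConfig(n_genomes=60, seed=42))
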