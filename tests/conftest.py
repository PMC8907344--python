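import pytest

from acetylome import DEFAULT_DESIGN, ProteinRecord, SiteRecord


@pytest.fixture
def design():
    return DEFAULT_DESIGN


@pytest.fixture
def samples(design):
    return design.sample_ids


def site(accession, gene, peptide, positions, values, samples):
    return SiteRecord(
        protein_accession=accession,
        gene_symbol=gene,
        peptide_sequence=peptide,
        site_positions=tuple(positions),
        intensity=dict(zip(samples, values)),
    )


def protein(accession, gene, values, samples):
    return ProteinRecord(
        protein_accession=accession,
        gene_symbol=gene,
        lfq=dict(zip(samples, values)),
    )


@pytest.fixture
def make_site(samples):
    def _make(accession="P1", gene="G1", peptide="AAKAA", positions=(3,), values=(1, 1, 1, 1)):
        return site(accession, gene, peptide, positions, values, samples)

    return _make


@pytest.fixture
def make_protein(samples):
    def _make(accession="P1", gene="G1", values=(1, 1, 1, 1)):
        return protein(accession, gene, values, samples)

    return _make
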