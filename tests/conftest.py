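import pytest

from fusionscape.gene_model import TranscriptModel
from fusionscape.synthetic import gen_gene_models


@pytest.fixture
def toy_model() -> TranscriptModel:
    """2-exon plus-strand transcript: exon1 100-199, exon2 300-499, ATG at 312."""
    return TranscriptModel(
        transcript_id="T_toy",
        gene_id="G_toy",
        gene_name="TOY",
        chrom="1",
        strand="+",
        exons=[(100, 199), (300, 499)],
        cds_start_genomic=312,
        cds_end_genomic=461,
    )


@pytest.fixture
def toy_gtf(tmp_path):
    attrs = 'gene_id "G_toy"; gene_name "TOY"; transcript_id "T_toy"; gene_biotype "protein_coding";'
    lines = [
        f"1\ttest\texon\t100\t199\t.\t+\t.\t{attrs}",
        f"1\ttest\texon\t300\t499\t.\t+\t.\t{attrs}",
        f"1\ttest\tCDS\t312\t461\t.\t+\t0\t{attrs}",
    ]
    path = tmp_path / "toy.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def default_models():
    return gen_gene_models(seed=0)


@pytest.fixture(scope="session")
def models_by_name(default_models):
    return {m.gene_name: m for m in default_models}
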