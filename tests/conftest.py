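from pathlib import Path

import pytest

from mitocub import extract_pcgs, parse_genbank
from mitocub.ingest import GeneSequence
from mitocub.simulate import SyntheticSpec, synthesize_genome

#: Real GenBank records, fetched once with scripts/fetch_genbank.py into
#: data/genbank/.  The reference-genome acceptance tests require them.
DATA_DIR = Path(__file__).resolve().parent.parent / "data" / "genbank"
REFERENCE_ACCESSION = "NC_062668"


def make_gene(codons, name="cox1", species="Testus testus", strand=1,
              stop_note="complete_TAA"):
    codons = tuple(codons)
    return GeneSequence(gene_name=name, species=species, strand=strand,
                        codons=codons, start_codon=codons[0],
                        stop_note=stop_note, cds_span=3 * len(codons) + 3)


@pytest.fixture(scope="session")
def synthetic_genome(tmp_path_factory):
    """One default 13-gene synthetic mitogenome: (path, spec, truth)."""
    spec = SyntheticSpec(species="Testus testus", seed=42)
    path = tmp_path_factory.mktemp("genomes") / "testus.gb"
    _, truth = synthesize_genome(spec, path)
    return path, spec, truth


@pytest.fixture(scope="session")
def synthetic_genes(synthetic_genome):
    path, spec, truth = synthetic_genome
    return extract_pcgs(parse_genbank(path)), truth
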