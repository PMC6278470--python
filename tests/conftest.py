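from pathlib import Path

import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

DATA_DIR = Path(__file__).resolve().parent.parent / "data"

#: GenBank records of the three study genomes, if the user has fetched them
#: (see README); all tests fall back to synthetic surrogates without them.
ACCESSIONS = {
    "R_officinale": "MH572012",
    "R_tanguticum": "MH572013",
    "R_palmatum": "KR816224",
}


def genbank_path(accession: str) -> Path | None:
    p = DATA_DIR / f"{accession}.gb"
    return p if p.exists() else None


@pytest.fixture(scope="session")
def officinale_record():
    """Parsed MH572012 record, or None when the flat file is absent."""
    from plastid_marker.io_genomes import read_genbank

    path = genbank_path(ACCESSIONS["R_officinale"])
    return read_genbank(path) if path else None


def make_genbank_file(path, seq: str, genes=(), record_id="SYN0001"):
    """Write a minimal GenBank flat file with CDS features for testing."""
    record = SeqRecord(Seq(seq), id=record_id, name=record_id,
                       description="synthetic test record",
                       annotations={"molecule_type": "DNA"})
    for name, start, end, strand in genes:
        feat = SeqFeature(FeatureLocation(start - 1, end, strand=strand),
                          type="CDS", qualifiers={"gene": [name]})
        record.features.append(feat)
        gene_feat = SeqFeature(FeatureLocation(start - 1, end, strand=strand),
                               type="gene", qualifiers={"gene": [name]})
        record.features.append(gene_feat)
    SeqIO.write(record, str(path), "genbank")
    return path
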