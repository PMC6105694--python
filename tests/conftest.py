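import logging

import numpy as np
import pytest
from hypothesis import settings

from mihascan.genome import GenotypeTable, ReferenceTranscript, Variant

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

logging.getLogger("mihascan").setLevel(logging.ERROR)


# one codon per residue, for deterministic back-translation of toy proteins
CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}


def cds_for(protein):
    """CDS encoding *protein* (must start with M) plus a TAA stop."""
    assert protein[0] == "M"
    return "".join(CODON[a] for a in protein) + "TAA"


def random_protein(n, seed=0, fixed=None):
    """Diverse toy protein of length n: distinct 9-mer windows, optional fixed
    residues at chosen positions ({index: residue})."""
    gen = np.random.default_rng(seed)
    residues = ["M"] + list(gen.choice(list("ACDEFGHIKLNPQRSTVWY"), size=n - 1))
    for index, residue in (fixed or {}).items():
        residues[index] = residue
    return "".join(residues)


def make_transcript(cds, transcript_id="TX1", chromosome="chr1", strand="+", offset=100,
                    exons=None):
    """Single- or multi-exon toy transcript holding *cds* on the given strand."""
    if exons is None:
        exons = [(offset, offset + len(cds))]
    return ReferenceTranscript(transcript_id, chromosome, strand, exons, cds)


def snv_at(transcript, cds_offset, alt_base, vid="v1", f=0.5):
    """A plus-strand-transcript SNV expressed as a genomic variant."""
    assert transcript.strand == "+"
    pos = transcript.cds_to_genomic(cds_offset)
    ref = transcript.cds_sequence[cds_offset]
    return Variant(vid, transcript.chromosome, pos, ref, (alt_base,), (f,))


def genotypes_for(samples_to_calls):
    """GenotypeTable from {sample: {variant_id: (hapA, hapB)}}."""
    table = GenotypeTable()
    for sample, calls in samples_to_calls.items():
        for vid, (a, b) in calls.items():
            table.add(sample, vid, a, b)
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
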