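"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's CDS-editing code paths: the proteome
oracle rebuilds the genomic sequence base by base, applies variants on the
chromosome, re-splices and translates; the probability oracles enumerate every
Hardy-Weinberg genotype (or parental-transmission) configuration.
"""

from Bio.Seq import Seq, reverse_complement

STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def naive_haplotype_protein(transcript, selections):
    """Rebuild the chromosome, apply genomic edits, splice, and translate.

    *selections* is a list of (Variant, allele_index>0) carried on the
    haplotype, with non-overlapping REF spans.
    """
    lo = min(s for s, _ in transcript.exons)
    hi = max(e for _, e in transcript.exons)
    # (original genomic position, base); inserted bases inherit the anchor's position
    chromosome = []
    for pos in range(lo, hi):
        cds_off = transcript.genomic_to_cds(pos)
        if cds_off is None:
            base = "N"
        elif transcript.strand == "+":
            base = transcript.cds_sequence[cds_off]
        else:
            base = transcript.cds_sequence[cds_off].translate(_COMPLEMENT)
        chromosome.append((pos, base))

    for variant, allele_index in sorted(selections, key=lambda t: -t[0].position):
        ref = variant.ref_allele
        alt = variant.alt_alleles[allele_index - 1]
        i = next(k for k, (pos, _) in enumerate(chromosome) if pos == variant.position)
        observed = "".join(b for _, b in chromosome[i : i + len(ref)])
        assert observed == ref, f"REF mismatch at {variant.variant_id}"
        replacement = [(variant.position, b) for b in alt]
        chromosome[i : i + len(ref)] = replacement

    exon_positions = set()
    for s, e in transcript.exons:
        exon_positions.update(range(s, e))
    mrna = "".join(b for pos, b in chromosome if pos in exon_positions)
    if transcript.strand == "-":
        mrna = reverse_complement(mrna)
    protein = []
    for i in range(0, len(mrna) - len(mrna) % 3, 3):
        codon = mrna[i : i + 3]
        if codon in STOPS:
            break
        protein.append(str(Seq(codon).translate()))
    return "".join(protein)


def urp_strings(recipient_proteins, donor_proteins, k=9):
    """Set-difference of k-mer windows computed straight from protein strings."""
    def windows(proteins):
        out = set()
        for p in proteins:
            out.update(p[s : s + k] for s in range(len(p) - k + 1))
        return out

    return windows(recipient_proteins) - windows(donor_proteins)


def hwe_pmm_unrelated(f):
    """Enumerate the 9 HWE genotype pairs: P(recipient carries, donor lacks)."""
    genotype_probs = {0: (1 - f) ** 2, 1: 2 * f * (1 - f), 2: f**2}
    total = 0.0
    for g_rec, p_rec in genotype_probs.items():
        for g_don, p_don in genotype_probs.items():
            if g_rec >= 1 and g_don == 0:
                total += p_rec * p_don
    return total


def hwe_pmm_sibling(f):
    """Enumerate parental allele configurations and Mendelian transmissions."""
    import itertools

    total = 0.0
    for alleles in itertools.product((0, 1), repeat=4):  # two alleles per parent
        p_alleles = 1.0
        for a in alleles:
            p_alleles *= f if a else (1 - f)
        pa, pb = alleles[:2], alleles[2:]
        for t in itertools.product((0, 1), repeat=4):  # transmissions
            sib1 = (pa[t[0]], pb[t[1]])
            sib2 = (pa[t[2]], pb[t[3]])
            if any(sib1) and not any(sib2):
                total += p_alleles / 16.0
    return total
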