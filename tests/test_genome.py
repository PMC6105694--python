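"""Transcript/variant readers, input filters, and unique-allele counting."""

import pytest

from conftest import genotypes_for, make_transcript
from mihascan import genome
from mihascan.genome import (
    CohortPair,
    FilterLog,
    GenotypeTable,
    ReferenceTranscript,
    Variant,
    VariantKind,
    count_unique_recipient_variants,
    read_transcripts,
    read_variants,
    write_transcripts,
    write_vcf,
)


def write_annotation(path, rows):
    with open(path, "w") as fh:
        fh.write("#transcript_id\tchromosome\tstrand\texon_start\texon_end\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


class TestReadTranscripts:
    def test_internal_stop_transcripts_are_excluded(self, tmp_path):
        fasta = tmp_path / "t.fasta"
        annot = tmp_path / "t.tsv"
        write_fasta(fasta, {
            "T1": "ATGGATTGCTAA",
            "T2": "ATGTGATGCTAA",  # in-frame TGA at codon 2
            "T3": "ATGAAATTTTGA",
        })
        write_annotation(annot, [
            ("T1", "chr1", "+", 100, 112),
            ("T2", "chr1", "+", 200, 212),
            ("T3", "chr1", "+", 300, 312),
        ])
        log = FilterLog()
        transcripts = read_transcripts(fasta, annot, filter_log=log)
        assert [t.transcript_id for t in transcripts] == ["T1", "T3"]
        assert log["internal_stop"] == 1

    def test_cds_sequence_and_translation(self, tmp_path):
        from mihascan.proteome import translate_cds

        fasta, annot = tmp_path / "t.fasta", tmp_path / "t.tsv"
        write_fasta(fasta, {"T1": "ATGGATTGCTAA"})
        write_annotation(annot, [("T1", "chr1", "+", 100, 112)])
        (tx,) = read_transcripts(fasta, annot)
        assert tx.cds_sequence == "ATGGATTGCTAA"
        assert translate_cds(tx.cds_sequence).protein == "MDC"

    def test_empty_annotation_yields_empty_list(self, tmp_path):
        fasta, annot = tmp_path / "t.fasta", tmp_path / "t.tsv"
        write_fasta(fasta, {"T1": "ATGGATTGCTAA"})
        annot.write_text("")
        assert read_transcripts(fasta, annot) == []

    def test_annotated_transcript_missing_from_fasta_is_skipped_not_fatal(self, tmp_path):
        fasta, annot = tmp_path / "t.fasta", tmp_path / "t.tsv"
        write_fasta(fasta, {"T1": "ATGGATTGCTAA"})
        write_annotation(annot, [("T1", "chr1", "+", 100, 112),
                                 ("T9", "chr1", "+", 500, 512)])
        log = FilterLog()
        transcripts = read_transcripts(fasta, annot, filter_log=log)
        assert [t.transcript_id for t in transcripts] == ["T1"]
        assert log["missing_sequence"] == 1

    def test_malformed_annotation_names_line(self, tmp_path):
        fasta, annot = tmp_path / "t.fasta", tmp_path / "t.tsv"
        write_fasta(fasta, {"T1": "ATGGATTGCTAA"})
        annot.write_text("T1\tchr1\t+\t100\n")
        with pytest.raises(ValueError, match=":1"):
            read_transcripts(fasta, annot)

    def test_round_trip_preserves_transcripts(self, tmp_path):
        original = [
            make_transcript("ATGGATTGCAAATTTTAA", "TA", "chr2", "+",
                            exons=[(50, 59), (70, 79)]),
            make_transcript("ATGCCCGGGTAA", "TB", "chr3", "-", offset=500),
        ]
        write_transcripts(original, tmp_path / "rt.fasta", tmp_path / "rt.tsv")
        reread = read_transcripts(tmp_path / "rt.fasta", tmp_path / "rt.tsv")
        assert len(reread) == 2
        for a, b in zip(sorted(original, key=lambda t: t.transcript_id), reread):
            assert (a.transcript_id, a.chromosome, a.strand, a.exons, a.cds_sequence) == (
                b.transcript_id, b.chromosome, b.strand, b.exons, b.cds_sequence)


class TestCoordinateProjection:
    def test_minus_strand_projection_reverse_complements(self):
        # CDS ATGGATTGCTAA on minus strand: genomic holds its reverse complement
        tx = make_transcript("ATGGATTGCTAA", strand="-", offset=100)
        # genomic base at position 100+11-i corresponds to CDS offset i
        v = Variant("v1", "chr1", 100 + 11 - 4, "T", ("A",), (0.5,))  # CDS A->T at offset 4
        proj = tx.project(v, 1)
        assert proj.cds_start == 4
        assert (proj.cds_ref, proj.cds_alt) == ("A", "T")
        assert proj.kind == VariantKind.MISSENSE_SNV

    def test_nonsense_and_synonymous_classification(self):
        tx = make_transcript("ATGGATTGCTAA")
        stop = tx.project(Variant("v1", "chr1", 100 + 8, "C", ("A",), (0.1,)), 1)
        assert stop.kind == VariantKind.NONSENSE_SNV  # TGC -> TGA
        syn = tx.project(Variant("v2", "chr1", 100 + 5, "T", ("C",), (0.1,)), 1)
        assert syn.kind == VariantKind.SYNONYMOUS_SNV  # GAT -> GAC, both Asp

    def test_indel_classification(self):
        tx = make_transcript("ATGGATTGCAAATTTTAA")
        ins3 = tx.project(Variant("v1", "chr1", 103, "G", ("GCCC",), (0.1,)), 1)
        assert ins3.kind == VariantKind.INFRAME_INSERTION
        del1 = tx.project(Variant("v2", "chr1", 103, "GA", ("G",), (0.1,)), 1)
        assert del1.kind == VariantKind.FRAMESHIFT_DELETION


def _vcf_text(records, samples=("R", "D")):
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=100000>\n"
        '##INFO=<ID=AF,Number=A,Type=Float,Description="AF">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n"
    )
    return header + "".join(records)


class TestReadVariants:
    def _transcript_files(self, tmp_path, cds="ATGGATTGCAAATTTGGGTAA",
                          exons=((100, 109), (120, 132))):
        # two-exon plus-strand transcript
        fasta, annot = tmp_path / "v.fasta", tmp_path / "v.tsv"
        write_fasta(fasta, {"T1": cds})
        write_annotation(annot, [("T1", "chr1", "+", s, e) for s, e in exons])
        return read_transcripts(fasta, annot)

    def test_deletion_crossing_exon_boundary_is_dropped(self, tmp_path):
        transcripts = self._transcript_files(tmp_path)
        vcf = tmp_path / "a.vcf"
        vcf.write_text(_vcf_text([
            "chr1\t106\tdel1\tGCAAAT\tG\t.\t.\t.\tGT\t0|1\t0|0\n",  # spans 105..111 across intron
            "chr1\t105\tsnv1\tT\tA\t.\t.\t.\tGT\t0|1\t0|0\n",
        ]))
        log = FilterLog()
        variants, _ = read_variants(vcf, transcripts, filter_log=log)
        assert [v.variant_id for v in variants] == ["snv1"]
        assert log["beyond_exon"] == 1

    def test_cohort_frequency_computed_when_info_absent(self, tmp_path):
        transcripts = self._transcript_files(tmp_path)
        samples = tuple(f"S{i}" for i in range(10))
        gts = ["0|1", "1|0", "1|1", "0|1", "0|1", "0|0", "0|0", "0|0", "0|0", "0|0"]
        vcf = tmp_path / "b.vcf"
        vcf.write_text(_vcf_text(
            ["chr1\t105\tsnv1\tT\tA\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"], samples))
        variants, genotypes = read_variants(vcf, transcripts)
        assert variants[0].allele_frequencies == (6 / 20,)
        assert genotypes.get("S2", "snv1") == (1, 1)

    def test_info_frequency_takes_precedence(self, tmp_path):
        transcripts = self._transcript_files(tmp_path)
        vcf = tmp_path / "c.vcf"
        vcf.write_text(_vcf_text(
            ["chr1\t105\tsnv1\tT\tA\t.\t.\tAF=0.7\tGT\t0|1\t0|0\n"]))
        variants, _ = read_variants(vcf, transcripts)
        assert variants[0].allele_frequencies[0] == pytest.approx(0.7, abs=1e-6)

    def test_multiallelic_per_allele_frequencies_match_counting_oracle(self, tmp_path):
        transcripts = self._transcript_files(tmp_path)
        samples = ("S0", "S1", "S2", "S3")
        gts = ["0|1", "1|2", "2|2", "0|0"]
        vcf = tmp_path / "d.vcf"
        vcf.write_text(_vcf_text(
            ["chr1\t105\tmulti\tT\tA,C\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"], samples))
        variants, genotypes = read_variants(vcf, transcripts)
        (v,) = variants
        # oracle: count allele occurrences over the 8 chromosomes
        alleles = [int(a) for gt in gts for a in gt.split("|")]
        assert v.allele_frequencies == (alleles.count(1) / 8, alleles.count(2) / 8)
        assert v.alt_alleles == ("A", "C")
        assert genotypes.get("S1", "multi") == (1, 2)

    def test_unphased_genotype_rejected_by_default(self, tmp_path):
        transcripts = self._transcript_files(tmp_path)
        vcf = tmp_path / "e.vcf"
        vcf.write_text(_vcf_text(["chr1\t105\tsnv1\tT\tA\t.\t.\t.\tGT\t0/1\t0|0\n"]))
        with pytest.raises(ValueError, match="unphased"):
            read_variants(vcf, transcripts)
        variants, _ = read_variants(vcf, transcripts, on_unphased="assign")
        assert len(variants) == 1

    def test_interior_snv_never_dropped_by_exon_filter(self, tmp_path):
        transcripts = self._transcript_files(tmp_path)
        records = [f"chr1\t{pos}\ts{pos}\t{'ATGGATTGC'[pos-101]}\tA\t.\t.\t.\tGT\t0|1\t0|0\n"
                   for pos in range(101, 110) if "ATGGATTGC"[pos - 101] != "A"]
        vcf = tmp_path / "f.vcf"
        vcf.write_text(_vcf_text(records))
        log = FilterLog()
        variants, _ = read_variants(vcf, transcripts, filter_log=log)
        assert len(variants) == len(records)
        assert log["beyond_exon"] == 0

    def test_vcf_round_trip(self, tmp_path):
        v1 = Variant("v1", "chr1", 104, "T", ("A",), (0.25,))
        v2 = Variant("v2", "chr1", 122, "TG", ("T", "TGG"), (0.1, 0.05))
        genotypes = genotypes_for({
            "R": {"v1": (0, 1), "v2": (2, 0)},
            "D": {"v1": (1, 1), "v2": (0, 0)},
        })
        path = tmp_path / "rt.vcf"
        write_vcf([v1, v2], genotypes, path)
        transcripts = self._transcript_files(tmp_path)
        variants, reread = read_variants(path, transcripts)
        assert [(v.variant_id, v.position, v.ref_allele, v.alt_alleles) for v in variants] == [
            ("v1", 104, "T", ("A",)), ("v2", 122, "TG", ("T", "TGG"))]
        for v, expected in zip(variants, [(0.25,), (0.1, 0.05)]):
            assert v.allele_frequencies == pytest.approx(expected, abs=1e-6)
        for sid in ("R", "D"):
            for vid in ("v1", "v2"):
                assert reread.get(sid, vid) == genotypes.get(sid, vid)


class TestUniqueRecipientVariants:
    VARIANTS = [
        Variant("v1", "chr1", 10, "A", ("T",), (0.5,)),
        Variant("v2", "chr1", 20, "C", ("G",), (0.5,)),
        Variant("v3", "chr1", 30, "G", ("A", "C"), (0.3, 0.2)),
        Variant("v4", "chr1", 40, "T", ("C",), (0.5,)),
        Variant("v5", "chr1", 50, "A", ("G",), (0.5,)),
    ]

    def test_recipient_specific_allele_counts(self):
        genotypes = genotypes_for({
            "R": {"v1": (0, 1)}, "D": {"v1": (0, 0)}})
        pair = CohortPair("R", "D")
        assert count_unique_recipient_variants(pair, self.VARIANTS[:1], genotypes) == 1

    def test_allele_shared_with_donor_not_counted(self):
        genotypes = genotypes_for({
            "R": {"v1": (1, 1)}, "D": {"v1": (0, 1)}})
        assert count_unique_recipient_variants(
            CohortPair("R", "D"), self.VARIANTS[:1], genotypes) == 0

    def test_five_site_table_matches_brute_force_set_difference(self):
        calls = {
            "R": {"v1": (0, 1), "v2": (1, 1), "v3": (1, 2), "v4": (0, 0), "v5": (1, 0)},
            "D": {"v1": (0, 0), "v2": (0, 1), "v3": (2, 2), "v4": (0, 1), "v5": (1, 1)},
        }
        genotypes = genotypes_for(calls)
        expected = len(
            {(vid, a) for vid, gt in calls["R"].items() for a in gt if a > 0}
            - {(vid, a) for vid, gt in calls["D"].items() for a in gt if a > 0}
        )
        got = count_unique_recipient_variants(CohortPair("R", "D"), self.VARIANTS, genotypes)
        assert got == expected == 2  # v1:1 and v3:1 are recipient-specific; the rest shared

    def test_asymmetric_and_zero_on_identical_genotypes(self):
        calls = {"R": {"v1": (0, 1)}, "D": {"v1": (1, 1)}, "R2": {"v1": (0, 1)}}
        genotypes = genotypes_for(calls)
        assert count_unique_recipient_variants(
            CohortPair("R", "D"), self.VARIANTS[:1], genotypes) == 0
        assert count_unique_recipient_variants(
            CohortPair("D", "R"), self.VARIANTS[:1], genotypes) == 0
        assert count_unique_recipient_variants(
            CohortPair("R", "R2"), self.VARIANTS[:1], genotypes) == 0

    def test_missing_sample_names_the_sample(self):
        genotypes = genotypes_for({"R": {"v1": (0, 1)}})
        with pytest.raises(KeyError, match="GHOST"):
            count_unique_recipient_variants(
                CohortPair("R", "GHOST"), self.VARIANTS[:1], genotypes)
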