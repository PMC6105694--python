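"""Domain types and readers/writers for transcripts, variants, genotypes and cohorts.

Coordinates: VCF positions are 1-based on disk; everything in memory is 0-based
half-open.  The conversion happens exactly once, at the reader/writer boundary.
Strand: ``cds_sequence`` is stored in coding-strand orientation; exon intervals
are genomic (plus-strand) and sorted genomically, so for minus-strand transcripts
CDS order runs through the exon list backwards.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class FilterLog(Counter):
    """Counter of records dropped per reason code, with per-record messages."""

    def __init__(self) -> None:
        super().__init__()
        self.messages: list[str] = []

    def drop(self, reason: str, message: str) -> None:
        self[reason] += 1
        self.messages.append(f"{reason}: {message}")
        logger.info("dropped %s", message)

    def write_summary(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key in sorted(self):
                fh.write(f"{key}\t{self[key]}\n")


class VariantKind(str, Enum):
    """Transcript-relative structural class of a single alternate allele."""

    SYNONYMOUS_SNV = "synonymous_SNV"
    MISSENSE_SNV = "missense_SNV"
    NONSENSE_SNV = "nonsense_SNV"
    INFRAME_INSERTION = "inframe_insertion"
    INFRAME_DELETION = "inframe_deletion"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    OTHER = "other"

    @property
    def is_frameshift(self) -> bool:
        return self in (VariantKind.FRAMESHIFT_INSERTION, VariantKind.FRAMESHIFT_DELETION)

    @property
    def is_truncating(self) -> bool:
        """Alleles expected to truncate the protein (frameshift or premature stop)."""
        return self.is_frameshift or self is VariantKind.NONSENSE_SNV


@dataclass(frozen=True)
class VariantProjection:
    """A variant allele mapped onto a transcript's CDS."""

    cds_start: int
    cds_ref: str
    cds_alt: str
    kind: VariantKind

    @property
    def cds_end(self) -> int:
        return self.cds_start + len(self.cds_ref)


@dataclass
class ReferenceTranscript:
    """A protein-coding transcript: spliced CDS plus its genomic footprint."""

    transcript_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_sequence: str

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        self._cds_to_genomic: list[int] | None = None
        self._genomic_to_cds: dict[int, int] | None = None

    # -- validation ---------------------------------------------------------
    def validate(self) -> str | None:
        """Return a reason code if the transcript violates an invariant, else None."""
        n = len(self.cds_sequence)
        if n < 3 or n % 3 != 0:
            return "bad_length"
        if not set(self.cds_sequence) <= NUCLEOTIDES:
            return "invalid_alphabet"
        if self.strand not in "+-":
            return "bad_strand"
        span = sum(e - s for s, e in self.exons)
        if span != n:
            return "exon_length_mismatch"
        prev_end = -1
        for s, e in self.exons:
            if s >= e or s < prev_end:
                return "bad_exons"
            prev_end = e
        # internal (premature) stop codon; a terminal stop is expected
        for i in range(0, n - 3, 3):
            if self.cds_sequence[i : i + 3] in STOP_CODONS:
                return "internal_stop"
        return None

    # -- coordinate maps ----------------------------------------------------
    def _build_maps(self) -> None:
        order = self.exons if self.strand == "+" else self.exons[::-1]
        positions: list[int] = []
        for s, e in order:
            rng = range(s, e) if self.strand == "+" else range(e - 1, s - 1, -1)
            positions.extend(rng)
        self._cds_to_genomic = positions
        self._genomic_to_cds = {g: i for i, g in enumerate(positions)}

    def cds_to_genomic(self, offset: int) -> int:
        if self._cds_to_genomic is None:
            self._build_maps()
        return self._cds_to_genomic[offset]

    def genomic_to_cds(self, pos: int) -> int | None:
        if self._genomic_to_cds is None:
            self._build_maps()
        return self._genomic_to_cds.get(pos)

    def contains_span(self, start: int, end: int) -> bool:
        """True if the genomic interval [start, end) lies within a single exon."""
        return any(s <= start and end <= e for s, e in self.exons)

    def project(self, variant: "Variant", alt_index: int) -> VariantProjection | None:
        """Map one alternate allele of *variant* onto this transcript's CDS.

        Returns None when the variant's REF span is not fully contained in a
        single exon.  The returned ref/alt strings are in coding-strand
        orientation and are guaranteed to match ``cds_sequence`` at the site.
        """
        ref = variant.ref_allele
        alt = variant.alt_alleles[alt_index - 1]
        g0 = variant.position
        g1 = g0 + len(ref)
        if not self.contains_span(g0, g1):
            return None
        if self.strand == "+":
            cds_start = self.genomic_to_cds(g0)
            cds_ref, cds_alt = ref, alt
        else:
            cds_start = self.genomic_to_cds(g1 - 1)
            cds_ref, cds_alt = reverse_complement(ref), reverse_complement(alt)
        if cds_start is None:
            return None
        found = self.cds_sequence[cds_start : cds_start + len(ref)]
        if found != cds_ref:
            raise ValueError(
                f"variant {variant.variant_id} REF {cds_ref!r} does not match "
                f"transcript {self.transcript_id} CDS {found!r} at offset {cds_start}"
            )
        kind = self._classify(cds_start, cds_ref, cds_alt)
        return VariantProjection(cds_start, cds_ref, cds_alt, kind)

    def _classify(self, cds_start: int, ref: str, alt: str) -> VariantKind:
        if len(ref) == len(alt) == 1:
            frame = cds_start - cds_start % 3
            codon = self.cds_sequence[frame : frame + 3]
            mutated = list(codon)
            mutated[cds_start % 3] = alt
            mutated = "".join(mutated)
            if mutated in STOP_CODONS:
                return VariantKind.NONSENSE_SNV
            if codon in STOP_CODONS:
                return VariantKind.OTHER  # stop-loss, handled at translation
            if str(Seq(codon).translate()) == str(Seq(mutated).translate()):
                return VariantKind.SYNONYMOUS_SNV
            return VariantKind.MISSENSE_SNV
        delta = len(alt) - len(ref)
        if delta == 0:
            return VariantKind.OTHER  # multi-nucleotide substitution
        if delta % 3 == 0:
            return VariantKind.INFRAME_INSERTION if delta > 0 else VariantKind.INFRAME_DELETION
        return VariantKind.FRAMESHIFT_INSERTION if delta > 0 else VariantKind.FRAMESHIFT_DELETION


@dataclass
class Variant:
    """A biallelic-or-multiallelic site with per-alternate population frequencies."""

    variant_id: str
    chromosome: str
    position: int  # 0-based genomic start of the REF span
    ref_allele: str
    alt_alleles: tuple[str, ...]
    allele_frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        self.alt_alleles = tuple(self.alt_alleles)
        self.allele_frequencies = tuple(float(f) for f in self.allele_frequencies)
        if not self.ref_allele or any(not a for a in self.alt_alleles):
            raise ValueError(f"{self.variant_id}: empty allele")
        if len(self.alt_alleles) != len(self.allele_frequencies):
            raise ValueError(f"{self.variant_id}: one frequency per alternate allele required")
        if any(not 0.0 <= f <= 1.0 for f in self.allele_frequencies):
            raise ValueError(f"{self.variant_id}: allele frequency outside [0, 1]")

    def frequency_of(self, allele_index: int) -> float:
        """Population frequency of allele *allele_index* (0 = reference)."""
        if allele_index == 0:
            return max(0.0, 1.0 - sum(self.allele_frequencies))
        return self.allele_frequencies[allele_index - 1]


@dataclass(frozen=True)
class PhasedGenotype:
    sample_id: str
    variant_id: str
    hapA_allele: int
    hapB_allele: int


@dataclass(frozen=True)
class CohortPair:
    """A virtual (recipient, donor) pair."""

    recipient_id: str
    donor_id: str
    relationship: str = "unrelated"

    def __post_init__(self) -> None:
        if self.recipient_id == self.donor_id:
            raise ValueError("recipient and donor must be distinct samples")
        if self.relationship not in ("unrelated", "sibling"):
            raise ValueError(f"unknown relationship {self.relationship!r}")


class GenotypeTable:
    """Phased genotypes per (sample, variant); haplotype A is one chromosome copy."""

    def __init__(self) -> None:
        self._data: dict[str, dict[str, tuple[int, int]]] = {}

    @property
    def samples(self) -> list[str]:
        return sorted(self._data)

    def add(self, sample_id: str, variant_id: str, hap_a: int, hap_b: int) -> None:
        self._data.setdefault(sample_id, {})[variant_id] = (int(hap_a), int(hap_b))

    def get(self, sample_id: str, variant_id: str) -> tuple[int, int]:
        try:
            sample = self._data[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} absent from genotype table") from None
        return sample.get(variant_id, (0, 0))

    def sample_records(self, sample_id: str) -> dict[str, tuple[int, int]]:
        if sample_id not in self._data:
            raise KeyError(f"sample {sample_id!r} absent from genotype table")
        return self._data[sample_id]

    def carried_alleles(self, sample_id: str) -> set[tuple[str, int]]:
        """All (variant_id, allele_index) alternate alleles on either haplotype."""
        out = set()
        for vid, (a, b) in self.sample_records(sample_id).items():
            if a > 0:
                out.add((vid, a))
            if b > 0:
                out.add((vid, b))
        return out

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._data

    def __len__(self) -> int:
        return len(self._data)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_transcripts(
    fasta_path: str | Path,
    annotation_path: str | Path,
    *,
    filter_log: FilterLog | None = None,
) -> list[ReferenceTranscript]:
    """Read CDS sequences (FASTA) plus an exon annotation and apply input filters.

    The annotation is either the native tab-separated exon table
    (``transcript_id  chromosome  strand  exon_start  exon_end``, one exon per
    row, 0-based half-open) or a GFF3 file with CDS features.  Transcripts with
    an internal in-frame stop codon, a CDS not divisible by three, or an exon
    footprint inconsistent with the CDS length are dropped and counted in
    *filter_log*; transcripts annotated but absent from the FASTA are skipped,
    not fatal.
    """
    log = filter_log if filter_log is not None else FilterLog()
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    annotation = _read_annotation(annotation_path)
    if not annotation:
        logger.warning("annotation %s contains no transcripts", annotation_path)
    transcripts: list[ReferenceTranscript] = []
    for tid, (chrom, strand, exons) in annotation.items():
        if tid not in sequences:
            log.drop("missing_sequence", f"transcript {tid} absent from FASTA")
            continue
        tx = ReferenceTranscript(tid, chrom, strand, exons, sequences[tid])
        reason = tx.validate()
        if reason is not None:
            log.drop(reason, f"transcript {tid} failed invariant {reason}")
            continue
        transcripts.append(tx)
    transcripts.sort(key=lambda t: t.transcript_id)
    return transcripts


def _read_annotation(path: str | Path) -> dict[str, tuple[str, str, list[tuple[int, int]]]]:
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_annotation_gff3(path)
    out: dict[str, tuple[str, str, list[tuple[int, int]]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 tab-separated fields, got {len(fields)}")
            tid, chrom, strand, start, end = fields
            try:
                interval = (int(start), int(end))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer exon bound") from exc
            if tid in out:
                if out[tid][0] != chrom or out[tid][1] != strand:
                    raise ValueError(f"{path}:{lineno}: inconsistent chromosome/strand for {tid}")
                out[tid][2].append(interval)
            else:
                out[tid] = (chrom, strand, [interval])
    return out


def _read_annotation_gff3(path: Path) -> dict[str, tuple[str, str, list[tuple[int, int]]]]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique", keep_order=True)
    out: dict[str, tuple[str, str, list[tuple[int, int]]]] = {}
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent") or feat.attributes.get("ID")
        if not parents:
            raise ValueError(f"{path}: CDS feature without Parent/ID at line {feat.start}")
        tid = parents[0]
        interval = (feat.start - 1, feat.end)  # GFF3 is 1-based inclusive
        if tid in out:
            out[tid][2].append(interval)
        else:
            out[tid] = (feat.seqid, feat.strand, [interval])
    return out


def write_transcripts(
    transcripts: Iterable[ReferenceTranscript],
    fasta_path: str | Path,
    annotation_path: str | Path,
) -> None:
    transcripts = list(transcripts)
    with open(fasta_path, "w") as fh:
        for tx in transcripts:
            fh.write(f">{tx.transcript_id}\n")
            for i in range(0, len(tx.cds_sequence), 60):
                fh.write(tx.cds_sequence[i : i + 60] + "\n")
    with open(annotation_path, "w") as fh:
        fh.write("#transcript_id\tchromosome\tstrand\texon_start\texon_end\n")
        for tx in transcripts:
            for s, e in tx.exons:
                fh.write(f"{tx.transcript_id}\t{tx.chromosome}\t{tx.strand}\t{s}\t{e}\n")


def read_variants(
    vcf_path: str | Path,
    transcripts: Sequence[ReferenceTranscript],
    *,
    af_info_key: str = "AF",
    on_unphased: str = "error",
    filter_log: FilterLog | None = None,
) -> tuple[list[Variant], GenotypeTable]:
    """Read phased variants from a VCF, keeping only exon-contained, non-structural sites.

    A variant is retained when its REF span lies fully within a single exon of
    at least one retained transcript; others are counted under ``beyond_exon``.
    Allele frequencies come from the *af_info_key* INFO field when present,
    otherwise they are computed from the cohort's genotype columns (per
    alternate allele); the source used is logged.

    ``on_unphased``: "error" rejects the file on the first unphased genotype,
    "assign" keeps the arbitrary phase pysam reports, with a warning.
    """
    if on_unphased not in ("error", "assign"):
        raise ValueError("on_unphased must be 'error' or 'assign'")
    log = filter_log if filter_log is not None else FilterLog()
    variants: list[Variant] = []
    genotypes = GenotypeTable()
    af_sources = Counter()
    with pysam.VariantFile(str(vcf_path)) as vcf:
        sample_ids = list(vcf.header.samples)
        for rec in vcf:
            vid = rec.id or f"{rec.chrom}:{rec.pos}"
            alts = rec.alts or ()
            if not alts or any(not a or not set(a) <= NUCLEOTIDES for a in alts) or not set(
                rec.ref
            ) <= NUCLEOTIDES:
                log.drop("structural", f"variant {vid} has symbolic/non-ACGT alleles")
                continue
            start, end = rec.start, rec.start + len(rec.ref)
            if not any(tx.chromosome == rec.chrom and tx.contains_span(start, end) for tx in transcripts):
                log.drop("beyond_exon", f"variant {vid} extends beyond exon boundaries")
                continue
            calls = []
            for sid in sample_ids:
                call = rec.samples[sid]
                gt = call["GT"]
                if gt is None or len(gt) != 2 or any(a is None for a in gt):
                    raise ValueError(f"variant {vid}: missing diploid genotype for {sid}")
                if not call.phased:
                    if on_unphased == "error":
                        raise ValueError(
                            f"variant {vid}: unphased genotype for sample {sid} "
                            "(pass on_unphased='assign' to keep arbitrary phase)"
                        )
                    logger.warning("variant %s: arbitrary phase assigned for %s", vid, sid)
                calls.append((sid, gt[0], gt[1]))
            info_af = rec.info.get(af_info_key) if af_info_key in rec.info else None
            if info_af is not None:
                freqs = tuple(float(f) for f in info_af)
                af_sources["info"] += 1
            else:
                n_chrom = 2 * len(calls)
                counts = Counter(a for _, x, y in calls for a in (x, y))
                freqs = tuple(counts.get(i, 0) / n_chrom for i in range(1, len(alts) + 1))
                af_sources["cohort"] += 1
            variants.append(Variant(vid, rec.chrom, start, rec.ref, alts, freqs))
            for sid, a, b in calls:
                genotypes.add(sid, vid, a, b)
    if af_sources:
        logger.info("allele-frequency source: %s", dict(af_sources))
    return variants, genotypes


def write_vcf(
    variants: Sequence[Variant],
    genotypes: GenotypeTable,
    path: str | Path,
    *,
    af_info_key: str = "AF",
) -> None:
    """Write variants and phased genotypes as an uncompressed VCF 4.2 file."""
    header = pysam.VariantHeader()
    contigs = sorted({v.chromosome for v in variants})
    max_pos: dict[str, int] = {}
    for v in variants:
        max_pos[v.chromosome] = max(max_pos.get(v.chromosome, 0), v.position + len(v.ref_allele))
    for chrom in contigs:
        header.contigs.add(chrom, length=max_pos[chrom] + 1000)
    header.info.add(af_info_key, "A", "Float", "Alternate allele frequency in the reference population")
    header.formats.add("GT", 1, "String", "Phased genotype")
    samples = genotypes.samples
    for sid in samples:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (v.chromosome, v.position)):
            rec = out.new_record(
                contig=v.chromosome,
                start=v.position,
                alleles=(v.ref_allele, *v.alt_alleles),
                id=v.variant_id,
            )
            rec.info[af_info_key] = v.allele_frequencies
            for sid in samples:
                a, b = genotypes.get(sid, v.variant_id)
                rec.samples[sid]["GT"] = (a, b)
                rec.samples[sid].phased = True
            out.write(rec)


# ---------------------------------------------------------------------------
# cohort-level helpers
# ---------------------------------------------------------------------------

def assign_variants_to_transcripts(
    transcripts: Sequence[ReferenceTranscript],
    variants: Sequence[Variant],
) -> dict[str, list[Variant]]:
    """Map each transcript id to the variants whose REF span its exons contain."""
    out: dict[str, list[Variant]] = {tx.transcript_id: [] for tx in transcripts}
    for v in variants:
        end = v.position + len(v.ref_allele)
        for tx in transcripts:
            if tx.chromosome == v.chromosome and tx.contains_span(v.position, end):
                out[tx.transcript_id].append(v)
    for lst in out.values():
        lst.sort(key=lambda v: v.position)
    return out


def count_unique_recipient_variants(
    pair: CohortPair,
    variants: Sequence[Variant],
    genotypes: GenotypeTable,
) -> int:
    """Number of alternate alleles carried by the recipient and absent from the donor."""
    known = {v.variant_id for v in variants}
    recipient = {x for x in genotypes.carried_alleles(pair.recipient_id) if x[0] in known}
    donor = genotypes.carried_alleles(pair.donor_id)
    return len(recipient - donor)
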