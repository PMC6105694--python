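"""Build per-haplotype individual proteomes by applying phased alleles to each CDS.

Each sample contributes two haplotype proteins per transcript (haplotype A and
B), obtained by editing the reference CDS with the alternate alleles carried on
that haplotype and translating with the standard genetic code.  Frameshift and
nonsense alleles end translation at the first in-frame stop codon of the new
frame, so the encoded protein is truncated; stop-loss alleles read through to
the end of the provided CDS (no 3'UTR is part of the input contract).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .genome import (
    GenotypeTable,
    ReferenceTranscript,
    Variant,
    VariantKind,
    VariantProjection,
    assign_variants_to_transcripts,
)

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class AppliedAllele:
    """Provenance of one allele applied to a haplotype CDS."""

    variant_id: str
    allele_index: int
    cds_offset: int            # offset of the allele in the *mutated* CDS
    kind: VariantKind
    alt_length: int            # length of the inserted alt string
    ref_cds_start: int = 0     # offset of the allele in the *reference* CDS
    length_delta: int = 0      # len(alt) - len(ref)


@dataclass
class TranslationResult:
    protein: str
    truncated: bool
    stop_lost: bool = False


@dataclass
class HaplotypeProtein:
    sample_id: str
    transcript_id: str
    haplotype: str  # "A" or "B"
    protein_sequence: str
    applied_variants: list[AppliedAllele]
    truncated: bool
    stop_lost: bool = False
    start_lost: bool = False
    # residue intervals [start, end) altered by each applied allele, used for
    # peptide-level provenance downstream
    altered_residues: list[tuple[str, int, int, int]] = field(default_factory=list)
    # residue intervals [start, end) of alternate alleles NOT carried on this
    # haplotype (the haplotype is reference at the site): windows overlapping
    # them can be missing from a sample homozygous for that alternate allele
    site_intervals: list[tuple[str, int, int, int]] = field(default_factory=list)


@dataclass
class IndividualProteome:
    """Both haplotype proteins of one sample over all transcripts, in stable order."""

    sample_id: str
    proteins: list[HaplotypeProtein]

    def __iter__(self):
        return iter(self.proteins)


def translate_cds(sequence: str) -> TranslationResult:
    """Translate a CDS with the standard genetic code, stopping at the first stop.

    ``truncated`` is True when the first in-frame stop precedes the end of the
    sequence or when the frame runs off the end (trailing incomplete codon);
    ``stop_lost`` marks a complete frame with no stop codon at all.
    """
    if not sequence:
        raise ValueError("empty coding sequence")
    bad = next((i for i, c in enumerate(sequence) if c not in _VALID), None)
    if bad is not None:
        raise ValueError(f"non-ACGT character {sequence[bad]!r} at offset {bad}")
    n_full = len(sequence) - len(sequence) % 3
    protein_full = str(Seq(sequence[:n_full]).translate())
    stop = protein_full.find("*")
    if stop >= 0:
        return TranslationResult(protein_full[:stop], truncated=3 * (stop + 1) < len(sequence))
    incomplete = len(sequence) % 3 != 0
    return TranslationResult(protein_full, truncated=incomplete, stop_lost=not incomplete)


def apply_haplotype(
    transcript: ReferenceTranscript,
    phased_alleles: Sequence[tuple[Variant, int]],
) -> tuple[str, list[AppliedAllele], list[str]]:
    """Apply the alternate alleles of one haplotype to the transcript CDS.

    Returns ``(mutated_cds, applied, skipped_variant_ids)``.  Alleles are
    applied right-to-left in CDS coordinates so upstream offsets stay valid;
    when two REF spans overlap on the same haplotype the downstream-most is
    applied and the other skipped (deterministic tie-break, logged).
    """
    projections: list[tuple[VariantProjection, Variant, int]] = []
    for variant, allele_index in phased_alleles:
        if allele_index == 0:
            continue
        proj = transcript.project(variant, allele_index)
        if proj is None:
            raise ValueError(
                f"variant {variant.variant_id} is not projectable onto {transcript.transcript_id}"
            )
        projections.append((proj, variant, allele_index))
    projections.sort(key=lambda t: (t[0].cds_start, t[1].variant_id))

    seq = transcript.cds_sequence
    applied_raw: list[tuple[VariantProjection, Variant, int]] = []
    skipped: list[str] = []
    bound = len(seq)  # start of the most recently applied (leftmost so far) edit
    for proj, variant, allele_index in reversed(projections):
        if proj.cds_end > bound:
            skipped.append(variant.variant_id)
            logger.warning(
                "overlap_conflict: variant %s on %s overlaps a downstream allele; skipped",
                variant.variant_id, transcript.transcript_id,
            )
            continue
        seq = seq[: proj.cds_start] + proj.cds_alt + seq[proj.cds_end :]
        applied_raw.append((proj, variant, allele_index))
        bound = proj.cds_start

    # offsets in the mutated CDS: each edit is shifted by the length deltas of
    # all edits applied strictly upstream of it
    applied_raw.reverse()  # ascending cds_start
    applied: list[AppliedAllele] = []
    shift = 0
    for proj, variant, allele_index in applied_raw:
        applied.append(
            AppliedAllele(
                variant_id=variant.variant_id,
                allele_index=allele_index,
                cds_offset=proj.cds_start + shift,
                kind=proj.kind,
                alt_length=len(proj.cds_alt),
                ref_cds_start=proj.cds_start,
                length_delta=len(proj.cds_alt) - len(proj.cds_ref),
            )
        )
        shift += len(proj.cds_alt) - len(proj.cds_ref)
    return seq, applied, skipped


def _altered_residue_interval(allele: AppliedAllele, protein_length: int) -> tuple[int, int]:
    """Residue window [start, end) whose identity can differ from reference."""
    first = allele.cds_offset // 3
    if allele.kind.is_frameshift:
        return min(first, protein_length), protein_length
    last_nt = allele.cds_offset + max(allele.alt_length, 1) - 1
    return min(first, protein_length), min(last_nt // 3 + 1, protein_length)


def build_haplotype_protein(
    sample_id: str,
    transcript: ReferenceTranscript,
    haplotype: str,
    phased_alleles: Sequence[tuple[Variant, int]],
    site_variants: Sequence[tuple["Variant", int]] = (),
) -> HaplotypeProtein:
    """Mutate and translate one haplotype of one transcript.

    *phased_alleles* are the (variant, allele_index) pairs carried on this
    haplotype; *site_variants* optionally lists every (variant, carried allele)
    at the transcript's sites, so the non-carried alternate alleles can be
    annotated as potential donor-side causes of peptide uniqueness.
    """
    mutated, applied, _ = apply_haplotype(transcript, phased_alleles)
    start_lost = bool(applied) and mutated[:3] != "ATG" and transcript.cds_sequence[:3] == "ATG"
    if start_lost:
        logger.warning(
            "start_lost: %s haplotype %s of %s; empty protein emitted",
            transcript.transcript_id, haplotype, sample_id,
        )
        result = TranslationResult("", truncated=True)
    else:
        result = translate_cds(mutated)
    hp = HaplotypeProtein(
        sample_id=sample_id,
        transcript_id=transcript.transcript_id,
        haplotype=haplotype,
        protein_sequence=result.protein,
        applied_variants=applied,
        truncated=result.truncated,
        stop_lost=result.stop_lost,
        start_lost=start_lost,
    )
    n = len(result.protein)
    for allele in applied:
        lo, hi = _altered_residue_interval(allele, n)
        hp.altered_residues.append((allele.variant_id, allele.allele_index, lo, hi))

    # map each non-carried alternate allele into this haplotype's residue
    # coordinates; downstream of an applied frameshift the reference frame no
    # longer exists, so such sites are dropped (those windows are recipient-
    # novel and already covered by the frameshift's own interval)
    fs_boundary = min(
        (a.ref_cds_start for a in applied if a.kind.is_frameshift), default=None
    )
    for variant, carried in site_variants:
        if carried != 0:
            continue  # the haplotype shows the alternate allele, not reference
        for ai in range(1, len(variant.alt_alleles) + 1):
            proj = transcript.project(variant, ai)
            if proj is None:
                continue
            p = proj.cds_start
            if fs_boundary is not None and p >= fs_boundary:
                continue
            offset = p + sum(a.length_delta for a in applied if a.ref_cds_start < p)
            lo = offset // 3
            if proj.kind.is_truncating:
                hi = n
            else:
                hi = min((offset + len(proj.cds_ref) - 1) // 3 + 1, n)
            lo = min(lo, n)
            if hi > lo:
                hp.site_intervals.append((variant.variant_id, ai, lo, hi))
    return hp


def build_proteome(
    sample_id: str,
    transcripts: Sequence[ReferenceTranscript],
    variants: Sequence[Variant],
    genotypes: GenotypeTable,
    *,
    transcript_variants: Mapping[str, Sequence[Variant]] | None = None,
) -> IndividualProteome:
    """Translate both haplotypes of every transcript for one sample.

    Homozygous-reference transcripts are still emitted: they contribute the
    reference peptides of the sample's peptidome.  *transcript_variants* may be
    precomputed with :func:`assign_variants_to_transcripts` and reused across
    samples.
    """
    if transcript_variants is None:
        transcript_variants = assign_variants_to_transcripts(transcripts, variants)
    proteins: list[HaplotypeProtein] = []
    for tx in sorted(transcripts, key=lambda t: t.transcript_id):
        site_variants = transcript_variants.get(tx.transcript_id, ())
        calls = [(v, genotypes.get(sample_id, v.variant_id)) for v in site_variants]
        for hap_index, hap_name in ((0, "A"), (1, "B")):
            selection = [(v, gt[hap_index]) for v, gt in calls if gt[hap_index] > 0]
            sites = [(v, gt[hap_index]) for v, gt in calls]
            proteins.append(
                build_haplotype_protein(sample_id, tx, hap_name, selection, site_variants=sites)
            )
    return IndividualProteome(sample_id, proteins)
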