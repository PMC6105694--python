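"""k-mer peptidomes, donor-subtracted unique recipient peptides (URPs),
polymorphism classification, frequency profiling, saturation and MS intersection.

A URP is a peptide string present somewhere in the recipient's peptidome (any
transcript, either haplotype) and absent from the donor's entire peptidome.
Distinct-peptide semantics hold throughout: a string appearing in two
transcripts is one URP with merged provenance.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome import (
    CohortPair,
    GenotypeTable,
    ReferenceTranscript,
    Variant,
    VariantKind,
)
from .proteome import IndividualProteome

logger = logging.getLogger(__name__)

# polymorphism classes of a URP
SINGLE_NSSNP = "single_nsSNP"
ADJACENT_NSSNPS = "adjacent_nsSNPs"
INFRAME_INDEL = "inframe_indel"
FRAMESHIFT_RECIPIENT = "frameshift_recipient"
HOM_FRAMESHIFT_DONOR = "homozygous_frameshift_donor"
HOM_NONSENSE_DONOR = "homozygous_nonsense_donor"
COMBINATION = "combination"
ALL_CLASSES = (
    SINGLE_NSSNP,
    ADJACENT_NSSNPS,
    INFRAME_INDEL,
    FRAMESHIFT_RECIPIENT,
    HOM_FRAMESHIFT_DONOR,
    HOM_NONSENSE_DONOR,
    COMBINATION,
)
NSSNP_CLASSES = (SINGLE_NSSNP, ADJACENT_NSSNPS)

# allele-frequency bins of the encoding polymorphism
FREQUENCY_BINS = ("f<0.01", "0.01<=f<0.1", "0.1<=f<=0.9", "f>0.9")


def frequency_bin(f: float) -> str:
    if f < 0.01:
        return FREQUENCY_BINS[0]
    if f < 0.1:
        return FREQUENCY_BINS[1]
    if f <= 0.9:
        return FREQUENCY_BINS[2]
    return FREQUENCY_BINS[3]


@dataclass(frozen=True)
class PeptideOccurrence:
    peptide: str
    sample_id: str
    transcript_id: str
    haplotype: str
    start_offset: int
    covering_variants: frozenset[tuple[str, int]]
    # alternate alleles NOT carried here whose site overlaps the window: if the
    # donor is homozygous for one of them, this reference-encoded window is
    # absent from the donor
    ref_site_overlaps: frozenset[tuple[str, int]] = frozenset()


@dataclass
class Peptidome:
    """All k-mer occurrences of one sample, with the distinct-string set view."""

    sample_id: str
    k: int
    occurrences: list[PeptideOccurrence]
    peptides: set[str] = field(init=False)
    by_peptide: dict[str, list[PeptideOccurrence]] = field(init=False)

    def __post_init__(self) -> None:
        self.by_peptide = defaultdict(list)
        for occ in self.occurrences:
            self.by_peptide[occ.peptide].append(occ)
        self.peptides = set(self.by_peptide)

    def __len__(self) -> int:
        return len(self.peptides)


@dataclass
class URPRecord:
    peptide: str
    causal_variants: frozenset[tuple[str, int]]
    polymorphism_class: str | None = None
    encoding_allele_frequency: float | None = None
    pmm: float | None = None
    therapeutic_tier: float | None = None
    occurrences: tuple[PeptideOccurrence, ...] = ()

    @property
    def transcript_ids(self) -> set[str]:
        return {occ.transcript_id for occ in self.occurrences}


@dataclass
class PolymorphismClassProfile:
    class_counts: dict[str, int]
    class_shares: dict[str, float]
    nssnp_bin_counts: dict[str, int]
    nssnp_bin_shares: dict[str, float]
    n_urps: int


def extract_peptides(proteome: IndividualProteome, k: int = 9) -> Peptidome:
    """Cut every haplotype protein into overlapping k-mers.

    A protein of length L contributes max(0, L-k+1) occurrences; each
    occurrence records the variants whose altered residues overlap its window.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    occurrences: list[PeptideOccurrence] = []
    for hp in proteome:
        protein = hp.protein_sequence
        n = len(protein)
        intervals = [(vid, ai, lo, hi) for vid, ai, lo, hi in hp.altered_residues if hi > lo]
        sites = [(vid, ai, lo, hi) for vid, ai, lo, hi in hp.site_intervals if hi > lo]
        for start in range(n - k + 1):
            end = start + k
            covering = frozenset(
                (vid, ai) for vid, ai, lo, hi in intervals if lo < end and hi > start
            )
            overlaps = frozenset(
                (vid, ai) for vid, ai, lo, hi in sites if lo < end and hi > start
            )
            occurrences.append(
                PeptideOccurrence(
                    peptide=protein[start:end],
                    sample_id=proteome.sample_id,
                    transcript_id=hp.transcript_id,
                    haplotype=hp.haplotype,
                    start_offset=start,
                    covering_variants=covering,
                    ref_site_overlaps=overlaps,
                )
            )
    return Peptidome(proteome.sample_id, k, occurrences)


def subtract_peptidomes(recipient: Peptidome, donor: Peptidome) -> list[URPRecord]:
    """Donor-subtracted unique recipient peptides, with provenance attached.

    The polymorphism class is left unset; causal variants are the union of
    covering variants over the recipient occurrences of each unique string
    (donor-shared alleles are pruned later, during classification, which needs
    the pair's genotypes).
    """
    if recipient.k != donor.k:
        raise ValueError(f"peptidome k mismatch: {recipient.k} != {donor.k}")
    urps: list[URPRecord] = []
    for peptide in sorted(recipient.peptides - donor.peptides):
        occs = tuple(recipient.by_peptide[peptide])
        covering = frozenset().union(*(o.covering_variants for o in occs))
        urps.append(URPRecord(peptide=peptide, causal_variants=covering, occurrences=occs))
    return urps


@dataclass
class PairContext:
    """Pair-level lookups needed to classify URPs and assign frequencies."""

    pair: CohortPair
    variants_by_id: dict[str, Variant]
    donor_alleles: set[tuple[str, int]]
    donor_homozygous: set[tuple[str, int]]  # (variant_id, allele) with donor GT ai|ai
    kinds: dict[tuple[str, str, int], VariantKind]  # (transcript, variant, allele) -> kind

    @classmethod
    def build(
        cls,
        pair: CohortPair,
        transcripts: Sequence[ReferenceTranscript],
        variants: Sequence[Variant],
        genotypes: GenotypeTable,
        *,
        transcript_variants: Mapping[str, Sequence[Variant]] | None = None,
    ) -> "PairContext":
        from .genome import assign_variants_to_transcripts

        if transcript_variants is None:
            transcript_variants = assign_variants_to_transcripts(transcripts, variants)
        kinds: dict[tuple[str, str, int], VariantKind] = {}
        tx_by_id = {tx.transcript_id: tx for tx in transcripts}
        donor_hom: set[tuple[str, int]] = set()
        for tid, site_variants in transcript_variants.items():
            tx = tx_by_id[tid]
            for v in site_variants:
                a, b = genotypes.get(pair.donor_id, v.variant_id)
                if a == b and a > 0:
                    donor_hom.add((v.variant_id, a))
                for ai in range(1, len(v.alt_alleles) + 1):
                    proj = tx.project(v, ai)
                    if proj is not None:
                        kinds[(tid, v.variant_id, ai)] = proj.kind
        return cls(
            pair=pair,
            variants_by_id={v.variant_id: v for v in variants},
            donor_alleles=genotypes.carried_alleles(pair.donor_id),
            donor_homozygous=donor_hom,
            kinds=kinds,
        )

    def kind_of(self, transcript_ids: Iterable[str], vid: str, ai: int) -> VariantKind:
        for tid in transcript_ids:
            kind = self.kinds.get((tid, vid, ai))
            if kind is not None:
                return kind
        return VariantKind.OTHER


# rule categories a causal allele can contribute, by side and structural kind
_RECIPIENT_RULES = {
    VariantKind.MISSENSE_SNV: "nssnp",
    VariantKind.INFRAME_INSERTION: "inframe",
    VariantKind.INFRAME_DELETION: "inframe",
    VariantKind.FRAMESHIFT_INSERTION: "fs_recipient",
    VariantKind.FRAMESHIFT_DELETION: "fs_recipient",
}
_DONOR_RULES = {
    VariantKind.MISSENSE_SNV: "nssnp",
    VariantKind.INFRAME_INSERTION: "inframe",
    VariantKind.INFRAME_DELETION: "inframe",
    VariantKind.FRAMESHIFT_INSERTION: "hom_fs_donor",
    VariantKind.FRAMESHIFT_DELETION: "hom_fs_donor",
    VariantKind.NONSENSE_SNV: "hom_stop_donor",
}
_RULE_TO_CLASS = {
    "inframe": INFRAME_INDEL,
    "fs_recipient": FRAMESHIFT_RECIPIENT,
    "hom_fs_donor": HOM_FRAMESHIFT_DONOR,
    "hom_stop_donor": HOM_NONSENSE_DONOR,
}


def classify_urps(urps: Sequence[URPRecord], ctx: PairContext) -> list[URPRecord]:
    """Assign a polymorphism class and encoding allele frequency to each URP.

    Two sides can make a recipient peptide unique.  Recipient-side: a covering
    alternate allele the donor lacks (the peptide shows the variant residues;
    its encoding allele is that alternate allele).  Donor-side: the peptide is
    reference-encoded, but the donor is homozygous for an overlapping
    protein-changing allele — a missense substitution, an indel, or a
    truncating allele that removes the region altogether (its encoding allele
    is the reference allele, frequency 1 - f of the donor's allele).  One rule
    matched gives the specific class; several give "combination".  The
    encoding allele frequency is the minimum over causal alleles (conservative
    for the mismatch probability).  Unclassifiable URPs fall back to
    "combination" with a diagnostic log, never silently dropped.
    """
    out = []
    for urp in urps:
        tids = urp.transcript_ids
        recipient_causal = {
            (vid, ai)
            for vid, ai in urp.causal_variants
            if (vid, ai) not in ctx.donor_alleles
            and ctx.kind_of(tids, vid, ai) is not VariantKind.SYNONYMOUS_SNV
        }
        donor_causal = {
            (vid, ai)
            for occ in urp.occurrences
            for vid, ai in occ.ref_site_overlaps
            if (vid, ai) in ctx.donor_homozygous
            and ctx.kind_of(tids, vid, ai) is not VariantKind.SYNONYMOUS_SNV
        }
        rules: set[str] = set()
        n_missense = 0
        unknown = False
        for vid, ai in recipient_causal:
            kind = ctx.kind_of(tids, vid, ai)
            rule = _RECIPIENT_RULES.get(kind)
            if rule is None:
                unknown = True
            else:
                rules.add(rule)
                n_missense += rule == "nssnp"
        for vid, ai in donor_causal:
            kind = ctx.kind_of(tids, vid, ai)
            rule = _DONOR_RULES.get(kind)
            if rule is None:
                unknown = True
            else:
                rules.add(rule)
                n_missense += rule == "nssnp"
        if not rules:
            cls = COMBINATION
            logger.warning(
                "URP %s has no identifiable cause; classified as combination", urp.peptide
            )
        elif unknown or len(rules) > 1:
            cls = COMBINATION
        elif rules == {"nssnp"}:
            cls = SINGLE_NSSNP if n_missense == 1 else ADJACENT_NSSNPS
        else:
            cls = _RULE_TO_CLASS[rules.pop()]
        frequencies = [
            ctx.variants_by_id[vid].frequency_of(ai) for vid, ai in recipient_causal
        ] + [
            ctx.variants_by_id[vid].frequency_of(0) for vid, ai in donor_causal
        ]
        urp.polymorphism_class = cls
        urp.encoding_allele_frequency = min(frequencies, default=0.0)
        urp.causal_variants = frozenset(recipient_causal | donor_causal) or urp.causal_variants
        out.append(urp)
    return out


def profile_pair(urps: Sequence[URPRecord]) -> PolymorphismClassProfile:
    """Per-class URP shares plus the nsSNP encoding-frequency bin shares."""
    class_counts = {c: 0 for c in ALL_CLASSES}
    bin_counts = {b: 0 for b in FREQUENCY_BINS}
    for urp in urps:
        if urp.polymorphism_class is None:
            raise ValueError("profile_pair requires classified URPs")
        class_counts[urp.polymorphism_class] += 1
        if urp.polymorphism_class in NSSNP_CLASSES:
            bin_counts[frequency_bin(urp.encoding_allele_frequency)] += 1
    n = len(urps)
    n_ns = sum(bin_counts.values())
    if n == 0:
        logger.warning("profile_pair: empty URP set; all shares reported as zero")
    class_shares = {c: (k / n if n else 0.0) for c, k in class_counts.items()}
    bin_shares = {b: (k / n_ns if n_ns else 0.0) for b, k in bin_counts.items()}
    return PolymorphismClassProfile(class_counts, class_shares, bin_counts, bin_shares, n)


def saturation_curve(
    pair_urp_sets: Sequence[Iterable[URPRecord]],
) -> pd.DataFrame:
    """Cumulative distinct-URP counts as pairs are added, per frequency bin.

    Pair order is the given order; shuffle upstream (seeded) to average curves.
    Returns a DataFrame with one row per prefix length n and columns
    ``n_pairs``, ``overall`` and one per frequency bin.
    """
    if not pair_urp_sets:
        raise ValueError("saturation_curve requires at least one pair")
    seen: set[str] = set()
    bin_seen: dict[str, set[str]] = {b: set() for b in FREQUENCY_BINS}
    rows = []
    for n, urps in enumerate(pair_urp_sets, start=1):
        for urp in urps:
            seen.add(urp.peptide)
            if urp.encoding_allele_frequency is not None:
                bin_seen[frequency_bin(urp.encoding_allele_frequency)].add(urp.peptide)
        rows.append(
            {"n_pairs": n, "overall": len(seen), **{b: len(s) for b, s in bin_seen.items()}}
        )
    return pd.DataFrame(rows)


def intersect_with_peptide_list(
    urps: Sequence[URPRecord],
    peptide_list: Iterable[str],
    *,
    k: int = 9,
) -> tuple[list[URPRecord], dict[str, int], int]:
    """Exact-string intersection of URPs with an external (e.g. MS-observed) list.

    Returns the matched records (provenance kept), a histogram of their
    encoding-allele frequencies over the standard bins, and the number of
    list entries skipped for not being k-mers over the amino-acid alphabet.
    """
    valid = set("ACDEFGHIKLMNPQRSTVWY")
    wanted: set[str] = set()
    skipped = 0
    for entry in peptide_list:
        entry = entry.strip().upper()
        if not entry:
            continue
        if len(entry) != k or not set(entry) <= valid:
            skipped += 1
            continue
        wanted.add(entry)
    matched = [u for u in urps if u.peptide in wanted]
    histogram = {b: 0 for b in FREQUENCY_BINS}
    for u in matched:
        if u.encoding_allele_frequency is not None:
            histogram[frequency_bin(u.encoding_allele_frequency)] += 1
    return matched, histogram, skipped
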