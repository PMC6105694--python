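"""Synthetic cohort generator: every input the pipeline needs, from one seed.

Emulates the statistical structure of phase-3-style population data at desk
scale: coding transcripts (start codon, no internal stop, terminal stop),
exonic variants of a configurable type mixture with true allele frequencies
drawn from a stated spectrum, phased diploid cohorts under Hardy-Weinberg
equilibrium, sibling pairs by Mendelian transmission from simulated parents
(one transmission draw per parent per child per chromosome, no recombination),
plus anchor-motif PSSMs and proteome-sampled background peptides.

The same config and seed reproduce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq, reverse_complement

from .binding import AMINO_ACIDS, PSSM
from .genome import (
    STOP_CODONS,
    CohortPair,
    GenotypeTable,
    ReferenceTranscript,
    Variant,
)
from .proteome import translate_cds

SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS
)
VARIANT_TYPES = ("missense", "adjacent_missense", "inframe_indel", "frameshift", "nonsense")


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    The defaults describe a desk-scale cohort dominated by missense SNVs (the
    variant class behind the vast majority of recipient-unique peptides in
    population data) with a uniform allele-frequency spectrum.
    """

    seed: int = 0
    n_transcripts: int = 30
    transcript_length_range: tuple[int, int] = (60, 120)  # coding codons, excl. stop
    n_variants: int = 300
    variant_type_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "missense": 0.80,
            "adjacent_missense": 0.05,
            "inframe_indel": 0.05,
            "frameshift": 0.05,
            "nonsense": 0.05,
        }
    )
    frequency_spectrum: object = "uniform"  # "uniform" | ("point", f) | ("truncated_1_over_f", f_min)
    n_samples: int = 50
    relationship_structure: str = "unrelated"  # "unrelated" | "sibling_families"

    def __post_init__(self) -> None:
        total = sum(self.variant_type_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("variant type mixture proportions must sum to 1")
        if set(self.variant_type_mixture) - set(VARIANT_TYPES):
            raise ValueError(f"unknown variant types in mixture; allowed: {VARIANT_TYPES}")
        lo, hi = self.transcript_length_range
        if lo < 12 or hi < lo:
            raise ValueError("transcript length range must satisfy 12 <= lo <= hi")
        if self.relationship_structure not in ("unrelated", "sibling_families"):
            raise ValueError("relationship_structure must be 'unrelated' or 'sibling_families'")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def draw_frequency(spectrum, rng: np.random.Generator) -> float:
    """One allele frequency from a named spectrum preset."""
    if spectrum == "uniform":
        return float(rng.uniform(0.0, 1.0))
    if isinstance(spectrum, tuple) and spectrum:
        if spectrum[0] == "point":
            return float(spectrum[1])
        if spectrum[0] == "truncated_1_over_f":
            f_min = float(spectrum[1])
            # inverse-CDF sampling of the density ~ 1/f on [f_min, 1]
            return float(f_min ** (1.0 - rng.uniform()))
    raise ValueError(f"unknown frequency spectrum {spectrum!r}")


# ---------------------------------------------------------------------------
# reference transcripts
# ---------------------------------------------------------------------------

def generate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[ReferenceTranscript]:
    """Random coding transcripts: ATG + uniform sense codons + one stop codon.

    Each transcript sits on its own chromosome, split into 1-3 exons with
    random intron gaps, on a random strand.
    """
    rng = rng if rng is not None else config.rng()
    lo, hi = config.transcript_length_range
    transcripts = []
    for i in range(config.n_transcripts):
        n_codons = int(rng.integers(lo, hi + 1))
        body = "".join(rng.choice(SENSE_CODONS, size=n_codons - 1))
        stop = str(rng.choice(sorted(STOP_CODONS)))
        cds = "ATG" + body + stop
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 4))
        cuts = sorted(rng.choice(np.arange(1, len(cds)), size=n_exons - 1, replace=False)) if n_exons > 1 else []
        chunk_lengths = np.diff([0, *map(int, cuts), len(cds)])
        # CDS-order chunks; lay them genomically left-to-right for +, right-to-left for -
        genomic_chunks = chunk_lengths if strand == "+" else chunk_lengths[::-1]
        pos = int(rng.integers(100, 1000))
        exons = []
        for length in genomic_chunks:
            exons.append((pos, pos + int(length)))
            pos += int(length) + int(rng.integers(50, 200))  # intron
        transcripts.append(
            ReferenceTranscript(
                transcript_id=f"TX{i:04d}",
                chromosome=f"chr{i + 1}",
                strand=strand,
                exons=exons,
                cds_sequence=cds,
            )
        )
    return transcripts


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def _cds_edit_to_variant(
    tx: ReferenceTranscript, vid: str, cds_start: int, cds_ref: str, cds_alt: str, f: float
) -> Variant | None:
    """Express a CDS-space replacement as a genomic VCF-style variant.

    Returns None when the edited span does not sit inside a single exon (the
    caller resamples).  On minus-strand transcripts the shared anchor base ends
    up genomically right-most; the record is still a valid replacement and
    round-trips through the reader.
    """
    positions = [tx.cds_to_genomic(cds_start + i) for i in range(len(cds_ref))]
    g0, g1 = min(positions), max(positions) + 1
    if g1 - g0 != len(cds_ref) or not tx.contains_span(g0, g1):
        return None
    if tx.strand == "+":
        ref, alt = cds_ref, cds_alt
    else:
        ref, alt = reverse_complement(cds_ref), reverse_complement(cds_alt)
    return Variant(vid, tx.chromosome, g0, ref, (alt,), (f,))


def _random_missense_edit(cds: str, codon_index: int, rng) -> tuple[int, str, str] | None:
    codon = cds[3 * codon_index : 3 * codon_index + 3]
    choices = [
        (off, base)
        for off in range(3)
        for base in "ACGT"
        if base != codon[off]
    ]
    rng.shuffle(choices)
    for off, base in choices:
        mutated = codon[:off] + base + codon[off + 1 :]
        if mutated in STOP_CODONS:
            continue
        if str(Seq(mutated).translate()) != str(Seq(codon).translate()):
            return 3 * codon_index + off, codon[off], base
    return None


def _random_nonsense_edit(cds: str, codon_index: int, rng) -> tuple[int, str, str] | None:
    codon = cds[3 * codon_index : 3 * codon_index + 3]
    choices = [(off, base) for off in range(3) for base in "ACGT" if base != codon[off]]
    rng.shuffle(choices)
    for off, base in choices:
        if codon[:off] + base + codon[off + 1 :] in STOP_CODONS:
            return 3 * codon_index + off, codon[off], base
    return None


def generate_variant_set(
    config: SimulationConfig,
    transcripts: Sequence[ReferenceTranscript],
    rng: np.random.Generator | None = None,
) -> tuple[list[Variant], dict[str, str]]:
    """Exonic variants of the configured type mixture with true frequencies.

    Positions are uniform over coding positions excluding the start and stop
    codons; missense labels are guaranteed nonsynonymous by construction
    (synonymous proposals are resampled).  Returns the variants and a map
    variant_id -> declared type, the ground truth for classifier tests.
    Raises when the requested count cannot be placed.
    """
    rng = rng if rng is not None else config.rng()
    types = sorted(config.variant_type_mixture)
    probs = [config.variant_type_mixture[t] for t in types]
    occupied: dict[str, set[int]] = {tx.transcript_id: set() for tx in transcripts}
    variants: list[Variant] = []
    labels: dict[str, str] = {}
    counter = 0
    consecutive_failures = 0
    max_consecutive_failures = 2000

    def reserve(tx_id: str, start: int, end: int) -> bool:
        span = set(range(start - 1, end + 1))
        if span & occupied[tx_id]:
            return False
        occupied[tx_id] |= span
        return True

    while counter < config.n_variants:
        if consecutive_failures > max_consecutive_failures:
            raise ValueError(
                f"could not place {config.n_variants} variants on the available "
                f"coding positions; placed {counter}"
            )
        vtype = str(rng.choice(types, p=probs))
        tx = transcripts[int(rng.integers(len(transcripts)))]
        cds = tx.cds_sequence
        n_codons = len(cds) // 3
        f = draw_frequency(config.frequency_spectrum, rng)
        made: list[tuple[int, str, str]] = []

        if vtype in ("missense", "nonsense"):
            codon_index = int(rng.integers(1, n_codons - 1))
            maker = _random_missense_edit if vtype == "missense" else _random_nonsense_edit
            edit = maker(cds, codon_index, rng)
            if edit is None:
                consecutive_failures += 1
                continue
            made.append(edit)
        elif vtype == "adjacent_missense":
            if counter + 2 > config.n_variants:
                vtype = "missense"
            c1 = int(rng.integers(1, max(2, n_codons - 10)))
            c2 = c1 + int(rng.integers(1, 9))
            if c2 >= n_codons - 1:
                consecutive_failures += 1
                continue
            e1 = _random_missense_edit(cds, c1, rng)
            e2 = _random_missense_edit(cds, c2, rng)
            if e1 is None or e2 is None:
                consecutive_failures += 1
                continue
            made.extend([e1, e2])
        elif vtype == "inframe_indel":
            length = 3
            if rng.random() < 0.5:  # insertion after an anchor base
                o = int(rng.integers(3, len(cds) - 3))
                ins = "".join(rng.choice(list("ACGT"), size=length))
                made.append((o, cds[o], cds[o] + ins))
            else:  # deletion with a left anchor in CDS space
                o = int(rng.integers(4, len(cds) - 3 - length))
                made.append((o - 1, cds[o - 1 : o + length], cds[o - 1]))
        elif vtype == "frameshift":
            length = int(rng.integers(1, 3))
            if rng.random() < 0.5:
                o = int(rng.integers(3, len(cds) - 3))
                ins = "".join(rng.choice(list("ACGT"), size=length))
                made.append((o, cds[o], cds[o] + ins))
            else:
                o = int(rng.integers(4, len(cds) - 3 - length))
                made.append((o - 1, cds[o - 1 : o + length], cds[o - 1]))

        new_variants = []
        ok = True
        for cds_start, cds_ref, cds_alt in made:
            vid = f"var{counter + len(new_variants):05d}"
            variant = _cds_edit_to_variant(tx, vid, cds_start, cds_ref, cds_alt, f)
            if variant is None or not reserve(tx.transcript_id, cds_start, cds_start + len(cds_ref)):
                ok = False
                break
            new_variants.append(variant)
        if not ok or not new_variants:
            consecutive_failures += 1
            continue
        consecutive_failures = 0
        for v in new_variants:
            variants.append(v)
            labels[v.variant_id] = vtype
        counter += len(new_variants)
    variants.sort(key=lambda v: (v.chromosome, v.position))
    return variants, labels


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def generate_cohort(
    config: SimulationConfig,
    variants: Sequence[Variant],
    rng: np.random.Generator | None = None,
    *,
    n_samples: int | None = None,
    sample_prefix: str = "S",
) -> GenotypeTable:
    """Phased genotypes under Hardy-Weinberg equilibrium.

    Each haplotype carries the alternate allele independently with probability
    f, independently across variants and samples.
    """
    rng = rng if rng is not None else config.rng()
    n = n_samples if n_samples is not None else config.n_samples
    table = GenotypeTable()
    freqs = np.array([v.allele_frequencies[0] for v in variants])
    draws = rng.random((n, len(variants), 2)) < freqs[None, :, None]
    for i in range(n):
        sid = f"{sample_prefix}{i:04d}"
        for j, v in enumerate(variants):
            table.add(sid, v.variant_id, int(draws[i, j, 0]), int(draws[i, j, 1]))
    return table


def disjoint_pairs(samples: Sequence[str], relationship: str = "unrelated") -> list[CohortPair]:
    """Pair samples disjointly (each sample used at most once)."""
    return [
        CohortPair(samples[2 * i], samples[2 * i + 1], relationship)
        for i in range(len(samples) // 2)
    ]


def generate_sibling_pairs(
    config: SimulationConfig,
    variants: Sequence[Variant],
    n_pairs: int,
    rng: np.random.Generator | None = None,
    *,
    sample_prefix: str = "SIB",
) -> tuple[GenotypeTable, list[CohortPair]]:
    """Sibling pairs by Mendelian transmission from HWE-drawn parents.

    For each family, both parents' haplotypes are drawn under HWE; each sibling
    receives one uniformly chosen haplotype from each parent, with a single
    transmission draw per parent per child per chromosome (no recombination).
    """
    rng = rng if rng is not None else config.rng()
    table = GenotypeTable()
    pairs: list[CohortPair] = []
    chroms = sorted({v.chromosome for v in variants})
    chrom_index = {c: i for i, c in enumerate(chroms)}
    freqs = np.array([v.allele_frequencies[0] for v in variants])
    for fam in range(n_pairs):
        parent_a = rng.random((len(variants), 2)) < freqs[:, None]
        parent_b = rng.random((len(variants), 2)) < freqs[:, None]
        # transmission[child, parent, chromosome] -> which parental haplotype
        transmission = rng.integers(0, 2, size=(2, 2, len(chroms)))
        sibling_ids = (f"{sample_prefix}{fam:04d}a", f"{sample_prefix}{fam:04d}b")
        for child, sid in enumerate(sibling_ids):
            for j, v in enumerate(variants):
                c = chrom_index[v.chromosome]
                hap_a = parent_a[j, transmission[child, 0, c]]
                hap_b = parent_b[j, transmission[child, 1, c]]
                table.add(sid, v.variant_id, int(hap_a), int(hap_b))
        pairs.append(CohortPair(sibling_ids[0], sibling_ids[1], "sibling"))
    return table, pairs


def simulate_mismatch_fraction(
    f: float,
    n_pairs: int,
    relationship: str = "unrelated",
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo fraction of pairs mismatched at a single HWE site.

    The brute-force counterpart of the closed-form model: recipient carries the
    allele, donor does not.  Vectorised, so 10^5-10^6 replicates are cheap.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if relationship == "unrelated":
        recipient = (rng.random((n_pairs, 2)) < f).any(axis=1)
        donor = (rng.random((n_pairs, 2)) < f).any(axis=1)
    elif relationship == "sibling":
        parent_a = rng.random((n_pairs, 2)) < f
        parent_b = rng.random((n_pairs, 2)) < f
        t = rng.integers(0, 2, size=(n_pairs, 2, 2))  # [pair, child, parent]
        idx = np.arange(n_pairs)
        recipient = parent_a[idx, t[:, 0, 0]] | parent_b[idx, t[:, 0, 1]]
        donor = parent_a[idx, t[:, 1, 0]] | parent_b[idx, t[:, 1, 1]]
    else:
        raise ValueError(f"unknown relationship {relationship!r}")
    return float(np.mean(recipient & ~donor))


# ---------------------------------------------------------------------------
# binding inputs
# ---------------------------------------------------------------------------

def generate_pssm(
    k: int = 9,
    motif_entropy: float = 0.2,
    rng: np.random.Generator | None = None,
    *,
    allele_name: str = "HLA-X*00:01",
    anchor_positions: tuple[int, ...] | None = None,
) -> PSSM:
    """A class-I-like anchor-motif PSSM.

    Anchor positions (2 and k by 1-based convention, like real class I motifs)
    prefer one residue; ``motif_entropy`` in [0, 1] scales how flat that
    preference is (0 = sharp anchors, 1 = no anchors).
    """
    rng = rng if rng is not None else np.random.default_rng()
    if not 0.0 <= motif_entropy <= 1.0:
        raise ValueError("motif_entropy must lie in [0, 1]")
    anchors = anchor_positions if anchor_positions is not None else (1, k - 1)
    weights = rng.normal(0.0, 0.25, size=(k, len(AMINO_ACIDS)))
    for pos in anchors:
        preferred = int(rng.integers(len(AMINO_ACIDS)))
        weights[pos, preferred] += 4.0 * (1.0 - motif_entropy)
    return PSSM(allele_name=allele_name, weights=weights, provenance="synthetic anchor-motif matrix")


def sample_background_peptides(
    transcripts: Sequence[ReferenceTranscript],
    n: int,
    k: int = 9,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Peptides sampled uniformly from the reference proteome's k-mer windows."""
    rng = rng if rng is not None else np.random.default_rng()
    proteins = [translate_cds(tx.cds_sequence).protein for tx in transcripts]
    windows = [(i, s) for i, p in enumerate(proteins) for s in range(len(p) - k + 1)]
    if not windows:
        raise ValueError(f"reference proteome has no {k}-mer windows")
    picks = rng.integers(0, len(windows), size=n)
    return [proteins[windows[j][0]][windows[j][1] : windows[j][1] + k] for j in picks]


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def simulate_inputs(config: SimulationConfig, outdir: str | Path, *, k: int = 9) -> dict[str, Path]:
    """Generate and write every pipeline input below *outdir*; returns the paths."""
    from . import genome
    from .binding import write_pssm

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng()
    transcripts = generate_reference(config, rng)
    variants, labels = generate_variant_set(config, transcripts, rng)
    if config.relationship_structure == "sibling_families":
        genotypes, pairs = generate_sibling_pairs(config, variants, config.n_samples // 2, rng)
    else:
        genotypes = generate_cohort(config, variants, rng)
        pairs = disjoint_pairs(genotypes.samples)
    pssm = generate_pssm(k=k, rng=rng)
    background = sample_background_peptides(transcripts, n=10_000, k=k, rng=rng)

    paths = {
        "fasta": outdir / "transcripts.fasta",
        "annotation": outdir / "transcripts.annotation.tsv",
        "vcf": outdir / "cohort.vcf",
        "pssm": outdir / "pssm.tsv",
        "background": outdir / "background_peptides.txt",
        "pairs": outdir / "pairs.tsv",
        "variant_types": outdir / "variant_types.tsv",
    }
    genome.write_transcripts(transcripts, paths["fasta"], paths["annotation"])
    genome.write_vcf(variants, genotypes, paths["vcf"])
    write_pssm(pssm, paths["pssm"])
    paths["background"].write_text("\n".join(background) + "\n")
    with open(paths["pairs"], "w") as fh:
        fh.write("#recipient_id\tdonor_id\trelationship\n")
        for pair in pairs:
            fh.write(f"{pair.recipient_id}\t{pair.donor_id}\t{pair.relationship}\n")
    with open(paths["variant_types"], "w") as fh:
        fh.write("#variant_id\tdeclared_type\n")
        for vid in sorted(labels):
            fh.write(f"{vid}\t{labels[vid]}\n")
    return paths
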