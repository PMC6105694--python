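"""Orchestration of the full workflow over a donor/recipient cohort.

Per pair: individual proteomes -> k-mer peptidomes -> donor-subtracted URP set
with polymorphism classes and mismatch probabilities -> optional MHC-binding
calls per HLA with two-predictor consensus.  Per cohort: per-pair counts with
mean +/- SD, the distinct-URP union, saturation curves per frequency bin, the
observed per-variant mismatch fraction against the closed-form model, and the
sibling-vs-unrelated fold comparison when both groups are present.

All tables are tab-separated UTF-8 with a header row and "." for missing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import SB, WB, BindingCall, PSSM, ThresholdCalibration, classify_binders, consensus_filter
from .genome import (
    CohortPair,
    GenotypeTable,
    ReferenceTranscript,
    Variant,
    assign_variants_to_transcripts,
)
from .mismatch import assign_pmm, pmm
from .peptidome import (
    PairContext,
    PolymorphismClassProfile,
    URPRecord,
    classify_urps,
    extract_peptides,
    profile_pair,
    saturation_curve,
    subtract_peptidomes,
)
from .proteome import build_proteome

MISSING = "."


@dataclass
class RunConfig:
    """Knobs of one analysis run; captured verbatim in the output manifest."""

    k: int = 9
    relationship: str = "unrelated"
    pmm_thresholds: tuple[float, float] = (0.1, 0.2)
    p_strong: float = 0.005
    p_weak: float = 0.02
    consensus_level: str = SB
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pmm_thresholds[0] < self.pmm_thresholds[1]:
            raise ValueError("pmm thresholds must be ordered")
        if not self.p_strong < self.p_weak:
            raise ValueError("p_strong must be < p_weak")


@dataclass
class PairResult:
    pair: CohortPair
    urps: list[URPRecord]
    profile: PolymorphismClassProfile
    recipient_peptidome_size: int
    urp_table: pd.DataFrame
    binding_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    consensus: dict[str, set[str]] = field(default_factory=dict)


def _urp_table(urps: Sequence[URPRecord]) -> pd.DataFrame:
    rows = []
    for u in sorted(urps, key=lambda u: u.peptide):
        rows.append(
            {
                "peptide": u.peptide,
                "polymorphism_class": u.polymorphism_class or MISSING,
                "causal_variants": ";".join(f"{v}:{a}" for v, a in sorted(u.causal_variants)) or MISSING,
                "encoding_allele_frequency": u.encoding_allele_frequency,
                "pmm": u.pmm,
                "therapeutic_tier": u.therapeutic_tier if u.therapeutic_tier is not None else MISSING,
            }
        )
    columns = [
        "peptide", "polymorphism_class", "causal_variants",
        "encoding_allele_frequency", "pmm", "therapeutic_tier",
    ]
    return pd.DataFrame(rows, columns=columns)


def run_pair_analysis(
    pair: CohortPair,
    transcripts: Sequence[ReferenceTranscript],
    variants: Sequence[Variant],
    genotypes: GenotypeTable,
    config: RunConfig | None = None,
    *,
    predictors: Sequence[tuple[PSSM, ThresholdCalibration]] = (),
    transcript_variants: Mapping[str, Sequence[Variant]] | None = None,
) -> PairResult:
    """The per-pair workflow: proteomes, peptidomes, URPs, classes, P_mm, binding."""
    config = config or RunConfig()
    if transcript_variants is None:
        transcript_variants = assign_variants_to_transcripts(transcripts, variants)
    relationship = pair.relationship if pair.relationship in ("unrelated", "sibling") else config.relationship

    recipient = build_proteome(pair.recipient_id, transcripts, variants, genotypes,
                               transcript_variants=transcript_variants)
    donor = build_proteome(pair.donor_id, transcripts, variants, genotypes,
                           transcript_variants=transcript_variants)
    recipient_pep = extract_peptides(recipient, k=config.k)
    donor_pep = extract_peptides(donor, k=config.k)
    urps = subtract_peptidomes(recipient_pep, donor_pep)
    ctx = PairContext.build(pair, transcripts, variants, genotypes,
                            transcript_variants=transcript_variants)
    urps = classify_urps(urps, ctx)
    urps = assign_pmm(urps, relationship, therapeutic_thresholds=config.pmm_thresholds)
    profile = profile_pair(urps)

    result = PairResult(
        pair=pair,
        urps=urps,
        profile=profile,
        recipient_peptidome_size=len(recipient_pep),
        urp_table=_urp_table(urps),
    )
    calls_by_allele: dict[str, list[BindingCall]] = {}
    for pssm, calibration in predictors:
        calls = classify_binders(urps, pssm, calibration)
        calls_by_allele[pssm.allele_name] = calls
        result.binding_tables[pssm.allele_name] = pd.DataFrame(
            [{"peptide": c.peptide, "allele": c.allele_name, "score": c.score,
              "category": c.category} for c in calls]
        )
    if len(predictors) == 2:
        a, b = (p.allele_name for p, _ in predictors)
        for level in (SB, WB):
            result.consensus[level] = consensus_filter(
                calls_by_allele[a], calls_by_allele[b], level
            )
    return result


@dataclass
class CohortResult:
    per_pair: pd.DataFrame
    distinct_urps: int
    saturation: pd.DataFrame
    mismatch_observed: pd.DataFrame
    class_share_mean: dict[str, float]
    fold_unrelated_over_sibling: float | None = None

    @property
    def mean_urps(self) -> float:
        return float(self.per_pair["n_urps"].mean())

    @property
    def sd_urps(self) -> float:
        return float(self.per_pair["n_urps"].std(ddof=1)) if len(self.per_pair) > 1 else 0.0


def observed_mismatch_fractions(
    pairs: Sequence[CohortPair],
    variants: Sequence[Variant],
    genotypes: GenotypeTable,
) -> pd.DataFrame:
    """Fraction of pairs mismatched per variant (recipient has the allele, donor
    lacks it) next to the model expectation for the pair relationship mix."""
    rows = []
    for v in variants:
        hits = 0
        for pair in pairs:
            ra, rb = genotypes.get(pair.recipient_id, v.variant_id)
            da, db = genotypes.get(pair.donor_id, v.variant_id)
            for ai in range(1, len(v.alt_alleles) + 1):
                if ai in (ra, rb) and ai not in (da, db):
                    hits += 1
                    break
        f = v.allele_frequencies[0]
        relationship = pairs[0].relationship if pairs else "unrelated"
        rows.append(
            {
                "variant_id": v.variant_id,
                "allele_frequency": f,
                "observed_fraction": hits / len(pairs) if pairs else float("nan"),
                "expected_pmm": pmm(f, relationship),
            }
        )
    return pd.DataFrame(rows)


def run_cohort_analysis(
    pairs: Sequence[CohortPair],
    transcripts: Sequence[ReferenceTranscript],
    variants: Sequence[Variant],
    genotypes: GenotypeTable,
    config: RunConfig | None = None,
    *,
    predictors: Sequence[tuple[PSSM, ThresholdCalibration]] = (),
) -> CohortResult:
    if len(pairs) < 2:
        raise ValueError("cohort analysis requires at least 2 pairs")
    config = config or RunConfig()
    transcript_variants = assign_variants_to_transcripts(transcripts, variants)
    results = [
        run_pair_analysis(p, transcripts, variants, genotypes, config,
                          predictors=predictors, transcript_variants=transcript_variants)
        for p in pairs
    ]
    per_pair = pd.DataFrame(
        {
            "recipient_id": [r.pair.recipient_id for r in results],
            "donor_id": [r.pair.donor_id for r in results],
            "relationship": [r.pair.relationship for r in results],
            "n_urps": [len(r.urps) for r in results],
            "recipient_peptidome": [r.recipient_peptidome_size for r in results],
            "urp_fraction": [
                len(r.urps) / r.recipient_peptidome_size if r.recipient_peptidome_size else np.nan
                for r in results
            ],
        }
    )
    union = set()
    for r in results:
        union.update(u.peptide for u in r.urps)
    saturation = saturation_curve([r.urps for r in results])
    mismatch = observed_mismatch_fractions(pairs, variants, genotypes)
    share_mean = {
        cls: float(np.mean([r.profile.class_shares[cls] for r in results]))
        for cls in results[0].profile.class_shares
    }
    fold = None
    groups = per_pair.groupby("relationship")["n_urps"].mean()
    if {"unrelated", "sibling"} <= set(groups.index) and groups["sibling"] > 0:
        fold = float(groups["unrelated"] / groups["sibling"])
    return CohortResult(
        per_pair=per_pair,
        distinct_urps=len(union),
        saturation=saturation,
        mismatch_observed=mismatch,
        class_share_mean=share_mean,
        fold_unrelated_over_sibling=fold,
    )


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def write_manifest(config: RunConfig, outdir: Path, extra: dict | None = None) -> Path:
    manifest = {
        "tool": "mihascan",
        "version": __version__,
        "config": dataclasses.asdict(config),
        **(extra or {}),
    }
    path = outdir / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path


def write_pair_report(result: PairResult, outdir: str | Path, config: RunConfig | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(result.urp_table, outdir / "urps.tsv")
    for allele, table in result.binding_tables.items():
        safe = allele.replace("*", "").replace(":", "")
        _write_tsv(table, outdir / f"urips.{safe}.tsv")
    profile_rows = [
        {"class": cls, "count": result.profile.class_counts[cls],
         "share": result.profile.class_shares[cls]}
        for cls in result.profile.class_counts
    ]
    _write_tsv(pd.DataFrame(profile_rows), outdir / "polymorphism_classes.tsv")
    if config is not None:
        write_manifest(config, outdir, {"recipient": result.pair.recipient_id,
                                        "donor": result.pair.donor_id})


def write_cohort_report(result: CohortResult, outdir: str | Path, config: RunConfig | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(result.per_pair, outdir / "per_pair_counts.tsv")
    _write_tsv(result.saturation, outdir / "saturation.tsv")
    _write_tsv(result.mismatch_observed, outdir / "mismatch_observed.tsv")
    summary = {
        "n_pairs": len(result.per_pair),
        "mean_urps": result.mean_urps,
        "sd_urps": result.sd_urps,
        "distinct_urps": result.distinct_urps,
        "fold_unrelated_over_sibling": result.fold_unrelated_over_sibling,
    }
    with open(outdir / "summary.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        for key, value in summary.items():
            fh.write(f"{key}\t{MISSING if value is None else value}\n")
    if config is not None:
        write_manifest(config, outdir, {"n_pairs": len(result.per_pair)})


def read_pairs_table(path: str | Path) -> list[CohortPair]:
    """Read a tab-separated pairs file: recipient_id, donor_id[, relationship]."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            relationship = fields[2] if len(fields) > 2 else "unrelated"
            pairs.append(CohortPair(fields[0], fields[1], relationship))
    return pairs
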