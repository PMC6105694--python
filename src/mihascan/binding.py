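"""PSSM-based MHC class I binding prediction with percentile-calibrated cutoffs.

The scorer is a plain additive position-specific scoring matrix; any external
predictor can be plugged in by providing scores for the same peptide universe.
Strong/weak binder cutoffs are calibrated so that a chosen fraction of a
background sample (peptides drawn from the reference proteome) scores at or
above them — the percentile convention the field's rank thresholds use
(defaults 0.005 and 0.02).  A peptide tied with the cutoff is a binder; tie
ranks resolve toward the stricter (higher) cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

SB = "SB"
WB = "WB"
NON_BINDER = "non-binder"


@dataclass
class PSSM:
    """Per-allele k x 20 additive scoring matrix over the standard residues."""

    allele_name: str
    weights: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != len(AMINO_ACIDS):
            raise ValueError("PSSM weights must have shape (k, 20)")

    @property
    def k(self) -> int:
        return self.weights.shape[0]


@dataclass
class ThresholdCalibration:
    allele_name: str
    strong_cutoff: float
    weak_cutoff: float
    background_size: int
    p_strong: float
    p_weak: float

    def __post_init__(self) -> None:
        if self.strong_cutoff < self.weak_cutoff:
            raise ValueError("strong cutoff must be >= weak cutoff")
        if not self.p_strong < self.p_weak:
            raise ValueError("p_strong must be < p_weak")


@dataclass(frozen=True)
class BindingCall:
    peptide: str
    allele_name: str
    score: float
    category: str  # SB, WB or non-binder; SB peptides are WB by definition

    @property
    def is_weak_or_better(self) -> bool:
        return self.category in (SB, WB)


def score_peptide(pssm: PSSM, peptide: str) -> float:
    """Additive PSSM score: sum over positions of the residue weight."""
    if len(peptide) != pssm.k:
        raise ValueError(f"peptide length {len(peptide)} != PSSM length {pssm.k}")
    total = 0.0
    for pos, residue in enumerate(peptide):
        idx = _AA_INDEX.get(residue)
        if idx is None:
            raise ValueError(f"nonstandard residue {residue!r} at position {pos}")
        total += pssm.weights[pos, idx]
    return total


def score_peptides(pssm: PSSM, peptides: Sequence[str]) -> np.ndarray:
    """Vectorised scoring of many equal-length peptides."""
    if not peptides:
        return np.empty(0)
    try:
        idx = np.array([[_AA_INDEX[r] for r in p] for p in peptides])
    except KeyError as exc:
        raise ValueError(f"nonstandard residue {exc.args[0]!r}") from None
    if idx.shape[1] != pssm.k:
        raise ValueError("peptide length does not match the PSSM")
    return pssm.weights[np.arange(pssm.k), idx].sum(axis=1)


def _top_fraction_cutoff(scores_desc: np.ndarray, p: float) -> float:
    """Largest score c with |{s >= c}| <= ceil(p*N); ties push the cutoff up."""
    n = len(scores_desc)
    m = math.ceil(p * n)
    values, counts = np.unique(scores_desc, return_counts=True)  # ascending
    at_or_above = counts[::-1].cumsum()[::-1]  # per distinct value
    ok = np.nonzero(at_or_above <= m)[0]
    if len(ok) == 0:
        # degenerate background (massive ties at the maximum): strictest cutoff
        return float(values[-1])
    return float(values[ok[0]])


def calibrate_thresholds(
    pssm: PSSM,
    background_peptides: Sequence[str],
    p_strong: float = 0.005,
    p_weak: float = 0.02,
) -> ThresholdCalibration:
    """Calibrate SB/WB score cutoffs as top-p order statistics of a background.

    The cutoffs are chosen so the background fraction scoring at or above each
    cutoff is at most p + 1/N (a peptide tied with the cutoff is a binder).
    """
    n = len(background_peptides)
    minimum = math.ceil(1.0 / p_strong)
    if n < minimum:
        raise ValueError(f"background too small: {n} peptides, need >= {minimum}")
    scores = np.sort(score_peptides(pssm, background_peptides))[::-1]
    strong = _top_fraction_cutoff(scores, p_strong)
    weak = _top_fraction_cutoff(scores, p_weak)
    return ThresholdCalibration(pssm.allele_name, strong, min(weak, strong), n, p_strong, p_weak)


def categorize(score: float, calibration: ThresholdCalibration) -> str:
    if score >= calibration.strong_cutoff:
        return SB
    if score >= calibration.weak_cutoff:
        return WB
    return NON_BINDER


def classify_binders(
    peptides: Iterable,
    pssm: PSSM,
    calibration: ThresholdCalibration,
    *,
    drop_non_binders: bool = False,
) -> list[BindingCall]:
    """Score and categorize peptides (strings or URP records) against one allele."""
    seqs = [p if isinstance(p, str) else p.peptide for p in peptides]
    scores = score_peptides(pssm, seqs)
    calls = [
        BindingCall(pep, pssm.allele_name, float(s), categorize(float(s), calibration))
        for pep, s in zip(seqs, scores)
    ]
    if drop_non_binders:
        calls = [c for c in calls if c.category != NON_BINDER]
    return calls


def _call_map(calls: Iterable[BindingCall] | Mapping[str, str]) -> dict[str, str]:
    if isinstance(calls, Mapping):
        return dict(calls)
    return {c.peptide: c.category for c in calls}


def consensus_filter(
    calls_predictor1: Iterable[BindingCall] | Mapping[str, str],
    calls_predictor2: Iterable[BindingCall] | Mapping[str, str],
    level: str = SB,
) -> set[str]:
    """Peptides called at >= *level* stringency by BOTH predictors.

    ``level`` is "SB" (both strong) or "WB" (both at least weak; strong counts).
    The two call sets must cover the same peptide universe.
    """
    if level not in (SB, WB):
        raise ValueError("level must be 'SB' or 'WB'")
    m1, m2 = _call_map(calls_predictor1), _call_map(calls_predictor2)
    if set(m1) != set(m2):
        diff = len(set(m1) ^ set(m2))
        raise ValueError(f"predictor call sets cover different universes ({diff} peptides differ)")
    accepted = (SB,) if level == SB else (SB, WB)
    return {p for p in m1 if m1[p] in accepted and m2[p] in accepted}


@dataclass
class CodominanceResult:
    n_codominant: int
    n_dominant: int

    @property
    def ratio(self) -> float:
        if self.n_dominant == 0:
            return math.inf
        return self.n_codominant / self.n_dominant


def codominance_ratio(
    allelic_peptides: Mapping[str, tuple[Iterable[str], Iterable[str]]],
    binders: set[str] | Callable[[str], bool],
    *,
    exclude_RK: bool = False,
) -> CodominanceResult:
    """Co-dominant / dominant ratio over biallelic nsSNPs.

    ``allelic_peptides`` maps each nsSNP id to the two allelic 9-mer variant
    sets (counterpart peptides built by swapping the allele).  An nsSNP is
    co-dominant when at least one peptide from EACH allelic set passes the
    binding level, dominant when only one side passes.  With ``exclude_RK``,
    peptides containing arginine or lysine are removed before counting (to
    factor out the increased proteasomal cleavage of R/K-containing peptides).
    A zero dominant count yields an infinite ratio, reported with the counts.
    """
    passes = binders if callable(binders) else (lambda p: p in binders)
    n_co = n_dom = 0
    for snp_id, (side_a, side_b) in allelic_peptides.items():
        sides = []
        for peptides in (side_a, side_b):
            pool = [p for p in peptides if not (exclude_RK and ("R" in p or "K" in p))]
            sides.append(any(passes(p) for p in pool))
        if all(sides):
            n_co += 1
        elif any(sides):
            n_dom += 1
    return CodominanceResult(n_co, n_dom)


# ---------------------------------------------------------------------------
# plain-text matrix i/o
# ---------------------------------------------------------------------------

def write_pssm(pssm: PSSM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#allele\t{pssm.allele_name}\n")
        if pssm.provenance:
            fh.write(f"#provenance\t{pssm.provenance}\n")
        fh.write("pos\t" + "\t".join(AMINO_ACIDS) + "\n")
        for pos in range(pssm.k):
            row = "\t".join(f"{w:.6g}" for w in pssm.weights[pos])
            fh.write(f"{pos + 1}\t{row}\n")


def read_pssm(path: str | Path) -> PSSM:
    allele = ""
    provenance = ""
    rows: list[list[float]] = []
    column_order: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#allele"):
                allele = line.split("\t", 1)[1]
            elif line.startswith("#provenance"):
                provenance = line.split("\t", 1)[1]
            elif line.startswith("pos\t"):
                column_order = line.split("\t")[1:]
                if sorted(column_order) != sorted(AMINO_ACIDS):
                    raise ValueError(f"{path}:{lineno}: PSSM must cover the 20 standard residues")
            elif not line.startswith("#"):
                fields = line.split("\t")
                if column_order is None or len(fields) != len(column_order) + 1:
                    raise ValueError(f"{path}:{lineno}: malformed PSSM row")
                rows.append([float(x) for x in fields[1:]])
    if not rows:
        raise ValueError(f"{path}: no PSSM rows found")
    raw = np.array(rows)
    weights = np.empty_like(raw)
    for j, aa in enumerate(column_order):
        weights[:, _AA_INDEX[aa]] = raw[:, j]
    return PSSM(allele_name=allele or Path(path).stem, weights=weights, provenance=provenance)
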