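# Methods

## Problem and model

Minor histocompatibility antigens arise when a polymorphic coding allele makes
the recipient's immunopeptidome differ from the donor's. The package treats
each peptide as uniquely determined by the haplotype sequence of its source
transcript, so the computation factorises into (i) deterministic sequence
algebra — apply phased alleles, translate, cut into k-mers, subtract — and
(ii) a population model for how often a given peptide is mismatched between
two genomes.

For a peptide encoded by an allele at population frequency `f`, assuming
Hardy–Weinberg equilibrium and independence of the two genomes, the mismatch
probability for unrelated pairs is

    P_mm(f) = f(1−f)²(2−f) = u(1−u),  u = (1−f)²,

the product of P(recipient carries the allele) = 1−(1−f)² and P(donor lacks
it) = (1−f)². For sibling pairs the two genomes share parents; enumerating
parental genotypes and Mendelian transmissions gives

    P_mm^sib(f) = (1−f)² f (4−f)/4.

Both formulas are implemented directly and verified in the tests against
brute-force enumeration oracles (the 9-genotype HWE table; the 256-term
parental-allele × transmission table) and against vectorised Monte-Carlo
simulation. Key analytic facts used downstream: the unrelated maximum is 1/4
at `f* = 1 − 1/√2`; the sibling maximum is `≈ 0.1362` at `f* = (7 − √33)/4`;
the ratio `P_mm/P_mm^sib = 4(2−f)/(4−f)` decreases from 2 to 4/3 on (0,1);
integrated over a uniform frequency spectrum the expected yields are 2/15 and
3/40, a 16/9 ≈ 1.8-fold reduction for siblings.

## Sequence pipeline

**Coordinates.** VCF positions are 1-based on disk; all internal arithmetic is
0-based half-open, converted exactly once at the reader boundary (pysam).
Exon intervals are genomic; minus-strand transcripts reverse-complement at
projection time. A variant is kept only if its REF span lies inside a single
exon of at least one retained transcript (the published pipelines discard the
negligible fraction that straddles exon boundaries); transcripts with internal
in-frame stops are rejected on input.

**Haplotype application.** Alleles are applied right-to-left in CDS
coordinates so upstream offsets stay valid; overlapping REF spans on one
haplotype keep the downstream-most allele (deterministic tie-break, logged).
Translation uses the standard code and stops at the first in-frame stop;
`truncated` marks a premature stop or a frame that runs off the end.
Stop-loss alleles translate through to the end of the provided CDS and are
flagged `stop_lost` (no 3'UTR read-through — UTR sequence is not part of the
input contract). Start-codon disruption yields an empty protein, logged; no
downstream-ATG rescue is attempted.

**Peptide provenance.** Each applied allele records the residue interval it
can alter (the codon span for substitutions and in-frame indels; everything
downstream for frameshifts). Each haplotype additionally records, for every
site where it carries the reference allele, the residue interval of each
non-carried alternate allele. A 9-mer occurrence therefore knows both the
variants it displays and the sites at which a *donor-homozygous* alternate
allele would delete it from the donor peptidome. Classification combines the
two sides:

- recipient-side causal alleles (covering the window, absent from the donor,
  non-synonymous) → single/adjacent nsSNP, in-frame indel, recipient
  frameshift;
- donor-side causal alleles (the window is reference-encoded and the donor is
  homozygous for an overlapping protein-changing allele) → nsSNP classes for
  missense, in-frame indel, or the donor-homozygous frameshift/nonsense
  classes for truncating alleles;
- more than one rule, or a cause expressible only as a joint phase
  configuration of several sites, → `combination` (never silently dropped).
  Combination URPs without a single causal allele carry a degenerate encoding
  frequency of 0 (their mismatch probability is not a single-locus quantity).

The encoding allele of a recipient-side URP is the alternate allele (its
frequency `f`); for donor-side causes it is the *reference* allele, frequency
`1 − f_alt`. With several causal alleles the minimum frequency is used —
conservative for `P_mm`. "Adjacent" nsSNPs are operationalised as ≥ 2 causal
missense SNVs whose altered residues fall inside one k-window. Distinct-string
semantics hold throughout: a peptide appearing in several transcripts is one
URP with merged provenance. `k` defaults to 9 (the dominant class I ligand
length) and all window arithmetic is k-generic.

## Binding model

The bundled predictor is an additive position-specific scoring matrix; the
published neural predictors are deliberately **not** reimplemented — any
external tool can be plugged in by supplying scores or calls over the same
peptide universe. What the package contributes is the percentile calibration:
strong/weak cutoffs are the scores at which at most a fraction `p` (defaults
0.005 and 0.02, the conventional strong/weak rank thresholds) of a background
sample scores at-or-above, with ties resolved toward the stricter cutoff; a
peptide tied with the cutoff is a binder. The calibration contract — the
background fraction at or above the strong cutoff never exceeds
`p + 1/N` — is exact by construction and asserted in tests. The background
defaults to peptides sampled uniformly from the reference proteome's k-mer
windows, seed-controlled. The consensus filter intersects two predictors'
calls at SB or WB stringency (SB ⊂ WB); the co-dominance statistic counts,
per biallelic nsSNP, whether both allelic variant sets contain a binder
(co-dominant) or only one (dominant), optionally removing peptides containing
arginine or lysine first, since substitutions to R/K raise the probability of
internal proteasomal cleavage and can bias the dominant side.

## Synthetic cohorts

The generator emulates the statistical structure of phase-3-style population
data at desk scale: transcripts of 60–120 codons of uniform sense codons
(start codon, terminal stop, no internal stop) on 1–3 exons and random strand,
one transcript per chromosome; exonic variants avoiding start/stop codons with
non-overlapping REF spans; a variant-type mixture defaulting to 80% missense /
5% adjacent-missense / 5% in-frame indel / 5% frameshift / 5% nonsense
(missense dominance mirrors coding polymorphism in population data; the minor
classes are kept large enough to exercise every classifier branch); and an
allele-frequency spectrum preset (uniform by default; point mass and truncated
1/f are available). Missense labels are guaranteed nonsynonymous by
construction — synonymous proposals are resampled — so classifier tests have
exact ground truth. Cohort haplotypes carry each alternate allele
independently with probability `f` (HWE); sibling pairs draw two parents under
HWE and transmit one uniformly chosen haplotype per parent per child per
chromosome, with no recombination — sufficient because the sibling formula is
per-locus. All generators are deterministic under a single seed, down to
byte-identical output files.

What the generator does **not** emulate: linkage disequilibrium, realistic
human allele-frequency spectra, transcript length and codon-usage
distributions, overlapping transcripts sharing loci, genotyping error, and
multiallelic sites (the reader supports them; the generator emits biallelic
records). Passing tests therefore demonstrate correctness of the algorithms
under the stated population model, not calibration against a real cohort —
absolute counts from real whole-genome panels are out of scope by design.
Because toy cohorts pack variants far more densely than real genomes, the
`combination` class share is larger than in population data.

## Numerical choices

- Extrema by bounded scalar minimisation (`xatol = 1e-12`), accurate to well
  beyond 6 decimals; closed forms retained as constants and cross-checked.
- Threshold windows by Brent root-finding on each side of the argmax
  (`xtol = 1e-12`); the unrelated model also has a closed form via
  `u(1−u) = t`, used as an independent check.
- Spectrum integrals by adaptive quadrature on `(ε, 1−ε)`, `ε = 1e-12`,
  relative tolerance 1e-10; the uniform case equals 16/9 analytically.
- `1 − (1−p)^n` computed via `expm1/log1p` for small-p accuracy.
- Degenerate inputs: empty URP sets profile to all-zero shares with a warning;
  a co-dominance ratio with zero dominant count reports infinity alongside the
  counts; an all-tied calibration background falls back to the strictest
  cutoff.

## Problem sizes

The acceptance computations run at desk scale: analytic targets are instant;
the Monte-Carlo recovery uses 200,000 simulated pairs per allele frequency
(3-SE agreement); the sibling fold-reduction simulation uses 50 unrelated and
50 sibling pairs over 250 missense variants on 25 transcripts, which bounds
the ratio's sampling error near ±0.2 at 3σ; the proteome oracle comparison
covers 100 random transcripts with ~400 variants.

## Known limitations

Only normal-reading-frame 9-mers from provided coding transcripts are
considered — no 10/11-mers, non-coding or alternative-reading-frame peptides,
no proteasomal splicing, and no immunogenicity prediction (binding is the last
modelled step). Selenocysteine recoding is not modelled; X/Y chromosomes and
structural variants are out of scope. The bundled PSSM is a generic stand-in
whose purpose is exercising the calibration and consensus machinery, not
predicting real HLA ligands.
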