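# Methods

This note documents the models, rules, and numerical choices behind each
module, what the synthetic-data generators do and do not emulate, and the
known limitations.

## Sequence handling (seqio)

Transcript models are read as FASTA and translated with the standard
genetic code in all six frames; partial trailing codons are dropped and
codons containing N translate to X (assemblers emit Ns; failing on them
would discard otherwise usable models). Candidate proteins are
stop-to-stop segments of at least 50 residues, *without* requiring an
initiator Met: transcript models are frequently 5′-incomplete, and a
Met requirement would truncate real precursors. All coordinates in the
package are 1-based inclusive; ORF coordinates always refer to the
forward strand of the source.

## Homology search (homology)

Candidate precursors are retrieved by optimal local alignment
(Smith–Waterman with the Gotoh affine-gap recurrence) rather than a
seeded heuristic: query precursors are short (typically 60–300 aa) and
target sets at desk scale are small enough that exact alignment is
affordable, and exactness makes the scores testable against brute-force
enumeration. Defaults are BLOSUM62 with gap open 11 / extend 1; a gap of
length g costs `11 + 1·g` (the NCBI convention). Significance uses the
Karlin–Altschul form `E = K·m·n·exp(−λS)` with the conventional gapped
BLOSUM62 constants λ = 0.267, K = 0.041; these are fixed, not fitted —
they rank and threshold hits, and no downstream quantity depends on
their absolute calibration. Nucleotide targets are searched through
their six-frame ORFs and the best frame is reported. Ties among optimal
alignments are broken deterministically: earliest query start, then
earliest target start, then fewest gaps.

## Precursor annotation (annotate)

**Signal peptide.** A rule-based predictor encoding the classical
tripartite architecture: a candidate cleavage position c ∈ [12, 45]
qualifies when (i) some 8-residue window within residues 2..c−3 has mean
Kyte–Doolittle hydropathy ≥ 1.6 (the h-region), (ii) position c holds a
small residue (A/G/S/C/T) and position c−2 a small/aliphatic residue
(the (−3,−1) rule of signal peptidase), and (iii) the n-region (residue
1 to the h-window start) has non-negative net charge (K/R minus D/E).
The reported position maximises `w_h·(best window hydropathy) + w_c +
w_n` with default weights 1/1/0.5; ties go to the smallest c. The
weights mainly rank competing sites — the three conditions do the
discriminating. This is a transparent heuristic, not a trained model;
on real sequences it will miss atypical signals and cannot distinguish
signal anchors.

**Processing sites.** Tier 1 (default on): every maximal run of ≥ 2
consecutive K/R is one site. Tier 2 (default off): a single K or R
whose successor exists and is not P. No site is called when the residue
after the run is P (P1′ proline suppression). Monobasic sites default
off because they dominate false positives; the flag exists because some
peptide families require them. Treating the whole maximal run as one
site with full trimming (carboxypeptidase-like) means a "KRR" never
leaves a stray basic residue on a peptide.

**Mature peptides.** Fragments are the maximal segments between the
signal end, the basic runs, and the termini — including the segment
before the first site and the C-terminal segment, which are genuine
peptide candidates. A fragment ending in G immediately followed by a
basic run loses the G and is flagged amidated (the amide-donor rule); a
fragment that *is* a single G is left alone. Fragments shorter than 3
residues after trimming are dropped (tetrapeptides such as APGW-amide
must survive; dipeptides are noise) but retained in the annotation so
that reconstruction stays lossless. Identical sequences within one
precursor get tandem `copy_index` numbers. Annotation is exactly
invertible: signal + fragments (with donor G re-inserted) + basic runs
+ dropped fragments concatenate back to the precursor, and the test
suite enforces this byte-exactly on 1,000 generated precursors.

## Mass spectrometry (masspec)

Masses are monoisotopic: the residue table is committed in the package
(version 1) and checked in the tests against an independent proteomics
library. Modification deltas: amidation −0.984016 Da, pyroGlu −17.026549
(from Q) / −18.010565 (from E), Met oxidation +15.994915, disulfide
−2.015650 per bond; water 18.010565. Variant enumeration is the
Cartesian product {pyroGlu if first residue Q/E} × {0..nMet oxidations}
× {0..⌊nCys/2⌋ disulfides}; amidation is a property of the peptide, not
a free variant.

Matching is sequence-first with mass as a filter: an observed de novo
sequence matches full-length when it equals a catalog peptide under I/L
equivalence (de novo sequencing cannot distinguish the isomers), else as
a fragment when it is a contiguous substring of a catalog peptide. When
an observed mass is present, some modification variant must lie within
the ppm tolerance (default 10 ppm, appropriate for Orbitrap-class
accuracy); for fragments the variant space of the matched substring is
used, keeping the amide only when the fragment reaches the peptide's
C-terminus. All tying best matches are reported rather than broken
silently. Coverage is counted over unique (precursor, sequence) pairs,
so tandem copies count once; a peptide counts as identified only via a
full-length match. Spectrum-level processing (peak picking, de novo
sequencing itself) is out of scope — the module consumes sequencing
output.

## Expression panel (panel)

Counts are normalized to RPM after adding a pseudocount of 1 to every
cell, which keeps fold changes defined for genes dropping to zero counts
(the interesting direction here); columns then sum to exactly 10⁶.
Group comparison is a per-gene two-sided Student's t-test with pooled
variance (Welch available by flag), SE = sd/√n, fold change =
mean_B/mean_A. Degenerate genes (zero variance in both groups, equal
means) get t = 0, p = 1. No multiple-testing correction is applied by
default — the panel is a small curated list read at raw p < 0.05, with
a second significance tier at 0.01 and Benjamini–Hochberg available by
flag. Z-score matrices standardize each gene across samples, dropping
constant genes with a log line; output row order is input order (no
clustering). `intersect_regulated` demands identical gene universes and
returns genes significant in the stated direction in both comparisons —
the operation that isolates a concomitantly regulated set across sexes.

## Synthetic data (synth)

The generators emulate the statistical structure each stage assumes, and
carry truth tables.

**Precursors** (default 88): a signal peptide built from an
M + n-region (2–5 residues, non-acidic), an 8-residue hydrophobic core
(I/V/L/F), and a c-region whose only (−3,−1)-qualifying position is the
true cleavage site — so the annotation heuristic should recover the
boundary exactly and the ±1 recovery criterion measures the rule set,
not generator slack. Then 1–10 cassettes of 4–18 residues drawn from
the 18 non-K/R amino acids (no accidental Tier-1 sites; accidental
monobasic sites cannot occur either since K/R are excluded entirely),
never ending in G (no accidental donors) and never starting with P (no
suppressed sites), separated by KR/RR/KK/RK runs. Non-terminal
cassettes carry a donor G with probability 0.5; with probability 0.1 a
cassette repeats its predecessor (tandem copies).

**Counts**: gene universe = the 88 panel genes plus 2,000 background
genes; baseline expression log-uniform over 5–5,000 RPM (matching the
few-thousand-fold spread seen across real precursor panels), converted
to expected counts at 2×10⁷ reads per library — a typical short-read
RNA-seq depth, at which Poisson counting noise is small against the
biological variability. Biological noise is gamma-Poisson with CV =
`count_dispersion` (default 0.2, i.e. 20% between-animal variability at
moderate expression). The design mirrors the study: 4 normal vs 3 CSM
female libraries, 3 vs 3 male. An 11-gene down set (4-fold, i.e. CSM
at ¼ of normal) and a 1-gene up set are implanted in both sexes, drawn
from panel genes only. What this does *not* emulate: count correlation
between genes, sample-level library-quality effects, and heavy-tailed
overdispersion — so passing recovery tests demonstrates correctness of
the statistics under the stated noise model, not robustness to real
RNA-seq pathology.

**MS observations**: each unique catalog peptide is detected with
probability 0.45 (detection decided per unique peptide so that the
matched fraction converges to the detection probability under the
tandem-copy accounting above), then perturbed by mass-neutral I↔L flips
(per eligible residue, default 0.05) and N-terminal truncation (default
0.1, producing fragment matches). Observed masses are exact theoretical
masses of the emitted species; real de novo output additionally contains
wholesale sequencing errors and chimeras, which are not modeled —
matching precision against such noise is not what the tests measure.

All generators are pure functions of their configuration; the seed is a
mandatory field.

## Problem sizes and determinism

The shipped tests and the acceptance script run at desk scale: 1,000
precursors for the reconstruction invariant, 400 for signal recovery,
2,000 background genes for null calibration, three replicate panels for
recovery, 20 seeds × 60 precursors for matching recovery, and 300–500
random short pairs (length ≤ 8, 4-letter alphabet) for the exhaustive
alignment oracle, where full enumeration of all local alignments is
tractable. Every stochastic test uses fixed seeds; the acceptance
script derives all of its randomness from `--seed`.

## Known limitations

- The signal and cleavage predictors are deliberate rule sets; they are
  not substitutes for trained predictors on distant real sequences.
- The aligner is exact but O(mn) per pair — appropriate for panels of
  precursors, not for genome-scale databases.
- E-value constants are conventional, not estimated from the scoring
  scheme; treat absolute E-values as rankings.
- Fragment matching searches catalog peptides only, not whole
  precursors; a fragment spanning a processing site will not match.
- The abundance model ignores gene–gene correlation and uses a single
  dispersion for all genes.
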