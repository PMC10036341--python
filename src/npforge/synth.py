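"""Synthetic study data with full truth tables.

Generates the three inputs the pipeline consumes — precursor proteins,
an RNA-seq count matrix with a two-group design in both sexes, and
de-novo MS peptide observations — with the statistical structure the
analysis assumes, so every stage is testable end to end without external
data. Every generator is a pure function of its configuration (which
carries the mandatory seed).

Defaults mirror the study conditions: 88 precursors; cassettes separated
by dibasic processing sites with about half the cassettes carrying an
amide-donor Gly; 4 vs 3 female and 3 vs 3 male libraries; an 11-gene
down-regulated set at 4-fold (and one up-regulated gene) on a
negative-binomial-like count background; and MS detection of 45% of
catalog peptides with I/L ambiguity and N-terminal truncation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import MaturePeptide, PrecursorAnnotation
from .masspec import ObservedPeptide, monoisotopic_mass, ModificationState
from .seqio import SequenceRecord

# cassette residues: no K/R (would create processing sites)
CASSETTE_ALPHABET = "ACDEFGHILMNPQSTVWY"
CASSETTE_FINAL = CASSETTE_ALPHABET.replace("G", "")   # no accidental amide donor
CASSETTE_FIRST = CASSETTE_ALPHABET.replace("P", "")   # P1' would suppress the site
SEPARATORS = ("KR", "RR", "KK", "RK")

# signal-peptide building blocks (see gen_precursors)
N_REGION = "KNQH"                  # neutral-to-positive, never small at -1
H_CORE = "ILVF"                    # strongly hydrophobic core residues
C_FILLER = "NQHYW"                 # not small: keeps the -1 rule unique
C_MINUS2 = "VLI"                   # satisfies the -3 rule only
C_LAST = "AST"                     # the small -1 residue


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the generators; the seed is mandatory."""

    seed: int
    # precursor architecture
    n_precursors: int = 88
    cassette_range: tuple[int, int] = (1, 10)
    cassette_len_range: tuple[int, int] = (4, 18)
    amide_donor_prob: float = 0.5
    tandem_repeat_prob: float = 0.1
    signal_len_range: tuple[int, int] = (16, 30)
    # expression panel
    n_genes_background: int = 2000
    n_female: tuple[int, int] = (4, 3)      # (normal, CSM) libraries
    n_male: tuple[int, int] = (3, 3)
    count_dispersion: float = 0.2           # biological CV of gene expression
    mean_rpm_range: tuple[float, float] = (5.0, 5000.0)
    library_size: float = 2e7               # sequenced reads per sample
    down_set_size: int = 11
    down_fold: float = 0.25
    up_set_size: int = 1
    # MS observation
    detection_prob: float = 0.45
    il_noise_prob: float = 0.05
    truncation_prob: float = 0.1

    def __post_init__(self) -> None:
        for name in ("amide_donor_prob", "tandem_repeat_prob",
                     "detection_prob", "il_noise_prob", "truncation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class TruthPeptide:
    start: int
    end: int            # excludes the donor Gly when amidated
    sequence: str
    amidated: bool


@dataclass(frozen=True)
class PrecursorTruth:
    precursor_id: str
    signal_end: int
    peptides: tuple[TruthPeptide, ...]


@dataclass(frozen=True)
class CountTruth:
    down_genes: frozenset[str]
    up_genes: frozenset[str]


@dataclass(frozen=True)
class ObservedTruth:
    """Provenance of one emitted MS observation."""

    precursor_id: str
    source_sequence: str
    emitted_sequence: str
    n_il_flips: int
    truncated: bool


def _choice(rng: np.random.Generator, alphabet: str, n: int = 1) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def _gen_signal(rng: np.random.Generator, cfg: SynthConfig) -> str:
    """Build a signal peptide the annotate heuristic recovers exactly.

    Layout: Met + n-region (no acidic residues) + 8-residue hydrophobic
    core + c-region whose only small -1 candidate is the final residue,
    so the true cleavage position is the unique qualifying one.
    """
    lo, hi = cfg.signal_len_range
    total = int(rng.integers(lo, hi + 1))
    n_len = int(rng.integers(2, 6))              # incl. the Met
    c_len = total - n_len - 8
    if c_len < 4:
        c_len = 4
        total = n_len + 8 + c_len
    n_region = "M" + _choice(rng, N_REGION, n_len - 1)
    core = _choice(rng, H_CORE, 8)
    c_region = list(_choice(rng, C_FILLER, c_len))
    c_region[-3] = _choice(rng, C_MINUS2)
    c_region[-1] = _choice(rng, C_LAST)
    return n_region + core + "".join(c_region)


def gen_precursors(cfg: SynthConfig,
                   ) -> tuple[list[SequenceRecord], list[PrecursorTruth]]:
    """Generate precursor proteins plus their ground-truth annotation.

    Each precursor is signal + cassette (+G?) + dibasic run + ... +
    terminal cassette. Non-terminal cassettes carry an amide-donor Gly
    with probability ``amide_donor_prob``; the terminal cassette never
    does (there is no downstream site to donate to). With probability
    ``tandem_repeat_prob`` a cassette repeats the previous one (tandem
    copies of the same peptide).
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[SequenceRecord] = []
    truths: list[PrecursorTruth] = []
    for idx in range(cfg.n_precursors):
        pid = f"prec_{idx:04d}"
        signal = _gen_signal(rng, cfg)
        n_cassettes = int(rng.integers(cfg.cassette_range[0],
                                       cfg.cassette_range[1] + 1))
        parts = [signal]
        truth_peps: list[TruthPeptide] = []
        pos = len(signal)
        prev_base: str | None = None
        for k in range(n_cassettes):
            terminal = k == n_cassettes - 1
            if prev_base is not None and rng.random() < cfg.tandem_repeat_prob:
                base = prev_base
            else:
                length = int(rng.integers(cfg.cassette_len_range[0],
                                          cfg.cassette_len_range[1] + 1))
                base = (_choice(rng, CASSETTE_FIRST)
                        + _choice(rng, CASSETTE_ALPHABET, length - 2)
                        + _choice(rng, CASSETTE_FINAL))
            prev_base = base
            donor = (not terminal) and rng.random() < cfg.amide_donor_prob
            truth_peps.append(TruthPeptide(
                start=pos + 1, end=pos + len(base), sequence=base,
                amidated=donor))
            parts.append(base + ("G" if donor else ""))
            pos += len(base) + (1 if donor else 0)
            if not terminal:
                sep = SEPARATORS[int(rng.integers(0, len(SEPARATORS)))]
                parts.append(sep)
                pos += len(sep)
        records.append(SequenceRecord(
            id=pid, sequence="".join(parts),
            description="synthetic neuropeptide precursor"))
        truths.append(PrecursorTruth(precursor_id=pid,
                                     signal_end=len(signal),
                                     peptides=tuple(truth_peps)))
    return records, truths


def gen_counts(cfg: SynthConfig,
               ) -> tuple[pd.DataFrame, pd.DataFrame, CountTruth]:
    """Generate the count matrix, sample design, and effect truth table.

    Genes are the precursor ids (the neuropeptide panel) plus a null
    background. Baseline means are log-uniform over ``mean_rpm_range``
    on the RPM scale and converted to expected read counts at
    ``library_size`` sequenced reads per sample; counts are gamma-Poisson
    draws whose biological CV equals ``count_dispersion`` (counting noise
    is negligible on top at realistic depth). The down set (drawn from
    the panel genes only) has its CSM-group mean multiplied by
    ``down_fold`` in both sexes; the up set by 1/``down_fold``.
    """
    rng = np.random.default_rng(cfg.seed)
    panel_genes = [f"prec_{i:04d}" for i in range(cfg.n_precursors)]
    bg_genes = [f"bg_{i:04d}" for i in range(cfg.n_genes_background)]
    genes = panel_genes + bg_genes

    picked = rng.choice(cfg.n_precursors,
                        size=cfg.down_set_size + cfg.up_set_size, replace=False)
    down = frozenset(panel_genes[i] for i in picked[:cfg.down_set_size])
    up = frozenset(panel_genes[i] for i in picked[cfg.down_set_size:])

    lo, hi = cfg.mean_rpm_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(genes)))
    samples: list[tuple[str, str, str]] = []
    for sex, (n_normal, n_csm) in (("female", cfg.n_female), ("male", cfg.n_male)):
        prefix = sex[0].upper()
        samples += [(f"N{prefix}{i+1}", "normal", sex) for i in range(n_normal)]
        samples += [(f"C{prefix}{i+1}", "csm", sex) for i in range(n_csm)]

    cv = cfg.count_dispersion
    shape = 1.0 / cv ** 2 if cv > 0 else None
    cols = {}
    for sample_id, group, _sex in samples:
        mu = base.copy()
        if group == "csm":
            is_down = np.array([g in down for g in genes])
            is_up = np.array([g in up for g in genes])
            mu = np.where(is_down, mu * cfg.down_fold, mu)
            mu = np.where(is_up, mu / cfg.down_fold, mu)
        depth = cfg.library_size / 1e6
        if shape is not None:
            lam = rng.gamma(shape, mu / shape) * depth
        else:
            lam = mu * depth
        cols[sample_id] = rng.poisson(lam)
    counts = pd.DataFrame(cols, index=genes)
    design = pd.DataFrame(
        [{"sample_id": s, "group": g, "sex": x} for s, g, x in samples]
    ).set_index("sample_id", drop=False)
    return counts, design, CountTruth(down_genes=down, up_genes=up)


def gen_observed(catalog: Sequence[MaturePeptide], cfg: SynthConfig,
                 ) -> tuple[list[ObservedPeptide], list[ObservedTruth]]:
    """Emit noisy de novo MS observations of the predicted catalog.

    Detection is decided once per unique (precursor, sequence) group
    (tandem copies are one detectable species), with probability
    ``detection_prob``. Emitted sequences are perturbed by I<->L swaps
    (per eligible residue, probability ``il_noise_prob``; mass-neutral,
    as in real de novo output) and by N-terminal truncation with
    probability ``truncation_prob``. The observed mass is the exact
    theoretical mass of the emitted species (amide retained, since
    truncation is N-terminal).
    """
    rng = np.random.default_rng(cfg.seed)
    seen: set[tuple[str, str]] = set()
    observed: list[ObservedPeptide] = []
    truth: list[ObservedTruth] = []
    for pep in catalog:
        key = (pep.precursor_id, pep.sequence)
        if key in seen:
            continue
        seen.add(key)
        if rng.random() >= cfg.detection_prob:
            continue
        seq = pep.sequence
        truncated = False
        if len(seq) > 4 and rng.random() < cfg.truncation_prob:
            cut = int(rng.integers(1, len(seq) - 3))
            seq = seq[cut:]
            truncated = True
        chars = list(seq)
        n_flips = 0
        for i, c in enumerate(chars):
            if c in "IL" and rng.random() < cfg.il_noise_prob:
                chars[i] = "L" if c == "I" else "I"
                n_flips += 1
        emitted = "".join(chars)
        mass = monoisotopic_mass(seq, ModificationState(amidated=pep.amidated))
        observed.append(ObservedPeptide(sequence=emitted,
                                        score=float(rng.uniform(60, 99)),
                                        observed_mass=mass))
        truth.append(ObservedTruth(precursor_id=pep.precursor_id,
                                   source_sequence=pep.sequence,
                                   emitted_sequence=emitted,
                                   n_il_flips=n_flips, truncated=truncated))
    return observed, truth
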