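"""Precursor annotation: signal peptide, processing sites, mature peptides.

A neuropeptide precursor (prohormone) is a secreted protein made of an
N-terminal signal peptide followed by peptide cassettes separated by runs
of basic residues (K/R), where prohormone convertases cleave.
Carboxypeptidase-like trimming removes the basic residues, and a Gly
immediately preceding a processing site is converted into a C-terminal
amide on the mature peptide.

The signal-peptide and processing-site predictors here are explicit,
documented heuristics (a hydrophobic h-region with the (-3,-1) small-
residue rule; Tier-1 multibasic / Tier-2 monobasic cleavage rules with
P1' proline suppression) rather than external model-based tools, so every
prediction is reproducible from the rules stated in this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

SMALL_M1 = frozenset("AGSCT")       # allowed at the -1 (last signal) position
SMALL_M3 = frozenset("AGSCTVLI")    # allowed at the -3 position
BASIC = frozenset("KR")
POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")


@dataclass(frozen=True)
class SignalParams:
    """Weights and thresholds of the signal-peptide heuristic."""

    w_hydrophobic: float = 1.0
    w_cterm: float = 1.0
    w_ncharge: float = 0.5
    min_core_hydropathy: float = 1.6   # mean Kyte-Doolittle over the h-window
    core_window: int = 8
    min_cleavage: int = 12
    max_cleavage: int = 45


@dataclass(frozen=True)
class SignalPrediction:
    has_signal: bool
    cleavage_after: int            # 1-based last signal residue; 0 if none
    score: float
    h_window: tuple[int, int]      # 1-based inclusive best hydrophobic window

    def __post_init__(self) -> None:
        if self.has_signal and not (12 <= self.cleavage_after <= 45):
            raise ValueError("signal cleavage must fall in residues 12..45")


@dataclass(frozen=True)
class CleavageSite:
    """A maximal basic-residue run recognised as a convertase site."""

    run_start: int
    end_of_basic_run: int
    motif: str
    tier: int                       # 1 = multibasic, 2 = monobasic

    def __post_init__(self) -> None:
        if self.run_start > self.end_of_basic_run:
            raise ValueError("run_start must be <= end_of_basic_run")
        if set(self.motif) - BASIC:
            raise ValueError("cleavage motif must consist of K/R only")


@dataclass(frozen=True)
class CleavageRules:
    multibasic: bool = True     # Tier 1: runs of >= 2 K/R
    monobasic: bool = False     # Tier 2: single K or R


@dataclass(frozen=True)
class MaturePeptide:
    """A predicted mature peptide (amide-donor Gly already removed)."""

    precursor_id: str
    start: int
    end: int
    sequence: str
    amidated: bool
    copy_index: int = 1
    passes_min_length: bool = True

    def __post_init__(self) -> None:
        if self.amidated and self.sequence.endswith("G"):
            raise ValueError("amidated peptide must not retain its donor Gly")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("peptide coordinates do not match sequence length")


@dataclass(frozen=True)
class PrecursorAnnotation:
    record: SequenceRecord
    signal: SignalPrediction
    sites: tuple[CleavageSite, ...]
    peptides: tuple[MaturePeptide, ...]
    dropped: tuple[MaturePeptide, ...] = ()

    @property
    def precursor_id(self) -> str:
        return self.record.id


def _mean_hydropathy(window: str) -> float:
    return sum(KYTE_DOOLITTLE[c] for c in window) / len(window)


def predict_signal(protein: str, params: SignalParams | None = None) -> SignalPrediction:
    """Heuristic N-terminal signal-peptide prediction.

    Scans candidate cleavage positions c in [12, 45] and requires
    (i) a hydrophobic core: some ``core_window``-residue window within
    residues 2..c-3 with mean Kyte-Doolittle >= ``min_core_hydropathy``;
    (ii) the (-3, -1) rule: a small residue at c and a small/aliphatic
    residue at c-2; (iii) a non-negative net charge in the n-region
    (residue 1 up to the h-window start). The returned position maximises
    the weighted score; ties go to the smallest c. Proteins shorter than
    20 residues are reported as signal-less.
    """
    params = params or SignalParams()
    none = SignalPrediction(False, 0, 0.0, (0, 0))
    if len(protein) < 20:
        return none
    w = params.core_window
    best: tuple[float, int, tuple[int, int]] | None = None
    for c in range(params.min_cleavage, min(params.max_cleavage, len(protein) - 1) + 1):
        # (ii) small residues at the -1 and -3 positions
        if protein[c - 1] not in SMALL_M1 or protein[c - 3] not in SMALL_M3:
            continue
        # (i) best hydrophobic window fully inside residues 2..c-3
        hi = c - 3
        if hi - 2 + 1 < w:
            continue
        windows = [(s, _mean_hydropathy(protein[s - 1:s - 1 + w]))
                   for s in range(2, hi - w + 2)]
        h_start, h_mean = max(windows, key=lambda t: t[1])
        if h_mean < params.min_core_hydropathy:
            continue
        # (iii) n-region net charge
        n_region = protein[:h_start - 1]
        charge = (sum(c_ in POSITIVE for c_ in n_region)
                  - sum(c_ in NEGATIVE for c_ in n_region))
        if charge < 0:
            continue
        score = (params.w_hydrophobic * h_mean + params.w_cterm * 1.0
                 + params.w_ncharge * 1.0)
        if best is None or score > best[0]:
            best = (score, c, (h_start, h_start + w - 1))
    if best is None:
        return none
    score, c, h_window = best
    return SignalPrediction(True, c, score, h_window)


def find_cleavage_sites(protein: str, signal: SignalPrediction,
                        rules: CleavageRules | None = None) -> list[CleavageSite]:
    """Locate convertase processing sites downstream of the signal peptide.

    Tier 1 (default on): every maximal run of >= 2 consecutive K/R.
    Tier 2 (default off): a single K or R whose following residue exists
    and is not P. No site is called when the residue after the run is P
    (P1' proline suppression).
    """
    rules = rules or CleavageRules()
    start = signal.cleavage_after  # 0-based index of first searched residue
    sites: list[CleavageSite] = []
    i = start
    n = len(protein)
    while i < n:
        if protein[i] not in BASIC:
            i += 1
            continue
        j = i
        while j < n and protein[j] in BASIC:
            j += 1
        run_len = j - i
        follows_p = j < n and protein[j] == "P"
        if not follows_p:
            if run_len >= 2 and rules.multibasic:
                sites.append(CleavageSite(i + 1, j, protein[i:j], 1))
            elif run_len == 1 and rules.monobasic and j < n:
                sites.append(CleavageSite(i + 1, j, protein[i:j], 2))
        i = j
    return sites


def _fragments(protein: str, signal: SignalPrediction,
               sites: Sequence[CleavageSite]):
    """Maximal segments between the signal end, basic runs, and termini.

    Yields (start, end, sequence, amidated) with the amide-donor Gly
    removed; ``end`` excludes the removed Gly.
    """
    boundaries = sorted(sites, key=lambda s: s.run_start)
    run_starts = {s.run_start for s in boundaries}
    prev_end = signal.cleavage_after
    edges = [(s.run_start - 1, s.end_of_basic_run) for s in boundaries]
    edges.append((len(protein), None))
    for frag_end, run_end in edges:
        frag_start = prev_end + 1
        if frag_end >= frag_start:
            seq = protein[frag_start - 1:frag_end]
            followed_by_run = (frag_end + 1) in run_starts
            # a lone G between two runs is a donor with nothing to amidate
            if followed_by_run and seq.endswith("G") and len(seq) > 1:
                yield frag_start, frag_end - 1, seq[:-1], True
            else:
                yield frag_start, frag_end, seq, False
        if run_end is not None:
            prev_end = run_end


def derive_mature_peptides(protein: str, signal: SignalPrediction,
                           sites: Sequence[CleavageSite], min_len: int = 3,
                           precursor_id: str = "precursor",
                           ) -> tuple[list[MaturePeptide], list[MaturePeptide]]:
    """Cut the precursor at its processing sites into mature peptides.

    Basic runs are trimmed away entirely; a fragment ending in G that is
    immediately followed by a basic run loses the G and is flagged
    amidated. Fragments shorter than ``min_len`` after trimming are
    dropped (returned separately, and logged). ``copy_index`` numbers
    identical sequences within one precursor (tandem copies).

    Returns ``(peptides, dropped)``.
    """
    kept: list[MaturePeptide] = []
    dropped: list[MaturePeptide] = []
    counts: dict[str, int] = {}
    for start, end, seq, amidated in _fragments(protein, signal, sites):
        if not seq:
            continue
        ok = len(seq) >= min_len
        counts[seq] = counts.get(seq, 0) + 1
        pep = MaturePeptide(precursor_id, start, end, seq, amidated,
                            copy_index=counts[seq], passes_min_length=ok)
        if ok:
            kept.append(pep)
        else:
            logger.info("dropped short fragment %r at %d-%d of %s",
                        seq, start, end, precursor_id)
            dropped.append(pep)
    return kept, dropped


def annotate_precursor(record: SequenceRecord,
                       signal_params: SignalParams | None = None,
                       rules: CleavageRules | None = None,
                       min_peptide_len: int = 3) -> PrecursorAnnotation:
    """Full annotation: signal -> processing sites -> mature peptides."""
    protein = record.sequence
    if "*" in protein:
        protein = protein.rstrip("*")
        if "*" in protein:
            raise ValueError(f"internal stop codon in {record.id!r}")
    signal = predict_signal(protein, signal_params)
    sites = find_cleavage_sites(protein, signal, rules)
    peptides, dropped = derive_mature_peptides(
        protein, signal, sites, min_len=min_peptide_len,
        precursor_id=record.id)
    return PrecursorAnnotation(record=record, signal=signal,
                               sites=tuple(sites), peptides=tuple(peptides),
                               dropped=tuple(dropped))


def reconstruct_precursor(annotation: PrecursorAnnotation) -> str:
    """Rebuild the precursor from its annotated parts.

    Concatenates, in order: the signal peptide, every fragment (with its
    removed amide-donor G re-inserted, including dropped short
    fragments), and every basic run. Annotation is lossless, so this
    reproduces the precursor exactly.
    """
    protein = annotation.record.sequence.rstrip("*")
    pieces: list[tuple[int, str]] = []
    if annotation.signal.has_signal:
        pieces.append((1, protein[:annotation.signal.cleavage_after]))
    for pep in list(annotation.peptides) + list(annotation.dropped):
        seq = pep.sequence + ("G" if pep.amidated else "")
        pieces.append((pep.start, seq))
    for site in annotation.sites:
        pieces.append((site.run_start, site.motif))
    pieces.sort(key=lambda p: p[0])
    return "".join(seq for _, seq in pieces)


def build_catalog(annotations: Sequence[PrecursorAnnotation]) -> list[MaturePeptide]:
    """Flatten annotations into the predicted-peptide catalog."""
    return [pep for ann in annotations for pep in ann.peptides]


def catalog_to_rows(catalog: Sequence[MaturePeptide]) -> list[dict]:
    return [{
        "precursor_id": p.precursor_id, "start": p.start, "end": p.end,
        "sequence": p.sequence, "amidated": p.amidated,
        "copy_index": p.copy_index,
    } for p in catalog]


def catalog_from_rows(rows: Sequence[dict]) -> list[MaturePeptide]:
    return [MaturePeptide(
        precursor_id=str(r["precursor_id"]), start=int(r["start"]),
        end=int(r["end"]), sequence=str(r["sequence"]),
        amidated=bool(r["amidated"]) if not isinstance(r["amidated"], str)
        else r["amidated"].lower() in ("1", "true", "yes"),
        copy_index=int(r.get("copy_index", 1)),
    ) for r in rows]
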