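"""Monoisotopic peptide masses, modification variants, and MS matching.

Computes monoisotopic masses for predicted mature peptides under the
post-translational modifications relevant to neuropeptides — C-terminal
amidation, N-terminal pyroglutamate (from Gln or Glu), methionine
oxidation, and disulfide bonds — enumerates the variant space, and
matches de-novo-sequenced MS peptides back to the predicted catalog.
De novo sequencing cannot distinguish isoleucine from leucine, so
matching treats I and L as equivalent by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .annotate import MaturePeptide

# Monoisotopic residue masses (Da), standard values. Version 1 of the
# committed table; peptide mass = sum(residues) + water.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047679, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}


@dataclass(frozen=True)
class ModificationSet:
    """Fixed mass deltas (Da) for the supported modifications."""

    amidation_delta: float = -0.984016
    pyroglu_from_q: float = -17.026549
    pyroglu_from_e: float = -18.010565
    met_oxidation: float = +15.994915
    disulfide_per_bond: float = -2.015650
    water: float = 18.010565
    residue_masses: dict[str, float] = field(
        default_factory=lambda: dict(RESIDUE_MASSES))


DEFAULT_MODSET = ModificationSet()


@dataclass(frozen=True)
class ModificationState:
    """One consistent combination of modifications on a peptide."""

    amidated: bool = False
    pyroglu: bool = False
    n_met_oxidized: int = 0
    n_disulfides: int = 0

    def label(self) -> str:
        parts = []
        if self.amidated:
            parts.append("amide")
        if self.pyroglu:
            parts.append("pyroGlu")
        if self.n_met_oxidized:
            parts.append(f"ox{self.n_met_oxidized}")
        if self.n_disulfides:
            parts.append(f"ss{self.n_disulfides}")
        return "+".join(parts) or "unmodified"


@dataclass(frozen=True)
class ObservedPeptide:
    """A de-novo-sequenced MS peptide (sequence as reported, I/L ambiguous)."""

    sequence: str
    score: float = 0.0
    observed_mass: float | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("observed peptide sequence must be non-empty")


@dataclass(frozen=True)
class MatchResult:
    observed: ObservedPeptide
    precursor_id: str
    peptide: MaturePeptide
    match_type: str                      # "full" or "fragment"
    il_substitutions: int
    mass_error_ppm: float | None = None
    modification_state: ModificationState | None = None


def monoisotopic_mass(sequence: str,
                      state: ModificationState | None = None,
                      modset: ModificationSet = DEFAULT_MODSET) -> float:
    """Monoisotopic mass of a peptide under one modification state.

    Raises ``ValueError`` naming the violated rule for inconsistent
    states (pyroGlu on a non-Q/E N-terminus, more oxidations than Met
    residues, more disulfides than floor(nCys/2)).
    """
    state = state or ModificationState()
    try:
        mass = sum(modset.residue_masses[c] for c in sequence)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}")
    mass += modset.water
    if state.amidated:
        mass += modset.amidation_delta
    if state.pyroglu:
        first = sequence[0]
        if first == "Q":
            mass += modset.pyroglu_from_q
        elif first == "E":
            mass += modset.pyroglu_from_e
        else:
            raise ValueError("pyroGlu requires an N-terminal Q or E residue")
    if state.n_met_oxidized:
        if state.n_met_oxidized > sequence.count("M"):
            raise ValueError("more Met oxidations than Met residues")
        mass += state.n_met_oxidized * modset.met_oxidation
    if state.n_disulfides:
        if state.n_disulfides > sequence.count("C") // 2:
            raise ValueError("more disulfide bonds than Cys pairs")
        mass += state.n_disulfides * modset.disulfide_per_bond
    return mass


def enumerate_variants(sequence: str, amidated: bool = False,
                       modset: ModificationSet = DEFAULT_MODSET,
                       ) -> list[tuple[ModificationState, float]]:
    """All consistent modification states of a peptide, with masses.

    The Cartesian set {pyroGlu on/off if the first residue is Q/E} x
    {0..nMet oxidations} x {0..floor(nCys/2) disulfides}. Amidation is
    fixed by the peptide's flag, never enumerated.
    """
    pyro_options = [False, True] if sequence[0] in "QE" else [False]
    ox_options = range(sequence.count("M") + 1)
    ss_options = range(sequence.count("C") // 2 + 1)
    out = []
    for pyro, n_ox, n_ss in itertools.product(pyro_options, ox_options, ss_options):
        state = ModificationState(amidated=amidated, pyroglu=pyro,
                                  n_met_oxidized=n_ox, n_disulfides=n_ss)
        out.append((state, monoisotopic_mass(sequence, state, modset)))
    return out


def variants_for_peptide(peptide: MaturePeptide,
                         modset: ModificationSet = DEFAULT_MODSET,
                         ) -> list[tuple[ModificationState, float]]:
    return enumerate_variants(peptide.sequence, peptide.amidated, modset)


def il_normalize(sequence: str) -> str:
    """Collapse the I/L ambiguity of de novo sequencing (L -> I)."""
    return sequence.replace("L", "I")


def _mass_filter(observed_mass: float | None, sequence: str, amidated: bool,
                 ppm_tol: float, modset: ModificationSet,
                 ) -> tuple[bool, float | None, ModificationState | None]:
    """Check whether some variant mass lies within ppm_tol of the observation."""
    if observed_mass is None:
        return True, None, None
    best_err, best_state = None, None
    for state, mass in enumerate_variants(sequence, amidated, modset):
        err = (observed_mass - mass) / mass * 1e6
        if abs(err) <= ppm_tol and (best_err is None or abs(err) < abs(best_err)):
            best_err, best_state = err, state
    return best_err is not None, best_err, best_state


def match_observed(observed_list: Sequence[ObservedPeptide],
                   catalog: Sequence[MaturePeptide],
                   ppm_tol: float = 10.0, il_equiv: bool = True,
                   modset: ModificationSet = DEFAULT_MODSET,
                   ) -> list[MatchResult]:
    """Assign de novo MS peptides to catalog peptides.

    Sequence-first: exact (full-length) matches take precedence over
    fragment (contiguous-substring) matches, with I and L interchangeable
    when ``il_equiv``. When an observed mass is present, a modification
    variant must exist within ``ppm_tol``; for fragment matches the
    variant space of the matched substring is used (retaining the
    amidation flag only when the fragment reaches the peptide's
    C-terminus). All tying best matches are reported.
    """
    norm = il_normalize if il_equiv else (lambda s: s)
    results: list[MatchResult] = []
    normed_catalog = [(pep, norm(pep.sequence)) for pep in catalog]
    for obs in observed_list:
        obs_norm = norm(obs.sequence)
        full: list[MatchResult] = []
        frag: list[MatchResult] = []
        for pep, pep_norm in normed_catalog:
            if obs_norm == pep_norm:
                n_sub = sum(a != b for a, b in zip(obs.sequence, pep.sequence))
                ok, err, state = _mass_filter(obs.observed_mass, pep.sequence,
                                              pep.amidated, ppm_tol, modset)
                if ok:
                    full.append(MatchResult(obs, pep.precursor_id, pep, "full",
                                            n_sub, err, state))
            elif obs_norm in pep_norm:
                at = pep_norm.find(obs_norm)
                sub = pep.sequence[at:at + len(obs_norm)]
                n_sub = sum(a != b for a, b in zip(obs.sequence, sub))
                amid = pep.amidated and at + len(obs_norm) == len(pep.sequence)
                ok, err, state = _mass_filter(obs.observed_mass, sub, amid,
                                              ppm_tol, modset)
                if ok:
                    frag.append(MatchResult(obs, pep.precursor_id, pep,
                                            "fragment", n_sub, err, state))
        results.extend(full if full else frag)
    return results


def coverage_summary(matches: Sequence[MatchResult],
                     catalog: Sequence[MaturePeptide]) -> dict:
    """Identification coverage of the predicted catalog.

    Peptides are counted at the level of unique (precursor, sequence)
    pairs, so tandem copies of the same peptide count once. A peptide
    counts as identified when it has at least one full-length match;
    ``percent_matched`` is reported to one decimal.
    """
    groups = {(p.precursor_id, p.sequence) for p in catalog}
    matched = {(m.peptide.precursor_id, m.peptide.sequence)
               for m in matches if m.match_type == "full"}
    matched &= groups
    precursors = {pid for pid, _ in matched}
    n_catalog = len(groups)
    n_matched = len(matched)
    percent = round(100.0 * n_matched / n_catalog, 1) if n_catalog else 0.0
    return {
        "n_catalog": n_catalog,
        "n_matched": n_matched,
        "percent_matched": percent,
        "n_precursors_with_match": len(precursors),
    }


def read_observed_tsv(path: str | Path) -> list[ObservedPeptide]:
    """Read de novo peptides from TSV (sequence, score, observed_mass?)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        mass = row.get("observed_mass")
        mass = None if mass is None or pd.isna(mass) else float(mass)
        out.append(ObservedPeptide(sequence=str(row["sequence"]),
                                   score=float(row.get("score", 0.0)),
                                   observed_mass=mass))
    return out


def matches_to_rows(matches: Sequence[MatchResult]) -> list[dict]:
    return [{
        "observed_sequence": m.observed.sequence,
        "precursor_id": m.precursor_id,
        "peptide_sequence": m.peptide.sequence,
        "peptide_start": m.peptide.start,
        "match_type": m.match_type,
        "il_substitutions": m.il_substitutions,
        "mass_error_ppm": m.mass_error_ppm,
        "modification_state": m.modification_state.label()
        if m.modification_state else "",
    } for m in matches]
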