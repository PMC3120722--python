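"""In-silico MRM (multiple reaction monitoring) method design.

The in-silico half of a MIDAS-style targeted workflow: digest each target
protein with trypsin, compute monoisotopic peptide and fragment masses
(carbamidomethyl-C fixed modification by default), pick proteotypic-style
peptides per protein, emit y-ion transitions at precursor charge 2, and pack
the transition list into instrument methods of bounded size without ever
splitting one peptide's transitions across two methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .constants import CARBAMIDOMETHYL, PROTON, RESIDUE_MASS, STANDARD_RESIDUES, WATER

__all__ = [
    "PeptideRecord",
    "Transition",
    "MrmMethod",
    "MethodDesign",
    "digest_tryptic",
    "peptide_mass",
    "precursor_mz",
    "fragment_y_mz",
    "fragment_b_mz",
    "design_method",
]

#: Default fixed modifications: carbamidomethylation of every cysteine.
DEFAULT_FIXED_MODS: Mapping[str, float] = {"C": CARBAMIDOMETHYL}


@dataclass(frozen=True)
class PeptideRecord:
    """A tryptic peptide with its coordinates in the parent sequence.

    ``start``/``end`` are 1-based inclusive positions; ``missed_cleavages``
    counts retained internal cleavage sites.
    """

    sequence: str
    start: int
    end: int
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide coordinates inconsistent with sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Transition:
    """One MRM transition: precursor -> y-ion fragment."""

    protein: str
    peptide: str
    precursor_charge: int
    precursor_mz: float
    fragment: str  # e.g. "y7"
    fragment_charge: int
    fragment_mz: float


@dataclass
class MrmMethod:
    """An ordered list of transitions bounded by instrument capacity."""

    transitions: list[Transition]
    capacity: int

    def __post_init__(self) -> None:
        if len(self.transitions) > self.capacity:
            raise ValueError("method exceeds capacity")

    def __len__(self) -> int:
        return len(self.transitions)


@dataclass
class MethodDesign:
    """Full design output: the methods plus coverage diagnostics."""

    methods: list[MrmMethod]
    under_covered: dict[str, int] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def transitions(self) -> list[Transition]:
        return [t for m in self.methods for t in m.transitions]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mi, method in enumerate(self.methods):
            for t in method.transitions:
                rows.append(
                    {
                        "protein": t.protein,
                        "peptide": t.peptide,
                        "precursor_mz": round(t.precursor_mz, 5),
                        "precursor_z": t.precursor_charge,
                        "fragment": t.fragment,
                        "fragment_mz": round(t.fragment_mz, 5),
                        "method_index": mi,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "protein", "peptide", "precursor_mz", "precursor_z",
                "fragment", "fragment_mz", "method_index",
            ],
        )


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------

def _cleavage_sites(sequence: str, proline_rule: bool) -> list[int]:
    """0-based positions after which trypsin cleaves (C-terminal of K/R)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and not (proline_rule and sequence[i + 1] == "P")
    ]


def digest_tryptic(
    sequence: str, max_missed_cleavages: int = 0, proline_rule: bool = True
) -> list[PeptideRecord]:
    """Tryptic digest of a protein sequence.

    Cleaves C-terminal of K and R; with ``proline_rule`` (the Keil rule,
    default) cleavage is suppressed when the next residue is proline.
    Returns every peptide with 0..``max_missed_cleavages`` retained internal
    sites, ordered by start position then length. The zero-missed-cleavage
    peptides tile the parent sequence exactly.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    bad = set(sequence) - STANDARD_RESIDUES - {"X"}
    if bad:
        raise ValueError(f"invalid residue(s) in sequence: {sorted(bad)}")
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    sites = _cleavage_sites(sequence, proline_rule)
    # fragment boundaries: [start, end) in 0-based coordinates
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    peptides: list[PeptideRecord] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for j in range(i, min(i + max_missed_cleavages + 1, n_frag)):
            start, end = bounds[i], bounds[j + 1]
            peptides.append(
                PeptideRecord(
                    sequence=sequence[start:end],
                    start=start + 1,
                    end=end,
                    missed_cleavages=j - i,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


# ---------------------------------------------------------------------------
# Masses and m/z
# ---------------------------------------------------------------------------

def peptide_mass(
    peptide: str | PeptideRecord,
    fixed_mods: Mapping[str, float] = DEFAULT_FIXED_MODS,
) -> float:
    """Monoisotopic peptide mass: residue masses + water + modification deltas.

    Each modified residue receives its delta once per occurrence (default:
    carbamidomethyl on every C). Unknown residues (including 'X') have no
    defined mass and raise ValueError.
    """
    seq = peptide.sequence if isinstance(peptide, PeptideRecord) else peptide
    if not seq:
        raise ValueError("empty peptide")
    mass = WATER
    for res in seq:
        try:
            mass += RESIDUE_MASS[res]
        except KeyError:
            raise ValueError(f"residue {res!r} has no defined monoisotopic mass") from None
        mass += fixed_mods.get(res, 0.0)
    return mass


def precursor_mz(mass: float, z: int) -> float:
    """m/z of a precursor of neutral monoisotopic mass ``mass`` at charge z."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (mass + z * PROTON) / z


def fragment_y_mz(
    peptide: str | PeptideRecord,
    y_index: int,
    z: int = 1,
    fixed_mods: Mapping[str, float] = DEFAULT_FIXED_MODS,
) -> float:
    """m/z of the y_i ion (C-terminal ``y_index`` residues + water), charge z."""
    seq = peptide.sequence if isinstance(peptide, PeptideRecord) else peptide
    if not 1 <= y_index < len(seq):
        raise ValueError(f"y index must be in [1, {len(seq) - 1}], got {y_index}")
    return precursor_mz(peptide_mass(seq[-y_index:], fixed_mods), z)


def fragment_b_mz(
    peptide: str | PeptideRecord,
    b_index: int,
    z: int = 1,
    fixed_mods: Mapping[str, float] = DEFAULT_FIXED_MODS,
) -> float:
    """m/z of the b_i ion (N-terminal ``b_index`` residues, no water), charge z."""
    seq = peptide.sequence if isinstance(peptide, PeptideRecord) else peptide
    if not 1 <= b_index < len(seq):
        raise ValueError(f"b index must be in [1, {len(seq) - 1}], got {b_index}")
    return precursor_mz(peptide_mass(seq[:b_index], fixed_mods) - WATER, z)


# ---------------------------------------------------------------------------
# Method design
# ---------------------------------------------------------------------------

def _eligible(p: PeptideRecord, min_len: int, max_len: int) -> bool:
    # no ambiguous residue, no oxidation-prone methionine, fully cleaved
    return (
        min_len <= len(p) <= max_len
        and "X" not in p.sequence
        and "M" not in p.sequence
        and p.missed_cleavages == 0
    )


def _rank_key(p: PeptideRecord):
    # fewer missed cleavages, length closest to 12, then lexicographic
    return (p.missed_cleavages, abs(len(p) - 12), p.sequence)


def _peptide_transitions(
    protein: str, pep: PeptideRecord, n_transitions: int, precursor_z: int
) -> list[Transition]:
    """Highest-m/z y-ions above the precursor m/z; fall back to highest available."""
    pmz = precursor_mz(peptide_mass(pep), precursor_z)
    candidates = [
        (fragment_y_mz(pep, i), i) for i in range(1, len(pep))
    ]
    above = sorted((c for c in candidates if c[0] > pmz), reverse=True)
    chosen = above[:n_transitions]
    if len(chosen) < n_transitions:
        rest = sorted((c for c in candidates if c[0] <= pmz), reverse=True)
        chosen += rest[: n_transitions - len(chosen)]
    chosen.sort(key=lambda c: -c[1])  # stable order: descending y index
    return [
        Transition(
            protein=protein,
            peptide=pep.sequence,
            precursor_charge=precursor_z,
            precursor_mz=pmz,
            fragment=f"y{i}",
            fragment_charge=1,
            fragment_mz=mz,
        )
        for mz, i in chosen
    ]


def design_method(
    proteins: Sequence[tuple[str, str]],
    min_peptides: int = 3,
    transitions_per_peptide: int = 3,
    capacity: int = 100,
    precursor_charge: int = 2,
    min_length: int = 7,
    max_length: int = 25,
    proline_rule: bool = True,
) -> MethodDesign:
    """Design MRM methods for a list of (name, sequence) target proteins.

    Per protein: digest with trypsin (0 missed cleavages), keep eligible
    peptides (length ``min_length``..``max_length``, no 'X', no methionine),
    rank them (length closest to 12, ties lexicographic) and select the top
    ``min_peptides``; per selected peptide, emit ``transitions_per_peptide``
    singly-charged y-ion transitions at precursor charge
    ``precursor_charge``. The full transition list is packed greedily into
    methods of at most ``capacity`` transitions; a peptide's transitions are
    never split across methods. Proteins yielding fewer than ``min_peptides``
    eligible peptides are still included with what they have and reported in
    ``under_covered``.
    """
    if not proteins:
        raise ValueError("empty protein list")
    if min_peptides < 1 or transitions_per_peptide < 1:
        raise ValueError("min_peptides and transitions_per_peptide must be >= 1")
    if capacity < transitions_per_peptide:
        raise ValueError("capacity smaller than one peptide's transition block")

    under_covered: dict[str, int] = {}
    blocks: list[list[Transition]] = []  # one block per peptide, never split
    for name, seq in proteins:
        peps = [
            p
            for p in digest_tryptic(seq, max_missed_cleavages=0, proline_rule=proline_rule)
            if _eligible(p, min_length, max_length)
        ]
        peps.sort(key=_rank_key)
        if len(peps) < min_peptides:
            under_covered[name] = len(peps)
        for pep in peps[:min_peptides]:
            block = _peptide_transitions(name, pep, transitions_per_peptide, precursor_charge)
            if block:
                blocks.append(block)

    methods: list[MrmMethod] = []
    current: list[Transition] = []
    for block in blocks:
        if len(current) + len(block) > capacity:
            methods.append(MrmMethod(transitions=current, capacity=capacity))
            current = []
        current.extend(block)
    if current:
        methods.append(MrmMethod(transitions=current, capacity=capacity))

    return MethodDesign(
        methods=methods,
        under_covered=under_covered,
        params={
            "min_peptides": min_peptides,
            "transitions_per_peptide": transitions_per_peptide,
            "capacity": capacity,
            "precursor_charge": precursor_charge,
            "min_length": min_length,
            "max_length": max_length,
            "proline_rule": proline_rule,
        },
    )
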