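"""Readers, writers and validation for every external format the pipeline touches.

Formats: tab-separated intensity matrices (proteins x patients with per-protein
identification scores; empty cell = missing value), one-accession-per-line
text lists, FASTA protein sequences (via Biopython), JSON reports, and the
search-engine acceptance rulesets applied downstream of Spectrum Mill /
Scaffold style identification output.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import FASTA_RESIDUES


class ParseError(ValueError):
    """Malformed input file (message carries the offending line/record)."""


_VERSION_SUFFIX = re.compile(r"\.\d+$")


def canonical_accession(accession: str) -> str:
    """Canonicalize a protein accession.

    Strips surrounding whitespace and a trailing ``.<digits>`` version suffix
    (IPI-style versioning is the main source of spurious set mismatches);
    comparison is case-sensitive otherwise.
    """
    return _VERSION_SUFFIX.sub("", accession.strip())


# ---------------------------------------------------------------------------
# Intensity matrix
# ---------------------------------------------------------------------------

@dataclass
class IntensityMatrix:
    """Protein x patient XIC intensity table with per-protein scores.

    ``values`` is a DataFrame indexed by accession with one column per
    patient; missing observations are NaN (never zero — the zero/ignore
    policy belongs to the analysis, not the container). ``scores`` holds the
    search-engine protein identification score, aligned to ``values.index``.
    """

    values: pd.DataFrame
    scores: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ParseError(f"duplicate accession(s): {dup}")
        if self.values.columns.has_duplicates:
            raise ParseError("duplicate patient identifiers")
        if not self.scores.index.equals(idx):
            raise ParseError("scores index does not match accession index")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ParseError("negative intensity value")

    @property
    def accessions(self) -> list[str]:
        return list(self.values.index)

    @property
    def patients(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def write_intensity_tsv(matrix: IntensityMatrix, path: str | Path) -> None:
    """Write a matrix as TSV: accession, score, then one column per patient.

    Missing cells are written as empty fields.
    """
    out = matrix.values.copy()
    out.insert(0, "score", matrix.scores)
    out.index.name = "accession"
    out.to_csv(path, sep="\t", na_rep="", float_format="%.6g")


def read_intensity_tsv(path: str | Path) -> IntensityMatrix:
    """Read a TSV intensity matrix (inverse of :func:`write_intensity_tsv`).

    Raises :class:`ParseError` with a line number for malformed rows,
    negative intensities, or duplicate accessions.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[1] != "score":
            raise ParseError(f"{path}: header must be accession<TAB>score<TAB>patients...")
        patients = header[2:]
        accessions: list[str] = []
        scores: list[float] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            acc = fields[0]
            if acc in seen:
                raise ParseError(f"{path}:{lineno}: duplicate accession {acc!r}")
            seen.add(acc)
            accessions.append(acc)
            try:
                scores.append(float(fields[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad score {fields[1]!r}") from exc
            row = []
            for cell in fields[2:]:
                if cell == "":
                    row.append(np.nan)
                else:
                    try:
                        v = float(cell)
                    except ValueError as exc:
                        raise ParseError(f"{path}:{lineno}: bad intensity {cell!r}") from exc
                    if v < 0:
                        raise ParseError(f"{path}:{lineno}: negative intensity {v}")
                    row.append(v)
            rows.append(row)
    values = pd.DataFrame(rows, index=accessions, columns=patients, dtype=float)
    return IntensityMatrix(values=values, scores=pd.Series(scores, index=accessions, dtype=float))


# ---------------------------------------------------------------------------
# Accession sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AccessionSet:
    """A named set of canonicalized protein accessions."""

    name: str
    accessions: frozenset[str]
    duplicates_dropped: int = 0

    def __len__(self) -> int:
        return len(self.accessions)

    def __contains__(self, item: str) -> bool:
        return canonical_accession(item) in self.accessions

    @classmethod
    def from_iterable(cls, name: str, items: Iterable[str]) -> "AccessionSet":
        canon = [canonical_accession(a) for a in items if a.strip()]
        unique = frozenset(canon)
        return cls(name=name, accessions=unique, duplicates_dropped=len(canon) - len(unique))


def read_accession_list(path: str | Path, name: str) -> AccessionSet:
    """Read a one-accession-per-line text file ('#' starts a comment).

    Duplicates (after canonicalization) are dropped and counted; an empty
    file yields an empty set with a warning rather than an error.
    """
    tokens: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.append(line)
    if not tokens:
        warnings.warn(f"accession list {path} is empty", stacklevel=2)
    out = AccessionSet.from_iterable(name, tokens)
    if out.duplicates_dropped:
        warnings.warn(
            f"accession list {path}: dropped {out.duplicates_dropped} duplicate(s)",
            stacklevel=2,
        )
    return out


def write_accession_list(accset: AccessionSet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{a}\n" for a in sorted(accset.accessions)), encoding="utf-8")


def read_targeted_tsv(path: str | Path) -> dict[str, int]:
    """Read targeted-identification outcomes: ``accession<TAB>count-or-ND``.

    'ND' (not detected) is encoded as peptide count 0 — the protein was
    tested, no peptide was found. Returns accession -> count.
    """
    out: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected accession<TAB>count")
            acc = canonical_accession(fields[0])
            token = fields[1].strip()
            if token.upper() == "ND":
                out[acc] = 0
            else:
                try:
                    count = int(token)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad peptide count {token!r}") from exc
                if count < 0:
                    raise ParseError(f"{path}:{lineno}: negative peptide count")
                out[acc] = count
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) pairs.

    Sequences must use the 20 standard residues plus 'X'; anything else
    raises :class:`ParseError` naming the offending record.
    """
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - FASTA_RESIDUES
        if bad:
            raise ParseError(
                f"record {rec.id!r}: invalid residue(s) {sorted(bad)}"
            )
        records.append((rec.id, seq))
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def parse_fasta_text(text: str) -> list[tuple[str, str]]:
    """Parse FASTA from an in-memory string (same validation as read_fasta)."""
    records = []
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - FASTA_RESIDUES
        if bad:
            raise ParseError(f"record {rec.id!r}: invalid residue(s) {sorted(bad)}")
        records.append((rec.id, seq))
    return records


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------

def write_report(report: dict, path: str | Path) -> None:
    """Serialize a report dict as deterministic JSON (sorted keys)."""
    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default) + "\n",
        encoding="utf-8",
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# Identification acceptance rules
# ---------------------------------------------------------------------------

@dataclass
class IdentificationRecord:
    """A peptide- or protein-level identification to be filtered.

    ``level`` is ``"peptide"`` or ``"protein"``. ``spi_percent`` is the
    percentage of the spectrum intensity explained by the match;
    ``probability`` the engine's probability of correct identification.
    ``fwd_rev_score`` / ``rank_score`` are the optional forward-minus-reverse
    and rank-1-minus-rank-2 score margins; rules that use them are skipped
    for records that do not carry them.
    """

    level: str = "peptide"
    charge: int | None = None
    score: float | None = None
    spi_percent: float | None = None
    probability: float | None = None
    n_peptides: int | None = None
    fwd_rev_score: float | None = None
    rank_score: float | None = None

    def __post_init__(self) -> None:
        if self.level not in ("peptide", "protein"):
            raise ValueError(f"level must be 'peptide' or 'protein', got {self.level!r}")
        if self.charge is not None and self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.spi_percent is not None and not 0 <= self.spi_percent <= 100:
            raise ValueError("spi_percent must be in [0, 100]")


def _spectrum_mill_margin_ok(rec: IdentificationRecord, threshold: float) -> bool:
    # Margin predicates only apply to records that carry the fields.
    if rec.fwd_rev_score is not None and rec.fwd_rev_score < threshold:
        return False
    if rec.rank_score is not None and rec.rank_score < threshold:
        return False
    return True


def _spectrum_mill_default(rec: IdentificationRecord) -> bool | None:
    """Spectrum Mill autovalidation-style rules (strict inequalities).

    Peptides: charge +2 needs score > 11 and %SPI > 60; charge +3 needs
    score > 13 and %SPI > 70. Proteins need score > 20. The score-margin
    threshold is 2 for both levels, relaxed to 1 for charge +2 spectra with
    score > 6 and %SPI > 90. Returns None when no rule covers the record's
    charge.
    """
    if rec.level == "protein":
        return rec.score is not None and rec.score > 20 and _spectrum_mill_margin_ok(rec, 2)
    if rec.charge == 2:
        if rec.score is None or rec.spi_percent is None:
            return False
        margin = 1 if (rec.score > 6 and rec.spi_percent > 90) else 2
        return rec.score > 11 and rec.spi_percent > 60 and _spectrum_mill_margin_ok(rec, margin)
    if rec.charge == 3:
        if rec.score is None or rec.spi_percent is None:
            return False
        return rec.score > 13 and rec.spi_percent > 70 and _spectrum_mill_margin_ok(rec, 2)
    return None


def _scaffold_default(rec: IdentificationRecord) -> bool | None:
    """Scaffold-style rules: probability > 0.95; proteins need >= 2 peptides."""
    if rec.probability is None:
        return False
    if rec.level == "protein":
        return rec.probability > 0.95 and (rec.n_peptides or 0) >= 2
    return rec.probability > 0.95


RULESETS: dict[str, Callable[[IdentificationRecord], bool | None]] = {
    "spectrum_mill_default": _spectrum_mill_default,
    "scaffold_default": _scaffold_default,
}


def apply_acceptance_rules(
    records: Sequence[IdentificationRecord],
    ruleset: str | Callable[[IdentificationRecord], bool | None] = "spectrum_mill_default",
    on_uncovered: str = "reject",
) -> list[IdentificationRecord]:
    """Filter identifications through a named or user-supplied ruleset.

    The rule callable returns True (keep), False (drop) or None (no rule for
    this record's charge/level); None is resolved by ``on_uncovered``:
    ``"reject"`` (default), ``"accept"``, or ``"error"``. Order-preserving
    and idempotent.
    """
    if isinstance(ruleset, str):
        try:
            rule = RULESETS[ruleset]
        except KeyError:
            raise ValueError(f"unknown ruleset {ruleset!r}; known: {sorted(RULESETS)}") from None
    else:
        rule = ruleset
    if on_uncovered not in ("reject", "accept", "error"):
        raise ValueError("on_uncovered must be 'reject', 'accept' or 'error'")
    kept = []
    for rec in records:
        verdict = rule(rec)
        if verdict is None:
            if on_uncovered == "error":
                raise ValueError(f"no acceptance rule covers record {rec}")
            verdict = on_uncovered == "accept"
        if verdict:
            kept.append(rec)
    return kept
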