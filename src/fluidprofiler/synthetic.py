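"""Synthetic data with the statistical structure the analyses assume.

Three generators: (1) label-free intensity matrices — log-normal per-protein
base abundance, multiplicative log-normal patient noise, a designated
"blood-protein" contamination signature multiplied up in perturbed patients
(emulating haemolysis of a fluid sample), abundance-dependent missingness
and abundance-correlated identification scores; (2) three accession
universes realizing an exact, requested seven-region overlap structure with
targeted-detection outcomes on the query-only region; (3) protein sequences
guaranteed to digest into enough tryptic peptides for MRM design. All
generators are bit-reproducible under a seed, and every generator returns
the ground truth needed for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import AccessionSet, IntensityMatrix
from .set_comparison import RegionCounts

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "gen_intensity_dataset",
    "gen_accession_universe",
    "gen_targeted_counts",
    "gen_protein_fasta",
]


class ConfigError(ValueError):
    """Invalid generator configuration (message names the field)."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the intensity-matrix generator.

    Defaults emulate the motivating cohort: 14 patients, 139 identified
    proteins, three perturbed patients (indices 2, 3, 11 — i.e. patients
    3, 4 and 12 under 1-based labels) carrying a 4-fold blood-contamination
    signature on 10% of proteins.

    ``abundance_sigma`` and ``patient_sigma`` are natural-log-scale standard
    deviations of the per-protein base abundance and the per-cell patient
    noise; ``missing_rate_base`` is the missingness probability of the very
    lowest-abundance observations (missingness decays with abundance).
    """

    n_patients: int = 14
    n_proteins: int = 139
    outlier_patients: tuple[int, ...] = (2, 3, 11)
    outlier_effect: float = 4.0
    contamination_fraction: float = 0.10
    missing_rate_base: float = 0.25
    abundance_sigma: float = 1.0
    patient_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigError("n_patients must be >= 2")
        if self.n_proteins < 2:
            raise ConfigError("n_proteins must be >= 2")
        if not 0 <= self.missing_rate_base < 1:
            raise ConfigError("missing_rate_base must be in [0, 1)")
        if not 0 <= self.contamination_fraction <= 1:
            raise ConfigError("contamination_fraction must be in [0, 1]")
        if self.outlier_effect <= 0:
            raise ConfigError("outlier_effect must be > 0")
        if self.abundance_sigma < 0:
            raise ConfigError("abundance_sigma must be >= 0")
        if self.patient_sigma < 0:
            raise ConfigError("patient_sigma must be >= 0")
        bad = [i for i in self.outlier_patients if not 0 <= i < self.n_patients]
        if bad:
            raise ConfigError(f"outlier_patients indices out of range: {bad}")
        object.__setattr__(self, "outlier_patients", tuple(self.outlier_patients))


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests."""

    perturbed_patients: tuple[str, ...] = ()
    contamination_proteins: tuple[str, ...] = ()
    partition_counts: RegionCounts | None = None
    targeted_detected: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "perturbed_patients": list(self.perturbed_patients),
            "contamination_proteins": list(self.contamination_proteins),
            "partition_counts": (
                self.partition_counts.as_dict() if self.partition_counts else None
            ),
            "targeted_detected": list(self.targeted_detected),
        }


def _unique_ipi_accessions(n: int, rng: np.random.Generator) -> list[str]:
    """IPI-style accessions ("IPI" + 8 digits), collision-free."""
    numbers = rng.choice(90_000_000, size=n, replace=False) + 10_000_000
    return [f"IPI{int(x):08d}" for x in numbers]


def gen_intensity_dataset(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[IntensityMatrix, SyntheticTruth]:
    """Simulate a label-free protein-intensity matrix with known perturbations.

    Per protein, a log-normal base abundance; per cell, multiplicative
    log-normal patient noise; the contamination-signature proteins of each
    perturbed patient are multiplied by ``outlier_effect``. Cells then go
    missing with probability ``missing_rate_base * (1 - q)**2`` where q is
    the cell's abundance quantile within the dataset (low-abundance signals
    are the ones label-free LC-MS fails to observe). Identification scores
    are positive and correlated with mean protein abundance.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    accessions = _unique_ipi_accessions(cfg.n_proteins, rng)
    width = max(2, len(str(cfg.n_patients)))
    patients = [f"P{i + 1:0{width}d}" for i in range(cfg.n_patients)]

    log_base = rng.normal(np.log(1e6), cfg.abundance_sigma, size=cfg.n_proteins)
    log_noise = rng.normal(0.0, cfg.patient_sigma, size=(cfg.n_proteins, cfg.n_patients))
    intensity = np.exp(log_base[:, None] + log_noise)

    # blood-protein signature: drawn abundance-weighted — the proteins a
    # haemolysed sample gains (haemoglobin, albumin, ...) are high-abundance
    n_contam = int(round(cfg.contamination_fraction * cfg.n_proteins))
    weights = np.exp(log_base) / np.exp(log_base).sum()
    contam_idx = np.sort(
        rng.choice(cfg.n_proteins, size=n_contam, replace=False, p=weights)
    )
    for j in cfg.outlier_patients:
        intensity[contam_idx, j] *= cfg.outlier_effect

    # abundance-dependent missingness: quantile of each cell in the dataset
    flat = intensity.ravel()
    quantile = np.empty_like(flat)
    quantile[np.argsort(flat, kind="stable")] = np.linspace(0, 1, flat.size)
    p_missing = cfg.missing_rate_base * (1.0 - quantile.reshape(intensity.shape)) ** 2
    missing = rng.random(intensity.shape) < p_missing

    values = pd.DataFrame(intensity, index=accessions, columns=patients)
    values = values.mask(missing)

    log_mean = np.log(intensity.mean(axis=1))
    z = (log_mean - log_mean.mean()) / (log_mean.std() or 1.0)
    scores = 50.0 * np.exp(z + rng.normal(0.0, 0.5, size=cfg.n_proteins))
    matrix = IntensityMatrix(
        values=values, scores=pd.Series(scores, index=accessions, dtype=float)
    )
    truth = SyntheticTruth(
        perturbed_patients=tuple(patients[j] for j in sorted(cfg.outlier_patients)),
        contamination_proteins=tuple(accessions[i] for i in contam_idx),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Accession universes
# ---------------------------------------------------------------------------

def gen_accession_universe(
    partition_counts: RegionCounts,
    targeted_hit_count: int = 0,
    seed: int = 0,
    names: tuple[str, str, str] = ("AC", "CSF", "plasma"),
) -> tuple[AccessionSet, AccessionSet, AccessionSet, SyntheticTruth]:
    """Three accession sets realizing an exact seven-region overlap structure.

    ``targeted_hit_count`` of the A-only region members are marked as
    detected by targeted MS (``truth.targeted_detected``); re-partitioning
    the returned sets reproduces ``partition_counts`` exactly.
    """
    if targeted_hit_count < 0:
        raise ConfigError("targeted_hit_count must be >= 0")
    if targeted_hit_count > partition_counts.a_only:
        raise ConfigError(
            f"targeted_hit_count ({targeted_hit_count}) exceeds the A-only "
            f"region size ({partition_counts.a_only})"
        )
    rng = np.random.default_rng(seed)
    pool = _unique_ipi_accessions(partition_counts.total, rng)
    it = iter(pool)
    region = {
        name: [next(it) for _ in range(getattr(partition_counts, name))]
        for name in ("a_only", "b_only", "c_only", "ab_only", "ac_only", "bc_only", "abc")
    }
    a = AccessionSet.from_iterable(
        names[0], region["a_only"] + region["ab_only"] + region["ac_only"] + region["abc"]
    )
    b = AccessionSet.from_iterable(
        names[1], region["b_only"] + region["ab_only"] + region["bc_only"] + region["abc"]
    )
    c = AccessionSet.from_iterable(
        names[2], region["c_only"] + region["ac_only"] + region["bc_only"] + region["abc"]
    )
    detected = rng.choice(
        np.array(region["a_only"], dtype=object), size=targeted_hit_count, replace=False
    ) if targeted_hit_count else np.array([], dtype=object)
    truth = SyntheticTruth(
        partition_counts=partition_counts,
        targeted_detected=tuple(sorted(str(x) for x in detected)),
    )
    return a, b, c, truth


def gen_targeted_counts(
    tested: Iterable[str],
    detected: Iterable[str],
    seed: int = 0,
    max_peptides: int = 12,
) -> dict[str, int]:
    """Targeted-MS peptide counts: detected proteins get 1..max_peptides, the
    rest of the tested proteins get 0 (ND)."""
    rng = np.random.default_rng(seed)
    detected = set(detected)
    out: dict[str, int] = {}
    for acc in sorted(tested):
        out[acc] = int(rng.integers(1, max_peptides + 1)) if acc in detected else 0
    missing = detected - set(out)
    if missing:
        raise ConfigError(f"detected accessions not among tested: {sorted(missing)}")
    return out


# ---------------------------------------------------------------------------
# Protein sequences
# ---------------------------------------------------------------------------

_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# anchor-segment bodies avoid K/R (would add cleavage sites), M (excluded by
# MRM peptide eligibility) and P (suppresses the upstream cleavage)
_ANCHOR_BODY = np.array(list("ACDEFGHLNQSTVWY"))


def _build_sequence(length: int, rng: np.random.Generator) -> str:
    """A random protein of exactly ``length`` residues whose tryptic digest
    contains >= 3 internal K/R sites, arranged as clean 'anchor' peptides."""
    if length < 7:
        raise ConfigError("sequence length must be >= 7")
    parts: list[str] = []
    remaining = length
    for anchors_left in (3, 2, 1):
        # leave room for the other anchors (>=2 residues each) and 1 tail residue
        reserve = (anchors_left - 1) * 2 + 1
        hi = min(16, remaining - reserve)
        lo = min(8, hi)
        seg_len = int(rng.integers(lo, hi + 1))
        body = rng.choice(_ANCHOR_BODY, size=seg_len - 1)
        parts.append("".join(body) + ("K" if rng.random() < 0.5 else "R"))
        remaining -= seg_len
    tail = rng.choice(_ALPHABET, size=remaining)
    while tail[0] == "P":  # would suppress the last anchor's cleavage
        tail[0] = rng.choice(_ANCHOR_BODY)
    return "".join(parts) + "".join(tail)


def gen_protein_fasta(
    n_proteins: int,
    length_range: tuple[int, int] = (120, 200),
    seed: int = 0,
) -> str:
    """FASTA text of random proteins suitable for in-silico MRM design.

    Every sequence carries at least three internal tryptic cleavage sites
    (and, when the length allows, at least three eligible 8-16-residue
    tryptic peptides free of K/R/M/P complications). Deterministic under
    ``seed``.
    """
    if n_proteins < 1:
        raise ConfigError("n_proteins must be >= 1")
    lo, hi = length_range
    if lo < 7 or hi < lo:
        raise ConfigError("length_range must satisfy 7 <= lo <= hi")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        records.append((f"SYN{i + 1:04d}", _build_sequence(length, rng)))
    lines = []
    for name, seq in records:
        lines.append(f">{name}")
        lines.extend(seq[j : j + 60] for j in range(0, len(seq), 60))
    return "\n".join(lines) + "\n"
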