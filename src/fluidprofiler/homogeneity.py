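"""Inter-patient protein-profile homogeneity analysis.

The screening question: given a label-free XIC intensity matrix
(proteins x patients), do any patients diverge systematically from the rest?
The procedure: (1) scale every patient column so its intensity total matches
a reference patient's total; (2) run PCA with patients as observations and
proteins as mean-centered variables; (3) express each patient's position in
the leading principal-component plane as a distance from the sample mean in
per-axis standard-deviation units; (4) stabilize the distance against the
influence of any single protein by redrawing random protein subsets
(by default 50 proteins, 1000 iterations) and averaging the per-patient
distance over the draws. Patients with consistently large mean subsampled
distance are candidate outliers (e.g. blood contamination of a fluid
sample); a homogeneous cohort shows no such separation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import IntensityMatrix

__all__ = [
    "NormalizedMatrix",
    "PcaResult",
    "DistanceReport",
    "normalize_total_sum",
    "top_k_by_score",
    "run_pca",
    "patient_distances",
    "subsample_distances",
    "homogeneity_report",
]


class DegenerateDataError(ValueError):
    """Raised when the data carry no variance to analyze."""


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizedMatrix:
    """Total-sum normalized intensities (missing cells already zero-filled).

    Every patient column is multiplied by ``total(reference)/total(patient)``
    so all column totals equal the reference patient's total.
    """

    values: pd.DataFrame
    scores: pd.Series
    reference: str
    scale_factors: pd.Series

    @property
    def patients(self) -> list[str]:
        return list(self.values.columns)

    @property
    def accessions(self) -> list[str]:
        return list(self.values.index)


def normalize_total_sum(
    matrix: IntensityMatrix, reference: str = "auto"
) -> NormalizedMatrix:
    """Scale each patient to the reference patient's total intensity.

    Missing cells are treated as zero (non-detection in label-free XIC data)
    both for the totals and in the returned values. ``reference="auto"``
    picks the patient whose total is closest to the median total (ties break
    on patient order). A patient whose total is zero cannot be scaled and is
    reported by name.
    """
    values = matrix.values.fillna(0.0)
    totals = values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"patient(s) with zero total intensity: {list(zero.index)}")
    if reference == "auto":
        med = totals.median()
        reference = (totals - med).abs().idxmin()
    elif reference not in values.columns:
        raise ValueError(f"unknown reference patient {reference!r}")
    factors = totals[reference] / totals
    return NormalizedMatrix(
        values=values * factors,
        scores=matrix.scores.copy(),
        reference=str(reference),
        scale_factors=factors,
    )


def top_k_by_score(
    matrix: IntensityMatrix | NormalizedMatrix, k: int
) -> "IntensityMatrix | NormalizedMatrix":
    """Restrict to the k proteins with highest identification score.

    Ties are broken by ascending accession so the selection is deterministic.
    Returns the same container type as the input.
    """
    n = len(matrix.scores)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    order = (
        pd.DataFrame({"score": matrix.scores})
        .rename_axis("accession")
        .sort_values(["score", "accession"], ascending=[False, True])
        .index[:k]
    )
    if isinstance(matrix, NormalizedMatrix):
        return NormalizedMatrix(
            values=matrix.values.loc[order],
            scores=matrix.scores.loc[order],
            reference=matrix.reference,
            scale_factors=matrix.scale_factors,
        )
    return IntensityMatrix(values=matrix.values.loc[order], scores=matrix.scores.loc[order])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    """PCA of patients (observations) over proteins (variables).

    ``scores`` is patients x components; ``loadings`` proteins x components
    with orthonormal columns; ``explained_fraction[i]`` the fraction of the
    total variance carried by component i (non-increasing).
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_fraction: np.ndarray
    n_components: int


def _pca_core(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of the mean-centered observation matrix.

    X is observations x variables. Returns (scores, loadings, explained),
    retaining min(n_obs - 1, n_vars) components. Raises DegenerateDataError
    when the centered matrix has no variance. Component signs are fixed so
    the largest-magnitude loading of each component is positive.
    """
    n_obs, n_vars = X.shape
    if n_obs < 2:
        raise DegenerateDataError("PCA needs at least 2 observations")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 0:
        raise DegenerateDataError("zero total variance: all observations identical")
    nc = min(n_obs - 1, n_vars)
    U, s, Vt = U[:, :nc], s[:nc], Vt[:nc]
    # deterministic sign convention
    flip = np.sign(Vt[np.arange(nc), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores = U * s * flip
    loadings = (Vt * flip[:, None]).T
    explained = s**2 / total
    return scores, loadings, explained


def run_pca(matrix: NormalizedMatrix | IntensityMatrix | pd.DataFrame) -> PcaResult:
    """PCA of the intensity table: patients are observations, proteins variables.

    Variables are mean-centered but not variance-scaled; components come from
    the singular value decomposition of the centered patients x proteins
    matrix, and ``explained_fraction`` is each eigenvalue's share of the
    total variance.
    """
    values = matrix if isinstance(matrix, pd.DataFrame) else matrix.values
    if isinstance(matrix, IntensityMatrix):
        values = values.fillna(0.0)
    X = values.to_numpy(dtype=float).T  # patients x proteins
    scores, loadings, explained = _pca_core(X)
    comps = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=values.columns, columns=comps),
        loadings=pd.DataFrame(loadings, index=values.index, columns=comps),
        explained_fraction=explained,
        n_components=len(comps),
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _standardized_distances(
    scores: np.ndarray, n_components: int, mode: str, warn: bool = True
) -> np.ndarray:
    """Distance of each observation from the score centroid, in SD units.

    PCA scores are centered, so the centroid (sample mean) is the origin of
    score space. ``mode="per-axis"`` divides each retained component by its
    own across-patient SD before taking the Euclidean norm; ``mode="pooled"``
    divides the plain Euclidean norm by the root-mean-square of the retained
    per-axis SDs. A zero-variance axis contributes nothing.
    """
    S = scores[:, :n_components]
    sd = S.std(axis=0, ddof=1)
    live = sd > 0
    if not live.all() and warn:
        warnings.warn("zero-variance principal component contributes 0 to distances")
    if mode == "per-axis":
        Z = np.zeros_like(S)
        Z[:, live] = S[:, live] / sd[live]
        return np.sqrt((Z**2).sum(axis=1))
    if mode == "pooled":
        pooled = np.sqrt((sd[live] ** 2).mean()) if live.any() else 0.0
        if pooled == 0:
            return np.zeros(S.shape[0])
        return np.sqrt((S[:, live] ** 2).sum(axis=1)) / pooled
    raise ValueError(f"mode must be 'per-axis' or 'pooled', got {mode!r}")


def patient_distances(
    pca: PcaResult, n_components: int = 2, mode: str = "per-axis"
) -> pd.Series:
    """Standardized distance of each patient from the sample mean.

    Uses the first ``n_components`` principal components (clipped to what the
    decomposition provides when requesting the full space).
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > pca.n_components:
        raise ValueError(
            f"n_components={n_components} exceeds available {pca.n_components}"
        )
    d = _standardized_distances(pca.scores.to_numpy(), n_components, mode)
    return pd.Series(d, index=pca.scores.index, name="distance")


def subsample_distances(
    matrix: NormalizedMatrix | pd.DataFrame,
    m: int = 50,
    B: int = 1000,
    seed: int | None = None,
    n_components: int = 2,
    mode: str = "per-axis",
    exhaustive: bool = False,
) -> tuple[pd.Series, int]:
    """Mean standardized distance over repeated random protein subsets.

    Each iteration draws ``m`` proteins uniformly without replacement, runs a
    self-contained PCA on the sub-matrix and measures each patient's
    standardized distance in the leading ``n_components``-dimensional score
    space; the result is the per-patient arithmetic mean over ``B``
    iterations. ``exhaustive=True`` replaces the random draws with one pass
    over every m-subset (ignoring ``B``) — feasible only for tiny problems.
    Iterations in which the sub-matrix is degenerate (zero variance) are
    skipped; the count of skipped iterations is returned alongside.
    """
    values = matrix if isinstance(matrix, pd.DataFrame) else matrix.values
    X = values.to_numpy(dtype=float).T  # patients x proteins
    n_patients, n_proteins = X.shape
    if not 1 <= m <= n_proteins:
        raise ValueError(f"m must be in [1, {n_proteins}], got {m}")
    if B < 1:
        raise ValueError("B must be >= 1")
    nc = min(n_components, n_patients - 1, m)

    if exhaustive:
        draws: Iterable[np.ndarray] = (
            np.fromiter(c, dtype=np.intp, count=m)
            for c in itertools.combinations(range(n_proteins), m)
        )
    else:
        rng = np.random.default_rng(seed)
        draws = (rng.choice(n_proteins, size=m, replace=False) for _ in range(B))

    acc = np.zeros(n_patients)
    used = 0
    skipped = 0
    for idx in draws:
        sub = X[:, idx]
        try:
            scores, _, _ = _pca_core(sub)
        except DegenerateDataError:
            skipped += 1
            continue
        acc += _standardized_distances(scores, min(nc, scores.shape[1]), mode, warn=False)
        used += 1
    if used == 0:
        raise DegenerateDataError("every subsampling iteration was degenerate")
    return pd.Series(acc / used, index=values.columns, name="mean_distance"), skipped


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class DistanceReport:
    """Per-patient distances for the full, top-k and subsampled analyses.

    ``table`` has one row per patient and columns ``d_all``, ``d_topk``,
    ``d_subsampled_mean`` (all in SD units) plus ``flagged`` when a flag
    threshold was given. ``params`` records every parameter and seed used.
    """

    table: pd.DataFrame
    params: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "params": dict(self.params),
            "patients": {
                str(p): {k: (bool(v) if k == "flagged" else float(v)) for k, v in row.items()}
                for p, row in self.table.iterrows()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DistanceReport":
        table = pd.DataFrame.from_dict(d["patients"], orient="index")
        return cls(table=table, params=dict(d["params"]))


def homogeneity_report(
    matrix: IntensityMatrix,
    k: int = 50,
    m: int = 50,
    B: int = 1000,
    seed: int | None = None,
    flag_threshold: float | None = None,
    reference: str = "auto",
    log_transform: bool = False,
    n_components: int = 2,
    mode: str = "per-axis",
) -> DistanceReport:
    """The full homogeneity screen: d_all, d_topk and subsampled mean distance.

    ``log_transform`` applies log10(x+1) to the normalized intensities before
    every PCA (off by default). When ``flag_threshold`` is given, patients
    with ``d_subsampled_mean >= flag_threshold`` are flagged as candidate
    outliers; otherwise the report ranks without flagging.
    """
    norm = normalize_total_sum(matrix, reference=reference)
    values = np.log10(norm.values + 1.0) if log_transform else norm.values

    d_all = patient_distances(run_pca(values), n_components=n_components, mode=mode)
    topk = top_k_by_score(norm, k)
    vals_topk = np.log10(topk.values + 1.0) if log_transform else topk.values
    d_topk = patient_distances(run_pca(vals_topk), n_components=n_components, mode=mode)
    d_sub, skipped = subsample_distances(
        values, m=m, B=B, seed=seed, n_components=n_components, mode=mode
    )

    table = pd.DataFrame(
        {"d_all": d_all, "d_topk": d_topk, "d_subsampled_mean": d_sub}
    )
    if flag_threshold is not None:
        table["flagged"] = table["d_subsampled_mean"] >= flag_threshold
    params = {
        "k": k,
        "m": m,
        "B": B,
        "seed": seed,
        "reference": norm.reference,
        "log_transform": log_transform,
        "n_components": n_components,
        "mode": mode,
        "flag_threshold": flag_threshold,
        "skipped_iterations": skipped,
    }
    return DistanceReport(table=table, params=params)
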