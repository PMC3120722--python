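"""Normalization, PCA, standardized distances and the subsampling scheme.

The PCA and distance routes are checked against independent brute-force
oracles: covariance eigendecomposition for the components, a straight-line
center/SVD/SD/norm recomputation for distances, and exhaustive subset
enumeration for the subsampling mean.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fluidprofiler.homogeneity import (
    DegenerateDataError,
    DistanceReport,
    homogeneity_report,
    normalize_total_sum,
    patient_distances,
    run_pca,
    subsample_distances,
    top_k_by_score,
)
from fluidprofiler.io_formats import IntensityMatrix, read_report, write_report
from fluidprofiler.synthetic import SyntheticConfig, gen_intensity_dataset


def _matrix_from(values: np.ndarray) -> IntensityMatrix:
    n = values.shape[0]
    idx = [f"IPI{i:08d}" for i in range(1, n + 1)]
    return IntensityMatrix(
        values=pd.DataFrame(values, index=idx,
                            columns=[f"S{j}" for j in range(values.shape[1])]),
        scores=pd.Series(np.arange(n, dtype=float) + 1, index=idx),
    )


class TestNormalization:
    def test_scale_factor_forced_by_totals(self):
        matrix = _matrix_from(np.array([[10.0, 20.0], [30.0, 60.0]]))
        norm = normalize_total_sum(matrix, reference="S1")
        assert norm.scale_factors["S0"] == pytest.approx(2.0)
        assert norm.values.loc["IPI00000001", "S0"] == pytest.approx(20.0)

    def test_reference_column_unchanged(self):
        matrix = _matrix_from(np.array([[10.0, 20.0], [30.0, 60.0]]))
        norm = normalize_total_sum(matrix, reference="S1")
        assert norm.values["S1"].equals(matrix.values["S1"])
        assert norm.scale_factors["S1"] == pytest.approx(1.0)

    def test_totals_conserved_on_generated_data(self):
        matrix, _ = gen_intensity_dataset(SyntheticConfig(seed=10))
        norm = normalize_total_sum(matrix)
        totals = norm.values.sum(axis=0)
        ref_total = totals[norm.reference]
        assert np.allclose(totals, ref_total, rtol=1e-9)

    def test_auto_reference_is_median_total_patient(self):
        values = np.array([[1.0, 2.0, 10.0]] * 3)  # totals 3, 6, 30
        norm = normalize_total_sum(_matrix_from(values))
        assert norm.reference == "S1"

    def test_zero_total_patient_named(self):
        values = np.array([[1.0, 0.0], [2.0, np.nan]])
        with pytest.raises(ValueError, match="S1"):
            normalize_total_sum(_matrix_from(values))


class TestTopK:
    def test_selects_highest_scores(self, tiny_matrix):
        top2 = top_k_by_score(tiny_matrix, 2)
        assert list(top2.scores.sort_values(ascending=False)) == [9.0, 7.0]

    def test_k_equal_n_is_identity(self, tiny_matrix):
        top = top_k_by_score(tiny_matrix, 4)
        assert set(top.accessions) == set(tiny_matrix.accessions)

    def test_tie_at_rank_k_breaks_by_accession(self):
        values = np.ones((3, 2))
        matrix = _matrix_from(values)
        matrix.scores[:] = [5.0, 5.0, 9.0]
        top2 = top_k_by_score(matrix, 2)
        assert list(top2.accessions) == ["IPI00000003", "IPI00000001"]

    def test_k_out_of_range(self, tiny_matrix):
        with pytest.raises(ValueError):
            top_k_by_score(tiny_matrix, 5)


class TestPca:
    def test_rank_one_configuration_explains_everything(self):
        # patients at (1,1), (-1,-1), (0,0) in 2-protein space
        values = np.array([[1.0, -1.0, 0.0], [1.0, -1.0, 0.0]]) + 5.0
        pca = run_pca(_matrix_from(values).values)
        assert pca.explained_fraction[0] == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.gamma(2.0, 10.0, size=(4, 5))  # 4 proteins x 5 patients
        pca = run_pca(pd.DataFrame(values))
        X = values.T - values.T.mean(axis=0)
        eigval, eigvec = np.linalg.eigh(np.cov(X, rowvar=False))
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        oracle_scores = X @ eigvec
        for j in range(pca.n_components):
            got = pca.scores.to_numpy()[:, j]
            want = oracle_scores[:, j]
            assert np.allclose(got, want, atol=1e-8) or np.allclose(got, -want, atol=1e-8)
        total = eigval.sum()
        assert np.allclose(pca.explained_fraction, (eigval / total)[: pca.n_components],
                           atol=1e-12)

    def test_explained_fractions_sum_to_one_at_full_rank(self):
        rng = np.random.default_rng(0)
        pca = run_pca(pd.DataFrame(rng.normal(size=(6, 5))))  # 6 proteins, 5 patients
        assert pca.n_components == 4
        assert pca.explained_fraction.sum() == pytest.approx(1.0)
        assert all(np.diff(pca.explained_fraction) <= 1e-12)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        pca = run_pca(pd.DataFrame(rng.normal(size=(8, 5))))
        gram = pca.loadings.to_numpy().T @ pca.loadings.to_numpy()
        assert np.allclose(gram, np.eye(pca.n_components), atol=1e-10)

    def test_identical_patients_degenerate(self):
        with pytest.raises(DegenerateDataError):
            run_pca(pd.DataFrame(np.ones((3, 4))))


class TestDistances:
    def test_patient_at_centroid_has_zero_distance(self):
        # S2 sits exactly at the mean of S0 and S1 for every protein
        values = pd.DataFrame(
            [[1.0, 3.0, 2.0], [5.0, 1.0, 3.0], [2.0, 6.0, 4.0]],
            columns=["S0", "S1", "S2"],
        )
        d = patient_distances(run_pca(values), n_components=2)
        assert d["S2"] == pytest.approx(0.0, abs=1e-10)

    def test_symmetric_patients_equidistant(self):
        values = pd.DataFrame([[1.0, 3.0], [5.0, 1.0]], columns=["S0", "S1"])
        d = patient_distances(run_pca(values), n_components=1)
        assert d["S0"] == pytest.approx(d["S1"])

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(8)
        values = rng.gamma(2.0, 5.0, size=(6, 4))
        d = patient_distances(run_pca(pd.DataFrame(values)), n_components=2)
        # independent straight-line recomputation: center, SVD, per-axis SD, norm
        X = values.T - values.T.mean(axis=0)
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        S = (U * s)[:, :2]
        Z = S / S.std(axis=0, ddof=1)
        want = np.sqrt((Z**2).sum(axis=1))
        assert np.allclose(d.to_numpy(), want, atol=1e-8)

    def test_scale_invariance(self):
        matrix, _ = gen_intensity_dataset(SyntheticConfig(seed=12))
        norm = normalize_total_sum(matrix)
        d1 = patient_distances(run_pca(norm.values))
        d2 = patient_distances(run_pca(norm.values * 1000.0))
        assert np.allclose(d1, d2, rtol=1e-9)

    def test_pooled_mode_and_component_bound(self):
        rng = np.random.default_rng(5)
        pca = run_pca(pd.DataFrame(rng.normal(size=(6, 4))))
        d = patient_distances(pca, n_components=2, mode="pooled")
        assert (d >= 0).all()
        with pytest.raises(ValueError):
            patient_distances(pca, n_components=99)


class TestSubsampling:
    def test_full_set_subsample_equals_full_distance(self):
        matrix, _ = gen_intensity_dataset(
            SyntheticConfig(n_patients=8, n_proteins=20, outlier_patients=(), seed=4)
        )
        norm = normalize_total_sum(matrix)
        d_full = patient_distances(run_pca(norm.values), n_components=2)
        d_sub, skipped = subsample_distances(norm.values, m=20, B=5, seed=0)
        assert skipped == 0
        assert np.allclose(d_sub.to_numpy(), d_full.to_numpy(), atol=1e-12)

    def test_exhaustive_enumeration_matches_brute_force(self):
        rng = np.random.default_rng(7)
        values = pd.DataFrame(rng.gamma(2.0, 5.0, size=(4, 5)))
        d_sub, skipped = subsample_distances(values, m=2, B=1, exhaustive=True)
        # brute force over all 6 two-protein subsets
        acc = np.zeros(5)
        for combo in itertools.combinations(range(4), 2):
            sub = values.iloc[list(combo)]
            acc += patient_distances(run_pca(sub), n_components=2).to_numpy()
        assert skipped == 0
        assert np.allclose(d_sub.to_numpy(), acc / 6, atol=1e-10)

    def test_seed_determinism(self):
        matrix, _ = gen_intensity_dataset(SyntheticConfig(seed=5))
        norm = normalize_total_sum(matrix)
        d1, _ = subsample_distances(norm.values, m=50, B=20, seed=42)
        d2, _ = subsample_distances(norm.values, m=50, B=20, seed=42)
        d3, _ = subsample_distances(norm.values, m=50, B=20, seed=43)
        assert d1.equals(d2)
        assert not d1.equals(d3)

    def test_mean_converges_as_iterations_grow(self):
        matrix, _ = gen_intensity_dataset(SyntheticConfig(seed=9))
        norm = normalize_total_sum(matrix)
        big, _ = subsample_distances(norm.values, m=50, B=800, seed=0)
        halves = [
            subsample_distances(norm.values, m=50, B=100, seed=s)[0] for s in (1, 2)
        ]
        spread_small = (halves[0] - halves[1]).abs().max()
        big2, _ = subsample_distances(norm.values, m=50, B=800, seed=3)
        spread_big = (big - big2).abs().max()
        assert spread_big < spread_small

    def test_m_larger_than_protein_count_rejected(self):
        values = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 3)))
        with pytest.raises(ValueError):
            subsample_distances(values, m=5, B=2)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    arrays(
        np.float64,
        st.tuples(st.integers(2, 6), st.integers(2, 6)),
        elements=st.floats(0.1, 100.0, allow_nan=False),
    )
)
def test_pca_oracle_equivalence_property(values):
    """SVD route equals covariance-eigendecomposition route on small matrices."""
    X = values.T - values.T.mean(axis=0)
    if np.allclose(X, 0):
        return
    pca = run_pca(pd.DataFrame(values))
    eigval, eigvec = np.linalg.eigh(np.cov(X, rowvar=False, ddof=1))
    order = np.argsort(eigval)[::-1]
    oracle = X @ eigvec[:, order]
    for j in range(pca.n_components):
        got, want = pca.scores.to_numpy()[:, j], oracle[:, j]
        assert np.allclose(got, want, atol=1e-8) or np.allclose(got, -want, atol=1e-8)


class TestReport:
    def test_flags_exactly_the_spiked_patients(self):
        matrix, truth = gen_intensity_dataset(SyntheticConfig(seed=21))
        report = homogeneity_report(matrix, B=300, seed=2)
        ranked = report.table["d_subsampled_mean"].sort_values(ascending=False)
        margin = (ranked.iloc[2] + ranked.iloc[3]) / 2  # between rank 3 and 4
        flagged = homogeneity_report(matrix, B=300, seed=2, flag_threshold=margin)
        hit = set(flagged.table.index[flagged.table["flagged"]])
        assert hit == set(truth.perturbed_patients)

    def test_unperturbed_cohort_not_flagged(self):
        cfg = SyntheticConfig(outlier_patients=(), seed=30)
        matrix, _ = gen_intensity_dataset(cfg)
        report = homogeneity_report(matrix, B=200, seed=1)
        d = report.table["d_subsampled_mean"]
        assert d.max() / d.min() < 5
        above = homogeneity_report(matrix, B=200, seed=1, flag_threshold=d.max() + 0.01)
        assert not above.table["flagged"].any()

    def test_report_serialization_round_trips(self, tmp_path):
        matrix, _ = gen_intensity_dataset(
            SyntheticConfig(n_patients=6, n_proteins=30, outlier_patients=(), seed=2)
        )
        report = homogeneity_report(matrix, k=10, m=10, B=20, seed=3)
        path = tmp_path / "report.json"
        write_report(report.to_dict(), path)
        back = DistanceReport.from_dict(read_report(path))
        assert np.allclose(
            back.table[["d_all", "d_topk", "d_subsampled_mean"]].to_numpy(),
            report.table.to_numpy(),
        )
        assert back.params["seed"] == 3
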