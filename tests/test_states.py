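"""State analysis: Ward clustering, PCA metrics, and the phi persistence metric."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import special_ortho_group
from sklearn.metrics import adjusted_rand_score

from signalome.states import (
    PCACoordinateSystem,
    adherence_pc1,
    cluster_drugs,
    drug_strength,
    fit_pca,
    pathway_correlations,
    phi_metric,
    psi_conformity,
)


def _frame(data, columns=None):
    data = np.asarray(data, float)
    columns = columns or [f"p{i}" for i in range(data.shape[1])]
    return pd.DataFrame(data, columns=columns, index=[f"d{i}" for i in range(len(data))])


class TestClusterDrugs:
    def test_one_dimensional_toy_splits_at_large_gap(self):
        m = _frame([[0.0], [0.1], [10.0], [10.1]])
        ca = cluster_drugs(m, k=2)
        assert ca.labels["d0"] == ca.labels["d1"]
        assert ca.labels["d2"] == ca.labels["d3"]
        assert ca.labels["d0"] != ca.labels["d2"]

    def test_identical_rows_merge_at_height_zero(self):
        m = _frame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        ca = cluster_drugs(m, k=2)
        assert ca.linkage_matrix[0, 2] == 0.0  # first merge height

    def test_k_exceeding_drug_count_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_drugs(_frame([[0.0], [1.0]]), k=3)

    def test_planted_groups_recovered(self, small_screen):
        design, _, truth, matrix = small_screen
        ca = cluster_drugs(matrix.slice(48.0), k=3)
        ari = adjusted_rand_score(
            truth.drug_table.loc[ca.labels.index, "group"], ca.labels
        )
        assert ari > 0.9


class TestPathwayCorrelations:
    def test_duplicated_pathway_correlates_perfectly(self, rng):
        x = rng.normal(size=10)
        m = _frame(np.column_stack([x, x, rng.normal(size=10)]))
        corr = pathway_correlations(m)
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_zero_variance_pathway_yields_na(self, rng):
        m = _frame(np.column_stack([np.ones(8), rng.normal(size=8)]))
        corr = pathway_correlations(m)
        assert np.isnan(corr.iloc[0, 1])
        assert corr.iloc[1, 1] == 1.0

    def test_fewer_than_three_drugs_raises(self):
        with pytest.raises(ValueError, match="3 drugs"):
            pathway_correlations(_frame([[0.0, 1.0], [1.0, 0.0]]))

    def test_intercluster_correlations_negative_at_high_snr(self, small_screen):
        design, _, truth, matrix = small_screen
        corr = pathway_correlations(matrix.slice(48.0))
        u = pd.Series(truth.state_axis, index=truth.pathways)
        pos = [p for p in corr.columns if u[p] > 0]
        neg = [p for p in corr.columns if u[p] < 0]
        inter = corr.loc[pos, neg].to_numpy().ravel()
        intra = np.concatenate(
            [
                corr.loc[pos, pos].to_numpy()[np.triu_indices(len(pos), 1)],
                corr.loc[neg, neg].to_numpy()[np.triu_indices(len(neg), 1)],
            ]
        )
        assert np.median(inter) < -0.5
        assert np.median(intra) > 0.5

    def test_correlations_strengthen_over_the_time_course(self, small_screen):
        *_, matrix = small_screen
        medians = []
        for t in matrix.timepoints:
            corr = pathway_correlations(matrix.slice(t))
            vals = np.abs(corr.to_numpy()[np.triu_indices(len(corr), 1)])
            medians.append(np.median(vals))
        assert all(np.diff(medians) > 0)


class TestFitPCA:
    def test_collinear_data_loads_entirely_on_pc1(self, rng):
        t = rng.normal(size=20)
        m = _frame(np.column_stack([t, 2 * t, -t]))
        system, _ = fit_pca(m)
        assert system.explained_fraction[0] == pytest.approx(1.0)

    def test_explained_fractions_sum_to_one(self, rng):
        m = _frame(rng.normal(size=(30, 5)))
        system, _ = fit_pca(m)
        assert system.explained_fraction.sum() == pytest.approx(1.0)

    def test_sign_convention_is_deterministic(self, rng):
        m = _frame(rng.normal(size=(25, 4)))
        a, _ = fit_pca(m)
        b, _ = fit_pca(m)
        assert np.array_equal(a.loadings, b.loadings)
        for j in range(a.loadings.shape[1]):
            col = a.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_rank_zero_and_missing_values_raise(self):
        with pytest.raises(ValueError, match="rank-0"):
            fit_pca(_frame([[1.0, 2.0], [1.0, 2.0]]))
        bad = _frame([[1.0, np.nan], [0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="missing"):
            fit_pca(bad)

    def test_planted_axis_recovered_at_high_snr(self, small_screen):
        design, _, truth, matrix = small_screen
        system, _ = fit_pca(matrix.slice(48.0))
        u = pd.Series(truth.state_axis, index=truth.pathways)
        cos = abs(float(np.dot(system.loadings[:, 0], u.loc[list(system.pathways)])))
        assert cos > 0.9


class TestPhi:
    def test_identity_reference_gives_exactly_one(self, rng):
        m = _frame(rng.normal(size=(40, 4)))
        ref = PCACoordinateSystem(
            loadings=np.eye(4),
            variances=np.ones(4),
            explained_fraction=np.full(4, 0.25),
            center=np.zeros(4),
            pathways=tuple(m.columns),
        )
        assert phi_metric(m, ref) == 1.0

    def test_own_eigenbasis_equals_determinant_ratio(self, rng):
        """phi(own PCA basis) = det(cov) / prod(per-axis var), by brute force."""
        for _ in range(20):
            m = _frame(rng.normal(size=(50, 4)) @ rng.normal(size=(4, 4)))
            system, _ = fit_pca(m)
            got = phi_metric(m, system)
            cov = np.cov(m.to_numpy(), rowvar=False, ddof=1)
            want = np.linalg.det(cov) / np.prod(np.diag(cov))
            assert got == pytest.approx(want, rel=1e-9)
            assert got <= 1.0 + 1e-12  # Hadamard's inequality

    def test_eigenbasis_minimizes_phi_over_rotations(self, rng):
        """Random-rotation search in 3 dims never beats the eigenbasis."""
        m = _frame(rng.normal(size=(60, 3)) @ np.diag([3.0, 1.0, 0.5]))
        system, _ = fit_pca(m)
        phi_eig = phi_metric(m, system)
        for _ in range(200):
            q = special_ortho_group.rvs(3, random_state=rng)
            ref = PCACoordinateSystem(
                loadings=q,
                variances=np.ones(3),
                explained_fraction=np.full(3, 1 / 3),
                center=np.zeros(3),
                pathways=tuple(m.columns),
            )
            assert phi_metric(m, ref) >= phi_eig - 1e-12

    def test_isotropic_data_keeps_phi_near_one_in_any_basis(self, rng):
        m = _frame(rng.normal(size=(4000, 3)))
        q = special_ortho_group.rvs(3, random_state=rng)
        ref = PCACoordinateSystem(
            loadings=q,
            variances=np.ones(3),
            explained_fraction=np.full(3, 1 / 3),
            center=np.zeros(3),
            pathways=tuple(m.columns),
        )
        assert phi_metric(m, ref) == pytest.approx(1.0, abs=0.1)

    def test_zero_variance_axis_raises(self):
        m = _frame([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        ref = PCACoordinateSystem(
            loadings=np.eye(2),
            variances=np.ones(2),
            explained_fraction=np.array([0.5, 0.5]),
            center=np.zeros(2),
            pathways=tuple(m.columns),
        )
        with pytest.raises(ValueError, match="zero variance"):
            phi_metric(m, ref)

    def test_phi_trajectory_dips_then_falls(self, rng):
        """Homeostasis dynamics: a reference fitted pre-perturbation explains
        the pre state (phi < 1), loses relevance when fresh isotropic noise is
        injected (phi -> 1), and regains it as the shared state re-emerges."""
        u = np.array([1.0, 1.0, -1.0, -1.0]) / 2.0
        cols = [f"p{i}" for i in range(4)]
        pre = _frame(
            rng.normal(size=(80, 1)) @ u[None, :] * 2 + rng.normal(size=(80, 4)) * 0.4,
            columns=cols,
        )
        reference, _ = fit_pca(pre)
        early = _frame(rng.normal(size=(80, 4)), columns=cols)  # fresh noise
        late = _frame(
            rng.normal(size=(80, 1)) @ u[None, :] * 6 + rng.normal(size=(80, 4)) * 0.4,
            columns=cols,
        )
        phi_pre = phi_metric(pre, reference)
        phi_early = phi_metric(early, reference)
        phi_late = phi_metric(late, reference)
        assert phi_pre < 0.7
        assert phi_early > 0.8  # rises toward 1 on fresh noise
        assert phi_late < phi_early  # falls again as the state re-emerges

    def test_phi_trajectory_on_generated_screen(self):
        """Same dynamics end-to-end: the compound-specific shock at 1 h
        scrambles the pre-treatment structure before the shared state
        re-establishes and deepens it."""
        from signalome.scoring import score_screen
        from signalome.simulate import generate_screen, three_group_design

        design = three_group_design(
            n_drugs=30,
            cells_per_well=150,
            seed=6,
            timepoints=(0.0, 1.0, 12.0, 48.0),
        )
        cells, _ = generate_screen(design)
        matrix = score_screen(cells, design.modes)
        reference, _ = fit_pca(matrix.slice(0.0))
        phis = [phi_metric(matrix.slice(t), reference) for t in matrix.timepoints]
        assert phis[1] > phis[0]  # dip of the pre-treatment structure at 1 h
        assert phis[3] < phis[1] and phis[3] < phis[0]  # then it deepens


class TestDrugMetrics:
    def test_psi_pythagorean_example(self):
        assert psi_conformity(np.array([[3.0, 4.0]])) == pytest.approx(0.6)

    def test_psi_is_sign_carrying_and_unit_for_pure_pc1(self):
        assert psi_conformity(np.array([[2.5, 0.0]])) == 1.0
        assert psi_conformity(np.array([[-2.5, 0.0]])) == -1.0

    def test_psi_scale_invariant(self, rng):
        pc = rng.normal(size=(1, 5))
        assert psi_conformity(pc) == pytest.approx(psi_conformity(10 * pc))

    def test_psi_zero_coordinates_are_nan(self):
        assert np.isnan(psi_conformity(np.zeros((1, 3))))

    def test_adherence_as_printed_is_scale_dependent(self):
        assert adherence_pc1(np.array([[2.0, 0.0]])) == pytest.approx(0.5)
        assert adherence_pc1(np.array([[0.0, 3.0]])) == 0.0
        assert adherence_pc1(np.array([[1.0, 0.0]])) == 1.0

    def test_normalized_adherence_is_scale_free(self):
        assert adherence_pc1(np.array([[3.0, 4.0]]), normalized=True) == pytest.approx(0.6)
        a = adherence_pc1(np.array([[3.0, 4.0]]), normalized=True)
        b = adherence_pc1(np.array([[30.0, 40.0]]), normalized=True)
        assert a == pytest.approx(b)

    def test_strength_is_euclidean_norm(self):
        assert drug_strength(np.array([[3.0, 4.0]])) == pytest.approx(5.0)
        assert drug_strength(np.zeros((1, 4))) == 0.0

    def test_strength_equals_centered_row_norm_rotation_invariance(self, rng):
        m = _frame(rng.normal(size=(15, 4)))
        _, coords = fit_pca(m)
        centered = m.to_numpy() - m.to_numpy().mean(axis=0)
        assert np.allclose(coords["strength"], np.linalg.norm(centered, axis=1))

    def test_unit_decomposition(self, rng):
        m = _frame(rng.normal(size=(10, 4)))
        _, coords = fit_pca(m)
        pcs = coords[[c for c in coords.columns if c.startswith("PC")]].to_numpy()
        ratios = (pcs / coords["strength"].to_numpy()[:, None]) ** 2
        assert np.allclose(ratios.sum(axis=1), 1.0)
        assert (coords["psi"].abs() <= 1 + 1e-12).all()
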