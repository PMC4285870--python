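import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from energyscape.bln import ContactMap
from energyscape.geometry import (build_chain, kabsch_align, zigzag_chain)
from energyscape.metrics import (MetricSet, dihedral_features, isomap_metric,
                                 mclachlan_average, native_contact_fraction,
                                 contacts_metric, pca_metric,
                                 project_pc_structure, rmsd_metric)
from energyscape.synthetic import (ensemble_members, generate_curved_manifold,
                                   generate_planted_gaussian)
from helpers import floyd_warshall, grid_search_rmsd


def random_rotation(rng):
    return Rotation.random(rng=rng).as_matrix()


# ---------------------------------------------------------------------------
# native contacts


class TestNativeContacts:
    def test_reference_structure_scores_one(self):
        folded = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                           [0, 1, 1], [1, 1, 1], [1, 0, 1], [0, 0, 1.0]])
        native = ContactMap.from_coordinates(folded)
        assert len(native) > 0
        assert native_contact_fraction(folded, native) == 1.0

    def test_straight_chain_scores_zero(self):
        folded = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                           [0, 1, 1], [1, 1, 1], [1, 0, 1], [0, 0, 1.0]])
        native = ContactMap.from_coordinates(folded)
        assert len(native) > 0
        straight = np.column_stack([np.arange(8.0), np.zeros(8), np.zeros(8)])
        assert native_contact_fraction(straight, native) == 0.0

    def test_hand_placed_half_contacts(self):
        """8-bead toy: 2 of 4 declared native pairs within the cutoff."""
        native = ContactMap(pairs=frozenset({(0, 4), (0, 5), (1, 5), (2, 6)}),
                            n_beads=8)
        coords = np.column_stack([np.arange(8.0), np.zeros(8), np.zeros(8)])
        coords[0] = [3.5, 0.5, 0.0]   # within 1.167 of bead 4 only
        coords[6] = [2.3, 0.8, 0.0]   # within 1.167 of bead 2 only
        d04 = np.linalg.norm(coords[0] - coords[4])
        d26 = np.linalg.norm(coords[2] - coords[6])
        d05 = np.linalg.norm(coords[0] - coords[5])
        d15 = np.linalg.norm(coords[1] - coords[5])
        assert d04 < 1.167 and d26 < 1.167 and d05 > 1.167 and d15 > 1.167
        assert native_contact_fraction(coords, native) == 0.5

    def test_empty_native_map_rejected(self):
        straight = np.column_stack([np.arange(8.0), np.zeros(8), np.zeros(8)])
        empty = ContactMap(pairs=frozenset(), n_beads=8)
        with pytest.raises(ValueError, match="empty"):
            native_contact_fraction(straight, empty)

    def test_sequence_neighbours_never_count_as_contacts(self):
        coords = zigzag_chain(6)  # all |i-j| <= 3 pairs are close
        cm = ContactMap.from_coordinates(coords)
        assert all(j - i > 3 for i, j in cm.pairs)

    def test_contact_map_rejects_excluded_pairs(self):
        with pytest.raises(ValueError, match="exclusion"):
            ContactMap(pairs=frozenset({(0, 2)}), n_beads=5)


# ---------------------------------------------------------------------------
# Kabsch / RMSd


class TestKabsch:
    def test_rigid_copy_has_zero_distance(self, rng):
        a = rng.normal(size=(12, 3))
        b = a @ random_rotation(rng).T + rng.uniform(-3, 3, 3)
        rot, trans, d = kabsch_align(a, b)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(b @ rot.T + trans, a, atol=1e-10)

    def test_mirror_image_keeps_proper_rotation(self, rng):
        a = rng.normal(size=(10, 3))
        mirror = a * np.array([-1.0, 1.0, 1.0])
        rot, _, d = kabsch_align(a, mirror)
        assert d > 0.1
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_symmetric_in_arguments(self, rng):
        a, b = rng.normal(size=(2, 9, 3))
        assert kabsch_align(a, b)[2] == pytest.approx(kabsch_align(b, a)[2])

    def test_matches_rotation_grid_search_on_four_point_toys(self, rng):
        for _ in range(3):
            a, b = rng.normal(size=(2, 4, 3))
            d = kabsch_align(a, b)[2]
            assert d == pytest.approx(grid_search_rmsd(a, b), abs=1e-4)

    def test_agrees_with_scipy_align_vectors(self, rng):
        a, b = rng.normal(size=(2, 15, 3))
        rot, _, d = kabsch_align(a, b)
        ref_rot, rssd = Rotation.align_vectors(a - a.mean(0), b - b.mean(0))
        assert d == pytest.approx(rssd / np.sqrt(len(a)), rel=1e-9)
        assert np.allclose(rot, ref_rot.as_matrix(), atol=1e-8)


class TestRmsdMetric:
    @pytest.fixture()
    def members(self, rng):
        base = zigzag_chain(8)
        ensemble = [base + rng.normal(0, s, (8, 3)) for s in
                    (0.0, 0.1, 0.3, 0.5)]
        return ensemble_members(ensemble)

    def test_reference_value_is_zero(self, members):
        ms = rmsd_metric(members, reference=1)
        assert ms.values[1] == pytest.approx(0.0, abs=1e-12)

    def test_invariant_under_stored_rigid_motion(self, members, rng):
        ms1 = rmsd_metric(members, reference=1)
        db = members.database
        for i in list(db.coordinates):
            rot = random_rotation(rng)
            db.coordinates[i] = db.coordinates[i] @ rot.T + rng.uniform(-2, 2, 3)
        ms2 = rmsd_metric(members, reference=1)
        for i in ms1.values:
            assert ms2.values[i] == pytest.approx(ms1.values[i], abs=1e-9)

    def test_values_match_elementwise_alignment(self, members):
        ms = rmsd_metric(members, reference=2)
        db = members.database
        for i in members.members:
            assert ms.values[i] == pytest.approx(
                kabsch_align(db.coords(2), db.coords(i))[2])


# ---------------------------------------------------------------------------
# iterative ensemble alignment


class TestMcLachlan:
    def test_identical_structures_converge_immediately(self):
        chain = zigzag_chain(7)
        res = mclachlan_average([chain.copy() for _ in range(5)])
        assert res.converged and res.n_iter == 1
        centered = chain - chain.mean(axis=0)
        assert np.allclose(res.mean, centered, atol=1e-12)

    def test_rotated_copies_realign_exactly(self, rng):
        chain = zigzag_chain(9)
        ensemble = [chain @ random_rotation(rng).T + rng.uniform(-2, 2, 3)
                    for _ in range(6)]
        res = mclachlan_average(ensemble)
        assert res.converged
        assert kabsch_align(res.mean, chain)[2] == pytest.approx(0.0, abs=1e-7)

    def test_equivariant_under_global_pre_rotation(self, rng):
        base = zigzag_chain(8)
        ensemble = [base + rng.normal(0, 0.2, (8, 3)) for _ in range(10)]
        res1 = mclachlan_average(ensemble)
        rot = random_rotation(rng)
        res2 = mclachlan_average([c @ rot.T for c in ensemble])
        assert kabsch_align(res1.mean, res2.mean)[2] == \
            pytest.approx(0.0, abs=1e-7)

    def test_drift_criterion_decreases(self, rng):
        base = zigzag_chain(10)
        ensemble = [base @ random_rotation(rng).T + rng.normal(0, 0.3, (10, 3))
                    for _ in range(12)]
        res = mclachlan_average(ensemble)
        assert res.converged
        drifts = np.array(res.s_history)
        assert np.all(np.diff(drifts) <= 1e-12)

    def test_single_structure_rejected(self):
        with pytest.raises(ValueError):
            mclachlan_average([zigzag_chain(5)])


# ---------------------------------------------------------------------------
# dihedral features


class TestDihedralFeatures:
    def test_planar_trans_chain_features(self):
        feats = dihedral_features(zigzag_chain(8))
        cos, sin = feats[0::2], feats[1::2]
        assert np.allclose(cos, -1.0, atol=1e-12)
        assert np.allclose(sin, 0.0, atol=1e-7)

    def test_feature_count_for_69_beads(self):
        assert dihedral_features(zigzag_chain(69)).size == 132

    def test_matches_independent_two_vector_formula(self, rng):
        """Oracle: cosine from normalized plane normals, sign from the
        scalar triple product — an algebraically different route."""
        coords = build_chain(10, dihedrals=rng.uniform(-np.pi, np.pi, 7))
        feats = dihedral_features(coords)
        for t in range(7):
            p0, p1, p2, p3 = coords[t:t + 4]
            b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            cos = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
            cos = np.clip(cos, -1, 1)
            psi = np.arccos(cos)
            if np.dot(np.cross(n1, n2), b2) < 0:
                psi = -psi
            assert feats[2 * t] == pytest.approx(np.cos(psi), abs=1e-10)
            assert feats[2 * t + 1] == pytest.approx(np.sin(psi), abs=1e-10)

    def test_rigid_motion_invariance(self, rng):
        coords = build_chain(9, dihedrals=rng.uniform(-np.pi, np.pi, 6))
        feats = dihedral_features(coords)
        moved = coords @ random_rotation(rng).T + rng.uniform(-4, 4, 3)
        assert np.allclose(dihedral_features(moved), feats, atol=1e-10)

    def test_collinear_triple_names_quadruplet(self):
        coords = np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)])
        coords[4:] += [[0.0, 1.0, 0.0], [0.0, 2.0, 0.0]]
        with pytest.raises(ValueError, match=r"\(0, 1, 2, 3\)"):
            dihedral_features(coords)

    def test_too_short_chain_rejected(self):
        with pytest.raises(ValueError):
            dihedral_features(zigzag_chain(3))


# ---------------------------------------------------------------------------
# PCA


class TestPCA:
    def test_two_structures_span_a_line(self, rng):
        base = zigzag_chain(6)
        members = ensemble_members([base, base + rng.normal(0, 0.3, (6, 3))])
        res = pca_metric(members)
        assert np.sum(res.variances > 1e-12) == 1
        assert res.fractions[0] == pytest.approx(1.0)

    def test_variance_fractions_are_ordered_and_sum_to_one(self, rng):
        ensemble, _ = generate_planted_gaussian(80, [4.0, 2.0, 1.0], seed=2)
        res = pca_metric(ensemble_members(ensemble))
        assert np.all(np.diff(res.fractions) <= 1e-12)
        assert res.fractions.sum() == pytest.approx(1.0)

    def test_total_variance_equals_mean_squared_deviation(self, rng):
        ensemble, _ = generate_planted_gaussian(50, [3.0, 1.0], seed=3)
        members = ensemble_members(ensemble)
        res = pca_metric(members)
        aligned = res.alignment.aligned.reshape(len(ensemble), -1)
        centered = aligned - aligned.mean(axis=0)
        msd = np.sum(centered ** 2) / len(ensemble)
        assert res.variances.sum() == pytest.approx(msd, rel=1e-8)

    def test_recovers_planted_fractions(self):
        ensemble, truth = generate_planted_gaussian(400, [4.0, 1.0], seed=4)
        res = pca_metric(ensemble_members(ensemble))
        assert res.fractions[0] == pytest.approx(truth.planted_fractions[0],
                                                 abs=0.05)

    def test_projections_invariant_under_stored_rigid_motion(self, rng):
        ensemble, _ = generate_planted_gaussian(40, [2.0, 0.5], seed=5)
        members = ensemble_members(ensemble)
        res1 = pca_metric(members)
        rotated = [c @ random_rotation(rng).T + rng.uniform(-3, 3, 3)
                   for c in ensemble]
        res2 = pca_metric(ensemble_members(rotated))
        for k in range(2):
            p1 = np.array([res1.projections[i][k] for i in res1.member_indices])
            p2 = np.array([res2.projections[i][k] for i in res2.member_indices])
            # agreement is limited by the alignment drift tolerance
            agree = np.allclose(p1, p2, atol=1e-3)
            flipped = np.allclose(p1, -p2, atol=1e-3)
            assert agree or flipped

    def test_identical_ensemble_gives_zero_variance_without_error(self):
        base = zigzag_chain(5)
        res = pca_metric(ensemble_members([base.copy() for _ in range(4)]))
        assert np.allclose(res.variances, 0.0, atol=1e-20)

    def test_dihedral_basis_features(self):
        ensemble, _ = generate_planted_gaussian(30, [1.0], seed=6)
        res = pca_metric(ensemble_members(ensemble), basis_kind="dihedral")
        assert res.components.shape[1] == 2 * (ensemble.shape[1] - 3)

    def test_metric_set_exposes_requested_component(self):
        ensemble, _ = generate_planted_gaussian(30, [2.0, 1.0], seed=7)
        res = pca_metric(ensemble_members(ensemble))
        ms = res.metric_set(component=2)
        assert ms.name.endswith("pc2")
        assert ms.values[1] == pytest.approx(res.projections[1][1])


class TestBackProjection:
    @pytest.fixture()
    def result(self):
        ensemble, _ = generate_planted_gaussian(60, [3.0, 1.0], seed=8)
        return ensemble, pca_metric(ensemble_members(ensemble))

    def test_zero_progress_leaves_reference_unchanged(self, result):
        ensemble, res = result
        ref = ensemble[0]
        out = project_pc_structure(ref, res.component_vector(1), 0.0)
        assert np.array_equal(out, ref)

    def test_projection_is_linear_in_lambda(self, result):
        ensemble, res = result
        ref = ensemble[0]
        q1 = res.component_vector(1)
        lam = 2.37
        out = project_pc_structure(ref, q1, lam)
        recovered = (out - ref).ravel() @ q1
        assert recovered == pytest.approx(lam, abs=1e-10)

    def test_each_bead_moves_on_a_straight_segment(self, result):
        ensemble, res = result
        ref = ensemble[0]
        q1 = res.component_vector(1).reshape(-1, 3)
        a = 1.5
        sweep = np.stack([
            project_pc_structure(ref, res.component_vector(1), lam)
            for lam in np.linspace(-a, a, 7)])
        for bead in range(ref.shape[0]):
            track = sweep[:, bead, :]
            length = np.linalg.norm(track[-1] - track[0])
            assert length == pytest.approx(2 * a * np.linalg.norm(q1[bead]),
                                           abs=1e-10)
            chords = np.diff(track, axis=0)
            straightness = np.linalg.norm(chords.sum(axis=0))
            assert straightness == pytest.approx(length, abs=1e-10)

    def test_dihedral_components_rejected(self, result):
        ensemble, _ = result
        with pytest.raises(ValueError, match="cartesian"):
            project_pc_structure(ensemble[0], np.ones(12) / np.sqrt(12), 1.0,
                                 basis_kind="dihedral")

    def test_non_unit_component_rejected(self, result):
        ensemble, _ = result
        bad = np.ones(ensemble[0].size)
        with pytest.raises(ValueError, match="unit norm"):
            project_pc_structure(ensemble[0], bad, 1.0)


# ---------------------------------------------------------------------------
# Isomap


class TestIsomap:
    def test_geodesics_dominate_direct_distances(self):
        ensemble, _ = generate_curved_manifold(40, curvature=3.0, seed=9)
        res = isomap_metric(ensemble_members(ensemble), k=6, n_dims=2)
        assert res.graph_connected
        assert np.all(res.geodesics >= res.distances - 1e-9)
        assert np.allclose(np.diag(res.geodesics), 0.0)
        assert np.allclose(res.geodesics, res.geodesics.T, atol=1e-12)

    def test_geodesics_match_floyd_warshall(self):
        ensemble, _ = generate_curved_manifold(30, curvature=3.0, seed=10)
        res = isomap_metric(ensemble_members(ensemble), k=5, n_dims=1)
        d = res.distances
        order = np.argsort(d, axis=1, kind="stable")
        w = np.full_like(d, np.inf)
        for a in range(d.shape[0]):
            for b in order[a, 1:6]:
                w[a, b] = w[b, a] = d[a, b]
        np.fill_diagonal(w, 0.0)
        assert np.allclose(res.geodesics, floyd_warshall(w), atol=1e-12)

    def test_linear_data_reduces_to_pca(self):
        ensemble, _ = generate_planted_gaussian(60, [4.0, 1.0], seed=11)
        members = ensemble_members(ensemble)
        iso = isomap_metric(members, k=59, n_dims=2)
        pca = pca_metric(members)
        e = np.stack([iso.embedding[i] for i in iso.embedded_indices])
        p = np.stack([pca.projections[i][:2] for i in iso.embedded_indices])
        from scipy.linalg import orthogonal_procrustes
        rot, _ = orthogonal_procrustes(e, p)
        residual = np.linalg.norm(e @ rot - p) / np.linalg.norm(p)
        assert residual < 1e-6

    def test_curved_manifold_rank_ordered_by_arc_length(self):
        ensemble, truth = generate_curved_manifold(60, curvature=4.5, seed=12)
        members = ensemble_members(ensemble)
        iso = isomap_metric(members, k=6, n_dims=1)
        emb = np.array([iso.embedding[i][0] for i in iso.embedded_indices])
        rho = abs(spearmanr(emb, truth.arc_parameter).statistic)
        assert rho == pytest.approx(1.0, abs=1e-12)
        # a single fixed-frame linear direction cannot do the same
        pca = pca_metric(members)
        pc1 = np.array([pca.projections[i][0] for i in iso.embedded_indices])
        rho_pc = abs(spearmanr(pc1, truth.arc_parameter).statistic)
        assert rho_pc < 0.99

    def test_agrees_with_sklearn_reference(self):
        from sklearn.manifold import Isomap as SkIsomap
        ensemble, _ = generate_curved_manifold(45, curvature=3.0, seed=13)
        members = ensemble_members(ensemble)
        res = isomap_metric(members, k=8, n_dims=2)
        aligned = mclachlan_average(np.stack(
            [members.coords(i) for i in members.members])).aligned
        X = aligned.reshape(45, -1)
        sk = SkIsomap(n_neighbors=8, n_components=2).fit(X)
        assert np.allclose(sk.dist_matrix_, res.geodesics, atol=1e-8)
        for dim in range(2):
            ours = np.array([res.embedding[i][dim]
                             for i in res.embedded_indices])
            theirs = sk.embedding_[:, dim]
            assert min(np.max(np.abs(ours - theirs)),
                       np.max(np.abs(ours + theirs))) < 1e-6

    def test_disconnected_graph_warns_and_embeds_largest_component(self, rng):
        # two internally different conformers; rigid moves would be aligned away
        open_chain = zigzag_chain(6)
        wound = build_chain(6, dihedrals=[0.4, 0.4, 0.4])
        blob1 = [open_chain + rng.normal(0, 0.02, (6, 3)) for _ in range(8)]
        blob2 = [wound + rng.normal(0, 0.02, (6, 3)) for _ in range(5)]
        members = ensemble_members(blob1 + blob2)
        with pytest.warns(UserWarning, match="components"):
            res = isomap_metric(members, k=4, n_dims=1)
        assert not res.graph_connected
        assert len(res.embedded_indices) == 8

    def test_invalid_dimension_count_rejected(self):
        ensemble, _ = generate_curved_manifold(20, curvature=2.0, seed=14)
        with pytest.raises(ValueError):
            isomap_metric(ensemble_members(ensemble), k=4, n_dims=0)

    def test_too_few_members_rejected(self):
        ensemble, _ = generate_curved_manifold(10, curvature=2.0, seed=15)
        with pytest.raises(ValueError, match="neighbours"):
            isomap_metric(ensemble_members(ensemble), k=15)


# ---------------------------------------------------------------------------
# MetricSet plumbing


def test_metric_set_round_trips_through_text(tmp_path):
    ms = MetricSet(name="rmsd", values={1: 0.25, 2: 1.5, 10: -0.125},
                   reference=1)
    ms.write(tmp_path / "m.tsv")
    back = MetricSet.read(tmp_path / "m.tsv")
    assert back.name == ms.name
    assert back.values == ms.values


def test_metric_set_rejects_non_finite_values():
    with pytest.raises(ValueError):
        MetricSet(name="bad", values={1: np.nan})


def test_contacts_metric_over_members(rng):
    folded = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                       [0, 1, 1], [1, 1, 1], [1, 0, 1], [0, 0, 1.0]])
    straight = np.column_stack([np.arange(8.0), np.zeros(8), np.zeros(8)])
    members = ensemble_members([folded, straight])
    ms = contacts_metric(members, reference=1)
    assert ms.values[1] == 1.0
    assert ms.values[2] == 0.0
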