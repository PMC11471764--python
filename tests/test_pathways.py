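import numpy as np
import pytest

from enmunfold.fixtures import ToySpec, make_family, make_toy
from enmunfold.network import build_network
from enmunfold.pathways import (
    PathwayEncoding,
    barnase_region_scheme,
    ci2_region_scheme,
    default_region_scheme,
    encode_pathway,
    family_covariance,
    floppy_curve_divergence,
    generic_region_scheme,
    tm_score_on_correspondence,
)
from enmunfold.structure_io import contact_list
from enmunfold.unfolding import BondBreakEvent, UnfoldingTrajectory, run_unfolding


def traj_from_pairs(pairs, n_residues=10):
    events = [
        BondBreakEvent(step=k + 1, pair=p, value=1.0) for k, p in enumerate(pairs)
    ]
    n = len(pairs)
    return UnfoldingTrajectory(
        events=events,
        q_series=np.linspace(1 - 1 / max(n, 1), 0, n),
        z_series=np.linspace(3, 2, n),
        f_series=None,
        mode="thermal",
        n_native=n,
        n_residues=n_residues,
    )


class TestRegionSchemes:
    def test_ci2_has_five_named_regions(self):
        labels = ["nterm", "beta1", "alpha", "loop2", "beta2", "beta3"]
        scheme = ci2_region_scheme(labels)
        assert scheme.n_regions == 5
        assert scheme.labels == [
            "N-terminus-beta3", "alpha-loop2", "beta1-beta2",
            "beta2-beta3", "rest",
        ]
        # beta1-beta2 bond -> third region (v_3).
        assert scheme.region_of((2, 5)) == 2
        # alpha-loop2 -> second region.
        assert scheme.region_of((3, 4)) == 1
        # anything unnamed falls into rest.
        assert scheme.region_of((1, 3)) == 4

    def test_generic_two_elements_gives_four_regions(self):
        scheme = generic_region_scheme(["a"] * 3 + ["b"] * 3)
        assert scheme.n_regions == 4  # a-a, a-b, b-b, rest

    def test_barnase_scheme_caps_at_thirty(self):
        # 18 residues, 9 elements twice over; contacts crafted to populate
        # far more than 29 element pairs.
        elements = [
            "nterm", "alpha1", "alpha2", "alpha3", "beta1", "beta2",
            "beta3", "loop1", "loop2",
        ] * 2
        contacts = [
            (i, j) for i in range(1, 19) for j in range(i + 2, 19)
        ]
        scheme = barnase_region_scheme(elements, contacts)
        assert scheme.n_regions == 30
        assert scheme.labels[-1] == "rest"

    def test_barnase_needs_contacts(self):
        with pytest.raises(ValueError, match="contact"):
            default_region_scheme(["nterm"] * 5, "barnase")

    def test_missing_labels_rejected(self):
        with pytest.raises(ValueError, match="annotation"):
            generic_region_scheme(None)


class TestEncodePathway:
    def test_single_region_flat_vector(self):
        labels = ["nterm"] * 5 + ["beta3"] * 5
        scheme = ci2_region_scheme(labels)
        traj = traj_from_pairs([(1, 6), (2, 7), (3, 8)])
        enc = encode_pathway(traj, scheme)
        expected = [1, 0, 0, 0, 0] * 3
        np.testing.assert_array_equal(enc.flat, expected)

    def test_rows_one_hot_and_padding(self):
        labels = ["a"] * 5 + ["b"] * 5
        scheme = generic_region_scheme(labels)
        traj = traj_from_pairs([(1, 3), (1, 6)])
        enc = encode_pathway(traj, scheme, n_b=4)
        assert enc.shape == (4, 4)
        assert enc.n_padded == 2
        np.testing.assert_array_equal(enc.matrix.sum(axis=1), [1, 1, 0, 0])

    def test_identical_trajectories_identical_encodings(self):
        labels = ["a"] * 5 + ["b"] * 5
        scheme = generic_region_scheme(labels)
        t = traj_from_pairs([(1, 3), (1, 6), (6, 8)])
        e1, e2 = encode_pathway(t, scheme), encode_pathway(t, scheme)
        np.testing.assert_array_equal(e1.matrix, e2.matrix)

    def test_encode_decode_roundtrip(self):
        labels = ["a"] * 5 + ["b"] * 5
        scheme = generic_region_scheme(labels)
        pairs = [(1, 3), (1, 6), (6, 8), (2, 4)]
        enc = encode_pathway(traj_from_pairs(pairs), scheme)
        decoded = [int(np.argmax(row)) for row in enc.matrix]
        assert decoded == [scheme.region_of(p) for p in pairs]


class TestFamilyCovariance:
    def test_identical_pathways_correlate_perfectly(self):
        mat = np.array([[1, 0], [1, 0], [0, 1]], dtype=float)
        fam = family_covariance(
            [PathwayEncoding(mat.copy(), "p1"), PathwayEncoding(mat.copy(), "p2")]
        )
        np.testing.assert_allclose(fam.pathway_correlation, 1.0)

    def test_hand_computed_two_protein_case(self):
        # N_b = 3, N_r = 2; every event of p2 sits in the other region.
        m1 = np.array([[1, 0], [1, 0], [0, 1]], dtype=float)
        m2 = np.array([[0, 1], [1, 0], [1, 0]], dtype=float)
        fam = family_covariance(
            [PathwayEncoding(m1, "p1"), PathwayEncoding(m2, "p2")]
        )
        # Hand calculation on the flattened 6-vectors:
        # x1 = [1,0,1,0,0,1], x2 = [0,1,1,0,1,0]; cov = -0.1, var = 0.3.
        assert fam.pathway_covariance[0, 1] == pytest.approx(-0.1)
        assert fam.pathway_covariance[0, 0] == pytest.approx(0.3)
        assert fam.pathway_correlation[0, 1] == pytest.approx(-1.0 / 3.0)
        assert fam.pathway_correlation[0, 1] < 1.0

    def test_covariance_psd_and_order_invariant(self):
        rng = np.random.default_rng(5)
        encs = []
        for k in range(4):
            mat = np.zeros((6, 3))
            mat[np.arange(6), rng.integers(0, 3, 6)] = 1.0
            encs.append(PathwayEncoding(mat, f"p{k}"))
        fam = family_covariance(encs)
        assert np.linalg.eigvalsh(fam.pathway_covariance).min() > -1e-10
        np.testing.assert_allclose(np.diag(fam.pathway_correlation), 1.0)
        perm = [2, 0, 3, 1]
        fam_p = family_covariance([encs[k] for k in perm])
        np.testing.assert_allclose(
            fam_p.pathway_covariance,
            fam.pathway_covariance[np.ix_(perm, perm)],
        )

    def test_mismatched_shapes_rejected(self):
        e1 = PathwayEncoding(np.zeros((3, 2)), "a")
        e2 = PathwayEncoding(np.zeros((4, 2)), "b")
        with pytest.raises(ValueError, match="mismatched"):
            family_covariance([e1, e2])


class TestTmScore:
    def test_identity_and_rigid_rotation_score_one(self, lattice_toy):
        coords = lattice_toy.coords
        assert tm_score_on_correspondence(coords, coords) == pytest.approx(1.0)
        theta = 1.2
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        moved = coords @ rot.T + np.array([4.0, -2.0, 9.0])
        assert tm_score_on_correspondence(coords, moved) == pytest.approx(1.0)

    def test_scores_bounded(self, lattice_toy):
        rng = np.random.default_rng(9)
        noisy = lattice_toy.coords + rng.normal(0, 3.0, lattice_toy.coords.shape)
        s = tm_score_on_correspondence(lattice_toy.coords, noisy)
        assert 0.0 < s < 1.0

    def test_displaced_point_matches_bruteforce_search(self):
        # 4 points; one displaced far away.  Oracle: dense grid over
        # rotations with numeric refinement of the translation.
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        a = np.array(
            [[0.0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [0, 3.8, 3.8]]
        )
        b = a.copy()
        b[3] += np.array([25.0, -10.0, 5.0])
        d0 = 0.5  # short correspondence: floor value

        def tm_at(rotvec, t):
            rot = Rotation.from_rotvec(rotvec).as_matrix()
            d = np.linalg.norm(a @ rot.T + t - b, axis=1)
            return np.sum(1.0 / (1.0 + (d / d0) ** 2)) / len(b)

        best = 0.0
        for rv in Rotation.random(300, rng=np.random.default_rng(1)).as_rotvec():
            res = minimize(
                lambda x: -tm_at(x[:3], x[3:]),
                np.concatenate([rv, b.mean(axis=0) - a.mean(axis=0)]),
                method="Nelder-Mead",
                options={"maxiter": 400, "xatol": 1e-6, "fatol": 1e-12},
            )
            best = max(best, -res.fun)
        impl = tm_score_on_correspondence(a, b, l_ref=4)
        assert impl < 1.0
        assert impl == pytest.approx(best, abs=0.01)

    def test_too_few_pairs_rejected(self):
        a = np.zeros((4, 3))
        with pytest.raises(ValueError, match="3"):
            tm_score_on_correspondence(a, a, pairs=[(1, 1), (2, 2)])


class TestFloppyCurveDivergence:
    def test_identical_curves_diverge_zero(self):
        z = np.linspace(4, 2, 30)
        f = 10 + (4 - z) ** 2
        div = floppy_curve_divergence([(z, f), (z, f)])
        np.testing.assert_allclose(div, 0.0, atol=1e-12)

    def test_known_offset(self):
        z = np.linspace(4, 2, 50)
        div = floppy_curve_divergence([(z, np.full_like(z, 5.0)),
                                       (z, np.full_like(z, 8.0))])
        assert div[0, 1] == pytest.approx(3.0)

    def test_disjoint_ranges_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            floppy_curve_divergence(
                [(np.array([1.0, 2.0]), np.array([0.0, 1.0])),
                 (np.array([3.0, 4.0]), np.array([0.0, 1.0]))]
            )


class TestSyntheticFamilyProperty:
    def test_tm_and_pathway_correlation_covary(self):
        """Structurally perturbed variants unfold along increasingly
        different pathways: pairwise TM-score and pathway correlation both
        fall with the rewiring rate and rank-correlate positively."""
        from scipy.stats import spearmanr

        template = make_toy(ToySpec("lattice-fold", 27, seed=11))
        scheme = generic_region_scheme(template.ss_labels)
        tm_means, corr_means = [], []
        for rate in (0.0, 0.3):
            tms, corrs = [], []
            for seed in range(5):
                variants = make_family(template, 3, rate, seed=seed)
                encs = []
                for v, s in enumerate(variants):
                    net = build_network(s, c=2.0, kappa=1.0, r_c=7.0)
                    traj = run_unfolding(
                        net, "thermal", stop_after=25, compute_floppy=False
                    )
                    encs.append(encode_pathway(traj, scheme, n_b=25, protein_id=str(v)))
                fam = family_covariance(encs)
                iu = np.triu_indices(3, k=1)
                corrs.append(fam.pathway_correlation[iu].mean())
                tms.append(np.mean([
                    tm_score_on_correspondence(variants[x].coords, variants[y].coords)
                    for x, y in zip(*iu)
                ]))
            tm_means.append(np.mean(tms))
            corr_means.append(np.mean(corrs))
        assert tm_means[0] > tm_means[1]
        assert corr_means[0] > corr_means[1]
        assert corr_means[0] == pytest.approx(1.0)
        rho = spearmanr(tm_means, corr_means).statistic
        assert rho > 0
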