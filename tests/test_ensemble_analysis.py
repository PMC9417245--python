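import itertools

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from dimerpipe.core_io import Ensemble, StructureFrame
from dimerpipe.ensemble_analysis import (
    contact_difference,
    contact_probability_map,
    gromos_cluster,
    progressive_fit,
    radius_of_gyration,
    rmsd_matrix,
    shape_descriptors,
    shrake_rupley_sasa,
    superpose,
)
from dimerpipe.synthetic import (
    DimerSpec,
    PropensityProfile,
    build_chain_frame,
    build_dimer,
    sample_dihedral_chain,
)


def frame_from_coords(coords, chain="A"):
    n = len(coords)
    return StructureFrame(
        coords=np.asarray(coords, dtype=float),
        atom_names=np.array(["CA"] * n, dtype=object),
        residue_index=np.arange(n),
        residue_name=np.array(["ALA"] * n, dtype=object),
        chain_id=np.array([chain] * n, dtype=object),
    )


def brute_force_min_rmsd(mobile, reference):
    """Independent superposition oracle: coarse rotation grid + local refine."""
    mobile = mobile - mobile.mean(axis=0)
    reference = reference - reference.mean(axis=0)

    def rmsd_of(euler):
        rot = Rotation.from_euler("zyx", euler).as_matrix()
        moved = mobile @ rot.T
        return np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1)))

    best = None
    grid = np.arange(-180, 180, 30.0)
    for e in itertools.product(grid, repeat=3):
        r = rmsd_of(e)
        if best is None or r < best[0]:
            best = (r, e)
    res = minimize(rmsd_of, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
    return min(best[0], res.fun)


class TestSuperpose:
    def test_identity(self):
        frame = frame_from_coords(np.random.default_rng(0).normal(size=(6, 3)))
        _, rmsd = superpose(frame, frame, atom_selection=None)
        assert rmsd < 1e-12

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(8, 3))
        rot = Rotation.from_euler("zyx", [30, 50, -20], degrees=True).as_matrix()
        moved = coords @ rot.T + np.array([1.0, -2.0, 0.5])
        ref = frame_from_coords(coords)
        mob = frame_from_coords(moved)
        fitted, rmsd = superpose(mob, ref, atom_selection=None)
        assert rmsd <= 1e-6
        assert np.allclose(fitted.coords, coords, atol=1e-6)

    def test_four_atom_toy_matches_grid_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(4, 3))
        b = rng.normal(size=(4, 3))
        _, rmsd = superpose(frame_from_coords(a), frame_from_coords(b),
                            atom_selection=None)
        oracle = brute_force_min_rmsd(a, b)
        assert abs(rmsd - oracle) < 1e-4

    def test_too_few_atoms(self):
        a = frame_from_coords([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            superpose(a, a, atom_selection=None)


class TestRmsdMatrix:
    def test_duplicate_frame_zero(self):
        rng = np.random.default_rng(3)
        f1 = frame_from_coords(rng.normal(size=(5, 3)))
        f2 = frame_from_coords(f1.coords.copy())
        f3 = frame_from_coords(rng.normal(size=(5, 3)))
        mat = rmsd_matrix(Ensemble(frames=[f1, f2, f3]), atom_selection=None)
        assert mat[0, 1] < 1e-10
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0.0)

    def test_consistency_with_direct_calls(self):
        rng = np.random.default_rng(4)
        frames = [frame_from_coords(rng.normal(size=(5, 3))) for _ in range(3)]
        ens = Ensemble(frames=frames)
        mat = rmsd_matrix(ens, atom_selection=None)
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                _, r = superpose(frames[i], frames[j], atom_selection=None)
                assert np.isclose(mat[i, j], r)

    def test_two_conformer_bimodality(self):
        prof_a = PropensityProfile.uniform(8, 1.0, 0.0)
        prof_b = PropensityProfile.uniform(8, 0.0, 1.0)
        ens_a = sample_dihedral_chain(prof_a, 5, seed=0)
        ens_b = sample_dihedral_chain(prof_b, 5, seed=1)
        ens = ens_a.concat(ens_b)
        mat = rmsd_matrix(ens)
        within = np.concatenate([mat[:5, :5][np.triu_indices(5, 1)],
                                 mat[5:, 5:][np.triu_indices(5, 1)]])
        across = mat[:5, 5:].ravel()
        assert across.min() > within.max()


def gromos_oracle(rmsd, cutoff):
    """Plain re-derivation of the greedy neighbour-count procedure."""
    T = rmsd.shape[0]
    remaining = set(range(T))
    assignments = {}
    clusters = []
    while remaining:
        best_center, best_members = None, None
        for c in sorted(remaining):
            members = {j for j in remaining if rmsd[c, j] <= cutoff} | {c}
            if best_members is None or len(members) > len(best_members):
                best_center, best_members = c, members
        clusters.append((best_center, sorted(best_members)))
        remaining -= best_members
    clusters_sorted = sorted(
        enumerate(clusters), key=lambda kv: (-len(kv[1][1]), kv[0])
    )
    out_assign = np.empty(T, dtype=int)
    reps, pops = [], []
    for new_id, (_, (center, members)) in enumerate(clusters_sorted):
        for m in members:
            out_assign[m] = new_id
        reps.append(center)
        pops.append(len(members) / T)
    return out_assign, np.array(reps), np.array(pops)


def random_rmsd_matrix(rng, n):
    x = rng.normal(size=(n, 2)) * rng.choice([0.2, 1.0], size=(n, 1))
    d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
    return d


class TestGromosCluster:
    def test_all_within_cutoff(self):
        mat = np.full((5, 5), 0.1)
        np.fill_diagonal(mat, 0.0)
        res = gromos_cluster(mat, 0.45)
        assert res.n_clusters == 1
        assert np.isclose(res.populations[0], 1.0)

    def test_all_beyond_cutoff(self):
        mat = np.full((5, 5), 2.0)
        np.fill_diagonal(mat, 0.0)
        res = gromos_cluster(mat, 0.45)
        assert res.n_clusters == 5
        assert np.allclose(res.populations, 0.2)

    def test_seven_frame_overlapping_neighbourhoods(self):
        # frames 0-3 mutually close; frames 3-5 close; frame 6 isolated
        mat = np.full((7, 7), 5.0)
        np.fill_diagonal(mat, 0.0)
        close = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3), (3, 4), (3, 5), (4, 5)]
        for i, j in close:
            mat[i, j] = mat[j, i] = 0.2
        res = gromos_cluster(mat, 0.45)
        oa, orep, opop = gromos_oracle(mat, 0.45)
        assert np.array_equal(res.assignments, oa)
        assert np.array_equal(res.representatives, orep)
        assert np.allclose(res.populations, opop)

    def test_random_matrices_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            mat = random_rmsd_matrix(rng, 15)
            res = gromos_cluster(mat, 0.5)
            oa, orep, opop = gromos_oracle(mat, 0.5)
            assert np.array_equal(res.assignments, oa)
            assert np.array_equal(res.representatives, orep)

    def test_population_conservation(self):
        rng = np.random.default_rng(12)
        mat = random_rmsd_matrix(rng, 30)
        res = gromos_cluster(mat, 0.4)
        assert np.isclose(res.populations.sum(), 1.0)
        for cid, rep in enumerate(res.representatives):
            assert res.assignments[rep] == cid

    def test_nan_rejected(self):
        mat = np.zeros((3, 3))
        mat[0, 1] = np.nan
        with pytest.raises(ValueError):
            gromos_cluster(mat, 0.45)


class TestContactMaps:
    def test_static_pair_within_cutoff(self):
        a = frame_from_coords([[0, 0, 0], [0.5, 0, 0]], chain="A")
        ens = Ensemble(frames=[a])
        cmap = contact_probability_map(ens, ("A", "A"), cutoff=0.8)
        assert cmap.matrix[0, 1] == 1.0
        assert cmap.mode == "intra"

    def test_far_chains_zero_inter_map(self):
        prof = PropensityProfile.uniform(6, 0.3, 0.2)
        spec = DimerSpec(profile_a=prof, profile_b=prof, inter_contact_pairs=[])
        ens = build_dimer(spec, 3, seed=15)
        cmap = contact_probability_map(ens, ("A", "B"), cutoff=0.8)
        assert cmap.mode == "inter"
        assert np.all(cmap.matrix == 0.0)

    def test_dimer_contacts_recovered(self):
        prof = PropensityProfile.uniform(10, 0.3, 0.2)
        pairs = [(2, 2), (7, 7)]
        spec = DimerSpec(profile_a=prof, profile_b=prof,
                         inter_contact_pairs=pairs, contact_distance=0.8)
        ens = build_dimer(spec, 20, seed=16)
        cmap = contact_probability_map(ens, ("A", "B"), cutoff=0.8)
        for i, j in pairs:
            assert cmap.matrix[i, j] >= 0.9

    def test_concatenation_exactness(self):
        prof = PropensityProfile.uniform(6, 0.4, 0.2)
        e1 = sample_dihedral_chain(prof, 4, seed=17)
        e2 = sample_dihedral_chain(prof, 8, seed=18)
        m1 = contact_probability_map(e1, ("A", "A"), cutoff=0.8).matrix
        m2 = contact_probability_map(e2, ("A", "A"), cutoff=0.8).matrix
        mc = contact_probability_map(e1.concat(e2), ("A", "A"), cutoff=0.8).matrix
        assert np.allclose(mc, (4 * m1 + 8 * m2) / 12)

    def test_intra_symmetry(self):
        prof = PropensityProfile.uniform(8, 0.4, 0.2)
        ens = sample_dihedral_chain(prof, 5, seed=19)
        m = contact_probability_map(ens, ("A", "A"), cutoff=0.8).matrix
        assert np.allclose(m, m.T)

    def test_exclude_bonded_masks_near_diagonal(self):
        prof = PropensityProfile.uniform(8, 0.4, 0.2)
        ens = sample_dihedral_chain(prof, 2, seed=20)
        m = contact_probability_map(ens, ("A", "A"), cutoff=0.8, exclude_bonded=2).matrix
        assert np.all(np.isnan(np.diag(m)))
        assert np.all(np.isnan(np.diag(m, k=2)))
        assert not np.any(np.isnan(np.diag(m, k=3)))

    def test_missing_chain(self):
        prof = PropensityProfile.uniform(5, 0.3, 0.2)
        ens = sample_dihedral_chain(prof, 1, seed=21)
        with pytest.raises(ValueError):
            contact_probability_map(ens, ("A", "Z"), cutoff=0.8)


class TestContactDifference:
    def test_identical_maps_zero(self):
        prof = PropensityProfile.uniform(6, 0.3, 0.2)
        ens = sample_dihedral_chain(prof, 3, seed=22)
        m = contact_probability_map(ens, ("A", "A"), cutoff=0.8)
        diff = contact_difference(m, m)
        assert np.allclose(diff.matrix, 0.0)
        assert diff.mode == "difference"

    def test_extremes(self):
        from dimerpipe.ensemble_analysis import ContactMap

        ones = ContactMap(matrix=np.ones((4, 4)), mode="intra", cutoff=0.8)
        zeros = ContactMap(matrix=np.zeros((4, 4)), mode="intra", cutoff=0.8)
        diff = contact_difference(ones, zeros)
        assert np.all(diff.matrix == 1.0)

    def test_distinct_architectures_signed_blocks(self):
        # chain A contacts (2, 8); chain B contacts (2, 5): difference map of
        # the two intra maps is positive at (2, 8) and negative at (2, 5)
        n = 10
        prof = PropensityProfile.uniform(n, 0.0, 0.0)

        def looped_ensemble(pair, seed):
            frames = []
            ens = sample_dihedral_chain(prof, 12, seed=seed)
            for f in ens.frames:
                ca_idx = np.where(f.atom_names == "CA")[0]
                i, j = pair
                shift = f.coords[ca_idx[i]] - f.coords[ca_idx[j]]
                # pull residue j next to residue i to create the loop contact
                mask = f.residue_index == j
                f.coords[mask] += shift * 0.95
                frames.append(f)
            return Ensemble(frames=frames)

        e_a = looped_ensemble((2, 8), seed=30)
        e_b = looped_ensemble((2, 5), seed=31)
        m_a = contact_probability_map(e_a, ("A", "A"), cutoff=0.8)
        m_b = contact_probability_map(e_b, ("A", "A"), cutoff=0.8)
        diff = contact_difference(m_a, m_b).matrix
        assert diff[2, 8] > 0.5
        assert diff[2, 5] < -0.5

    def test_shape_mismatch(self):
        from dimerpipe.ensemble_analysis import ContactMap

        a = ContactMap(matrix=np.zeros((3, 3)), mode="intra", cutoff=0.8)
        b = ContactMap(matrix=np.zeros((4, 4)), mode="intra", cutoff=0.8)
        with pytest.raises(ValueError):
            contact_difference(a, b)


class TestShapeDescriptors:
    def test_two_point_rg(self):
        assert np.isclose(radius_of_gyration(np.array([[0.0, 0, 0], [1.0, 0, 0]])), 0.5)

    def test_single_sphere_sasa(self):
        r, w = 0.17, 0.14
        sasa = shrake_rupley_sasa(np.zeros((1, 3)), np.array([r]),
                                  probe_radius=w, sphere_points=960)
        exact = 4 * np.pi * (r + w) ** 2
        assert abs(sasa - exact) / exact < 0.02

    def test_unit_cube_volume(self):
        corners = np.array(list(itertools.product([0.0, 1.0], repeat=3)))
        frame = frame_from_coords(corners)
        d = shape_descriptors(frame)
        assert np.isclose(d.volume, 1.0)

    def test_buried_atom_zero_sasa(self):
        # central atom fully enclosed by 6 overlapping neighbours
        coords = np.vstack([[0, 0, 0], np.eye(3) * 0.15, -np.eye(3) * 0.15])
        radii = np.full(7, 0.17)
        sasa_all = shrake_rupley_sasa(coords, radii, probe_radius=0.0)
        sasa_shell = shrake_rupley_sasa(coords[1:], radii[1:], probe_radius=0.0)
        assert sasa_all <= sasa_shell + 1e-9

    def test_degenerate_volume(self):
        frame = frame_from_coords([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError):
            shape_descriptors(frame)

    def test_descriptors_non_negative(self):
        prof = PropensityProfile.uniform(8, 0.4, 0.2)
        ens = sample_dihedral_chain(prof, 1, seed=23)
        d = shape_descriptors(ens.frames[0], sphere_points=120)
        assert d.radius_of_gyration > 0
        assert d.volume > 0
        assert d.sasa > 0


def test_progressive_fit_reduces_drift():
    prof = PropensityProfile.uniform(6, 1.0, 0.0)
    ens = sample_dihedral_chain(prof, 4, seed=24)
    drifted = []
    for k, f in enumerate(ens.frames):
        g = f.select(np.ones(f.n_atoms, dtype=bool))
        g.coords = f.coords + np.array([5.0 * k, 0.0, 0.0])
        drifted.append(g)
    fitted = progressive_fit(Ensemble(frames=drifted))
    centers = np.array([f.coords.mean(axis=0) for f in fitted.frames])
    assert np.linalg.norm(centers[-1] - centers[0]) < 1.0
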