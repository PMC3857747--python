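"""m-rep chain geometry: coordinates, correspondence, fitting, shape
space."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles
from scipy.spatial import cKDTree

from mrepmap import mrep, phantom
from mrepmap.errors import DomainError, ValidationError
from mrepmap.mrep import (
    MedialAtom,
    ModelCoordinate,
    MRepChain,
    build_shape_space,
    chain_from_radial,
    chain_to_params,
    correspond,
    extrapolate_rind,
    fit_chain_to_contours,
    image_to_model,
    image_to_model_batch,
    interpolator,
    model_to_image,
    params_to_chain,
    surface_distance,
    surface_grid,
    surface_points,
)

from conftest import bumpy_radial, ellipsoid_radial, interior_points


def _scaled_chain(chain, factor):
    atoms = [MedialAtom(a.hub, a.directions.copy(), a.lengths * factor)
             for a in chain.atoms]
    return MRepChain(atoms)


class TestChainBasics:
    def test_surface_points_resolution_one_is_spoke_tips(self, ellipsoid_chain):
        grid = surface_grid(ellipsoid_chain, 1)
        np.testing.assert_allclose(grid, ellipsoid_chain.tips, atol=1e-9)

    def test_surface_points_translation_equivariance(self, bumpy_chain):
        t = np.array([3.0, -2.0, 5.0])
        a = surface_grid(bumpy_chain, 3)
        b = surface_grid(bumpy_chain.translated(t), 3)
        np.testing.assert_allclose(b, a + t, atol=1e-9)

    def test_refinement_keeps_existing_points(self, bumpy_chain):
        g1 = surface_grid(bumpy_chain, 1)
        g2 = surface_grid(bumpy_chain, 2)
        np.testing.assert_allclose(g2[::2, ::2], g1, atol=1e-9)

    def test_sphere_like_chain_surface_is_spherical(self):
        # near-coincident hubs and equal spoke lengths: every surface
        # point sits at distance L from the hub centroid (closed form)
        L = 30.0
        n, m = 7, 16
        theta = np.pi * np.arange(n) / (n - 1)
        phi = mrep.spoke_azimuths(m)
        atoms = []
        for i, th in enumerate(theta):
            hub = np.array([0.0, 0.0, 1e-3 * (n - 1 - 2 * i)])
            T, P = th * np.ones(m), phi
            dirs = np.column_stack([np.sin(T) * np.cos(P),
                                    np.sin(T) * np.sin(P), np.cos(T)])
            atoms.append(MedialAtom(hub, dirs, np.full(m, L)))
        chain = MRepChain(atoms)
        pts = surface_grid(chain, 4).reshape(-1, 3)
        center = chain.hubs.mean(axis=0)
        d = np.linalg.norm(pts - center, axis=1)
        np.testing.assert_allclose(d, L, atol=0.05)

    def test_resolution_convergence_hausdorff_non_increasing(self, bumpy_chain):
        def hausdorff(A, B):
            da = cKDTree(B).query(A)[0].max()
            db = cKDTree(A).query(B)[0].max()
            return max(da, db)

        grids = [surface_grid(bumpy_chain, r).reshape(-1, 3)
                 for r in (1, 2, 4, 8)]
        d = [hausdorff(grids[i], grids[i + 1]) for i in range(3)]
        assert d[0] >= d[1] >= d[2]

    def test_chain_validation(self, ellipsoid_chain):
        with pytest.raises(ValidationError):
            MRepChain(ellipsoid_chain.atoms[:2])
        bad_dir = np.ones((16, 3))
        with pytest.raises(ValidationError):
            MedialAtom(np.zeros(3), bad_dir, np.ones(16))

    def test_serialization_round_trip(self, bumpy_chain, tmp_path):
        path = tmp_path / "chain.json"
        bumpy_chain.with_rind(3.0).save(path)
        back = MRepChain.load(path)
        np.testing.assert_allclose(back.hubs, bumpy_chain.hubs)
        np.testing.assert_allclose(back.lengths, bumpy_chain.lengths)
        assert back.rind_mm == 3.0


class TestModelImageCoordinates:
    def test_k0_is_hub_and_k1_is_tip(self, bumpy_chain):
        for i, j in [(0, 0), (3, 5), (12, 15)]:
            hub = model_to_image(ModelCoordinate(i, j, 0.0), bumpy_chain)
            np.testing.assert_allclose(hub, bumpy_chain.atoms[i].hub, atol=1e-9)
            tip = model_to_image(ModelCoordinate(i, j, 1.0), bumpy_chain)
            np.testing.assert_allclose(tip, bumpy_chain.atoms[i].tips[j],
                                       atol=1e-9)

    def test_k_half_is_spoke_midpoint(self, bumpy_chain):
        a, j = 4, 7
        mid = model_to_image(ModelCoordinate(a, j, 0.5), bumpy_chain)
        atom = bumpy_chain.atoms[a]
        np.testing.assert_allclose(mid, 0.5 * (atom.hub + atom.tips[j]),
                                   atol=1e-9)

    def test_out_of_domain_raises(self, bumpy_chain):
        with pytest.raises(DomainError):
            model_to_image(ModelCoordinate(-1.0, 0, 0.5), bumpy_chain)
        with pytest.raises(DomainError):
            model_to_image(ModelCoordinate(3.0, 0, 1.5), bumpy_chain)

    def test_spoke_tip_inverts_to_k1(self, bumpy_chain):
        c = image_to_model(bumpy_chain.atoms[5].tips[3], bumpy_chain)
        assert c.k == pytest.approx(1.0, abs=1e-3)
        assert c.i == pytest.approx(5.0, abs=1e-3)

    def test_hub_inverts_to_k0(self, bumpy_chain):
        c = image_to_model(bumpy_chain.atoms[6].hub, bumpy_chain)
        assert c.k == pytest.approx(0.0, abs=1e-3)

    def test_round_trip_interior_points(self, bumpy_chain):
        pts = interior_points(bumpy_chain, 300, seed=3)
        ijk, ok = image_to_model_batch(pts, bumpy_chain)
        assert ok.all()
        back = interpolator(bumpy_chain).position(ijk[:, 0], ijk[:, 1],
                                                  ijk[:, 2])
        err = np.linalg.norm(back - pts, axis=1)
        assert err.max() < 0.1

    def test_inversion_matches_dense_lattice_search(self, ellipsoid_chain):
        # independent oracle: nearest point over a fine (i,j,k) lattice
        interp = interpolator(ellipsoid_chain)
        n, m = ellipsoid_chain.n_atoms, ellipsoid_chain.n_spokes
        ii = np.linspace(0, n - 1, 8 * (n - 1) + 1)
        jj = np.arange(8 * m) / 8.0
        kk = np.linspace(0.05, 1.0, 24)
        I, J, K = np.meshgrid(ii, jj, kk, indexing="ij")
        lat = interp.position(I, J, K).reshape(-1, 3)
        lat_ijk = np.stack([I, J, K], axis=-1).reshape(-1, 3)
        tree = cKDTree(lat)
        pts = interior_points(ellipsoid_chain, 40, seed=5)
        ijk, ok = image_to_model_batch(pts, ellipsoid_chain)
        assert ok.all()
        _, idx = tree.query(pts)
        ref = lat_ijk[idx]
        # positions agree even where (i,j) is ambiguous near the axis
        a = interp.position(ijk[:, 0], ijk[:, 1], ijk[:, 2])
        b = interp.position(ref[:, 0], ref[:, 1], ref[:, 2])
        assert np.linalg.norm(a - pts, axis=1).max() <= \
            np.linalg.norm(b - pts, axis=1).max() + 1e-6

    def test_outside_point_raises_domain_error(self, bumpy_chain):
        with pytest.raises(DomainError):
            image_to_model(np.array([0.0, 0.0, 100.0]), bumpy_chain)


class TestCorrespond:
    def test_identity(self, bumpy_chain):
        pts = interior_points(bumpy_chain, 25, seed=1)
        mapped = correspond(pts, bumpy_chain, bumpy_chain)
        np.testing.assert_allclose(mapped, pts, atol=0.05)

    def test_translation_equivariance(self, bumpy_chain):
        t = np.array([4.0, -1.0, 7.0])
        pts = interior_points(bumpy_chain, 25, seed=2)
        mapped = correspond(pts, bumpy_chain, bumpy_chain.translated(t))
        np.testing.assert_allclose(mapped, pts + t, atol=0.05)

    def test_radial_scaling_closed_form(self, ellipsoid_chain):
        scaled = _scaled_chain(ellipsoid_chain, 1.2)
        pts = interior_points(ellipsoid_chain, 25, seed=4)
        mapped = correspond(pts, ellipsoid_chain, scaled)
        ijk, _ = image_to_model_batch(pts, ellipsoid_chain)
        interp = interpolator(ellipsoid_chain)
        hub = interp.hub(ijk[:, 0])
        np.testing.assert_allclose(mapped, hub + 1.2 * (pts - hub), atol=0.06)


class TestRind:
    def test_zero_thickness_unchanged(self, bumpy_chain):
        assert extrapolate_rind(bumpy_chain, 0.0).rind_mm == 0.0

    def test_rind_point_lies_d_beyond_surface(self, bumpy_chain):
        d = 2.5
        chain = extrapolate_rind(bumpy_chain, d)
        a, j = 6, 4
        L = chain.atoms[a].lengths[j]
        p = model_to_image(ModelCoordinate(a, j, 1.0 + d / L), chain)
        tip = chain.atoms[a].tips[j]
        np.testing.assert_allclose(p, tip + d * chain.atoms[a].directions[j],
                                   atol=1e-9)

    def test_negative_thickness_rejected(self, bumpy_chain):
        with pytest.raises(ValidationError):
            extrapolate_rind(bumpy_chain, -1.0)

    def test_default_thickness_inside_clinical_band(self):
        assert 2.0 <= mrep.DEFAULT_RIND_MM <= 5.0


class TestDisplacementField:
    def test_identity_field_is_zero(self, ellipsoid_chain, small_grid):
        f = mrep.displacement_field(ellipsoid_chain, ellipsoid_chain,
                                    small_grid)
        assert f.defined.any()
        assert np.abs(f.vectors[f.defined]).max() < 0.05

    def test_translated_field_is_constant(self, ellipsoid_chain, small_grid):
        t = np.array([2.0, 1.0, -3.0])
        f = mrep.displacement_field(ellipsoid_chain,
                                    ellipsoid_chain.translated(t), small_grid)
        np.testing.assert_allclose(f.vectors[f.defined],
                                   np.broadcast_to(t, (f.defined.sum(), 3)),
                                   atol=0.05)

    def test_agrees_with_correspond_at_voxel_centers(self, ellipsoid_chain,
                                                     small_grid):
        deformed = _scaled_chain(ellipsoid_chain, 1.1).translated([1, 2, 0.0])
        f = mrep.displacement_field(ellipsoid_chain, deformed, small_grid)
        vox = np.argwhere(f.defined)[::500]
        P = small_grid.world(vox)
        expected = correspond(P, ellipsoid_chain, deformed) - P
        got = f.vectors[vox[:, 0], vox[:, 1], vox[:, 2]]
        np.testing.assert_allclose(got, expected, atol=0.05)

    def test_undefined_outside_model(self, ellipsoid_chain, small_grid):
        f = mrep.displacement_field(ellipsoid_chain, ellipsoid_chain,
                                    small_grid)
        corner = f.defined[0, 0, 0]
        assert not corner


class TestFit:
    def test_contours_from_chain_recover_chain(self, bumpy_chain):
        zs = np.arange(-28.5, 29, 3.0)
        stack = mrep.chain_axial_sections(bumpy_chain, zs, 60)
        res = fit_chain_to_contours(stack)
        assert res.mean_residual_mm < 0.05
        assert np.abs(res.chain.hubs - bumpy_chain.hubs).max() < 0.5

    def test_smooth_synthetic_stack_residual_below_threshold(self):
        chain = chain_from_radial([0, 0, 0], bumpy_radial(seed=9))
        zs = np.arange(-28.5, 29, 3.0)
        stack = mrep.chain_axial_sections(chain, zs, 60)
        res = fit_chain_to_contours(stack)
        assert res.mean_residual_mm < 0.2

    def test_ellipsoid_residual_matches_dense_distance_oracle(self):
        chain = chain_from_radial([0, 0, 0], ellipsoid_radial())
        zs = np.arange(-28.5, 29, 3.0)
        stack = mrep.chain_axial_sections(chain, zs, 48)
        res = fit_chain_to_contours(stack)
        # independent oracle: per-vertex Nelder-Mead minimization of the
        # vertex-to-surface distance, seeded by a dense sampling
        from scipy.optimize import minimize

        interp = interpolator(res.chain)
        dense = surface_grid(res.chain, 8).reshape(-1, 3)
        n, m = res.chain.n_atoms, res.chain.n_spokes
        ii = np.linspace(0, n - 1, 8 * (n - 1) + 1)
        jj = np.arange(8 * m) / 8.0
        I, J = np.meshgrid(ii, jj, indexing="ij")
        ij = np.stack([I, J], axis=-1).reshape(-1, 2)
        tree = cKDTree(dense)
        per = []
        for z, ring in stack.rings():
            pts = np.column_stack([ring, np.full(len(ring), z)])[::6]
            dz = []
            for p in pts:
                x0 = ij[tree.query(p)[1]]
                r = minimize(lambda x: np.linalg.norm(
                    interp.surface(np.clip(x[0], 0, n - 1), x[1]) - p),
                    x0, method="Nelder-Mead",
                    options={"xatol": 1e-6, "fatol": 1e-12})
                dz.append(r.fun)
            per.append(np.mean(dz))
        oracle = float(np.mean(per))
        assert res.mean_residual_mm == pytest.approx(oracle, abs=0.02)
        assert res.mean_residual_mm < 0.2

    def test_crossing_contours_rejected(self):
        sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10.]])
        far = sq + 100.0
        with pytest.raises(ValidationError):
            fit_chain_to_contours(
                mrep.ContourStack([(0.0, sq), (3.0, far), (6.0, sq)]))

    def test_too_few_slices_rejected(self):
        sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10.]])
        with pytest.raises(ValidationError):
            fit_chain_to_contours(mrep.ContourStack([(0.0, sq), (3.0, sq)]))

    def test_residual_decreases_with_smoothness(self):
        chain = chain_from_radial([0, 0, 0], bumpy_radial(seed=11,
                                                          amplitude=0.03))
        zs = np.arange(-28.5, 29, 3.0)
        stack = mrep.chain_axial_sections(chain, zs, 60)
        loose = fit_chain_to_contours(stack, smoothness_weight=1e-6)
        tight = fit_chain_to_contours(stack, smoothness_weight=1e-3)
        assert loose.mean_residual_mm <= tight.mean_residual_mm + 1e-6


class TestShapeSpace:
    def test_identical_chains_zero_variance_mean_is_input(self, bumpy_chain):
        space = build_shape_space([bumpy_chain] * 4)
        assert np.all(space.variances < 1e-18)
        np.testing.assert_allclose(chain_to_params(space.mean_chain),
                                   chain_to_params(bumpy_chain), atol=1e-9)

    def test_mismatched_topologies_rejected(self, bumpy_chain):
        other = chain_from_radial([0, 0, 0], ellipsoid_radial(), n_atoms=9)
        with pytest.raises(ValidationError):
            build_shape_space([bumpy_chain, other])

    def test_two_mode_subspace_recovery(self):
        # chains drawn from a known 2-mode generative model
        spec = phantom.PhantomSpec(seed=21, mode_sigmas=(0.04, 0.04, 0.0))
        chains = phantom.generate_training_chains(spec, 200)
        space = build_shape_space(chains)
        base = phantom.planning_chain(spec)
        modes, sigmas = phantom.generative_modes(base, spec)
        angles = np.degrees(subspace_angles(modes[:2].T, space.modes[:2].T))
        assert angles.max() < 5.0
        # variances within sampling error of the generative sigmas
        gen_var = np.sort(sigmas[:2] ** 2)[::-1]
        np.testing.assert_allclose(space.variances[:2], gen_var, rtol=0.3)

    def test_full_mode_reconstruction_is_exact(self):
        spec = phantom.PhantomSpec(seed=22)
        chains = phantom.generate_training_chains(spec, 6)
        space = build_shape_space(chains)
        for c in chains:
            p = chain_to_params(c)
            coeff = space.modes @ (p - space.mean)
            rec = space.mean + coeff @ space.modes
            np.testing.assert_allclose(rec, p, atol=1e-9)

    def test_synthesize_zero_is_mean(self):
        spec = phantom.PhantomSpec(seed=23)
        space = build_shape_space(phantom.generate_training_chains(spec, 10))
        np.testing.assert_allclose(
            chain_to_params(space.synthesize(np.zeros(3))),
            chain_to_params(space.mean_chain), atol=1e-12)

    def test_serialization_round_trip(self, tmp_path):
        spec = phantom.PhantomSpec(seed=24)
        space = build_shape_space(phantom.generate_training_chains(spec, 10))
        path = tmp_path / "space.json"
        space.save(path)
        back = mrep.ShapeSpace.load(path)
        np.testing.assert_allclose(back.mean, space.mean)
        np.testing.assert_allclose(back.modes, space.modes)
        np.testing.assert_allclose(back.variances, space.variances)


class TestMask:
    def test_mask_volume_close_to_analytic(self, ellipsoid_chain, small_grid):
        mask = mrep.chain_mask(ellipsoid_chain, small_grid)
        vol = mask.sum() * small_grid.voxel_volume_mm3
        analytic = 4.0 / 3.0 * np.pi * 25 * 20 * 30
        assert vol == pytest.approx(analytic, rel=0.03)

    def test_rind_mask_strictly_larger(self, ellipsoid_chain, small_grid):
        plain = mrep.chain_mask(ellipsoid_chain, small_grid)
        rind = mrep.chain_mask(ellipsoid_chain.with_rind(3.0), small_grid,
                               include_rind=True)
        assert rind.sum() > plain.sum()
        assert np.all(rind[plain])

    def test_dice_of_identical_masks_is_one(self, ellipsoid_chain, small_grid):
        a = mrep.chain_mask(ellipsoid_chain, small_grid)
        b = mrep.chain_mask(ellipsoid_chain, small_grid)
        assert mrep.dice_coefficient(a, b) == 1.0


def test_surface_points_returns_labeled_set(ellipsoid_chain):
    ps = surface_points(ellipsoid_chain, 1)
    assert len(ps) == 13 * 16
    with pytest.raises(ValidationError):
        surface_points(ellipsoid_chain, 0)


def test_surface_distance_zero_on_tips(bumpy_chain):
    d = surface_distance(bumpy_chain.tips.reshape(-1, 3), bumpy_chain)
    assert d.max() < 1e-6
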