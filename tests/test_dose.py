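"""Isocenter mapping, dose mapping/accumulation, error dose, DVHs."""

import numpy as np
import pytest

from mrepmap import dose as dm, mrep, phantom
from mrepmap.core_io import Volume3D
from mrepmap.errors import DomainError, ValidationError
from mrepmap.mrep import MedialAtom, MRepChain

RIND = 3.0


def _scaled(chain, f):
    return MRepChain([MedialAtom(a.hub, a.directions.copy(), a.lengths * f)
                      for a in chain.atoms], rind_mm=chain.rind_mm)


@pytest.fixture(scope="module")
def chain_r(ellipsoid_chain):
    return ellipsoid_chain.with_rind(RIND)


class TestMapIsocenter:
    def test_identity(self, chain_r):
        iso = np.array([2.0, -3.0, -6.0])
        np.testing.assert_allclose(dm.map_isocenter(iso, chain_r, chain_r),
                                   iso, atol=0.05)

    def test_translation(self, chain_r):
        iso = np.array([2.0, -3.0, -6.0])
        t = np.array([5.0, 4.0, -9.0])
        np.testing.assert_allclose(
            dm.map_isocenter(iso, chain_r, chain_r.translated(t)), iso + t,
            atol=0.05)

    def test_radial_scaling_closed_form(self, chain_r):
        iso = np.array([2.0, -3.0, -6.0])
        mapped = dm.map_isocenter(iso, chain_r, _scaled(chain_r, 1.2))
        ijk, _ = mrep.image_to_model_batch(iso[None], chain_r)
        hub = mrep.interpolator(chain_r).hub(ijk[:, 0])[0]
        np.testing.assert_allclose(mapped, hub + 1.2 * (iso - hub), atol=0.1)

    def test_round_trip_within_tolerance(self, chain_r):
        deformed = _scaled(chain_r, 1.15).translated([4.0, -2.0, 7.0])
        iso = np.array([2.0, -3.0, -6.0])
        fwd = dm.map_isocenter(iso, chain_r, deformed)
        back = dm.map_isocenter(fwd, deformed, chain_r)
        assert np.linalg.norm(back - iso) <= 0.1

    def test_outside_isocenter_diagnostic(self, chain_r):
        with pytest.raises(DomainError, match="distance to surface"):
            dm.map_isocenter(np.array([100.0, 0, 0]), chain_r, chain_r)


def _dose_on(vol_shape, spacing, origin, fn):
    vol = Volume3D(np.zeros(vol_shape), spacing, origin)
    ax = vol.grid_world()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    return dm.DoseGrid(vol.copy_with(fn(X, Y, Z)))


@pytest.fixture(scope="module")
def grid5(chain_r):
    return Volume3D(np.zeros((18, 16, 16)), (5.0, 5.0, 5.0),
                    (-42.5, -37.5, -37.5))


class TestMapDose:
    def test_identity_chains_uniform_dose_exact(self, chain_r, grid5):
        dose = dm.DoseGrid(grid5.copy_with(np.full(grid5.shape, 180.0)))
        mapped = dm.map_dose_to_planning(dose, chain_r, chain_r, RIND,
                                        planning_grid=grid5)
        assert mapped.defined.any()
        np.testing.assert_allclose(mapped.volume.data[mapped.defined], 180.0)
        assert mapped.flagged_outside == 0

    def test_linear_ramp_translated_chains(self, chain_r, grid5):
        t = np.array([6.0, -4.0, 5.0])
        big = Volume3D(np.zeros((40, 36, 36)), (5, 5, 5), (-97.5, -87.5, -87.5))
        ramp = dm.DoseGrid(big.copy_with(
            300.0 + 2.0 * np.meshgrid(*big.grid_world(), indexing="ij")[0]))
        mapped = dm.map_dose_to_planning(ramp, chain_r.translated(t), chain_r,
                                         RIND, planning_grid=grid5)
        vox = np.argwhere(mapped.defined)
        P = grid5.world(vox)
        expected = 300.0 + 2.0 * (P[:, 0] + t[0])
        got = mapped.volume.data[vox[:, 0], vox[:, 1], vox[:, 2]]
        np.testing.assert_allclose(got, expected, atol=0.5)

    def test_undefined_outside_model(self, chain_r, grid5):
        dose = dm.DoseGrid(grid5.copy_with(np.full(grid5.shape, 50.0)))
        mapped = dm.map_dose_to_planning(dose, chain_r, chain_r, RIND,
                                        planning_grid=grid5)
        assert not mapped.defined[0, 0, 0]

    def test_out_of_source_voxels_flagged(self, chain_r, grid5):
        small = Volume3D(np.zeros((4, 4, 4)), (5, 5, 5), (-7.5, -7.5, -7.5))
        dose = dm.DoseGrid(small.copy_with(np.full(small.shape, 10.0)))
        mapped = dm.map_dose_to_planning(dose, chain_r, chain_r, RIND,
                                        planning_grid=grid5)
        assert mapped.flagged_outside > 0


class TestPlacement:
    def test_zero_shift_identical(self, grid5):
        dose = dm.DoseGrid(grid5.copy_with(np.random.default_rng(0)
                                           .uniform(0, 200, grid5.shape)))
        iso = np.array([0.0, 0.0, 0.0])
        placed = dm.place_delivered_dose(dose, iso, iso)
        np.testing.assert_array_equal(placed.volume.data, dose.volume.data)
        np.testing.assert_array_equal(placed.volume.origin, dose.volume.origin)

    def test_peak_moves_with_shift(self):
        peak = _dose_on((21, 21, 21), (1, 1, 1), (-10, -10, -10),
                        lambda X, Y, Z: 100.0 * np.exp(-(X**2 + Y**2 + Z**2)
                                                       / 8.0))
        placed = dm.place_delivered_dose(peak, np.zeros(3),
                                         np.array([0, 0, 10.0]))
        pts = np.array([[0, 0, 10.0], [0, 0, 0.0]])
        vals = placed.volume.sample(pts)
        assert vals[0] == pytest.approx(100.0, abs=1e-6)
        assert vals[1] < 10.0

    def test_dose_at_isocenter_preserved(self, grid5):
        rng = np.random.default_rng(1)
        dose = dm.DoseGrid(grid5.copy_with(rng.uniform(0, 200, grid5.shape)))
        p_iso = np.array([1.0, 2.0, 3.0])
        t_iso = np.array([-7.0, 4.0, 11.0])
        placed = dm.place_delivered_dose(dose, p_iso, t_iso)
        assert placed.volume.sample(t_iso[None])[0] == pytest.approx(
            dose.volume.sample(p_iso[None])[0], abs=1e-9)


class TestAccumulate:
    def test_single_grid_resamples_to_itself(self, grid5):
        dose = dm.DoseGrid(grid5.copy_with(np.random.default_rng(2)
                                           .uniform(0, 100, grid5.shape)))
        acc = dm.accumulate([dose], grid5)
        np.testing.assert_allclose(acc.volume.data, dose.volume.data,
                                   atol=1e-9)

    def test_linearity(self, grid5):
        dose = dm.DoseGrid(grid5.copy_with(np.random.default_rng(3)
                                           .uniform(0, 100, grid5.shape)))
        acc = dm.accumulate([dose] * 4, grid5)
        np.testing.assert_allclose(acc.volume.data, 4 * dose.volume.data,
                                   atol=1e-9)
        assert acc.n_fractions == 4

    def test_mixed_resolution_order_of_operations(self, grid5):
        fine = _dose_on((41, 41, 41), (2, 2, 2), (-40, -40, -40),
                        lambda X, Y, Z: 150.0 + X + 0.5 * Y - 0.25 * Z)
        coarse = _dose_on((17, 17, 17), (5, 5, 5), (-40, -40, -40),
                          lambda X, Y, Z: 20.0 + 0.1 * X * 0 + Z * 0.2)
        acc = dm.accumulate([fine, coarse], grid5)
        # oracle: resample each separately then add voxelwise
        a1, in1 = dm._resample_to(fine, grid5)
        a2, in2 = dm._resample_to(coarse, grid5)
        both = in1 & in2
        np.testing.assert_allclose(acc.volume.data[both],
                                   (a1 + a2)[both], atol=1e-9)
        assert np.all(acc.volume.data[~both] == 0)

    def test_empty_list_rejected(self, grid5):
        with pytest.raises(ValidationError):
            dm.accumulate([], grid5)


class TestErrorDose:
    def test_exact_delivery_gives_zero(self, grid5):
        planned = dm.DoseGrid(grid5.copy_with(
            np.random.default_rng(4).uniform(0, 200, grid5.shape)))
        placed = [dm.place_delivered_dose(planned, np.zeros(3), np.zeros(3))
                  for _ in range(15)]
        acc = dm.accumulate(placed, grid5)
        err = dm.error_dose(acc, planned, 15)
        np.testing.assert_allclose(err.volume.data, 0, atol=1e-9)

    def test_single_fraction_identity(self, grid5):
        planned = dm.DoseGrid(grid5.copy_with(np.full(grid5.shape, 70.0)))
        err = dm.error_dose(planned, planned, 1)
        np.testing.assert_allclose(err.volume.data, 0, atol=1e-12)

    def test_grid_mismatch_rejected(self, grid5):
        planned = dm.DoseGrid(grid5.copy_with(np.zeros(grid5.shape)))
        other = dm.DoseGrid(Volume3D(np.zeros((4, 4, 4)), (5, 5, 5),
                                     (0, 0, 0)))
        with pytest.raises(ValidationError):
            dm.error_dose(other, planned, 1)

    def test_superior_shift_underdoses_the_apex(self, chain_r):
        # delivered dose shifted superiorly (+z) while the prostate did
        # not move: the inferior (apex) edge of the target is underdosed
        spec = phantom.PhantomSpec(seed=51)
        planned = phantom.generate_planned_dose(spec, chain_r,
                                                np.array([2.0, -3.0, -6.0]))
        placed = dm.place_delivered_dose(planned, np.zeros(3),
                                         np.array([0.0, 0.0, 8.0]))
        acc = dm.accumulate([placed], planned.volume)
        err = dm.error_dose(acc, planned, 1)
        # direct-subtraction oracle
        direct = placed.volume.sample(
            np.stack(np.meshgrid(*planned.volume.grid_world(), indexing="ij"),
                     axis=-1).reshape(-1, 3)).reshape(planned.volume.shape) \
            - planned.volume.data
        np.testing.assert_allclose(err.volume.data[err.defined_mask()],
                                   direct[err.defined_mask()], atol=1e-6)
        gz = planned.volume.grid_world()[2]
        apex = err.volume.data[:, :, gz < -20.0]
        sup = err.volume.data[:, :, (gz > -5) & (gz < 20)]
        assert apex.min() < -50.0          # strong underdose at the apex
        assert np.abs(sup).max() < np.abs(apex.min())  # plateau unaffected


class TestDVH:
    def test_uniform_dose_single_bin(self, chain_r, grid5):
        dose = dm.DoseGrid(grid5.copy_with(np.full(grid5.shape, 185.0)))
        curve = dm.dvh(dose, chain_r)
        occupied = np.flatnonzero(curve.differential_cm3 > 0)
        assert occupied.size == 1
        lo = curve.bin_edges[occupied[0]]
        assert lo <= 185.0 <= curve.bin_edges[occupied[0] + 1]
        cum = curve.cumulative_percent
        assert cum[occupied[0]] == pytest.approx(100.0)

    def test_default_bin_width_10(self):
        assert dm.DEFAULT_BIN_CGY == 10.0

    def test_linear_ramp_flat_histogram_voxel_count_oracle(self):
        # box region: a chain scaled so the grid inside is a thick slab
        big = Volume3D(np.zeros((30, 26, 24)), (2, 2, 3), (-29, -25, -34.5))
        chain = mrep.chain_from_radial(
            [0, 0, 0], lambda t, p: np.full(np.broadcast(t, p).shape, 24.0))
        ramp = dm.DoseGrid(big.copy_with(
            5.0 * (np.meshgrid(*big.grid_world(), indexing="ij")[2] + 40.0)))
        curve = dm.dvh(ramp, chain, bin_cGy=15.0)
        mask = mrep.chain_mask(chain, big)
        counts, _ = np.histogram(ramp.volume.data[mask], bins=curve.bin_edges)
        np.testing.assert_allclose(curve.differential_cm3,
                                   counts * big.voxel_volume_mm3 / 1000.0)

    def test_volume_conservation_random_fields(self, chain_r, grid5):
        rng = np.random.default_rng(6)
        mask = mrep.chain_mask(chain_r, grid5)
        region = mask.sum() * grid5.voxel_volume_mm3 / 1000.0
        for _ in range(5):
            dose = dm.DoseGrid(grid5.copy_with(
                rng.uniform(0, 300, grid5.shape)))
            curve = dm.dvh(dose, chain_r)
            assert abs(curve.total_volume_cm3 - region) \
                <= grid5.voxel_volume_mm3 / 1000.0

    def test_empty_region_rejected(self, chain_r):
        tiny = Volume3D(np.zeros((3, 3, 3)), (1, 1, 1), (200, 200, 200))
        with pytest.raises(ValidationError):
            dm.dvh(dm.DoseGrid(tiny), chain_r)

    def test_dvh_after_mapping_matches_treatment_space_dvh(self, chain_r):
        # translation-only deformation preserves volume: the DVH of the
        # mapped dose on the planning grid matches the direct treatment-
        # space DVH on the treatment chain
        t = np.array([6.5, -4.25, 5.0])
        tchain = chain_r.translated(t)
        big = Volume3D(np.zeros((131, 131, 131)), (1, 1, 1),
                       (-65.0, -65.0, -65.0))
        Z = np.meshgrid(*big.grid_world(), indexing="ij")[2]
        dose_t = dm.DoseGrid(big.copy_with(150.0 + 1.5 * (Z - t[2])))
        grid_p = Volume3D(np.zeros((101, 101, 101)), (1, 1, 1),
                          (-50.0, -50.0, -50.0))
        mapped = dm.map_dose_to_planning(dose_t, tchain, chain_r, RIND,
                                         planning_grid=grid_p)
        dvh_p = dm.dvh(mapped, chain_r, bin_cGy=10.0)
        dvh_t = dm.dvh(dose_t, tchain, bin_cGy=10.0)
        # align edge ranges before comparing per-bin volumes
        lo = min(dvh_p.bin_edges[0], dvh_t.bin_edges[0])
        hi = max(dvh_p.bin_edges[-1], dvh_t.bin_edges[-1])
        edges = np.arange(lo, hi + 5.0, 10.0)

        def vols(curve):
            v = np.zeros(len(edges) - 1)
            idx = np.searchsorted(edges, curve.bin_edges[:-1] + 1e-9) - 1
            for i, x in zip(idx, curve.differential_cm3):
                v[i] += x
            return v

        vp, vt = vols(dvh_p), vols(dvh_t)
        assert np.abs(vp - vt).max() / vt.sum() <= 0.02
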