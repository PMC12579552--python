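"""Density synthesis, masks, noise and real-space metrics vs brute force."""

import numpy as np
import pytest

from trxscore import (
    AtomRecord,
    DensityGrid,
    GridSpec,
    ResidueKey,
    ResidueSelection,
    StructureModel,
    compute_model_density,
    difference_grid,
    estimate_sigma,
    read_ccp4,
    residue_difference_weights,
    residue_mask,
    rscc,
    rszd,
    rszo,
    write_ccp4,
)
from trxscore.density import NoiseEstimate
from trxscore.structure import ValidationError


def single_atom_model(pos, element="C", occ=1.0, b=20.0):
    return StructureModel(residues={
        ResidueKey("A", 1, "", "ALA"): [
            AtomRecord("CA", element, np.asarray(pos, float), "", occ, b)
        ]
    })


GRID = GridSpec(cell=(20.0, 20.0, 20.0), spacing=(0.4, 0.4, 0.4),
                origin=(-10.0, -10.0, -10.0))


def random_grid(rng, n=12):
    return DensityGrid(rng.normal(0, 1, (n, n, n)), (0.5, 0.5, 0.5),
                       np.zeros(3))


def random_mask(rng, grid, n_vox=50):
    from trxscore.density import ResidueMask

    shape = grid.shape
    flat = rng.choice(np.prod(shape), size=n_vox, replace=False)
    idx = np.stack(np.unravel_index(flat, shape), axis=1)
    return ResidueMask(indices=idx, radius=2.0,
                       residue=ResidueKey("A", 1, "", "ALA"))


class TestModelDensity:
    def test_single_carbon_integral_and_peak(self):
        model = single_atom_model([0.0, 0.0, 0.0])
        grid = compute_model_density(model, GRID)
        integral = grid.values.sum() * grid.voxel_volume
        assert integral == pytest.approx(6.0, rel=0.01)  # carbon: 6 electrons
        peak = np.unravel_index(grid.values.argmax(), grid.shape)
        assert peak == (25, 25, 25)  # the voxel holding the atom

    def test_occupancy_linearity(self):
        full = compute_model_density(single_atom_model([0, 0, 0], occ=1.0), GRID)
        half = compute_model_density(single_atom_model([0, 0, 0], occ=0.5), GRID)
        assert np.allclose(half.values, 0.5 * full.values, atol=0, rtol=1e-12)

    def test_two_state_mixture_linearity(self, helix10):
        """Occupancy-weighted two-state density is the exact convex mix."""
        from trxscore import merge_alt_conformers, make_truth_conformer

        sel = ResidueSelection.from_keys(list(helix10.residues)[4:6])
        truth = make_truth_conformer(helix10, sel, shift=1.0, seed=3)
        merged = merge_alt_conformers(helix10, truth, sel, q_init=0.25)
        spec = GridSpec.from_model(helix10, spacing=0.8, margin=4.0)
        mixed = compute_model_density(merged, spec, altlocs={"A", "B"})
        grid_a = compute_model_density(merged, spec, altlocs={"A"},
                                       occupancy_weighted=False)
        grid_b = compute_model_density(merged, spec, altlocs={"B"},
                                       occupancy_weighted=False)
        assert np.allclose(
            mixed.values, 0.75 * grid_a.values + 0.25 * grid_b.values,
            atol=1e-10,
        )

    def test_atom_outside_grid_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            compute_model_density(single_atom_model([100.0, 0, 0]), GRID)


class TestDifferenceGrid:
    def test_antisymmetry_and_identity(self, rng):
        a = random_grid(rng)
        b = random_grid(rng)
        zero = DensityGrid(np.zeros(a.shape), a.spacing, a.origin.copy())
        assert np.all(difference_grid(a, a).values == 0)
        assert np.allclose(difference_grid(a, zero).values, a.values)
        ab = difference_grid(a, b)
        ba = difference_grid(b, a)
        assert np.allclose(ab.values + ba.values, 0.0)

    def test_geometry_mismatch_rejected(self, rng):
        a = random_grid(rng, 12)
        b = random_grid(rng, 13)
        with pytest.raises(ValidationError):
            difference_grid(a, b)


class TestNoiseEstimate:
    def test_rms_on_unit_normal(self, rng):
        grid = DensityGrid(rng.normal(0, 1, (64, 64, 64)), (1, 1, 1))
        est = estimate_sigma(grid, "rms")
        assert est.sigma == pytest.approx(1.0, rel=0.02)

    def test_constant_grid_flagged(self):
        grid = DensityGrid(np.full((8, 8, 8), 5.0), (1, 1, 1))
        with pytest.warns(UserWarning, match="constant"):
            est = estimate_sigma(grid, "rms")
        assert est.sigma == 0.0 and est.constant_grid

    def test_mad_robust_to_outliers(self, rng):
        values = rng.normal(0, 1, (32, 32, 32))
        flat = values.ravel()
        hot = rng.choice(flat.size, size=flat.size // 100, replace=False)
        flat[hot] = 100.0
        grid = DensityGrid(flat.reshape(32, 32, 32), (1, 1, 1))
        mad = estimate_sigma(grid, "mad")
        rms = estimate_sigma(grid, "rms")
        assert mad.sigma == pytest.approx(1.0, rel=0.05)
        assert rms.sigma > 5.0


class TestResidueMask:
    def test_tiny_radius_single_voxel(self):
        model = single_atom_model([0.0, 0.0, 0.0])
        grid = compute_model_density(model, GRID)
        mask = residue_mask(model, next(iter(model.residues)), grid,
                            radius=0.04)  # 0.1 x spacing
        assert mask.size == 1
        assert tuple(mask.indices[0]) == (25, 25, 25)

    def test_radius_monotonicity(self, helix10):
        spec = GridSpec.from_model(helix10, spacing=0.8, margin=4.0)
        grid = compute_model_density(helix10, spec)
        key = list(helix10.residues)[3]
        small = residue_mask(helix10, key, grid, radius=2.0)
        large = residue_mask(helix10, key, grid, radius=4.0)
        small_set = set(map(tuple, small.indices))
        large_set = set(map(tuple, large.indices))
        assert small_set <= large_set

    def test_matches_brute_force_scan(self, helix10):
        spec = GridSpec.from_model(helix10, spacing=1.1, margin=3.0)
        grid = compute_model_density(helix10, spec)
        key = list(helix10.residues)[5]
        mask = residue_mask(helix10, key, grid, radius=2.0)
        coords = np.array([a.position for a in helix10.residues[key]])
        ax, ay, az = grid.axis_coords()
        brute = set()
        for i in range(grid.shape[0]):
            for j in range(grid.shape[1]):
                for k in range(grid.shape[2]):
                    p = np.array([ax[i], ay[j], az[k]])
                    if np.min(np.linalg.norm(coords - p, axis=1)) <= 2.0:
                        brute.add((i, j, k))
        assert set(map(tuple, mask.indices)) == brute


class TestMetricsAgainstBruteForce:
    def test_rscc_perfect_and_inverted(self, rng):
        grid = random_grid(rng)
        mask = random_mask(rng, grid)
        neg = DensityGrid(-grid.values, grid.spacing, grid.origin.copy())
        assert rscc(grid, grid, mask) == pytest.approx(1.0, abs=1e-12)
        assert rscc(grid, neg, mask) == pytest.approx(-1.0, abs=1e-12)

    def test_hundred_random_instances_match_oracles(self, rng):
        """RSCC, RSZO and RSZD agree with direct brute-force computations
        over the masked voxels to 1e-12 on 100 random (grid, mask) draws."""
        for _ in range(100):
            obs = random_grid(rng)
            calc = random_grid(rng)
            mask = random_mask(rng, obs, n_vox=int(rng.integers(10, 80)))
            sigma = NoiseEstimate(sigma=float(rng.uniform(0.5, 2.0)), method="rms")

            x = np.array([obs.values[tuple(ix)] for ix in mask.indices])
            y = np.array([calc.values[tuple(ix)] for ix in mask.indices])
            cc = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
            )
            assert rscc(obs, calc, mask) == pytest.approx(cc, abs=1e-12)
            assert rszo(obs, mask, sigma) == pytest.approx(
                x.mean() / sigma.sigma, abs=1e-12
            )
            plus, minus = rszd(obs, mask, sigma)
            assert plus == pytest.approx(max(0.0, x.max() / sigma.sigma), abs=1e-12)
            assert minus == pytest.approx(max(0.0, -x.min() / sigma.sigma), abs=1e-12)

    def test_rszd_single_hot_voxel(self, rng):
        grid = DensityGrid(np.zeros((10, 10, 10)), (1, 1, 1))
        mask = random_mask(rng, grid, n_vox=20)
        hot = tuple(mask.indices[3])
        grid.values[hot] = 5.0
        plus, minus = rszd(grid, mask, NoiseEstimate(1.0, "rms"))
        assert (plus, minus) == (5.0, 0.0)

    def test_rscc_zero_variance_is_missing(self, rng):
        grid = random_grid(rng)
        flat = DensityGrid(np.zeros(grid.shape), grid.spacing, grid.origin.copy())
        mask = random_mask(rng, grid)
        assert rscc(grid, flat, mask) is None


class TestResidueWeights:
    def make_scene(self):
        atoms = {
            ResidueKey("A", 1, "", "ALA"): np.array([2.0, 2.0, 2.0]),
            ResidueKey("A", 2, "", "ALA"): np.array([8.0, 8.0, 8.0]),
        }
        model = StructureModel(residues={
            k: [AtomRecord("CA", "C", p, "", 1.0, 20.0)]
            for k, p in atoms.items()
        })
        grid = DensityGrid(np.zeros((11, 11, 11)), (1.0, 1.0, 1.0))
        return model, grid, atoms

    def test_zero_map_warns_all_zero(self):
        model, grid, _ = self.make_scene()
        sel = ResidueSelection.from_keys(model.residues)
        with pytest.warns(UserWarning, match="no voxel"):
            w = residue_difference_weights(
                grid, model, sel, NoiseEstimate(1.0, "rms"))
        assert all(v == 0 for v in w.rho_pos.values())
        assert all(v == 0 for v in w.rho_neg.values())
        assert w.m == 2

    def test_locality_of_blob_assignment(self):
        model, grid, atoms = self.make_scene()
        sel = ResidueSelection.from_keys(model.residues)
        grid.values[3, 2, 2] = 5.0  # 1 A from residue 1 only
        w = residue_difference_weights(grid, model, sel,
                                       NoiseEstimate(1.0, "rms"))
        k1, k2 = sorted(atoms)
        assert w.rho_pos[k1] == 5.0 and w.rho_neg[k1] == 0.0
        assert w.rho_pos[k2] == 0.0 and w.rho_neg[k2] == 0.0

    def test_capture_radius_discards_remote_voxels(self):
        model, grid, _ = self.make_scene()
        sel = ResidueSelection.from_keys(model.residues)
        grid.values[5, 2, 8] = 9.0  # > 3.5 A from both residues
        w = residue_difference_weights(grid, model, sel,
                                       NoiseEstimate(1.0, "rms"))
        assert all(v == 0.0 for v in w.rho_pos.values())

    def test_threshold_monotonicity(self, rng):
        """Raising the Z threshold never increases any weight."""
        model, grid, _ = self.make_scene()
        sel = ResidueSelection.from_keys(model.residues)
        grid.values[:] = rng.normal(0, 1, grid.shape)
        sigma = NoiseEstimate(1.0, "rms")
        prev = None
        for z in (0.5, 1.0, 2.0, 3.0):
            w = residue_difference_weights(grid, model, sel, sigma, z_threshold=z)
            if prev is not None:
                for key in w.keys():
                    assert w.rho_pos[key] <= prev.rho_pos[key] + 1e-12
                    assert w.rho_neg[key] <= prev.rho_neg[key] + 1e-12
            prev = w

    def test_scale_invariance_of_membership(self, rng):
        model, grid, _ = self.make_scene()
        sel = ResidueSelection.from_keys(model.residues)
        grid.values[:] = rng.normal(0, 1, grid.shape)
        w1 = residue_difference_weights(grid, model, sel,
                                        NoiseEstimate(1.0, "rms"))
        scaled = DensityGrid(7.0 * grid.values, grid.spacing, grid.origin.copy())
        w2 = residue_difference_weights(scaled, model, sel,
                                        NoiseEstimate(7.0, "rms"))
        for key in w1.keys():
            assert w2.rho_pos[key] == pytest.approx(7.0 * w1.rho_pos[key], rel=1e-12)
            assert w2.rho_neg[key] == pytest.approx(7.0 * w1.rho_neg[key], rel=1e-12)

    def test_brute_force_assignment_on_mixture(self, small_dataset):
        """Nearest-atom weight assignment equals a per-voxel brute-force scan
        on a noise-free two-state mixture map."""
        _, ds = small_dataset
        sigma = estimate_sigma(ds.diff, "rms")
        w = residue_difference_weights(ds.diff, ds.reference, ds.selection, sigma)

        keys = [k for k in ds.reference.residues if k in ds.selection]
        coords, owners = [], []
        for k in keys:
            for a in ds.reference.residues[k]:
                coords.append(a.position)
                owners.append(k)
        coords = np.array(coords)
        expected_pos = {k: 0.0 for k in keys}
        expected_neg = {k: 0.0 for k in keys}
        ax, ay, az = ds.diff.axis_coords()
        strong = np.argwhere(np.abs(ds.diff.values) >= 3.0 * sigma.sigma)
        for i, j, k in strong:
            p = np.array([ax[i], ay[j], az[k]])
            d = np.linalg.norm(coords - p, axis=1)
            if d.min() > 3.5:
                continue
            owner = owners[int(d.argmin())]
            v = ds.diff.values[i, j, k]
            if v > 0:
                expected_pos[owner] += v
            else:
                expected_neg[owner] += -v
        for key in keys:
            assert w.rho_pos[key] == pytest.approx(expected_pos[key], abs=1e-10)
            assert w.rho_neg[key] == pytest.approx(expected_neg[key], abs=1e-10)


class TestCcp4RoundTrip:
    def test_round_trip_values_and_geometry(self, rng, tmp_path):
        grid = DensityGrid(
            rng.normal(0, 1, (8, 10, 12)),
            (0.5, 0.5, 0.5),
            np.array([2.0, -1.5, 0.0]),
        )
        path = tmp_path / "map.ccp4"
        write_ccp4(grid, path)
        back = read_ccp4(path)
        assert back.shape == grid.shape
        assert np.allclose(back.spacing, grid.spacing, atol=1e-6)
        assert np.allclose(back.origin, grid.origin, atol=1e-6)
        assert np.allclose(back.values, grid.values, atol=1e-6)  # float32 file
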