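import itertools

import numpy as np
import pytest

from nucleoscatter import nucleus_models as nm
from nucleoscatter.errors import ContainmentError, DataError, ParameterError


def axis_acf(field: np.ndarray, lag: int) -> float:
    """Brute-force empirical autocovariance at an integer voxel lag, averaged
    over the three axes (independent of the spectral synthesis route)."""
    vals = []
    for axis in range(3):
        a = np.moveaxis(field, axis, 0)
        vals.append(np.mean(a[:-lag] * a[lag:]))
    return float(np.mean(vals))


class TestNucleusSpec:
    def test_sphere_requires_radius(self):
        with pytest.raises(ParameterError):
            nm.NucleusSpec(shape="sphere", corr_length_um=0.5, fluct_std=0.01)

    def test_voxel_must_resolve_correlation_length(self):
        with pytest.raises(ParameterError, match="resolve"):
            nm.NucleusSpec(shape="sphere", radius_um=2.0, corr_length_um=0.3,
                           fluct_std=0.01, voxel_um=0.2)

    def test_index_ordering_enforced(self):
        with pytest.raises(ParameterError):
            nm.NucleusSpec(shape="sphere", radius_um=2.0, corr_length_um=0.5,
                           fluct_std=0.01, n_mean=1.36, n_cyto=1.40)

    def test_grid_must_contain_body(self):
        with pytest.raises(ContainmentError):
            nm.NucleusSpec(shape="sphere", radius_um=4.0, corr_length_um=0.5,
                           fluct_std=0.01, grid_shape=(41, 41, 41))

    def test_negative_fluct_std_rejected(self):
        with pytest.raises(ParameterError):
            nm.NucleusSpec(shape="sphere", radius_um=2.0, corr_length_um=0.5,
                           fluct_std=-0.01)


class TestMask:
    def test_sphere_voxel_count_matches_volume(self):
        # R = 4 um, voxel 0.1 um: (4/3) pi R^3 / voxel^3 = 268,082.6
        spec = nm.NucleusSpec(shape="sphere", radius_um=4.0, corr_length_um=0.5,
                              fluct_std=0.0, voxel_um=0.1)
        count = int(nm.make_nucleus_mask(spec).sum())
        expected = 4.0 / 3.0 * np.pi * 4.0**3 / 0.1**3
        assert abs(count - expected) / expected < 0.005

    def test_subvoxel_oracle_small_sphere(self):
        # independent oracle: count sub-voxel samples inside the ball
        spec = nm.NucleusSpec(shape="sphere", radius_um=1.0, corr_length_um=0.5,
                              fluct_std=0.0, voxel_um=0.1, padding_um=0.3)
        count = int(nm.make_nucleus_mask(spec).sum())
        fine = 0.02
        half = 1.3
        coords = np.arange(-half, half + fine / 2, fine)
        xx, yy, zz = np.meshgrid(coords, coords, coords, indexing="ij")
        fine_volume = np.sum(xx**2 + yy**2 + zz**2 <= 1.0) * fine**3
        assert abs(count * 0.1**3 - fine_volume) / fine_volume < 0.01

    def test_center_voxel_inside(self, small_sphere_spec):
        mask = nm.make_nucleus_mask(small_sphere_spec)
        center = tuple(n // 2 for n in mask.shape)
        assert mask[center]

    def test_ellipsoid_point_beyond_major_semiaxis_outside(self):
        spec = nm.NucleusSpec(shape="ellipsoid", semiaxes_um=(3.0, 4.0, 5.0),
                              corr_length_um=0.5, fluct_std=0.0, voxel_um=0.1)
        mask = nm.make_nucleus_mask(spec)
        x, y, z = spec.axis_coordinates()
        iz = int(np.argmin(np.abs(z - 5.1)))  # first voxel center beyond 5.05
        assert abs(z[iz] - 5.1) < 1e-9
        assert not mask[len(x) // 2, len(y) // 2, iz]
        iz_in = int(np.argmin(np.abs(z - 4.9)))
        assert mask[len(x) // 2, len(y) // 2, iz_in]

    def test_sphere_mask_symmetric_under_signed_permutations(self):
        spec = nm.NucleusSpec(shape="sphere", radius_um=1.0, corr_length_um=0.5,
                              fluct_std=0.0, voxel_um=0.2, grid_shape=(13, 13, 13))
        mask = nm.make_nucleus_mask(spec)
        flips = [(slice(None), slice(None, None, -1))] * 3
        for perm in itertools.permutations(range(3)):
            permuted = np.transpose(mask, perm)
            for signs in itertools.product([1, -1], repeat=3):
                sl = tuple(slice(None, None, s) for s in signs)
                assert np.array_equal(permuted[sl], mask)


class TestFluctuations:
    def test_zero_std_gives_zero_field(self, small_sphere_spec):
        spec = nm.NucleusSpec(shape="sphere", radius_um=1.5, corr_length_um=0.5,
                              fluct_std=0.0, voxel_um=0.14, seed=3)
        field = nm.sample_correlated_fluctuations(spec)
        assert np.all(field == 0.0)

    def test_deterministic_given_seed(self, small_sphere_spec):
        f1 = nm.sample_correlated_fluctuations(small_sphere_spec)
        f2 = nm.sample_correlated_fluctuations(small_sphere_spec)
        assert np.array_equal(f1, f2)

    def test_different_seeds_differ(self, small_sphere_spec):
        other = nm.NucleusSpec(
            shape="sphere", radius_um=1.5, corr_length_um=0.5, fluct_std=0.02,
            voxel_um=0.14, padding_um=0.7, seed=8,
        )
        assert not np.array_equal(
            nm.sample_correlated_fluctuations(small_sphere_spec),
            nm.sample_correlated_fluctuations(other),
        )

    @pytest.mark.parametrize("lag_frac,expected", [(0.5, 0.779), (1.0, 0.368),
                                                   (2.0, 0.018)])
    def test_empirical_acf_matches_gaussian_model(self, lag_frac, expected):
        # lc = 0.8 um, voxel 0.1 um -> lags at 4, 8, 16 voxels
        lc, dn, voxel = 0.8, 0.02, 0.1
        estimates = []
        for seed in range(10):
            spec = nm.NucleusSpec(shape="sphere", radius_um=2.0, corr_length_um=lc,
                                  fluct_std=dn, voxel_um=voxel, seed=seed,
                                  grid_shape=(72, 72, 72))
            field = nm.sample_correlated_fluctuations(spec)
            lag = int(round(lag_frac * lc / voxel))
            estimates.append(axis_acf(field, lag) / field.var())
        assert abs(np.mean(estimates) - expected) < 0.05

    def test_power_spectrum_slope(self):
        # log-power vs k^2 regression slope should be -lc^2/4 within 10%
        lc, voxel = 0.6, 0.1
        slopes = []
        for seed in range(10):
            spec = nm.NucleusSpec(shape="sphere", radius_um=2.0, corr_length_um=lc,
                                  fluct_std=0.02, voxel_um=voxel, seed=seed,
                                  grid_shape=(64, 64, 64))
            field = nm.sample_correlated_fluctuations(spec)
            power = np.abs(np.fft.fftn(field)) ** 2
            freqs = 2 * np.pi * np.fft.fftfreq(64, d=voxel)
            k2 = (freqs[:, None, None]**2 + freqs[None, :, None]**2
                  + freqs[None, None, :]**2)
            k2f, pf = k2.ravel(), power.ravel()
            sel = (k2f > 0) & (k2f < (4.0 / lc**2) * 4)  # keep well-populated band
            bins = np.linspace(0, k2f[sel].max(), 24)
            which = np.digitize(k2f[sel], bins)
            xs, ys = [], []
            for b in range(1, len(bins)):
                m = which == b
                if m.sum() > 20:
                    xs.append(k2f[sel][m].mean())
                    ys.append(np.log(pf[sel][m].mean()))
            slope = np.polyfit(xs, ys, 1)[0]
            slopes.append(slope)
        assert abs(np.mean(slopes) - (-lc**2 / 4)) < 0.1 * lc**2 / 4


class TestRIVolume:
    def test_two_valued_when_std_zero(self):
        spec = nm.NucleusSpec(shape="sphere", radius_um=1.5, corr_length_um=0.5,
                              fluct_std=0.0, voxel_um=0.14, seed=0)
        volume = nm.build_ri_volume(spec)
        assert set(np.unique(volume.values)) == {1.36, 1.40}

    def test_exact_masked_statistics(self, small_sphere_spec):
        volume = nm.build_ri_volume(small_sphere_spec)
        inside = volume.values[volume.mask]
        assert abs(inside.mean() - 1.40) < 1e-9
        assert abs(inside.std() - 0.02) < 1e-9

    def test_outside_equals_cytoplasm_exactly(self, small_sphere_spec):
        volume = nm.build_ri_volume(small_sphere_spec)
        assert np.all(volume.values[~volume.mask] == 1.36)

    def test_determinism_bit_identical(self, small_sphere_spec):
        v1 = nm.build_ri_volume(small_sphere_spec)
        v2 = nm.build_ri_volume(small_sphere_spec)
        assert np.array_equal(v1.values, v2.values)

    def test_all_values_above_one(self, small_sphere_spec):
        volume = nm.build_ri_volume(small_sphere_spec)
        assert np.all(volume.values > 1.0)


class TestEnumerate:
    def test_full_grid_count(self):
        specs = nm.enumerate_dataset(
            shapes=("sphere", "ellipsoid"),
            corr_lengths_um=[0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
            fluct_stds=[0.005, 0.010, 0.015, 0.020, 0.025, 0.030, 0.035],
            replicates=3,
        )
        assert len(specs) == 294

    def test_explicit_pair_list_matches_published_dataset_size(self):
        pairs = [(lc, dn) for lc in (0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
                 for dn in (0.005, 0.010, 0.015, 0.020, 0.025)][:33]
        specs = nm.enumerate_dataset(shapes=("sphere", "ellipsoid"), pairs=pairs,
                                     replicates=3)
        assert len(specs) == 198
        assert sum(s.shape == "sphere" for s in specs) == 99

    def test_single_combination(self):
        specs = nm.enumerate_dataset(shapes=("sphere",), pairs=[(0.5, 0.02)],
                                     replicates=1)
        assert len(specs) == 1

    def test_seeds_distinct_and_reproducible(self):
        kwargs = dict(shapes=("sphere",), corr_lengths_um=[0.4, 0.6],
                      fluct_stds=[0.01, 0.02], replicates=2, base_seed=5)
        specs1 = nm.enumerate_dataset(**kwargs)
        specs2 = nm.enumerate_dataset(**kwargs)
        seeds = [s.seed for s in specs1]
        assert len(set(seeds)) == len(seeds)
        assert seeds == [s.seed for s in specs2]

    def test_empty_grid_rejected(self):
        with pytest.raises(ParameterError):
            nm.enumerate_dataset(shapes=("sphere",), corr_lengths_um=[],
                                 fluct_stds=[0.01])


class TestDisorderStrength:
    def test_alpha_one(self):
        assert nm.disorder_strength(1.0, 0.01, 1) == pytest.approx(0.01)

    def test_alpha_two(self):
        assert nm.disorder_strength(0.5, 0.02, 2) == pytest.approx(2.0e-4)

    def test_zero_fluctuations(self):
        assert nm.disorder_strength(0.7, 0.0, 1) == 0.0
        assert nm.disorder_strength(0.7, 0.0, 2) == 0.0

    def test_invalid_alpha(self):
        with pytest.raises(ParameterError):
            nm.disorder_strength(0.5, 0.02, 3)


class TestPersistence:
    def test_hdf5_round_trip(self, tmp_path, small_sphere_spec):
        volume = nm.build_ri_volume(small_sphere_spec)
        path = tmp_path / nm.volume_filename(small_sphere_spec)
        nm.save_volume(volume, path)
        loaded = nm.load_volume(path)
        assert np.array_equal(loaded.values, volume.values)
        assert np.array_equal(loaded.mask, volume.mask)
        assert loaded.spec == small_sphere_spec

    def test_manifest(self, tmp_path):
        specs = nm.enumerate_dataset(shapes=("sphere",), pairs=[(0.5, 0.02)],
                                     replicates=2)
        df = nm.write_manifest(specs, ["a.h5", "b.h5"], tmp_path / "manifest.csv")
        assert len(df) == 2
        assert (tmp_path / "manifest.csv").exists()
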