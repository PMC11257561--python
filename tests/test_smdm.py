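import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from ifkit import smdm, synth
from ifkit.errors import InputError


def make_table(x0, y0, dx=0.0, dy=0.0):
    return pd.DataFrame(
        {"x0_um": np.atleast_1d(x0), "y0_um": np.atleast_1d(y0),
         "dx_um": np.full(np.size(x0), dx), "dy_um": np.full(np.size(x0), dy),
         "label": "free"}
    )


class TestBinLattice:
    def test_origin_record_in_first_bin(self):
        lat = smdm.BinLattice((0.0, 0.0), 0.4, 4, 4)
        row, col, ok = lat.bin_index(np.array([0.0]), np.array([0.0]))
        assert (row[0], col[0], ok[0]) == (0, 0, True)

    def test_boundary_goes_to_higher_bin(self):
        # half-open [lo, hi): a point exactly on the boundary belongs above
        lat = smdm.BinLattice((0.0, 0.0), 0.4, 4, 4)
        row, col, _ = lat.bin_index(np.array([0.4]), np.array([0.8]))
        assert (row[0], col[0]) == (2, 1)

    def test_invalid_lattice(self):
        with pytest.raises(InputError):
            smdm.BinLattice((0, 0), 0.0, 4, 4)
        with pytest.raises(InputError):
            smdm.BinLattice((0, 0), 0.4, 0, 4)


class TestBinDisplacements:
    def test_conservation(self):
        rng = np.random.default_rng(0)
        lat = smdm.BinLattice((0.0, 0.0), 0.4, 8, 8)
        table = make_table(rng.uniform(-1, 4, 100), rng.uniform(-1, 4, 100))
        bins, out = smdm.bin_displacements(table, lat)
        assert sum(v.size for v in bins.values()) + out == 100

    def test_empty_table(self):
        lat = smdm.BinLattice((0.0, 0.0), 0.4, 8, 8)
        bins, out = smdm.bin_displacements(make_table([], []), lat)
        assert bins == {} and out == 0

    def test_scale_budget(self, settings):
        """~1e5 records bin in well under a second."""
        import time

        rng = np.random.default_rng(1)
        n = 100_000
        table = make_table(rng.uniform(0, 12.8, n), rng.uniform(0, 12.8, n))
        lat = smdm.BinLattice((0.0, 0.0), 0.4, 32, 32)
        t0 = time.perf_counter()
        bins, out = smdm.bin_displacements(table, lat)
        assert time.perf_counter() - t0 < 1.0
        assert sum(v.size for v in bins.values()) + out == n


class TestFitDiffusivity:
    def test_closed_form_oracle(self, noiseless_settings):
        # four displacements of 0.1 um: D = sum(r^2) / (4 N dt) = 2.5
        r = np.full(4, 0.1)
        fit = smdm.fit_diffusivity(r, noiseless_settings, smdm.FitOptions(n_min=1))
        assert fit.D_hat == pytest.approx(2.5, abs=1e-12)
        assert fit.converged

    def test_all_zero_displacements(self, noiseless_settings):
        fit = smdm.fit_diffusivity(np.zeros(20), noiseless_settings, smdm.FitOptions(n_min=1))
        assert fit.D_hat == 0.0

    def test_numeric_matches_closed_form_over_seeds(self, noiseless_settings):
        """Dual route: bounded numeric MLE vs sum(r^2)/(4 N dt), 100 seeds."""
        opts = smdm.FitOptions(n_min=1)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            d_true = rng.uniform(0.5, 10.0)
            s = np.sqrt(2 * d_true * 1e-3)
            r = s * np.sqrt(rng.standard_normal(200) ** 2 + rng.standard_normal(200) ** 2)
            closed = float(np.sum(r**2) / (4 * r.size * 1e-3))
            fit_closed = smdm.fit_diffusivity(r, noiseless_settings, opts)
            fit_num = smdm.fit_diffusivity_numeric(r, noiseless_settings, opts,
                                                   fix_background=0.0)
            assert fit_closed.D_hat == pytest.approx(closed, rel=1e-12)
            assert fit_num.D_hat == pytest.approx(closed, rel=1e-9)

    @pytest.mark.parametrize("d_true", [1.5, 7.0])
    def test_parameter_recovery(self, d_true, settings):
        s2 = 2 * d_true * settings.dt + 2 * settings.sigma_loc**2
        rng = np.random.default_rng(42)
        r = np.sqrt(s2) * np.sqrt(rng.standard_normal(5000) ** 2
                                  + rng.standard_normal(5000) ** 2)
        fit = smdm.fit_diffusivity(r, settings)
        assert abs(fit.D_hat - d_true) / d_true < 0.05

    def test_monotone_in_msd(self, noiseless_settings):
        rng = np.random.default_rng(3)
        base = np.sort(rng.uniform(0.01, 0.3, 500))
        scales = np.linspace(0.5, 2.0, 20)
        fits = [smdm.fit_diffusivity(c * base, noiseless_settings).D_hat for c in scales]
        assert np.all(np.diff(fits) >= 0)

    def test_background_fit_recovers_mixture(self, settings):
        rng = np.random.default_rng(8)
        d_true, phi_true, n = 2.0, 0.2, 20_000
        s2 = 2 * d_true * settings.dt + 2 * settings.sigma_loc**2
        n_bg = rng.binomial(n, phi_true)
        fg = np.sqrt(s2) * np.sqrt(rng.standard_normal(n - n_bg) ** 2
                                   + rng.standard_normal(n - n_bg) ** 2)
        bg = settings.capture_radius * np.sqrt(rng.random(n_bg))
        r = np.concatenate([fg[fg <= settings.capture_radius], bg])
        fit = smdm.fit_diffusivity(r, settings, smdm.FitOptions(fit_background=True))
        assert fit.D_hat == pytest.approx(d_true, rel=0.1)
        assert fit.background_fraction == pytest.approx(phi_true, abs=0.05)

    def test_under_threshold_masked_not_raised(self, settings):
        fit = smdm.fit_diffusivity(np.array([0.1] * 5), settings, smdm.FitOptions(n_min=10))
        assert not fit.converged
        assert np.isnan(fit.D_hat)

    def test_nonfinite_rejected(self, settings):
        with pytest.raises(InputError):
            smdm.fit_diffusivity(np.array([0.1, np.nan]), settings)


class TestMapDiffusivity:
    def test_uniform_recovery(self, settings):
        field = synth.DiffusivityField(np.full((32, 32), 1.5),
                                       np.zeros((32, 32), bool), 0.0, bin_size=0.4)
        table, _ = synth.simulate_displacements(field, settings, 200_000)
        lat = smdm.BinLattice((0.0, 0.0), 0.4, 32, 32)
        dmap = smdm.map_diffusivity(table, lat, settings)
        assert dmap.median_D == pytest.approx(1.5, rel=0.10)

    def test_two_region_contrast(self, two_region_field, settings):
        table, _ = synth.simulate_displacements(two_region_field, settings, 150_000)
        lat = smdm.BinLattice((0.0, 0.0), 0.4, 32, 32)
        dmap = smdm.map_diffusivity(table, lat, settings)
        inside = np.nanmedian(dmap.D[:, :16])
        outside = np.nanmedian(dmap.D[:, 16:])
        assert inside < outside
        assert outside / inside > 2.0

    def test_empty_table_fully_masked(self, settings):
        lat = smdm.BinLattice((0.0, 0.0), 0.4, 8, 8)
        dmap = smdm.map_diffusivity(make_table([], []), lat, settings)
        assert dmap.mask.all()
        assert np.isnan(dmap.median_D)


class TestDisplacementHistogram:
    def _fit_and_hist(self, settings, d_true=2.5, n=5000, seed=0, n_bins=40):
        rng = np.random.default_rng(seed)
        s2 = 2 * d_true * settings.dt + 2 * settings.sigma_loc**2
        r = np.sqrt(s2) * np.sqrt(rng.standard_normal(n) ** 2 + rng.standard_normal(n) ** 2)
        r = r[r <= settings.capture_radius]
        fit = smdm.fit_diffusivity(r, settings)
        return r, fit, smdm.displacement_histogram(r, fit, settings, n_bins=n_bins)

    def test_curve_normalized(self, settings):
        _, fit, _ = self._fit_and_hist(settings)
        integral, _ = quad(lambda r: smdm.model_pdf(np.array([r]), fit, settings)[0],
                           0.0, settings.capture_radius)
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_counts_conserved(self, settings):
        r, _, hist = self._fit_and_hist(settings)
        assert hist["counts"].sum() == r.size

    def test_mode_at_s(self, settings):
        _, fit, _ = self._fit_and_hist(settings)
        s = np.sqrt(2 * fit.D_hat * settings.dt + 2 * settings.sigma_loc**2)
        grid = np.linspace(1e-4, settings.capture_radius, 20001)
        pdf = smdm.model_pdf(grid, fit, settings)
        assert grid[np.argmax(pdf)] == pytest.approx(s, rel=1e-3)

    def test_histogram_density_integral(self, settings):
        _, _, hist = self._fit_and_hist(settings)
        widths = np.diff(hist["bin_edges"])
        assert np.sum(hist["density"] * widths) == pytest.approx(1.0, rel=1e-9)

    def test_too_few_bins_rejected(self, settings):
        r, fit, _ = self._fit_and_hist(settings)
        with pytest.raises(InputError):
            smdm.displacement_histogram(r, fit, settings, n_bins=1)


def test_map_io_roundtrip(tmp_path, two_region_field, settings):
    table, _ = synth.simulate_displacements(two_region_field, settings, 30_000)
    lat = smdm.BinLattice((0.0, 0.0), 0.4, 32, 32)
    dmap = smdm.map_diffusivity(table, lat, settings)
    import tifffile

    p = tmp_path / "dmap.tif"
    smdm.save_map(dmap, p)
    loaded = tifffile.imread(p)
    np.testing.assert_allclose(loaded, dmap.D.astype(np.float32), equal_nan=True)
    frame = smdm.fits_to_frame(dmap)
    assert len(frame) == len(dmap.fits)
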