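import numpy as np
import pytest

from osteofabric.compactness import (
    DiscriminantCoefficients,
    binarize_midshaft,
    classify_lifestyle,
    compute_centres,
    fit_lifestyle_discriminant,
    fit_sigmoid,
    observed_compactness,
    radial_profile,
    sigmoid,
    CompactnessProfile,
)
from osteofabric.phantom import make_cross_section


def annulus(outer=80.0, inner=40.0, size=None, offset=(0, 0)):
    n = size or int(2 * outer) + 9
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r2o = (xx - c) ** 2 + (yy - c) ** 2
    r2i = (xx - c - offset[1]) ** 2 + (yy - c - offset[0]) ** 2
    return (r2o <= outer**2) & (r2i > inner**2)


class TestBinarize:
    def test_binary_input_idempotent(self):
        sec = annulus()
        np.testing.assert_array_equal(binarize_midshaft(sec), sec)

    def test_dust_speck_removed(self):
        sec = annulus().copy()
        sec[2:4, 2:4] = True
        out = binarize_midshaft(sec)
        assert not out[2:4, 2:4].any()
        assert out.sum() == annulus().sum()

    def test_bimodal_gray_fraction(self, rng):
        n = 120
        truth = annulus(50.0, 25.0, size=n)
        gray = np.where(truth, 200.0, 50.0) + rng.normal(0, 8, (n, n))
        out = binarize_midshaft(gray.astype(np.float32))
        assert abs(out.mean() - truth.mean()) / truth.mean() < 0.02

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            binarize_midshaft(np.zeros((10, 10), dtype=bool))


class TestCentres:
    def test_centred_annulus_all_centres_agree(self):
        sec = annulus()
        c = (sec.shape[0] - 1) / 2.0
        res = compute_centres(sec)
        for centre in (res.section_centre, res.medullary_centre, res.ontogenetic_centre):
            assert np.linalg.norm(centre - c) <= 1.5

    def test_offset_cavity_moves_medullary_centre(self):
        sec = annulus(offset=(10, 0))
        res = compute_centres(sec)
        shift = res.medullary_centre[0] - res.section_centre[0]
        assert shift > 5.0  # cavity centroid follows the offset

    def test_solid_disc_fallback(self):
        n = 61
        c = 30.0
        yy, xx = np.mgrid[0:n, 0:n]
        disc = (xx - c) ** 2 + (yy - c) ** 2 <= 25**2
        res = compute_centres(disc)
        np.testing.assert_allclose(res.medullary_centre, res.section_centre)


class TestRadialProfile:
    def test_solid_disc_fully_compact(self):
        n = 81
        yy, xx = np.mgrid[0:n, 0:n]
        disc = (xx - 40) ** 2 + (yy - 40) ** 2 <= 35**2
        prof = radial_profile(disc, (40.0, 40.0))
        vals = prof.compactness[np.isfinite(prof.compactness)]
        assert vals.mean() > 0.97

    def test_annulus_structure(self):
        sec = annulus(80.0, 40.0)
        c = (sec.shape[0] - 1) / 2.0
        prof = radial_profile(sec, (c, c))
        d = prof.radial_centres
        inner_cells = prof.compactness[:, d < 0.4]
        outer_cells = prof.compactness[:, d > 0.6]
        assert np.nanmean(inner_cells) < 0.05
        assert np.nanmean(outer_cells) > 0.9

    def test_pixel_conservation(self):
        sec = annulus()
        c = (sec.shape[0] - 1) / 2.0
        prof = radial_profile(sec, (c, c))
        from scipy import ndimage

        filled = ndimage.binary_fill_holes(sec)
        assert prof.pixel_counts.sum() == filled.sum()
        assert prof.bone_counts.sum() == sec.sum()

    def test_missing_wedge_undefined_sectors(self):
        sec = annulus().copy()
        n = sec.shape[0]
        c = (n - 1) / 2.0
        yy, xx = np.mgrid[0:n, 0:n]
        theta = np.mod(np.arctan2(xx - c, yy - c), 2 * np.pi)
        sec[(theta >= 0) & (theta < np.pi / 2)] = False  # 90 degree wedge gone
        prof = radial_profile(sec, (c, c), n_sectors=60)
        undefined = np.isnan(prof.compactness).all(axis=1).sum()
        assert 13 <= undefined <= 17  # ~15 of 60 sectors

    def test_centre_outside_rejected(self):
        sec = annulus()
        with pytest.raises(ValueError):
            radial_profile(sec, (1.0, 1.0))


class TestFitSigmoid:
    def _profile_from_params(self, mn, mx, p, s, noise=0.0, rng=None):
        d = np.linspace(0.01, 0.99, 51)
        comp = np.tile(sigmoid(d, mn, mx, p, s), (60, 1))
        if noise:
            comp += rng.normal(0, noise, comp.shape)
        comp = np.clip(comp, 0, 1)
        return CompactnessProfile(
            compactness=comp,
            pixel_counts=np.ones_like(comp),
            bone_counts=comp,
            centre=np.zeros(2),
        )

    def test_noise_free_recovery_within_one_percent(self):
        truth = (0.1, 0.95, 0.5, 0.05)
        prof = self._profile_from_params(*truth)
        fit = fit_sigmoid(prof, scope="global")
        for got, want in zip((fit.min_asymptote, fit.max_asymptote, fit.p, fit.s), truth):
            assert abs(got - want) <= 0.01 * max(want, 0.02)

    def test_noisy_recovery_within_ten_percent(self, rng):
        truth = (0.1, 0.95, 0.5, 0.05)
        prof = self._profile_from_params(*truth, noise=0.01, rng=rng)
        fit = fit_sigmoid(prof, scope="global")
        for got, want in zip((fit.min_asymptote, fit.max_asymptote, fit.p, fit.s), truth):
            assert abs(got - want) <= 0.1 * want + 0.005

    def test_flat_profile_degenerate_flag(self):
        prof = self._profile_from_params(1.0, 1.0, 0.5, 0.05)
        fit = fit_sigmoid(prof, scope="global")
        assert fit.degenerate
        assert fit.min_asymptote > 0.9

    def test_per_sector_summary(self, rng):
        prof = self._profile_from_params(0.2, 0.9, 0.6, 0.04, noise=0.005, rng=rng)
        fit = fit_sigmoid(prof, scope="per-sector")
        assert fit.per_sector["n_sectors_fit"] == 60
        assert fit.per_sector["mean"]["P"] == pytest.approx(0.6, abs=0.05)
        assert set(fit.per_sector) >= {"mean", "sd", "median"}

    def test_filled_cavity_gives_positive_rmin(self):
        section, analytic = make_cross_section(80.0, 20.0, fill=0.5, seed=2)
        centre = ((section.shape[0] - 1) / 2.0,) * 2
        fit = fit_sigmoid(radial_profile(section, centre), scope="global")
        assert fit.min_asymptote > 0.3

    def test_open_cavity_rmin_near_zero_and_p_matches_geometry(self):
        section, analytic = make_cross_section(80.0, 20.0, fill=0.0)
        centre = ((section.shape[0] - 1) / 2.0,) * 2
        fit = fit_sigmoid(radial_profile(section, centre), scope="global")
        assert fit.min_asymptote < 0.05
        assert abs(fit.p - analytic["endosteal_frac"]) < 0.05


class TestObservedCompactness:
    def test_solid_disc_is_one(self):
        n = 41
        yy, xx = np.mgrid[0:n, 0:n]
        disc = (xx - 20) ** 2 + (yy - 20) ** 2 <= 15**2
        assert observed_compactness(disc) == 1.0

    def test_annulus_three_quarters(self):
        sec = annulus(80.0, 40.0)
        assert observed_compactness(sec) == pytest.approx(0.75, abs=0.01)

    def test_checkerboard_half_fill(self):
        sec = annulus(80.0, 40.0).copy()
        n = sec.shape[0]
        c = (n - 1) / 2.0
        yy, xx = np.mgrid[0:n, 0:n]
        cavity = (xx - c) ** 2 + (yy - c) ** 2 <= 40.0**2
        checker = ((xx + yy) % 2).astype(bool)
        sec |= cavity & checker
        assert observed_compactness(sec) == pytest.approx(0.875, abs=0.01)

    def test_rotation_invariant(self):
        sec = annulus(60.0, 25.0, offset=(8, 3))
        assert observed_compactness(np.rot90(sec)) == observed_compactness(sec)


class TestLifestyleCall:
    @pytest.fixture(scope="class")
    def refit_coefficients(self):
        rmins, labels = [], []
        for seed in range(6):
            filled, _ = make_cross_section(60.0, 15.0, fill=0.45, seed=seed)
            open_, _ = make_cross_section(60.0, 15.0, fill=0.0)
            for section, label in ((filled, "aquatic"), (open_, "terrestrial")):
                centre = ((section.shape[0] - 1) / 2.0,) * 2
                fit = fit_sigmoid(radial_profile(section, centre), scope="global")
                rmins.append(fit.min_asymptote)
                labels.append(label)
        return fit_lifestyle_discriminant(np.array(rmins), labels)

    def test_refit_separates_morphologies(self, refit_coefficients):
        low = classify_lifestyle({"Rmin": 0.0}, refit_coefficients)
        high = classify_lifestyle({"Rmin": 0.9}, refit_coefficients)
        assert low.call == "terrestrial"
        assert high.call == "aquatic"

    def test_boundary_score_is_aquatic(self):
        coeffs = DiscriminantCoefficients(intercept=-0.5, coefficients={"Rmin": 1.0})
        call = classify_lifestyle({"Rmin": 0.5}, coeffs)
        assert call.score == pytest.approx(0.0)
        assert call.call == "aquatic"

    def test_missing_variable_rejected(self):
        coeffs = DiscriminantCoefficients(intercept=0.0, coefficients={"Cg": 1.0})
        with pytest.raises(ValueError):
            classify_lifestyle({"Rmin": 0.5}, coeffs)
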