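"""The synthetic dose-field and film-scan forward model."""

import numpy as np
import pytest

from filmdose import (DomainError, DoseMap, FilmRenderSpec, GeometryError,
                      RangeError, SourceModel, drift_per_scan,
                      drift_scan_series, extract_red, line_source_dose_field,
                      make_qa_film_set, mean_od, nod_map, reconstruct_dose,
                      render_film, to_dose)


def point_like_source(**kwargs):
    """Two coincident short pellets approximating a point at the origin."""
    defaults = dict(strength_gy_cm2_per_s=0.5, pellet_centers_mm=(0.0, 0.0),
                    pellet_length_mm=1e-9, mu_eff_per_cm=0.0,
                    exposure_time_s=1.0)
    defaults.update(kwargs)
    return SourceModel(**defaults)


class TestLineSourceField:
    def test_inverse_square_point_kernel(self):
        # S*t = 1 Gy cm^2 concentrated at the origin; pixel centers land
        # exactly on 10 mm and 20 mm lateral distance
        src = point_like_source(strength_gy_cm2_per_s=1.0)
        field = line_source_dose_field(src, ((-0.5, 0.5), (4.5, 24.5)), 1.0)
        rows, cols = field.axes_mm()
        assert rows == pytest.approx([0.0])
        d1 = field.values[0, cols == 10.0][0]
        d2 = field.values[0, cols == 20.0][0]
        assert d1 == pytest.approx(1.0, rel=1e-9)
        assert d2 == pytest.approx(0.25, rel=1e-9)

    def test_attenuated_ratio(self):
        src = point_like_source(mu_eff_per_cm=0.06)
        field = line_source_dose_field(src, ((-0.5, 0.5), (4.5, 24.5)), 1.0)
        _, cols = field.axes_mm()
        d1 = field.values[0, cols == 10.0][0]
        d2 = field.values[0, cols == 20.0][0]
        assert d2 / d1 == pytest.approx(0.25 * np.exp(-0.06), rel=1e-9)

    def test_axial_reflection_symmetry(self, line_source):
        field = line_source_dose_field(line_source,
                                       ((-30.0, 30.0), (12.0, 40.0)), 0.5)
        np.testing.assert_allclose(field.values, field.values[::-1, :],
                                   rtol=1e-12)

    def test_monotone_decay_with_lateral_distance(self, phantom_field):
        diffs = np.diff(phantom_field.values, axis=1)
        assert np.all(diffs < 0)

    def test_grid_touching_source_rejected(self, line_source):
        # lateral pixel centers reach 0.2 mm from the source axis
        with pytest.raises(GeometryError):
            line_source_dose_field(line_source,
                                   ((-10.0, 10.0), (-0.95, 10.05)), 0.5)

    def test_calibrated_strength_hits_prescription(self, line_source):
        # single pixel centered exactly on the 2 cm / 2 cm prescription point
        field = line_source_dose_field(
            line_source, ((19.75, 20.25), (19.75, 20.25)), 0.5)
        assert field.values[0, 0] == pytest.approx(5.0, rel=1e-9)

    def test_coarse_pellet_discretization_rejected(self, line_source):
        with pytest.raises(DomainError):
            line_source_dose_field(line_source, ((-30, 30), (12, 40)), 0.5,
                                   n_elements=5)


class TestRenderFilm:
    def test_zero_dose_matches_background(self):
        spec = FilmRenderSpec(seed=2)
        zero = DoseMap(values=np.zeros((40, 30)), pixel_spacing_mm=0.254)
        rendered = render_film(zero, spec)
        np.testing.assert_array_equal(rendered.exposed[0].pixels,
                                      rendered.background[0].pixels)

    def test_uniform_dose_round_trip(self, ebt_model):
        spec = FilmRenderSpec(quantize=False)
        dose = DoseMap(values=np.full((30, 20), 5.0), pixel_spacing_mm=0.254)
        rendered = render_film(dose, spec)
        bg, exp = rendered.averaged_pair()
        nod = nod_map(exp, bg)
        assert np.allclose(nod.values, nod.values.flat[0])
        recovered = to_dose(nod, ebt_model)
        np.testing.assert_allclose(recovered.values, 5.0, rtol=1e-6)

    def test_fixed_seed_reproducible(self, phantom_field):
        spec = FilmRenderSpec(pixel_noise_sigma=80.0, seed=123)
        a = render_film(phantom_field, spec, n_scans=2)
        b = render_film(phantom_field, spec, n_scans=2)
        for x, y in zip(a.background + a.exposed, b.background + b.exposed):
            np.testing.assert_array_equal(x.pixels, y.pixels)

    def test_dose_above_range_rejected(self, ebt_model):
        too_hot = DoseMap(values=np.full((5, 5), 100.0), pixel_spacing_mm=0.5)
        with pytest.raises(RangeError):
            render_film(too_hot, FilmRenderSpec())

    def test_red_channel_carries_signal(self):
        spec = FilmRenderSpec(seed=0)
        dose = DoseMap(values=np.full((20, 20), 5.0), pixel_spacing_mm=0.5)
        rendered = render_film(dose, spec)
        img = rendered.exposed[0]
        # green/blue respond weakly: higher transmission than red
        assert img.pixels[:, :, 1].mean() > img.pixels[:, :, 0].mean()

    def test_end_to_end_identity_zero_noise(self, phantom_field, ebt_model):
        spec = FilmRenderSpec(quantize=False)
        rendered = render_film(phantom_field, spec, n_scans=3)
        recovered = reconstruct_dose(rendered.background, rendered.exposed,
                                     ebt_model)
        rel = np.abs(recovered.values - phantom_field.values) \
            / phantom_field.values
        assert rel.max() < 1e-6

    def test_end_to_end_identity_quantized(self, phantom_field, ebt_model):
        # 16-bit quantization limits the round trip to ~2e-4 relative
        spec = FilmRenderSpec(quantize=True)
        rendered = render_film(phantom_field, spec, n_scans=3)
        recovered = reconstruct_dose(rendered.background, rendered.exposed,
                                     ebt_model)
        rel = np.abs(recovered.values - phantom_field.values) \
            / phantom_field.values
        assert rel.max() < 5e-4


class TestQAFilmSet:
    def test_zero_injection_statistics_near_zero(self, ebt_model):
        films = make_qa_film_set(2, FilmRenderSpec(seed=4),
                                 film_size_cm=(6.0, 4.0),
                                 roi_size_cm=(4.0, 3.0), n_scans=1)
        for f in films:
            assert f.true_cv_percent < 1e-6
            assert f.true_delta_od_longitudinal_percent < 1e-6
            assert f.true_delta_od_transverse_percent < 1e-6

    def test_gain_profile_truth_matches_injection(self, ebt_model):
        films = make_qa_film_set(1, FilmRenderSpec(seed=6),
                                 injected_longitudinal_pp=0.0285,
                                 injected_transverse_pp=0.0497,
                                 film_size_cm=(8.0, 6.0),
                                 roi_size_cm=(6.0, 4.0), n_scans=1)
        f = films[0]
        assert f.true_delta_od_longitudinal_percent == \
            pytest.approx(2.85, abs=0.05)
        assert f.true_delta_od_transverse_percent == \
            pytest.approx(4.97, abs=0.05)

    def test_cv_truth_matches_injection(self):
        films = make_qa_film_set(1, FilmRenderSpec(seed=8), injected_cv=0.03,
                                 film_size_cm=(8.0, 6.0),
                                 roi_size_cm=(6.0, 4.0), n_scans=1)
        assert films[0].true_cv_percent == pytest.approx(3.0, abs=0.05)

    def test_zero_films_rejected(self):
        with pytest.raises(DomainError):
            make_qa_film_set(0)


class TestDriftSeries:
    def test_injected_drift_recovered_with_convention_factor(self):
        delta = 0.0002
        spec = FilmRenderSpec(per_scan_delta_od=delta, seed=3)
        series = drift_scan_series(spec, n_scans=15, film_size_cm=(5.0, 4.0))
        ods = [mean_od(extract_red(s)) for s in series]
        report = drift_per_scan(ods)
        assert report.per_scan_delta_od == \
            pytest.approx(delta * 14 / 15, rel=0.02)

    def test_no_drift_flat_series(self):
        spec = FilmRenderSpec(seed=3)
        series = drift_scan_series(spec, n_scans=5, film_size_cm=(5.0, 4.0))
        ods = [mean_od(extract_red(s)) for s in series]
        assert drift_per_scan(ods).total_delta_od == pytest.approx(0.0,
                                                                   abs=1e-6)
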