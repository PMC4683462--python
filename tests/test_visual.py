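import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from avigamut.spectra import GRID, ReflectanceSpectrum, SpectrumSet
from avigamut.visual import (TETRA_VOLUME, DegenerateSpectrumError,
                             aggregate_species_sex, build_sensitivity_set,
                             cone_template, model_set, quantum_catches,
                             relative_catches, tetra_coords, tetra_vertices)


class TestConeTemplate:
    @pytest.mark.parametrize("lmax", [372.0, 419.0, 500.0, 609.0])
    def test_unit_peak_at_nearest_grid_point(self, lmax):
        curve = cone_template(lmax)
        assert curve.min() >= 0
        assert curve.max() == pytest.approx(1.0)
        assert GRID[np.argmax(curve)] == pytest.approx(lmax, abs=2.5)

    def test_uv_cone_sees_more_uv_than_violet_cone(self):
        at340 = GRID.tolist().index(340)
        assert cone_template(372)[at340] > cone_template(419)[at340]

    def test_lambda_max_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            cone_template(250.0)


class TestSensitivitySet:
    def test_build_is_deterministic(self):
        a, b = build_sensitivity_set("U"), build_sensitivity_set("U")
        np.testing.assert_array_equal(a.curves, b.curves)

    def test_csv_round_trip_is_exact(self, tmp_path, sens_u):
        sens_u.to_csv(tmp_path / "sens.csv")
        back = build_sensitivity_set(path=tmp_path / "sens.csv")
        np.testing.assert_array_equal(back.curves, sens_u.curves)

    def test_v_type_short_cone_peaks_longer_than_u_type(self, sens_u, sens_v):
        peak = lambda c: GRID[np.argmax(c)]
        assert peak(sens_v.curves[0]) > peak(sens_u.curves[0])

    def test_missing_cone_column_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text("wavelength_nm,u,s,m\n300,1,1,1\n")
        with pytest.raises(ValueError, match="missing"):
            build_sensitivity_set(path=tmp_path / "bad.csv")


def spectrum_of(values, **meta):
    return ReflectanceSpectrum(GRID.copy(), np.asarray(values, float), **meta)


class TestQuantumCatches:
    def test_black_gives_zero_catches(self, sens_u):
        q = quantum_catches(spectrum_of(np.zeros(81)), sens_u)
        np.testing.assert_array_equal(q, 0.0)

    def test_perfect_reflector_is_achromatic(self, sens_u):
        # a 100% flat reflector catches exactly the white-standard catch in
        # every cone, hence maps to the achromatic origin
        q = quantum_catches(spectrum_of(np.full(81, 100.0)), sens_u)
        np.testing.assert_allclose(q, 1.0)
        np.testing.assert_allclose(tetra_coords(relative_catches(q)),
                                   np.zeros(3), atol=1e-12)

    def test_linearity_in_reflectance(self, sens_u):
        rng = np.random.default_rng(0)
        r = rng.uniform(0, 50, 81)
        q1 = quantum_catches(spectrum_of(r), sens_u)
        q2 = quantum_catches(spectrum_of(2 * r), sens_u)
        np.testing.assert_allclose(q2, 2 * q1)

    def test_flat_irradiance_is_the_default(self, sens_u):
        r = np.linspace(0, 80, 81)
        q_default = quantum_catches(spectrum_of(r), sens_u)
        q_flat = quantum_catches(spectrum_of(r), sens_u,
                                 irradiance=np.ones(81))
        np.testing.assert_allclose(q_default, q_flat, rtol=1e-12)


class TestRelativeCatches:
    @pytest.mark.parametrize("q,f", [
        ((1, 1, 1, 1), (0.25, 0.25, 0.25, 0.25)),
        ((2, 0, 0, 0), (1, 0, 0, 0)),
        ((1, 2, 3, 4), (0.1, 0.2, 0.3, 0.4)),
    ])
    def test_normalisation(self, q, f):
        np.testing.assert_allclose(relative_catches(np.array(q)), f)

    def test_all_zero_catch_is_an_error(self):
        with pytest.raises(DegenerateSpectrumError):
            relative_catches(np.zeros(4))


class TestTetraCoords:
    def test_achromatic_point_maps_to_origin(self):
        np.testing.assert_allclose(tetra_coords(np.full(4, 0.25)),
                                   np.zeros(3), atol=1e-15)

    def test_l_vertex_is_the_apex(self):
        np.testing.assert_allclose(tetra_coords([0, 0, 0, 1]),
                                   [0, 0, 0.75], atol=1e-15)

    def test_u_vertex_placement_and_circumradius(self):
        v = tetra_coords([1, 0, 0, 0])
        np.testing.assert_allclose(
            v, [np.sqrt(3 / 8), -1 / (2 * np.sqrt(2)), -0.25])
        assert np.linalg.norm(v) == pytest.approx(0.75)

    def test_vertices_pairwise_equidistant(self):
        v = tetra_vertices()
        dists = [np.linalg.norm(v[i] - v[j])
                 for i, j in itertools.combinations(range(4), 2)]
        np.testing.assert_allclose(dists, np.sqrt(1.5))

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=4,
                    max_size=4),
           st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=4,
                    max_size=4),
           st.floats(min_value=0, max_value=1))
    def test_map_is_affine_and_bounded(self, qa, qb, alpha):
        fa = np.array(qa) / np.sum(qa)
        fb = np.array(qb) / np.sum(qb)
        mix = tetra_coords(alpha * fa + (1 - alpha) * fb)
        np.testing.assert_allclose(
            mix, alpha * tetra_coords(fa) + (1 - alpha) * tetra_coords(fb),
            atol=1e-12)
        assert np.linalg.norm(mix) <= 0.75 + 1e-9

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            tetra_coords([0.5, 0.5, 0.5, 0.5])


class TestModelSetAndAggregation:
    def test_model_set_matches_scalar_pipeline(self, sens_u, default_avifauna):
        sset, _ = default_avifauna
        sub = SpectrumSet(sset.spectra[:20])
        df = model_set(sub, sens_u)
        for i, s in enumerate(sub):
            f = relative_catches(quantum_catches(s, sens_u))
            np.testing.assert_allclose(df[["x", "y", "z"]].iloc[i],
                                       tetra_coords(f), atol=1e-12)

    def test_all_points_inside_distance_bound(self, default_points):
        d = np.linalg.norm(default_points[["x", "y", "z"]], axis=1)
        assert d.max() <= 0.75 + 1e-9

    def test_aggregate_identity_for_single_specimens(self, sens_u):
        s = ReflectanceSpectrum(GRID.copy(), np.linspace(5, 60, 81),
                                species="a", order="O", sex="male",
                                specimen_id="1", patch="p")
        df = model_set(SpectrumSet([s]), sens_u)
        agg = aggregate_species_sex(df)
        np.testing.assert_allclose(agg[["x", "y", "z"]], df[["x", "y", "z"]])

    def test_aggregate_averages_specimens_to_midpoint(self, sens_u):
        import pandas as pd
        df = pd.DataFrame({
            "species": ["a", "a"], "order": ["O", "O"], "sex": ["male"] * 2,
            "specimen_id": ["1", "2"], "patch": ["p"] * 2,
            "x": [0.0, 0.0], "y": [0.0, 0.0], "z": [0.2, 0.4],
        })
        agg = aggregate_species_sex(df)
        assert len(agg) == 1
        assert agg["z"].iloc[0] == pytest.approx(0.3)

    def test_hull_of_simplex_image_is_tetra_volume(self):
        from avigamut.gamut import hull_volume
        assert hull_volume(tetra_vertices()).volume == pytest.approx(
            TETRA_VOLUME)
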