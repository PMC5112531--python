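"""Synthetic longitudinal surfaces, perturbation fields, parcel fixture."""

import numpy as np
import pytest

from gyrogen.mechanics import build_bilayer_mesh
from gyrogen.metrics import fit_growth_rates
from gyrogen.synthetic import (SynthGrowthParams, make_perturbation,
                               make_surface_series, table1_fixture)

SMALL = dict(grid_n=24, sheet_size=200.0)


def test_series_structure_and_topology():
    s = make_surface_series(SynthGrowthParams(seed=3, **SMALL))
    assert s.timepoints == list(range(25, 32))
    assert len(s.white) == len(s.pial) == 7
    faces0 = s.white[0].faces
    for surf in s.white + s.pial:
        assert surf.n_vertices == s.white[0].n_vertices
        np.testing.assert_array_equal(surf.faces, faces0)


def test_pial_outside_white_with_positive_thickness():
    s = make_surface_series(SynthGrowthParams(seed=3, **SMALL))
    for w, p in zip(s.white, s.pial):
        gap = np.linalg.norm(p.vertices - w.vertices, axis=1)
        assert (gap > 0).all()


def test_outward_offset_increases_area():
    # at the default vertex density the pial sheet is strictly larger
    s = make_surface_series(SynthGrowthParams(seed=3))
    for w, p in zip(s.white, s.pial):
        assert p.area() > w.area()


def test_ridge_thickness_exact_when_noise_free():
    p = SynthGrowthParams(noise_sd=0.0, seed=0, **SMALL)
    s = make_surface_series(p)
    ridge = s.white[0].scalars["gyral_label"] > 0
    t31 = s.white[-1].scalars["thickness"]
    np.testing.assert_allclose(t31[ridge], p.baseline_thickness + 0.35 * 6,
                               rtol=0, atol=1e-12)
    valley = ~ridge
    np.testing.assert_allclose(t31[valley], p.baseline_thickness + 0.10 * 6,
                               rtol=0, atol=1e-12)


def test_zero_growth_zero_noise_gives_identical_maps():
    p = SynthGrowthParams(gyral_slope=0.0, sulcal_slope=0.0, noise_sd=0.0,
                          seed=0, **SMALL)
    s = make_surface_series(p)
    t0 = s.white[0].scalars["thickness"]
    for w in s.white[1:]:
        np.testing.assert_array_equal(w.scalars["thickness"], t0)


def test_determinism_given_seed():
    a = make_surface_series(SynthGrowthParams(seed=11, **SMALL))
    b = make_surface_series(SynthGrowthParams(seed=11, **SMALL))
    for sa, sb in zip(a.white + a.pial, b.white + b.pial):
        np.testing.assert_array_equal(sa.vertices, sb.vertices)
    c = make_surface_series(SynthGrowthParams(seed=12, **SMALL))
    assert not np.array_equal(a.pial[0].vertices, c.pial[0].vertices)


def test_noise_free_series_regresses_to_exact_slopes():
    p = SynthGrowthParams(noise_sd=0.0, seed=0, **SMALL)
    s = make_surface_series(p)
    t = np.stack([w.scalars["thickness"] for w in s.white])
    slope, _, r2 = fit_growth_rates(t, s.timepoints)
    lab = s.white[0].scalars["gyral_label"]
    np.testing.assert_allclose(slope, np.where(lab > 0, 0.35, 0.10), atol=1e-12)
    np.testing.assert_allclose(r2, 1.0, atol=1e-12)


def test_degenerate_offset_raises_with_geometry_in_message():
    p = SynthGrowthParams(fold_amplitude=5.0, fold_wavelength=12.0,
                          baseline_thickness=3.0, seed=0, **SMALL)
    with pytest.raises(ValueError, match="fold_amplitude"):
        make_surface_series(p)


def test_parameter_validation():
    with pytest.raises(ValueError):
        SynthGrowthParams(noise_sd=-0.1)
    with pytest.raises(ValueError):
        SynthGrowthParams(baseline_thickness=0.0)


class TestPerturbation:
    def setup_method(self):
        self.mesh = build_bilayer_mesh(length=40, depth=10, cortex_thickness=2)

    def test_contract_bounded_and_demeaned(self):
        f = make_perturbation(self.mesh, amplitude=0.05, seed=1)
        assert np.abs(f.displacements).max() <= 0.05 + 1e-15
        assert abs(f.displacements.mean()) < 1e-12
        assert len(f.node_ids) == len(self.mesh.top_surface_nodes())

    def test_seed_determinism_and_variation(self):
        a = make_perturbation(self.mesh, 0.05, seed=1)
        b = make_perturbation(self.mesh, 0.05, seed=1)
        c = make_perturbation(self.mesh, 0.05, seed=2)
        np.testing.assert_array_equal(a.displacements, b.displacements)
        assert not np.array_equal(a.displacements, c.displacements)

    def test_large_amplitude_warns(self):
        with pytest.warns(UserWarning, match="10%"):
            make_perturbation(self.mesh, 0.5, seed=1)

    def test_invalid_amplitude(self):
        with pytest.raises(ValueError):
            make_perturbation(self.mesh, 0.0, seed=1)


class TestTable1Fixture:
    def test_row_counts_and_values(self):
        t = table1_fixture()
        assert (t["class"] == "gyral").sum() == 30
        assert (t["class"] == "sulcal").sum() == 31
        assert float(t.loc[t.parcel == "G_insular_short", "thickness_mm"].iloc[0]) == 3.73
        assert float(t.loc[t.parcel == "S_pericallosal", "thickness_mm"].iloc[0]) == 1.83

    def test_column_means(self):
        t = table1_fixture()
        su = t.loc[t["class"] == "sulcal", "thickness_mm"]
        gy = t.loc[t["class"] == "gyral", "thickness_mm"]
        assert round(su.mean(), 2) == 2.59
        assert round(gy.mean(), 2) == 2.92
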