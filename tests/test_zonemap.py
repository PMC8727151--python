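"""Thickness maps over synthetic double-cone fields, growth maps and
near-root summaries."""

import numpy as np
import pytest

import rootshear as rs


@pytest.fixture(scope="module")
def noiseless_map():
    cfg = rs.FieldGenConfig(
        extent_mm=40.0, pitch_mm=1.0, z_max_mm=20.0, noise_sigma_mm=0.0,
        schedule_mm=(2.0, 5.0, 8.0, 11.0, 14.0, 17.0, 20.0),
    )
    field = rs.generate_field(cfg, 7)
    zmap = rs.thickness_map(field, rs.FitSettings(noise_sigma_mm=0.0))
    return cfg, zmap


class TestThicknessMap:
    def test_exact_recovery_of_generator_thickness(self, noiseless_map):
        cfg, zmap = noiseless_map
        true = rs.zone_thickness(cfg, *np.meshgrid(zmap.x_mm, zmap.y_mm, indexing="ij"))
        assert zmap.n_ok == zmap.ok.size
        np.testing.assert_allclose(zmap.thickness_mm, true, atol=1e-6)

    def test_double_cone_shape(self, noiseless_map):
        """Thickest at the tube axis, thinnest at the window periphery."""
        _, zmap = noiseless_map
        ci = np.argmin(np.abs(zmap.x_mm))
        cj = np.argmin(np.abs(zmap.y_mm))
        assert zmap.thickness_mm[ci, cj] == np.nanmax(zmap.thickness_mm)
        corner = zmap.thickness_mm[0, 0]
        assert corner == pytest.approx(np.nanmin(zmap.thickness_mm), abs=1e-9)

    def test_root_bump_creates_local_maximum(self):
        cfg = rs.FieldGenConfig(
            extent_mm=40.0, pitch_mm=1.0, z_max_mm=14.0, noise_sigma_mm=0.0,
            bumps=(rs.Bump(10.0, -5.0, 6.0, 4.0),),
            schedule_mm=(3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 20.0),
        )
        zmap = rs.thickness_map(rs.generate_field(cfg, 7), rs.FitSettings(noise_sigma_mm=0.0))
        i = int(np.argmin(np.abs(zmap.x_mm - 10.0)))
        j = int(np.argmin(np.abs(zmap.y_mm + 5.0)))
        patch = zmap.thickness_mm[i - 3 : i + 4, j - 3 : j + 4]
        ring = patch.copy()
        ring[2:5, 2:5] = np.nan
        assert zmap.thickness_mm[i, j] > np.nanmax(ring) - 1e-9

    def test_rigid_translation_yields_no_band(self, small_field_cfg):
        field = rs.generate_field(small_field_cfg, 7)
        field.u_mm[..., 0] = 4.0  # both halves moved together
        zmap = rs.thickness_map(field, rs.FitSettings(noise_sigma_mm=0.0))
        assert zmap.n_ok == 0

    def test_symmetric_field_gives_symmetric_map(self):
        cfg = rs.FieldGenConfig(
            extent_mm=30.0, pitch_mm=1.0, z_max_mm=16.0, noise_sigma_mm=0.0,
            bumps=(rs.Bump(8.0, 4.0, 5.0, 4.0), rs.Bump(-8.0, -4.0, 5.0, 4.0)),
            schedule_mm=(3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 20.0),
        )
        zmap = rs.thickness_map(rs.generate_field(cfg, 7), rs.FitSettings(noise_sigma_mm=0.0))
        t = zmap.thickness_mm
        np.testing.assert_allclose(t, t[::-1, ::-1], atol=1e-6)

    def test_single_bad_column_does_not_abort_map(self, small_field_cfg):
        field = rs.generate_field(small_field_cfg, 7)
        field.mask[3, 3, :] = False
        zmap = rs.thickness_map(field, rs.FitSettings(noise_sigma_mm=0.0))
        assert not zmap.ok[3, 3]
        assert zmap.n_ok == zmap.ok.size - 1

    def test_deterministic(self, small_field_cfg):
        field = rs.generate_field(small_field_cfg, 7)
        a = rs.thickness_map(field, rs.FitSettings(noise_sigma_mm=0.0))
        b = rs.thickness_map(field, rs.FitSettings(noise_sigma_mm=0.0))
        np.testing.assert_array_equal(a.thickness_mm, b.thickness_mm)
        np.testing.assert_array_equal(a.ok, b.ok)


class TestGrowthMap:
    def _map(self, z_min, z_max):
        cfg = rs.FieldGenConfig(
            extent_mm=24.0, pitch_mm=1.0, z_min_mm=z_min, z_max_mm=z_max,
            noise_sigma_mm=0.0, schedule_mm=(3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 20.0),
        )
        return rs.thickness_map(rs.generate_field(cfg, 7), rs.FitSettings(noise_sigma_mm=0.0))

    def test_map_minus_itself_is_zero(self):
        a = self._map(2.0, 12.8)
        diff = rs.growth_map(a, a)
        np.testing.assert_allclose(diff.thickness_mm[diff.ok], 0.0, atol=1e-12)

    def test_growing_zone_quarter_increase(self):
        """Scaling the whole thickness field by 1.25 (80% -> 100% of peak)
        shows up as a +0.25 * thickness_a difference at every column."""
        a = self._map(2.0, 12.8)
        b = self._map(2.5, 16.0)
        diff = rs.growth_map(a, b)
        ratio = diff.thickness_mm[diff.ok] / a.thickness_mm[diff.ok]
        np.testing.assert_allclose(ratio, 0.25, atol=1e-6)

    def test_shrinking_zone_is_negative(self):
        a = self._map(2.5, 16.0)
        b = self._map(2.0, 12.8)
        diff = rs.growth_map(a, b)
        assert np.all(diff.thickness_mm[diff.ok] < 0)

    def test_grid_mismatch_rejected(self):
        a = self._map(2.0, 12.8)
        cfg = rs.FieldGenConfig(
            extent_mm=20.0, pitch_mm=1.0, z_max_mm=12.0, noise_sigma_mm=0.0,
            schedule_mm=(3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 20.0),
        )
        b = rs.thickness_map(rs.generate_field(cfg, 7), rs.FitSettings(noise_sigma_mm=0.0))
        with pytest.raises(ValueError, match="grids"):
            rs.growth_map(a, b)


@pytest.fixture(scope="module")
def bumped():
    cfg = rs.FieldGenConfig(
        extent_mm=40.0, pitch_mm=1.0, z_max_mm=14.0, noise_sigma_mm=0.0,
        bumps=(rs.Bump(10.0, -5.0, 6.0, 4.0),),
        schedule_mm=(3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 20.0),
    )
    zmap = rs.thickness_map(rs.generate_field(cfg, 7), rs.FitSettings(noise_sigma_mm=0.0))
    root = rs.Root(10.0, -5.0, 1.5, 200.0, "big")
    return zmap, root


class TestSummarizeMap:

    def test_at_root_mean_exceeds_far_field(self, bumped):
        zmap, root = bumped
        table = rs.summarize_map(zmap, [root], radius_mm=4.0)
        at_root = table.loc[table.region == "root", "mean_thickness_mm"].iloc[0]
        far = table.loc[table.region == "far_field", "mean_thickness_mm"].iloc[0]
        assert at_root > far

    def test_no_roots_gives_global_stats_only(self, bumped):
        zmap, _ = bumped
        table = rs.summarize_map(zmap, [], radius_mm=4.0)
        assert set(table.region) == {"far_field", "global"}
        assert np.isfinite(table.loc[table.region == "global", "max_thickness_mm"]).all()

    def test_zero_radius_returns_nearest_node(self, bumped):
        zmap, root = bumped
        table = rs.summarize_map(zmap, [root], radius_mm=0.0)
        i = int(np.argmin(np.abs(zmap.x_mm - root.x_mm)))
        j = int(np.argmin(np.abs(zmap.y_mm - root.y_mm)))
        got = table.loc[table.region == "root", "mean_thickness_mm"].iloc[0]
        assert got == zmap.thickness_mm[i, j]

    def test_root_outside_footprint_skipped_with_warning(self, bumped):
        zmap, _ = bumped
        outside = rs.Root(45.0, 0.0, 1.0, 200.0, "far")
        with pytest.warns(UserWarning, match="outside the map footprint"):
            table = rs.summarize_map(zmap, [outside], radius_mm=4.0)
        assert "root" not in set(table.region)
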