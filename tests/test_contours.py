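"""StDev*Coeff maps, contour levels, and cube-file round-trips."""

import numpy as np
import pytest

from fieldqsar.contours import (
    ContourError,
    ContourMap,
    contour_levels,
    export_cube,
    favored_center_of_mass,
    read_cube,
    stdev_coeff_map,
)
from fieldqsar.fields import (
    BlockScaler,
    FieldTable,
    GridSpec,
    ProbeSpec,
    compute_field_tables,
    make_grid,
)
from fieldqsar.chem_io import prepare
from fieldqsar.pls import PLSQSAR

from test_alignment import rotation_about_axis


def grid222():
    return GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(2, 2, 2))


def fit_field_model(mols, y, kinds=("comsia_steric",), grid=None, n_components=2):
    grid = grid or make_grid(mols, spacing=2.0, margin=4.0)
    tables = compute_field_tables(mols, grid, ProbeSpec(), kinds)
    block = BlockScaler(min_sigma=0.0).fit_transform(tables)
    model = PLSQSAR(n_components=n_components).fit(block, y)
    return model, block, grid


class TestStdevCoeffMap:
    def _toy(self):
        rng = np.random.default_rng(91)
        mat = rng.normal(size=(12, 8))
        mat[:, 5] = 4.0  # zero-variance column
        table = FieldTable(grid222(), "comsia_steric", mat,
                           tuple(f"m{i}" for i in range(12)))
        block = BlockScaler(min_sigma=0.01).fit_transform({"comsia_steric": table})
        y = mat[:, 0] - 0.5 * mat[:, 3] + rng.normal(0, 0.05, 12)
        model = PLSQSAR(n_components=2).fit(block, y)
        return model, block, mat

    def test_zero_variance_column_maps_to_zero(self):
        model, block, _ = self._toy()
        cmap = stdev_coeff_map(model, block, "comsia_steric")
        assert cmap.values[5] == 0.0

    def test_values_equal_coef_times_sd(self):
        model, block, mat = self._toy()
        cmap = stdev_coeff_map(model, block, "comsia_steric")
        info = block.block("comsia_steric")
        expected = model.coef_[info.cols] * block.X[:, info.cols].std(axis=0, ddof=1)
        assert np.allclose(cmap.values[info.kept], expected, atol=1e-12)

    def test_single_column_value_is_c_times_s(self):
        rng = np.random.default_rng(93)
        col = rng.normal(size=(15, 1))
        rest = np.zeros((15, 7))
        mat = np.hstack([col, rest])
        table = FieldTable(grid222(), "comsia_steric", mat,
                          tuple(f"m{i}" for i in range(15)))
        block = BlockScaler(min_sigma=0.001).fit_transform({"comsia_steric": table})
        y = 3.0 * col[:, 0] + 1.0
        model = PLSQSAR(n_components=1).fit(block, y)
        cmap = stdev_coeff_map(model, block, "comsia_steric")
        c = model.coef_[0]
        s = block.X[:, 0].std(ddof=1)
        assert cmap.values[0] == pytest.approx(c * s, abs=1e-12)
        # and the product is invariant under the block scaling: it equals
        # (raw-column sd) x (coefficient mapped back to raw units)
        raw_sd = mat[:, 0].std(ddof=1)
        raw_coef = c * block.block("comsia_steric").scale
        assert cmap.values[0] == pytest.approx(raw_coef * raw_sd, abs=1e-12)

    def test_consistency_with_block_contributions(self):
        model, block, _ = self._toy()
        cmap = stdev_coeff_map(model, block, "comsia_steric")
        weight = np.abs(model.coef_) * model._train_col_std_
        assert np.abs(cmap.values).sum() == pytest.approx(weight.sum(), rel=1e-9)

    def test_negating_activity_flips_every_value(self):
        rng = np.random.default_rng(95)
        mat = rng.normal(size=(12, 8))
        table = FieldTable(grid222(), "comsia_steric", mat,
                          tuple(f"m{i}" for i in range(12)))
        block = BlockScaler(min_sigma=0.0).fit_transform({"comsia_steric": table})
        y = mat @ rng.normal(size=8) + rng.normal(0, 0.1, 12)
        m1 = PLSQSAR(n_components=3).fit(block, y)
        m2 = PLSQSAR(n_components=3).fit(block, -y)
        v1 = stdev_coeff_map(m1, block, "comsia_steric").values
        v2 = stdev_coeff_map(m2, block, "comsia_steric").values
        assert np.allclose(v1, -v2, atol=1e-10)

    def test_unknown_field_kind_errors(self):
        model, block, _ = self._toy()
        with pytest.raises(ContourError):
            stdev_coeff_map(model, block, "comsia_acceptor")

    def test_map_equivariant_under_co_rotation(self, small_series):
        _, (mols, act, _) = small_series
        from fieldqsar.alignment import align_set
        from fieldqsar.synthetic import CORE_SMARTS

        template = act.loc[act["value"].idxmax(), "id"]
        aligned, _ = align_set(mols, template, core_smarts=CORE_SMARTS)
        prepared = [prepare(m) for m in aligned[:12]]
        y = act["value"].to_numpy()[:12]
        grid = make_grid(prepared, spacing=2.0, margin=4.0)
        model, block, _ = fit_field_model(prepared, y, grid=grid)
        base = stdev_coeff_map(model, block, "comsia_steric")

        R = rotation_about_axis([0.3, 1.0, -0.7], 0.8)
        t = np.array([1.0, -2.0, 0.5])
        moved = [m.transformed(R, t) for m in prepared]
        o = np.asarray(grid.origin)
        # co-rotated grid: same lattice carried through the rigid motion is
        # not axis-aligned, so evaluate fields directly on transformed points
        pts = grid.points() @ R.T + t
        tables = {}
        cols = []
        for m in moved:
            xyz = m.coords
            diff = pts[:, None, :] - xyz[None, :, :]
            r2 = (diff**2).sum(axis=2)
            cols.append(-(np.exp(-0.3 * r2) @ m.steric))
        mat = np.array(cols)
        table = FieldTable(grid, "comsia_steric", mat, tuple(m.id for m in moved))
        block2 = BlockScaler(min_sigma=0.0).fit_transform({"comsia_steric": table})
        model2 = PLSQSAR(n_components=2).fit(block2, y)
        rotated = stdev_coeff_map(model2, block2, "comsia_steric")
        assert np.allclose(base.values, rotated.values, atol=1e-9)


class TestContourLevels:
    def _map(self, values):
        values = np.asarray(values, dtype=float)
        n = len(values)
        dims = (max(-(-n // 4), 2), 2, 2)
        grid = GridSpec(origin=(0, 0, 0), spacing=1.0, dims=dims)
        v = np.zeros(grid.n_points)
        v[: len(values)] = values
        return ContourMap(grid=grid, kind="comsia_steric", values=v)

    def test_all_equal_positive_values(self):
        cmap = self._map([0.7] * 8)
        favored, disfavored = contour_levels(cmap, 80, 20)
        assert favored == pytest.approx(0.7)
        assert disfavored == 0.0
        assert cmap.no_negative_values

    def test_planted_cumulative_split(self):
        # positives 1..10 (total 55); favored 80% level: cumulative mass in
        # ascending order crosses 44 at value 9 -> level 9
        vals = list(range(1, 11))
        cmap = self._map(vals)
        favored, _ = contour_levels(cmap, 80, 20)
        assert favored == 9.0

    def test_symmetric_negative_levels(self):
        vals = [-v for v in range(1, 11)] + list(range(1, 11))
        cmap = self._map(vals)
        favored, disfavored = contour_levels(cmap, 80, 20)
        assert favored == 9.0
        assert disfavored == -9.0

    def test_all_zero_map_rejected(self):
        cmap = self._map([0.0] * 8)
        with pytest.raises(ContourError):
            contour_levels(cmap)


class TestCubeIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(97)
        grid = GridSpec(origin=(-2.0, 0.0, 4.0), spacing=2.0, dims=(3, 4, 5))
        cmap = ContourMap(grid=grid, kind="comsia_hydrophobic",
                          values=rng.normal(size=grid.n_points))
        path = tmp_path / "map.cube"
        export_cube(cmap, path)
        back = read_cube(path)
        assert back.grid.dims == grid.dims
        assert np.allclose(back.grid.origin, grid.origin, atol=1e-6)
        assert back.grid.spacing == pytest.approx(grid.spacing, abs=1e-6)
        assert np.allclose(back.values, cmap.values, atol=1e-6)
        assert back.kind == "comsia_hydrophobic"

    def test_tiny_map_has_eight_values(self, tmp_path):
        cmap = ContourMap(grid=grid222(), kind="comsia_steric",
                          values=np.ones(8))
        path = tmp_path / "ones.cube"
        export_cube(cmap, path)
        data = []
        lines = path.read_text().splitlines()
        for line in lines[7:]:  # header + 1 dummy atom
            data.extend(float(x) for x in line.split())
        assert len(data) == 8
        assert all(x == 1.0 for x in data)


class TestHotspotRecovery:
    def test_favored_region_centers_on_planted_hotspot(self, headline_pipeline):
        res = headline_pipeline
        cmap = res.maps["comsia_steric"]
        com = favored_center_of_mass(cmap)
        hotspot = np.array([-4.2, 0.0, 0.0])
        assert np.linalg.norm(com - hotspot) <= 2.0  # one grid spacing

    def test_map_sign_positive_through_planted_region(self, headline_pipeline):
        res = headline_pipeline
        cmap = res.maps["comsia_steric"]
        pts = cmap.grid.points()
        near = np.linalg.norm(pts - np.array([-4.2, 0.0, 0.0]), axis=1) <= 1.5
        vals = cmap.values[near]
        assert vals.size > 0
        assert (vals > 0).all()
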