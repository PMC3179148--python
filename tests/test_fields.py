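"""Lattice construction and CoMFA/CoMSIA field evaluation."""

import numpy as np
import pytest

from fieldqsar.chem_io import Molecule, prepare
from fieldqsar.fields import (
    COULOMB_CONSTANT,
    BlockScaler,
    FieldError,
    FieldTable,
    GridSpec,
    ProbeSpec,
    comfa_fields,
    comsia_field,
    compute_field_tables,
    make_grid,
    scale_and_filter,
)
from fieldqsar.synthetic import build_molecule

from conftest import mol_from_smiles
from test_alignment import rotation_about_axis


def single_atom(element="C", coords=(0.0, 0.0, 0.0), charge=0.0, steric=1.0):
    """A bare one-atom Molecule with hand-set properties (no valence chemistry)."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    rw.AddAtom(Chem.Atom(element))
    rd = rw.GetMol()
    conf = Chem.Conformer(1)
    conf.SetAtomPosition(0, Point3D(*coords))
    conf.Set3D(True)
    rd.AddConformer(conf)
    mol = Molecule(id="atom", rd=rd)
    n = 1
    mol.charges = np.array([charge])
    mol.steric = np.array([steric])
    mol.hydrophobic = np.array([0.5])
    mol.donor = np.zeros(n)
    mol.acceptor = np.zeros(n)
    mol.vdw_radius = np.array([1.7])
    mol.lj_radius = np.array([1.7])
    mol.lj_epsilon = np.array([0.107])
    return mol


def tiny_grid(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(2, 2, 2)):
    return GridSpec(origin=origin, spacing=spacing, dims=dims)


class TestMakeGrid:
    def test_single_atom_default_margin(self):
        mol = single_atom("C", (0.0, 0.0, 0.0))
        grid = make_grid([mol], spacing=2.0, margin=4.0)
        assert grid.dims == (5, 5, 5)
        assert grid.origin == (-4.0, -4.0, -4.0)

    def test_translation_by_spacing_shifts_origin_exactly(self):
        mol = single_atom("C", (0.3, 0.7, -0.2))
        g1 = make_grid([mol], spacing=2.0, margin=4.0)
        moved = single_atom("C", (2.3, 0.7, -0.2))
        g2 = make_grid([moved], spacing=2.0, margin=4.0)
        assert np.allclose(np.array(g2.origin) - np.array(g1.origin), [2.0, 0, 0])
        assert g1.dims == g2.dims

    def test_all_heavy_atoms_strictly_inside(self, headline_series):
        _, (mols, _, _) = headline_series
        grid = make_grid(mols[:25], spacing=2.0, margin=4.0)
        lo = np.asarray(grid.origin)
        hi = grid.max_corner()
        for m in mols[:25]:
            pts = m.coords[m.heavy_mask]
            assert (pts > lo).all() and (pts < hi).all()

    def test_empty_set_rejected(self):
        with pytest.raises(FieldError):
            make_grid([])


class TestCoMSIA:
    @pytest.mark.parametrize("r, expected", [
        (0.0, -1.0),
        (1.0, -np.exp(-0.3)),
        (2.0, -np.exp(-0.3 * 4.0)),
    ])
    def test_single_atom_analytic_value(self, r, expected):
        mol = single_atom("C", (0.0, 0.0, float(r)), steric=1.0)
        grid = tiny_grid(origin=(0, 0, 0), spacing=5.0, dims=(2, 2, 2))
        col = comsia_field(mol, grid, ProbeSpec(), "comsia_steric")
        # grid point 0 is the origin, at distance r from the atom
        assert col[0] == pytest.approx(expected, abs=1e-12)

    def test_additivity_over_atoms(self):
        a = single_atom("C", (0.0, 0.0, 1.5))
        grid = tiny_grid(spacing=3.0)
        single = comsia_field(a, grid, ProbeSpec(), "comsia_steric")

        from rdkit import Chem
        from rdkit.Geometry import Point3D

        rw = Chem.RWMol()
        rw.AddAtom(Chem.Atom("C"))
        rw.AddAtom(Chem.Atom("C"))
        rd = rw.GetMol()
        conf = Chem.Conformer(2)
        conf.SetAtomPosition(0, Point3D(0.0, 0.0, 1.5))
        conf.SetAtomPosition(1, Point3D(0.0, 0.0, 1.5))
        conf.Set3D(True)
        rd.AddConformer(conf)
        pair = Molecule(id="pair", rd=rd)
        pair.steric = np.array([1.0, 1.0])
        double = comsia_field(pair, grid, ProbeSpec(), "comsia_steric")
        assert np.allclose(double, 2.0 * single, atol=1e-14)

    def test_attenuation_strictly_monotone_in_distance(self):
        mol = single_atom("C", (0.0, 0.0, 0.0))
        rs = np.linspace(0.0, 6.0, 25)
        vals = []
        for r in rs:
            grid = tiny_grid(origin=(r, 0, 0), spacing=10.0)
            vals.append(abs(comsia_field(mol, grid, ProbeSpec(), "comsia_steric")[0]))
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_unassigned_property_errors(self):
        mol = single_atom("C")
        mol.hydrophobic = None
        with pytest.raises(FieldError, match="hydrophobic"):
            comsia_field(mol, tiny_grid(), ProbeSpec(), "comsia_hydrophobic")


class TestCoMFA:
    def test_zero_charges_give_zero_electrostatics(self):
        mol = single_atom("C", (0.0, 0.0, 0.9), charge=0.0)
        _, elec, excl = comfa_fields(mol, tiny_grid(spacing=4.0), ProbeSpec())
        assert np.all(elec[~excl] == 0.0)

    def test_probe_overlap_pins_steric_at_cutoff(self):
        mol = single_atom("C", (0.0, 0.0, 0.0))
        steric, _, excl = comfa_fields(mol, tiny_grid(spacing=4.0), ProbeSpec())
        assert steric[0] == pytest.approx(30.0)
        assert excl[0]

    def test_coulomb_with_distance_dependent_dielectric(self):
        mol = single_atom("C", (0.0, 0.0, 2.0), charge=1.0)
        # kill the LJ term so the point is not sterically excluded, and raise
        # the cutoff above the expected value to read the raw Coulomb sum
        mol.lj_epsilon = np.array([0.0])
        _, elec, excl = comfa_fields(mol, tiny_grid(spacing=5.0),
                                     ProbeSpec(energy_cutoff=100.0))
        assert not excl[0]
        assert elec[0] == pytest.approx(COULOMB_CONSTANT / 4.0, rel=1e-12)
        assert elec[0] == pytest.approx(83.0159, abs=1e-3)

    def test_charge_negation_negates_field(self):
        mol = prepare(build_molecule("m", {"C3": "F", "C4": "Cl", "C5": "H"}))
        grid = make_grid([mol], spacing=2.0, margin=4.0)
        _, elec, excl = comfa_fields(mol, grid, ProbeSpec())
        neg = mol.copy()
        neg.charges = -mol.charges
        _, elec2, excl2 = comfa_fields(neg, grid, ProbeSpec())
        assert np.array_equal(excl, excl2)
        assert np.allclose(elec2[~excl], -elec[~excl], atol=1e-12)

    def test_columns_bounded_by_cutoff(self, small_series):
        _, (mols, _, _) = small_series
        prepared = [prepare(m) for m in mols[:5]]
        grid = make_grid(prepared, spacing=2.0, margin=4.0)
        for m in prepared:
            steric, elec, _ = comfa_fields(m, grid, ProbeSpec())
            assert np.all(np.abs(steric) <= 30.0 + 1e-12)
            assert np.all(np.abs(elec) <= 30.0 + 1e-12)


class TestOracleAndInvariance:
    def naive_comsia(self, mol, grid, alpha, prop):
        pts = grid.points()
        out = np.zeros(len(pts))
        xyz = mol.coords
        for qi, q in enumerate(pts):
            acc = 0.0
            for i in range(mol.n_atoms):
                r2 = float(((q - xyz[i]) ** 2).sum())
                acc += prop[i] * np.exp(-alpha * r2)
            out[qi] = -acc
        return out

    def naive_comfa(self, mol, grid, probe):
        pts = grid.points()
        steric = np.zeros(len(pts))
        elec = np.zeros(len(pts))
        xyz = mol.coords
        for qi, q in enumerate(pts):
            s = e = 0.0
            for i in range(mol.n_atoms):
                r = float(np.linalg.norm(q - xyz[i]))
                r = max(r, 1e-12)
                rij = mol.lj_radius[i] + probe.lj_radius
                epsij = np.sqrt(mol.lj_epsilon[i] * probe.lj_epsilon)
                s += epsij * ((rij / r) ** 12 - 2 * (rij / r) ** 6)
                e += COULOMB_CONSTANT * probe.charge * mol.charges[i] / r**2
            steric[qi] = np.clip(s, -probe.energy_cutoff, probe.energy_cutoff)
            elec[qi] = np.clip(e, -probe.energy_cutoff, probe.energy_cutoff)
        excluded = steric >= probe.energy_cutoff
        elec[excluded] = 0.0
        return steric, elec

    def test_vectorized_equals_double_loop(self, small_series):
        _, (mols, _, _) = small_series
        prepared = [prepare(m) for m in mols[:5]]
        grid = GridSpec(origin=(-6.0, -6.0, -4.0), spacing=2.5, dims=(5, 5, 5))
        probe = ProbeSpec()
        for m in prepared:
            fast = comsia_field(m, grid, probe, "comsia_steric")
            slow = self.naive_comsia(m, grid, probe.alpha, m.steric)
            assert np.allclose(fast, slow, atol=1e-10)
            fast_h = comsia_field(m, grid, probe, "comsia_hydrophobic")
            slow_h = self.naive_comsia(m, grid, probe.alpha, m.hydrophobic)
            assert np.allclose(fast_h, slow_h, atol=1e-10)
            st, el, _ = comfa_fields(m, grid, probe)
            st2, el2 = self.naive_comfa(m, grid, probe)
            assert np.allclose(st, st2, atol=1e-10)
            assert np.allclose(el, el2, atol=1e-10)

    def test_rotational_invariance(self, small_series):
        _, (mols, _, _) = small_series
        prepared = [prepare(m) for m in mols[:3]]
        grid = make_grid(prepared, spacing=2.0, margin=4.0)
        probe = ProbeSpec()
        R = rotation_about_axis([1.0, -0.4, 2.0], 0.9)
        t = np.array([3.0, -1.0, 2.0])
        for m in prepared:
            base = comsia_field(m, grid, probe, "comsia_steric")
            moved = m.transformed(R, t)
            # co-rotate the grid: transform every lattice point identically
            pts = grid.points() @ R.T + t
            xyz = moved.coords
            diff = pts[:, None, :] - xyz[None, :, :]
            r = np.sqrt((diff**2).sum(axis=2))
            rotated = -(np.exp(-probe.alpha * r**2) @ m.steric)
            assert np.allclose(base, rotated, atol=1e-9)


class TestScaleAndFilter:
    def _table(self, kind, matrix, grid=None):
        grid = grid or tiny_grid(dims=(2, 2, 2))
        return FieldTable(grid=grid, kind=kind,
                          matrix=np.asarray(matrix, dtype=float),
                          mol_ids=tuple(f"m{i}" for i in range(len(matrix))))

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(size=(6, 8))
        mat[:, 3] = 5.0
        block = scale_and_filter(
            {"comsia_steric": self._table("comsia_steric", mat)}, min_sigma=0.01
        )
        info = block.block("comsia_steric")
        assert 3 not in info.kept
        assert block.X.shape == (6, 7)

    def test_min_sigma_zero_keeps_everything(self):
        mat = np.zeros((5, 8))
        mat[:, 0] = [0, 1, 2, 3, 4]
        block = scale_and_filter(
            {"comsia_steric": self._table("comsia_steric", mat)}, min_sigma=0.0
        )
        assert block.X.shape == (5, 8)

    def test_planted_variance_ratio_equalized(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 2.0, size=(10, 6))   # 4x the variance of b
        b = rng.normal(0, 1.0, size=(10, 6))
        block = scale_and_filter(
            {
                "comsia_steric": self._table("comsia_steric", a),
                "comsia_hydrophobic": self._table("comsia_hydrophobic", b),
            },
            min_sigma=0.0,
        )
        va = block.X[:, block.block("comsia_steric").cols].var(axis=0, ddof=1).sum()
        vb = block.X[:, block.block("comsia_hydrophobic").cols].var(axis=0, ddof=1).sum()
        assert va == pytest.approx(vb, abs=1e-9)
        assert va == pytest.approx(1.0, abs=1e-9)

    def test_all_columns_filtered_is_an_error(self):
        mat = np.ones((5, 4))
        with pytest.raises(FieldError):
            scale_and_filter(
                {"comsia_steric": self._table("comsia_steric", mat)}, min_sigma=0.5
            )

    def test_electrostatic_mean_substitution_frozen_for_test(self):
        grid = tiny_grid(dims=(2, 2, 2))
        rng = np.random.default_rng(2)
        train = rng.normal(size=(6, 8))
        excl_train = np.zeros((6, 8), dtype=bool)
        excl_train[0, 2] = excl_train[3, 2] = True
        t_train = FieldTable(grid, "comfa_electrostatic", train.copy(),
                             tuple(f"m{i}" for i in range(6)), excluded=excl_train)
        scaler = BlockScaler(min_sigma=0.0)
        scaler.fit({"comfa_electrostatic": t_train})
        expected_mean = train[[1, 2, 4, 5], 2].mean()
        assert scaler.elec_means_[2] == pytest.approx(expected_mean)

        test = rng.normal(size=(2, 8))
        excl_test = np.zeros((2, 8), dtype=bool)
        excl_test[1, 2] = True
        t_test = FieldTable(grid, "comfa_electrostatic", test.copy(),
                            ("t0", "t1"), excluded=excl_test)
        block = scaler.transform({"comfa_electrostatic": t_test})
        col = block.X[:, block.block("comfa_electrostatic").cols]
        scale = block.block("comfa_electrostatic").scale
        assert col[1, 2] == pytest.approx(expected_mean * scale)
        assert col[0, 2] == pytest.approx(test[0, 2] * scale)
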