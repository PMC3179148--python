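"""Ligand I/O, partial charges, and per-field atomic properties.

The ligand record used throughout the pipeline is :class:`Molecule`: an RDKit
molecule with one 3D conformer plus numpy vectors of the atomic properties
that enter the field calculations — partial charge, a scaled-vdW-volume
steric property, an atomic hydrophobicity (logP) contribution, hydrogen-bond
donor/acceptor flags, and Lennard-Jones parameters.  Input conformers are
treated as authoritative; no geometry optimization is performed here.

Activities are pKi values (−log10 of Ki in molar units); :func:`ki_to_pki`
converts binding constants given in nM.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors, rdPartialCharges


class ChemIOError(ValueError):
    """Raised for unparseable records, missing 3D coordinates, bad tables."""


# --------------------------------------------------------------------------
# property scheme
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PropertyScheme:
    """Versioned atomic-property tables (vdW radii, LJ parameters, H-bond rules)."""

    name: str
    version: int
    vdw_radius: dict[str, float]
    hydrophobicity_method: str
    lj_probe: dict[str, float]
    lj_atoms: dict[str, dict[str, float]]
    donor_smarts: tuple[str, ...]
    acceptor_smarts: tuple[str, ...]
    protonate_aliphatic_amines: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "PropertyScheme":
        if path is None:
            text = (
                resources.files("fieldqsar").joinpath("schemes/default.yaml").read_text()
            )
        else:
            text = Path(path).read_text()
        cfg = yaml.safe_load(text)
        return cls(
            name=cfg["name"],
            version=int(cfg["version"]),
            vdw_radius={k: float(v) for k, v in cfg["vdw_radius"].items()},
            hydrophobicity_method=cfg["hydrophobicity"]["method"],
            lj_probe={k: float(v) for k, v in cfg["lennard_jones"]["probe"].items()},
            lj_atoms={
                el: {k: float(v) for k, v in d.items()}
                for el, d in cfg["lennard_jones"]["atoms"].items()
            },
            donor_smarts=tuple(cfg["donor_smarts"]),
            acceptor_smarts=tuple(cfg["acceptor_smarts"]),
            protonate_aliphatic_amines=bool(cfg.get("protonate_aliphatic_amines", True)),
        )


_DEFAULT_SCHEME: PropertyScheme | None = None


def default_scheme() -> PropertyScheme:
    global _DEFAULT_SCHEME
    if _DEFAULT_SCHEME is None:
        _DEFAULT_SCHEME = PropertyScheme.from_yaml()
    return _DEFAULT_SCHEME


# --------------------------------------------------------------------------
# molecule container
# --------------------------------------------------------------------------

@dataclass
class Atom:
    """Read-only per-atom view (element, coordinates and field properties)."""

    element: str
    coords: np.ndarray
    partial_charge: float | None
    steric_property: float | None
    hydrophobicity: float | None
    is_donor: bool | None
    is_acceptor: bool | None
    vdw_radius: float | None
    lj_epsilon: float | None


@dataclass
class Molecule:
    """A ligand: RDKit mol with a 3D conformer plus atomic property vectors.

    Property vectors are ``None`` until assigned by :func:`assign_charges`
    and :func:`assign_field_properties` (or :func:`prepare`).
    """

    id: str
    rd: Chem.Mol
    activity: float | None = None
    charges: np.ndarray | None = None
    steric: np.ndarray | None = None
    hydrophobic: np.ndarray | None = None
    donor: np.ndarray | None = None
    acceptor: np.ndarray | None = None
    vdw_radius: np.ndarray | None = None
    lj_radius: np.ndarray | None = None
    lj_epsilon: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return self.rd.GetNumAtoms()

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.rd.GetConformer().GetPositions(), dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.GetSymbol() for a in self.rd.GetAtoms()]

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.GetAtomicNum() > 1 for a in self.rd.GetAtoms()])

    @property
    def bonds(self) -> list[tuple[int, int, float]]:
        out = []
        for b in self.rd.GetBonds():
            order = 1.5 if b.GetIsAromatic() else float(b.GetBondTypeAsDouble())
            out.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
        return out

    @property
    def atoms(self) -> list[Atom]:
        xyz = self.coords

        def pick(arr, i):
            return None if arr is None else arr[i]

        return [
            Atom(
                element=a.GetSymbol(),
                coords=xyz[i],
                partial_charge=pick(self.charges, i),
                steric_property=pick(self.steric, i),
                hydrophobicity=pick(self.hydrophobic, i),
                is_donor=None if self.donor is None else bool(self.donor[i]),
                is_acceptor=None if self.acceptor is None else bool(self.acceptor[i]),
                vdw_radius=pick(self.vdw_radius, i),
                lj_epsilon=pick(self.lj_epsilon, i),
            )
            for i, a in enumerate(self.rd.GetAtoms())
        ]

    def set_coords(self, xyz: np.ndarray) -> None:
        conf = self.rd.GetConformer()
        for i, p in enumerate(np.asarray(xyz, dtype=float)):
            conf.SetAtomPosition(i, p.tolist())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule":
        """Return a copy with coordinates ``R @ x + t``."""
        new = self.copy()
        new.set_coords(self.coords @ np.asarray(rotation).T + np.asarray(translation))
        return new

    def copy(self) -> "Molecule":
        new = replace(self, rd=Chem.Mol(self.rd))
        for name in ("charges", "steric", "hydrophobic", "donor", "acceptor",
                     "vdw_radius", "lj_radius", "lj_epsilon"):
            v = getattr(new, name)
            if v is not None:
                setattr(new, name, v.copy())
        return new


# --------------------------------------------------------------------------
# reading / writing
# --------------------------------------------------------------------------

def _check_3d(rdmol: Chem.Mol, mol_id: str) -> None:
    if rdmol.GetNumConformers() == 0:
        raise ChemIOError(f"molecule {mol_id!r} has no coordinates")
    conf = rdmol.GetConformer()
    xyz = np.asarray(conf.GetPositions(), dtype=float)
    if not np.all(np.isfinite(xyz)):
        raise ChemIOError(f"molecule {mol_id!r} has non-finite coordinates")
    if rdmol.GetNumAtoms() >= 4 and np.allclose(xyz[:, 2], 0.0, atol=1e-8):
        raise ChemIOError(
            f"molecule {mol_id!r} has 2D-only coordinates (all z = 0)"
        )


def _mol_id(rdmol: Chem.Mol, index: int) -> str:
    name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
    return name.strip() or f"mol_{index}"


def read_ligands(path: str | Path, fmt: str | None = None) -> list[Molecule]:
    """Read an SDF (V2000) or multi-record MOL2 file into :class:`Molecule` list.

    Every record must carry true 3D coordinates; flat (all z = 0) or
    unparseable records raise :class:`ChemIOError` naming the offender.
    """
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"no such file: {path}")
    if fmt is None:
        fmt = "mol2" if path.suffix.lower() == ".mol2" else "sdf"

    mols: list[Molecule] = []
    bad: list[str] = []
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for i, rdmol in enumerate(supplier):
            if rdmol is None:
                raise ChemIOError(f"unparseable SDF record at index {i} in {path}")
            mid = _mol_id(rdmol, i)
            _check_3d(rdmol, mid)
            activity = None
            if rdmol.HasProp("pKi"):
                activity = float(rdmol.GetProp("pKi"))
            mols.append(Molecule(id=mid, rd=rdmol, activity=activity))
    elif fmt == "mol2":
        blocks = _split_mol2(path.read_text())
        for i, block in enumerate(blocks):
            rdmol = Chem.MolFromMol2Block(block, removeHs=False, sanitize=True)
            if rdmol is None:
                raise ChemIOError(f"unparseable MOL2 record at index {i} in {path}")
            mid = _mol_id(rdmol, i)
            _check_3d(rdmol, mid)
            mols.append(Molecule(id=mid, rd=rdmol))
    else:
        raise ChemIOError(f"unknown format {fmt!r} (expected 'sdf' or 'mol2')")

    seen: set[str] = set()
    for m in mols:
        if m.id in seen:
            raise ChemIOError(f"duplicate molecule id {m.id!r}")
        seen.add(m.id)
    if bad:
        raise ChemIOError("records without 3D coordinates: " + ", ".join(bad))
    return mols


def _split_mol2(text: str) -> list[str]:
    marker = "@<TRIPOS>MOLECULE"
    parts = text.split(marker)
    return [marker + p for p in parts[1:]]


def write_ligands(mols: Sequence[Molecule], path: str | Path) -> None:
    """Write molecules to SDF; the activity (if any) is stored as a ``pKi`` tag."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    try:
        for m in mols:
            rdmol = Chem.Mol(m.rd)
            rdmol.SetProp("_Name", m.id)
            if m.activity is not None:
                rdmol.SetProp("pKi", f"{m.activity:.6f}")
            writer.write(rdmol)
    finally:
        writer.close()


def read_activities(path: str | Path) -> pd.DataFrame:
    """Read an activity CSV with header ``id,value,scale`` → DataFrame with pKi.

    ``scale`` is ``Ki_nM`` (converted via :func:`ki_to_pki`) or ``pKi``.
    """
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "value", "scale"}
    if not required.issubset(df.columns):
        raise ChemIOError(f"activity table must have columns {sorted(required)}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ChemIOError(f"duplicate activity ids: {dups}")
    pki = []
    for _, row in df.iterrows():
        if row["scale"] == "Ki_nM":
            pki.append(ki_to_pki(float(row["value"])))
        elif row["scale"] == "pKi":
            pki.append(float(row["value"]))
        else:
            raise ChemIOError(f"unknown activity scale {row['scale']!r}")
    out = df[["id"]].copy()
    out["pKi"] = pki
    return out


def ki_to_pki(ki_nm: float) -> float:
    """Convert a binding constant Ki given in nM to pKi = −log10(Ki [M])."""
    if not ki_nm > 0:
        raise ChemIOError(f"Ki must be positive, got {ki_nm}")
    return -math.log10(ki_nm * 1e-9)


# --------------------------------------------------------------------------
# charges and field properties
# --------------------------------------------------------------------------

def protonate_aliphatic_amines(mol: Molecule) -> Molecule:
    """Protonate neutral aliphatic (sp3, non-amide, non-aryl) amines (pH 7.4)."""
    patt = Chem.MolFromSmarts("[NX3;+0;!$(NC=[O,S,N]);!$(N[a]);!$(N[S,P]=O);!$(N=*)]")
    new = mol.copy()
    rw = Chem.RWMol(new.rd)
    hits = [m[0] for m in rw.GetSubstructMatches(patt)]
    if not hits:
        return new
    for idx in hits:
        atom = rw.GetAtomWithIdx(idx)
        atom.SetFormalCharge(1)
        atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
        atom.SetNoImplicit(True)
    m2 = rw.GetMol()
    Chem.SanitizeMol(m2)
    m2 = AllChem.AddHs(m2, addCoords=True)
    new.rd = m2
    return new


def assign_charges(mol: Molecule) -> Molecule:
    """Assign Gasteiger (PEOE) partial charges.

    The charge sum is checked against the net formal charge (1e-3 e).
    """
    new = mol.copy()
    try:
        rdPartialCharges.ComputeGasteigerCharges(new.rd, throwOnParamFailure=True)
    except Exception as exc:  # rdkit raises generic exceptions for bad valence
        raise ChemIOError(f"charge assignment failed for {mol.id!r}: {exc}") from exc
    q = np.array(
        [float(a.GetProp("_GasteigerCharge")) for a in new.rd.GetAtoms()], dtype=float
    )
    if not np.all(np.isfinite(q)):
        raise ChemIOError(f"non-finite Gasteiger charges for {mol.id!r}")
    formal = float(sum(a.GetFormalCharge() for a in new.rd.GetAtoms()))
    if abs(q.sum() - formal) > 1e-3:
        raise ChemIOError(
            f"charge sum {q.sum():.4f} != formal charge {formal:.1f} for {mol.id!r}"
        )
    new.charges = q
    return new


def assign_field_properties(
    mol: Molecule, scheme: PropertyScheme | None = None
) -> Molecule:
    """Attach the per-atom field properties required by the field engine.

    steric   — (r_vdw / r_vdw[C])^3, carbon = 1.0 (vdW-volume-like)
    hydrophobic — Wildman–Crippen atomic logP contribution
    donor / acceptor — substructure-rule flags (on the heavy atom)
    lj_radius / lj_epsilon — 6-12 parameters for the probe energies
    """
    scheme = scheme or default_scheme()
    new = mol.copy()
    rdmol = new.rd
    symbols = [a.GetSymbol() for a in rdmol.GetAtoms()]
    for table_name, table in (
        ("vdw_radius", scheme.vdw_radius),
        ("lennard_jones.atoms", scheme.lj_atoms),
    ):
        missing = sorted({s for s in symbols if s not in table})
        if missing:
            raise ChemIOError(
                f"elements {missing} of {mol.id!r} absent from scheme table {table_name}"
            )

    r_c = scheme.vdw_radius["C"]
    vdw = np.array([scheme.vdw_radius[s] for s in symbols])
    new.vdw_radius = vdw
    new.steric = (vdw / r_c) ** 3
    new.lj_radius = np.array([scheme.lj_atoms[s]["radius"] for s in symbols])
    new.lj_epsilon = np.array([scheme.lj_atoms[s]["epsilon"] for s in symbols])

    if scheme.hydrophobicity_method == "crippen":
        contribs = rdMolDescriptors._CalcCrippenContribs(rdmol)
        new.hydrophobic = np.array([c[0] for c in contribs])
    else:
        raise ChemIOError(
            f"unknown hydrophobicity method {scheme.hydrophobicity_method!r}"
        )

    donor = np.zeros(len(symbols))
    for smarts in scheme.donor_smarts:
        patt = Chem.MolFromSmarts(smarts)
        for match in rdmol.GetSubstructMatches(patt):
            donor[match[0]] = 1.0
    acceptor = np.zeros(len(symbols))
    for smarts in scheme.acceptor_smarts:
        patt = Chem.MolFromSmarts(smarts)
        for match in rdmol.GetSubstructMatches(patt):
            acceptor[match[0]] = 1.0
    new.donor = donor
    new.acceptor = acceptor
    return new


def prepare(
    mol: Molecule,
    scheme: PropertyScheme | None = None,
    protonate: bool | None = None,
) -> Molecule:
    """Full ligand preparation: explicit Hs, protonation, charges, properties."""
    scheme = scheme or default_scheme()
    new = mol.copy()
    if any(a.GetImplicitValence() > 0 for a in new.rd.GetAtoms()):
        new.rd = AllChem.AddHs(new.rd, addCoords=True)
    do_protonate = scheme.protonate_aliphatic_amines if protonate is None else protonate
    if do_protonate:
        new = protonate_aliphatic_amines(new)
    new = assign_charges(new)
    new = assign_field_properties(new, scheme)
    return new


def prepare_all(
    mols: Iterable[Molecule],
    scheme: PropertyScheme | None = None,
    protonate: bool | None = None,
) -> list[Molecule]:
    return [prepare(m, scheme, protonate) for m in mols]
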