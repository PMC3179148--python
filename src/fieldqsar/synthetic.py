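"""Synthetic congeneric ligand series with a planted structure–activity relation.

The generator emulates the study design that field-based 3D-QSAR assumes: a
rigid shared scaffold (a 2-methylbenzenesulfonamide core, echoing the
sulfonyl/aryl SAR vocabulary of serotonin-receptor ligand series) carrying
variable substituents at three ring positions, with activities created as a
linear function of the molecule's own similarity-field values integrated
over planted lattice regions, plus Gaussian noise.  Because the response is
built from the pipeline's field definitions, a downstream fit can in
principle recover the planted hotspot exactly; field *correctness* is tested
analytically elsewhere — this module tests *recovery*.

Activities are scaled to a fixed pKi span (default 3.0 log units, matching
the ~6.3–9.6 range typical of a congeneric binding series) above a base pKi
of 6.3.  Every molecule except the emitted template is additionally given a
random rigid motion so the alignment stage has real work to do; the core is
perturbed by a small Gaussian jitter.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from .alignment import kabsch_superpose
from .chem_io import Molecule, prepare, write_ligands
from .fields import GridSpec, ProbeSpec, DEFAULT_PROBE, comsia_field

# Heavy-atom core emitted by the scaffold builder (always atoms 0..10).
CORE_SMARTS = "Cc1ccccc1S(N)(=O)=O"

_RING_R = 1.396
_COS60, _SIN60 = 0.5, math.sqrt(3.0) / 2.0


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedRegion:
    """A lattice region (center ± extent) tied to one field kind and coefficient."""

    center: tuple[float, float, float]
    kind: str = "comsia_steric"
    coefficient: float = 1.0
    half_extent: float = 2.0     # Angstrom; region sampled as a 3x3x3 mini-grid

    def region_grid(self) -> GridSpec:
        c = np.asarray(self.center)
        return GridSpec(
            origin=tuple((c - self.half_extent).tolist()),
            spacing=self.half_extent,
            dims=(3, 3, 3),
        )


# Default planted hotspot: on the para axis of the scaffold ring, where the
# bulk of a para substituent sits (ring C4 is at (-1.396, 0, 0)).  The region
# center and sampling pitch sit on the even-2 A lattice the analysis grid
# snaps to, so the planted response is exactly linear in retained columns.
DEFAULT_REGIONS = (PlantedRegion(center=(-4.0, 0.0, 0.0)),)

# Substituent vocabulary per attachment point.  The para position (C4)
# spans the full bulk range and drives the planted steric signal; the meta
# positions add uncorrelated chemical variation.
DEFAULT_LIBRARY = {
    "C3": ("H", "F", "Cl", "hydroxyl", "amino", "methoxy"),
    "C4": ("H", "methyl", "Cl", "Br", "phenyl", "aryl_extended", "methylsulfonyl"),
    "C5": ("H", "F", "methyl", "methoxy"),
}


@dataclass(frozen=True)
class SeriesSpec:
    """Generation conditions for one synthetic congeneric series."""

    n_molecules: int = 120
    noise_sd: float = 0.15          # pKi units
    core_jitter_sd: float = 0.05    # Angstrom
    seed: int = 7
    n_train: int = 90
    n_test: int = 30
    activity_span: float = 3.0      # pKi units, by construction
    base_pki: float = 6.3
    planted_regions: tuple[PlantedRegion, ...] = DEFAULT_REGIONS
    library: dict = dc_field(default_factory=lambda: dict(DEFAULT_LIBRARY))

    def __post_init__(self):
        if self.n_train + self.n_test != self.n_molecules:
            raise SyntheticError("n_train + n_test must equal n_molecules")
        if self.noise_sd < 0 or self.core_jitter_sd < 0:
            raise SyntheticError("noise and jitter standard deviations must be >= 0")


@dataclass
class GroundTruth:
    """What the generator planted; never read by the pipeline under test."""

    noiseless_activity: dict[str, float]
    substituents: dict[str, dict[str, str]]
    planted: list[dict]
    intercept: float
    activity_scale: float
    template_id: str
    core_rmsd: dict[str, float]
    core_atom_indices: tuple[int, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "noiseless_activity": self.noiseless_activity,
                "substituents": self.substituents,
                "planted": self.planted,
                "intercept": self.intercept,
                "activity_scale": self.activity_scale,
                "template_id": self.template_id,
                "core_rmsd": self.core_rmsd,
                "core_atom_indices": list(self.core_atom_indices),
            },
            indent=2,
            sort_keys=True,
        )


# --------------------------------------------------------------------------
# scaffold and fragment geometry
# --------------------------------------------------------------------------

def _scaffold_atoms() -> tuple[list[tuple[str, np.ndarray]], list[tuple[int, int, int]]]:
    """2-methylbenzenesulfonamide heavy atoms (indices 0..10) and bonds.

    Ring C1..C6 = indices 0..5 (C1 carries SO2NH2, C2 the methyl marker that
    breaks the ring mirror symmetry); S=6, O=7,8, N=9, methyl C=10.
    """
    ring = [
        np.array([_RING_R * math.cos(math.radians(60 * k)),
                  _RING_R * math.sin(math.radians(60 * k)), 0.0])
        for k in range(6)
    ]
    u1 = np.array([1.0, 0.0, 0.0])
    s = ring[0] + 1.77 * u1
    o1 = s + 1.43 * np.array([0.25, 0.63, 0.73])
    o2 = s + 1.43 * np.array([0.25, 0.63, -0.73])
    nn = s + 1.63 * np.array([0.55, -0.835, 0.0])
    me = ring[1] + 1.50 * np.array([_COS60, _SIN60, 0.0])
    atoms = [("C", p) for p in ring] + [
        ("S", s), ("O", o1), ("O", o2), ("N", nn), ("C", me),
    ]
    # kekulized ring + sulfonamide + marker methyl
    bonds = [
        (0, 1, 2), (1, 2, 1), (2, 3, 2), (3, 4, 1), (4, 5, 2), (5, 0, 1),
        (0, 6, 1), (6, 7, 2), (6, 8, 2), (6, 9, 1), (1, 10, 1),
    ]
    return atoms, bonds


_ATTACH = {  # ring atom index and outward radial unit vector
    "C3": (2, np.array([-_COS60, _SIN60, 0.0])),
    "C4": (3, np.array([-1.0, 0.0, 0.0])),
    "C5": (4, np.array([-_COS60, -_SIN60, 0.0])),
}


def _phenyl_local(tilt_deg: float = 45.0) -> tuple[list[tuple[str, np.ndarray]], list]:
    """Phenyl in a plane containing +x, twisted out of the scaffold plane."""
    v = np.array([0.0, math.cos(math.radians(tilt_deg)),
                  math.sin(math.radians(tilt_deg))])
    center = np.array([1.48 + _RING_R, 0.0, 0.0])
    atoms = []
    for k in range(6):
        th = math.radians(60 * k)
        pos = center + _RING_R * (math.cos(th) * np.array([-1.0, 0, 0]) + math.sin(th) * v)
        atoms.append(("C", pos))
    bonds = [(k, (k + 1) % 6, 2 if k % 2 == 0 else 1) for k in range(6)]
    return atoms, bonds


def _fragment(name: str) -> tuple[list[tuple[str, np.ndarray]], list]:
    """Fragment atoms in the local attachment frame (+x outward); the first
    atom bonds to the ring carbon with a single bond."""
    if name == "methyl":
        return [("C", np.array([1.50, 0.0, 0.0]))], []
    if name == "F":
        return [("F", np.array([1.35, 0.0, 0.0]))], []
    if name == "Cl":
        return [("Cl", np.array([1.74, 0.0, 0.0]))], []
    if name == "Br":
        return [("Br", np.array([1.90, 0.0, 0.0]))], []
    if name == "hydroxyl":
        return [("O", np.array([1.36, 0.0, 0.0]))], []
    if name == "amino":
        return [("N", np.array([1.40, 0.0, 0.0]))], []
    if name == "methoxy":
        return [
            ("O", np.array([1.36, 0.0, 0.0])),
            ("C", np.array([1.83, 1.34, 0.0])),
        ], [(0, 1, 1)]
    if name == "methylsulfonyl":
        return [
            ("S", np.array([1.77, 0.0, 0.0])),
            ("O", np.array([1.77, 0.94, 1.07])),
            ("O", np.array([1.77, 0.94, -1.07])),
            ("C", np.array([2.75, -1.48, 0.0])),
        ], [(0, 1, 2), (0, 2, 2), (0, 3, 1)]
    if name == "phenyl":
        return _phenyl_local()
    if name == "aryl_extended":
        atoms, bonds = _phenyl_local()
        para = atoms[3][1]  # k=3 is the para position (opposite the ipso)
        atoms = atoms + [("C", para + np.array([1.50, 0.0, 0.0]))]
        bonds = bonds + [(3, 6, 1)]
        return atoms, bonds
    raise SyntheticError(f"unknown fragment {name!r}")


def _attachment_frame(direction: np.ndarray) -> np.ndarray:
    """Rotation mapping the local +x axis onto ``direction`` (in-plane)."""
    x = direction / np.linalg.norm(direction)
    z = np.array([0.0, 0.0, 1.0])
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def build_molecule(
    mol_id: str, substituents: dict[str, str], jitter: np.ndarray | None = None
) -> Molecule:
    """Assemble scaffold + substituents into a sanitized RDKit molecule with
    explicit-hydrogen 3D coordinates.  ``jitter`` (11 x 3) perturbs the core."""
    atoms, bonds = _scaffold_atoms()
    atoms = [(el, p.copy()) for el, p in atoms]
    if jitter is not None:
        for i in range(len(atoms)):
            atoms[i] = (atoms[i][0], atoms[i][1] + jitter[i])
    all_bonds = list(bonds)
    for site, frag_name in substituents.items():
        if frag_name == "H":
            continue
        ring_idx, direction = _ATTACH[site]
        R = _attachment_frame(direction)
        base = atoms[ring_idx][1]
        frag_atoms, frag_bonds = _fragment(frag_name)
        offset = len(atoms)
        for el, local in frag_atoms:
            atoms.append((el, base + R @ local))
        all_bonds.append((ring_idx, offset, 1))
        for i, j, order in frag_bonds:
            all_bonds.append((offset + i, offset + j, order))

    rw = Chem.RWMol()
    for el, _ in atoms:
        rw.AddAtom(Chem.Atom(el))
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
    for i, j, order in all_bonds:
        rw.AddBond(i, j, order_map[order])
    rdmol = rw.GetMol()
    conf = Chem.Conformer(rdmol.GetNumAtoms())
    for i, (_, p) in enumerate(atoms):
        conf.SetAtomPosition(i, Point3D(*p.tolist()))
    conf.Set3D(True)
    rdmol.AddConformer(conf)
    Chem.SanitizeMol(rdmol)
    rdmol = AllChem.AddHs(rdmol, addCoords=True)
    rdmol.SetProp("_Name", mol_id)
    return Molecule(id=mol_id, rd=rdmol)


# --------------------------------------------------------------------------
# series generation
# --------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _region_signal(mol: Molecule, regions: tuple[PlantedRegion, ...],
                   probe: ProbeSpec) -> float:
    total = 0.0
    for reg in regions:
        col = comsia_field(mol, reg.region_grid(), probe, reg.kind)
        total += reg.coefficient * float(col.mean())
    return total


def generate_series(
    spec: SeriesSpec, probe: ProbeSpec = DEFAULT_PROBE
) -> tuple[list[Molecule], pd.DataFrame, GroundTruth]:
    """Generate the series: molecules (scrambled frames), an activity table
    (id,value,scale with scale='pKi'), and the planted ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_molecules
    ids = [f"mol_{k:03d}" for k in range(n)]
    ideal_core = np.array([p for _, p in _scaffold_atoms()[0]])
    core_idx = tuple(range(len(ideal_core)))

    canonical: list[Molecule] = []
    subs_record: dict[str, dict[str, str]] = {}
    core_rmsd: dict[str, float] = {}
    for mid in ids:
        subs = {
            site: choices[rng.integers(len(choices))]
            for site, choices in spec.library.items()
        }
        jitter = rng.normal(0.0, spec.core_jitter_sd, size=(len(ideal_core), 3))
        mol = build_molecule(mid, subs, jitter=jitter)
        subs_record[mid] = subs
        jittered = mol.coords[list(core_idx)]
        if spec.core_jitter_sd > 0:
            _, rmsd = kabsch_superpose(ideal_core, jittered)
        else:
            rmsd = 0.0
        core_rmsd[mid] = rmsd
        canonical.append(mol)

    prepared = [prepare(m) for m in canonical]
    raw = np.array([_region_signal(m, spec.planted_regions, probe) for m in prepared])
    span = raw.max() - raw.min()
    if span <= 0:
        raise SyntheticError("planted regions produce no activity variation")
    scale = spec.activity_span / span
    noiseless = spec.base_pki + (raw - raw.min()) * scale
    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else np.zeros(n)
    observed = noiseless + noise

    template_id = ids[int(np.argmax(observed))]
    out_mols: list[Molecule] = []
    for mid, mol, act in zip(ids, canonical, observed):
        mol = mol.copy()
        mol.activity = float(act)
        if mid != template_id:
            R = _random_rotation(rng)
            t = rng.uniform(-5.0, 5.0, size=3)
            mol = mol.transformed(R, t)
            mol.activity = float(act)
        out_mols.append(mol)

    activities = pd.DataFrame(
        {"id": ids, "value": np.round(observed, 6), "scale": "pKi"}
    )
    truth = GroundTruth(
        noiseless_activity={m: float(v) for m, v in zip(ids, noiseless)},
        substituents=subs_record,
        planted=[
            {
                "center": list(r.center),
                "kind": r.kind,
                "coefficient_raw": r.coefficient,
                "coefficient_effective": r.coefficient * scale,
                "half_extent": r.half_extent,
            }
            for r in spec.planted_regions
        ],
        intercept=spec.base_pki,
        activity_scale=float(scale),
        template_id=template_id,
        core_rmsd=core_rmsd,
        core_atom_indices=core_idx,
    )
    return out_mols, activities, truth


def split_set(
    table: pd.DataFrame, n_test: int, seed: int
) -> tuple[list[str], list[str]]:
    """Activity-stratified train/test split.

    Molecules are binned into activity quintiles; the test set draws
    proportionally (largest-remainder rounding) from each, and the global
    minimum and maximum activities are forced into the training set so the
    test range lies inside the training range.  With fewer than 5 test
    molecules stratification is meaningless and a simple random draw is used
    (with a warning).
    """
    col = "value" if "value" in table.columns else "pKi"
    ids = table["id"].astype(str).to_numpy()
    y = table[col].to_numpy(dtype=float)
    n = len(ids)
    if not 0 < n_test < n:
        raise SyntheticError(f"n_test must be in (0, {n})")
    rng = np.random.default_rng(seed)

    order = np.argsort(y, kind="stable")
    if n_test < 5:
        warnings.warn("n_test < 5: falling back to a simple random split")
        protected = {order[0], order[-1]}
        candidates = np.array([i for i in range(n) if i not in protected])
        test_idx = set(rng.choice(candidates, size=n_test, replace=False).tolist())
    else:
        strata = np.array_split(order, 5)
        counts = _proportional_counts([len(s) for s in strata], n_test)
        test_idx = set()
        lo, hi = order[0], order[-1]
        for stratum, c in zip(strata, counts):
            pool = np.array([i for i in stratum if i not in (lo, hi)])
            c = min(c, len(pool))
            if c > 0:
                test_idx.update(rng.choice(pool, size=c, replace=False).tolist())
        # top up (protected extremes may have shrunk a stratum's pool)
        while len(test_idx) < n_test:
            pool = [i for i in range(n) if i not in test_idx and i not in (lo, hi)]
            test_idx.add(int(rng.choice(pool)))
    train = [ids[i] for i in range(n) if i not in test_idx]
    test = [ids[i] for i in range(n) if i in test_idx]
    return train, test


def _proportional_counts(sizes: list[int], total: int) -> list[int]:
    n = sum(sizes)
    quotas = [total * s / n for s in sizes]
    counts = [int(math.floor(q)) for q in quotas]
    remainders = [(q - c, k) for k, (q, c) in enumerate(zip(quotas, counts))]
    for _, k in sorted(remainders, key=lambda t: (-t[0], t[1]))[: total - sum(counts)]:
        counts[k] += 1
    return counts


def write_series(
    spec: SeriesSpec, outdir: str | Path, probe: ProbeSpec = DEFAULT_PROBE
) -> dict[str, Path]:
    """Emit SDF + activity CSV + ground-truth JSON into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mols, activities, truth = generate_series(spec, probe)
    paths = {
        "sdf": outdir / "ligands.sdf",
        "activities": outdir / "activities.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_ligands(mols, paths["sdf"])
    activities.to_csv(paths["activities"], index=False)
    paths["ground_truth"].write_text(truth.to_json() + "\n")
    return paths
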