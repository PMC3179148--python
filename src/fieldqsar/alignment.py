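"""Rigid common-substructure alignment of a congeneric series.

Every ligand is superposed onto a chosen template by least-squares (Kabsch)
fitting of the atoms matched by a shared core — either the maximum common
substructure of the series or a user-supplied SMARTS pattern.  Fitting is
rigid-body only; substituent torsions are left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFMCS

from .chem_io import Molecule


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise AlignmentError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise AlignmentError("rotation columns not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise AlignmentError("rotation determinant != +1 (improper transform)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class SubstructureMap:
    """A core pattern and, per molecule id, its candidate atom matches."""

    smarts: str
    matches: dict[str, tuple[tuple[int, ...], ...]]  # id -> candidate index tuples

    @property
    def n_core_atoms(self) -> int:
        return len(next(iter(self.matches.values()))[0])


def _candidate_matches(rdmol: Chem.Mol, query: Chem.Mol) -> tuple[tuple[int, ...], ...]:
    matches = rdmol.GetSubstructMatches(query, uniquify=False, maxMatches=256)
    # deterministic order: sort by the index tuple itself
    return tuple(sorted(set(matches)))


def find_common_substructure(
    mols: list[Molecule], core_smarts: str | None = None, timeout: int = 30
) -> SubstructureMap:
    """Find the shared heavy-atom core of the series (or verify a given SMARTS).

    The MCS search is connected and ring-bond-constrained.  A core of fewer
    than 3 atoms (or one absent from any molecule) raises
    :class:`AlignmentError` listing the offending ids.
    """
    if len(mols) < 2 and core_smarts is None:
        raise AlignmentError("need at least 2 molecules to search for a common core")
    if core_smarts is None:
        heavy = [Chem.RemoveHs(m.rd) for m in mols]
        res = rdFMCS.FindMCS(
            heavy,
            ringMatchesRingOnly=True,
            completeRingsOnly=False,
            bondCompare=rdFMCS.BondCompare.CompareOrder,
            timeout=timeout,
        )
        if res.canceled:
            raise AlignmentError("MCS search timed out")
        core_smarts = res.smartsString
    query = Chem.MolFromSmarts(core_smarts)
    if query is None:
        raise AlignmentError(f"invalid core SMARTS {core_smarts!r}")
    if query.GetNumAtoms() < 3:
        raise AlignmentError(
            f"common substructure has only {query.GetNumAtoms()} atoms (need >= 3)"
        )
    matches: dict[str, tuple[tuple[int, ...], ...]] = {}
    missing = []
    for m in mols:
        cand = _candidate_matches(m.rd, query)
        if not cand:
            missing.append(m.id)
        else:
            matches[m.id] = cand
    if missing:
        raise AlignmentError(f"core does not match molecules: {missing}")
    return SubstructureMap(smarts=core_smarts, matches=matches)


def kabsch_superpose(
    ref_coords: np.ndarray, mov_coords: np.ndarray
) -> tuple[RigidTransform, float]:
    """Optimal proper rigid superposition of ``mov`` onto ``ref`` (Kabsch, SVD).

    Returns the transform and the minimal RMSD.  Reflections are never
    returned; collinear (rotationally degenerate) point sets raise.
    """
    P = np.asarray(ref_coords, dtype=float)
    Q = np.asarray(mov_coords, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise AlignmentError("coordinate arrays must both be (n, 3)")
    if len(P) < 3:
        raise AlignmentError("need at least 3 points for superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    s = np.linalg.svd(Q0, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise AlignmentError("points are collinear; rotation is underdetermined")
    H = Q0.T @ P0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    diff = Q0 @ R.T - P0
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return RigidTransform(rotation=R, translation=t), rmsd


def align_set(
    mols: list[Molecule],
    template_id: str,
    smap: SubstructureMap | None = None,
    core_smarts: str | None = None,
) -> tuple[list[Molecule], pd.DataFrame]:
    """Superpose every molecule's core onto the template's core.

    When a molecule has several candidate core matches (symmetric cores), the
    correspondence with the lowest post-superposition RMSD is used; ties fall
    back to the lexicographically smallest index tuple.  The template is
    returned unchanged.  Returns the aligned molecules (input order) and a
    per-molecule core-RMSD report.
    """
    ids = [m.id for m in mols]
    if template_id not in ids:
        raise AlignmentError(f"template {template_id!r} not in the set")
    if smap is None:
        smap = find_common_substructure(mols, core_smarts=core_smarts)
    missing = [i for i in ids if i not in smap.matches]
    if missing:
        raise AlignmentError(f"no core match for molecules: {missing}")

    template = next(m for m in mols if m.id == template_id)
    tmatch = smap.matches[template_id][0]
    ref = template.coords[list(tmatch)]
    if len(tmatch) >= 3:
        s = np.linalg.svd(ref - ref.mean(axis=0), compute_uv=False)
        if s[1] < 1e-8 * max(s[0], 1.0):
            raise AlignmentError("template core atoms are collinear")

    aligned: list[Molecule] = []
    rows = []
    for m in mols:
        if m.id == template_id:
            aligned.append(m.copy())
            rows.append((m.id, 0.0))
            continue
        best: tuple[float, tuple[int, ...], RigidTransform] | None = None
        for cand in smap.matches[m.id]:
            tf, rmsd = kabsch_superpose(ref, m.coords[list(cand)])
            if best is None or rmsd < best[0] - 1e-12:
                best = (rmsd, cand, tf)
        assert best is not None
        rmsd, _, tf = best
        aligned.append(m.transformed(tf.rotation, tf.translation))
        rows.append((m.id, rmsd))
    report = pd.DataFrame(rows, columns=["id", "core_rmsd"])
    return aligned, report
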